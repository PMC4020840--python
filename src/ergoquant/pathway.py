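"""Strain × metabolite analytics: presence/absence calls, blocked-step
inference, Se-compound identity verification and colony viability.

The biosynthetic chain is modelled as it operates in fission yeast: the
bifunctional Egt1 enzyme takes histidine through hercynine to
hercynylcysteine sulfoxide (step 1), and the PLP-dependent desulfurase Egt2
cleaves the sulfoxide to ergothioneine (step 2).  Under selenium the same
enzymes run a parallel branch through hercynylselenocysteine (no sulfoxide
intermediate) to selenoneine.  A knockout therefore shows a characteristic
fingerprint in the strain × metabolite matrix: products of the blocked step
vanish or drop, while the step's substrate may pile up — e.g. an egt2
deletion accumulates hercynylcysteine sulfoxide ~26-fold over wild type
while retaining a reduced EGT level from slow non-enzymatic conversion.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .chem import IsotopePattern, isotope_pattern, pattern_match_score
from .quant import extract_xic, integrate_peak
from .synthetic import (
    DELETION_PANEL_AREAS,
    EGT,
    HCS,
    HERCYNINE,
    HISTIDINE,
    HSEC,
    LCMSRun,
    MetaboliteSpec,
    SELENONEINE,
)

__all__ = [
    "PathwayStep",
    "PathwayDefinition",
    "PathwayCall",
    "default_pathway",
    "deletion_panel_matrix",
    "call_status",
    "infer_block",
    "residual_fraction",
    "verify_identity",
    "viability_percent",
    "call_matrix",
]

ABSENT = "absent"
REDUCED = "reduced"
NORMAL = "normal"
ACCUMULATED = "accumulated"


@dataclass(frozen=True)
class PathwayStep:
    substrate: str
    products: Tuple[str, ...]  # intermediate(s) then final product
    gene: str


@dataclass(frozen=True)
class PathwayDefinition:
    """An ordered enzymatic chain plus an optional parallel branch."""

    steps: Tuple[PathwayStep, ...]
    branch: Tuple[PathwayStep, ...] = ()

    def chain_metabolites(self, steps: Optional[Sequence[PathwayStep]] = None) -> List[str]:
        steps = self.steps if steps is None else steps
        seen: List[str] = []
        for st in steps:
            for name in (st.substrate, *st.products):
                if name not in seen:
                    seen.append(name)
        return seen


def default_pathway() -> PathwayDefinition:
    """The two-step EGT chain with the selenoneine branch."""
    return PathwayDefinition(
        steps=(
            PathwayStep(HISTIDINE, (HERCYNINE, HCS), "egt1"),
            PathwayStep(HCS, (EGT,), "egt2"),
        ),
        branch=(
            PathwayStep(HERCYNINE, (HSEC,), "egt1"),
            PathwayStep(HSEC, (SELENONEINE,), "egt2"),
        ),
    )


def deletion_panel_matrix() -> pd.DataFrame:
    """The published normalized-peak-area matrix for the deletion panel
    (WT, Δegt1, Δegt2 × EMM2/EMM2-N/EMM2-LG), as a (strain, condition) ×
    metabolite DataFrame — the worked example for the pathway caller."""
    df = pd.DataFrame.from_dict(DELETION_PANEL_AREAS, orient="index")
    df.index = pd.MultiIndex.from_tuples(df.index, names=["strain", "condition"])
    return df


# ---------------------------------------------------------------------------
# Status calling
# ---------------------------------------------------------------------------

def call_status(
    values: Mapping[str, float],
    wt_values: Mapping[str, float],
    absent_frac: float = 0.05,
    accum_fold: float = 5.0,
    eps: float = 1e-12,
) -> Dict[str, str]:
    """Classify each metabolite of a mutant row against the matched WT row.

    ratio = mutant/WT:  ≤ absent_frac → absent;  (absent_frac, 0.5] →
    reduced;  ≥ accum_fold → accumulated;  otherwise normal.  When WT ≈ 0
    a mutant value ≈ 0 is normal and any real signal is accumulated.
    """
    if not (0.0 < absent_frac < 1.0):
        raise ValueError("absent_frac must lie in (0, 1)")
    if accum_fold <= 1.0:
        raise ValueError("accum_fold must be > 1")
    statuses: Dict[str, str] = {}
    for name, v in values.items():
        if name not in wt_values:
            raise KeyError(f"WT row lacks metabolite {name!r}")
        wt = wt_values[name]
        if v < 0 or wt < 0:
            raise ValueError("normalized areas must be non-negative")
        if wt <= eps:
            statuses[name] = NORMAL if v <= eps else ACCUMULATED
            continue
        ratio = v / wt
        if ratio <= absent_frac:
            statuses[name] = ABSENT
        elif ratio >= accum_fold:
            statuses[name] = ACCUMULATED
        elif ratio <= 0.5:
            statuses[name] = REDUCED
        else:
            statuses[name] = NORMAL
    return statuses


@dataclass
class PathwayCall:
    strain: str
    condition: str
    blocked_step: Optional[int]  # 1-based step index in the main chain
    blocked_gene: Optional[str]
    branch_blocked_step: Optional[int]
    statuses: Dict[str, str]
    ratios: Dict[str, float]
    inconsistent: bool = False
    candidates: Tuple[int, ...] = ()

    def to_dict(self) -> Dict:
        return {
            "strain": self.strain,
            "condition": self.condition,
            "blocked_step": self.blocked_step,
            "blocked_gene": self.blocked_gene,
            "branch_blocked_step": self.branch_blocked_step,
            "statuses": self.statuses,
            "ratios": self.ratios,
            "inconsistent": self.inconsistent,
            "candidates": list(self.candidates),
        }


def _blocked_steps(
    steps: Sequence[PathwayStep], statuses: Mapping[str, str]
) -> List[int]:
    blocked = []
    for i, st in enumerate(steps, start=1):
        sub = statuses[st.substrate]
        prods = [statuses[p] for p in st.products]
        if sub in (NORMAL, ACCUMULATED) and any(p in (ABSENT, REDUCED) for p in prods):
            blocked.append(i)
    return blocked


def _chain_consistent(chain: Sequence[str], statuses: Mapping[str, str]) -> bool:
    """Once a chain metabolite is absent, everything downstream must be
    absent or reduced — a normal/accumulated product past a gap is
    contradictory."""
    gap = False
    for name in chain:
        st = statuses[name]
        if gap and st in (NORMAL, ACCUMULATED):
            return False
        if st == ABSENT:
            gap = True
    return True


def infer_block(
    pathway: PathwayDefinition,
    statuses: Mapping[str, str],
    strain: str = "",
    condition: str = "",
    ratios: Optional[Mapping[str, float]] = None,
) -> PathwayCall:
    """Infer which enzymatic step a mutant blocks from its status map.

    The blocked step is the earliest step whose product is absent or
    reduced while its substrate is normal or accumulated; all candidate
    steps are reported.  Contradictory chains (a downstream metabolite
    normal while an upstream one is absent) yield no call and an
    ``inconsistent`` flag.
    """
    for name in pathway.chain_metabolites():
        if name not in statuses:
            raise KeyError(f"statuses missing pathway metabolite {name!r}")

    chain = pathway.chain_metabolites()
    if not _chain_consistent(chain, statuses):
        return PathwayCall(strain, condition, None, None, None,
                           dict(statuses), dict(ratios or {}), inconsistent=True)

    candidates = _blocked_steps(pathway.steps, statuses)
    blocked = candidates[0] if candidates else None
    gene = pathway.steps[blocked - 1].gene if blocked else None

    branch_blocked = None
    if pathway.branch and all(
        name in statuses for name in pathway.chain_metabolites(pathway.branch)
    ):
        branch_candidates = _blocked_steps(pathway.branch, statuses)
        branch_blocked = branch_candidates[0] if branch_candidates else None

    return PathwayCall(
        strain, condition, blocked, gene, branch_blocked,
        dict(statuses), dict(ratios or {}), candidates=tuple(candidates),
    )


def residual_fraction(mutant_value: float, wt_value: float) -> float:
    """Mutant/WT ratio of a normalized area (e.g. the EGT remaining in an
    egt2 deletion).  WT = 0 is undefined and returns NaN with a warning."""
    if wt_value < 0 or mutant_value < 0:
        raise ValueError("normalized areas must be non-negative")
    if wt_value == 0:
        warnings.warn("residual fraction undefined for WT value 0", stacklevel=2)
        return math.nan
    return mutant_value / wt_value


def call_matrix(
    matrix: pd.DataFrame,
    pathway: Optional[PathwayDefinition] = None,
    wt_strain: str = "WT",
    absent_frac: float = 0.05,
    accum_fold: float = 5.0,
) -> List[PathwayCall]:
    """Run status calling and block inference for every non-WT row of a
    (strain, condition)-indexed matrix, against the same-condition WT row.
    Conditions are never pooled; each row yields its own call."""
    pathway = pathway or default_pathway()
    calls = []
    for (strain, condition), row in matrix.iterrows():
        if strain == wt_strain:
            continue
        try:
            wt_row = matrix.loc[(wt_strain, condition)]
        except KeyError as exc:
            raise KeyError(
                f"no WT row for condition {condition!r} (strain {wt_strain!r})"
            ) from exc
        values = row.dropna().to_dict()
        wt_values = wt_row.dropna().to_dict()
        statuses = call_status(values, wt_values, absent_frac, accum_fold)
        ratios = {
            k: (values[k] / wt_values[k]) if wt_values[k] > 0 else math.inf
            for k in values
            if k in wt_values and (values[k] > 0 or wt_values[k] > 0)
        }
        calls.append(infer_block(pathway, statuses, strain, condition, ratios))
    return calls


# ---------------------------------------------------------------------------
# Isotope-pattern identity verification
# ---------------------------------------------------------------------------

def verify_identity(
    run: LCMSRun,
    spec: MetaboliteSpec,
    mz_tol: float = 0.01,
    min_score: float = 0.95,
    tol_ppm: float = 5.0,
    rt_window: float = 0.5,
    min_snr: float = 3.0,
    theoretical: Optional[IsotopePattern] = None,
    align_base: bool = False,
) -> Tuple[bool, float]:
    """Verify a detected peak's elemental composition by its isotope
    envelope (the check that distinguishes selenoneine's six-isotope Se
    signature from the two-peak S envelope of ergothioneine).

    The observed envelope is read from the centroids of the peak's apex
    scan within the theoretical pattern's m/z span and scored against the
    theoretical envelope (by default, the one of ``spec`` itself; pass
    ``theoretical`` with ``align_base=True`` to test a peak against the
    envelope of a different composition aligned on the base peak).
    """
    xic = extract_xic(run, spec.mz, tol_ppm)
    peak = integrate_peak(xic, spec.rt, rt_window, min_snr)
    if not peak.detected:
        raise ValueError(f"{spec.name}: peak not detected — nothing to verify")

    if theoretical is None:
        theoretical = isotope_pattern(spec.ion, charge=spec.adduct.charge, prune=1e-5)

    apex_idx = min(range(len(run.scans)), key=lambda i: abs(run.scans[i].rt - peak.apex_rt))
    scan = run.scans[apex_idx]
    # window the observed envelope by mapping the theoretical span, taken
    # relative to its base peak, onto the detected (base) peak m/z — the Se
    # envelope extends several Da *below* its Se-80 base peak
    theo_base = theoretical.base_peak[0]
    span_lo = spec.mz - (theo_base - theoretical.mz[0]) - 0.2
    span_hi = spec.mz + (theoretical.mz[-1] - theo_base) + 0.2
    mask = (scan.mz >= span_lo) & (scan.mz <= span_hi)
    total = scan.intensity[mask].sum()
    if total <= 0:
        return False, 0.0
    observed = IsotopePattern(
        [(m, x / total) for m, x in zip(scan.mz[mask], scan.intensity[mask])],
        charge=spec.adduct.charge,
    )
    score = pattern_match_score(observed, theoretical, mz_tol, align_base=align_base)
    return score >= min_score, score


def viability_percent(colonies_t: int, colonies_t0: int) -> float:
    """Colony-forming viability relative to the first time point, percent.
    Values above 100 are possible from counting noise and are reported
    as-is."""
    if colonies_t0 <= 0:
        raise ValueError("colonies at the first time point must be > 0")
    if colonies_t < 0:
        raise ValueError("colony counts must be non-negative")
    return 100.0 * colonies_t / colonies_t0
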
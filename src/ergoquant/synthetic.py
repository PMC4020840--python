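"""Seeded generator of centroided LC-MS runs for the ergothioneine pathway.

Emulates HILIC–Orbitrap-style MS1 centroid data for *S. pombe* metabolome
samples: Gaussian chromatographic elution of each pathway metabolite at its
known retention time, full theoretical isotope envelopes (so selenium
compounds carry their diagnostic multi-isotope signature), spiked HEPES and
PIPES internal standards, relative m/z jitter, random noise centroids, and a
small multiplicative response variability per compound and run.  Every run
is paired with a ground-truth record (true amounts and areas) so the whole
quantification pipeline can be validated end to end.

Strain/condition scenarios mirror the biology of the pathway:

* ``deletion_panel`` — WT, Δegt1 and Δegt2 under vegetative growth (EMM2),
  nitrogen starvation (EMM2-N) and glucose starvation (EMM2-LG).  Δegt1
  lacks every pathway intermediate; Δegt2 accumulates hercynylcysteine
  sulfoxide and retains a reduced EGT level.
* ``overexpression_panel`` — the three thiamine-repressible nmt1 promoter
  strengths driving egt1+ (P81 < P41 < P3), with and without thiamine.
* ``selenium_panel`` — selenate-supplemented media; the Se branch
  (hercynylselenocysteine → selenoneine) appears only in egt1+-competent
  strains, and EGT supplementation of Δegt1 yields no selenoneine.
* ``timecourse`` — 0–20 days of starvation with monotone EGT accumulation.
"""

from __future__ import annotations

import base64
import json
import struct
import zlib
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .chem import (
    Adduct,
    ChemicalFormula,
    IsotopePattern,
    PROTONATED,
    adduct_mz,
    ion_composition,
    isotope_pattern,
    parse_formula,
)

__all__ = [
    "HEPES",
    "PIPES",
    "RESPONSE_FACTOR",
    "SAMPLE_IS_SPIKE_MOL",
    "CALIBRATION_IS_SPIKE_MOL",
    "METABOLITE_FORMULAS",
    "DELETION_PANEL_AREAS",
    "MetaboliteSpec",
    "StrainProfile",
    "SampleMeta",
    "Scan",
    "LCMSRun",
    "GeneratorConfig",
    "default_pathway_panel",
    "internal_standard_specs",
    "scenario_profiles",
    "generate_run",
    "generate_calibration_series",
    "write_run_csv",
    "write_run_mzml",
    "write_manifest",
    "write_truth_json",
]

# ---------------------------------------------------------------------------
# Panel definitions
# ---------------------------------------------------------------------------

HISTIDINE = "histidine"
HERCYNINE = "hercynine"
HCS = "hercynylcysteine sulfoxide"
EGT = "ergothioneine"
HC = "hercynylcysteine"
SELENONEINE = "selenoneine"
HSEC = "hercynylselenocysteine"
HSEC_OX = "hercynylselenocysteine sulfoxide"
HEPES = "HEPES"
PIPES = "PIPES"

METABOLITE_FORMULAS: Dict[str, str] = {
    HISTIDINE: "C6H9N3O2",
    HERCYNINE: "C9H15N3O2",
    HCS: "C12H20N4O5S",
    EGT: "C9H15N3O2S",
    HC: "C12H20N4O4S",
    SELENONEINE: "C9H15N3O2Se",
    HSEC: "C12H20N4O4Se",
    HSEC_OX: "C12H20N4O5Se",
    HEPES: "C8H18N2O4S",
    PIPES: "C8H18N2O6S2",
}

#: nominal detector response, XIC area units per mol of analyte
RESPONSE_FACTOR = 4.4e9

#: internal-standard spike per metabolome sample (10 nmol each of HEPES/PIPES)
SAMPLE_IS_SPIKE_MOL = 1e-8
#: internal-standard spike per calibration injection (250 pmol each)
CALIBRATION_IS_SPIKE_MOL = 2.5e-10

#: cells per sample and cell volume (µm³) by cultivation condition:
#: vegetative cultures are 40 ml at 3.3e6 cells/ml with 148.5 µm³ cells;
#: starved cultures are 40 ml at 1e7 cells/ml with volumes shrunk to 1/3
#: (nitrogen starvation) or 2/3 (glucose starvation) of vegetative.
CONDITION_CELLS: Dict[str, Tuple[float, float]] = {
    "EMM2": (1.32e8, 148.5),
    "EMM2+thiamine": (1.32e8, 148.5),
    "EMM2+Se": (1.32e8, 148.5),
    "EMM2-N": (4.0e8, 148.5 / 3.0),
    "EMM2-N+Se": (4.0e8, 148.5 / 3.0),
    "EMM2-LG": (4.0e8, 148.5 * 2.0 / 3.0),
}


@dataclass(frozen=True)
class MetaboliteSpec:
    """A targeted compound: neutral formula, adduct, retention behaviour and
    detector response."""

    name: str
    neutral_formula: ChemicalFormula
    adduct: Adduct = PROTONATED
    rt: float = 12.0  # minutes
    rt_sigma: float = 0.08  # minutes
    response_factor: float = RESPONSE_FACTOR  # area units per mol

    def __post_init__(self) -> None:
        if not (0.0 <= self.rt <= 30.0):
            raise ValueError(f"{self.name}: rt {self.rt} outside the 0-30 min gradient")
        if self.rt_sigma <= 0:
            raise ValueError(f"{self.name}: rt_sigma must be > 0")
        if self.response_factor <= 0:
            raise ValueError(f"{self.name}: response_factor must be > 0")

    @property
    def mz(self) -> float:
        return adduct_mz(self.neutral_formula, self.adduct)

    @property
    def ion(self) -> ChemicalFormula:
        return ion_composition(self.neutral_formula, self.adduct)


def _spec(name: str, rt: float) -> MetaboliteSpec:
    return MetaboliteSpec(name, parse_formula(METABOLITE_FORMULAS[name]), PROTONATED, rt)


def default_pathway_panel() -> List[MetaboliteSpec]:
    """The full targeted panel: the four S-branch pathway compounds at their
    published retention times, the Se-branch analogs, hercynylcysteine, and
    the two spiked internal standards.

    Retention times of the Se analogs are set equal to their S counterparts
    (the scaffolds co-elute on HILIC); the internal standards elute late in
    the gradient, clear of all analytes.
    """
    return [
        _spec(HISTIDINE, 12.4),
        _spec(HERCYNINE, 10.3),
        _spec(HCS, 12.2),
        _spec(EGT, 12.6),
        _spec(HC, 12.3),
        _spec(SELENONEINE, 12.6),
        _spec(HSEC, 12.3),
        _spec(HSEC_OX, 12.2),
        _spec(HEPES, 14.0),
        _spec(PIPES, 15.2),
    ]


def internal_standard_specs() -> List[MetaboliteSpec]:
    return [s for s in default_pathway_panel() if s.name in (HEPES, PIPES)]


# ---------------------------------------------------------------------------
# Strain profiles
# ---------------------------------------------------------------------------

#: published normalized peak areas for the deletion panel (strain ×
#: condition × the four S-branch pathway compounds), used both as the worked
#: example for the pathway caller and to anchor the generator's ground-truth
#: amounts (amount = area / RESPONSE_FACTOR).
DELETION_PANEL_AREAS: Dict[Tuple[str, str], Dict[str, float]] = {
    ("WT", "EMM2"): {HISTIDINE: 14.4, HERCYNINE: 1.7, HCS: 0.0, EGT: 0.1},
    ("WT", "EMM2-N"): {HISTIDINE: 2.2, HERCYNINE: 3.2, HCS: 2.2, EGT: 13.7},
    ("WT", "EMM2-LG"): {HISTIDINE: 55.4, HERCYNINE: 65.9, HCS: 3.5, EGT: 6.7},
    ("del_egt1", "EMM2"): {HISTIDINE: 10.7, HERCYNINE: 0.3, HCS: 0.0, EGT: 0.0},
    ("del_egt1", "EMM2-N"): {HISTIDINE: 2.8, HERCYNINE: 0.1, HCS: 0.0, EGT: 0.0},
    ("del_egt1", "EMM2-LG"): {HISTIDINE: 54.1, HERCYNINE: 0.0, HCS: 0.0, EGT: 0.0},
    ("del_egt2", "EMM2"): {HISTIDINE: 11.4, HERCYNINE: 0.9, HCS: 3.9, EGT: 0.0},
    ("del_egt2", "EMM2-N"): {HISTIDINE: 1.9, HERCYNINE: 1.8, HCS: 58.2, EGT: 3.1},
    ("del_egt2", "EMM2-LG"): {HISTIDINE: 61.1, HERCYNINE: 64.7, HCS: 44.1, EGT: 1.6},
}

#: measured intracellular EGT concentrations (µM) under vegetative growth
#: used to set overexpression-tier amounts (P81 < P41 < P3)
OVEREXPRESSION_EGT_UM: Dict[str, float] = {
    "WT": 0.3,
    "P81nmt1-egt1": 32.4,
    "P41nmt1-egt1": 181.2,
    "P3nmt1-egt1": 1606.3,
}


@dataclass
class StrainProfile:
    """Ground-truth metabolite content of one cultivated sample."""

    strain: str
    condition: str
    truth_amounts: Dict[str, float]  # metabolite -> mol per sample
    n_cells: float
    cell_volume_um3: float

    def __post_init__(self) -> None:
        for name, amt in self.truth_amounts.items():
            if amt < 0:
                raise ValueError(f"negative amount for {name}")

    @property
    def run_id(self) -> str:
        return f"{self.strain}__{self.condition}".replace(" ", "_").replace("+", "p")


def _profile(strain: str, condition: str, areas: Mapping[str, float]) -> StrainProfile:
    n_cells, vol = CONDITION_CELLS[condition]
    amounts = {name: area / RESPONSE_FACTOR for name, area in areas.items()}
    return StrainProfile(strain, condition, amounts, n_cells, vol)


def _conc_to_mol(conc_um: float, condition: str) -> float:
    """Convert an intracellular concentration (µM) into mol per sample for
    the given cultivation condition."""
    n_cells, vol = CONDITION_CELLS[condition]
    return conc_um * 1e-6 * n_cells * vol * 1e-15


def scenario_profiles(scenario: str) -> List[StrainProfile]:
    """Ground-truth strain profiles for one of the four study scenarios."""
    if scenario == "deletion_panel":
        return [
            _profile(strain, cond, areas)
            for (strain, cond), areas in DELETION_PANEL_AREAS.items()
        ]

    if scenario == "overexpression_panel":
        profiles = []
        his = DELETION_PANEL_AREAS[("WT", "EMM2")][HISTIDINE] / RESPONSE_FACTOR
        for strain, conc in OVEREXPRESSION_EGT_UM.items():
            egt = _conc_to_mol(conc, "EMM2")
            # overexpressed Egt1 outruns native Egt2, so the intermediate
            # accumulates in proportion to promoter strength
            hcs = 0.5 * egt if strain == "P3nmt1-egt1" else 0.15 * egt
            herc = 0.1 * egt
            n_cells, vol = CONDITION_CELLS["EMM2"]
            profiles.append(
                StrainProfile(
                    strain,
                    "EMM2",
                    {HISTIDINE: his, HERCYNINE: herc, HCS: hcs if strain != "WT" else 0.0, EGT: egt},
                    n_cells,
                    vol,
                )
            )
            if strain != "WT":
                # thiamine represses the nmt1 promoter back to WT levels
                egt_thi = _conc_to_mol(OVEREXPRESSION_EGT_UM["WT"], "EMM2+thiamine")
                n_cells, vol = CONDITION_CELLS["EMM2+thiamine"]
                profiles.append(
                    StrainProfile(
                        strain,
                        "EMM2+thiamine",
                        {HISTIDINE: his, HERCYNINE: 0.1 * egt_thi, HCS: 0.0, EGT: egt_thi},
                        n_cells,
                        vol,
                    )
                )
        return profiles

    if scenario == "selenium_panel":
        rf = RESPONSE_FACTOR
        rows: List[Tuple[str, str, Dict[str, float]]] = [
            ("WT", "EMM2+Se",
             {HISTIDINE: 14.4 / rf, HERCYNINE: 1.7 / rf, EGT: 0.1 / rf}),
            # nitrogen-starved WT: selenoneine is a trace signal, <1 % of EGT
            ("WT", "EMM2-N+Se",
             {HISTIDINE: 2.2 / rf, HERCYNINE: 3.2 / rf, HCS: 2.2 / rf,
              EGT: 13.7 / rf, SELENONEINE: 0.008 * 13.7 / rf}),
            ("del_egt1", "EMM2-N+Se",
             {HISTIDINE: 2.8 / rf}),
            # EGT-supplemented Δegt1: strong EGT peak, still no selenoneine
            ("del_egt1+EGT", "EMM2+Se",
             {HISTIDINE: 10.7 / rf, EGT: 100.0 / rf}),
            ("P3nmt1-egt1", "EMM2+Se",
             {HISTIDINE: 14.0 / rf, HERCYNINE: 10.0 / rf, HCS: 60.0 / rf,
              EGT: 138.0 / rf, SELENONEINE: 12.0 / rf, HSEC: 5.0 / rf}),
            # blocking egt2 raises the Se-branch intermediate and lowers
            # selenoneine — and the intermediate is NOT a sulfoxide
            ("P3nmt1-egt1 del_egt2", "EMM2+Se",
             {HISTIDINE: 14.0 / rf, HERCYNINE: 10.0 / rf, HCS: 120.0 / rf,
              EGT: 20.0 / rf, SELENONEINE: 2.0 / rf, HSEC: 15.0 / rf}),
        ]
        out = []
        for strain, cond, amounts in rows:
            n_cells, vol = CONDITION_CELLS[cond]
            out.append(StrainProfile(strain, cond, amounts, n_cells, vol))
        return out

    if scenario == "timecourse":
        profiles = []
        params = {"EMM2-N": (13.7, 26.0), "EMM2-LG": (6.7, 14.0)}
        for cond, (base, amp) in params.items():
            n_cells, vol = CONDITION_CELLS[cond]
            for day in range(21):
                egt_area = base + amp * (1.0 - np.exp(-day / 5.0))
                amounts = {EGT: egt_area / RESPONSE_FACTOR}
                profiles.append(
                    StrainProfile("WT", f"{cond} day{day:02d}", amounts, n_cells, vol)
                )
        return profiles

    raise ValueError(f"unknown scenario: {scenario!r}")


# ---------------------------------------------------------------------------
# Run generation
# ---------------------------------------------------------------------------

@dataclass
class SampleMeta:
    strain: str
    condition: str
    n_cells: float
    cell_volume_um3: float
    spiked_is: Dict[str, float]  # standard -> mol


@dataclass
class Scan:
    rt: float  # minutes
    mz: np.ndarray
    intensity: np.ndarray


@dataclass
class LCMSRun:
    run_id: str
    scans: List[Scan]
    sample_meta: Optional[SampleMeta] = None

    def __post_init__(self) -> None:
        rts = [s.rt for s in self.scans]
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise ValueError("scan retention times must be strictly increasing")


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic instrument.

    ``ppm_jitter`` is the 1-sigma relative mass error; ``response_cv`` the
    per-compound, per-run multiplicative response variability (lognormal);
    ``run_scale_cv`` a shared per-run injection/extraction scale factor
    hitting every centroid alike (the variation internal-standard
    normalization exists to cancel); ``noise_peak_rate`` the Poisson mean
    of random noise centroids per scan, with exponential intensities of
    mean ``baseline_noise``.
    """

    seed: int = 0
    ppm_jitter: float = 2.0
    scan_interval: float = 0.05  # minutes
    rt_start: float = 0.0
    rt_end: float = 30.0
    baseline_noise: float = 1.0
    noise_peak_rate: float = 20.0
    response_cv: float = 0.02
    run_scale_cv: float = 0.10
    envelope_prune: float = 1e-4
    mz_range: Tuple[float, float] = (100.0, 600.0)


@lru_cache(maxsize=128)
def _cached_pattern(formula_str: str, charge: int, prune: float) -> IsotopePattern:
    return isotope_pattern(parse_formula(formula_str), charge=charge, prune=prune)


def _run_rng(cfg: GeneratorConfig, run_id: str) -> np.random.Generator:
    # stable per-run stream: master seed plus a CRC of the run identity
    return np.random.default_rng([cfg.seed, zlib.crc32(run_id.encode())])


def generate_run(
    profile: StrainProfile,
    panel: Sequence[MetaboliteSpec],
    cfg: GeneratorConfig,
    is_spike_mol: float = SAMPLE_IS_SPIKE_MOL,
) -> Tuple[LCMSRun, Dict]:
    """Generate one centroided run plus its ground-truth record.

    Each metabolite with a positive amount elutes as a Gaussian whose total
    XIC area (summed over the whole isotope envelope) is amount ×
    response_factor × a lognormal response fluctuation; within every scan
    the envelope peak intensities follow the theoretical isotope pattern.
    Internal standards are emitted the same way from ``is_spike_mol``.
    """
    rng = _run_rng(cfg, profile.run_id)
    run_scale = rng.lognormal(0.0, cfg.run_scale_cv) if cfg.run_scale_cv > 0 else 1.0
    rts = np.arange(cfg.rt_start, cfg.rt_end + 1e-9, cfg.scan_interval)
    n_scans = len(rts)
    scan_mz: List[List[np.ndarray]] = [[] for _ in range(n_scans)]
    scan_int: List[List[np.ndarray]] = [[] for _ in range(n_scans)]

    spiked = {HEPES: is_spike_mol, PIPES: is_spike_mol}
    truth_amounts: Dict[str, float] = {}
    truth_areas: Dict[str, float] = {}

    for spec in panel:
        if spec.name in spiked:
            amount = spiked[spec.name]
        else:
            amount = profile.truth_amounts.get(spec.name, 0.0)
        truth_amounts[spec.name] = amount
        if amount <= 0.0:
            truth_areas[spec.name] = 0.0
            continue
        if cfg.response_cv > 0:
            amount_eff = amount * rng.lognormal(0.0, cfg.response_cv)
        else:
            amount_eff = amount
        # the run-level scale hits every compound (analytes and IS) alike
        area = amount_eff * spec.response_factor * run_scale
        truth_areas[spec.name] = area

        pattern = _cached_pattern(str(spec.ion), spec.adduct.charge, cfg.envelope_prune)
        pk_mz = np.array(pattern.mz)
        pk_ab = np.array(pattern.abundance)

        height = area / (spec.rt_sigma * np.sqrt(2.0 * np.pi))
        lo = np.searchsorted(rts, spec.rt - 4.0 * spec.rt_sigma)
        hi = np.searchsorted(rts, spec.rt + 4.0 * spec.rt_sigma, side="right")
        for i in range(lo, hi):
            total = height * np.exp(-0.5 * ((rts[i] - spec.rt) / spec.rt_sigma) ** 2)
            if total <= 0:
                continue
            intens = total * pk_ab
            if cfg.ppm_jitter > 0:
                mzs = pk_mz * (1.0 + rng.normal(0.0, cfg.ppm_jitter, pk_mz.size) * 1e-6)
            else:
                mzs = pk_mz.copy()
            scan_mz[i].append(mzs)
            scan_int[i].append(intens)

    # random noise centroids
    if cfg.noise_peak_rate > 0 and cfg.baseline_noise > 0:
        counts = rng.poisson(cfg.noise_peak_rate, n_scans)
        total_noise = int(counts.sum())
        noise_mz = rng.uniform(cfg.mz_range[0], cfg.mz_range[1], total_noise)
        noise_int = rng.exponential(cfg.baseline_noise, total_noise)
        pos = 0
        for i, c in enumerate(counts):
            if c:
                scan_mz[i].append(noise_mz[pos : pos + c])
                scan_int[i].append(noise_int[pos : pos + c])
                pos += c

    scans: List[Scan] = []
    for i in range(n_scans):
        if scan_mz[i]:
            mz = np.concatenate(scan_mz[i])
            inten = np.concatenate(scan_int[i])
            order = np.argsort(mz)
            scans.append(Scan(float(rts[i]), mz[order], inten[order]))
        else:
            scans.append(Scan(float(rts[i]), np.empty(0), np.empty(0)))

    meta = SampleMeta(
        profile.strain, profile.condition, profile.n_cells, profile.cell_volume_um3, spiked
    )
    truth = {
        "run_id": profile.run_id,
        "strain": profile.strain,
        "condition": profile.condition,
        "amount_mol": truth_amounts,
        "area": truth_areas,
        "is_spike_mol": is_spike_mol,
    }
    return LCMSRun(profile.run_id, scans, meta), truth


def generate_calibration_series(
    amounts: Optional[Sequence[float]] = None,
    cfg: GeneratorConfig = GeneratorConfig(),
    panel: Optional[Sequence[MetaboliteSpec]] = None,
) -> List[Tuple[LCMSRun, Dict]]:
    """Pure-standard injection series for the EGT calibration curve.

    Defaults to eight 10-fold dilution steps from 1 fmol to 10 nmol, each
    run containing only the EGT ion plus 250 pmol spikes of each internal
    standard.
    """
    if amounts is None:
        amounts = [10.0 ** e for e in range(-15, -7)]  # 1 fmol .. 10 nmol
    if any(a <= 0 for a in amounts):
        raise ValueError("calibration amounts must be positive")
    panel = list(panel) if panel is not None else default_pathway_panel()
    egt_and_is = [s for s in panel if s.name in (EGT, HEPES, PIPES)]
    out = []
    for i, amount in enumerate(amounts):
        profile = StrainProfile(
            strain=f"cal_{i:02d}",
            condition="standard",
            truth_amounts={EGT: float(amount)},
            n_cells=1.0,
            cell_volume_um3=1.0,
        )
        out.append(
            generate_run(profile, egt_and_is, cfg, is_spike_mol=CALIBRATION_IS_SPIKE_MOL)
        )
    return out


# ---------------------------------------------------------------------------
# File output: CSV dialect, minimal mzML, manifest, ground truth
# ---------------------------------------------------------------------------

def write_run_csv(run: LCMSRun, path) -> None:
    """Write the centroid-list CSV dialect: ``scan_rt_min,mz,intensity``.

    Every scan is represented; scans without centroids contribute no rows
    but are recovered on reading from the monotone rt grid of nonempty
    scans (empty scans carry no signal and do not affect XIC areas).
    """
    with open(path, "w") as fh:
        fh.write("scan_rt_min,mz,intensity\n")
        for scan in run.scans:
            for m, x in zip(scan.mz, scan.intensity):
                fh.write(f"{scan.rt:.4f},{m:.6f},{x:.6g}\n")


def _b64(values: np.ndarray) -> str:
    return base64.b64encode(
        struct.pack("<%dd" % len(values), *map(float, values))
    ).decode()


def write_run_mzml(run: LCMSRun, path) -> None:
    """Write a minimal centroided MS1 mzML document (uncompressed 64-bit
    float arrays with standard PSI-MS cvParams)."""
    parts = [
        '<?xml version="1.0" encoding="utf-8"?>',
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">',
        '<cvList count="2">'
        '<cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" '
        'URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>'
        '<cv id="UO" fullName="Unit Ontology" '
        'URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>'
        "</cvList>",
        f'<run id="{run.run_id}">',
        f'<spectrumList count="{len(run.scans)}">',
    ]
    for idx, scan in enumerate(run.scans):
        n = len(scan.mz)
        mz_b64 = _b64(scan.mz)
        int_b64 = _b64(scan.intensity)
        parts.append(
            f'<spectrum index="{idx}" id="scan={idx + 1}" defaultArrayLength="{n}">'
            '<cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>'
            '<cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>'
            '<scanList count="1"><scan>'
            f'<cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{scan.rt:.4f}" '
            'unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>'
            "</scan></scanList>"
            '<binaryDataArrayList count="2">'
            f'<binaryDataArray encodedLength="{len(mz_b64)}">'
            '<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>'
            '<cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>'
            '<cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" '
            'unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>'
            f"<binary>{mz_b64}</binary></binaryDataArray>"
            f'<binaryDataArray encodedLength="{len(int_b64)}">'
            '<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>'
            '<cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>'
            '<cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" '
            'unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>'
            f"<binary>{int_b64}</binary></binaryDataArray>"
            "</binaryDataArrayList></spectrum>"
        )
    parts += ["</spectrumList>", "</run>", "</mzML>"]
    Path(path).write_text("\n".join(parts))


def write_manifest(runs: Sequence[LCMSRun], path) -> None:
    """Sample manifest CSV:
    run_id,strain,condition,n_cells,cell_volume_um3,IS_hepes_mol,IS_pipes_mol
    """
    with open(path, "w") as fh:
        fh.write(
            "run_id,strain,condition,n_cells,cell_volume_um3,IS_hepes_mol,IS_pipes_mol\n"
        )
        for run in runs:
            m = run.sample_meta
            fh.write(
                f"{run.run_id},{m.strain},{m.condition},{m.n_cells:.6g},"
                f"{m.cell_volume_um3:.6g},{m.spiked_is[HEPES]:.6g},{m.spiked_is[PIPES]:.6g}\n"
            )


def write_truth_json(truths: Sequence[Dict], path) -> None:
    Path(path).write_text(json.dumps({t["run_id"]: t for t in truths}, indent=1))
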
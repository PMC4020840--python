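"""Chemical-formula arithmetic for targeted small-molecule mass spectrometry.

Provides formula parsing (Hill notation), monoisotopic masses, adduct m/z
with electron correction, isotope-envelope simulation by per-element
multinomial expansion and cross-element convolution, and a cosine similarity
score between envelopes used to verify elemental composition (in particular
to distinguish the sulfur and selenium forms of the same scaffold, whose
envelopes differ through selenium's six natural isotopes).

Conventions
-----------
* The *monoisotopic* mass of an element is the mass of its most abundant
  natural isotope.  For C, H, N, O and S this coincides with the lightest
  isotope; for Se it is Se-80.
* Cation m/z subtracts one electron mass per positive charge (and adds it
  per negative charge), so that e.g. the protonated ergothioneine cation
  comes out at 230.096 rather than 230.096 + m_e.
* Isotope envelopes are reported at "unit" resolution: isotopologues closer
  than ``merge_window`` (default 0.01 Da) are merged into one centroid at
  their abundance-weighted mean m/z.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from itertools import product as _iter_product
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

__all__ = [
    "ELECTRON_MASS",
    "ELEMENT_ISOTOPES",
    "ChemicalFormula",
    "Adduct",
    "IsotopePattern",
    "FormulaError",
    "parse_formula",
    "parse_adduct",
    "monoisotopic_mass",
    "adduct_mz",
    "isotope_pattern",
    "pattern_match_score",
]

# CODATA electron mass, Da
ELECTRON_MASS = 0.000548579909

# IUPAC 2021 isotope masses (Da) and natural abundances (mole fraction).
# Only the elements occurring in the pathway metabolites and the internal
# standards (plus Na for sodium adducts) are tabulated.
ELEMENT_ISOTOPES: Dict[str, Tuple[Tuple[float, float], ...]] = {
    "H": ((1.00782503207, 0.999885), (2.01410177785, 0.000115)),
    "C": ((12.0, 0.9893), (13.00335483507, 0.0107)),
    "N": ((14.00307400443, 0.99636), (15.00010889888, 0.00364)),
    "O": (
        (15.99491461957, 0.99757),
        (16.99913175650, 0.00038),
        (17.99915961286, 0.00205),
    ),
    "S": (
        (31.9720711744, 0.9499),
        (32.9714589098, 0.0075),
        (33.967867004, 0.0425),
        (35.96708071, 0.0001),
    ),
    "Se": (
        (73.922475934, 0.0089),
        (75.919213704, 0.0937),
        (76.919914154, 0.0763),
        (77.91730928, 0.2377),
        (79.9165218, 0.4961),
        (81.9166995, 0.0873),
    ),
    "Na": ((22.989769282, 1.0),),
    "P": ((30.97376199842, 1.0),),
}

#: monoisotopic (most-abundant-isotope) mass per element
MONOISOTOPIC_MASS: Dict[str, float] = {
    el: max(isos, key=lambda p: p[1])[0] for el, isos in ELEMENT_ISOTOPES.items()
}


class FormulaError(ValueError):
    """Raised for malformed formula or adduct strings."""


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ChemicalFormula:
    """Elemental composition of a neutral molecule or an ion.

    ``counts`` maps element symbol to a strictly positive atom count;
    elements with count zero are simply absent.
    """

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        cleaned = {}
        for el, n in self.counts.items():
            if el not in ELEMENT_ISOTOPES:
                raise FormulaError(f"unknown element symbol: {el!r}")
            if n < 0:
                raise FormulaError(f"negative count for element {el}: {n}")
            if n > 0:
                cleaned[el] = int(n)
        object.__setattr__(self, "counts", cleaned)

    # -- arithmetic ---------------------------------------------------
    def __add__(self, other: "ChemicalFormula") -> "ChemicalFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return ChemicalFormula(merged)

    def __sub__(self, other: "ChemicalFormula") -> "ChemicalFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            left = merged.get(el, 0) - n
            if left < 0:
                raise FormulaError(
                    f"cannot remove {n} × {el} from {self}: only {merged.get(el, 0)} present"
                )
            merged[el] = left
        return ChemicalFormula(merged)

    def total_atoms(self) -> int:
        return sum(self.counts.values())

    # -- canonical form -----------------------------------------------
    def __str__(self) -> str:
        """Hill order: C first, then H, then the rest alphabetically."""
        parts: List[str] = []
        symbols = sorted(self.counts)
        if "C" in self.counts:
            order = ["C"] + (["H"] if "H" in self.counts else [])
            order += [s for s in symbols if s not in ("C", "H")]
        else:
            order = symbols
        for el in order:
            n = self.counts[el]
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)

    @property
    def monoisotopic_mass(self) -> float:
        return monoisotopic_mass(self)


def parse_formula(text: str) -> ChemicalFormula:
    """Parse a Hill-notation formula string such as ``"C12H21N4O4S"``.

    Raises :class:`FormulaError` naming the offending symbol for unknown
    elements and for explicit zero counts.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: Dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _FORMULA_TOKEN.match(text, pos)
        if not m or not m.group(1):
            raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
        el, digits = m.group(1), m.group(2)
        if el not in ELEMENT_ISOTOPES:
            raise FormulaError(f"unknown element symbol: {el!r}")
        n = int(digits) if digits else 1
        if n <= 0:
            raise FormulaError(f"non-positive count for element {el} in {text!r}")
        counts[el] = counts.get(el, 0) + n
        pos = m.end()
    return ChemicalFormula(counts)


def monoisotopic_mass(f: ChemicalFormula | Mapping[str, int]) -> float:
    """Sum of count × most-abundant-isotope mass over the composition."""
    counts = f.counts if isinstance(f, ChemicalFormula) else f
    total = 0.0
    for el, n in counts.items():
        if el not in MONOISOTOPIC_MASS:
            raise FormulaError(f"element {el!r} missing from the isotope table")
        total += n * MONOISOTOPIC_MASS[el]
    return total


# ---------------------------------------------------------------------------
# Adducts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Adduct:
    """Ion adduct: atoms added to (or removed from) the neutral molecule
    plus a signed charge.  ``delta`` uses signed counts so that e.g. the
    deprotonated anion is ``{"H": -1}`` with charge −1.
    """

    name: str
    delta: Mapping[str, int]
    charge: int

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise FormulaError("adduct charge must be nonzero")
        for el in self.delta:
            if el not in ELEMENT_ISOTOPES:
                raise FormulaError(f"unknown element symbol in adduct: {el!r}")


PROTONATED = Adduct("[M+H]+", {"H": 1}, +1)
SODIATED = Adduct("[M+Na]+", {"Na": 1}, +1)
DEPROTONATED = Adduct("[M-H]-", {"H": -1}, -1)

_ADDUCT_RE = re.compile(
    r"\[M(?P<sign>[+\-−])(?P<mult>\d*)(?P<species>[A-Za-z0-9]+)\](?P<z>\d*)(?P<zsign>[+\-−])"
)


def parse_adduct(text: str) -> Adduct:
    """Parse adduct strings like ``"[M+H]+"``, ``"[M+Na]+"``, ``"[M-H]-"``.

    The ASCII hyphen and the Unicode minus sign are both accepted.
    """
    m = _ADDUCT_RE.fullmatch(text.strip())
    if not m:
        raise FormulaError(f"cannot parse adduct string {text!r}")
    mult = int(m.group("mult") or 1)
    species = parse_formula(m.group("species"))
    sign = 1 if m.group("sign") == "+" else -1
    delta = {el: sign * mult * n for el, n in species.counts.items()}
    z = int(m.group("z") or 1)
    charge = z if m.group("zsign") == "+" else -z
    return Adduct(text.strip(), delta, charge)


def ion_composition(f: ChemicalFormula, a: Adduct) -> ChemicalFormula:
    """Atomic composition of the ion formed by applying ``a`` to ``f``."""
    counts = dict(f.counts)
    for el, n in a.delta.items():
        new = counts.get(el, 0) + n
        if new < 0:
            raise FormulaError(
                f"adduct {a.name} removes {el} atoms not present in {f}"
            )
        counts[el] = new
    return ChemicalFormula(counts)


def adduct_mz(f: ChemicalFormula, a: Adduct, decimals: int | None = None) -> float:
    """Electron-corrected m/z of the adduct ion of neutral formula ``f``.

    m/z = (M + Δ − z·m_e) / |z|, with Δ the adduct mass and z the signed
    charge, so cations lose and anions gain one electron mass per charge.
    """
    ion = ion_composition(f, a)
    mz = (monoisotopic_mass(ion) - a.charge * ELECTRON_MASS) / abs(a.charge)
    return round(mz, decimals) if decimals is not None else mz


# ---------------------------------------------------------------------------
# Isotope envelopes
# ---------------------------------------------------------------------------

@dataclass
class IsotopePattern:
    """Centroided isotope envelope: (m/z, relative abundance) peaks sorted by
    ascending m/z, abundances normalized to sum to 1.
    """

    peaks: List[Tuple[float, float]]
    charge: int = 1

    def __post_init__(self) -> None:
        self.peaks = sorted(((float(m), float(a)) for m, a in self.peaks))

    @property
    def mz(self) -> List[float]:
        return [m for m, _ in self.peaks]

    @property
    def abundance(self) -> List[float]:
        return [a for _, a in self.peaks]

    @property
    def base_peak(self) -> Tuple[float, float]:
        return max(self.peaks, key=lambda p: p[1])

    def as_base100(self) -> "IsotopePattern":
        """View with the base peak scaled to 100 % (not normalized to sum 1)."""
        base = self.base_peak[1]
        return IsotopePattern.__new__(IsotopePattern).__init_view__(
            [(m, 100.0 * a / base) for m, a in self.peaks], self.charge
        )

    def __init_view__(self, peaks, charge):
        self.peaks = peaks
        self.charge = charge
        return self

    def to_csv(self, path) -> None:
        """Write a two-column CSV (mz, relative_abundance_percent)."""
        base = self.base_peak[1]
        with open(path, "w") as fh:
            fh.write("mz,relative_abundance_percent\n")
            for m, a in self.peaks:
                fh.write(f"{m:.5f},{100.0 * a / base:.6g}\n")


def _compositions(n: int, k: int) -> Iterable[Tuple[int, ...]]:
    """All ways to put n identical atoms into k isotope slots."""
    if k == 1:
        yield (n,)
        return
    for first in range(n + 1):
        for rest in _compositions(n - first, k - 1):
            yield (first,) + rest


def _element_distribution(
    el: str, n: int, floor: float = 1e-15
) -> List[Tuple[float, float]]:
    """Exact multinomial isotope distribution of n atoms of one element."""
    isos = ELEMENT_ISOTOPES[el]
    out: List[Tuple[float, float]] = []
    log_fact_n = math.lgamma(n + 1)
    for comp in _compositions(n, len(isos)):
        log_p = log_fact_n
        mass = 0.0
        skip = False
        for c, (m, p) in zip(comp, isos):
            if c and p == 0.0:
                skip = True
                break
            log_p -= math.lgamma(c + 1)
            if c:
                log_p += c * math.log(p)
            mass += c * m
        if skip:
            continue
        p = math.exp(log_p)
        if p >= floor:
            out.append((mass, p))
    return out


def _merge_centroids(
    peaks: Sequence[Tuple[float, float]], window: float
) -> List[Tuple[float, float]]:
    """Single-linkage merge of centroids closer than ``window`` (in the peaks'
    own m/z units) into abundance-weighted means."""
    if not peaks:
        return []
    peaks = sorted(peaks)
    merged: List[Tuple[float, float]] = []
    cur_m, cur_a = peaks[0]
    last_m = cur_m
    for m, a in peaks[1:]:
        if m - last_m <= window:
            total = cur_a + a
            cur_m = (cur_m * cur_a + m * a) / total
            cur_a = total
        else:
            merged.append((cur_m, cur_a))
            cur_m, cur_a = m, a
        last_m = m
    merged.append((cur_m, cur_a))
    return merged


def isotope_pattern(
    f: ChemicalFormula,
    charge: int = 1,
    prune: float = 1e-5,
    merge_window: float = 0.01,
) -> IsotopePattern:
    """Theoretical isotope envelope of an ion of composition ``f``.

    The envelope is the convolution of per-element multinomial isotope
    distributions.  After converting isotopologue masses to m/z (with
    electron correction for ``charge``), peaks closer than ``merge_window``
    are merged and species below ``prune`` of the total are dropped;
    abundances are renormalized to sum to 1.

    ``f`` is interpreted as the atomic composition of the ion itself (e.g.
    C9H16N3O2S for protonated ergothioneine).
    """
    if charge == 0:
        raise FormulaError("charge must be nonzero")
    if not (0 <= prune <= 0.01):
        raise ValueError("prune must lie in [0, 0.01]")
    if merge_window < 0:
        raise ValueError("merge_window must be >= 0")

    dist: List[Tuple[float, float]] = [(0.0, 1.0)]
    for el, n in sorted(f.counts.items()):
        el_dist = _element_distribution(el, n)
        dist = [
            (m1 + m2, a1 * a2)
            for (m1, a1), (m2, a2) in _iter_product(dist, el_dist)
            if a1 * a2 >= 1e-15
        ]
        # collapse numerically identical species to keep the product small
        dist = _merge_centroids(dist, 1e-9)

    mz_peaks = [
        ((mass - charge * ELECTRON_MASS) / abs(charge), a) for mass, a in dist
    ]
    merged = _merge_centroids(mz_peaks, merge_window)
    total = sum(a for _, a in merged)
    kept = [(m, a) for m, a in merged if a >= prune * total]
    norm = sum(a for _, a in kept)
    if norm == 0:
        return IsotopePattern([], charge)
    return IsotopePattern([(m, a / norm) for m, a in kept], charge)


def pattern_match_score(
    observed: IsotopePattern,
    theoretical: IsotopePattern,
    mz_tol: float = 0.01,
    align_base: bool = False,
) -> float:
    """Cosine similarity between two envelopes after greedy peak pairing.

    Candidate pairs within ``mz_tol`` are matched greedily by ascending m/z
    distance; unmatched peaks on either side contribute zeros to the other
    vector, so missing or extra peaks lower the score.  The score is
    symmetric in its arguments and lies in [0, 1].

    With ``align_base=True`` the observed pattern is first shifted so its
    base peak coincides with the theoretical base peak — useful to compare
    the *shape* of envelopes of different scaffolds (e.g. the S form of a
    metabolite against the Se form's theoretical envelope).
    """
    if mz_tol <= 0:
        raise ValueError("mz_tol must be > 0")
    obs = observed.peaks
    theo = theoretical.peaks
    if not obs or not theo:
        return 0.0
    if align_base:
        shift = theoretical.base_peak[0] - observed.base_peak[0]
        obs = [(m + shift, a) for m, a in obs]

    candidates = [
        (abs(mo - mt), i, j)
        for i, (mo, _) in enumerate(obs)
        for j, (mt, _) in enumerate(theo)
        if abs(mo - mt) <= mz_tol
    ]
    candidates.sort()
    used_o: set = set()
    used_t: set = set()
    pairs: List[Tuple[int, int]] = []
    for _, i, j in candidates:
        if i not in used_o and j not in used_t:
            pairs.append((i, j))
            used_o.add(i)
            used_t.add(j)

    vo: List[float] = []
    vt: List[float] = []
    for i, j in pairs:
        vo.append(obs[i][1])
        vt.append(theo[j][1])
    for i, (_, a) in enumerate(obs):
        if i not in used_o:
            vo.append(a)
            vt.append(0.0)
    for j, (_, a) in enumerate(theo):
        if j not in used_t:
            vo.append(0.0)
            vt.append(a)

    dot = sum(x * y for x, y in zip(vo, vt))
    no = math.sqrt(sum(x * x for x in vo))
    nt = math.sqrt(sum(y * y for y in vt))
    if no == 0 or nt == 0:
        return 0.0
    return dot / (no * nt)
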
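"""Formula arithmetic, exact masses, isotope envelopes and envelope scoring."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ergoquant.chem import (
    ELECTRON_MASS,
    ELEMENT_ISOTOPES,
    Adduct,
    ChemicalFormula,
    FormulaError,
    IsotopePattern,
    PROTONATED,
    adduct_mz,
    ion_composition,
    isotope_pattern,
    monoisotopic_mass,
    parse_adduct,
    parse_formula,
    pattern_match_score,
)

# ---------------------------------------------------------------------------
# Parsing and canonical form
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "text,expected",
    [
        ("C12H21N4O4S", {"C": 12, "H": 21, "N": 4, "O": 4, "S": 1}),
        ("H", {"H": 1}),
        ("C9H15N3O2Se", {"C": 9, "H": 15, "N": 3, "O": 2, "Se": 1}),
        ("NaH", {"Na": 1, "H": 1}),
    ],
)
def test_parse_formula(text, expected):
    assert dict(parse_formula(text).counts) == expected


@pytest.mark.parametrize("bad", ["", "Xx3", "C0", "H-2", "c6h12", "C6 H12"])
def test_parse_formula_rejects_malformed(bad):
    with pytest.raises(FormulaError):
        parse_formula(bad)


def test_parse_error_names_unknown_symbol():
    with pytest.raises(FormulaError, match="Xq"):
        parse_formula("C2Xq3")


_element_counts = st.dictionaries(
    st.sampled_from(sorted(ELEMENT_ISOTOPES)),
    st.integers(min_value=1, max_value=40),
    min_size=1,
    max_size=5,
)


@settings(derandomize=True, max_examples=60)
@given(_element_counts)
def test_formula_string_round_trip(counts):
    f = ChemicalFormula(counts)
    assert dict(parse_formula(str(f)).counts) == dict(f.counts)


def test_hill_order():
    assert str(parse_formula("O2SeH15N3C9")) == "C9H15N3O2Se"
    assert str(parse_formula("O4S2H2")) == "H2O4S2"  # no carbon: alphabetical


# ---------------------------------------------------------------------------
# Monoisotopic mass and adduct m/z
# ---------------------------------------------------------------------------

def test_monoisotopic_mass_examples():
    assert monoisotopic_mass(parse_formula("H2O")) == pytest.approx(18.010565, abs=1e-6)
    assert monoisotopic_mass(ChemicalFormula({})) == 0.0
    assert monoisotopic_mass(parse_formula("C")) == 12.0


def test_monoisotopic_uses_most_abundant_selenium_isotope():
    # Se-80, not the lightest Se-74
    assert monoisotopic_mass(parse_formula("Se")) == pytest.approx(79.9165218, abs=1e-6)


@settings(derandomize=True, max_examples=40)
@given(_element_counts, _element_counts)
def test_mass_additivity(c1, c2):
    f1, f2 = ChemicalFormula(c1), ChemicalFormula(c2)
    assert monoisotopic_mass(f1 + f2) == pytest.approx(
        monoisotopic_mass(f1) + monoisotopic_mass(f2), abs=1e-9
    )


PRINTED_MZ = [
    ("C6H9N3O2", 156.077),    # histidine
    ("C9H15N3O2", 198.124),   # hercynine
    ("C12H20N4O5S", 333.123),  # hercynylcysteine sulfoxide
    ("C9H15N3O2S", 230.096),  # ergothioneine
    ("C12H20N4O4S", 317.128),  # hercynylcysteine
    ("C12H20N4O5Se", 381.067),  # hercynylselenocysteine sulfoxide
]


@pytest.mark.parametrize("formula,expected", PRINTED_MZ)
def test_protonated_mz_matches_published_values(formula, expected):
    """The six reported ion m/z values reproduce at 3 decimals with
    electron-corrected protonated cations."""
    assert adduct_mz(parse_formula(formula), PROTONATED, decimals=3) == expected


def test_selenoneine_mz_from_atomic_masses():
    # independent summation: hercynine cation plus Se-80 (S->Se swap on EGT)
    expected = (
        9 * 12.0 + 16 * 1.00782503207 + 3 * 14.00307400443
        + 2 * 15.99491461957 + 79.9165218 - ELECTRON_MASS
    )
    got = adduct_mz(parse_formula("C9H15N3O2Se"), PROTONATED)
    assert got == pytest.approx(expected, abs=1e-9)
    assert round(got, 3) == 278.040


def test_sulfur_to_selenium_shift_is_isotope_mass_difference():
    shift = 79.9165218 - 31.9720711744
    for formula, _ in PRINTED_MZ:
        if "S" not in parse_formula(formula).counts:
            continue
        se_formula = ChemicalFormula(
            {**{k: v for k, v in parse_formula(formula).counts.items() if k != "S"},
             "Se": 1}
        )
        delta = adduct_mz(se_formula, PROTONATED) - adduct_mz(parse_formula(formula), PROTONATED)
        assert delta == pytest.approx(shift, abs=1e-9)


def test_electron_correction_sign():
    f = parse_formula("C9H15N3O2S")
    plus = adduct_mz(f, PROTONATED)
    minus = adduct_mz(f, parse_adduct("[M-H]-"))
    neutral = monoisotopic_mass(f)
    h = monoisotopic_mass(parse_formula("H"))
    assert plus == pytest.approx(neutral + h - ELECTRON_MASS, abs=1e-12)
    assert minus == pytest.approx(neutral - h + ELECTRON_MASS, abs=1e-12)


def test_adduct_parsing_variants():
    assert parse_adduct("[M+Na]+").delta == {"Na": 1}
    assert parse_adduct("[M-H]-").charge == -1
    assert parse_adduct("[M−H]−").delta == {"H": -1}  # unicode minus
    with pytest.raises(FormulaError):
        parse_adduct("M+H")


def test_adduct_cannot_remove_absent_atoms():
    with pytest.raises(FormulaError):
        ion_composition(parse_formula("C2H6"), parse_adduct("[M-Na]-"))


def test_cross_check_against_pyteomics():
    """Independent oracle: pyteomics' NIST-based mass calculator."""
    mass = pytest.importorskip("pyteomics.mass")
    for formula, _ in PRINTED_MZ:
        ours = adduct_mz(parse_formula(formula), PROTONATED)
        theirs = mass.calculate_mass(formula=formula, ion_type="M", charge=1)
        assert ours == pytest.approx(theirs, abs=2e-5)


# ---------------------------------------------------------------------------
# Isotope envelopes
# ---------------------------------------------------------------------------

def _brute_force_pattern(counts, charge=1, merge_window=0.01):
    """Exhaustive enumeration over per-atom isotope assignments, merged with
    the same single-linkage semantics (independent of the convolution path).
    """
    atoms = []
    for el, n in counts.items():
        atoms.extend([ELEMENT_ISOTOPES[el]] * n)
    peaks = {}
    species = [(0.0, 1.0)]
    for isotopes in atoms:
        species = [
            (m + mi, p * pi)
            for m, p in species
            for mi, pi in isotopes
        ]
    for m, p in species:
        mz = (m - charge * ELECTRON_MASS) / abs(charge)
        peaks[mz] = peaks.get(mz, 0.0) + p
    items = sorted(peaks.items())
    merged = []
    for mz, p in items:
        if merged and mz - merged[-1][2] <= merge_window:
            m0, p0, _ = merged[-1]
            merged[-1] = ((m0 * p0 + mz * p) / (p0 + p), p0 + p, mz)
        else:
            merged.append((mz, p, mz))
    total = sum(p for _, p, _ in merged)
    return [(m, p / total) for m, p, _ in merged]


def _random_small_formulas(rng, n=50, max_atoms=20, max_states=200_000):
    out = []
    elements = ["C", "H", "N", "O", "S", "Se"]
    while len(out) < n:
        k = rng.integers(1, 4)
        chosen = rng.choice(elements, size=k, replace=False)
        counts = {}
        budget = max_atoms
        for el in chosen:
            c = int(rng.integers(1, budget + 1))
            counts[el] = c
            budget -= c
            if budget == 0:
                break
        states = math.prod(len(ELEMENT_ISOTOPES[el]) ** c for el, c in counts.items())
        if states <= max_states:
            out.append(counts)
    return out


def test_envelope_matches_exhaustive_enumeration():
    """Convolution envelope equals brute-force isotopologue enumeration to
    1e-9 abundance on random formulas of up to 20 atoms."""
    rng = np.random.default_rng(20140514)
    for counts in _random_small_formulas(rng):
        pat = isotope_pattern(ChemicalFormula(counts), charge=1, prune=0.0)
        for m, a in _brute_force_pattern(counts):
            if a < 1e-11:
                continue
            nearest_mz, nearest_ab = min(pat.peaks, key=lambda p: abs(p[0] - m))
            assert abs(nearest_mz - m) < 1e-6, (counts, m)
            assert nearest_ab == pytest.approx(a, abs=1e-9), counts


def test_single_carbon_pattern_is_isotope_ratio():
    pat = isotope_pattern(parse_formula("C"), charge=1)
    assert len(pat.peaks) == 2
    assert pat.abundance[0] == pytest.approx(0.9893, abs=1e-6)
    assert pat.abundance[1] == pytest.approx(0.0107, abs=1e-6)


def test_selenium_envelope_signature():
    """The selenoneine cation envelope spans ~6 Da with the base peak at the
    Se-80 species and major peaks for five other Se isotopes."""
    ion = ion_composition(parse_formula("C9H15N3O2Se"), PROTONATED)
    pat = isotope_pattern(ion, charge=1)
    base_mz, _ = pat.base_peak
    assert base_mz == pytest.approx(278.040, abs=2e-3)
    major = [m for m, a in pat.peaks if a > 0.005]
    assert max(major) - min(major) > 5.9
    se_offsets = {-4.0, -3.0, -2.0, 0.0, 2.0}  # Se-76/77/78/80/82 species
    offsets = {round(m - base_mz) for m in major}
    assert se_offsets.issubset({float(o) for o in offsets})


@pytest.mark.parametrize("prune,window", [(1e-5, 0.01), (0.0, 0.01), (1e-4, 0.05)])
def test_envelope_abundances_normalized(prune, window):
    pat = isotope_pattern(parse_formula("C12H21N4O5Se"), 1, prune, window)
    assert sum(pat.abundance) == pytest.approx(1.0, abs=1e-9)
    assert pat.mz == sorted(pat.mz)


def test_envelope_requires_charge():
    with pytest.raises(FormulaError):
        isotope_pattern(parse_formula("C2H6"), charge=0)


def test_pattern_base100_and_csv(tmp_path):
    pat = isotope_pattern(parse_formula("C9H16N3O2S"), charge=1)
    scaled = pat.as_base100()
    assert max(a for _, a in scaled.peaks) == pytest.approx(100.0)
    out = tmp_path / "pattern.csv"
    pat.to_csv(out)
    lines = out.read_text().splitlines()
    assert lines[0] == "mz,relative_abundance_percent"
    assert len(lines) == len(pat.peaks) + 1


# ---------------------------------------------------------------------------
# Envelope similarity
# ---------------------------------------------------------------------------

def test_score_identity_and_orthogonality():
    pat = isotope_pattern(parse_formula("C9H16N3O2S"), charge=1)
    assert pattern_match_score(pat, pat, 0.01) == pytest.approx(1.0, abs=1e-12)
    shifted = IsotopePattern([(m + 50.0, a) for m, a in pat.peaks], 1)
    assert pattern_match_score(shifted, pat, 0.01) == 0.0


def test_score_symmetry():
    a = isotope_pattern(parse_formula("C9H16N3O2S"), charge=1)
    b = isotope_pattern(parse_formula("C6H10N3O2"), charge=1)
    s1 = pattern_match_score(a, b, 0.01, align_base=True)
    s2 = pattern_match_score(b, a, 0.01, align_base=True)
    assert s1 == pytest.approx(s2, abs=1e-9)


def test_sulfur_vs_selenium_envelopes_are_distinguishable():
    """Aligned on the base peak, the S and Se forms of the same scaffold
    score ~0.87 — far below both the self-match (≥0.999) and the 0.95
    verification threshold, so the envelope check separates the elements."""
    s_pat = isotope_pattern(parse_formula("C9H16N3O2S"), charge=1)
    se_pat = isotope_pattern(parse_formula("C9H16N3O2Se"), charge=1)
    cross = pattern_match_score(s_pat, se_pat, 0.01, align_base=True)
    assert cross == pytest.approx(0.8697, abs=2e-3)
    assert cross < 0.95
    assert pattern_match_score(se_pat, se_pat, 0.01) > 0.999


def test_empty_observed_scores_zero():
    pat = isotope_pattern(parse_formula("C2H6"), charge=1)
    assert pattern_match_score(IsotopePattern([], 1), pat, 0.01) == 0.0
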
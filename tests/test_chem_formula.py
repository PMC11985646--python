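"""Mass engine: parsing dialects, masses, adducts, formula generation."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pyteomics import mass as pyteomics_mass

from phytoms.chem_formula import (
    ADDUCTS,
    DEFAULT_BOUNDS,
    FormulaError,
    MolecularFormula,
    PROTON_MASS,
    adduct_mz,
    generate_formulas,
    hill_order,
    monoisotopic_mass,
    nominal_mass,
    parse_formula,
    ppm_error,
)

ELEMENTS = ["C", "H", "N", "O", "S", "P", "Na"]

formula_maps = st.dictionaries(
    st.sampled_from(ELEMENTS), st.integers(min_value=1, max_value=99),
    min_size=1, max_size=5,
)


@pytest.mark.parametrize(
    "text, expected",
    [
        ("C16H32O2", {"C": 16, "H": 32, "O": 2}),
        ("C_16_H_32_O_2_", {"C": 16, "H": 32, "O": 2}),
        ("C₁₆H₃₂O₂", {"C": 16, "H": 32, "O": 2}),
        ("H2O", {"H": 2, "O": 1}),
        ("C6H14N4O2", {"C": 6, "H": 14, "N": 4, "O": 2}),
        ("CH4", {"C": 1, "H": 4}),
    ],
)
def test_parse_dialects(text, expected):
    assert dict(parse_formula(text).counts) == expected


@pytest.mark.parametrize(
    "bad", ["C16H32O2Xx", "", "  ", "H0", "C016H2", "16C", "c6h6"]
)
def test_parse_rejects_malformed(bad):
    with pytest.raises(FormulaError):
        parse_formula(bad)


@given(formula_maps)
@settings(deadline=None, max_examples=200)
def test_parse_format_round_trip(counts):
    f = MolecularFormula(counts)
    assert parse_formula(hill_order(f)) == f


def test_hill_order_c_first_then_alphabetical():
    assert hill_order(parse_formula("O2S1N3H10C5")) == "C5H10N3O2S"
    assert hill_order(parse_formula("H2O")) == "H2O"


@pytest.mark.parametrize(
    "text, expected",
    [("C16H32O2", 256), ("C30H50O2", 442), ("C15H10O7", 302), ("C29H48O", 412)],
)
def test_nominal_mass_matches_printed_mwt(text, expected):
    assert nominal_mass(parse_formula(text)) == expected


def test_nominal_and_monoisotopic_of_empty_formula():
    empty = MolecularFormula({})
    assert nominal_mass(empty) == 0
    assert monoisotopic_mass(empty) == 0.0


@pytest.mark.parametrize(
    "text, expected",
    [("C15H10O7", 302.04265), ("H", 1.00783), ("C21H20O12", 464.09548)],
)
def test_monoisotopic_mass_frozen_values(text, expected):
    assert monoisotopic_mass(parse_formula(text)) == pytest.approx(
        expected, abs=2e-5
    )


@given(formula_maps)
@settings(deadline=None, max_examples=100)
def test_monoisotopic_against_pyteomics(counts):
    """Independent oracle: pyteomics' NIST mass table."""
    f = MolecularFormula(counts)
    expected = sum(
        n * pyteomics_mass.nist_mass[el][0][0] for el, n in counts.items()
    )
    assert monoisotopic_mass(f) == pytest.approx(expected, abs=1e-6)


@given(formula_maps, formula_maps)
@settings(deadline=None, max_examples=100)
def test_mass_additivity(c1, c2):
    f1, f2 = MolecularFormula(c1), MolecularFormula(c2)
    assert monoisotopic_mass(f1 + f2) == pytest.approx(
        monoisotopic_mass(f1) + monoisotopic_mass(f2), abs=1e-9
    )
    assert nominal_mass(f1 + f2) == nominal_mass(f1) + nominal_mass(f2)


def test_adduct_mz_deprotonated_quercetin():
    q = parse_formula("C15H10O7")
    assert adduct_mz(q, "[M-H]-") == pytest.approx(301.03537, abs=2e-5)


@given(formula_maps)
@settings(deadline=None, max_examples=50)
def test_adduct_symmetry(counts):
    f = MolecularFormula(counts)
    gap = adduct_mz(f, "[M+H]+") - adduct_mz(f, "[M-H]-")
    assert gap == pytest.approx(2 * PROTON_MASS, abs=1e-9)
    assert gap == pytest.approx(2.014552, abs=1e-5)


def test_adduct_mass_shift_antisymmetric():
    assert ADDUCTS["[M+H]+"].mass_shift == -ADDUCTS["[M-H]-"].mass_shift


def test_unsupported_adduct_rejected():
    with pytest.raises(ValueError):
        adduct_mz(parse_formula("C15H10O7"), "[M+2H]2+")


def test_ppm_error_examples():
    assert ppm_error(463.0918, 463.0918) == 0.0
    t = 523.4
    assert ppm_error(t * (1 + 1e-5), t) == pytest.approx(10.0, rel=1e-9)
    # The printed deprotonated quercetin mass is far outside its stated
    # error — the engine reports what the arithmetic says.
    assert ppm_error(301.0233, 301.03537) == pytest.approx(-40.1, abs=0.2)
    with pytest.raises(ValueError):
        ppm_error(300.0, 0.0)


@given(
    formula_maps,
    st.floats(min_value=0.5, max_value=50.0),
    st.sampled_from(["[M-H]-", "[M+H]+"]),
)
@settings(deadline=None, max_examples=100)
def test_ppm_round_trip(counts, e, adduct):
    amz = adduct_mz(MolecularFormula(counts), adduct)
    assert ppm_error(amz * (1 + e * 1e-6), amz) == pytest.approx(e, rel=1e-6)


def _brute_force_formulas(mz, adduct, tol_ppm, bounds):
    """Independent enumerator over the full bounded lattice (pyteomics masses)."""
    shift = ADDUCTS[adduct].mass_shift
    elements = sorted(bounds)
    out = set()
    for combo in itertools.product(*(range(bounds[e] + 1) for e in elements)):
        theo = sum(
            n * pyteomics_mass.nist_mass[e][0][0]
            for e, n in zip(elements, combo)
        ) + shift
        if theo > 0 and abs((mz - theo) / theo * 1e6) <= tol_ppm:
            counts = {e: n for e, n in zip(elements, combo) if n}
            if counts:
                out.add(hill_order(MolecularFormula(counts)))
    return out


@pytest.mark.parametrize(
    "mz, adduct, tol, bounds",
    [
        (301.03537, "[M-H]-", 20.0, {"C": 20, "H": 30, "N": 3, "O": 10}),
        (256.240, "[M+H]+", 15.0, {"C": 18, "H": 36, "N": 2, "O": 4}),
        (447.093, "[M-H]-", 10.0, {"C": 25, "H": 30, "N": 2, "O": 12, "S": 1}),
    ],
)
def test_generate_formulas_matches_brute_force(mz, adduct, tol, bounds):
    ours = {hill_order(f) for f in generate_formulas(mz, adduct, tol, bounds)}
    assert ours == _brute_force_formulas(mz, adduct, tol, bounds)


def test_generate_formulas_contains_quercetin_and_sorts_by_ppm():
    hits = generate_formulas(
        301.03537, "[M-H]-", 20.0, {"C": 20, "H": 30, "N": 3, "O": 10}
    )
    names = [hill_order(f) for f in hits]
    assert "C15H10O7" in names
    errs = [abs(ppm_error(301.03537, adduct_mz(f, "[M-H]-"))) for f in hits]
    assert errs == sorted(errs)
    assert names[0] == "C15H10O7"


def test_generate_formulas_zero_tolerance_limit():
    q = parse_formula("C15H10O7")
    target = adduct_mz(q, "[M-H]-")
    hits = generate_formulas(target, "[M-H]-", 0.0, {"C": 20, "H": 15, "O": 10})
    assert hits == [q]


def test_generate_formulas_input_validation():
    with pytest.raises(ValueError):
        generate_formulas(-5.0, "[M-H]-", 20.0, DEFAULT_BOUNDS)
    with pytest.raises(ValueError):
        generate_formulas(301.0, "[M-H]-", 20.0, {})


def test_formula_subtraction_guards_negative_counts():
    with pytest.raises(FormulaError):
        parse_formula("CH4") - parse_formula("O")
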
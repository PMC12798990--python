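"""Exact-mass arithmetic, formula enumeration and isotope patterns."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ligandfish.chem import (
    A1_MASS_OFFSET,
    InvalidFormulaError,
    MassTolerance,
    MolecularFormula,
    enumerate_formulas,
    isotope_pattern,
    monoisotopic_mass,
    mz_from_neutral,
    neutral_from_mz,
    ppm_error,
    rdbe,
)

formulas = st.builds(
    MolecularFormula,
    st.integers(1, 60),
    st.integers(0, 120),
    st.integers(0, 40),
)


class TestMonoisotopicMass:
    @pytest.mark.parametrize(
        "formula, expected, atol",
        [
            ("C19H18O7", 358.1052, 358.1052 * 5e-6),  # flavone anchor, 5 ppm
            ("C28H34O15", 610.1898, 0.0005),  # hand-summed IUPAC masses
            ("CH4", 16.0313, 0.0005),
            ("H2O", 18.010565, 1e-5),
        ],
    )
    def test_reference_masses(self, formula, expected, atol):
        f = MolecularFormula.from_string(formula)
        assert monoisotopic_mass(f) == pytest.approx(expected, abs=atol)

    def test_empty_formula_is_massless(self):
        assert monoisotopic_mass(MolecularFormula(0, 0, 0)) == 0.0

    def test_negative_count_rejected(self):
        with pytest.raises(InvalidFormulaError):
            MolecularFormula(-1, 4, 0)

    @given(formulas, formulas)
    def test_additive_in_composition(self, f1, f2):
        total = monoisotopic_mass(f1 + f2)
        assert total == pytest.approx(
            monoisotopic_mass(f1) + monoisotopic_mass(f2), abs=1e-9
        )

    @given(formulas)
    def test_hill_notation_round_trip(self, f):
        assert MolecularFormula.from_string(str(f)) == f

    def test_unsupported_element_rejected(self):
        with pytest.raises(InvalidFormulaError):
            MolecularFormula.from_string("C6H5N")


class TestAdductConversion:
    def test_proton_adduct_shift(self):
        assert mz_from_neutral(358.1052) == pytest.approx(359.1125, abs=0.0005)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            mz_from_neutral(0.0)

    def test_unsupported_adduct_lists_supported(self):
        with pytest.raises(ValueError, match=r"\[M\+H\]\+"):
            mz_from_neutral(100.0, adduct="[M+Na]+")

    @given(st.floats(1.0, 2000.0))
    def test_round_trip_identity(self, mass):
        assert neutral_from_mz(mz_from_neutral(mass)) == pytest.approx(
            mass, abs=1e-9
        )


class TestRdbe:
    @pytest.mark.parametrize(
        "formula, expected",
        [("C19H18O7", 11.0), ("CH4", 0.0), ("H2O", 0.0), ("C6H6", 4.0)],
    )
    def test_known_values(self, formula, expected):
        assert rdbe(MolecularFormula.from_string(formula)) == expected


def brute_force_enumeration(query, ppm, rdbe_bounds=(0.0, 40.0)):
    """Exhaustive oracle: vectorized sweep of all CHO compositions up to
    the C90 H190 O90 extraction ceiling."""
    c = np.arange(1, 91)
    h = np.arange(0, 191)
    o = np.arange(0, 91)
    C, H, O = np.meshgrid(c, h, o, indexing="ij", sparse=True)
    mass = C * 12.0 + H * 1.00782503207 + O * 15.99491461956
    rd = C - H / 2.0 + 1.0
    hit = (np.abs(mass - query) <= query * ppm * 1e-6) & (
        (rd >= rdbe_bounds[0]) & (rd <= rdbe_bounds[1])
    )
    idx = np.argwhere(hit)
    return {(int(i + 1), int(j), int(k)) for i, j, k in idx}


class TestEnumeration:
    def test_flavone_mass_yields_its_formula(self):
        cands = enumerate_formulas(358.1052)
        assert MolecularFormula(19, 18, 7) in [c.formula for c in cands]

    def test_methane_unique_in_window(self):
        cands = enumerate_formulas(16.0313)
        assert [c.formula for c in cands] == [MolecularFormula(1, 4, 0)]

    def test_matches_exhaustive_oracle(self):
        got = {
            (c.formula.n_C, c.formula.n_H, c.formula.n_O)
            for c in enumerate_formulas(610.1894)
        }
        assert got == brute_force_enumeration(610.1894, 5.0)

    def test_sorted_by_abs_ppm_then_lexicographic(self):
        cands = enumerate_formulas(610.1894, MassTolerance(20.0))
        keys = [(abs(c.ppm_error), (c.formula.n_C, c.formula.n_H, c.formula.n_O))
                for c in cands]
        assert keys == sorted(keys)

    def test_nonpositive_tolerance_rejected(self):
        with pytest.raises(ValueError):
            MassTolerance(0.0)

    def test_min_above_max_rejected(self):
        with pytest.raises(ValueError):
            enumerate_formulas(
                300.0,
                min_counts=MolecularFormula(10, 0, 0),
                max_counts=MolecularFormula(5, 190, 90),
            )


class TestIsotopePattern:
    def test_first_satellite_tracks_carbon_count(self):
        pattern = isotope_pattern(MolecularFormula(19, 18, 7), 2)
        ratio = pattern[1][1] / pattern[0][1]
        assert ratio == pytest.approx(19 * 0.0107, rel=0.05)

    def test_single_carbon(self):
        pattern = isotope_pattern(MolecularFormula(1, 0, 0), 2)
        assert pattern[1][1] == pytest.approx(0.0107, rel=0.02)

    @given(formulas)
    def test_masses_and_abundances_well_formed(self, f):
        pattern = isotope_pattern(f, 3)
        mono = monoisotopic_mass(f)
        assert pattern[0][1] == 1.0
        for k, (mass, rel) in enumerate(pattern):
            assert rel >= 0.0
            assert mass == pytest.approx(mono + k * A1_MASS_OFFSET, abs=1e-3)

    def test_empty_formula_rejected(self):
        with pytest.raises(InvalidFormulaError):
            isotope_pattern(MolecularFormula(0, 0, 0))


def test_ppm_error_sign_convention():
    assert ppm_error(100.0005, 100.0) == pytest.approx(5.0)
    assert ppm_error(99.9995, 100.0) == pytest.approx(-5.0)
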
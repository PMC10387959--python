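import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from quenchbind import cocrystal_phys as cp


class TestFormula:
    def test_parse_counts(self):
        f = cp.Formula.from_string("C15H10O5")
        assert f.element_counts == {"C": 15, "H": 10, "O": 5}

    def test_repeated_symbols_accumulate(self):
        f = cp.Formula.from_string("CH3COOH")
        assert f.element_counts == {"C": 2, "H": 4, "O": 2}

    @pytest.mark.parametrize("text", ["Xx2O", "c15", "C15H10O5!", ""])
    def test_malformed_formulas_rejected(self, text):
        with pytest.raises(ValueError):
            cp.Formula.from_string(text)

    def test_molar_mass_uses_standard_weights(self):
        assert cp.Formula.from_string("C").molar_mass == pytest.approx(12.011)
        assert cp.Formula.from_string("H2O").molar_mass == pytest.approx(18.015)


class TestMassFractions:
    def test_apigenin_carbon(self):
        frac = cp.mass_fractions(cp.Formula.from_string("C15H10O5"))
        assert round(frac["C"], 2) == 66.67

    def test_cocrystal_nitrogen_and_hydrogen(self):
        frac = cp.mass_fractions(cp.Formula.from_string("C21H16N2O6"))
        assert round(frac["N"], 2) == 7.14
        assert round(frac["H"], 2) == 4.11

    def test_single_element_is_all_of_it(self):
        assert cp.mass_fractions(cp.Formula.from_string("C"))["C"] == 100.0

    @pytest.mark.parametrize(
        "formula", ["C15H10O5", "C6H6N2O", "C21H16N2O6", "NaCl", "Fe2O3"]
    )
    def test_fractions_sum_to_hundred(self, formula):
        total = sum(cp.mass_fractions(cp.Formula.from_string(formula)).values())
        assert total == pytest.approx(100.0, abs=0.01)

    @given(k=st.integers(min_value=2, max_value=9))
    @settings(max_examples=8, derandomize=True)
    def test_scaling_the_formula_leaves_fractions_unchanged(self, k):
        base = cp.Formula.from_string("C21H16N2O6")
        scaled = cp.Formula({s: k * n for s, n in base.element_counts.items()})
        for sym, val in cp.mass_fractions(base).items():
            assert cp.mass_fractions(scaled)[sym] == pytest.approx(val, rel=1e-12)


class TestCompositionCheck:
    def test_combustion_values_pass_at_five_percent(self):
        report = cp.composition_check(
            cp.Formula.from_string("C15H10O5"), {"C": 64.68}, tolerance=5.0
        )
        assert report.relative_errors["C"] == pytest.approx(2.98, abs=0.01)
        assert report.overall_pass

    def test_exact_measurement_has_zero_error(self):
        f = cp.Formula.from_string("C21H16N2O6")
        theo = cp.mass_fractions(f)
        report = cp.composition_check(f, {"N": theo["N"]})
        assert report.relative_errors["N"] == 0.0
        assert report.overall_pass

    def test_large_deviation_names_the_element(self):
        f = cp.Formula.from_string("C15H10O5")
        theo = cp.mass_fractions(f)
        report = cp.composition_check(f, {"C": theo["C"] * 1.10, "H": theo["H"]})
        assert not report.overall_pass
        assert report.failing_elements == ("C",)

    def test_element_absent_from_formula_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            cp.composition_check(cp.Formula.from_string("C15H10O5"), {"N": 5.0})


class TestCumulativeRelease:
    def test_single_draw_needs_no_correction(self):
        series = cp.DissolutionSeries((30.0,), (0.25,), 5.0, 100.0)
        assert cp.cumulative_release(series).q_percent == (25.0,)

    def test_worked_three_draw_example(self):
        series = cp.DissolutionSeries((10.0, 20.0, 30.0), (0.10, 0.20, 0.30), 4.0, 100.0)
        profile = cp.cumulative_release(series)
        assert profile.q_percent[2] == pytest.approx(31.2, rel=1e-12)

    def test_zero_sample_volume_returns_raw_fractions(self):
        series = cp.DissolutionSeries((10.0, 20.0, 30.0), (0.1, 0.2, 0.3), 0.0, 100.0)
        assert cp.cumulative_release(series).q_percent == pytest.approx((10.0, 20.0, 30.0))

    def test_nondecreasing_fractions_give_nondecreasing_release(self):
        rng = np.random.default_rng(11)
        draws = np.sort(rng.uniform(0, 0.2, size=8))
        series = cp.DissolutionSeries(
            tuple(range(1, 9)), tuple(draws), 5.0, 100.0
        )
        q = cp.cumulative_release(series).q_percent
        assert all(b >= a for a, b in zip(q, q[1:]))

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(times=(), fractions=(), v_sample=5.0, v_medium=100.0),
            dict(times=(10.0, 5.0), fractions=(0.1, 0.2), v_sample=5.0, v_medium=100.0),
            dict(times=(10.0,), fractions=(-0.1,), v_sample=5.0, v_medium=100.0),
            dict(times=(10.0,), fractions=(0.1,), v_sample=200.0, v_medium=100.0),
        ],
    )
    def test_invalid_series_rejected(self, kwargs):
        with pytest.raises(ValueError):
            cp.DissolutionSeries(**kwargs)


class TestSolubilityRatio:
    def test_apparent_solubility_enhancement_rounds_to_three_fold(self):
        ratio, fold = cp.solubility_ratio(0.81e-5, 0.28e-5)
        assert ratio == pytest.approx(2.89, abs=0.005)
        assert fold == 3

    def test_equal_solubilities(self):
        assert cp.solubility_ratio(1e-5, 1e-5) == (1.0, 1)

    def test_low_temperature_ratio(self):
        ratio, _ = cp.solubility_ratio(0.57e-5, 0.23e-5)
        assert ratio == pytest.approx(2.48, abs=0.005)

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            cp.solubility_ratio(0.0, 1e-5)


class TestPxrdNewPhase:
    AP = cp.PeakSet((11.08, 14.08, 15.86))
    NICO = cp.PeakSet((14.92, 25.84, 27.71))

    def test_product_with_unmatched_peaks_is_a_new_phase(self):
        product = cp.PeakSet((7.31, 10.36, 20.68, 11.08))
        res = cp.pxrd_new_phase(product, [self.AP, self.NICO])
        assert res.verdict == "new_phase"
        assert res.new_peaks.angles == (7.31, 10.36, 20.68)
        assert res.matched_peaks.angles == (11.08,)

    def test_physical_mixture_is_a_superposition(self):
        union = cp.PeakSet(self.AP.angles + self.NICO.angles)
        assert cp.pxrd_new_phase(union, [self.AP, self.NICO]).verdict == "superposition"

    def test_peak_within_tolerance_is_matched(self):
        res = cp.pxrd_new_phase(cp.PeakSet((11.15,)), [self.AP], tolerance=0.2)
        assert res.verdict == "superposition"  # |11.15 - 11.08| = 0.07 < 0.2

    def test_widening_tolerance_never_creates_new_peaks(self):
        rng = np.random.default_rng(3)
        product = cp.PeakSet(tuple(rng.uniform(5, 40, size=12)))
        parents = [cp.PeakSet(tuple(rng.uniform(5, 40, size=10)))]
        previous = None
        for tol in (0.05, 0.2, 0.5, 2.0, 10.0):
            new = set(cp.pxrd_new_phase(product, parents, tol).new_peaks.angles)
            if previous is not None:
                assert new <= previous
            previous = new

    def test_peakset_validation(self):
        with pytest.raises(ValueError):
            cp.PeakSet((95.0,))
        assert cp.PeakSet((10.0, 10.0, 5.0)).angles == (5.0, 10.0)

    def test_empty_product_rejected(self):
        with pytest.raises(ValueError, match="empty product"):
            cp.pxrd_new_phase(cp.PeakSet(()), [self.AP])
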
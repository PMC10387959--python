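import math

import numpy as np
import pytest

from quenchbind import binding as b
from quenchbind import cocrystal_phys as cp
from quenchbind import quenching as q
from quenchbind import synthetic_data as sd
from quenchbind import titration_io as tio


class TestSimulateTitration:
    def test_noiseless_stern_volmer_is_exact(self):
        series = sd.simulate_titration(
            sd.TitrationScenario(model="stern_volmer", true_ksv=5.54e5, noise_sd=0.0)
        )
        f0 = series.f0
        for p in series.quenched_points:
            assert f0 / p.f_measured - 1.0 == pytest.approx(5.54e5 * p.q_conc, rel=1e-12)

    def test_same_seed_is_bit_identical(self):
        scen = sd.TitrationScenario(
            model="stern_volmer", true_ksv=5.54e5, noise_sd=0.02, seed=42
        )
        assert sd.simulate_titration(scen) == sd.simulate_titration(scen)

    def test_different_seeds_differ(self):
        mk = lambda s: sd.simulate_titration(
            sd.TitrationScenario(model="stern_volmer", true_ksv=5.54e5, noise_sd=0.02, seed=s)
        )
        assert mk(1) != mk(2)

    def test_double_log_round_trip(self):
        series = sd.simulate_titration(
            sd.TitrationScenario(model="double_log", true_k=1e6, true_n=1.0, noise_sd=0.0)
        )
        res = b.fit_double_log(series)
        assert res.log_k == pytest.approx(6.000, abs=1e-9)
        assert res.n_sites == pytest.approx(1.000, abs=1e-9)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(model="unknown", true_ksv=1e5),
            dict(model="stern_volmer"),  # missing constant
            dict(model="double_log", true_k=1e6),  # missing n
            dict(model="stern_volmer", true_ksv=1e5, noise_sd=-0.1),
            dict(model="stern_volmer", true_ksv=1e5, q_grid=(1e-5, 2e-5)),  # no 0
        ],
    )
    def test_invalid_scenarios_rejected(self, kwargs):
        with pytest.raises(ValueError):
            sd.TitrationScenario(**kwargs)


class TestInnerFilterDistortion:
    def base_series(self):
        return sd.simulate_titration(
            sd.TitrationScenario(model="stern_volmer", true_ksv=5.54e5, noise_sd=0.0)
        )

    def test_zero_coefficients_leave_intensities_unchanged(self):
        series = self.base_series()
        distorted = sd.distort_inner_filter(series, 0.0, 0.0)
        assert [p.f_measured for p in distorted.points] == [
            p.f_measured for p in series.points
        ]

    @pytest.mark.parametrize("base", ["ten", "e"])
    def test_distort_then_correct_recovers_original(self, base):
        series = self.base_series()
        distorted = sd.distort_inner_filter(series, 2500.0, 1800.0, base)
        recovered = tio.correct_series(distorted, base)
        for orig, rec in zip(series.points, recovered.points):
            assert rec.f_corrected == pytest.approx(orig.f_measured, rel=1e-9)

    def test_attenuation_factor_at_highest_level(self):
        series = self.base_series()
        distorted = sd.distort_inner_filter(series, 2500.0, 2500.0, "ten")
        p_orig = series.points[-1]  # q = 4e-5 -> a_ex = a_em = 0.1
        p_dist = distorted.points[-1]
        assert p_dist.a_ex == pytest.approx(0.1)
        assert p_dist.f_measured / p_orig.f_measured == pytest.approx(
            10.0**-0.1, rel=1e-12
        )

    def test_negative_coefficients_rejected(self):
        with pytest.raises(ValueError):
            sd.distort_inner_filter(self.base_series(), -1.0, 0.0)


class TestCompetitionSimulator:
    def test_published_like_displacements(self):
        markers = sd.simulate_competition_pair(4.57e6, 0.977, 0.962)
        assert markers["warfarin"][1] == pytest.approx(1.05e5, rel=0.01)
        assert markers["ibuprofen"][1] == pytest.approx(1.74e5, rel=0.01)
        res = b.competition_site_assignment(4.57e6, markers, tie_margin=0.01)
        assert res.assigned_site == b.SITE_I

    def test_zero_displacements_are_indeterminate(self):
        markers = sd.simulate_competition_pair(1e6, 0.0, 0.0)
        res = b.competition_site_assignment(1e6, markers)
        assert res.assigned_site == "indeterminate"

    def test_planted_site_two_recovered(self):
        markers = sd.simulate_competition_pair(1e6, 0.2, 0.8)
        res = b.competition_site_assignment(1e6, markers)
        assert res.assigned_site == b.SITE_II

    def test_displacement_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sd.simulate_competition_pair(1e6, 1.0, 0.5)


class TestDissolutionSimulator:
    def test_zero_time_releases_nothing(self):
        series = sd.simulate_dissolution(
            sd.DissolutionScenario(q_inf=0.75, rate_k=0.01, times=(0.0, 60.0))
        )
        assert series.fractions[0] == 0.0

    def test_release_formula_recovers_planted_truth(self):
        scen = sd.DissolutionScenario(
            q_inf=0.75, rate_k=0.012, times=(5.0, 15.0, 30.0, 60.0, 120.0, 240.0)
        )
        profile = cp.cumulative_release(sd.simulate_dissolution(scen))
        for t, q_pct in zip(scen.times, profile.q_percent):
            truth = scen.q_inf * (1.0 - math.exp(-scen.rate_k * t))
            assert q_pct == pytest.approx(100.0 * truth, rel=1e-9)

    def test_planted_seventy_one_percent_at_240_minutes(self):
        # rate chosen so the cumulative release reads 71% at 240 min
        q_inf = 0.75
        rate_k = -math.log(1.0 - 0.71 / q_inf) / 240.0
        scen = sd.DissolutionScenario(
            q_inf=q_inf, rate_k=rate_k, times=(30.0, 60.0, 120.0, 180.0, 240.0)
        )
        profile = cp.cumulative_release(sd.simulate_dissolution(scen))
        assert profile.q_percent[-1] == pytest.approx(71.0, rel=1e-9)

    def test_seeded_noise_is_deterministic(self):
        scen = sd.DissolutionScenario(
            q_inf=0.75, rate_k=0.01, times=(10.0, 20.0), noise_sd=0.05, seed=9
        )
        assert sd.simulate_dissolution(scen) == sd.simulate_dissolution(scen)


class TestNoiselessPipelineIdentity:
    @pytest.mark.parametrize(
        "k, n", [(0.67e6, 1.36), (4.57e6, 1.48), (5.01e6, 1.93)]
    )
    def test_simulate_distort_correct_fit_is_identity(self, k, n):
        scen = sd.TitrationScenario(
            model="double_log", true_k=k, true_n=n, noise_sd=0.0, ife=(2500.0, 1800.0)
        )
        series = tio.correct_series(sd.simulate_titration(scen), "ten")
        res = b.fit_double_log(series)
        assert res.k_b == pytest.approx(k, rel=1e-6)
        assert res.n_sites == pytest.approx(n, rel=1e-6)

    def test_stern_volmer_identity_through_inner_filter(self):
        scen = sd.TitrationScenario(
            model="stern_volmer", true_ksv=3.82e5, noise_sd=0.0, ife=(2000.0, 2000.0)
        )
        series = tio.correct_series(sd.simulate_titration(scen), "ten")
        res = q.fit_stern_volmer(series)
        assert res.ksv == pytest.approx(3.82e5, rel=1e-6)
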
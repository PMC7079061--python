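import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

import forestflow as ff
from forestflow.catchment_models import fit_form, select_catchment_model
from forestflow.recovery import (
    analyze_recovery,
    confounded_recovery,
    drop_zero_forested_flow,
    fisher_exact_rxc,
    minimum_age,
    recovery_evidence,
    response_group_tests,
)

from conftest import response_frame


class TestZeroFlowExclusion:
    def test_trailing_zero_years_removed(self):
        df = response_frame("A", np.arange(1.0, 11.0), np.full(10, -50.0), q_c=60.0)
        df.loc[df.index[-3:], "q_f_mm"] = 0.0
        out, n = drop_zero_forested_flow(df)
        assert n == 3 and len(out) == 7

    def test_no_zeros_is_identity(self):
        df = response_frame("A", [1.0, 2.0], [-10.0, -20.0])
        out, n = drop_zero_forested_flow(df)
        assert n == 0
        pd.testing.assert_frame_equal(out, df)

    def test_isolated_mid_series_zero_removed_neighbours_kept(self):
        df = response_frame("A", [1.0, 2.0, 3.0], [-10.0, -20.0, -30.0])
        df.loc[df.index[1], "q_f_mm"] = 0.0
        out, n = drop_zero_forested_flow(df)
        assert n == 1
        assert list(out["age_years"]) == [1.0, 3.0]


class TestMinimumAge:
    def test_simple_minimum(self):
        assert minimum_age(-10.0, 0.5) == pytest.approx(10.0)

    def test_mean_coefficient_minimum_matches_numeric_minimisation(self):
        a, b = -10.1, 0.176
        analytic = minimum_age(a, b)
        numeric = optimize.minimize_scalar(
            lambda t: a * t + b * t**2, bounds=(0, 100), method="bounded",
            options={"xatol": 1e-10},
        ).x
        assert analytic == pytest.approx(28.69, abs=0.005)
        assert analytic == pytest.approx(numeric, abs=1e-6)

    @pytest.mark.parametrize("a,b", [(5.0, 0.2), (-5.0, -0.1), (-5.0, 0.0)])
    def test_undefined_outside_recovering_quadrant(self, a, b):
        assert minimum_age(a, b) is None


class TestRecoveryEvidence:
    def test_noise_free_recovering_curve(self):
        ages = np.arange(1.0, 31.0)
        df = response_frame("A", ages, -8.0 * ages + 0.2 * ages**2)
        fit = fit_form(df, "polynomial", included_terms=())
        fit.classification = "recovering_negative"
        res = recovery_evidence(fit, ages)
        assert res.age_min == pytest.approx(20.0, abs=1e-8)
        assert res.strong_evidence is True  # zero-width CIs are disjoint
        # q(25) - q(20) = (-75) - (-80) = 5
        assert res.recovery_5yr == pytest.approx(5.0, abs=1e-8)

    def test_noisy_curve_with_overlapping_cis(self):
        rng = np.random.default_rng(99)
        ages = np.linspace(2, 30, 12)
        q = -8.0 * ages + 0.2 * ages**2 + rng.normal(0, 40, 12)
        df = response_frame("A", ages, q)
        fit = fit_form(df, "polynomial", included_terms=())
        res = recovery_evidence(fit, ages)
        if res.age_min is not None and res.age_min <= ages.max():
            assert res.strong_evidence is False

    def test_minimum_beyond_data_not_evaluated(self):
        ages = np.arange(1.0, 31.0)
        # minimum at 35, beyond the series
        df = response_frame("A", ages, -14.0 * ages + 0.2 * ages**2)
        fit = fit_form(df, "polynomial", included_terms=())
        res = recovery_evidence(fit, ages)
        assert res.age_min == pytest.approx(35.0)
        assert res.strong_evidence is None
        assert res.recovery_5yr is None

    def test_recovery_rate_depends_only_on_age_coefficients(self):
        ages = np.arange(1.0, 31.0)
        rng = np.random.default_rng(3)
        p_t = rng.normal(0, 100, 30)
        p_t -= p_t.mean()
        q = -8.0 * ages + 0.2 * ages**2 - 0.06 * p_t
        f1 = fit_form(response_frame("A", ages, q, p_t=p_t), "polynomial", ("p_t",))
        r1 = recovery_evidence(f1, ages)
        # shifting every climate anomaly by a constant leaves the rate alone
        q2 = -8.0 * ages + 0.2 * ages**2 - 0.06 * (p_t + 50.0)
        f2 = fit_form(response_frame("A", ages, q2, p_t=p_t + 50.0), "polynomial", ("p_t",))
        r2 = recovery_evidence(f2, ages)
        assert r1.recovery_5yr == pytest.approx(r2.recovery_5yr, abs=1e-6)


class TestConfounding:
    def test_declining_precipitation_flags_confounding(self):
        ages = np.arange(10.0, 25.0)
        df = response_frame("A", ages, np.zeros(15))
        df["p_mm"] = 1200.0 - 15.0 * ages  # strictly declining with age
        assert confounded_recovery(df, "p") is True

    def test_independent_climate_not_flagged(self):
        rng = np.random.default_rng(17)
        ages = np.arange(10.0, 30.0)
        df = response_frame("A", ages, np.zeros(20))
        df["p_mm"] = 1000.0 + rng.normal(0, 100, 20)
        assert confounded_recovery(df, "p") is False

    def test_threshold_is_strict_at_point_seven(self, monkeypatch):
        # the boundary |r| == .7 must NOT fire (strict inequality); pin the
        # correlation to exactly 0.7 to make the float comparison exact
        df = pd.DataFrame(
            {"age_years": np.arange(5.0), "p_mm": np.arange(5.0), "pet_mm": np.arange(5.0)}
        )
        import forestflow.recovery as rec

        monkeypatch.setattr(
            rec.np, "corrcoef", lambda *a, **k: np.array([[1.0, 0.7], [0.7, 1.0]])
        )
        assert confounded_recovery(df, "p") is False

    def test_too_few_records_returns_null(self):
        df = pd.DataFrame({"age_years": [1.0, 2.0], "p_mm": [1.0, 2.0], "pet_mm": [1.0, 2.0]})
        assert confounded_recovery(df, "p") is None


class TestGroupTests:
    def test_fisher_2x2_matches_exact_enumeration_values(self):
        assert fisher_exact_rxc(np.array([[3, 1], [1, 3]])) == pytest.approx(0.4857, abs=2e-4)
        assert fisher_exact_rxc(np.array([[4, 0], [0, 4]])) == pytest.approx(0.0286, abs=2e-4)

    @pytest.mark.parametrize("seed", range(6))
    def test_fisher_2x2_cross_checked_against_scipy(self, seed):
        rng = np.random.default_rng(seed)
        table = rng.integers(0, 8, size=(2, 2))
        if table.sum() == 0:
            table[0, 0] = 1
        mine = fisher_exact_rxc(table)
        _, p_scipy = stats.fisher_exact(table)
        assert mine == pytest.approx(p_scipy, abs=1e-10)

    def test_rx2_table_p_in_unit_interval_and_symmetric(self):
        table = np.array([[5, 1], [2, 4], [0, 3]])
        p = fisher_exact_rxc(table)
        assert 0.0 < p <= 1.0
        assert fisher_exact_rxc(table[:, ::-1]) == pytest.approx(p, abs=1e-12)

    def test_identical_durations_give_zero_kw_statistic(self):
        fits = [
            ff.CatchmentModelFit(str(i), "polynomial", {"age": -1.0}, 0.0, 1.0, n=10,
                                 classification=("negative" if i % 2 else "positive"))
            for i in range(6)
        ]
        out = response_group_tests(fits)
        assert out["duration_kruskal"]["statistic"] == 0.0

    def test_group_fisher_tables_built_from_annotations(self):
        fits = [
            ff.CatchmentModelFit(f"C{i}", "polynomial", {"age": -1.0}, 0.0, 1.0, n=5 + i,
                                 classification=("negative" if i < 4 else "positive"))
            for i in range(8)
        ]
        structure = {f"C{i}": ("uniform" if i % 2 else "non_uniform") for i in range(8)}
        out = response_group_tests(fits, age_structure=structure)
        assert out["age_structure_fisher"]["p"] is not None
        assert np.asarray(out["age_structure_fisher"]["table"]).sum() == 8


class TestAnalyzeRecovery:
    def test_full_screen_on_recovering_catchment(self):
        ages = np.arange(1.0, 31.0)
        rng = np.random.default_rng(5)
        q = -12.0 * ages + 0.3 * ages**2 + rng.normal(0, 8, 30)
        df = response_frame("A", ages, q, q_c=500.0)
        results = analyze_recovery(df)
        res = results[0]
        assert res.age_min == pytest.approx(20.0, abs=2.0)
        assert res.confounded_precip is False
        assert res.zero_flow_points_removed == 0
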
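import itertools

import numpy as np
import pytest

import forestflow as ff
from forestflow.catchment_models import (
    AGE_TERMS,
    aic_ls,
    classify_response,
    fit_form,
    select_catchment_model,
)
from forestflow.hierarchical import RandomStructure
from forestflow.synthetic import GeneratorConfig, simulate_covariates, simulate_panel

from conftest import response_frame


def asym_grid_oracle(ages, q):
    """Brute-force (h, k) grid search for the asymptotic curve."""
    best = (np.inf, None, None)
    for k in np.linspace(-4, 1, 400):
        g = 1.0 - np.exp(-np.exp(k) * ages)
        h = float(g @ q / (g @ g))
        rss = float(((q - h * g) ** 2).sum())
        if rss < best[0]:
            best = (rss, h, k)
    return best


class TestFitForm:
    def test_polynomial_recovers_exact_coefficients(self):
        ages = np.arange(1, 21, dtype=float)
        df = response_frame("A", ages, -8.0 * ages + 0.2 * ages**2)
        fit = fit_form(df, "polynomial", included_terms=())
        assert fit.coefs["age"] == pytest.approx(-8.0, abs=1e-6)
        assert fit.coefs["age_sq"] == pytest.approx(0.2, abs=1e-6)

    def test_asymptotic_recovers_h_k_and_matches_grid_oracle(self):
        ages = np.arange(1, 31, dtype=float)
        q = -150.0 * (1.0 - np.exp(-np.exp(-1.5) * ages))
        df = response_frame("A", ages, q)
        fit = fit_form(df, "asymptotic", included_terms=())
        assert fit.coefs["asym_scale"] == pytest.approx(-150.0, abs=1e-4)
        assert fit.coefs["asym_lograte"] == pytest.approx(-1.5, abs=1e-4)
        _, h_o, k_o = asym_grid_oracle(ages, q)
        assert fit.coefs["asym_scale"] == pytest.approx(h_o, abs=0.5)
        assert fit.coefs["asym_lograte"] == pytest.approx(k_o, abs=0.05)

    def test_no_age_effect_slope_ci_covers_zero(self):
        rng = np.random.default_rng(42)
        ages = np.arange(1, 31, dtype=float)
        p_t = rng.normal(0, 150, 30)
        p_t -= p_t.mean()
        q = -0.1 * p_t + rng.normal(0, 20, 30)
        df = response_frame("A", ages, q, p_t=p_t)
        fit = fit_form(df, "linear", included_terms=("p_t",))
        i = fit.vcov_terms.index("age")
        se = np.sqrt(fit.vcov[i, i])
        assert abs(fit.coefs["age"]) < 2.0 * se

    def test_through_origin_for_every_form(self):
        ages = np.arange(1, 16, dtype=float)
        for form in ("linear", "polynomial", "asymptotic"):
            df = response_frame("A", ages, -5.0 * ages + 0.1 * ages**2)
            fit = fit_form(df, form, included_terms=())
            assert fit.predict_age_curve(np.array([0.0]))[0] == 0.0

    def test_insufficient_df_raises(self):
        df = response_frame("A", [1.0, 2.0], [-5.0, -9.0])
        with pytest.raises(ValueError):
            fit_form(df, "polynomial", included_terms=("p_t", "pet_t"))


class TestAicAgainstAllSubsetsOracle:
    def test_backward_elimination_never_beats_exhaustive_best(self):
        """On a small instance the selected Eq-2 term set's AIC must equal the
        exhaustive all-subsets optimum over the same candidate terms."""
        rng = np.random.default_rng(11)
        ages = np.arange(1, 26, dtype=float)
        p_t = rng.normal(0, 120, 25)
        p_t -= p_t.mean()
        pet_t = rng.normal(0, 30, 25)
        pet_t -= pet_t.mean()
        q = -6.0 * ages + 0.12 * ages**2 - 0.08 * p_t + rng.normal(0, 30, 25)
        df = response_frame("A", ages, q, p_t=p_t, pet_t=pet_t)

        candidates = ["p_t", "p_t_sq", "pet_t", "pet_t_sq"]
        best_oracle = np.inf
        for r in range(len(candidates) + 1):
            for combo in itertools.combinations(candidates, r):
                if "p_t_sq" in combo and "p_t" not in combo:
                    continue
                if "pet_t_sq" in combo and "pet_t" not in combo:
                    continue
                best_oracle = min(best_oracle, fit_form(df, "polynomial", combo).aic)

        selected = select_catchment_model(df)
        if selected.form == "polynomial":
            assert selected.aic == pytest.approx(best_oracle, abs=1e-9)
        else:  # a different family won; it must beat the polynomial optimum
            assert selected.aic <= best_oracle + 2.0 + 1e-9

    def test_aic_convention(self):
        # n log(RSS/n) + 2(p+1), identical for every form
        assert aic_ls(100.0, 20, 3) == pytest.approx(20 * np.log(5.0) + 8.0)


class TestSelection:
    def test_correlated_variables_never_coincluded(self):
        rng = np.random.default_rng(5)
        ages = np.arange(1, 41, dtype=float)
        # p_t deliberately correlated with age at r ~ 0.9
        p_t = 10.0 * ages + rng.normal(0, 60, 40)
        p_t -= p_t.mean()
        q = -4.0 * ages + rng.normal(0, 30, 40)
        df = response_frame("A", ages, q, p_t=p_t)
        assert abs(np.corrcoef(ages, p_t)[0, 1]) > 0.7
        fit = select_catchment_model(df)
        has_age = any(t in fit.coefs for t in ("age", "age_sq", "asym_scale"))
        has_p = "p_t" in fit.coefs
        assert not (has_age and has_p)

    @pytest.mark.parametrize(
        "scenario,check",
        [
            ("asymptotic", lambda f: f.form == "asymptotic"),
            ("recovering", lambda f: f.form == "polynomial" and f.classification == "recovering_negative"),
            ("positive", lambda f: f.classification == "positive"),
            ("null", lambda f: f.form == "none"),
        ],
    )
    def test_noise_free_forms_recovered_exactly(self, scenario, check):
        rs = RandomStructure(sds=np.zeros(4), corr=np.eye(4), phi=np.zeros(3), sigma=0.0)
        cfg = GeneratorConfig(
            seed=5, n_catchments=3, years_per_catchment=40, scenario=scenario, random=rs
        )
        metas = simulate_covariates(cfg)
        panel, _ = simulate_panel(cfg, metas)
        for _, grp in panel.groupby("catchment_id"):
            assert check(select_catchment_model(grp))

    def test_polynomial_wins_over_asymptotic_when_daic_large(self):
        ages = np.arange(1, 31, dtype=float)
        q = -12.0 * ages + 0.3 * ages**2  # strong curvature with a minimum
        df = response_frame("A", ages, q)
        fit = select_catchment_model(df)
        assert fit.form == "polynomial"


class TestClassification:
    @pytest.mark.parametrize(
        "coefs,form,max_age,expected",
        [
            ({"age": -10.0, "age_sq": 0.2}, "polynomial", 30.0, "recovering_negative"),
            ({"age": -10.0, "age_sq": 0.1}, "polynomial", 30.0, "negative"),  # min at 50
            ({"asym_scale": -150.0, "asym_lograte": -1.5}, "asymptotic", 30.0, "negative"),
            ({"age": 5.0}, "linear", 30.0, "positive"),
        ],
    )
    def test_classification_rules(self, coefs, form, max_age, expected):
        fit = ff.CatchmentModelFit(
            catchment_id="A", form=form, coefs=coefs, aic=0.0, r2_adj=1.0, n=30
        )
        assert classify_response(fit, max_age) == expected
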
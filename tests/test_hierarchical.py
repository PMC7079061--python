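import numpy as np
import pandas as pd
import pytest
import scipy.linalg as sla
from hypothesis import given, settings, strategies as st
from scipy.stats import multivariate_normal

import forestflow as ff
from forestflow.hierarchical import (
    RandomStructure,
    ar_correlation_matrix,
    ar_correlations,
    ar_is_stationary,
    ar_to_pacf,
    build_design,
    fit_hierarchical,
    marginal_anova,
    marginal_loglik,
    pacf_to_ar,
    predict_mean_response,
)
from forestflow.synthetic import GeneratorConfig, simulate_covariates, simulate_panel

from conftest import iid_structure, make_meta, response_frame


def dense_loglik_oracle(design, beta, random):
    """Independent oracle: one explicit block covariance per catchment."""
    total = 0.0
    for g in design.groups:
        R = ar_correlation_matrix(random.phi, g.years)
        V = g.Z @ random.psi @ g.Z.T + random.sigma**2 * R
        total += multivariate_normal.logpdf(g.y - g.X @ beta, mean=np.zeros(len(g.y)), cov=V)
    return float(total)


class TestArMachinery:
    @given(
        st.lists(st.floats(-0.95, 0.95), min_size=1, max_size=3).map(np.array)
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_pacf_transform_roundtrips_and_is_stationary(self, pacf):
        phi = pacf_to_ar(pacf)
        assert ar_is_stationary(phi)
        assert np.allclose(ar_to_pacf(phi), pacf, atol=1e-10)

    def test_autocorrelations_match_statsmodels_oracle(self):
        from statsmodels.tsa.arima_process import arma_acf

        phi = pacf_to_ar([0.5, -0.3, 0.2])
        rho = ar_correlations(phi, 10)
        rho_sm = arma_acf(np.r_[1.0, -phi], [1.0], lags=11)
        assert np.allclose(rho, rho_sm, atol=1e-10)

    def test_zero_phi_gives_identity_correlation(self):
        R = ar_correlation_matrix(np.zeros(3), [1990, 1991, 1995])
        assert np.allclose(R, np.eye(3))

    def test_gapped_years_use_actual_lags(self):
        phi = pacf_to_ar([0.6])
        R = ar_correlation_matrix(phi, [2000, 2001, 2005])
        rho = ar_correlations(phi, 5)
        assert R[0, 1] == pytest.approx(rho[1])
        assert R[0, 2] == pytest.approx(rho[5])

    def test_nonstationary_phi_rejected(self):
        with pytest.raises(ValueError):
            ar_correlations(np.array([1.2, 0.0, 0.0]), 5)


class TestMarginalLoglik:
    def _tiny_design(self):
        meta = [make_meta("A")]
        df = response_frame("A", [1.0, 2.0], [0.0, 0.0])
        return build_design(meta, df)

    def test_closed_form_two_zero_residuals(self):
        design = self._tiny_design()
        rs = RandomStructure(sds=np.zeros(4), corr=np.eye(4), phi=np.zeros(3), sigma=1.0)
        ll = marginal_loglik(design, np.zeros(design.p), rs)
        assert ll == pytest.approx(-np.log(2 * np.pi), abs=1e-12)

    def test_matches_dense_oracle_on_random_instances(self):
        rng = np.random.default_rng(0)
        for trial in range(5):
            cfg = GeneratorConfig(
                seed=300 + trial,
                n_catchments=int(rng.integers(2, 4)),
                years_per_catchment=int(rng.integers(3, 9)),
            )
            metas = simulate_covariates(cfg)
            panel, _ = simulate_panel(cfg, metas)
            design = build_design(metas, panel)
            beta = rng.normal(0, 0.01, design.p)
            rs = RandomStructure(
                sds=np.abs(rng.normal(0, [5, 0.1, 0.05, 0.3])),
                corr=np.eye(4),
                phi=pacf_to_ar(rng.uniform(-0.7, 0.7, 3)),
                sigma=float(rng.uniform(10, 60)),
            )
            ll = marginal_loglik(design, beta, rs)
            assert ll == pytest.approx(dense_loglik_oracle(design, beta, rs), abs=1e-8)

    def test_invariant_to_catchment_order(self):
        cfg = GeneratorConfig(seed=8, n_catchments=6, years_per_catchment=7)
        metas = simulate_covariates(cfg)
        panel, _ = simulate_panel(cfg, metas)
        rs = iid_structure()
        design1 = build_design(metas, panel)
        beta = np.full(design1.p, 0.001)
        ll1 = marginal_loglik(design1, beta, rs)
        perm = panel.iloc[::-1].reset_index(drop=True)
        design2 = build_design(metas[::-1], perm)
        assert design2.x_names == design1.x_names
        ll2 = marginal_loglik(design2, beta, rs)
        assert abs(ll1 - ll2) < 1e-9


class TestBuildDesign:
    def test_base_variant_row_expansion(self):
        meta = [make_meta("A", map_mm=1000.0, fc_s=50.0)]
        df = response_frame("A", [10.0], [0.0])
        design = build_design(meta, df)
        row = design.groups[0].X[0]
        expected = {
            "age": 10.0, "age:map": 10000.0, "age:fc_s": 500.0,
            "age:map:fc_s": 500000.0, "age_sq": 100.0,
        }
        for name, value in expected.items():
            assert row[design.x_names.index(name)] == pytest.approx(value)
        # reference levels: all contrast columns zero (and hence dropped)
        assert not any(n.startswith(("age:hf[", "age:plu[")) for n in design.x_names)

    def test_random_design_is_per_catchment_4_column(self):
        cfg = GeneratorConfig(seed=2, n_catchments=2, years_per_catchment=5)
        metas = simulate_covariates(cfg)
        panel, _ = simulate_panel(cfg, metas)
        design = build_design(metas, panel)
        assert len(design.groups) == 2
        assert all(g.Z.shape == (5, 4) for g in design.groups)

    def test_variant_column_swaps(self):
        cfg = GeneratorConfig(seed=2, n_catchments=6, years_per_catchment=5)
        metas = simulate_covariates(cfg)
        panel, _ = simulate_panel(cfg, metas)
        base = build_design(metas, panel, "base")
        ft = build_design(metas, panel, "ft_for_fcs")
        plc = build_design(metas, panel, "plc_for_plu")
        assert "age:fc_s" in base.x_names
        assert "age:fc_s" not in ft.x_names
        assert any(n.startswith("age:ft[") for n in ft.x_names)
        assert any(n.startswith("age:plc[") for n in plc.x_names)
        with pytest.raises(ValueError):
            build_design(metas, panel, "bogus")


class TestFitHierarchical:
    def test_single_catchment_rejected(self):
        meta = [make_meta("A")]
        df = response_frame("A", np.arange(1.0, 9.0), np.zeros(8))
        with pytest.raises(ValueError):
            fit_hierarchical(build_design(meta, df))

    def test_ml_fit_loglik_consistent_with_exact_marginal_likelihood(self):
        cfg = GeneratorConfig(seed=21, n_catchments=30, years_per_catchment=10)
        metas = simulate_covariates(cfg)
        panel, _ = simulate_panel(cfg, metas)
        design = build_design(metas, panel)
        fit = fit_hierarchical(design, method="ml")
        ll = marginal_loglik(design, fit.beta, fit.random)
        assert fit.loglik == pytest.approx(ll, abs=1e-6)
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * (design.p + 14), abs=1e-8)

    def test_zero_variance_truth_estimated_at_boundary(self):
        """With no true random slopes and no AR, the estimated
        random-effect SDs must collapse toward the boundary."""
        rs = RandomStructure(sds=np.zeros(4), corr=np.eye(4), phi=np.zeros(3), sigma=45.0)
        cfg = GeneratorConfig(seed=77, n_catchments=200, years_per_catchment=30, random=rs)
        metas = simulate_covariates(cfg)
        panel, _ = simulate_panel(cfg, metas)
        fit = fit_hierarchical(build_design(metas, panel), method="reml")
        assert np.all(fit.random.sds < 0.05 * fit.random.sigma)

    def test_agrees_with_statsmodels_mixedlm_without_ar(self):
        """Dual route: same design, phi=0 -> statsmodels MixedLM.

        At statsmodels' variance estimates the GLS fixed effects from this
        package's likelihood must reproduce statsmodels' fixed effects
        almost exactly; the independently optimized estimates must agree
        within a small fraction of a standard error.
        """
        import warnings

        import statsmodels.api as sm

        rs = iid_structure(sds=np.sqrt([56.4, 0.0353, 0.00602, 0.333]))  # diagonal Psi
        cfg = GeneratorConfig(
            seed=42, n_catchments=60, years_per_catchment=12, random=rs
        )
        metas = simulate_covariates(cfg)
        panel, _ = simulate_panel(cfg, metas)
        design = build_design(metas, panel)
        fit = fit_hierarchical(design, method="reml", ar_order=0)

        X = np.vstack([g.X for g in design.groups])
        y = np.concatenate([g.y for g in design.groups])
        scale = np.sqrt((X**2).sum(axis=0))
        groups = np.concatenate([[g.catchment_id] * len(g.y) for g in design.groups])
        Z = np.vstack([g.Z for g in design.groups])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mf = sm.MixedLM(y, X / scale, groups=groups, exog_re=Z).fit(
                reml=True, method="powell", maxiter=2000
            )
        beta_sm = mf.fe_params / scale
        se = np.sqrt(np.diag(fit.fixed_vcov))
        assert np.all(np.abs(beta_sm - fit.beta) / se < 0.05)

        # formula equivalence: GLS at statsmodels' variance parameters
        psi_sm = np.asarray(mf.cov_re)
        beta_gls = gls_beta(design, psi_sm, mf.scale)
        assert np.all(np.abs(beta_gls - beta_sm) / se < 1e-4)

        # and this package's optimum is no worse under the dense criterion
        ll_mine = dense_reml_criterion(
            design, fit.random.psi, fit.random.sigma**2, np.zeros(3)
        )
        ll_sm = dense_reml_criterion(design, psi_sm, mf.scale, np.zeros(3))
        assert ll_mine >= ll_sm - 1e-6

    def test_reml_loglik_matches_dense_restricted_criterion(self):
        cfg = GeneratorConfig(seed=23, n_catchments=25, years_per_catchment=8)
        metas = simulate_covariates(cfg)
        panel, _ = simulate_panel(cfg, metas)
        design = build_design(metas, panel)
        fit = fit_hierarchical(design, method="reml")
        ll = dense_reml_criterion(design, fit.random.psi, fit.random.sigma**2, fit.random.phi)
        assert fit.loglik == pytest.approx(ll, abs=1e-6)


def gls_beta(design, psi, sigma2, phi=None):
    p = design.p
    Sxx = np.zeros((p, p))
    Sxy = np.zeros(p)
    for g in design.groups:
        R = np.eye(len(g.y)) if phi is None else ar_correlation_matrix(phi, g.years)
        V = g.Z @ psi @ g.Z.T + sigma2 * R
        c = sla.cho_factor(V, lower=True)
        Xi = sla.cho_solve(c, g.X)
        Sxx += g.X.T @ Xi
        Sxy += Xi.T @ g.y
    return np.linalg.solve(Sxx, Sxy)


def dense_reml_criterion(design, psi, sigma2, phi):
    X = np.vstack([g.X for g in design.groups])
    n, p = X.shape
    logdetV = 0.0
    Sxx = np.zeros((p, p))
    Sxy = np.zeros(p)
    Syy = 0.0
    for g in design.groups:
        R = ar_correlation_matrix(phi, g.years)
        V = g.Z @ psi @ g.Z.T + sigma2 * R
        c = sla.cholesky(V, lower=True)
        logdetV += 2 * np.log(np.diag(c)).sum()
        Xi = sla.cho_solve((c, True), g.X)
        Sxx += g.X.T @ Xi
        Sxy += Xi.T @ g.y
        Syy += g.y @ sla.cho_solve((c, True), g.y)
    beta = np.linalg.solve(Sxx, Sxy)
    quad = Syy - Sxy @ beta
    _, logdetS = np.linalg.slogdet(Sxx)
    return -0.5 * ((n - p) * np.log(2 * np.pi) + logdetV + logdetS + quad)


class TestMarginalAnova:
    def test_single_column_f_equals_squared_wald_z(self):
        cfg = GeneratorConfig(seed=31, n_catchments=25, years_per_catchment=8)
        metas = simulate_covariates(cfg)
        panel, _ = simulate_panel(cfg, metas)
        design = build_design(metas, panel)
        fit = fit_hierarchical(design, method="reml")
        table = marginal_anova(fit).set_index("term")
        for term, idx in fit.term_groups.items():
            if len(idx) != 1:
                continue
            i = idx[0]
            z = fit.beta[i] / np.sqrt(fit.fixed_vcov[i, i])
            assert table.loc[term, "F"] == pytest.approx(z**2, rel=1e-6)

    def test_denominator_df_follow_containment(self):
        cfg = GeneratorConfig(seed=31, n_catchments=25, years_per_catchment=8)
        metas = simulate_covariates(cfg)
        panel, _ = simulate_panel(cfg, metas)
        design = build_design(metas, panel)
        fit = fit_hierarchical(design, method="reml")
        table = marginal_anova(fit).set_index("term")
        n_cat_cols = sum(
            len(ix) for t, ix in fit.term_groups.items() if fit.term_level[t] == "catchment"
        )
        assert table.loc["age:map", "df_den"] == fit.n_catchments - n_cat_cols
        assert table.loc["p_t", "df_den"] == fit.n_obs - len(fit.beta)


class TestPredictMeanResponse:
    def test_worked_age_prediction(self):
        fe = ff.FixedEffects(l_levels={"idle": -2.8, "other": 0.8})
        # a = -5.3 - 0.36 + 6.5 - 7.5 = -6.66; Q = -66.6 + 18.0 = -48.6
        q = predict_mean_response(fe, map_mm=1000, fc_s=50, age=10)
        assert q == pytest.approx(-48.6, abs=1e-10)

    def test_precipitation_sensitivity_contribution(self):
        fe = ff.FixedEffects()
        # c = 0.015 - 0.07 = -0.055 per mm; +100 mm anomaly -> -5.5 mm
        q = predict_mean_response(fe, map_mm=1000, fc_s=0, aridity=1.0, p_t=100.0)
        base = predict_mean_response(fe, map_mm=1000, fc_s=0, aridity=1.0)
        assert q - base == pytest.approx(-5.5, abs=1e-10)

    def test_through_origin(self):
        fe = ff.FixedEffects()
        assert predict_mean_response(fe, map_mm=1500, fc_s=80, age=0.0) == 0.0
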
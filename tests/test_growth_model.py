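import numpy as np
import pandas as pd
import pytest
from scipy import interpolate

from vpdgrowth.growth_model import (
    GrowthModelFit,
    GrowthModelSpec,
    build_spline_basis,
    classify_response,
    fit_growth_gamm,
    fit_partial_smi_model,
    goodness_of_fit,
    wald_tests,
)
from vpdgrowth.synthgen import SimulationConfig, simulate_site_dataset


class TestSplineBasis:
    def test_penalty_annihilates_linear(self):
        ages = np.arange(1.0, 61.0)
        Bz, Sz, basis = build_spline_basis(ages, 10)
        # a centred straight line lies in the constrained span; its penalty
        # quadratic form must vanish (second derivative is zero)
        line = 2.0 * ages + 1.0
        line = line - line.mean()
        coef, res, *_ = np.linalg.lstsq(Bz, line, rcond=None)
        np.testing.assert_allclose(Bz @ coef, line, atol=1e-8)
        assert coef @ Sz @ coef == pytest.approx(0.0, abs=1e-6)

    def test_penalty_psd_and_rank(self):
        Bz, Sz, _ = build_spline_basis(np.arange(1.0, 81.0), 12)
        w = np.linalg.eigvalsh(Sz)
        assert np.all(w > -1e-8)
        assert np.sum(w > 1e-8 * w.max()) == 12 - 2

    def test_reproduces_cubic(self):
        ages = np.linspace(1.0, 60.0, 200)
        Bz, _, basis = build_spline_basis(ages, 12)
        k = basis.constraint.shape[0]
        B = interpolate.BSpline.design_matrix(ages, basis.knots, 3).toarray()
        target = 0.01 * ages**3 - 0.5 * ages**2 + ages
        coef, res, *_ = np.linalg.lstsq(B, target, rcond=None)
        np.testing.assert_allclose(B @ coef, target, atol=1e-8)

    def test_sum_to_zero_constraint(self):
        ages = np.arange(1.0, 51.0)
        Bz, _, _ = build_spline_basis(ages, 8)
        np.testing.assert_allclose(Bz.mean(axis=0), 0.0, atol=1e-12)

    def test_too_few_ages_reduces_basis(self):
        with pytest.warns(UserWarning, match="reducing basis"):
            Bz, Sz, _ = build_spline_basis(np.array([1.0, 2, 3, 4, 5, 6]), 12)
        assert Bz.shape[1] == 5  # 6 -> k=6 minus constraint

    def test_infinite_penalty_collapses_smooth(self, site_dataset):
        df, _, _ = site_dataset
        spec = GrowthModelSpec(basis_dim=8, fixed_lambda=1e12, fixed_phi=0.0,
                               fixed_tree_var_ratio=0.0)
        fit = fit_growth_gamm(df, spec)
        assert fit.converged
        smooth = fit.basis.design(df["age"].to_numpy()) @ fit.spline_coefs
        # under the sum-to-zero constraint all curvature is penalized away;
        # only a (centred) linear trend in age can survive
        resid = smooth - np.polyval(np.polyfit(df["age"], smooth, 1), df["age"])
        assert np.max(np.abs(resid)) < 1e-4 * max(np.max(np.abs(smooth)), 1.0)


class TestOracleEquivalence:
    def test_matches_direct_penalized_least_squares(self):
        # single tree, no random effect, phi = 0, fixed lambda
        cfg = SimulationConfig(n_sites=1, trees_per_site=1, year_start=1955,
                               year_end=2014, sigma_tree=0.0, phi=0.0,
                               sigma_eps=0.2, seed=3)
        df, _ = simulate_site_dataset(cfg, seed=3)
        lam = 2.5
        spec = GrowthModelSpec(basis_dim=9, fixed_lambda=lam, fixed_phi=0.0,
                               fixed_tree_var_ratio=0.0)
        fit = fit_growth_gamm(df, spec)
        assert fit.converged
        # independent oracle: dense penalized normal equations
        Bz, Sz, _ = build_spline_basis(df["age"].to_numpy(float), 9)
        X = np.column_stack([np.ones(len(df)), df["log_ba_prev"], df["vpd_t"],
                             df["vpd_t1"], Bz])
        S = np.zeros((X.shape[1],) * 2)
        S[4:, 4:] = Sz
        b = np.linalg.solve(X.T @ X + lam * S, X.T @ df["log_bai"].to_numpy())
        assert fit.coef["intercept"] == pytest.approx(b[0], abs=1e-8)
        assert fit.alpha_hat == pytest.approx(b[1], abs=1e-8)
        assert fit.beta1_hat == pytest.approx(b[2], abs=1e-8)
        assert fit.beta2_hat == pytest.approx(b[3], abs=1e-8)

    def test_whitening_removes_known_ar1(self):
        # with phi known and fixed, whitened residuals are ~ serially flat
        cfg = SimulationConfig(n_sites=1, trees_per_site=5, year_start=1955,
                               year_end=2014, sigma_tree=0.0, phi=0.6,
                               sigma_eps=0.3, seed=8)
        df, _ = simulate_site_dataset(cfg, seed=8)
        spec = GrowthModelSpec(basis_dim=8, fixed_phi=0.6, fixed_tree_var_ratio=0.0)
        fit = fit_growth_gamm(df, spec)
        assert fit.converged
        acs = []
        for tid, grp in df.groupby("tree_id"):
            idx = grp.sort_values("year").index.to_numpy()
            r = (fit.observed - fit.fitted_marginal)[idx]
            w = r.copy()
            w[1:] = r[1:] - 0.6 * r[:-1]  # AR1 innovations
            z = w[1:] - w[1:].mean()
            acs.append(float(z[1:] @ z[:-1] / (z @ z)))
        assert abs(np.mean(acs)) < 0.12


class TestRecovery:
    def test_noise_free_recovers_generating_coefficients(self):
        cfg = SimulationConfig(n_sites=1, trees_per_site=5, year_start=1950,
                               year_end=2019, alpha=0.3, beta1=-0.4, beta2=-1.0,
                               sigma_tree=0.0, phi=0.0, sigma_eps=1e-8,
                               initial_radius_sd_log=0.3, seed=7)
        df, _ = simulate_site_dataset(cfg, seed=7)
        spec = GrowthModelSpec(basis_dim=12, fixed_lambda=1e-7, fixed_phi=0.0,
                               fixed_tree_var_ratio=0.0)
        fit = fit_growth_gamm(df, spec)
        assert fit.converged
        assert fit.alpha_hat == pytest.approx(0.3, abs=1e-4)
        assert fit.beta1_hat == pytest.approx(-0.4, abs=1e-4)
        assert fit.beta2_hat == pytest.approx(-1.0, abs=1e-4)

    def test_near_noise_free_full_estimator(self):
        cfg = SimulationConfig(n_sites=1, trees_per_site=5, year_start=1950,
                               year_end=2019, alpha=0.3, beta1=-0.4, beta2=-1.0,
                               sigma_tree=0.0, phi=0.0, sigma_eps=1e-6,
                               initial_radius_sd_log=0.3, seed=21)
        df, _ = simulate_site_dataset(cfg, seed=21)
        fit = fit_growth_gamm(df, GrowthModelSpec(basis_dim=12))
        assert fit.converged
        assert fit.beta1_hat == pytest.approx(-0.4, abs=1e-3)
        assert fit.beta2_hat == pytest.approx(-1.0, abs=1e-3)

    def test_tree_order_invariance(self, site_dataset):
        df, _, _ = site_dataset
        spec = GrowthModelSpec(basis_dim=8)
        a = fit_growth_gamm(df, spec)
        shuffled = df.sample(frac=1.0, random_state=4).reset_index(drop=True)
        b = fit_growth_gamm(shuffled, spec)
        assert a.beta2_hat == pytest.approx(b.beta2_hat, abs=1e-8)
        assert a.alpha_hat == pytest.approx(b.alpha_hat, abs=1e-8)

    def test_phi_recovered(self, site_dataset):
        df, truth, cfg = site_dataset
        fit = fit_growth_gamm(df, GrowthModelSpec(basis_dim=8))
        assert fit.converged
        assert fit.phi_hat == pytest.approx(cfg.phi, abs=0.25)

    def test_gcv_mode_agrees_roughly(self, site_dataset):
        df, _, _ = site_dataset
        reml = fit_growth_gamm(df, GrowthModelSpec(basis_dim=8))
        gcv = fit_growth_gamm(df, GrowthModelSpec(basis_dim=8,
                                                  smoothness_selection="GCV"))
        assert gcv.converged
        assert gcv.beta2_hat == pytest.approx(reml.beta2_hat, abs=0.1)


class TestDegenerate:
    def test_constant_vpd_nonconvergent_not_crash(self, site_dataset):
        df, _, _ = site_dataset
        bad = df.copy()
        bad["vpd_t"] = 0.8
        fit = fit_growth_gamm(bad, GrowthModelSpec(basis_dim=8))
        assert not fit.converged
        assert fit.reason is not None

    def test_too_small_dataset(self):
        df = pd.DataFrame({
            "tree_id": ["a"] * 6, "year": range(2000, 2006),
            "log_bai": np.random.default_rng(0).normal(size=6),
            "log_ba_prev": np.linspace(1, 2, 6), "age": range(10, 16),
            "vpd_t": np.linspace(0.5, 1, 6), "vpd_t1": np.linspace(0.6, 1.1, 6),
        })
        fit = fit_growth_gamm(df, GrowthModelSpec(basis_dim=8))
        assert not fit.converged


class TestWaldAndClassification:
    def _fake_fit(self, t1, p1, t2, p2, converged=True):
        return GrowthModelFit(converged=converged, t_beta1=t1, p_beta1=p1,
                              t_beta2=t2, p_beta2=p2, site_id="S", species="X")

    def test_classification_rules(self):
        r = classify_response(self._fake_fit(-3.1, 0.002, 2.0, 0.051))
        assert r.class_vpd_t == "negative"
        assert r.class_vpd_t1 == "nonsignificant"

    def test_boundary_not_significant(self):
        r = classify_response(self._fake_fit(2.0, 0.051, -1.0, 0.5), alpha_level=0.05)
        assert r.class_vpd_t == "nonsignificant"

    def test_nonconvergent_propagates(self):
        r = classify_response(self._fake_fit(1.0, 0.01, 1.0, 0.01, converged=False))
        assert r.class_vpd_t == "nonconvergent" and r.class_vpd_t1 == "nonconvergent"

    def test_alpha_level_one_everything_significant(self, site_dataset):
        df, _, _ = site_dataset
        fit = fit_growth_gamm(df, GrowthModelSpec(basis_dim=8))
        r = classify_response(fit, alpha_level=1.0)
        assert r.class_vpd_t in ("negative", "positive")

    def test_wald_requires_convergence(self):
        with pytest.raises(ValueError):
            wald_tests(GrowthModelFit(converged=False))

    def test_wald_consistency(self, site_dataset):
        df, _, _ = site_dataset
        fit = fit_growth_gamm(df, GrowthModelSpec(basis_dim=8))
        w = wald_tests(fit)
        assert w["vpd_t1"]["t"] == pytest.approx(
            w["vpd_t1"]["estimate"] / w["vpd_t1"]["se"])
        assert 0.0 <= w["vpd_t1"]["p"] <= 1.0


class TestPartialSmi:
    def _with_smi(self, beta_smi, beta2, seed):
        cfg = SimulationConfig(n_sites=1, trees_per_site=5, year_start=1955,
                               year_end=2014, alpha=0.3, beta1=0.0, beta2=beta2,
                               sigma_tree=0.2, phi=0.3, sigma_eps=0.25, seed=seed)
        df, _ = simulate_site_dataset(cfg, seed=seed)
        rng = np.random.default_rng(seed + 1)
        smi_by_year = {y: 60 + 10 * rng.standard_normal()
                       for y in df["year"].unique()}
        df["smi_t"] = df["year"].map(smi_by_year)
        df["log_bai"] = df["log_bai"] + beta_smi * (df["smi_t"] - 60) / 10.0
        return df

    def test_independent_effects_unchanged(self):
        df = self._with_smi(beta_smi=-0.2, beta2=-1.0, seed=5)
        plain = fit_growth_gamm(df, GrowthModelSpec(basis_dim=8))
        partial = fit_partial_smi_model(df, GrowthModelSpec(basis_dim=8))
        assert partial.converged and partial.include_smi
        assert partial.beta2_hat == pytest.approx(plain.beta2_hat, abs=0.15)
        assert partial.beta2_hat == pytest.approx(-1.0, abs=0.3)

    def test_constant_smi_nonconvergent(self, site_dataset):
        df, _, _ = site_dataset
        df = df.copy()
        df["smi_t"] = 55.0
        fit = fit_partial_smi_model(df, GrowthModelSpec(basis_dim=8))
        assert not fit.converged


class TestGoodnessOfFit:
    def test_noise_free_r2_one(self):
        cfg = SimulationConfig(n_sites=1, trees_per_site=3, year_start=1960,
                               year_end=2014, sigma_tree=0.0, phi=0.0,
                               sigma_eps=1e-7, initial_radius_sd_log=0.3, seed=2)
        df, _ = simulate_site_dataset(cfg, seed=2)
        fit = fit_growth_gamm(df, GrowthModelSpec(basis_dim=12))
        assert fit.r2_fluctuations == pytest.approx(1.0, abs=1e-5)

    def test_constant_prediction_r2_zero(self):
        fit = GrowthModelFit(converged=True, observed=np.array([1.0, 2, 3]),
                             fitted=np.full(3, 2.0))
        assert goodness_of_fit(fit) == 0.0

    def test_r2_increases_with_less_noise(self):
        r2s = []
        for sig in (0.5, 0.1):
            cfg = SimulationConfig(n_sites=1, trees_per_site=5, year_start=1960,
                                   year_end=2014, sigma_tree=0.2, phi=0.4,
                                   sigma_eps=sig, seed=31)
            df, _ = simulate_site_dataset(cfg, seed=31)
            r2s.append(fit_growth_gamm(df, GrowthModelSpec(basis_dim=8)).r2_fluctuations)
        assert r2s[1] > r2s[0]
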
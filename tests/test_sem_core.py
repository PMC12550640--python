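"""SEM engine: implied moments, FIML likelihood, fitting, scores, indices."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import one_factor_spec
from fusionern.sem import (MissingPatterns, SEMModel, SEMSpec,
                           ModelSpecificationError, fiml_loglik,
                           fiml_loglik_grad, implied_moments,
                           saturated_fiml)

LOG2PI = np.log(2 * np.pi)


def _saturated_spec(cols):
    spec = SEMSpec()
    spec.add_observed(*cols)
    for i, a in enumerate(cols):
        spec.variance(a)
        spec.intercept(a)
        for b in cols[i + 1:]:
            spec.covariance(a, b)
    return spec


class TestImpliedMoments:
    def test_no_latents_returns_intercepts_and_theta(self):
        spec = _saturated_spec(["a", "b"]).compile()
        theta = np.array([1.0, 0.5, 2.0, 0.25, 0.3])
        mats = spec.build(theta)
        mu, sigma, _ = implied_moments(mats)
        assert np.allclose(mu, mats["nu"])
        assert np.allclose(sigma, mats["theta"])

    def test_rank_one_unit_loadings(self):
        spec = SEMSpec()
        spec.add_observed("a", "b", "c").add_latent("f")
        for obs in ("a", "b", "c"):
            spec.loading(obs, "f", free=False, value=1.0)
            spec.variance(obs, free=False, value=0.0)
            spec.intercept(obs, free=False, value=0.0)
        spec.variance("f", free=False, value=1.0)
        spec.mean("f", free=False, value=0.0)
        mats = spec.compile().build(np.zeros(0))
        _, sigma, _ = implied_moments(mats)
        assert np.allclose(sigma, np.ones((3, 3)))

    def test_two_factor_model_matches_sympy_expansion(self):
        sympy = pytest.importorskip("sympy")
        l2, l3, l5, l6 = sympy.symbols("l2 l3 l5 l6")
        ph11, ph22, ph21 = sympy.symbols("ph11 ph22 ph21")
        th = sympy.symbols("t1:7")
        lam = sympy.Matrix([[1, 0], [l2, 0], [l3, 0],
                            [0, 1], [0, l5], [0, l6]])
        phi = sympy.Matrix([[ph11, ph21], [ph21, ph22]])
        theta = sympy.diag(*th)
        sigma_sym = lam * phi * lam.T + theta

        vals = {l2: 0.7, l3: 1.3, l5: 0.9, l6: 1.1,
                ph11: 2.0, ph22: 1.5, ph21: 0.6}
        vals.update({t: 0.2 + 0.1 * i for i, t in enumerate(th)})
        expected = np.array(sigma_sym.subs(vals)).astype(float)

        spec = SEMSpec()
        obs = [f"y{i}" for i in range(1, 7)]
        spec.add_observed(*obs).add_latent("f1", "f2")
        fixed = {("y1", "f1"), ("y4", "f2")}
        loads = {("y2", "f1"): 0.7, ("y3", "f1"): 1.3,
                 ("y5", "f2"): 0.9, ("y6", "f2"): 1.1}
        for (o, f) in fixed:
            spec.loading(o, f, free=False, value=1.0)
        for (o, f), v in loads.items():
            spec.loading(o, f, free=False, value=v)
        for i, o in enumerate(obs):
            spec.variance(o, free=False, value=0.2 + 0.1 * i)
            spec.intercept(o, free=False, value=0.0)
        spec.variance("f1", free=False, value=2.0)
        spec.variance("f2", free=False, value=1.5)
        spec.covariance("f1", "f2", free=False, value=0.6)
        spec.mean("f1", free=False, value=0.0)
        spec.mean("f2", free=False, value=0.0)
        _, sigma, _ = implied_moments(spec.compile().build(np.zeros(0)))
        assert np.allclose(sigma, expected, atol=1e-12)

    def test_structural_cycle_is_rejected(self):
        spec = SEMSpec()
        spec.add_observed("a").add_latent("u", "v")
        spec.loading("a", "u", free=False, value=1.0)
        spec.variance("a", free=False, value=0.0)
        spec.path("u", "v")
        spec.path("v", "u")
        spec.variance("u")
        spec.variance("v", free=False, value=1.0)
        with pytest.raises(ModelSpecificationError, match="cycle"):
            spec.compile()


class TestFIMLLoglik:
    def test_standard_normal_single_case(self):
        pats = MissingPatterns(np.array([[0.0]]))
        ll = fiml_loglik(np.zeros(1), np.eye(1), pats)
        assert ll == pytest.approx(-0.5 * LOG2PI, abs=1e-12)
        assert ll == pytest.approx(-0.9189385, abs=1e-6)

    def test_complete_data_equals_multivariate_normal(self, rng):
        n, p = 60, 4
        y = rng.standard_normal((n, p)) @ rng.standard_normal((p, p))
        mu = rng.standard_normal(p)
        a = rng.standard_normal((p, p))
        sigma = a @ a.T + np.eye(p)
        ll = fiml_loglik(mu, sigma, MissingPatterns(y))
        direct = stats.multivariate_normal(mu, sigma).logpdf(y).sum()
        assert ll == pytest.approx(direct, rel=1e-10)

    def test_mixed_patterns_match_casewise_sum(self, rng):
        y = np.array([
            [0.3, 1.2, -0.5],
            [np.nan, 0.7, 0.1],
            [1.1, np.nan, np.nan],
            [0.0, -0.2, np.nan],
            [-1.4, 0.9, 2.0],
        ])
        mu = np.array([0.1, 0.4, -0.2])
        a = rng.standard_normal((3, 3))
        sigma = a @ a.T + 2 * np.eye(3)
        expected = 0.0
        for row in y:  # brute-force case-by-case marginal densities
            obs = ~np.isnan(row)
            expected += stats.multivariate_normal(
                mu[obs], sigma[np.ix_(obs, obs)]).logpdf(row[obs])
        ll = fiml_loglik(mu, sigma, MissingPatterns(y))
        assert ll == pytest.approx(expected, rel=1e-12)

    def test_loglik_invariant_to_variable_order(self, one_factor_data):
        spec = one_factor_spec()
        model = SEMModel(spec, one_factor_data)
        theta = model.start_values()
        ll1 = model.loglik(theta)

        spec2 = SEMSpec()
        spec2.add_observed("x3", "x1", "x2").add_latent("f")
        spec2.loading("x1", "f", free=False, value=1.0)
        spec2.loading("x2", "f")
        spec2.loading("x3", "f")
        for obs in ("x1", "x2", "x3"):
            spec2.variance(obs)
            spec2.intercept(obs)
        spec2.variance("f")
        spec2.mean("f", free=False, value=0.0)
        model2 = SEMModel(spec2, one_factor_data)
        # map starts by parameter name
        names1 = model.spec.param_names
        names2 = model2.spec.param_names
        theta2 = np.array([theta[names1.index(nm)] for nm in names2])
        assert model2.loglik(theta2) == pytest.approx(ll1, rel=1e-12)

    def test_all_missing_case_rejected(self):
        with pytest.raises(ValueError, match="no observed values"):
            MissingPatterns(np.array([[1.0, 2.0], [np.nan, np.nan]]))

    def test_analytic_gradient_matches_finite_differences(
            self, one_factor_data):
        model = SEMModel(one_factor_spec(), one_factor_data)
        theta = model.start_values() * 1.07 + 0.03
        _, grad = model.loglik_grad(theta)
        h = 1e-6
        for i in range(len(theta)):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += h
            tm[i] -= h
            num = (model.loglik(tp) - model.loglik(tm)) / (2 * h)
            assert grad[i] == pytest.approx(num, rel=2e-5, abs=1e-6)


class TestSaturatedModel:
    def test_complete_data_closed_form(self, rng):
        y = rng.standard_normal((120, 3)) + np.array([1.0, -0.5, 2.0])
        frame = pd.DataFrame(y, columns=["a", "b", "c"])
        model = SEMModel(_saturated_spec(["a", "b", "c"]), frame)
        res = model.fit(compute_se=False)
        assert model.df_model == 0
        mu_hat, sigma_hat = res.mu, res.sigma
        assert np.allclose(mu_hat, y.mean(axis=0), atol=1e-6)
        dev = y - y.mean(axis=0)
        assert np.allclose(sigma_hat, dev.T @ dev / len(y), atol=1e-5)

    def test_saturated_em_equals_direct_opt_with_missing(self, rng):
        y = rng.standard_normal((150, 3)) * [1.0, 2.0, 0.5]
        y[rng.random(150) < 0.25, 1] = np.nan
        y[rng.random(150) < 0.25, 2] = np.nan
        mu_em, sig_em, ll_em, _ = saturated_fiml(y)
        frame = pd.DataFrame(y, columns=["a", "b", "c"])
        res = SEMModel(_saturated_spec(["a", "b", "c"]), frame).fit(
            compute_se=False)
        assert res.loglik == pytest.approx(ll_em, abs=1e-6)
        assert np.allclose(res.mu, mu_em, atol=1e-4)
        assert np.allclose(res.sigma, sig_em, atol=1e-3)


class TestFitAndInference:
    def test_estimates_near_truth_large_n(self, rng):
        n = 20000
        eta = rng.normal(0, 1.5, n)
        frame = pd.DataFrame({
            "x1": eta + rng.normal(0, 1, n),
            "x2": 0.8 * eta + rng.normal(0, 1, n),
            "x3": 1.2 * eta + rng.normal(0, 1, n),
        })
        res = SEMModel(one_factor_spec(), frame).fit(compute_se=False)
        assert res.converged
        assert res.get("f=~x2") == pytest.approx(0.8, abs=0.05)
        assert res.get("f=~x3") == pytest.approx(1.2, abs=0.05)
        assert res.get("f~~f") == pytest.approx(1.5 ** 2, abs=0.12)

    def test_equality_constraint_is_exact(self, one_factor_data):
        spec = SEMSpec()
        spec.add_observed("x1", "x2", "x3").add_latent("f")
        spec.loading("x1", "f", free=False, value=1.0)
        spec.loading("x2", "f", label="lab")
        spec.loading("x3", "f", label="lab")
        for obs in ("x1", "x2", "x3"):
            spec.variance(obs)
            spec.intercept(obs)
        spec.variance("f")
        spec.mean("f", free=False, value=0.0)
        res = SEMModel(spec, one_factor_data).fit(compute_se=False)
        lam = res.mats["lam"]
        assert lam[1, 0] == lam[2, 0]  # byte-identical shared parameter

    def test_standardization_rules(self, one_factor_data):
        res = SEMModel(one_factor_spec(), one_factor_data).fit(
            compute_se=False)
        sd_obs = np.sqrt(np.diag(res.sigma))
        sd_lat = np.sqrt(res._cache["v"][0, 0])
        lam2 = res.get("f=~x2")
        assert res.get("f=~x2", "std_est") == pytest.approx(
            lam2 * sd_lat / sd_obs[1], rel=1e-10)
        assert res.get("f~~f", "std_est") == pytest.approx(1.0, rel=1e-10)

    def test_standardized_covariance_is_correlation(self):
        # implied SDs 2 and 3 with covariance 3 -> correlation 0.5
        spec = _saturated_spec(["a", "b"])
        frame = pd.DataFrame({"a": [0.0, 1, 2, 3], "b": [0.1, 2, 1, 3]})
        model = SEMModel(spec, frame)
        theta = np.zeros(model.spec.n_free)
        names = model.spec.param_names
        theta[names.index("a~~a")] = 4.0
        theta[names.index("b~~b")] = 9.0
        theta[names.index("a~~b")] = 3.0
        from fusionern.sem.model import SEMResults
        res = SEMResults(model, theta, 0.0, True, None)
        assert res.get("a~~b", "std_est") == pytest.approx(0.5, rel=1e-12)

    def test_wald_and_ci_shape(self, one_factor_data):
        res = SEMModel(one_factor_spec(), one_factor_data).fit()
        tab = res.params
        row = tab.loc["f=~x2"]
        assert row["ci_low"] == pytest.approx(
            row["est"] - 1.959963984540054 * row["se"], rel=1e-9)
        assert row["pvalue"] == pytest.approx(
            2 * stats.norm.sf(abs(row["z"])), rel=1e-9)
        assert res.df == 9 - res.model.spec.n_free  # p(p+3)/2 - free


class TestFitIndices:
    def test_just_identified_reports_not_applicable(self, rng):
        frame = pd.DataFrame(rng.standard_normal((50, 2)),
                             columns=["a", "b"])
        res = SEMModel(_saturated_spec(["a", "b"]), frame).fit(
            compute_se=False)
        fi = res.fit_indices()
        assert fi.chi2 is None and "just-identified" in fi.note

    def test_formula_oracle_on_one_factor_model(self, one_factor_data):
        from fusionern.sem import independence_loglik
        # equality-constrained loadings give the model df > 0
        spec = SEMSpec()
        spec.add_observed("x1", "x2", "x3").add_latent("f")
        spec.loading("x1", "f", free=False, value=1.0)
        spec.loading("x2", "f", label="l")
        spec.loading("x3", "f", label="l")
        for obs in ("x1", "x2", "x3"):
            spec.variance(obs)
            spec.intercept(obs)
        spec.variance("f")
        spec.mean("f", free=False, value=0.0)
        res = SEMModel(spec, one_factor_data).fit(compute_se=False)
        fi = res.fit_indices()
        y = one_factor_data.to_numpy(float)
        _, _, ll_sat, _ = saturated_fiml(y)
        ll_ind, k_ind = independence_loglik(y)
        chi2 = 2 * (ll_sat - res.loglik)
        df = res.df
        n = res.nobs
        assert fi.chi2 == pytest.approx(chi2, rel=1e-9)
        assert fi.rmsea == pytest.approx(
            np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1))), rel=1e-9)
        chi2_b = 2 * (ll_sat - ll_ind)
        df_b = 9 - k_ind  # p(p+3)/2 - 2p with p=3
        expect_cfi = 1 - max(chi2 - df, 0) / max(chi2_b - df_b, chi2 - df, 0)
        assert fi.cfi == pytest.approx(expect_cfi, rel=1e-9)
        assert fi.srmr >= 0

    def test_near_saturated_model_has_zero_rmsea(self, rng):
        # a model with df > 0 whose restrictions hold exactly in the
        # population: chi2 < df at moderate n, so rmsea = 0
        n = 500
        eta = rng.normal(0, 1, n)
        frame = pd.DataFrame({f"x{i}": eta + rng.normal(0, 1, n)
                              for i in (1, 2, 3)})
        spec = SEMSpec()
        spec.add_observed("x1", "x2", "x3").add_latent("f")
        spec.loading("x1", "f", free=False, value=1.0)
        spec.loading("x2", "f", label="l")
        spec.loading("x3", "f", label="l")
        for obs in ("x1", "x2", "x3"):
            spec.variance(obs)
            spec.intercept(obs)
        spec.variance("f")
        spec.mean("f", free=False, value=0.0)
        fi = SEMModel(spec, frame).fit(compute_se=False).fit_indices()
        assert fi.rmsea == pytest.approx(0.0, abs=0.02)
        assert fi.cfi > 0.99


class TestFactorScores:
    @staticmethod
    def _fitted(frame):
        return SEMModel(one_factor_spec(), frame).fit(compute_se=False)

    def test_regression_scores_closed_form_complete(self, rng):
        n = 80
        eta = rng.normal(0, 2, n)
        frame = pd.DataFrame({
            "x1": eta + rng.normal(0, 1, n),
            "x2": 0.8 * eta + rng.normal(0, 1, n),
            "x3": 1.2 * eta + rng.normal(0, 1, n),
        })
        res = self._fitted(frame)
        scores = res.factor_scores()["f"].to_numpy()
        lam = res.mats["lam"]
        psi = res.mats["psi"]
        alpha = res._cache["a"]
        dev = frame.to_numpy() - res.mu
        expected = alpha + (psi @ lam.T @ np.linalg.inv(res.sigma)
                            @ dev.T).ravel()
        assert np.allclose(scores, expected, atol=1e-10)

    def test_zero_residual_scores_reproduce_observations(self, rng):
        n = 40
        eta = rng.normal(1.0, 2.0, n)
        frame = pd.DataFrame({"x1": eta, "x2": eta, "x3": eta})
        spec = SEMSpec()
        spec.add_observed("x1", "x2", "x3").add_latent("f")
        for obs in ("x1", "x2", "x3"):
            spec.loading(obs, "f", free=False, value=1.0)
            spec.variance(obs, free=False, value=0.0)
            spec.intercept(obs, free=False, value=0.0)
        spec.variance("f")
        spec.mean("f")
        res = SEMModel(spec, frame).fit(compute_se=False)
        scores = res.factor_scores()["f"].to_numpy()
        assert np.allclose(scores, eta, atol=1e-6)

    def test_large_residual_scores_shrink_to_mean(self, rng):
        n = 40
        frame = pd.DataFrame({
            "x1": rng.normal(0, 1, n), "x2": rng.normal(0, 1, n),
            "x3": rng.normal(0, 1, n)})
        spec = one_factor_spec()
        model = SEMModel(spec, frame)
        theta = model.start_values()
        names = model.spec.param_names
        for obs in ("x1", "x2", "x3"):
            theta[names.index(f"{obs}~~{obs}")] = 1e8
            theta[names.index(f"{obs}~1")] = 0.0
        theta[names.index("f~~f")] = 1.0
        from fusionern.sem.model import SEMResults
        res = SEMResults(model, theta, 0.0, True, None)
        scores = res.factor_scores()["f"].to_numpy()
        assert np.max(np.abs(scores - 0.0)) < 1e-4  # latent mean is 0

    def test_scores_defined_per_missingness_pattern(self, one_factor_data):
        res = self._fitted(one_factor_data.dropna())
        res2 = SEMModel(one_factor_spec(), one_factor_data).fit(
            compute_se=False)
        scores = res2.factor_scores()
        assert scores["f"].notna().all()
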
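"""SEMModel / SEMResults: fitting, inference, fit indices and factor scores."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .likelihood import (
    MissingPatterns, fiml_loglik, fiml_loglik_grad, fisher_diag,
    implied_moments, independence_loglik, saturated_fiml,
)
from .spec import CompiledSpec, ModelSpecificationError, SEMSpec

__all__ = ["SEMModel", "SEMResults", "FitIndices"]

_PENALTY = 1e12
Z95 = 1.959963984540054


@dataclass
class FitIndices:
    chi2: Optional[float]
    df: int
    pvalue: Optional[float]
    rmsea: Optional[float]
    srmr: Optional[float]
    cfi: Optional[float]
    chi2_baseline: Optional[float] = None
    df_baseline: Optional[int] = None
    note: str = ""

    def __repr__(self):  # compact, REPL-friendly
        if self.chi2 is None:
            return f"FitIndices(df={self.df}; {self.note})"
        return (f"FitIndices(chi2={self.chi2:.3f}, df={self.df}, "
                f"rmsea={self.rmsea:.3f}, srmr={self.srmr:.3f}, "
                f"cfi={self.cfi:.3f})")


class SEMModel:
    """Mean-and-covariance structure model bound to a data set.

    Parameters
    ----------
    spec : SEMSpec or CompiledSpec
        Model description (matrices with free/fixed/equality-labelled cells).
    data : pandas.DataFrame
        One row per case; must contain every observed variable of the model.
        Missing cells are NaN and are handled by casewise (full-information)
        maximum likelihood.
    """

    def __init__(self, spec, data: pd.DataFrame, name: str = "SEM"):
        self.spec: CompiledSpec = spec.compile() if isinstance(spec, SEMSpec) else spec
        self.name = name
        missing_cols = [c for c in self.spec.observed if c not in data.columns]
        if missing_cols:
            raise ModelSpecificationError(f"data lacks columns {missing_cols}")
        frame = data[self.spec.observed].astype(float)
        keep = ~frame.isna().all(axis=1)
        if not keep.all():
            warnings.warn(f"dropping {int((~keep).sum())} case(s) with no "
                          "observed values")
            frame = frame.loc[keep]
        self.data = frame
        self.index = frame.index
        self.y = frame.to_numpy(float)
        self.nobs = self.y.shape[0]
        self.patterns = MissingPatterns(self.y)
        p = len(self.spec.observed)
        self.n_moments = p * (p + 3) // 2
        self.df_model = self.n_moments - self.spec.n_free
        if self.nobs <= self.spec.n_free:
            warnings.warn(
                f"n={self.nobs} does not exceed the number of free "
                f"parameters ({self.spec.n_free}); estimates may be unstable")

    # -- likelihood ----------------------------------------------------------
    def loglik(self, theta: np.ndarray) -> float:
        mu, sigma, _ = implied_moments(self.spec.build(np.asarray(theta, float)))
        try:
            return fiml_loglik(mu, sigma, self.patterns)
        except np.linalg.LinAlgError:
            return -np.inf

    def loglik_grad(self, theta: np.ndarray):
        mats = self.spec.build(np.asarray(theta, float))
        ll, grads = fiml_loglik_grad(mats, self.patterns)
        return ll, self.spec.contract(grads)

    # -- start values --------------------------------------------------------
    def start_values(self) -> np.ndarray:
        """Builder-provided starts, with moment-based defaults elsewhere.

        Defaults: loadings 1, observed intercepts at sample means, residual
        variances at half the sample variances, structural paths 0, latent
        variances at half the mean indicator variance, latent means 0
        (phantom-latent means at the indicator mean).
        """
        starts = self.spec.starts.copy()
        if not np.isnan(starts).any():
            return starts
        col_mean = np.nanmean(self.y, axis=0)
        col_var = np.nanvar(self.y, axis=0)
        col_var[~np.isfinite(col_var) | (col_var <= 0)] = 1.0
        oi = {n: i for i, n in enumerate(self.spec.observed)}
        li = {n: i for i, n in enumerate(self.spec.latent)}

        # indicator lists per latent, and phantom detection
        lam_fixed_unit = {}  # latent -> observed with fixed unit loading
        indicators = {n: [] for n in self.spec.latent}
        nu_fixed = set()
        theta_fixed_zero = set()
        for e in self.spec.entries:
            if e.matrix == "lam" and (e.free or e.value != 0):
                indicators[e.col].append(e.row)
                if not e.free and e.value == 1.0:
                    lam_fixed_unit.setdefault(e.col, e.row)
            elif e.matrix == "nu" and not e.free:
                nu_fixed.add(e.row)
            elif e.matrix == "theta" and e.row == e.col and not e.free \
                    and e.value == 0.0:
                theta_fixed_zero.add(e.row)

        for e in self.spec.entries:
            if not e.free:
                continue
            rows, cols, tidx = self.spec.free_idx[e.matrix]
            # locate this entry's theta index
            k = self._theta_index_of(e)
            if not np.isnan(starts[k]):
                continue
            if e.matrix == "lam":
                starts[k] = 1.0
            elif e.matrix == "beta":
                starts[k] = 0.0
            elif e.matrix == "nu":
                starts[k] = col_mean[oi[e.row]]
            elif e.matrix == "theta":
                starts[k] = 0.5 * col_var[oi[e.row]] if e.row == e.col else 0.0
            elif e.matrix == "psi":
                if e.row != e.col:
                    starts[k] = 0.0
                else:
                    inds = indicators.get(e.row, [])
                    marker = lam_fixed_unit.get(e.row)
                    if marker is not None and marker in theta_fixed_zero:
                        starts[k] = col_var[oi[marker]]  # phantom
                    elif inds:
                        starts[k] = 0.5 * float(np.mean(
                            [col_var[oi[o]] for o in inds]))
                    else:
                        starts[k] = 1.0
            elif e.matrix == "alpha":
                marker = lam_fixed_unit.get(e.row)
                if marker is not None and marker in nu_fixed:
                    starts[k] = col_mean[oi[marker]]
                else:
                    starts[k] = 0.0
        return starts

    def _theta_index_of(self, e) -> int:
        oi = {n: i for i, n in enumerate(self.spec.observed)}
        li = {n: i for i, n in enumerate(self.spec.latent)}
        mat = e.matrix
        rows, cols, tidx = self.spec.free_idx[mat]
        if mat in ("nu", "alpha"):
            i = oi[e.row] if mat == "nu" else li[e.row]
            pos = np.where(rows == i)[0]
        else:
            if mat == "lam":
                i, j = oi[e.row], li[e.col]
            elif mat == "theta":
                i, j = oi[e.row], oi[e.col]
            else:
                i, j = li[e.row], li[e.col]
            pos = np.where((rows == i) & (cols == j))[0]
        return int(tidx[pos[0]])

    # -- fitting -------------------------------------------------------------
    def fit(self, start: Optional[np.ndarray] = None, maxiter: int = 2000,
            restarts: int = 5, seed: int = 0, compute_se: bool = True,
            gtol: float = 1e-5) -> "SEMResults":
        """Maximize the FIML log-likelihood by quasi-Newton (L-BFGS-B).

        On non-convergence the start values are jittered (seeded) up to
        ``restarts`` times; the result carries an explicit convergence flag.
        """
        theta0 = np.asarray(self.start_values() if start is None else start,
                            float).copy()
        rng = np.random.default_rng(seed)
        best = None
        n_restarts_used = 0
        for attempt in range(restarts + 1):
            res = self._minimize(theta0 if attempt == 0 else self._jitter(
                theta0, rng, attempt), maxiter, gtol)
            if best is None or res.fun < best.fun:
                best = res
            if self._converged(best):
                break
            n_restarts_used = attempt + 1 if attempt else 0
        converged = self._converged(best)
        theta = best.x
        ll = -best.fun
        cov = None
        se_warning = ""
        if compute_se:
            cov, se_warning = self._observed_information_cov(theta)
        return SEMResults(self, theta, ll, converged, cov,
                          n_restarts=n_restarts_used,
                          optimizer_message=str(best.message),
                          se_warning=se_warning)

    def _jitter(self, theta0, rng, attempt):
        scale = 0.1 * attempt
        return theta0 * (1.0 + scale * rng.standard_normal(theta0.shape)) \
            + 0.05 * scale * rng.standard_normal(theta0.shape)

    def _precondition(self, theta0):
        """Per-parameter scale from the Fisher-information diagonal."""
        try:
            info = fisher_diag(self.spec.build(theta0), self.nobs)
        except np.linalg.LinAlgError:
            return np.ones_like(theta0)
        scale = self.spec.contract(info)
        top = float(np.max(scale)) if len(scale) else 1.0
        if not np.isfinite(top) or top <= 0:
            return np.ones_like(theta0)
        return np.sqrt(np.clip(scale, 1e-10 * top, None))

    def _minimize(self, theta0, maxiter, gtol):
        ref = np.asarray(theta0, float)
        s = self._precondition(ref)

        def objective(phi):
            theta = phi / s
            try:
                ll, grad = self.loglik_grad(theta)
            except (np.linalg.LinAlgError, ValueError):
                ll = -np.inf
            if not np.isfinite(ll):
                # outside the PD region: finite penalty sloping back
                dev = theta - ref
                return _PENALTY * (1.0 + float(dev @ dev)), \
                    2 * _PENALTY * dev / s
            return -ll, -grad / s

        bounds = None
        phi0 = ref * s
        vp = self.spec.variance_param
        if vp is not None and vp.any():
            bounds = [(0.0, None) if v else (None, None) for v in vp]
            phi0 = np.where(vp, np.maximum(phi0, 0.0), phi0)
        res = optimize.minimize(
            objective, phi0, jac=True, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter, "maxcor": 30,
                     "ftol": 1e-11, "gtol": gtol})
        res.x = res.x / s
        return res

    @staticmethod
    def _converged(res) -> bool:
        return bool(res.success) and res.fun < _PENALTY / 2

    def _observed_information_cov(self, theta):
        """Covariance of estimates from the inverse observed information.

        Central finite differences of the analytic gradient.
        """
        k = len(theta)
        h = 1e-5 * np.maximum(1.0, np.abs(theta))
        hess = np.zeros((k, k))
        for i in range(k):
            tp = theta.copy()
            tp[i] += h[i]
            tm = theta.copy()
            tm[i] -= h[i]
            try:
                _, gp = self.loglik_grad(tp)
                _, gm = self.loglik_grad(tm)
            except np.linalg.LinAlgError:
                return None, "information matrix not computable at optimum"
            hess[:, i] = -(gp - gm) / (2.0 * h[i])
        hess = 0.5 * (hess + hess.T)
        try:
            cov = np.linalg.inv(hess)
            if not np.all(np.isfinite(cov)):
                raise np.linalg.LinAlgError
            warning = ""
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(hess)
            warning = "observed information singular; pseudo-inverse used"
        if np.any(np.diag(cov) < 0):
            warning = warning or "negative variance estimate in inverse information"
        return cov, warning


class SEMResults:
    """Estimates, uncertainties and diagnostics of a fitted model."""

    def __init__(self, model: SEMModel, theta, loglik, converged, cov_params,
                 n_restarts=0, optimizer_message="", se_warning=""):
        self.model = model
        self.theta = np.asarray(theta, float)
        self.loglik = float(loglik)
        self.converged = bool(converged)
        self.cov_theta = cov_params
        self.n_restarts = n_restarts
        self.optimizer_message = optimizer_message
        self.se_warning = se_warning
        self.nobs = model.nobs
        self.df = model.df_model
        self.mats = model.spec.build(self.theta)
        self.mu, self.sigma, self._cache = implied_moments(self.mats)
        self._params: Optional[pd.DataFrame] = None

    # -- parameter table -----------------------------------------------------
    @property
    def params(self) -> pd.DataFrame:
        if self._params is None:
            se = np.full(len(self.theta), np.nan)
            if self.cov_theta is not None:
                var = np.diag(self.cov_theta)
                se = np.sqrt(np.where(var > 0, var, np.nan))
            z = self.theta / se
            p = 2.0 * stats.norm.sf(np.abs(z))
            std = self._standardized_theta()
            self._params = pd.DataFrame({
                "param": self.model.spec.param_names,
                "est": self.theta,
                "se": se,
                "z": z,
                "pvalue": p,
                "ci_low": self.theta - Z95 * se,
                "ci_high": self.theta + Z95 * se,
                "std_est": std,
            }).set_index("param")
        return self._params

    def get(self, name: str, column: str = "est") -> float:
        """Look up a parameter row by its canonical name or label."""
        tab = self.params
        if name in tab.index:
            return float(tab.loc[name, column])
        hits = [ix for ix in tab.index if f"({name})" in ix or ix.startswith(name)]
        if len(hits) != 1:
            raise KeyError(f"parameter {name!r} not found or ambiguous: {hits}")
        return float(tab.loc[hits[0], column])

    # -- standardization -----------------------------------------------------
    def _sd_maps(self):
        sd_obs = np.sqrt(np.clip(np.diag(self.sigma), 0, None))
        sd_lat = np.sqrt(np.clip(np.diag(self._cache["v"]), 0, None))
        return sd_obs, sd_lat

    def standardize(self) -> pd.Series:
        """Standardized solution; raises on zero implied variance."""
        sd_obs, sd_lat = self._sd_maps()
        if np.any(sd_obs == 0) or np.any(sd_lat == 0):
            bad_o = [n for n, s in zip(self.model.spec.observed, sd_obs)
                     if s == 0]
            bad_l = [n for n, s in zip(self.model.spec.latent, sd_lat)
                     if s == 0]
            raise ZeroDivisionError(
                f"zero implied variance for {bad_o + bad_l}; cannot standardize")
        return self.standardized

    def _standardized_theta(self) -> np.ndarray:
        sd_obs, sd_lat = self._sd_maps()
        if np.any(sd_obs == 0) or np.any(sd_lat == 0):
            warnings.warn("zero implied variance; affected standardized "
                          "estimates reported as NaN")
            sd_obs = np.where(sd_obs == 0, np.nan, sd_obs)
            sd_lat = np.where(sd_lat == 0, np.nan, sd_lat)
        std = np.full(len(self.theta), np.nan)
        for mat in ("lam", "beta", "psi", "theta", "nu", "alpha"):
            rows, cols, tidx = self.model.spec.free_idx[mat]
            if len(tidx) == 0:
                continue
            m = self.mats[mat]
            if mat == "lam":
                vals = m[rows, cols] * sd_lat[cols] / sd_obs[rows]
            elif mat == "beta":
                vals = m[rows, cols] * sd_lat[cols] / sd_lat[rows]
            elif mat == "psi":
                vals = m[rows, cols] / (sd_lat[rows] * sd_lat[cols])
            elif mat == "theta":
                vals = m[rows, cols] / (sd_obs[rows] * sd_obs[cols])
            elif mat == "nu":
                vals = m[rows] / sd_obs[rows]
            else:
                vals = m[rows] / sd_lat[rows]
            std[tidx] = vals
        return std

    @property
    def standardized(self) -> pd.Series:
        return self.params["std_est"]

    # -- fit indices ---------------------------------------------------------
    def fit_indices(self) -> FitIndices:
        """ML chi-square-based RMSEA / SRMR / CFI (non-robust).

        Not applicable for just-identified models (df = 0).
        """
        df = self.df
        if df <= 0:
            return FitIndices(None, df, None, None, None, None,
                              note="model is just-identified (df = 0); "
                                   "fit indices are not reported")
        y = self.model.y
        mu_s, sig_s, ll_sat, _ = saturated_fiml(y)
        ll_ind, k_ind = independence_loglik(y)
        chi2 = max(2.0 * (ll_sat - self.loglik), 0.0)
        chi2_b = max(2.0 * (ll_sat - ll_ind), 0.0)
        df_b = self.model.n_moments - k_ind
        n = self.nobs
        rmsea = float(np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1))))
        denom = max(chi2_b - df_b, chi2 - df, 0.0)
        cfi = 1.0 - (max(chi2 - df, 0.0) / denom if denom > 0 else 0.0)
        # SRMR over standardized covariance and mean residuals, using the
        # saturated FIML moments as the "sample" moments
        sd = np.sqrt(np.diag(sig_s))
        res_cov = (sig_s - self.sigma) / np.outer(sd, sd)
        iu = np.triu_indices_from(res_cov)
        res_mean = (mu_s - self.mu) / sd
        srmr = float(np.sqrt(np.mean(np.concatenate(
            [res_cov[iu] ** 2, res_mean ** 2]))))
        pval = float(stats.chi2.sf(chi2, df))
        return FitIndices(chi2, df, pval, rmsea, srmr, cfi, chi2_b, df_b)

    # -- factor scores -------------------------------------------------------
    def factor_scores(self, method: str = "regression") -> pd.DataFrame:
        """Per-subject latent scores, computed per missingness pattern.

        ``regression`` (empirical-Bayes) scores are the conditional means
        E[eta | observed subvector]; they shrink toward the latent mean as
        residual noise grows and reproduce the observed data transformation
        exactly when residual variances are zero.  ``bartlett`` scores are
        available for complete rows with invertible residual covariance.
        """
        spec = self.model.spec
        m = len(spec.latent)
        out = np.full((self.model.nobs, m), np.nan)
        a, v = self._cache["a"], self._cache["v"]
        c = self._cache["lam_v"]  # Cov(y, eta), p x m
        y = self.model.y
        if method == "regression":
            for pat, rows in zip(self.model.patterns.patterns,
                                 self.model.patterns.rows_by_pattern):
                o = pat.obs
                sub = self.sigma[np.ix_(o, o)]
                co = c[o]  # k x m
                try:
                    w = np.linalg.solve(sub, co)  # k x m
                except np.linalg.LinAlgError:
                    # zero-residual models give singular implied covariances;
                    # the least-norm solution still conditions correctly on
                    # the observed manifold
                    w = np.linalg.pinv(sub) @ co
                dev = y[np.ix_(rows, o)] - self.mu[o]
                scores = a + dev @ w
                # latents with no observed information in this pattern
                uninformed = np.max(np.abs(co), axis=0) < 1e-12 * max(
                    1.0, float(np.max(np.abs(c))))
                scores[:, uninformed] = np.nan
                out[rows] = scores
        elif method == "bartlett":
            lam, theta_m = self.mats["lam"], self.mats["theta"]
            for pat, rows in zip(self.model.patterns.patterns,
                                 self.model.patterns.rows_by_pattern):
                o = pat.obs
                lam_o = lam[o]
                th_inv = np.linalg.pinv(theta_m[np.ix_(o, o)])
                mstar = np.linalg.pinv(lam_o.T @ th_inv @ lam_o) \
                    @ lam_o.T @ th_inv
                dev = y[np.ix_(rows, o)] - self.mats["nu"][o]
                out[rows] = (mstar @ dev.T).T
        else:
            raise ValueError(f"unknown factor-score method {method!r}")
        return pd.DataFrame(out, index=self.model.index, columns=spec.latent)

    # -- reporting -----------------------------------------------------------
    def summary(self) -> str:
        lines = [
            f"{self.model.name}",
            "=" * max(len(self.model.name), 60),
            f"n = {self.nobs}   free parameters = {self.model.spec.n_free}   "
            f"df = {self.df}",
            f"log-likelihood (FIML) = {self.loglik:.4f}   "
            f"converged = {self.converged}"
            + (f"   restarts = {self.n_restarts}" if self.n_restarts else ""),
        ]
        if self.se_warning:
            lines.append(f"warning: {self.se_warning}")
        with pd.option_context("display.width", 120,
                               "display.float_format", "{:10.4f}".format):
            lines.append(str(self.params))
        return "\n".join(lines)

    def __repr__(self):
        return (f"<SEMResults {self.model.name}: n={self.nobs}, "
                f"ll={self.loglik:.2f}, converged={self.converged}>")
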
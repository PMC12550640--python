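"""Blockwise incremental validity and focused path models.

Predictors enter in ordered blocks (covariates; EEG; fMRI; EEG-fMRI fusion,
each neural block holding baseline/change ROI scores and their BI
interactions).  The outcome is the latent anxiety-change factor with its
two-wave measurement model embedded (an observed proxy column can be
substituted).  The structural part among predictors and outcome is
saturated, so the fitted model is maximum-likelihood equivalent to any
phantom-variable reparameterization of the same blocks; the block
quantities are read off the implied joint moments:

* ``gamma_k`` — the semipartial multiple correlation of block k with the
  outcome after removing blocks 1..k-1,
* ``delta_r2_k = gamma_k**2`` — block k's increment to explained variance,

with delta-method standard errors from the observed-information covariance
and a joint Wald chi-square (df = block size) on block k's semipartial
coefficients as the test of ``gamma_k = 0``.  On complete data with an
observed outcome these increments equal hierarchical OLS increments.
"""

from __future__ import annotations

from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .lcs import (ANXIETY_OBSERVED, _two_wave_core, add_anxiety_measurement,
                  measurement_starts)
from .sem import SEMModel, SEMSpec, saturated_fiml
from .sem.likelihood import implied_moments

__all__ = [
    "build_interaction_terms", "ols_hierarchical_r2",
    "IncrementalValidityModel", "BlockPathResults",
]

LATENT_BASELINE = "eta13"
LATENT_OUTCOME = "delta"


def build_interaction_terms(scores: pd.DataFrame, bi: Optional[str] = "bi",
                            columns: Optional[Sequence[str]] = None
                            ) -> pd.DataFrame:
    """Z-score neural predictors and BI and append their products.

    Product columns are named ``<score>_x_bi``; a missing score yields a
    missing product (never an implicit zero).  Raises on zero-variance
    input, naming the column.
    """
    out = scores.copy()
    if columns is None:
        columns = [c for c in scores.columns
                   if c.split("_")[0] in ("eeg", "fmri", "fusion")
                   and (c.endswith("_13") or c.endswith("_15")
                        or c.endswith("_change"))]
    for col in list(columns) + [bi]:
        sd = out[col].std(skipna=True)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"cannot z-score zero-variance column {col!r}")
        out[col] = (out[col] - out[col].mean(skipna=True)) / sd
    for col in columns:
        out[f"{col}_x_bi"] = out[col] * out[bi]
    return out


def ols_hierarchical_r2(data: pd.DataFrame, blocks: Sequence[Sequence[str]],
                        outcome: str):
    """Hierarchical least-squares R-squared increments (complete data).

    Independent of the SEM machinery: R^2 after cumulatively adding each
    block is computed from least-squares projections.  Rank-deficient
    designs (e.g. a duplicated predictor in a later block) are handled by
    the projection itself, contributing zero increment.  Returns
    ``(cumulative_r2, delta_r2)`` arrays.
    """
    cols = [c for blk in blocks for c in blk] + [outcome]
    frame = data[cols]
    if frame.isna().any().any():
        raise ValueError("ols_hierarchical_r2 requires complete data")
    y = frame[outcome].to_numpy(float)
    y = y - y.mean()
    tss = float(y @ y)
    if tss == 0:
        raise ValueError("outcome has zero variance")
    r2 = []
    used: List[str] = []
    for blk in blocks:
        used += list(blk)
        x = frame[used].to_numpy(float)
        x = np.column_stack([np.ones(len(x)), x])
        coef, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ coef
        r2.append(1.0 - float(resid @ resid) / tss)
    r2 = np.asarray(r2)
    return r2, np.diff(np.concatenate([[0.0], r2]))


def _hierarchical_from_cov(cov: np.ndarray, block_sizes: Sequence[int]):
    """Cumulative R^2 of the outcome (last row) on nested predictor sets."""
    k = cov.shape[0] - 1
    syy = cov[k, k]
    out = []
    stop = 0
    for m in block_sizes:
        stop += m
        sxx = cov[:stop, :stop]
        sxy = cov[:stop, k]
        beta = np.linalg.lstsq(sxx, sxy, rcond=None)[0]
        out.append(float(sxy @ beta) / syy)
    return np.asarray(out)


class IncrementalValidityModel:
    """Blockwise structural model for sequential increments in R^2.

    Parameters
    ----------
    data : DataFrame
        Analysis table holding every observed predictor plus either the six
        anxiety indicator columns (latent-outcome mode) or an observed
        outcome column.
    blocks : list of lists of predictor names
        Ordered blocks.  The name ``"eta13"`` denotes the latent baseline
        anxiety factor and may appear only with the latent outcome.
    outcome : "latent" or a column name
    """

    def __init__(self, data: pd.DataFrame, blocks: Sequence[Sequence[str]],
                 outcome: str = "latent", name: str = "incremental validity"):
        self.blocks = [list(b) for b in blocks]
        self.block_sizes = [len(b) for b in self.blocks]
        self.predictors = [c for b in self.blocks for c in b]
        self.latent_mode = outcome == "latent"
        self.outcome = LATENT_OUTCOME if self.latent_mode else outcome
        obs_preds = [p for p in self.predictors if p != LATENT_BASELINE]
        if not self.latent_mode and LATENT_BASELINE in self.predictors:
            raise ValueError("latent baseline requires the latent outcome")
        extra = ANXIETY_OBSERVED if self.latent_mode else [outcome]
        self._obs_cols = obs_preds + extra
        frame = data[self._obs_cols]
        frame = frame.loc[~frame.isna().all(axis=1)]
        self._frame = frame
        mu_s, sig_s, _, _ = saturated_fiml(frame.to_numpy(float))
        self._saturated = (mu_s, sig_s)
        spec = self._build_spec(obs_preds, mu_s, sig_s)
        self.model = SEMModel(spec, frame, name=name)

    # -- specification -------------------------------------------------------
    def _build_spec(self, obs_preds, mu_s, sig_s) -> SEMSpec:
        ci = {c: i for i, c in enumerate(self._obs_cols)}
        spec = SEMSpec()
        spec.add_observed(*self._obs_cols)
        for x in obs_preds:
            spec.phantom(x, var_start=sig_s[ci[x], ci[x]],
                         mean_start=mu_s[ci[x]])
        for i, a in enumerate(obs_preds):
            for b in obs_preds[i + 1:]:
                spec.covariance(a, b, start=sig_s[ci[a], ci[b]])

        if self.latent_mode:
            starts = measurement_starts(self._frame)
            _two_wave_core(spec, cov_baseline_change=False)
            add_anxiety_measurement(spec, starts)
            p13, p15 = ci["scared_parent_13"], ci["scared_parent_15"]
            var13 = 0.75 * sig_s[p13, p13]
            spec.variance(LATENT_BASELINE, start=var13)
            spec.mean(LATENT_BASELINE, start=mu_s[p13])
            for x in obs_preds:
                spec.covariance(LATENT_BASELINE, x,
                                start=0.9 * sig_s[p13, ci[x]])
            # structural starts from a least-squares solve on the saturated
            # moments, with the wave-difference of the marker as outcome proxy
            idx = [ci[x] for x in obs_preds]
            sxx = np.zeros((len(self.predictors), len(self.predictors)))
            sxy = np.zeros(len(self.predictors))
            mx = np.zeros(len(self.predictors))
            for i, a in enumerate(self.predictors):
                ia = p13 if a == LATENT_BASELINE else ci[a]
                mx[i] = mu_s[ia]
                sxy[i] = sig_s[ia, p15] - sig_s[ia, p13]
                for j, b in enumerate(self.predictors):
                    jb = p13 if b == LATENT_BASELINE else ci[b]
                    sxx[i, j] = sig_s[ia, jb]
            beta0 = np.linalg.lstsq(sxx, sxy, rcond=None)[0]
            y_var = sig_s[p13, p13] + sig_s[p15, p15] - 2 * sig_s[p13, p15]
            resid0 = max(y_var - float(sxy @ beta0), 0.1 * max(y_var, 1e-6))
            for b0, x in zip(beta0, self.predictors):
                spec.path(LATENT_OUTCOME, x, start=float(b0))
            spec.variance(LATENT_OUTCOME, start=resid0)
            spec.mean(LATENT_OUTCOME,
                      start=float(mu_s[p15] - mu_s[p13] - beta0 @ mx))
        else:
            iy = ci[self.outcome]
            idx = [ci[x] for x in obs_preds]
            sxx = sig_s[np.ix_(idx, idx)]
            sxy = sig_s[idx, iy]
            beta0 = np.linalg.lstsq(sxx, sxy, rcond=None)[0]
            resid0 = max(sig_s[iy, iy] - float(sxy @ beta0),
                         0.05 * sig_s[iy, iy])
            spec.phantom(self.outcome, var_start=resid0,
                         mean_start=float(mu_s[iy] - beta0 @ mu_s[idx]))
            for b0, x in zip(beta0, obs_preds):
                spec.path(self.outcome, x, start=float(b0))
        return spec

    # -- fitting -------------------------------------------------------------
    def fit(self, compute_se: bool = True, **kwargs) -> "BlockPathResults":
        res = self.model.fit(compute_se=compute_se, **kwargs)
        return BlockPathResults(self, res)

    # joint (predictors, outcome) covariance at a parameter vector
    def _joint_cov(self, theta) -> np.ndarray:
        mats = self.model.spec.build(np.asarray(theta, float))
        _, _, cache = implied_moments(mats)
        li = {n: i for i, n in enumerate(self.model.spec.latent)}
        sel = [li[p] for p in self.predictors] + [li[self.outcome]]
        return cache["v"][np.ix_(sel, sel)]


class BlockPathResults:
    """Results wrapper: block increments, coefficients, moderation probing."""

    def __init__(self, parent: IncrementalValidityModel, sem_results):
        self.model = parent
        self.sem = sem_results
        self.converged = sem_results.converged
        self.nobs = sem_results.nobs

    # -- low-level block statistics -----------------------------------------
    def _cum_r2(self, theta) -> np.ndarray:
        return _hierarchical_from_cov(self.model._joint_cov(theta),
                                      self.model.block_sizes)

    def _semipartial_coefs(self, theta) -> list:
        """Block-k coefficients in the regression on blocks 1..k."""
        cov = self.model._joint_cov(theta)
        out = []
        stop = 0
        k = cov.shape[0] - 1
        for m in self.model.block_sizes:
            stop += m
            beta = np.linalg.lstsq(cov[:stop, :stop], cov[:stop, k],
                                   rcond=None)[0]
            out.append(beta[stop - m:stop])
        return out

    @property
    def delta_r2(self) -> np.ndarray:
        cum = self._cum_r2(self.sem.theta)
        return np.diff(np.concatenate([[0.0], cum]))

    @property
    def cumulative_r2(self) -> np.ndarray:
        return self._cum_r2(self.sem.theta)

    @property
    def gamma(self) -> np.ndarray:
        return np.sqrt(np.clip(self.delta_r2, 0.0, None))

    # -- inference -----------------------------------------------------------
    def increments(self) -> pd.DataFrame:
        """Per-block gamma, delta-R^2, Wald test and cumulative R^2.

        Standard errors by the delta method from the observed-information
        covariance; the p-value tests gamma_k = 0 through the joint Wald
        chi-square on block k's semipartial coefficients (df = block size).
        """
        theta = self.sem.theta
        nb = len(self.model.blocks)
        dr2 = self.delta_r2
        gam = self.gamma
        cum = self.cumulative_r2
        se_g = np.full(nb, np.nan)
        pvals = np.full(nb, np.nan)
        wald = np.full(nb, np.nan)
        if self.sem.cov_theta is not None:
            jac_r2, jac_c = self._jacobians(theta)
            cov_t = self.sem.cov_theta
            var_dr2 = np.einsum("kt,ts,ks->k", jac_r2, cov_t, jac_r2)
            with np.errstate(divide="ignore", invalid="ignore"):
                se_g = np.sqrt(np.clip(var_dr2, 0, None)) / (2.0 * gam)
            coefs = self._semipartial_coefs(theta)
            # small-sample reference: the Wald statistic scaled to an F with
            # the fitted model's residual df (the chi-square reference is
            # anticonservative at n = 176 with many predictors; this is the
            # analogue of the least-squares partial F-test)
            df2 = self.nobs - len(self.model.predictors) - 1
            for k in range(nb):
                jc = jac_c[k]
                vc = jc @ cov_t @ jc.T
                ck = coefs[k]
                try:
                    w = float(ck @ np.linalg.solve(vc, ck))
                except np.linalg.LinAlgError:
                    w = float(ck @ np.linalg.pinv(vc) @ ck)
                wald[k] = w
                m = len(ck)
                if df2 > 0:
                    f_stat = w * df2 / (self.nobs * m)
                    pvals[k] = float(stats.f.sf(f_stat, m, df2))
                else:
                    pvals[k] = float(stats.chi2.sf(w, m))
        return pd.DataFrame({
            "block": [f"block{k + 1}" for k in range(nb)],
            "size": self.model.block_sizes,
            "gamma": gam, "se_gamma": se_g,
            "delta_r2": dr2, "cumulative_r2": cum,
            "wald": wald, "pvalue": pvals,
        }).set_index("block")

    def _jacobians(self, theta):
        """Numeric Jacobians of (delta-R^2 per block, semipartial coefs)."""
        theta = np.asarray(theta, float)
        nb = len(self.model.blocks)
        h = 1e-6 * np.maximum(1.0, np.abs(theta))
        jac_r2 = np.zeros((nb, len(theta)))
        jac_c = [np.zeros((m, len(theta))) for m in self.model.block_sizes]
        for i in range(len(theta)):
            tp = theta.copy(); tp[i] += h[i]
            tm = theta.copy(); tm[i] -= h[i]
            cp = np.diff(np.concatenate([[0.0], self._cum_r2(tp)]))
            cm = np.diff(np.concatenate([[0.0], self._cum_r2(tm)]))
            jac_r2[:, i] = (cp - cm) / (2 * h[i])
            sp = self._semipartial_coefs(tp)
            sm = self._semipartial_coefs(tm)
            for k in range(nb):
                jac_c[k][:, i] = (sp[k] - sm[k]) / (2 * h[i])
        return jac_r2, jac_c

    def significant_blocks(self, alpha: float = 0.05) -> list:
        tab = self.increments()
        return [b for b, row in tab.iterrows() if row["pvalue"] < alpha]

    # -- structural coefficients --------------------------------------------
    def coefficients(self) -> pd.DataFrame:
        """Unstandardized (B) and standardized (beta) outcome regressions."""
        rows = []
        tab = self.sem.params
        for x in self.model.predictors:
            key = f"{self.model.outcome}~{x}"
            row = tab.loc[key]
            rows.append({"predictor": x, "B": row["est"], "se": row["se"],
                         "z": row["z"], "pvalue": row["pvalue"],
                         "ci_low": row["ci_low"], "ci_high": row["ci_high"],
                         "beta": row["std_est"]})
        return pd.DataFrame(rows).set_index("predictor")

    def summary(self) -> str:
        lines = [self.sem.model.name, "=" * 60,
                 f"n = {self.nobs}   converged = {self.converged}",
                 "", "Block increments:", str(self.increments().round(4))]
        return "\n".join(lines)
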
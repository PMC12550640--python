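"""Synthetic two-wave cohorts with the statistical structure the analyses assume.

Three generators share one configuration:

* :func:`generate_cohort` — demographics, behavioral inhibition, latent
  anxiety at ages 13/15 with three indicators per wave, and true ROI
  activations per modality/region/wave (the ``LatentTruth``).
* :func:`generate_incremental_cohort` — a cohort whose anxiety-change factor
  carries exact population block contributions (covariates / EEG / fMRI /
  fusion) for the incremental-validity recovery study.
* :func:`generate_path_cohort` — a cohort generated from the focused fusion
  path-model coefficients (BI moderation of dACC/PCC effects).

All draws are reproducible from ``(config, seed)``.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .config import MODALITIES, REGIONS, GeneratorConfig

__all__ = [
    "generate_cohort", "generate_roi_scores", "apply_missingness",
    "generate_incremental_cohort", "generate_path_cohort",
    "incremental_blocks", "score_columns",
]

ANXIETY_COLUMNS = ["scared_parent_13", "scared_child_13", "dx_13",
                   "scared_parent_15", "scared_child_15", "dx_15"]


def score_columns(wide: bool = True) -> list:
    """Column names of the ROI score table (modality-major order)."""
    cols = []
    for mod in MODALITIES:
        for reg in REGIONS:
            cols += [f"{mod}_{reg}_13", f"{mod}_{reg}_15"]
    return cols


def _predictor_columns(mod: str) -> list:
    base = [f"{mod}_dacc_13", f"{mod}_pcc_13",
            f"{mod}_dacc_change", f"{mod}_pcc_change"]
    return base + [c + "_x_bi" for c in base]


def incremental_blocks() -> list:
    """Default four-block predictor structure of the incremental model."""
    return [["sex", "minority", "bi", "eta13"]] + \
        [_predictor_columns(mod) for mod in MODALITIES]


# ---------------------------------------------------------------------------
# basic cohort
# ---------------------------------------------------------------------------

def _draw_demographics(cfg: GeneratorConfig, rng, n):
    sex = (rng.random(n) < cfg.female_prob).astype(float)  # 1 = female
    minority = (rng.random(n) < cfg.minority_prob).astype(float)
    bi = rng.standard_normal(n)
    return sex, minority, bi


def _draw_anxiety_latents(cfg: GeneratorConfig, rng, bi):
    ax = cfg.anxiety
    n = len(bi)
    rho = cfg.bi_anxiety_corr
    s1 = np.sqrt(ax.var_eta13)
    z1 = rho * bi + np.sqrt(max(1.0 - rho ** 2, 0.0)) * rng.standard_normal(n)
    eta13 = ax.mean_eta13 + s1 * z1
    if ax.var_eta13 > 0:
        slope = ax.cov_eta13_delta / ax.var_eta13
        resid = ax.var_delta - ax.cov_eta13_delta ** 2 / ax.var_eta13
    else:
        slope, resid = 0.0, ax.var_delta
    delta = ax.mean_delta + slope * (eta13 - ax.mean_eta13) \
        + np.sqrt(max(resid, 0.0)) * rng.standard_normal(n)
    return eta13, delta


def _measure_anxiety(cfg: GeneratorConfig, rng, eta13, delta,
                     clip: bool = True) -> pd.DataFrame:
    ind = cfg.indicators
    n = len(eta13)
    out = {}
    for wave, eta in (("13", eta13), ("15", eta13 + delta)):
        parent = eta + rng.normal(0.0, np.sqrt(ind.parent_resid_var), n)
        child = ind.child_intercept + ind.child_loading * eta \
            + rng.normal(0.0, np.sqrt(ind.child_resid_var), n)
        if clip:
            parent = np.clip(np.round(parent), ind.clip_low, ind.clip_high)
            child = np.clip(np.round(child), ind.clip_low, ind.clip_high)
        dx = (rng.random(n) < expit(ind.dx_intercept + ind.dx_slope * eta)
              ).astype(float)
        out[f"scared_parent_{wave}"] = parent
        out[f"scared_child_{wave}"] = child
        out[f"dx_{wave}"] = dx
    return pd.DataFrame(out)


def generate_cohort(config: GeneratorConfig,
                    seed: Optional[int] = None
                    ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a cohort table and its latent truth.

    Returns ``(cohort, truth)``.  ``cohort`` has one row per subject with
    demographics, BI and the six anxiety indicators (SCARED scores rounded
    and clipped to [0, 82]; diagnosis binary).  ``truth`` carries the latent
    anxiety factors and the true ROI activation per modality, region and
    wave (columns ``{modality}_{region}_13`` / ``_change``).
    """
    cfg = config.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.n_subjects
    sex, minority, bi = _draw_demographics(cfg, rng, n)
    eta13, delta = _draw_anxiety_latents(cfg, rng, bi)
    ind = _measure_anxiety(cfg, rng, eta13, delta)

    corr = cfg.neural_corr.full_corr()
    z = rng.multivariate_normal(np.zeros(12), corr, size=n,
                                method="cholesky")
    truth = {"eta13": eta13, "delta": delta, "eta15": eta13 + delta}
    for m, mod in enumerate(MODALITIES):
        for r, reg in enumerate(REGIONS):
            pars = cfg.neural[(mod, reg)]
            lev = pars.mean_13 + np.sqrt(pars.var_13) * z[:, 4 * m + r]
            chg = pars.mean_change \
                + np.sqrt(pars.var_change) * z[:, 4 * m + 2 + r]
            truth[f"{mod}_{reg}_13"] = lev
            truth[f"{mod}_{reg}_change"] = chg

    subject_id = [f"s{i:04d}" for i in range(n)]
    cohort = pd.DataFrame({"subject_id": subject_id, "sex": sex,
                           "minority": minority, "bi": bi})
    cohort = pd.concat([cohort, ind], axis=1)
    truth_df = pd.DataFrame(truth)
    truth_df.insert(0, "subject_id", subject_id)
    return cohort, truth_df


def generate_roi_scores(truth: pd.DataFrame, config: GeneratorConfig,
                        seed: Optional[int] = None) -> pd.DataFrame:
    """Observed ROI score table from the latent truth (plus residual noise)."""
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    n = len(truth)
    out = {"subject_id": truth["subject_id"].to_numpy()}
    for mod in MODALITIES:
        for reg in REGIONS:
            pars = config.neural[(mod, reg)]
            sd = np.sqrt(pars.resid_var)
            lev = truth[f"{mod}_{reg}_13"].to_numpy()
            chg = truth[f"{mod}_{reg}_change"].to_numpy()
            out[f"{mod}_{reg}_13"] = lev + rng.normal(0, sd, n) \
                if sd > 0 else lev.copy()
            out[f"{mod}_{reg}_15"] = lev + chg + rng.normal(0, sd, n) \
                if sd > 0 else lev + chg
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# missingness
# ---------------------------------------------------------------------------

def _calibrated_intercept(cfg: GeneratorConfig, target: float) -> float:
    """Intercept of the MAR logistic model giving the target marginal rate."""
    mp = cfg.missing
    nodes, weights = np.polynomial.hermite_e.hermegauss(41)
    weights = weights / weights.sum()

    def marginal(a):
        tot = 0.0
        for m, pm in ((0.0, 1 - cfg.minority_prob), (1.0, cfg.minority_prob)):
            for s, ps in ((0.0, 1 - cfg.female_prob), (1.0, cfg.female_prob)):
                lo = a + mp.minority_logodds * m + mp.sex_logodds * s \
                    + mp.bi_logodds * nodes
                tot += pm * ps * float(weights @ expit(lo))
        return tot - target

    return brentq(marginal, -30.0, 30.0)


def _session_missing(cfg: GeneratorConfig, rng, sex, minority, bi,
                     rate: float) -> np.ndarray:
    if rate == 0.0:
        return np.zeros(len(bi), bool)
    mp = cfg.missing
    a = _calibrated_intercept(cfg, rate)
    p = expit(a + mp.minority_logodds * minority + mp.sex_logodds * sex
              + mp.bi_logodds * bi)
    return rng.random(len(bi)) < p


def apply_missingness(cohort: pd.DataFrame, scores: Optional[pd.DataFrame],
                      config: GeneratorConfig,
                      seed: Optional[int] = None):
    """Remove cells under a logistic MAR model on (sex, minority, BI).

    EEG and fMRI sessions go missing independently per wave at the
    configured marginal rate; a missing session removes both regions'
    scores, and fusion scores are missing whenever either constituent
    modality is.  Anxiety assessments can optionally go missing per wave.
    Returns new objects; inputs are not mutated.
    """
    cfg = config.validate()
    rng = np.random.default_rng(cfg.seed + 2 if seed is None else seed)
    cohort = cohort.copy()
    sex = cohort["sex"].to_numpy(float)
    minority = cohort["minority"].to_numpy(float)
    bi = cohort["bi"].to_numpy(float)

    if scores is not None:
        scores = scores.copy()
        for wave in ("13", "15"):
            miss = {mod: _session_missing(cfg, rng, sex, minority, bi,
                                          cfg.missing.rate)
                    for mod in ("eeg", "fmri")}
            miss["fusion"] = miss["eeg"] | miss["fmri"]
            for mod in MODALITIES:
                for reg in REGIONS:
                    col = f"{mod}_{reg}_{wave}"
                    if col in scores.columns:
                        scores.loc[miss[mod], col] = np.nan

    if cfg.missing.anxiety_rate > 0:
        for wave in ("13", "15"):
            miss = _session_missing(cfg, rng, sex, minority, bi,
                                    cfg.missing.anxiety_rate)
            for stem in ("scared_parent", "scared_child", "dx"):
                cohort.loc[miss, f"{stem}_{wave}"] = np.nan
    return cohort, scores


# ---------------------------------------------------------------------------
# block-structured generators for the recovery studies
# ---------------------------------------------------------------------------

def _neural_predictor_draw(cfg: GeneratorConfig, rng, n):
    """Z-scored baseline/change predictor draw, modality-major.

    Returns an (n, 12) array ordered (dacc13, pcc13, dacc_change,
    pcc_change) within each modality.
    """
    corr = cfg.neural_corr.full_corr()
    return rng.multivariate_normal(np.zeros(12), corr, size=n,
                                   method="cholesky"), corr


def _population_predictor_cov(cfg: GeneratorConfig, corr12) -> np.ndarray:
    """Population covariance of the 28 incremental-model predictors.

    Order: (sex, minority, bi, eta13) then per modality 4 z-scored scores
    followed by their 4 BI products.  BI is independent of the neural
    scores, so products have zero covariance with everything except other
    products, where cov(bi*s_i, bi*s_j) = cov(s_i, s_j).
    """
    s = np.zeros((28, 28))
    pf, pm = cfg.female_prob, cfg.minority_prob
    s[0, 0] = pf * (1 - pf)
    s[1, 1] = pm * (1 - pm)
    s[2, 2] = 1.0
    s[3, 3] = cfg.anxiety.var_eta13
    s[2, 3] = s[3, 2] = cfg.bi_anxiety_corr * np.sqrt(cfg.anxiety.var_eta13)
    for m in range(3):
        for m2 in range(3):
            blk = corr12[4 * m:4 * m + 4, 4 * m2:4 * m2 + 4]
            i, j = 4 + 8 * m, 4 + 8 * m2
            s[i:i + 4, j:j + 4] = blk              # scores
            s[i + 4:i + 8, j + 4:j + 8] = blk      # products
    return s


def _block_indices() -> list:
    return [list(range(4))] + [list(range(4 + 8 * m, 12 + 8 * m))
                               for m in range(3)]


def _orthogonal_block_weights(cfg: GeneratorConfig, s: np.ndarray):
    """Weights on residualized blocks hitting the target contributions.

    Block k's signal lives in the part of block k orthogonal (at the
    population level) to blocks 1..k-1, so the population hierarchical
    increment of R^2 for block k equals ``delta_r2[k]`` exactly.
    Returns (weights per block, projection matrices per block).
    """
    inc = cfg.incremental
    var_delta = cfg.anxiety.var_delta
    blocks = _block_indices()
    sds = np.sqrt(np.diag(s))
    directions = [np.asarray(inc.direction_block1, float)] + \
        [np.asarray(inc.direction_neural, float)] * 3
    weights, projections = [], []
    for k, idx in enumerate(blocks):
        d = directions[k] / sds[idx]
        if k == 0:
            a = None
            cov_z = s[np.ix_(idx, idx)]
        else:
            prev = [i for blk in blocks[:k] for i in blk]
            a = np.linalg.solve(s[np.ix_(prev, prev)],
                                s[np.ix_(prev, idx)]).T
            cov_z = s[np.ix_(idx, idx)] - a @ s[np.ix_(prev, idx)]
        target = inc.delta_r2[k] * var_delta
        base = float(d @ cov_z @ d)
        w = d * np.sqrt(target / base) if base > 0 and target > 0 else d * 0.0
        weights.append(w)
        projections.append(a)
    return weights, projections


def generate_incremental_cohort(config: GeneratorConfig,
                                seed: Optional[int] = None,
                                with_missing: bool = True):
    """Cohort for the blockwise incremental-validity recovery study.

    The anxiety-change factor is built from block-orthogonalized composites
    so its population variance decomposes over the four blocks exactly as
    ``config.incremental.delta_r2`` (fractions of ``var_delta``), with the
    remainder as residual variance.  Returns ``(frame, truth)`` where
    ``frame`` holds demographics, the 24 neural predictors (z-scored scores
    and BI products, MAR-missing when requested) and the six anxiety
    indicators.
    """
    cfg = config.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.n_subjects
    sex, minority, bi = _draw_demographics(cfg, rng, n)
    rho = cfg.bi_anxiety_corr
    s1 = np.sqrt(cfg.anxiety.var_eta13)
    eta13 = cfg.anxiety.mean_eta13 + s1 * (
        rho * bi + np.sqrt(1 - rho ** 2) * rng.standard_normal(n))
    z, corr12 = _neural_predictor_draw(cfg, rng, n)

    x = np.empty((n, 28))
    x[:, 0], x[:, 1], x[:, 2], x[:, 3] = sex, minority, bi, eta13
    for m in range(3):
        x[:, 4 + 8 * m: 8 + 8 * m] = z[:, 4 * m: 4 * m + 4]
        x[:, 8 + 8 * m: 12 + 8 * m] = z[:, 4 * m: 4 * m + 4] * bi[:, None]

    s = _population_predictor_cov(cfg, corr12)
    means = np.zeros(28)
    means[0], means[1], means[3] = cfg.female_prob, cfg.minority_prob, \
        cfg.anxiety.mean_eta13
    weights, projections = _orthogonal_block_weights(cfg, s)
    blocks = _block_indices()

    dev = x - means
    delta = np.full(n, cfg.anxiety.mean_delta)
    for k, idx in enumerate(blocks):
        zk = dev[:, idx]
        if projections[k] is not None:
            prev = [i for blk in blocks[:k] for i in blk]
            zk = zk - dev[:, prev] @ projections[k].T
        delta = delta + zk @ weights[k]
    resid_var = (1.0 - sum(cfg.incremental.delta_r2)) * cfg.anxiety.var_delta
    delta = delta + rng.normal(0.0, np.sqrt(resid_var), n)

    ind = _measure_anxiety(cfg, rng, eta13, delta)
    frame = pd.DataFrame({"sex": sex, "minority": minority, "bi": bi})
    for m, mod in enumerate(MODALITIES):
        names = _predictor_columns(mod)
        for t, name in enumerate(names):
            frame[name] = x[:, 4 + 8 * m + t]
    frame = pd.concat([frame, ind], axis=1)
    frame.insert(0, "subject_id", [f"s{i:04d}" for i in range(n)])

    if with_missing:
        frame = _mask_neural_predictors(cfg, rng, frame)
    truth = pd.DataFrame({"eta13": eta13, "delta": delta})
    return frame, truth


def _mask_neural_predictors(cfg, rng, frame: pd.DataFrame) -> pd.DataFrame:
    """Session-level MAR masking of the z-scored predictor columns.

    A missing wave-13 session removes that modality's baseline and change
    predictors; a missing wave-15 session removes the change predictors.
    Products follow their scores; fusion follows the union of EEG and fMRI.
    """
    frame = frame.copy()
    sex = frame["sex"].to_numpy(float)
    minority = frame["minority"].to_numpy(float)
    bi = frame["bi"].to_numpy(float)
    for wave in ("13", "15"):
        miss = {mod: _session_missing(cfg, rng, sex, minority, bi,
                                      cfg.missing.rate)
                for mod in ("eeg", "fmri")}
        miss["fusion"] = miss["eeg"] | miss["fmri"]
        for mod in MODALITIES:
            for reg in REGIONS:
                targets = [f"{mod}_{reg}_change", f"{mod}_{reg}_change_x_bi"]
                if wave == "13":
                    targets += [f"{mod}_{reg}_13", f"{mod}_{reg}_13_x_bi"]
                for col in targets:
                    if col in frame.columns:
                        frame.loc[miss[mod], col] = np.nan
    return frame


def generate_path_cohort(config: GeneratorConfig,
                         seed: Optional[int] = None,
                         with_missing: bool = True):
    """Cohort for the focused fusion path-model recovery study.

    The anxiety-change factor is a linear function of z-scored fusion
    dACC/PCC baseline and change scores, their BI products, covariates and
    latent baseline anxiety, with coefficients from ``config.path``
    (SCARED-change points per predictor SD).  The anxiety indicators are
    kept continuous (no 0-82 clipping): with moderation effects of the
    configured size the change factor's scale exceeds the questionnaire
    range, and clipping would distort the measurement model this study is
    probing.  Returns ``(frame, truth)``.
    """
    cfg = config.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.n_subjects
    pp = cfg.path
    sex, minority, bi = _draw_demographics(cfg, rng, n)
    rho = cfg.bi_anxiety_corr
    s1 = np.sqrt(cfg.anxiety.var_eta13)
    eta13 = cfg.anxiety.mean_eta13 + s1 * (
        rho * bi + np.sqrt(1 - rho ** 2) * rng.standard_normal(n))
    z, corr12 = _neural_predictor_draw(cfg, rng, n)
    scores = z[:, 8:12]  # fusion block, (dacc13, pcc13, dacc_chg, pcc_chg)
    products = scores * bi[:, None]

    coefs = pp.neural_coefs()
    lin = (sex - cfg.female_prob) * pp.sex \
        + (minority - cfg.minority_prob) * pp.minority \
        + bi * pp.bi + (eta13 - cfg.anxiety.mean_eta13) * pp.anxiety13 \
        + scores @ coefs[:4] + products @ coefs[4:]

    # population explained variance -> residual variance at the target R^2
    r4 = corr12[8:12, 8:12]
    pf, pm = cfg.female_prob, cfg.minority_prob
    explained = pp.sex ** 2 * pf * (1 - pf) + pp.minority ** 2 * pm * (1 - pm) \
        + pp.bi ** 2 + pp.anxiety13 ** 2 * cfg.anxiety.var_eta13 \
        + 2 * pp.bi * pp.anxiety13 * rho * s1 \
        + coefs[:4] @ r4 @ coefs[:4] + coefs[4:] @ r4 @ coefs[4:]
    resid_var = explained * (1.0 - pp.r_squared) / pp.r_squared
    delta = cfg.anxiety.mean_delta + lin \
        + rng.normal(0.0, np.sqrt(resid_var), n)

    ind = _measure_anxiety(cfg, rng, eta13, delta, clip=False)
    frame = pd.DataFrame({"sex": sex, "minority": minority, "bi": bi})
    names = _predictor_columns("fusion")
    for t in range(4):
        frame[names[t]] = scores[:, t]
        frame[names[4 + t]] = products[:, t]
    frame = pd.concat([frame, ind], axis=1)
    frame.insert(0, "subject_id", [f"s{i:04d}" for i in range(n)])
    if with_missing:
        frame = _mask_neural_predictors(cfg, rng, frame)
    truth = pd.DataFrame({"eta13": eta13, "delta": delta})
    return frame, truth
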
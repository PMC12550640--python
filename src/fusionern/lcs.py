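"""Two-wave latent change score (LCS) models.

The anxiety LCS measures a latent anxiety factor at ages 13 and 15 with
three indicators (parent SCARED as the fixed-unit marker, child SCARED, and
a binary diagnosis treated as a continuous 0/1 indicator under normal-theory
ML), constrains unstandardized loadings and intercepts to be equal across
waves (measurement invariance), and decomposes the wave-15 factor as

    eta15 = eta13 + delta,

with free mean/variance for eta13 and delta and their covariance.  The
neural LCS is the single-indicator analogue for one modality x region ROI
score with observed residual variances fixed at zero, which makes it the
FIML-consistent model of the classical difference score while retaining
subjects with a single observed wave.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .sem import SEMModel, SEMSpec

__all__ = ["build_anxiety_lcs", "build_neural_lcs", "AnxietyLCS",
           "NeuralLCS", "estimate_change_scores"]

ANXIETY_OBSERVED = ["scared_parent_13", "scared_child_13", "dx_13",
                    "scared_parent_15", "scared_child_15", "dx_15"]


def _two_wave_core(spec: SEMSpec, eta13="eta13", eta15="eta15",
                   delta="delta", cov_baseline_change=True):
    """eta15 = 1*eta13 + 1*delta; free moments for eta13 and delta.

    ``cov_baseline_change=False`` drops the free eta13-delta covariance for
    models in which the change factor is regressed on eta13 (the covariance
    is then implied by the path).
    """
    spec.add_latent(eta13, eta15, delta)
    spec.path(eta15, eta13, free=False, value=1.0)
    spec.path(eta15, delta, free=False, value=1.0)
    spec.variance(eta13)
    spec.variance(delta)
    if cov_baseline_change:
        spec.covariance(eta13, delta)
    spec.variance(eta15, free=False, value=0.0)
    spec.mean(eta13)
    spec.mean(delta)
    spec.mean(eta15, free=False, value=0.0)
    return spec


def measurement_starts(data: Optional[pd.DataFrame]) -> dict:
    """Moment-based start values for the anxiety measurement model."""
    if data is None:
        return {}
    def col(name):
        return data[name].dropna()
    p13, p15 = col("scared_parent_13"), col("scared_parent_15")
    c13, d13 = col("scared_child_13"), col("dx_13")
    both = data[["scared_parent_13", "scared_child_13"]].dropna()
    lam_child = float(np.cov(both.iloc[:, 1], both.iloc[:, 0])[0, 1]
                      / p13.var()) if len(both) > 2 else 0.9
    return {
        "mean_eta13": float(p13.mean()),
        "mean_delta": float(p15.mean() - p13.mean()),
        "var_eta13": 0.7 * float(p13.var()),
        "var_delta": 0.15 * float(p13.var() + p15.var()),
        "lam_child": lam_child,
        "nu_child": float(c13.mean()) - lam_child * float(p13.mean()),
        "lam_dx": 0.02,
        "nu_dx": float(d13.mean()) - 0.02 * float(p13.mean()),
        "theta": {f"{stem}_{wave}": 0.3 * float(col(f"{stem}_{wave}").var())
                  for stem in ("scared_parent", "scared_child")
                  for wave in ("13", "15")}
        | {f"dx_{wave}": 0.8 * float(col(f"dx_{wave}").var())
           for wave in ("13", "15")},
    }


def add_anxiety_measurement(spec: SEMSpec, starts: Optional[dict] = None):
    """Loadings, intercepts and residuals of the six anxiety indicators.

    Parent SCARED is the fixed-unit, zero-intercept marker at both waves;
    child SCARED and diagnosis loadings/intercepts are constrained equal
    across waves (measurement invariance).  Latents ``eta13``/``eta15`` must
    already exist on the spec.
    """
    starts = starts or {}
    theta_starts = starts.get("theta", {})
    for wave, eta in (("13", "eta13"), ("15", "eta15")):
        spec.loading(f"scared_parent_{wave}", eta, free=False, value=1.0)
        spec.loading(f"scared_child_{wave}", eta, label="lam_child",
                     start=starts.get("lam_child", 0.9))
        spec.loading(f"dx_{wave}", eta, label="lam_dx",
                     start=starts.get("lam_dx", 0.02))
        spec.intercept(f"scared_parent_{wave}", free=False, value=0.0)
        spec.intercept(f"scared_child_{wave}", label="nu_child",
                       start=starts.get("nu_child"))
        spec.intercept(f"dx_{wave}", label="nu_dx",
                       start=starts.get("nu_dx", 0.2))
        for stem in ("scared_parent", "scared_child", "dx"):
            spec.variance(f"{stem}_{wave}",
                          start=theta_starts.get(f"{stem}_{wave}"))
    return spec


def build_anxiety_lcs(data: Optional[pd.DataFrame] = None) -> SEMSpec:
    """Anxiety LCS specification (optionally with moment-based starts).

    Free parameters: 2 invariant loadings, 2 invariant intercepts, 6
    residual variances, and the 5 latent moments — 15 in all against the 27
    observed moments of the 6 indicators, hence 12 degrees of freedom.
    """
    spec = SEMSpec()
    spec.add_observed(*ANXIETY_OBSERVED)
    _two_wave_core(spec)
    starts = measurement_starts(data)
    add_anxiety_measurement(spec, starts)
    spec.mean("eta13", start=starts.get("mean_eta13"))
    spec.mean("delta", start=starts.get("mean_delta"))
    spec.variance("eta13", start=starts.get("var_eta13"))
    spec.variance("delta", start=starts.get("var_delta"))
    return spec


def build_neural_lcs(modality: str, region: str,
                     data: Optional[pd.DataFrame] = None) -> SEMSpec:
    """Single-indicator two-wave LCS for one modality x region ROI score.

    Identified by fixing both observed residual variances to zero; with
    complete data the estimated change mean equals the sample mean of
    (wave15 - wave13) exactly.
    """
    c13, c15 = f"{modality}_{region}_13", f"{modality}_{region}_15"
    spec = SEMSpec()
    spec.add_observed(c13, c15)
    _two_wave_core(spec, eta13="level13", eta15="level15", delta="change")
    spec.loading(c13, "level13", free=False, value=1.0)
    spec.loading(c15, "level15", free=False, value=1.0)
    spec.intercept(c13, free=False, value=0.0)
    spec.intercept(c15, free=False, value=0.0)
    spec.variance(c13, free=False, value=0.0)
    spec.variance(c15, free=False, value=0.0)
    if data is not None:
        x13, x15 = data[c13], data[c15]
        both = (x15 - x13).dropna()
        dvar = both.var() if len(both) > 2 else \
            x13.var(skipna=True) + x15.var(skipna=True)
        spec.mean("level13", start=float(x13.mean(skipna=True)))
        spec.mean("change", start=float(both.mean()) if len(both) else 0.0)
        spec.variance("level13",
                      start=float(max(x13.var(skipna=True), 1e-4)))
        spec.variance("change", start=float(max(dvar, 1e-4)))
        spec.covariance("level13", "change", start=0.0)
    return spec


class AnxietyLCS:
    """Convenience constructor: ``AnxietyLCS.from_dataframe(df).fit()``."""

    @staticmethod
    def from_dataframe(data: pd.DataFrame) -> SEMModel:
        return SEMModel(build_anxiety_lcs(data), data, name="anxiety LCS")


class NeuralLCS:
    @staticmethod
    def from_dataframe(data: pd.DataFrame, modality: str,
                       region: str) -> SEMModel:
        return SEMModel(build_neural_lcs(modality, region, data), data,
                        name=f"neural LCS ({modality}, {region})")


def estimate_change_scores(scores: pd.DataFrame,
                           modalities=("eeg", "fmri", "fusion"),
                           regions=("dacc", "pcc"),
                           compute_se: bool = False):
    """Fit the six neural LCS models and extract per-subject factor scores.

    Returns ``(table, fits)``.  ``table`` has, per modality x region, the
    baseline score (``{m}_{r}_13``), the change score (``{m}_{r}_change``)
    and a ``{m}_{r}_model_based`` flag marking subjects whose score is a
    conditional (shrunken) estimate because a wave was missing.  For
    complete subjects the zero-residual constraint makes the change score
    the observed wave difference exactly.
    """
    out = pd.DataFrame(index=scores.index)
    if "subject_id" in scores.columns:
        out["subject_id"] = scores["subject_id"]
    fits = {}
    for mod in modalities:
        for reg in regions:
            c13, c15 = f"{mod}_{reg}_13", f"{mod}_{reg}_15"
            model = NeuralLCS.from_dataframe(scores, mod, reg)
            res = model.fit(compute_se=compute_se)
            fits[(mod, reg)] = res
            fs = res.factor_scores().reindex(scores.index)
            out[f"{mod}_{reg}_13"] = fs["level13"]
            out[f"{mod}_{reg}_change"] = fs["change"]
            observed = scores[[c13, c15]].notna()
            out[f"{mod}_{reg}_model_based"] = (
                fs["change"].notna() & ~(observed[c13] & observed[c15]))
    return out, fits
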
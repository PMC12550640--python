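"""Focused fusion path model and simple-slopes moderation probing.

After the incremental model identifies which neural block adds explained
variance, a focused path model regresses the latent anxiety-change factor on
the covariates, baseline anxiety, that block's baseline/change ROI scores
and their BI interactions.  Significant interactions are probed with simple
slopes at -1 SD / mean / +1 SD of the (z-scored) moderator, with
delta-method standard errors from the coefficient covariance.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .incremental import IncrementalValidityModel, BlockPathResults

__all__ = ["FinalPathModel", "conditional_slope", "simple_slopes",
           "plot_simple_slopes"]

Z95 = 1.959963984540054

COVARIATE_BLOCK = ["sex", "minority", "bi", "eta13"]


def _neural_block(modality: str) -> list:
    base = [f"{modality}_dacc_13", f"{modality}_pcc_13",
            f"{modality}_dacc_change", f"{modality}_pcc_change"]
    return base + [c + "_x_bi" for c in base]


def conditional_slope(b_focal: float, b_interaction: float,
                      moderator_value: float,
                      sd_moderator: float = 1.0) -> float:
    """Slope of the focal predictor at a fixed moderator value.

    With a z-scored moderator (SD 1), the slope at +/-1 SD is the mean-level
    slope plus/minus the interaction coefficient.
    """
    return b_focal + moderator_value * sd_moderator * b_interaction


class FinalPathModel(IncrementalValidityModel):
    """Path model for one neural modality (default: EEG-fMRI fusion).

    A thin configuration of the blockwise model with two blocks —
    covariates (sex, minority status, BI, baseline anxiety) and the chosen
    modality's ROI scores plus BI interactions — reported through its
    unstandardized (B) and standardized (beta) coefficients rather than
    block increments.
    """

    def __init__(self, data: pd.DataFrame, modality: str = "fusion",
                 outcome: str = "latent",
                 extra_covariates: Sequence[str] = ()):
        self.modality = modality
        block1 = COVARIATE_BLOCK + list(extra_covariates)
        if outcome != "latent":
            block1 = [c if c != "eta13" else "anxiety13" for c in block1]
        super().__init__(data, [block1, _neural_block(modality)],
                         outcome=outcome,
                         name=f"final path model ({modality})")

    def fit(self, compute_se: bool = True, **kwargs) -> "FinalPathResults":
        res = self.model.fit(compute_se=compute_se, **kwargs)
        return FinalPathResults(self, res)


class FinalPathResults(BlockPathResults):
    def simple_slopes(self, focal: str, moderator: str = "bi",
                      levels: Sequence[float] = (-1.0, 0.0, 1.0)
                      ) -> pd.DataFrame:
        return simple_slopes(self, focal, moderator, levels)

    def summary(self) -> str:
        lines = [self.sem.model.name, "=" * 60,
                 f"n = {self.nobs}   converged = {self.converged}", "",
                 "Coefficients on the anxiety-change outcome:",
                 str(self.coefficients().round(4))]
        return "\n".join(lines)


def simple_slopes(results: BlockPathResults, focal: str,
                  moderator: str = "bi",
                  levels: Sequence[float] = (-1.0, 0.0, 1.0)) -> pd.DataFrame:
    """Conditional effects of ``focal`` at fixed moderator levels (in SD).

    Requires the fitted model to contain both the focal main effect and the
    ``<focal>_x_<moderator>`` product term.  The moderator is assumed
    z-scored (the convention of the analysis table builders), so levels are
    in SD units.  Var(slope) = Var(b_f) + m^2 Var(b_i) + 2 m Cov(b_f, b_i).
    """
    sem = results.sem
    outcome = results.model.outcome
    name_f = f"{outcome}~{focal}"
    name_i = f"{outcome}~{focal}_x_{moderator}"
    tab = sem.params
    if name_i not in tab.index:
        raise KeyError(f"model has no interaction term {name_i!r}")
    if sem.cov_theta is None:
        raise ValueError("fit with compute_se=True to probe simple slopes")
    idx = {n: k for k, n in enumerate(sem.model.spec.param_names)}
    i_f, i_i = idx[name_f], idx[name_i]
    b_f, b_i = sem.theta[i_f], sem.theta[i_i]
    v_f = sem.cov_theta[i_f, i_f]
    v_i = sem.cov_theta[i_i, i_i]
    c_fi = sem.cov_theta[i_f, i_i]
    rows = []
    for m in levels:
        slope = conditional_slope(b_f, b_i, m)
        var = v_f + m * m * v_i + 2.0 * m * c_fi
        se = np.sqrt(var) if var > 0 else np.nan
        z = slope / se
        rows.append({"moderator_sd": m, "slope": slope, "se": se, "z": z,
                     "pvalue": 2 * stats.norm.sf(abs(z)),
                     "ci_low": slope - Z95 * se,
                     "ci_high": slope + Z95 * se})
    return pd.DataFrame(rows).set_index("moderator_sd")


def plot_simple_slopes(results: BlockPathResults, focal: str,
                       moderator: str = "bi", ax=None,
                       levels: Sequence[float] = (-1.0, 1.0)):
    """Crossover plot of predicted anxiety change against the focal score."""
    import matplotlib.pyplot as plt

    tab = simple_slopes(results, focal, moderator, levels=levels)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    x = np.linspace(-2, 2, 50)
    for m, row in tab.iterrows():
        label = f"{moderator} = {m:+.0f} SD"
        ax.plot(x, row["slope"] * x, label=label)
    ax.set_xlabel(f"{focal} (z)")
    ax.set_ylabel("predicted anxiety change (centered)")
    ax.legend(frameon=False)
    ax.axhline(0.0, color="0.8", lw=0.8)
    return ax
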
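"""Configuration dataclasses for the synthetic cohort generators.

Defaults encode the study conditions the models assume: a two-wave cohort of
176 adolescents (52.3% female), latent anxiety measured by parent SCARED,
child SCARED and a binary diagnosis, a standard-normal behavioral-inhibition
(BI) moderator, error-related dACC/PCC activity for three modalities (EEG,
fMRI, EEG-fMRI fusion), and MAR missingness on neural data elevated for
minority-status participants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np

MODALITIES = ("eeg", "fmri", "fusion")
REGIONS = ("dacc", "pcc")

__all__ = [
    "MODALITIES", "REGIONS", "AnxietyParams", "IndicatorParams",
    "NeuralRegionParams", "NeuralCorrParams", "MissingParams",
    "IncrementalGenParams", "FinalPathParams", "GeometryParams",
    "EpochParams", "GeneratorConfig",
]


class ConfigError(ValueError):
    pass


@dataclass
class AnxietyParams:
    """Latent anxiety (SCARED units): baseline factor and change factor."""
    mean_eta13: float = 22.0
    var_eta13: float = 49.0
    mean_delta: float = -0.76
    var_delta: float = 14.30
    cov_eta13_delta: float = -5.0

    def covariance(self) -> np.ndarray:
        return np.array([[self.var_eta13, self.cov_eta13_delta],
                         [self.cov_eta13_delta, self.var_delta]])

    def validate(self):
        if self.var_eta13 < 0 or self.var_delta < 0:
            raise ConfigError("anxiety variances must be non-negative")
        if np.min(np.linalg.eigvalsh(self.covariance())) < -1e-12:
            raise ConfigError(
                "anxiety (eta13, delta) covariance matrix is not positive "
                "semidefinite")


@dataclass
class IndicatorParams:
    """Measurement model for the three anxiety indicators per wave."""
    child_loading: float = 0.9
    child_intercept: float = 2.0
    parent_resid_var: float = 16.0
    child_resid_var: float = 16.0
    # binary diagnosis via a logistic link on latent anxiety; the default
    # intercept gives roughly 20% prevalence at the default latent mean
    dx_slope: float = 0.15
    dx_intercept: float = -4.686
    clip_low: float = 0.0
    clip_high: float = 82.0

    def validate(self):
        if self.parent_resid_var < 0 or self.child_resid_var < 0:
            raise ConfigError("residual variances must be non-negative")


@dataclass
class NeuralRegionParams:
    """Two-wave ROI activation: baseline level and latent change."""
    mean_13: float = 0.5
    mean_change: float = 0.15
    var_13: float = 0.25
    var_change: float = 0.20
    resid_var: float = 0.0  # measurement noise on the ROI score

    def validate(self):
        if min(self.var_13, self.var_change, self.resid_var) < 0:
            raise ConfigError("neural variances must be non-negative")


def _default_neural() -> Dict[Tuple[str, str], NeuralRegionParams]:
    # fusion values chosen so the generating standardized change equals the
    # reference estimates (0.17/sqrt(v) = 0.37 for dACC, 0.18/sqrt(v) = 0.43
    # for PCC); EEG/fMRI use comparable magnitudes
    out = {}
    for mod in MODALITIES:
        for reg in REGIONS:
            out[(mod, reg)] = NeuralRegionParams()
    out[("fusion", "dacc")] = NeuralRegionParams(
        mean_change=0.17, var_change=(0.17 / 0.37) ** 2)
    out[("fusion", "pcc")] = NeuralRegionParams(
        mean_change=0.18, var_change=(0.18 / 0.43) ** 2)
    return out


@dataclass
class NeuralCorrParams:
    """Cross-correlation structure of ROI scores (Kronecker construction)."""
    eeg_fmri: float = 0.3
    eeg_fusion: float = 0.5
    fmri_fusion: float = 0.5
    region: float = 0.3         # dACC-PCC, same wave/type
    level_change: float = -0.2  # baseline level vs change, same region

    def modality_corr(self) -> np.ndarray:
        m = np.array([[1.0, self.eeg_fmri, self.eeg_fusion],
                      [self.eeg_fmri, 1.0, self.fmri_fusion],
                      [self.eeg_fusion, self.fmri_fusion, 1.0]])
        return m

    def region_type_corr(self) -> np.ndarray:
        r, lc = self.region, self.level_change
        # order: (dacc level, pcc level, dacc change, pcc change)
        return np.array([[1.0, r, lc, 0.0],
                         [r, 1.0, 0.0, lc],
                         [lc, 0.0, 1.0, r],
                         [0.0, lc, r, 1.0]])

    def full_corr(self) -> np.ndarray:
        """12 x 12 correlation of z-scored scores, modality-major order."""
        c = np.kron(self.modality_corr(), self.region_type_corr())
        if np.min(np.linalg.eigvalsh(c)) < -1e-12:
            raise ConfigError("neural cross-correlation matrix is not PSD")
        return c


@dataclass
class MissingParams:
    """Logistic MAR model on fully observed covariates (sex, minority, BI)."""
    rate: float = 0.14            # marginal rate per modality x wave session
    minority_logodds: float = 0.7
    bi_logodds: float = 0.15
    sex_logodds: float = 0.0
    anxiety_rate: float = 0.0     # per-wave anxiety assessment missingness

    def validate(self):
        for r in (self.rate, self.anxiety_rate):
            if not (0.0 <= r < 1.0):
                raise ConfigError(f"missing rate {r} outside [0, 1)")


@dataclass
class IncrementalGenParams:
    """Generating structure of the blockwise incremental-validity study.

    ``delta_r2`` are the population semipartial variance contributions of the
    four predictor blocks (covariates; EEG; fMRI; fusion) as fractions of the
    anxiety-change variance.  ``direction_*`` set the within-block
    composition of the signal; magnitudes are rescaled to hit ``delta_r2``
    exactly at the population level.
    """
    delta_r2: Tuple[float, float, float, float] = (0.54, 0.01, 0.01, 0.25)
    # (sex, minority, BI, baseline anxiety), on standardized scales
    direction_block1: Tuple[float, ...] = (0.1, 0.1, -0.3, -0.9)
    # (dacc13, pcc13, dacc_change, pcc_change, and the 4 BI products), shaped
    # like the focused path-model coefficient pattern
    direction_neural: Tuple[float, ...] = (
        1.29, 0.5, -4.90, 2.58, 8.77, 0.0, 0.0, -16.89)

    def validate(self):
        if any(r < 0 for r in self.delta_r2) or sum(self.delta_r2) > 1.0:
            raise ConfigError("block delta-R2 values must be >= 0 and sum <= 1")


@dataclass
class FinalPathParams:
    """Generating coefficients of the focused fusion path model.

    Units: SCARED points of anxiety change per SD of the (z-scored)
    predictor.  Neural coefficients follow the reference estimates; the
    covariate effects and the total explained fraction (R^2 = 0.81, matching
    the cumulative incremental model) are package choices.
    """
    sex: float = 0.5
    minority: float = 0.5
    bi: float = 1.0
    anxiety13: float = -0.25        # per SCARED point of baseline anxiety
    dacc_13: float = 1.29
    pcc_13: float = 0.5
    dacc_change: float = -4.90
    pcc_change: float = 2.58
    bi_x_dacc_13: float = 8.77
    bi_x_pcc_13: float = 0.0
    bi_x_dacc_change: float = 0.0
    bi_x_pcc_change: float = -16.89
    r_squared: float = 0.81

    def neural_coefs(self) -> np.ndarray:
        return np.array([self.dacc_13, self.pcc_13, self.dacc_change,
                         self.pcc_change, self.bi_x_dacc_13, self.bi_x_pcc_13,
                         self.bi_x_dacc_change, self.bi_x_pcc_change])


@dataclass
class GeometryParams:
    """Shared bounding box for the tetrahedral source mesh and voxel grid."""
    grid_shape: Tuple[int, int, int] = (18, 18, 12)
    voxel_size_mm: float = 3.0
    mesh_cube_mm: float = 6.0  # cube edge; each cube splits into 5 tetrahedra
    # ROI boxes in voxel indices (start, stop) per axis; the defaults are
    # aligned with the mesh-cube lattice so each ROI is tiled exactly by
    # whole elements and the zero-noise fusion round trip is exact
    dacc_box: Tuple[Tuple[int, int], ...] = ((4, 8), (10, 14), (4, 8))
    pcc_box: Tuple[Tuple[int, int], ...] = ((10, 14), (2, 6), (4, 8))
    cdr_noise_sd: float = 0.0
    contrast_noise_sd: float = 0.0


@dataclass
class EpochParams:
    sampling_rate: float = 250.0
    t_min_ms: float = -100.0
    t_max_ms: float = 300.0
    channels: Tuple[str, ...] = ("Fz", "FCz", "Cz", "F3", "F4", "Pz", "P3", "P4")
    frontocentral: Tuple[str, ...] = ("Fz", "FCz", "Cz")
    ern_latency_ms: float = 50.0
    ern_width_ms: float = 20.0
    ern_gain: float = -5.0      # microvolt per unit of true dACC activation
    noise_sd: float = 4.0
    n_error_trials: int = 20
    n_correct_trials: int = 40


@dataclass
class GeneratorConfig:
    n_subjects: int = 176
    seed: int = 0
    female_prob: float = 0.523
    minority_prob: float = 0.244
    bi_anxiety_corr: float = 0.25
    anxiety: AnxietyParams = field(default_factory=AnxietyParams)
    indicators: IndicatorParams = field(default_factory=IndicatorParams)
    neural: Dict[Tuple[str, str], NeuralRegionParams] = field(
        default_factory=_default_neural)
    neural_corr: NeuralCorrParams = field(default_factory=NeuralCorrParams)
    missing: MissingParams = field(default_factory=MissingParams)
    incremental: IncrementalGenParams = field(
        default_factory=IncrementalGenParams)
    path: FinalPathParams = field(default_factory=FinalPathParams)
    geometry: GeometryParams = field(default_factory=GeometryParams)
    epochs: EpochParams = field(default_factory=EpochParams)

    def validate(self) -> "GeneratorConfig":
        for p in (self.female_prob, self.minority_prob):
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"probability {p} outside [0, 1]")
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be positive")
        self.anxiety.validate()
        self.indicators.validate()
        for v in self.neural.values():
            v.validate()
        self.neural_corr.full_corr()
        self.missing.validate()
        self.incremental.validate()
        return self
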
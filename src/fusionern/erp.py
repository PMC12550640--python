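"""Condition ERPs, the error-minus-correct difference wave and the ERN peak.

The error-related negativity (ERN) is a frontocentral negative-going
deflection shortly after an erroneous button response.  The participant- and
wave-specific peak latency of the difference wave (incongruent-error minus
incongruent-correct) selects the source map used downstream; "maximal" ERN
is read as the most negative cluster-mean value, with ties broken by the
earliest time point so output is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np

__all__ = ["EpochSet", "ERPWave", "baseline_correct", "average_erp",
           "difference_wave", "find_ern_peak"]

ERROR, CORRECT = "inc_error", "inc_correct"


@dataclass
class EpochSet:
    """Epoched single-trial EEG around the button response.

    ``data`` is (channels, time, trials) in microvolt; ``time_ms`` is
    strictly increasing and relative to the response; ``condition`` labels
    each trial (``inc_error`` / ``inc_correct``).
    """
    sampling_rate: float
    time_ms: np.ndarray
    channels: Tuple[str, ...]
    data: np.ndarray
    condition: np.ndarray

    def __post_init__(self):
        self.time_ms = np.asarray(self.time_ms, float)
        self.data = np.asarray(self.data, float)
        self.condition = np.asarray(self.condition)
        if self.data.shape != (len(self.channels), len(self.time_ms),
                               len(self.condition)):
            raise ValueError("data must be (channels, time, trials)")
        if np.any(np.diff(self.time_ms) <= 0):
            raise ValueError("time axis must be strictly increasing")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite amplitudes")

    def n_trials(self, condition: str) -> int:
        return int(np.sum(self.condition == condition))


@dataclass
class ERPWave:
    condition: str
    channels: Tuple[str, ...]
    time_ms: np.ndarray
    data: np.ndarray  # (channels, time), microvolt
    n_trials: int


def _window_index(time_ms: np.ndarray, window) -> np.ndarray:
    lo, hi = window
    idx = np.where((time_ms >= lo) & (time_ms <= hi))[0]
    if len(idx) == 0:
        raise ValueError(f"window {window} does not intersect the time axis")
    return idx


def baseline_correct(epochs: EpochSet, window) -> EpochSet:
    """Subtract each trial/channel's mean over the baseline window."""
    idx = _window_index(epochs.time_ms, window)
    base = epochs.data[:, idx, :].mean(axis=1, keepdims=True)
    return EpochSet(epochs.sampling_rate, epochs.time_ms, epochs.channels,
                    epochs.data - base, epochs.condition)


def average_erp(epochs: EpochSet, condition: str) -> ERPWave:
    """Pointwise mean over trials of one condition."""
    sel = epochs.condition == condition
    n = int(sel.sum())
    if n == 0:
        raise ValueError(f"no trials of condition {condition!r}")
    return ERPWave(condition, epochs.channels, epochs.time_ms,
                   epochs.data[:, :, sel].mean(axis=2), n)


def difference_wave(err: ERPWave, corr: ERPWave) -> ERPWave:
    """Error minus correct, pointwise, on matching axes."""
    if err.channels != corr.channels or \
            not np.array_equal(err.time_ms, corr.time_ms):
        raise ValueError("ERP channel/time axes do not match")
    return ERPWave("difference", err.channels, err.time_ms,
                   err.data - corr.data, min(err.n_trials, corr.n_trials))


def find_ern_peak(diff: ERPWave, cluster: Sequence[str],
                  window=(0.0, 100.0)) -> Tuple[float, float]:
    """Latency (ms) and amplitude (microvolt) of the ERN peak.

    The peak is the most negative cluster-mean difference within the search
    window; at ties the earliest sample wins.
    """
    if len(cluster) == 0:
        raise ValueError("empty channel cluster")
    missing = [c for c in cluster if c not in diff.channels]
    if missing:
        raise ValueError(f"cluster channels {missing} absent from data")
    rows = [diff.channels.index(c) for c in cluster]
    idx = _window_index(diff.time_ms, window)
    trace = diff.data[rows][:, idx].mean(axis=0)
    k = int(np.argmin(trace))  # argmin returns the first (earliest) minimum
    return float(diff.time_ms[idx[k]]), float(trace[k])
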
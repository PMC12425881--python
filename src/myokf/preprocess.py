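"""EMG feature construction: filtering, channel expansion, MAV, baseline
subtraction and reaction-time alignment.

The fixed pipeline order for raw 1-kHz recordings is
filter_raw -> expand_channels -> compute_mav -> subtract_baseline ->
align_lag.  Differential pairs are formed on the time-domain signals before
rectification (MAV of a difference is not the difference of MAVs); when the
input is already MAV-level, expand_channels is applied to the MAV signals
directly and the filtering/MAV stages are skipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .movements import REST

__all__ = [
    "FeatureConfig",
    "AlignResult",
    "filter_raw",
    "expand_channels",
    "compute_mav",
    "subtract_baseline",
    "align_lag",
]


@dataclass(frozen=True)
class FeatureConfig:
    """Front-end parameters: 15-375 Hz band-pass, 60/120/180 Hz notches,
    trailing 300-ms MAV windows emitted at 30 Hz."""

    mav_window_ms: float = 300.0
    out_rate_hz: float = 30.0
    bandpass_hz: tuple[float, float] = (15.0, 375.0)
    notch_hz: tuple[float, ...] = (60.0, 120.0, 180.0)
    raw_rate_hz: float = 1000.0
    max_lag_ms: float = 500.0
    notch_q: float = 30.0

    def __post_init__(self) -> None:
        lo, hi = self.bandpass_hz
        if not 0 < lo < hi < self.raw_rate_hz / 2:
            raise ValueError("bandpass must satisfy 0 < low < high < raw_rate/2")
        if self.mav_window_ms <= 1000.0 / self.out_rate_hz:
            raise ValueError("MAV window must exceed one output-sample period")


# Causal filters need this many samples before their output is meaningful.
_FILTER_WARMUP = 64


def filter_raw(raw: np.ndarray, config: FeatureConfig = FeatureConfig()) -> np.ndarray:
    """Band-pass then notch-filter each channel (causal, forward-only).

    4th-order Butterworth band-pass followed by 2nd-order IIR notches.
    """
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    if raw.shape[0] < _FILTER_WARMUP:
        raise ValueError(
            f"need at least {_FILTER_WARMUP} samples for filter warm-up, got {raw.shape[0]}"
        )
    sos = sps.butter(4, config.bandpass_hz, btype="bandpass", fs=config.raw_rate_hz, output="sos")
    out = sps.sosfilt(sos, raw, axis=0)
    for f0 in config.notch_hz:
        b, a = sps.iirnotch(f0, config.notch_q, fs=config.raw_rate_hz)
        out = sps.lfilter(b, a, out, axis=0)
    return out


def expand_channels(signals: np.ndarray, names: list[str] | None = None):
    """Append all pairwise differences (i < j: signal_i - signal_j).

    n single-ended channels become n + n(n-1)/2 columns (32 -> 528).
    Returns (expanded, column_names).
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    n = signals.shape[1]
    if n < 1:
        raise ValueError("need at least one channel")
    if names is None:
        names = [f"e{i:02d}" for i in range(n)]
    if len(names) != n:
        raise ValueError("names must match channel count")
    i, j = np.triu_indices(n, k=1)
    expanded = np.hstack([signals, signals[:, i] - signals[:, j]])
    out_names = list(names) + [f"{names[a]}-{names[b]}" for a, b in zip(i, j)]
    return expanded, out_names


def compute_mav(
    signals: np.ndarray, config: FeatureConfig = FeatureConfig()
) -> np.ndarray:
    """Trailing-window mean absolute value, emitted at out_rate_hz.

    Output sample i is the mean of |signal| over the mav_window_ms ending at
    raw time (i+1)/out_rate_hz; early windows shrink to the available
    history.
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    t_raw = signals.shape[0]
    if t_raw == 0:
        raise ValueError("empty input")
    w = int(round(config.mav_window_ms / 1000.0 * config.raw_rate_hz))
    if w < 2:
        raise ValueError("MAV window must span at least 2 raw samples")
    step = config.raw_rate_hz / config.out_rate_hz
    n_out = int(np.floor(t_raw / step + 1e-9))
    ends = np.minimum(np.round(np.arange(1, n_out + 1) * step).astype(int) - 1, t_raw - 1)
    starts = np.maximum(ends - w + 1, 0)
    csum = np.vstack([np.zeros((1, signals.shape[1])), np.cumsum(np.abs(signals), axis=0)])
    return (csum[ends + 1] - csum[starts]) / (ends - starts + 1)[:, None]


def subtract_baseline(features: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Subtract the per-channel mean resting MAV (negatives are permitted)."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    rest = np.asarray(labels, dtype=object) == REST
    if not np.any(rest):
        raise ValueError("no REST-labeled samples to estimate the baseline from")
    return features - features[rest].mean(axis=0, keepdims=True)


@dataclass
class AlignResult:
    """Reaction-time alignment: kinematics (and labels) delayed by lag_ms."""

    kinematics: np.ndarray
    lag_ms: float
    labels: np.ndarray | None = None
    degenerate: bool = False


def align_lag(
    kinematics: np.ndarray,
    features: np.ndarray,
    config: FeatureConfig = FeatureConfig(),
    labels: np.ndarray | None = None,
) -> AlignResult:
    """Estimate one reaction-time lag per session and shift the kinematics.

    The lag (in whole output samples, searched over [0, max_lag_ms])
    maximizes the summed-over-axes correlation between |kinematics| and the
    feature envelope (features summed across channels).  The kinematics and
    labels are then delayed by that lag, the vacated leading samples padded
    with rest.
    """
    kinematics = np.atleast_2d(np.asarray(kinematics, dtype=float))
    features = np.atleast_2d(np.asarray(features, dtype=float))
    t = kinematics.shape[0]
    rate = config.out_rate_hz
    max_lag = int(round(config.max_lag_ms / 1000.0 * rate))
    if t <= 2 * max_lag:
        raise ValueError("recording shorter than twice the lag search bound")
    env = features.sum(axis=1)
    kin_mag = np.abs(kinematics)

    degenerate = env.std() < 1e-12 or kin_mag.std() < 1e-12
    lag = 0
    if not degenerate:
        best = -np.inf
        for cand in range(max_lag + 1):
            e = env[cand:] if cand else env
            score = 0.0
            for d in range(kin_mag.shape[1]):
                k = kin_mag[: t - cand, d]
                if k.std() < 1e-12 or e.std() < 1e-12:
                    continue
                score += float(np.corrcoef(k, e)[0, 1])
            if score > best + 1e-12:
                best = score
                lag = cand
    else:
        warnings.warn("degenerate (constant) inputs; returning lag 0", stacklevel=2)

    if lag:
        kin_shift = np.vstack([np.zeros((lag, kinematics.shape[1])), kinematics[:-lag]])
    else:
        kin_shift = kinematics.copy()
    labels_shift = None
    if labels is not None:
        labels = np.asarray(labels, dtype=object)
        labels_shift = (
            np.concatenate([np.full(lag, REST, dtype=object), labels[: t - lag]])
            if lag
            else labels.copy()
        )
    return AlignResult(
        kinematics=kin_shift,
        lag_ms=lag * 1000.0 / rate,
        labels=labels_shift,
        degenerate=degenerate,
    )
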
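"""Synthetic paretic-EMG session generator.

Emulates offline data-collection sessions in which a participant mimics
cued hand/wrist movements while 32-electrode surface EMG is recorded.  The
generator emits 30-Hz mean-absolute-value (MAV) features directly: each
movement drives a distinct synergy (a non-negative electrode weighting),
scaled by the instructed trapezoidal envelope, with paretic co-activation
bleeding a fraction of that envelope onto the other movements' synergies,
a per-channel resting baseline, a reaction-time lag of the EMG relative to
the cue, multiplicative between-session gain drift, and additive noise.
An optional raw mode emits 1-kHz amplitude-modulated band-limited noise
per electrode for exercising the filtering front end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .movements import (
    DOF_AXES,
    MOVEMENT_CODES,
    REST,
    TrialProtocol,
    axis_index,
    get_movement,
)

__all__ = [
    "SynthConfig",
    "SessionRecording",
    "generate_target_kinematics",
    "generate_synergies",
    "generate_session",
    "generate_participant",
    "generate_raw_emg",
]


@dataclass
class SynthConfig:
    """Generative parameters for one synthetic participant.

    noise_sd, baseline and the synergy weights are in MAV units on a scale
    where a movement held at its peak drives its dominant electrodes at
    roughly 0.5-1.5.  crosstalk is the fraction of the active movement's
    envelope co-activating every other movement's synergy (and, in the
    synergy matrix itself, the fraction of diffuse spatial mixing).
    """

    n_electrodes: int = 32
    synergy_matrix: np.ndarray | None = None
    crosstalk: float = 0.2
    noise_sd: float = 0.05
    baseline: float | np.ndarray = 0.1
    lag_ms: float = 200.0
    session_gain_sd: float = 0.1
    movement_gains: dict[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_electrodes < 2:
            raise ValueError("n_electrodes must be >= 2")
        if not 0.0 <= self.crosstalk <= 1.0:
            raise ValueError("crosstalk must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if np.any(np.asarray(self.baseline) < 0):
            raise ValueError("baseline must be >= 0")
        if self.lag_ms < 0:
            raise ValueError("lag_ms must be >= 0")
        if self.session_gain_sd < 0:
            raise ValueError("session_gain_sd must be >= 0")
        if self.synergy_matrix is not None:
            s = np.asarray(self.synergy_matrix, dtype=float)
            if s.shape != (len(MOVEMENT_CODES), self.n_electrodes):
                raise ValueError(
                    f"synergy_matrix must be {len(MOVEMENT_CODES)} x {self.n_electrodes}"
                )
            if np.any(s < 0):
                raise ValueError("synergy_matrix must be non-negative")


@dataclass
class SessionRecording:
    """One collection session: synchronized features, kinematics and labels.

    features are non-negative MAV values (T x C) at rate_hz; kinematics are
    the instructed signed positions (T x D) in [-1, 1]; labels hold the cued
    movement code (or REST) per sample.
    """

    features: np.ndarray
    kinematics: np.ndarray
    labels: np.ndarray
    rate_hz: float
    channel_names: list[str]
    axis_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.kinematics = np.asarray(self.kinematics, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.features.shape[0] != self.kinematics.shape[0]:
            raise ValueError("features and kinematics must share T")
        if self.labels.shape[0] != self.features.shape[0]:
            raise ValueError("labels must have one entry per sample")
        if np.any(self.features < 0):
            raise ValueError("features must be non-negative")
        if np.any(np.abs(self.kinematics) > 1.0 + 1e-12):
            raise ValueError("kinematics must lie within [-1, 1]")
        if len(self.channel_names) != self.features.shape[1]:
            raise ValueError("channel_names must match feature columns")
        if self.axis_names is None:
            d = self.kinematics.shape[1]
            self.axis_names = list(DOF_AXES) if d == len(DOF_AXES) else [f"axis{i}" for i in range(d)]
        if len(self.axis_names) != self.kinematics.shape[1]:
            raise ValueError("axis_names must match kinematic columns")


def generate_target_kinematics(
    protocol: TrialProtocol,
    sequence: list[str],
    mode: str = "uni",
):
    """Instructed target trajectories for an ordered movement sequence.

    Each movement in ``sequence`` occupies one trapezoid (linear rise to the
    peak, hold, mirrored fall) preceded and followed by ``rest_s`` of zeros.
    In ``uni`` mode every distinct movement gets its own column peaking at
    +1 (magnitude encoding); in ``bi`` mode movements sharing a DOF axis
    share a signed column peaking at direction * 1 (-1 = maximum
    extension/open/supination, +1 = maximum flexion/close/pronation).

    Returns (kinematics T x D, labels length T, column_names).
    """
    if mode not in ("uni", "bi"):
        raise ValueError(f"mode must be 'uni' or 'bi', got {mode!r}")
    moves = [get_movement(code) for code in sequence]

    if mode == "uni":
        columns = list(dict.fromkeys(m.code for m in moves))
        col_of = {code: i for i, code in enumerate(columns)}
    else:
        columns = list(dict.fromkeys(m.dof_axis for m in moves))
        col_of = {axis: i for i, axis in enumerate(columns)}

    trap = protocol.trapezoid()
    rest_n = protocol.rest_n
    n_mov = protocol.movement_n
    total = rest_n + len(moves) * (n_mov + rest_n)
    kin = np.zeros((total, max(len(columns), 1)))
    labels = np.full(total, REST, dtype=object)

    t = rest_n
    for m in moves:
        col = col_of[m.code] if mode == "uni" else col_of[m.dof_axis]
        peak_sign = 1.0 if mode == "uni" else float(m.direction)
        kin[t : t + n_mov, col] = peak_sign * trap
        labels[t : t + n_mov] = m.code
        t += n_mov + rest_n
    if not moves:
        kin = np.zeros((total, 0))
    return kin, labels, columns


def generate_synergies(config: SynthConfig) -> np.ndarray:
    """Per-movement electrode activation weights (n_movements x n_electrodes).

    With crosstalk 0 each movement has a disjoint dominant electrode subset
    (the 32 electrodes are partitioned across the 8 movements); increasing
    crosstalk mixes in a diffuse positive background so that at crosstalk 1
    every movement activates every electrode.  Deterministic under seed.
    """
    n_mov = len(MOVEMENT_CODES)
    if config.n_electrodes < n_mov:
        raise ValueError(
            f"need at least {n_mov} electrodes for disjoint per-movement supports, "
            f"got {config.n_electrodes}"
        )
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(config.n_electrodes)
    groups = np.array_split(perm, n_mov)
    s0 = np.zeros((n_mov, config.n_electrodes))
    for m, grp in enumerate(groups):
        s0[m, grp] = rng.uniform(0.5, 1.5, size=grp.size)
    background = rng.uniform(0.2, 0.6, size=s0.shape)
    return (1.0 - config.crosstalk) * s0 + config.crosstalk * background


def _activation_matrix(
    kinematics: np.ndarray,
    labels: np.ndarray,
    config: SynthConfig,
) -> np.ndarray:
    """T x n_movements activation drive: instructed envelope on the active
    movement plus crosstalk-scaled co-activation of every other movement."""
    env = np.abs(kinematics).max(axis=1) if kinematics.shape[1] else np.zeros(len(labels))
    gains = {code: 1.0 for code in MOVEMENT_CODES}
    if config.movement_gains:
        gains.update(config.movement_gains)
    act = np.zeros((len(labels), len(MOVEMENT_CODES)))
    code_idx = {code: i for i, code in enumerate(MOVEMENT_CODES)}
    active = labels != REST
    if np.any(active):
        act[active, :] = config.crosstalk * env[active, None]
        rows = np.nonzero(active)[0]
        cols = np.array([code_idx[labels[r]] for r in rows])
        act[rows, cols] = env[rows]
    act *= np.array([gains[c] for c in MOVEMENT_CODES])[None, :]
    return act


def generate_session(
    kinematics: np.ndarray,
    labels: np.ndarray,
    config: SynthConfig,
    *,
    protocol: TrialProtocol | None = None,
    seed=None,
    axis_names: list[str] | None = None,
) -> SessionRecording:
    """Simulate the 32-channel MAV recording for instructed kinematics.

    MAV(t) = baseline + [activation(t - lag) @ synergies] * session_gain
    + noise, truncated at zero.  ``seed`` (int or SeedSequence) controls the
    session-specific randomness (gain drift, noise); the synergy matrix is
    taken from the config (or regenerated from config.seed) so that the two
    sessions of one participant share their synergies.
    """
    protocol = protocol or TrialProtocol()
    rate = protocol.kin_rate_hz
    kinematics = np.atleast_2d(np.asarray(kinematics, dtype=float))
    labels = np.asarray(labels, dtype=object)
    lag_n = int(round(config.lag_ms / 1000.0 * rate))
    if lag_n >= protocol.rest_n:
        raise ValueError(
            f"lag {config.lag_ms} ms spans a whole rest period "
            f"({protocol.rest_s} s); alignment would be unidentifiable"
        )
    synergies = (
        np.asarray(config.synergy_matrix, dtype=float)
        if config.synergy_matrix is not None
        else generate_synergies(config)
    )
    rng = np.random.default_rng(config.seed if seed is None else seed)
    act = _activation_matrix(kinematics, labels, config)
    if lag_n:
        act = np.vstack([np.zeros((lag_n, act.shape[1])), act[:-lag_n]])
    clean = act @ synergies
    gain = rng.lognormal(mean=0.0, sigma=config.session_gain_sd, size=synergies.shape[1])
    features = np.asarray(config.baseline, dtype=float) + clean * gain[None, :]
    if config.noise_sd > 0:
        features = features + rng.normal(0.0, config.noise_sd, size=features.shape)
    np.maximum(features, 0.0, out=features)
    names = [f"e{i:02d}" for i in range(synergies.shape[1])]
    return SessionRecording(
        features=features,
        kinematics=kinematics,
        labels=labels,
        rate_hz=rate,
        channel_names=names,
        axis_names=list(axis_names) if axis_names is not None else None,
    )


def session_sequence(protocol: TrialProtocol, movements=MOVEMENT_CODES) -> list[str]:
    """Movement-major cue order: all repetitions of each movement in a block."""
    return [code for code in movements for _ in range(protocol.reps)]


def generate_participant(
    config: SynthConfig,
    protocol: TrialProtocol | None = None,
):
    """Two full sessions (train, test) for one synthetic participant.

    Both sessions cue all eight movements (reps per the protocol) with the
    physical signed per-axis kinematics of the virtual hand; they share the
    participant's synergy matrix but draw independent session gain drift and
    noise from sub-seeds of config.seed.
    """
    protocol = protocol or TrialProtocol()
    seq = session_sequence(protocol)
    kin, labels, axes = generate_target_kinematics(protocol, seq, mode="bi")
    cfg = config
    if cfg.synergy_matrix is None:
        cfg = replace(config, synergy_matrix=generate_synergies(config))
    train_ss, test_ss = np.random.SeedSequence(config.seed).spawn(2)
    train = generate_session(
        kin, labels, cfg, protocol=protocol, seed=train_ss, axis_names=axes
    )
    test = generate_session(
        kin, labels, cfg, protocol=protocol, seed=test_ss, axis_names=axes
    )
    return train, test


def generate_raw_emg(
    session: SessionRecording,
    config: SynthConfig,
    *,
    raw_rate_hz: float = 1000.0,
    band=(15.0, 375.0),
    seed=None,
) -> np.ndarray:
    """1-kHz amplitude-modulated band-limited noise whose MAV tracks the
    session's feature envelopes.  Exists to exercise the filtering front end;
    makes no claim of physiological realism.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    up = int(round(raw_rate_hz / session.rate_hz))
    t_raw = session.features.shape[0] * up
    sos = sps.butter(4, band, btype="bandpass", fs=raw_rate_hz, output="sos")
    carrier = sps.sosfilt(sos, rng.standard_normal((t_raw, session.features.shape[1])), axis=0)
    carrier /= np.mean(np.abs(carrier), axis=0, keepdims=True)
    amp = np.repeat(session.features, up, axis=0)
    return amp * carrier
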
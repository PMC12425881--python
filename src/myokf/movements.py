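"""Movement vocabulary and trial timing for hand/wrist myoelectric sessions.

Eight cued movements span four degrees of freedom (DOFs): full-hand
grasp/open, tripod grasp/open, wrist flexion/extension (pitch) and wrist
pronation/supination (roll).  By convention flexion/close/pronation is the
positive direction of its axis and extension/open/supination the negative
direction; rest is the zero position of every axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

REST = "REST"

DOF_AXES: tuple[str, ...] = ("hand", "tripod", "wrist_pitch", "wrist_roll")


@dataclass(frozen=True)
class MovementLabel:
    """One cued movement: its code, DOF axis, and signed direction."""

    code: str
    dof_axis: str
    direction: int  # +1 flexion/close/pronation, -1 extension/open/supination, 0 rest


MOVEMENTS: dict[str, MovementLabel] = {
    "HC": MovementLabel("HC", "hand", +1),          # full hand grasp (digits 1-5)
    "HO": MovementLabel("HO", "hand", -1),          # full hand open
    "TC": MovementLabel("TC", "tripod", +1),        # tripod close (digits 1-3)
    "TO": MovementLabel("TO", "tripod", -1),        # tripod open
    "WF": MovementLabel("WF", "wrist_pitch", +1),   # wrist flexion
    "WE": MovementLabel("WE", "wrist_pitch", -1),   # wrist extension
    "WP": MovementLabel("WP", "wrist_roll", +1),    # pronation
    "WS": MovementLabel("WS", "wrist_roll", -1),    # supination
}

MOVEMENT_CODES: tuple[str, ...] = tuple(MOVEMENTS)

REST_LABEL = MovementLabel(REST, "none", 0)


def get_movement(code: str) -> MovementLabel:
    try:
        return MOVEMENTS[code]
    except KeyError:
        raise ValueError(f"unknown movement code: {code!r}") from None


def axis_index(axis: str) -> int:
    return DOF_AXES.index(axis)


@dataclass(frozen=True)
class TrialProtocol:
    """Timing of one cued movement trial.

    Each attempt is a trapezoid: a linear rise away from rest, a hold at
    the peak, and a mirrored fall back to rest, followed by a rest period.
    Defaults give the standard 4.4-s movement (0.7 + 3.0 + 0.7 s) with 3 s
    of rest, 10 repetitions per movement, cued at 30 Hz.
    """

    rise_s: float = 0.7
    hold_s: float = 3.0
    fall_s: float = 0.7
    rest_s: float = 3.0
    reps: int = 10
    kin_rate_hz: float = 30.0

    def __post_init__(self) -> None:
        for name in ("rise_s", "hold_s", "fall_s", "rest_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.kin_rate_hz <= 0:
            raise ValueError("kin_rate_hz must be > 0")

    # Sample-count convention: the rise spans round(rise_s * rate) samples
    # taking values k/n_rise (k = 1..n_rise, so the last rise sample is the
    # peak); the hold contributes round(hold_s * rate) + 1 samples at the
    # peak; the fall mirrors the rise.  At defaults: 21 + 91 + 21 = 133.
    @property
    def rise_n(self) -> int:
        return int(round(self.rise_s * self.kin_rate_hz))

    @property
    def hold_n(self) -> int:
        return int(round(self.hold_s * self.kin_rate_hz)) + 1

    @property
    def fall_n(self) -> int:
        return int(round(self.fall_s * self.kin_rate_hz))

    @property
    def rest_n(self) -> int:
        return int(round(self.rest_s * self.kin_rate_hz))

    @property
    def movement_n(self) -> int:
        """Samples in one movement attempt (rest excluded)."""
        return self.rise_n + self.hold_n + self.fall_n

    def trapezoid(self) -> np.ndarray:
        """Unit-peak trapezoidal profile of one movement attempt."""
        rise = np.arange(1, self.rise_n + 1, dtype=float) / self.rise_n
        hold = np.ones(self.hold_n)
        fall = np.arange(self.fall_n, 0, -1, dtype=float) / self.fall_n
        return np.concatenate([rise, hold, fall])
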
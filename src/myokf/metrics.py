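"""Intended/unintended movement RMSE, aggregation, and functional-control
classification.

Intended movement RMSE measures how precisely the instructed DOFs track
their target trajectory over one movement attempt:

    RMSE = sqrt( (1 / (H * M_m)) * sum_k sum_j (x_{j,k} - xhat_{j,k})^2 )

where H is the number of samples in the attempt (the movement trapezoid;
inter-trial rest is excluded) and M_m the number of DOFs instructed to
move.  Unintended movement RMSE (xRMSE) measures spurious deflection of the
M_s DOFs instructed to stay at rest:

    xRMSE = sqrt( (1 / (H * M_s)) * sum_k sum_j xhat^S_{j,k}^2 )

With a single controllable DOF there is inherently no unintended movement,
so xRMSE is reported as absent (None), never as zero.  Control is
"functional" when intended RMSE <= 0.45 and xRMSE <= 0.04 (inclusive),
benchmarks taken from healthy-participant regression performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "EvalWindow",
    "RmseReport",
    "FunctionalCriteria",
    "GroupComparison",
    "intended_rmse",
    "unintended_rmse",
    "attempt_windows",
    "aggregate",
    "classify_functional",
    "select_best_combination",
    "group_comparison",
]


@dataclass
class EvalWindow:
    """One movement attempt: targets/predictions on the moving DOFs and
    predictions on the stationary DOFs (H x M_m / H x M_s arrays)."""

    target: np.ndarray
    pred_moving: np.ndarray
    pred_stationary: np.ndarray | None = None


@dataclass
class FunctionalCriteria:
    """Inclusive thresholds for functional control."""

    intended_max: float = 0.45
    unintended_max: float = 0.04

    def __post_init__(self) -> None:
        if self.intended_max <= 0 or self.unintended_max <= 0:
            raise ValueError("criteria thresholds must be > 0")


def _as_window_2d(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    return a[:, None] if a.ndim == 1 else a


def intended_rmse(window: EvalWindow | None = None, *, target=None, pred=None) -> float:
    """RMSE between target and prediction over the moving DOFs."""
    if window is not None:
        target, pred = window.target, window.pred_moving
    t = _as_window_2d(target)
    p = _as_window_2d(pred)
    if t.shape != p.shape:
        raise ValueError("target and prediction must share shape")
    if t.shape[0] == 0:
        raise ValueError("empty attempt window (H = 0)")
    if t.shape[1] == 0:
        raise ValueError("no moving DOFs in window")
    return float(np.sqrt(np.mean((t - p) ** 2)))


def unintended_rmse(window: EvalWindow | None = None, *, pred_stationary=None) -> float | None:
    """Root mean square of the stationary-DOF predictions, averaged across
    stationary DOFs; None (defined-absent) when there are no stationary DOFs."""
    if window is not None:
        pred_stationary = window.pred_stationary
    if pred_stationary is None:
        return None
    p = _as_window_2d(pred_stationary)
    if p.shape[1] == 0:
        return None
    if p.shape[0] == 0:
        raise ValueError("empty attempt window (H = 0)")
    return float(np.sqrt(np.mean(p**2)))


def attempt_windows(labels: np.ndarray, code: str) -> list[slice]:
    """Slices of consecutive samples labeled with the given movement code."""
    labels = np.asarray(labels, dtype=object)
    mask = labels == code
    if not np.any(mask):
        return []
    edges = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
    return [slice(int(s), int(e)) for s, e in zip(edges[::2], edges[1::2])]


@dataclass
class RmseReport:
    """Per-attempt values with the within-combination aggregation."""

    attempts: pd.DataFrame  # columns: movement, attempt, intended, unintended
    per_movement: pd.DataFrame  # columns: movement, intended, unintended
    intended: float = np.nan
    unintended: float | None = None
    meta: dict = field(default_factory=dict)


def aggregate(attempts: pd.DataFrame, scheme: str = "mean-attempts/mean-movements") -> RmseReport:
    """Mean across attempts per movement, then mean across movements.

    (Group summaries across participants take medians downstream.)  The
    unintended summary is None when every attempt reported it absent.
    """
    if len(attempts) == 0:
        raise ValueError("no attempts to aggregate")
    per_movement = (
        attempts.groupby("movement", sort=False)[["intended", "unintended"]]
        .mean()
        .reset_index()
    )
    intended = float(per_movement["intended"].mean())
    unintended = (
        None
        if per_movement["unintended"].isna().all()
        else float(per_movement["unintended"].mean())
    )
    return RmseReport(
        attempts=attempts.reset_index(drop=True),
        per_movement=per_movement,
        intended=intended,
        unintended=unintended,
        meta={"scheme": scheme},
    )


def classify_functional(
    intended: float,
    unintended: float | None,
    criteria: FunctionalCriteria = FunctionalCriteria(),
) -> bool:
    """Functional iff intended <= 0.45 and (when defined) unintended <= 0.04.

    Comparisons are inclusive; with a single DOF only the intended RMSE is
    compared.
    """
    if intended < 0:
        raise ValueError("intended RMSE must be >= 0")
    if unintended is not None and unintended < 0:
        raise ValueError("unintended RMSE must be >= 0")
    ok = intended <= criteria.intended_max
    if unintended is not None:
        ok = ok and unintended <= criteria.unintended_max
    return bool(ok)


def select_best_combination(summaries: dict[str, tuple[float, float | None]]) -> str:
    """Pick the combination minimizing intended + unintended RMSE.

    Ties break toward the lower unintended RMSE, then the lexicographically
    first combination name.  Absent unintended values count as 0.
    """
    if not summaries:
        raise ValueError("no combinations to choose from")

    def key(item):
        name, (intended, unintended) = item
        u = 0.0 if unintended is None else unintended
        return (intended + u, u, name)

    return min(summaries.items(), key=key)[0]


@dataclass
class GroupComparison:
    """Nonparametric group-comparison result."""

    statistic: float
    pvalue: float
    n: int
    method: str
    degenerate: bool = False


def group_comparison(groups, design: str = "independent") -> GroupComparison:
    """Kruskal-Wallis (independent groups) or Wilcoxon signed-rank (paired).

    Paired vectors with all-zero differences are a degenerate case (the
    signed-rank test is undefined) and are flagged rather than raised.
    """
    if design == "independent":
        groups = [np.asarray(g, dtype=float) for g in groups]
        if len(groups) < 2 or any(len(g) < 1 for g in groups):
            raise ValueError("need >= 2 non-empty groups")
        if all(np.array_equal(g, groups[0]) for g in groups[1:]) and all(
            np.ptp(g) == 0 for g in groups
        ):
            # all observations identical: H = 0 by definition, p = 1
            return GroupComparison(0.0, 1.0, sum(len(g) for g in groups), "kruskal-wallis")
        stat, p = sstats.kruskal(*groups)
        return GroupComparison(float(stat), float(p), sum(len(g) for g in groups), "kruskal-wallis")
    if design == "paired":
        a, b = (np.asarray(g, dtype=float) for g in groups)
        if len(a) != len(b) or len(a) < 2:
            raise ValueError("paired design needs two equal-length vectors (n >= 2)")
        if np.allclose(a, b):
            return GroupComparison(np.nan, np.nan, len(a), "wilcoxon", degenerate=True)
        stat, p = sstats.wilcoxon(a, b)
        return GroupComparison(float(stat), float(p), len(a), "wilcoxon")
    raise ValueError(f"unknown design: {design!r}")
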
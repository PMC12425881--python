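"""Stepwise Gram-Schmidt (forward orthogonal least squares) channel selection.

Greedy forward selection of the k feature channels most informative about
the kinematic targets.  At each step every unselected channel is scored by
the squared correlation between its residual (the component orthogonal to
the span of the already-selected channels) and the targets' residuals,
summed over target axes; the argmax is appended and the remaining channels
and targets are orthogonalized against it.  The score equals the fraction
of residual target variance the channel would explain, so the procedure is
the classical error-reduction-ratio forward OLS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["SelectionResult", "gram_schmidt_select"]


@dataclass
class SelectionResult:
    """Ordered selected channel indices with their per-step scores."""

    indices: list[int]
    scores: list[float]


def gram_schmidt_select(
    features: np.ndarray,
    targets: np.ndarray,
    k: int = 48,
    tol: float = 1e-10,
) -> SelectionResult:
    """Select up to k channels by greedy orthogonal correlation scoring.

    features: T x C, targets: T x D (both mean-centered internally).
    Stops early when every remaining channel's or target's residual norm
    falls below ``tol`` relative to its original norm (duplicated or
    constant channels are never selected).  Ties break toward the lowest
    channel index.
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(targets, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    t, c = x.shape
    if y.shape[0] != t:
        raise ValueError("features and targets must share T")
    if k > c:
        warnings.warn(f"k={k} exceeds channel count {c}; selecting all channels", stacklevel=2)
        k = c
    if t <= k:
        raise ValueError(f"need more samples than channels to select (T={t}, k={k})")

    xr = x - x.mean(axis=0)
    yr = y - y.mean(axis=0)
    x_norm0 = np.linalg.norm(xr, axis=0)
    y_norm0 = np.linalg.norm(yr, axis=0)
    # channels with no variance at all are never candidates
    scale = max(float(x_norm0.max(initial=0.0)), 1.0)
    alive = x_norm0 > tol * scale

    indices: list[int] = []
    scores: list[float] = []
    for _ in range(k):
        x_norm = np.linalg.norm(xr, axis=0)
        cand = alive & (x_norm > tol * np.maximum(x_norm0, tol))
        cand[indices] = False
        y_norm = np.linalg.norm(yr, axis=0)
        live_targets = y_norm > tol * np.maximum(y_norm0, tol)
        if not np.any(cand) or not np.any(live_targets):
            break
        proj = xr.T @ yr  # C x D
        with np.errstate(divide="ignore", invalid="ignore"):
            corr2 = proj**2 / np.outer(x_norm**2, y_norm**2)
        corr2[~np.isfinite(corr2)] = 0.0
        corr2[:, ~live_targets] = 0.0
        step_scores = corr2.sum(axis=1)
        step_scores[~cand] = -np.inf
        best = int(np.argmax(step_scores))  # argmax takes the lowest index on ties
        indices.append(best)
        scores.append(float(step_scores[best]))
        q = xr[:, best] / x_norm[best]
        xr -= np.outer(q, q @ xr)
        yr -= np.outer(q, q @ yr)
    return SelectionResult(indices=indices, scores=scores)
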
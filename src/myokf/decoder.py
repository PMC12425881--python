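"""Modified Kalman filter (MKF) decoding of multi-DOF kinematic position.

A linear Kalman filter maps selected, baseline-subtracted EMG features to
continuous kinematic positions.  The state is the vector of kinematic
positions augmented with a constant 1 (which absorbs feature offsets that
survive baseline subtraction); there are no velocity states.  Training is
by least squares: the state-transition matrix is a one-step state
regression and the observation matrix regresses features on the state,
with residual covariances as the noise models.  The "modified" outputs
apply a dead-band (outputs stay at zero until the unmodified output's
magnitude exceeds the threshold, per-sample and non-latching) followed by
clipping to [-1, +1], where -1 is maximum extension and +1 maximum flexion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla

__all__ = ["KalmanModel", "Prediction", "train_kf", "kf_predict", "apply_modifications", "predict"]


@dataclass
class KalmanModel:
    """Trained MKF: transition A, process noise W, observation H, observation
    noise Q, plus the dead-band threshold and output clip bounds.

    state_dim = D + 1 (kinematic axes plus the constant-1 augmentation);
    H maps the state to the k selected feature channels.
    """

    A: np.ndarray
    W: np.ndarray
    H: np.ndarray
    Q: np.ndarray
    threshold: float = 0.2
    clip: tuple[float, float] = (-1.0, 1.0)

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")
        lo, hi = self.clip
        if not (lo < 0 < hi):
            raise ValueError("clip bounds must straddle 0")

    @property
    def state_dim(self) -> int:
        return self.A.shape[0]

    @property
    def n_dofs(self) -> int:
        return self.state_dim - 1


@dataclass
class Prediction:
    """raw: unmodified filter outputs; modified: after dead-band and clip."""

    raw: np.ndarray
    modified: np.ndarray


def _ridge_solve(bbt: np.ndarray, abt: np.ndarray, ridge: float) -> np.ndarray:
    """Solve M @ bbt = abt for M with a trace-scaled ridge on bbt."""
    dim = bbt.shape[0]
    lam = ridge * np.trace(bbt) / dim
    if not np.isfinite(lam) or lam <= 0:
        lam = ridge
    try:
        return np.linalg.solve(bbt + lam * np.eye(dim), abt.T).T
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"rank-deficient normal equations beyond ridge repair: {exc}") from exc


def train_kf(
    features: np.ndarray,
    kinematics: np.ndarray,
    threshold: float = 0.2,
    clip: tuple[float, float] = (-1.0, 1.0),
    ridge: float = 1e-6,
) -> KalmanModel:
    """Fit the Kalman matrices by least squares on one training session.

    State x_t = [kinematics_t; 1].  A = argmin ||X2 - A X1||^2 with W the
    residual covariance; H = argmin ||Z - H X||^2 with Q the residual
    covariance.  A small trace-scaled ridge stabilizes both normal
    equations; the constant-1 state row of A is pinned exactly.
    """
    z = np.atleast_2d(np.asarray(features, dtype=float)).T  # k x T
    kin = np.asarray(kinematics, dtype=float)
    if kin.ndim == 1:
        kin = kin[:, None]
    t, d = kin.shape
    k = z.shape[0]
    if z.shape[1] != t:
        raise ValueError("features and kinematics must share T")
    if t <= k + d + 1:
        raise ValueError(f"need T > k + D + 1 samples to train (T={t}, k={k}, D={d})")
    if not (np.all(np.isfinite(z)) and np.all(np.isfinite(kin))):
        raise ValueError("non-finite training data")

    x = np.vstack([kin.T, np.ones(t)])  # (D+1) x T
    x1, x2 = x[:, :-1], x[:, 1:]
    a = _ridge_solve(x1 @ x1.T, x2 @ x1.T, ridge)
    a[-1, :] = 0.0
    a[-1, -1] = 1.0
    ra = x2 - a @ x1
    w = ra @ ra.T / (t - 1)
    w[-1, :] = 0.0
    w[:, -1] = 0.0

    h = _ridge_solve(x @ x.T, z @ x.T, ridge)
    rh = z - h @ x
    q = rh @ rh.T / t
    # diagonal floor keeps the innovation covariance invertible when the
    # observation model is (numerically) exact
    q_floor = 1e-8 * np.trace(q) / k + 1e-12 * float(np.mean(z**2) + 1.0)
    q += q_floor * np.eye(k)
    return KalmanModel(A=a, W=w, H=h, Q=q, threshold=threshold, clip=clip)


def kf_predict(model: KalmanModel, features: np.ndarray) -> np.ndarray:
    """Run the Kalman recursion over a feature stream; returns raw T x D.

    Standard predict/update recursion starting from the rest state
    [0,...,0,1] with P = W; the constant-1 state element is re-pinned to 1
    after each update.
    """
    z = np.atleast_2d(np.asarray(features, dtype=float))
    if z.size == 0:
        return np.zeros((0, model.n_dofs))
    if z.shape[1] != model.H.shape[0]:
        raise ValueError(f"feature count {z.shape[1]} does not match H ({model.H.shape[0]})")
    bad = ~np.all(np.isfinite(z), axis=1)
    if np.any(bad):
        raise ValueError(f"non-finite features at sample {int(np.nonzero(bad)[0][0])}")

    a, w, h, q = model.A, model.W, model.H, model.Q
    n = model.state_dim
    x = np.zeros(n)
    x[-1] = 1.0
    p = w.copy()
    eye = np.eye(n)
    raw = np.empty((z.shape[0], model.n_dofs))
    for i in range(z.shape[0]):
        x = a @ x
        p = a @ p @ a.T + w
        ph = p @ h.T  # n x k
        s = h @ ph + q
        try:
            cf = sla.cho_factor(s, check_finite=False)
            gain = sla.cho_solve(cf, ph.T, check_finite=False).T  # n x k
        except np.linalg.LinAlgError:
            gain = np.linalg.solve(s, ph.T).T
        x = x + gain @ (z[i] - h @ x)
        x[-1] = 1.0
        p = (eye - gain @ h) @ p
        p = 0.5 * (p + p.T)
        raw[i] = x[:-1]
    return raw


def apply_modifications(raw: np.ndarray, model: KalmanModel) -> np.ndarray:
    """Dead-band then clip: zero wherever |raw| <= threshold, then bound."""
    raw = np.asarray(raw, dtype=float)
    out = np.where(np.abs(raw) <= model.threshold, 0.0, raw)
    return np.clip(out, model.clip[0], model.clip[1])


def predict(model: KalmanModel, features: np.ndarray) -> Prediction:
    """Convenience wrapper returning both raw and modified outputs."""
    raw = kf_predict(model, features)
    return Prediction(raw=raw, modified=apply_modifications(raw, model))
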
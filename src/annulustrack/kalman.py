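"""Extended Kalman filter core: prediction, information-form update, and
bidirectional assimilation.

Prediction regularizes the estimate toward a per-frame rest state x_0,k with
a diagonal gain A (entries in [0, 1]):

    x_pred = A x_prev + (I - A) x_0,k
    P_pred = A P_prev A^T + Q_0,k

The measurement update accumulates the scalar edge measurements in
information form,

    P_post^-1 = P_pred^-1 + sum_i h_i r_i^-1 h_i^T
    x_post    = x_pred + P_post sum_i h_i r_i^-1 v_i,

which costs one state-sized solve regardless of the number of edges.
Forward and backward tracking passes over the cycle are fused per frame by
precision-weighted averaging of the two estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FilterState", "MotionModel", "predict", "update", "assimilate"]

EIG_FLOOR = 1e-10


@dataclass
class FilterState:
    x: np.ndarray  # state estimate
    P: np.ndarray  # covariance
    frame: int = 0

    @property
    def dim(self) -> int:
        return self.x.size


@dataclass
class MotionModel:
    """Per-frame regularization: diagonal gain a (vector), rest states x0
    and process noise covariances Q0 (diagonal vectors or full matrices),
    each either one array (constant model) or a list per frame."""

    a: np.ndarray
    x0: object
    Q0: object

    def rest_state(self, k: int) -> np.ndarray:
        return self.x0[k] if isinstance(self.x0, list) else self.x0

    def process_noise(self, k: int) -> np.ndarray:
        return self.Q0[k] if isinstance(self.Q0, list) else self.Q0


def _symmetrize(P: np.ndarray) -> np.ndarray:
    P = 0.5 * (P + P.T)
    w, V = np.linalg.eigh(P)
    if w.min() < EIG_FLOOR:
        w = np.maximum(w, EIG_FLOOR)
        P = (V * w) @ V.T
        P = 0.5 * (P + P.T)
    return P


def predict(prev: FilterState, model: MotionModel, k: int) -> FilterState:
    a = np.asarray(model.a, dtype=float)
    x0 = np.asarray(model.rest_state(k), dtype=float)
    Q0 = np.asarray(model.process_noise(k), dtype=float)
    if Q0.ndim == 1:
        Q0 = np.diag(Q0)
    x_pred = a * prev.x + (1.0 - a) * x0
    P_pred = (a[:, None] * prev.P) * a[None, :] + Q0
    return FilterState(x=x_pred, P=_symmetrize(P_pred), frame=k)


def update(
    pred: FilterState,
    H: np.ndarray,
    v: np.ndarray,
    r: np.ndarray,
) -> FilterState:
    """Assimilate scalar edge measurements v_i with variances r_i and
    measurement vectors h_i (rows of H).  With no measurements the
    prediction passes through unchanged."""
    H = np.atleast_2d(np.asarray(H, dtype=float))
    v = np.atleast_1d(np.asarray(v, dtype=float))
    r = np.atleast_1d(np.asarray(r, dtype=float))
    if v.size == 0:
        return FilterState(x=pred.x.copy(), P=pred.P.copy(), frame=pred.frame)
    if np.any(r <= 0):
        raise ValueError("measurement variances must be positive")
    Hw = H / r[:, None]
    info_gain = H.T @ Hw
    info_vec = Hw.T @ v
    try:
        P_inv = np.linalg.inv(pred.P)
    except np.linalg.LinAlgError:
        P_inv = np.linalg.pinv(pred.P)
    Lam = P_inv + info_gain
    Lam = 0.5 * (Lam + Lam.T)
    try:
        L = np.linalg.cholesky(Lam)
        P_post = np.linalg.inv(L.T) @ np.linalg.inv(L)
    except np.linalg.LinAlgError:
        # singular information matrix: ridge-regularized solve
        Lam = Lam + 1e-8 * np.eye(Lam.shape[0]) * max(1.0, np.trace(Lam) / Lam.shape[0])
        P_post = np.linalg.inv(Lam)
    P_post = _symmetrize(P_post)
    x_post = pred.x + P_post @ info_vec
    return FilterState(x=x_post, P=P_post, frame=pred.frame)


def _fuse(xa, Pa, xb, Pb):
    Pa_inv = np.linalg.inv(Pa)
    Pb_inv = np.linalg.inv(Pb)
    P = np.linalg.inv(Pa_inv + Pb_inv)
    P = _symmetrize(P)
    x = P @ (Pa_inv @ xa + Pb_inv @ xb)
    return x, P


def assimilate(
    fwd: list[FilterState], bwd: list[FilterState]
) -> list[FilterState]:
    """Precision-weighted fusion of forward and backward tracking passes:
    P_k = (P_f^-1 + P_b^-1)^-1, x_k = P_k (P_f^-1 x_f + P_b^-1 x_b)."""
    if len(fwd) != len(bwd):
        raise ValueError("forward and backward passes must cover the same frames")
    out = []
    for f, b in zip(fwd, bwd):
        if f.frame != b.frame:
            raise ValueError("frame index mismatch between passes")
        x, P = _fuse(f.x, f.P, b.x, b.P)
        out.append(FilterState(x=x, P=P, frame=f.frame))
    return out
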
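"""Global similarity transform and its state-space Jacobians.

The global pose state is x_g = [t_x, t_y, t_z, s, theta_x, theta_y, theta_z]
(mm, unitless scale, radians) and acts on model-frame points as

    T_g(p; x_g) = s R_x(theta_x) R_y(theta_y) R_z(theta_z) p + t

with the rotation matrices composed exactly in that order, right-handed and
counter-clockwise about each axis.  The composite model-to-image map is
T(p; x) = T_g(T_l(p; x_l); x_g): deform locally, then pose globally.

For a similarity transform the point Jacobian is M = dT_g/dp = s R, so
surface normals map as n_g = R n_l (|M| M^{-T} is proportional to R) and the
local deformation Jacobian maps as M J_l.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GlobalState",
    "GlobalSample",
    "IDENTITY_STATE",
    "rotation_matrix",
    "rotation_derivatives",
    "transform_point",
    "transform_sample",
    "transform_batch",
    "euler_from_matrix",
    "axis_to_euler",
]

N_GLOBAL = 7

IDENTITY_STATE = np.array([0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0])


@dataclass(frozen=True)
class GlobalState:
    """Convenience wrapper over the 7-vector [t, s, theta]."""

    x: np.ndarray

    @property
    def translation(self) -> np.ndarray:
        return self.x[0:3]

    @property
    def scale(self) -> float:
        return float(self.x[3])

    @property
    def angles(self) -> np.ndarray:
        return self.x[4:7]


@dataclass(frozen=True)
class GlobalSample:
    p_g: np.ndarray
    n_g: np.ndarray
    J_g: np.ndarray  # 3 x (7 + n_local)
    M: np.ndarray  # 3 x 3 point Jacobian of T_g


def _rx(c, s):
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _ry(c, s):
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _rz(c, s):
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def rotation_matrix(angles: np.ndarray) -> np.ndarray:
    """R = R_x R_y R_z, each right-handed counter-clockwise."""
    ax, ay, az = angles
    return _rx(np.cos(ax), np.sin(ax)) @ _ry(np.cos(ay), np.sin(ay)) @ _rz(
        np.cos(az), np.sin(az)
    )


def rotation_derivatives(angles: np.ndarray) -> list[np.ndarray]:
    """Analytic dR/dtheta_k for R = R_x R_y R_z."""
    ax, ay, az = angles
    Rx, Ry, Rz = (
        _rx(np.cos(ax), np.sin(ax)),
        _ry(np.cos(ay), np.sin(ay)),
        _rz(np.cos(az), np.sin(az)),
    )
    dRx = np.array(
        [
            [0.0, 0.0, 0.0],
            [0.0, -np.sin(ax), -np.cos(ax)],
            [0.0, np.cos(ax), -np.sin(ax)],
        ]
    )
    dRy = np.array(
        [
            [-np.sin(ay), 0.0, np.cos(ay)],
            [0.0, 0.0, 0.0],
            [-np.cos(ay), 0.0, -np.sin(ay)],
        ]
    )
    dRz = np.array(
        [
            [-np.sin(az), -np.cos(az), 0.0],
            [np.cos(az), -np.sin(az), 0.0],
            [0.0, 0.0, 0.0],
        ]
    )
    return [dRx @ Ry @ Rz, Rx @ dRy @ Rz, Rx @ Ry @ dRz]


def transform_point(x_g: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Apply T_g to one point or an (n, 3) stack of points."""
    x_g = np.asarray(x_g, dtype=float)
    p = np.asarray(p, dtype=float)
    R = rotation_matrix(x_g[4:7])
    s = x_g[3]
    return s * (p @ R.T) + x_g[0:3]


def transform_batch(x: np.ndarray, P_l: np.ndarray, N_l: np.ndarray):
    """Map model-frame positions and normals to image space.

    Returns (P_g, N_g, R, s): positions s R p + t, rotated unit normals, and
    the rotation/scale needed to assemble measurement vectors.
    """
    x = np.asarray(x, dtype=float)
    R = rotation_matrix(x[4:7])
    s = float(x[3])
    P_g = s * (P_l @ R.T) + x[0:3]
    N_g = N_l @ R.T
    return P_g, N_g, R, s


def global_jacobian(x: np.ndarray, p_l: np.ndarray) -> np.ndarray:
    """3 x 7 derivative of T_g(p_l) with respect to [t, s, theta]."""
    x = np.asarray(x, dtype=float)
    p_l = np.asarray(p_l, dtype=float)
    s = float(x[3])
    R = rotation_matrix(x[4:7])
    dRs = rotation_derivatives(x[4:7])
    J = np.empty((3, N_GLOBAL))
    J[:, 0:3] = np.eye(3)
    J[:, 3] = R @ p_l
    for k in range(3):
        J[:, 4 + k] = s * (dRs[k] @ p_l)
    return J


def transform_sample(x: np.ndarray, sample) -> GlobalSample:
    """Lift one model-frame sample into image space with full Jacobian.

    The Jacobian is the horizontal concatenation of the 3x7 global block and
    M J_l, with M = s R the point Jacobian of the similarity transform.
    """
    x = np.asarray(x, dtype=float)
    s = float(x[3])
    R = rotation_matrix(x[4:7])
    M = s * R
    p_g = M @ sample.p_l + x[0:3]
    n_g = R @ sample.n_l
    n_g = n_g / np.linalg.norm(n_g)
    J = np.concatenate([global_jacobian(x, sample.p_l), M @ sample.J_l], axis=1)
    return GlobalSample(p_g=p_g, n_g=n_g, J_g=J, M=M)


def measurement_vectors(
    x: np.ndarray,
    P_l: np.ndarray,
    N_l: np.ndarray,
    Ws: np.ndarray | None,
    dirs: np.ndarray | None,
):
    """Vectorized h_i = J_i^T n_i for a batch of samples.

    For the 7 global states h carries [n, n.(R p_l), s n.(dR_k p_l)]; for
    deformation state j it is w_ij * n.(s R d_j), the chain rule through the
    subdivision weights.  Returns (P_g, N_g, H) with H of shape (n, dim).
    """
    x = np.asarray(x, dtype=float)
    s = float(x[3])
    R = rotation_matrix(x[4:7])
    dRs = rotation_derivatives(x[4:7])
    P_g = s * (P_l @ R.T) + x[0:3]
    N_g = N_l @ R.T
    n_local = 0 if Ws is None else (dirs.shape[0] if dirs is not None else 0)
    H = np.zeros((len(P_l), N_GLOBAL + n_local))
    H[:, 0:3] = N_g
    H[:, 3] = np.einsum("ij,ij->i", N_g, P_l @ R.T)
    for k in range(3):
        H[:, 4 + k] = s * np.einsum("ij,ij->i", N_g, P_l @ dRs[k].T)
    if n_local:
        D = s * (dirs @ R.T)  # (n_local, 3): image-space deformation directions
        H[:, N_GLOBAL:] = Ws * (N_g @ D.T)
    return P_g, N_g, H


def euler_from_matrix(R: np.ndarray) -> np.ndarray:
    """Angles (theta_x, theta_y, theta_z) with R = R_x R_y R_z."""
    ty = np.arcsin(np.clip(R[0, 2], -1.0, 1.0))
    if abs(R[0, 2]) < 1.0 - 1e-12:
        tx = np.arctan2(-R[1, 2], R[2, 2])
        tz = np.arctan2(-R[0, 1], R[0, 0])
    else:  # gimbal lock: fold z into x
        tx = np.arctan2(R[2, 1], R[1, 1])
        tz = 0.0
    return np.array([tx, ty, tz])


def axis_to_euler(axis: np.ndarray) -> np.ndarray:
    """Euler angles rotating the model z-axis onto ``axis`` (unit)."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    ty = np.arcsin(np.clip(axis[0], -1.0, 1.0))
    tx = np.arctan2(-axis[1], axis[2]) if (abs(axis[1]) + abs(axis[2])) > 0 else 0.0
    return np.array([tx, ty, 0.0])
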
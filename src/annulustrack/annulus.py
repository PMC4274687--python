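"""Annulus quantification: surface/disc-plane intersection, least-squares
ellipse fitting, and diameter measures.

The annulus contour is the intersection of the deformed tube surface with
the rigid valve disc's plane.  An ellipse is fitted to the contour by a
direct algebraic least-squares fit (Fitzgibbon's ellipse-constrained conic
fit) followed by a geometric refinement, and four diameters are reported:
major, minor, the diameter of the equal-area circle 2*sqrt(ab) and of the
equal-perimeter circle P/pi.  The perimeter-derived diameter varies least
over the cycle and is the headline output.  Mid-systole is the frame of
maximum fitted annulus area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

__all__ = [
    "AnnulusResult",
    "EllipseParams",
    "intersect_annulus",
    "fit_ellipse",
    "fit_ellipse_2d",
    "ellipse_measures",
    "select_mid_systole",
]


@dataclass
class EllipseParams:
    center: np.ndarray  # 2D, in-plane
    a: float  # semi-major
    b: float  # semi-minor
    phi: float  # in-plane orientation, radians


@dataclass
class AnnulusResult:
    frame_index: int
    center: np.ndarray  # 3D image space, mm
    normal: np.ndarray
    major_d: float
    minor_d: float
    area: float
    perimeter: float
    area_derived_d: float
    perimeter_derived_d: float
    valid: bool = True


class AnnulusFailure(RuntimeError):
    """No usable annulus contour for a frame."""


def intersect_annulus(verts: np.ndarray, edges: np.ndarray, plane_z: float = 0.0):
    """Intersect a tube mesh (model frame) with the plane z = plane_z.

    ``edges`` are the unique undirected edges of the triangulation.  Returns
    the crossing points ordered by angle about the axis, forming one closed
    polyline for a star-shaped tube.
    """
    z = verts[:, 2] - plane_z
    e0, e1 = edges[:, 0], edges[:, 1]
    z0, z1 = z[e0], z[e1]
    crossing = (z0 * z1) < 0.0
    if not np.any(crossing):
        raise AnnulusFailure("annulus plane does not intersect the surface")
    t = z0[crossing] / (z0[crossing] - z1[crossing])
    pts = verts[e0[crossing]] + t[:, None] * (verts[e1[crossing]] - verts[e0[crossing]])
    order = np.argsort(np.arctan2(pts[:, 1], pts[:, 0]))
    return pts[order]


def _algebraic_fit(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Fitzgibbon's direct ellipse-constrained conic fit; returns conic
    coefficients [A, B, C, D, E, F] with 4AC - B^2 > 0."""
    D1 = np.stack([x * x, x * y, y * y], axis=1)
    D2 = np.stack([x, y, np.ones_like(x)], axis=1)
    S1 = D1.T @ D1
    S2 = D1.T @ D2
    S3 = D2.T @ D2
    try:
        T = -np.linalg.solve(S3, S2.T)
    except np.linalg.LinAlgError as exc:
        raise AnnulusFailure("degenerate point set for ellipse fit") from exc
    M = S1 + S2 @ T
    C = np.array([[0.0, 0.0, 2.0], [0.0, -1.0, 0.0], [2.0, 0.0, 0.0]])
    try:
        w, V = np.linalg.eig(np.linalg.solve(C, M))
    except np.linalg.LinAlgError as exc:
        raise AnnulusFailure("singular system in ellipse fit") from exc
    cond = 4.0 * V[0] * V[2] - V[1] ** 2
    good = np.where(np.isreal(w) & (cond > 0))[0]
    if good.size == 0:
        raise AnnulusFailure("no elliptical solution")
    a1 = np.real(V[:, good[0]])
    coeffs = np.concatenate([a1, T @ a1])
    return coeffs


def _conic_to_params(c: np.ndarray) -> EllipseParams:
    A, B, C, D, E, F = c
    den = 4.0 * A * C - B * B
    if den <= 0:
        raise AnnulusFailure("conic is not an ellipse")
    cx = (B * E - 2.0 * C * D) / den
    cy = (B * D - 2.0 * A * E) / den
    # value of the quadratic form at the center
    Fc = A * cx * cx + B * cx * cy + C * cy * cy + D * cx + E * cy + F
    M = np.array([[A, B / 2.0], [B / 2.0, C]])
    w, V = np.linalg.eigh(M)
    if np.any(w * (-Fc) <= 0):
        raise AnnulusFailure("degenerate ellipse")
    axes = np.sqrt(-Fc / w)
    i_maj = int(np.argmax(axes))
    a = float(axes[i_maj])
    b = float(axes[1 - i_maj])
    phi = float(np.arctan2(V[1, i_maj], V[0, i_maj]))
    return EllipseParams(center=np.array([cx, cy]), a=a, b=b, phi=phi)


def _geometric_residuals(p, x, y):
    cx, cy, a, b, phi = p
    ct, st = np.cos(phi), np.sin(phi)
    u = (x - cx) * ct + (y - cy) * st
    v = -(x - cx) * st + (y - cy) * ct
    # algebraic distance scaled by the local gradient (Sampson distance)
    f = (u / a) ** 2 + (v / b) ** 2 - 1.0
    g = 2.0 * np.sqrt((u / a**2) ** 2 + (v / b**2) ** 2)
    return f / np.maximum(g, 1e-12)


def fit_ellipse_2d(points: np.ndarray, refine: bool = True) -> EllipseParams:
    """Least-squares ellipse through 2D points: direct algebraic fit plus an
    optional geometric (Sampson-distance) refinement."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 5:
        raise AnnulusFailure("need at least 5 points for an ellipse fit")
    mu = pts.mean(axis=0)
    x, y = pts[:, 0] - mu[0], pts[:, 1] - mu[1]
    par = _conic_to_params(_algebraic_fit(x, y))
    if refine:
        p0 = np.array([par.center[0], par.center[1], par.a, par.b, par.phi])
        sol = optimize.least_squares(
            _geometric_residuals, p0, args=(x, y), method="lm", max_nfev=200
        )
        cx, cy, a, b, phi = sol.x
        a, b = abs(a), abs(b)
        if b > a:
            a, b = b, a
            phi += np.pi / 2.0
        par = EllipseParams(center=np.array([cx, cy]), a=float(a), b=float(b), phi=float(phi))
    return EllipseParams(
        center=par.center + mu, a=par.a, b=par.b, phi=par.phi
    )


def fit_ellipse(points: np.ndarray, plane_origin, plane_normal, refine: bool = True):
    """Fit an ellipse to 3D points lying near a plane.

    The points are projected into an orthonormal in-plane basis; the
    returned tuple is (EllipseParams, basis) with basis rows (e1, e2)."""
    pts = np.asarray(points, dtype=float)
    n = np.asarray(plane_normal, dtype=float)
    n = n / np.linalg.norm(n)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(n @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(n, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    rel = pts - np.asarray(plane_origin, dtype=float)
    uv = np.stack([rel @ e1, rel @ e2], axis=1)
    return fit_ellipse_2d(uv, refine=refine), np.stack([e1, e2])


def ellipse_perimeter(a: float, b: float) -> float:
    """Circumference 4 a E(e^2) via the complete elliptic integral."""
    a, b = max(a, b), min(a, b)
    if a <= 0:
        raise ValueError("degenerate ellipse")
    m = 1.0 - (b / a) ** 2
    return float(4.0 * a * special.ellipe(m))


def ellipse_measures(ellipse: EllipseParams) -> dict:
    """Major/minor diameters, area, perimeter and the equal-area /
    equal-perimeter circle diameters."""
    a, b = ellipse.a, ellipse.b
    if a <= 0 or b <= 0:
        raise ValueError("ellipse axes must be positive")
    perimeter = ellipse_perimeter(a, b)
    return {
        "major_d": 2.0 * a,
        "minor_d": 2.0 * b,
        "area": np.pi * a * b,
        "perimeter": perimeter,
        "area_derived_d": 2.0 * np.sqrt(a * b),
        "perimeter_derived_d": perimeter / np.pi,
    }


def select_mid_systole(results: list[AnnulusResult]) -> int:
    """Frame of maximum fitted annulus area (earliest on ties)."""
    best = None
    for res in results:
        if not res.valid or not np.isfinite(res.area):
            continue
        if best is None or res.area > best[0]:
            best = (res.area, res.frame_index)
    if best is None:
        raise AnnulusFailure("no valid annulus measurement in any frame")
    return best[1]
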
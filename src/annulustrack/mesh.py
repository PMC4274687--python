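"""Cylindrical Doo-Sabin subdivision surface of the LVOT / aortic root.

The shape model is a coarse control net of ``rings`` circles of
``points_per_ring`` control points each, arranged on an open cylinder whose
long axis is the model z-axis.  The smooth surface is the Doo-Sabin limit
surface of that net.  Local deformation displaces every control point along
its own fixed radial direction (perpendicular to the long axis), so a single
scalar per control point maximizes deformation per degree of freedom and the
surface stays a star-shaped tube.

Because Doo-Sabin refinement is linear, every refined vertex is a fixed
linear combination of the control points.  We exploit this twice: refinement
is a single cached matrix product, and the Jacobian of any surface sample
with respect to the radial deformation states is available in closed form
(column j = weight of control point j at the sample times its radial
direction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ControlMesh",
    "LocalSample",
    "AnnulusDisc",
    "make_default_mesh",
    "apply_local_deform",
    "subdivide",
    "SubdivisionSurface",
    "sample_surface",
    "limit_shrink_factor",
    "vertex_normals",
]

DEFAULT_LEVELS = 3


@dataclass(frozen=True)
class ControlMesh:
    """Doo-Sabin control net with per-point radial deformation directions."""

    rings: int
    points_per_ring: int
    control_points: np.ndarray  # (n, 3) mm, model frame
    deformation_dirs: np.ndarray  # (n, 3) unit, z-component 0
    faces: tuple  # quad faces, closed circumferentially, open ends

    @property
    def n_points(self) -> int:
        return self.rings * self.points_per_ring


@dataclass(frozen=True)
class LocalSample:
    """One surface sample in the model frame.

    ``J_l`` is the 3 x n_states Jacobian of the position with respect to the
    radial deformation states; disc samples are rigid and carry J_l = 0.
    """

    p_l: np.ndarray
    n_l: np.ndarray
    J_l: np.ndarray
    surface_id: str  # "tube" | "disc"
    param: tuple


@dataclass(frozen=True)
class AnnulusDisc:
    """Non-deformable disc marking the annulus plane at model mid-height."""

    center: np.ndarray
    normal: np.ndarray
    radius: float


def _cylinder_faces(rings: int, ppr: int) -> tuple:
    faces = []
    for r in range(rings - 1):
        for j in range(ppr):
            a = r * ppr + j
            b = r * ppr + (j + 1) % ppr
            c = (r + 1) * ppr + (j + 1) % ppr
            d = (r + 1) * ppr + j
            faces.append((a, b, c, d))
    return tuple(faces)


def make_default_mesh(
    init_diameter: float,
    init_length: float,
    rings: int = 5,
    points_per_ring: int = 6,
) -> ControlMesh:
    """Build the canonical control net: ``rings`` circles of
    ``points_per_ring`` uniformly distributed points, radius
    ``init_diameter / 2``, rings evenly spaced over ``init_length`` along z
    and centred on z = 0 (the annulus plane)."""
    if init_diameter <= 0 or init_length <= 0:
        raise ValueError("init_diameter and init_length must be positive")
    if rings < 2 or points_per_ring < 3:
        raise ValueError("need at least 2 rings of 3 points")
    radius = init_diameter / 2.0
    zs = np.linspace(-init_length / 2.0, init_length / 2.0, rings)
    ang = 2.0 * np.pi * np.arange(points_per_ring) / points_per_ring
    pts = np.empty((rings * points_per_ring, 3))
    dirs = np.empty_like(pts)
    for r in range(rings):
        sl = slice(r * points_per_ring, (r + 1) * points_per_ring)
        pts[sl, 0] = radius * np.cos(ang)
        pts[sl, 1] = radius * np.sin(ang)
        pts[sl, 2] = zs[r]
        dirs[sl, 0] = np.cos(ang)
        dirs[sl, 1] = np.sin(ang)
        dirs[sl, 2] = 0.0
    return ControlMesh(
        rings=rings,
        points_per_ring=points_per_ring,
        control_points=pts,
        deformation_dirs=dirs,
        faces=_cylinder_faces(rings, points_per_ring),
    )


def apply_local_deform(mesh: ControlMesh, x_l: np.ndarray) -> ControlMesh:
    """Displace control point i by ``x_l[i]`` along its radial direction."""
    x_l = np.asarray(x_l, dtype=float)
    if x_l.shape != (mesh.n_points,):
        raise ValueError(
            f"x_l has length {x_l.size}, mesh has {mesh.n_points} control points"
        )
    pts = mesh.control_points + x_l[:, None] * mesh.deformation_dirs
    return replace(mesh, control_points=pts)


# ---------------------------------------------------------------------------
# Doo-Sabin refinement


def _doo_sabin_weights(n: int) -> np.ndarray:
    """Per-face refinement weights: alpha_0 = (n+5)/4n for the point's own
    vertex, alpha_j = (3 + 2 cos(2 pi j / n))/4n otherwise."""
    w = np.empty((n, n))
    for i in range(n):
        for k in range(n):
            j = (k - i) % n
            if j == 0:
                w[i, k] = (n + 5.0) / (4.0 * n)
            else:
                w[i, k] = (3.0 + 2.0 * math.cos(2.0 * math.pi * j / n)) / (4.0 * n)
    return w


def _order_faces_around_vertex(vid, incident, faces):
    """Cyclic order of the faces incident to an interior vertex, found by
    walking across shared edges; purely topological."""
    nbrs = {}
    for fi in incident:
        face = faces[fi]
        i = face.index(vid)
        n = len(face)
        nbrs[fi] = (face[(i - 1) % n], face[(i + 1) % n])
    order = [incident[0]]
    cur = incident[0]
    cur_out = nbrs[cur][1]
    while len(order) < len(incident):
        nxt = None
        for fj in incident:
            if fj is cur or fj in order:
                continue
            if cur_out in nbrs[fj]:
                nxt = fj
                break
        if nxt is None:
            return None  # fan does not close: boundary-like, skip
        order.append(nxt)
        a, b = nbrs[nxt]
        cur_out = b if a == cur_out else a
        cur = nxt
    return order


def _doo_sabin_once(points: np.ndarray, faces: Sequence[tuple]):
    """One Doo-Sabin refinement of a polygon mesh.

    ``points`` may carry any number of columns (positions, or rows of a
    weight matrix): the scheme is linear, so both refine identically.
    Boundary faces use the standard weights on their truncated neighborhood;
    edge- and vertex-faces are only built where the neighborhood is complete,
    which leaves the two cylinder ends open.
    """
    weights_cache: dict[int, np.ndarray] = {}
    new_pts = []
    fp_index: dict[tuple, int] = {}
    for fi, face in enumerate(faces):
        n = len(face)
        w = weights_cache.get(n)
        if w is None:
            w = _doo_sabin_weights(n)
            weights_cache[n] = w
        pts = w @ points[list(face)]
        for i, vid in enumerate(face):
            fp_index[(fi, vid)] = len(new_pts)
            new_pts.append(pts[i])
    new_pts = np.asarray(new_pts)

    edge_faces: dict[frozenset, list] = {}
    vert_faces: dict[int, list] = {}
    for fi, face in enumerate(faces):
        n = len(face)
        for i in range(n):
            e = frozenset((face[i], face[(i + 1) % n]))
            edge_faces.setdefault(e, []).append(fi)
        for vid in face:
            vert_faces.setdefault(vid, []).append(fi)
    boundary_verts = set()
    for e, fs in edge_faces.items():
        if len(fs) == 1:
            boundary_verts |= set(e)

    new_faces = [tuple(fp_index[(fi, v)] for v in face) for fi, face in enumerate(faces)]
    for e, fs in edge_faces.items():
        if len(fs) != 2:
            continue
        a, b = tuple(e)
        f, g = fs
        new_faces.append(
            (fp_index[(f, a)], fp_index[(f, b)], fp_index[(g, b)], fp_index[(g, a)])
        )
    for vid, fs in vert_faces.items():
        if vid in boundary_verts or len(fs) < 3:
            continue
        order = _order_faces_around_vertex(vid, fs, faces)
        if order is None:
            continue
        new_faces.append(tuple(fp_index[(fi, vid)] for fi in order))
    return new_pts, new_faces


def subdivide(mesh: ControlMesh | tuple, levels: int):
    """Apply ``levels`` Doo-Sabin refinements.

    Accepts either a :class:`ControlMesh` or a ``(points, faces)`` pair and
    returns ``(points, faces)``.  ``levels = 0`` returns the input unchanged.
    """
    if isinstance(mesh, ControlMesh):
        pts, faces = mesh.control_points, list(mesh.faces)
    else:
        pts, faces = mesh
        pts = np.asarray(pts, dtype=float)
        faces = list(faces)
    if levels < 0:
        raise ValueError("levels must be >= 0")
    for _ in range(levels):
        pts, faces = _doo_sabin_once(pts, faces)
    return pts, faces


def _triangulate(faces) -> np.ndarray:
    tris = []
    for face in faces:
        for i in range(1, len(face) - 1):
            tris.append((face[0], face[i], face[i + 1]))
    return np.asarray(tris, dtype=np.int64)


def vertex_normals(verts: np.ndarray, tris: np.ndarray) -> np.ndarray:
    """Area-weighted vertex normals of a tube mesh, oriented radially
    outward from the z-axis (the surface is star-shaped about the axis, so
    the outward side is unambiguous)."""
    a = verts[tris[:, 1]] - verts[tris[:, 0]]
    b = verts[tris[:, 2]] - verts[tris[:, 0]]
    fn = np.cross(a, b)
    cen = (verts[tris[:, 0]] + verts[tris[:, 1]] + verts[tris[:, 2]]) / 3.0
    rad = cen.copy()
    rad[:, 2] = 0.0
    flip = np.einsum("ij,ij->i", fn, rad) < 0.0
    fn[flip] *= -1.0
    vn = np.zeros_like(verts)
    for k in range(3):
        np.add.at(vn, tris[:, k], fn)
    nrm = np.linalg.norm(vn, axis=1)
    nrm[nrm == 0.0] = 1.0
    vn /= nrm[:, None]
    return vn


# ---------------------------------------------------------------------------
# Cached evaluator

_TOPO_CACHE: dict[tuple, tuple] = {}


def _refine_topology(rings: int, ppr: int, levels: int):
    """Refined-vertex weight matrix and triangulation for the cylinder
    topology; combinatorial, hence shared by every mesh of the same layout."""
    key = (rings, ppr, levels)
    hit = _TOPO_CACHE.get(key)
    if hit is not None:
        return hit
    n = rings * ppr
    W = np.eye(n)
    faces = list(_cylinder_faces(rings, ppr))
    for _ in range(levels):
        W, faces = _doo_sabin_once(W, faces)
    tris = _triangulate(faces)
    # unique undirected edges of the triangulation, for plane intersection
    e = np.concatenate([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
    e.sort(axis=1)
    edges = np.unique(e, axis=0)
    out = (W, tuple(tuple(f) for f in faces), tris, edges)
    _TOPO_CACHE[key] = out
    return out


def _pick_grid(n_tube: int) -> tuple[int, int]:
    """Factor the tube sample budget into an (angular, axial) grid close to
    the 4:3 aspect that 300 -> 20 x 15 implies."""
    best = None
    target = math.sqrt(n_tube * 4.0 / 3.0)
    for nt in range(3, n_tube + 1):
        if n_tube % nt:
            continue
        na = n_tube // nt
        if na < 2:
            continue
        score = abs(nt - target)
        if best is None or score < best[0]:
            best = (score, nt, na)
    if best is None:  # prime budgets: nearest non-exact grid
        nt = max(3, int(round(target)))
        na = max(2, int(round(n_tube / nt)))
        return nt, na
    return best[1], best[2]


class SubdivisionSurface:
    """Evaluator for one control-mesh geometry at a fixed refinement depth.

    Holds the (topology-cached) refined weight matrix, the triangulation and
    a fixed set of sample vertices laid out on a uniform (angle, axial)
    parameter grid of the undeformed reference surface.  The sample
    parameterization is material: the same refined vertices are tracked no
    matter the deformation state.
    """

    def __init__(
        self,
        mesh: ControlMesh,
        levels: int = DEFAULT_LEVELS,
        n_tube: int = 300,
        n_disc: int = 40,
    ):
        self.mesh = mesh
        self.levels = levels
        self.W, self.faces, self.tris, self.edges = _refine_topology(
            mesh.rings, mesh.points_per_ring, levels
        )
        self.ref_verts = self.W @ mesh.control_points
        self.n_theta, self.n_axial = _pick_grid(n_tube)
        self._select_tube_samples()
        self._build_disc(n_disc)

    # -- tube samples -----------------------------------------------------
    def _select_tube_samples(self) -> None:
        v = self.ref_verts
        theta = np.arctan2(v[:, 1], v[:, 0])
        z = v[:, 2]
        rbar = float(np.hypot(v[:, 0], v[:, 1]).mean())
        z_lo, z_hi = z.min(), z.max()
        t_theta = 2.0 * np.pi * (np.arange(self.n_theta) + 0.5) / self.n_theta - np.pi
        t_z = z_lo + (np.arange(self.n_axial) + 0.5) / self.n_axial * (z_hi - z_lo)
        dth = theta[None, :] - t_theta[:, None]
        dth = (dth + np.pi) % (2.0 * np.pi) - np.pi
        idx = np.empty((self.n_theta, self.n_axial), dtype=np.int64)
        for j in range(self.n_axial):
            d2 = (rbar * dth) ** 2 + (z[None, :] - t_z[j]) ** 2
            idx[:, j] = np.argmin(d2, axis=1)
        self.sample_idx = idx.reshape(-1)
        gi, gj = np.meshgrid(
            np.arange(self.n_theta), np.arange(self.n_axial), indexing="ij"
        )
        self.grid_idx = np.stack([gi.reshape(-1), gj.reshape(-1)], axis=1)
        self.params = np.stack(
            [np.repeat(t_theta, self.n_axial), np.tile(t_z, self.n_theta)], axis=1
        )
        self.Ws = self.W[self.sample_idx]  # (n_samples, n_ctrl)

    # -- annulus disc ------------------------------------------------------
    def _build_disc(self, n_disc: int) -> None:
        ring = self.annulus_ring(np.zeros(self.mesh.n_points))
        radius = float(np.hypot(ring[:, 0], ring[:, 1]).mean()) if len(ring) else 0.0
        self.disc = AnnulusDisc(
            center=np.zeros(3), normal=np.array([0.0, 0.0, 1.0]), radius=radius
        )
        ang = 2.0 * np.pi * np.arange(n_disc) / n_disc
        self.disc_points = np.stack(
            [radius * np.cos(ang), radius * np.sin(ang), np.zeros(n_disc)], axis=1
        )
        # two probing directions for the disc rim.  Axial probes (along the
        # disc-plane normal) see the echogenic annulus band as a peak and
        # localize the annulus plane along the axis -- tube normals on a
        # stiff cylinder are purely radial and carry no axial information.
        # Radial probes reinforce the waist radius once the plane is found.
        self.disc_normals_axial = np.tile(np.array([0.0, 0.0, 1.0]), (n_disc, 1))
        self.disc_normals_radial = np.stack(
            [np.cos(ang), np.sin(ang), np.zeros(n_disc)], axis=1
        )
        self.disc_normals = self.disc_normals_axial

    # -- evaluation --------------------------------------------------------
    def deformed_controls(self, x_l: np.ndarray) -> np.ndarray:
        x_l = np.asarray(x_l, dtype=float)
        return self.mesh.control_points + x_l[:, None] * self.mesh.deformation_dirs

    def refined_verts(self, x_l: np.ndarray) -> np.ndarray:
        return self.W @ self.deformed_controls(x_l)

    def sample_batch(self, x_l: np.ndarray):
        """Vectorized tube samples: positions (n,3), unit outward normals
        (n,3) and subdivision weights (n, n_ctrl) from which the deformation
        Jacobian follows as J_l[:, j] = Ws[:, j, None] * deformation_dirs[j]."""
        verts = self.refined_verts(x_l)
        normals = vertex_normals(verts, self.tris)
        return verts[self.sample_idx], normals[self.sample_idx], self.Ws

    def annulus_ring(self, x_l: np.ndarray) -> np.ndarray:
        """Intersection polyline of the deformed surface with the annulus
        plane z = 0, ordered by angle about the axis."""
        verts = self.refined_verts(x_l)
        z = verts[:, 2]
        e0, e1 = self.edges[:, 0], self.edges[:, 1]
        z0, z1 = z[e0], z[e1]
        crossing = (z0 * z1) < 0.0
        if not np.any(crossing):
            on = np.abs(z) < 1e-12
            pts = verts[on]
        else:
            t = z0[crossing] / (z0[crossing] - z1[crossing])
            pts = verts[e0[crossing]] + t[:, None] * (
                verts[e1[crossing]] - verts[e0[crossing]]
            )
        if len(pts) == 0:
            return np.empty((0, 3))
        order = np.argsort(np.arctan2(pts[:, 1], pts[:, 0]))
        return pts[order]


def limit_shrink_factor(
    points_per_ring: int = 6, rings: int = 5, levels: int = DEFAULT_LEVELS
) -> float:
    """Ratio of the limit-surface waist radius to the control-ring radius.

    A control polygon circumscribes its Doo-Sabin limit curve, so a net built
    at radius R yields a surface of radius ~0.87 R for hexagonal rings.  The
    pipeline divides by this factor when posing the initial model so that the
    rendered surface, not the control cage, matches the requested diameter.
    """
    mesh = make_default_mesh(2.0, 2.0, rings=rings, points_per_ring=points_per_ring)
    surf = SubdivisionSurface(mesh, levels=levels, n_tube=60, n_disc=8)
    return surf.disc.radius / 1.0


def sample_surface(
    mesh: ControlMesh,
    x_l: np.ndarray,
    n_tube: int = 300,
    n_disc: int = 40,
    levels: int = DEFAULT_LEVELS,
) -> list[LocalSample]:
    """Sample the deformed surface and the annulus disc in the model frame.

    Returns ``n_tube`` tube samples on a fixed (angle, axial) grid, each with
    position, outward unit normal and deformation Jacobian, followed by
    ``n_disc`` rigid samples on the disc rim (J_l = 0).
    """
    if n_tube <= 0 or n_disc <= 0:
        raise ValueError("sample counts must be positive")
    x_l = np.asarray(x_l, dtype=float)
    if x_l.shape != (mesh.n_points,):
        raise ValueError("x_l length mismatch")
    surf = SubdivisionSurface(mesh, levels=levels, n_tube=n_tube, n_disc=n_disc)
    P, N, Ws = surf.sample_batch(x_l)
    dirs = mesh.deformation_dirs
    out = []
    for i in range(len(P)):
        J = dirs.T * Ws[i][None, :]
        out.append(
            LocalSample(
                p_l=P[i],
                n_l=N[i],
                J_l=J,
                surface_id="tube",
                param=(float(surf.params[i, 0]), float(surf.params[i, 1])),
            )
        )
    nz = np.zeros((3, mesh.n_points))
    for i in range(len(surf.disc_points)):
        out.append(
            LocalSample(
                p_l=surf.disc_points[i],
                n_l=surf.disc_normals[i],
                J_l=nz,
                surface_id="disc",
                param=(float(i) / len(surf.disc_points), 0.0),
            )
        )
    return out
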
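"""Annulus extraction: plane intersection, ellipse fitting and measures."""

import numpy as np
import pytest
from scipy import integrate

from annulustrack import annulus as A
from annulustrack import mesh as M


def analytic_cylinder(radius=10.0, height=30.0, n_theta=80, n_z=40, tilt=0.0):
    """Fine triangulated cylinder, optionally tilted about the x-axis, as an
    analytic oracle mesh (independent of the subdivision machinery)."""
    th = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    z = np.linspace(-height / 2, height / 2, n_z)
    T, Z = np.meshgrid(th, z, indexing="ij")
    pts = np.stack(
        [radius * np.cos(T).ravel(), radius * np.sin(T).ravel(), Z.ravel()], axis=1
    )
    if tilt:
        c, s = np.cos(tilt), np.sin(tilt)
        R = np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
        pts = pts @ R.T
    tris = []
    for i in range(n_theta):
        for j in range(n_z - 1):
            a = i * n_z + j
            b = ((i + 1) % n_theta) * n_z + j
            tris.append((a, b, a + 1))
            tris.append((b, b + 1, a + 1))
    tris = np.asarray(tris)
    e = np.concatenate([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
    e.sort(axis=1)
    return pts, np.unique(e, axis=0)


class TestIntersection:
    def test_perpendicular_section_is_circle(self):
        verts, edges = analytic_cylinder(radius=10.0)
        pts = A.intersect_annulus(verts, edges)
        r = np.hypot(pts[:, 0], pts[:, 1])
        # crossings on diagonal edges sag by the chord factor cos(pi/n)
        np.testing.assert_allclose(r, 10.0, atol=10.0 * (1 - np.cos(np.pi / 80)) + 1e-9)

    def test_oblique_section_is_analytic_ellipse(self):
        alpha = np.deg2rad(30.0)
        verts, edges = analytic_cylinder(radius=10.0, tilt=alpha, n_theta=400, n_z=200)
        pts = A.intersect_annulus(verts, edges)
        par = A.fit_ellipse_2d(pts[:, :2], refine=True)
        assert par.a == pytest.approx(10.0 / np.cos(alpha), rel=2e-3)
        assert par.b == pytest.approx(10.0, rel=2e-3)

    def test_plane_outside_tube_fails(self):
        verts, edges = analytic_cylinder(height=10.0)
        with pytest.raises(A.AnnulusFailure):
            A.intersect_annulus(verts, edges, plane_z=20.0)

    def test_subdivision_section_of_cylinder(self):
        surf = M.SubdivisionSurface(M.make_default_mesh(24.0, 40.0))
        ring = surf.annulus_ring(np.zeros(30))
        r = np.hypot(ring[:, 0], ring[:, 1])
        # hexagonal control ring leaves a small azimuthal ripple
        assert r.std() / r.mean() < 0.02


class TestEllipseFit:
    def test_exact_circle(self):
        th = np.linspace(0, 2 * np.pi, 40, endpoint=False)
        pts = 10.0 * np.stack([np.cos(th), np.sin(th)], axis=1)
        par = A.fit_ellipse_2d(pts)
        assert par.a == pytest.approx(10.0, abs=1e-9)
        assert par.b == pytest.approx(10.0, abs=1e-9)
        np.testing.assert_allclose(par.center, 0.0, atol=1e-9)

    def test_exact_ellipse(self):
        th = np.linspace(0, 2 * np.pi, 40, endpoint=False)
        pts = np.stack([15.0 * np.cos(th) + 2.0, 10.0 * np.sin(th) - 1.0], axis=1)
        par = A.fit_ellipse_2d(pts)
        assert par.a == pytest.approx(15.0, abs=1e-8)
        assert par.b == pytest.approx(10.0, abs=1e-8)
        np.testing.assert_allclose(par.center, [2.0, -1.0], atol=1e-8)

    def test_noisy_ellipse_monte_carlo(self):
        rng = np.random.default_rng(33)
        th = np.linspace(0, 2 * np.pi, 40, endpoint=False)
        a_hat = []
        for _ in range(500):
            pts = np.stack([15.0 * np.cos(th), 10.0 * np.sin(th)], axis=1)
            pts += rng.normal(0, 0.2, pts.shape)
            a_hat.append(A.fit_ellipse_2d(pts).a)
        assert abs(np.mean(a_hat) - 15.0) < 0.1

    def test_too_few_points(self):
        with pytest.raises(A.AnnulusFailure):
            A.fit_ellipse_2d(np.zeros((4, 2)))

    def test_3d_fit_in_tilted_plane(self):
        rng = np.random.default_rng(0)
        n = np.array([0.2, -0.3, 0.93])
        n /= np.linalg.norm(n)
        e1 = np.cross(n, [1.0, 0, 0])
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(n, e1)
        th = np.linspace(0, 2 * np.pi, 50, endpoint=False)
        pts3 = (
            np.array([1.0, 2.0, 3.0])
            + 12.0 * np.outer(np.cos(th), e1)
            + 8.0 * np.outer(np.sin(th), e2)
        )
        par, basis = A.fit_ellipse(pts3, [1.0, 2.0, 3.0], n)
        assert par.a == pytest.approx(12.0, abs=1e-6)
        assert par.b == pytest.approx(8.0, abs=1e-6)


class TestMeasures:
    def test_circle_closed_forms(self):
        m = A.ellipse_measures(A.EllipseParams(np.zeros(2), 5.0, 5.0, 0.0))
        assert m["area"] == pytest.approx(np.pi * 25.0)
        assert m["perimeter"] == pytest.approx(2 * np.pi * 5.0, rel=1e-12)
        assert m["area_derived_d"] == pytest.approx(10.0)
        assert m["perimeter_derived_d"] == pytest.approx(10.0)

    def test_two_to_one_ellipse(self):
        m = A.ellipse_measures(A.EllipseParams(np.zeros(2), 2.0, 1.0, 0.0))
        assert m["area"] == pytest.approx(2 * np.pi)
        assert m["area_derived_d"] == pytest.approx(2 * np.sqrt(2.0))

    def test_perimeter_matches_quadrature(self):
        a, b = 15.0, 10.0
        arc = lambda t: np.sqrt((a * np.sin(t)) ** 2 + (b * np.cos(t)) ** 2)
        expected, _ = integrate.quad(arc, 0, 2 * np.pi, limit=200)
        assert A.ellipse_perimeter(a, b) == pytest.approx(expected, rel=1e-6)

    @pytest.mark.parametrize("a,b", [(5.0, 5.0), (12.0, 9.0), (20.0, 6.0)])
    def test_measure_orderings(self, a, b):
        m = A.ellipse_measures(A.EllipseParams(np.zeros(2), a, b, 0.3))
        assert m["minor_d"] <= m["area_derived_d"] + 1e-12
        assert m["area_derived_d"] <= m["major_d"] + 1e-12
        # isoperimetric inequality, equality only for the circle
        assert m["perimeter_derived_d"] >= m["area_derived_d"] - 1e-9
        if a == b:
            assert m["perimeter_derived_d"] == pytest.approx(
                m["area_derived_d"], abs=1e-9
            )

    def test_rigid_motion_invariance(self):
        th = np.linspace(0, 2 * np.pi, 50, endpoint=False)
        pts = np.stack(
            [12.0 * np.cos(th), 8.0 * np.sin(th), np.zeros_like(th)], axis=1
        )
        from annulustrack.transform import rotation_matrix

        R = rotation_matrix([0.4, -0.2, 0.7])
        t = np.array([5.0, -3.0, 11.0])
        moved = pts @ R.T + t
        n = R @ np.array([0.0, 0.0, 1.0])
        par, _ = A.fit_ellipse(moved, t, n)
        m = A.ellipse_measures(par)
        assert m["major_d"] == pytest.approx(24.0, abs=1e-6)
        assert m["minor_d"] == pytest.approx(16.0, abs=1e-6)


class TestMidSystole:
    def _results(self, areas, valid=None):
        valid = valid or [True] * len(areas)
        return [
            A.AnnulusResult(
                frame_index=i,
                center=np.zeros(3),
                normal=np.array([0, 0, 1.0]),
                major_d=1,
                minor_d=1,
                area=a,
                perimeter=1,
                area_derived_d=1,
                perimeter_derived_d=1,
                valid=ok,
            )
            for i, (a, ok) in enumerate(zip(areas, valid))
        ]

    def test_argmax(self):
        assert A.select_mid_systole(self._results([3.0, 5.0, 4.0])) == 1

    def test_tie_breaks_earliest(self):
        assert A.select_mid_systole(self._results([5.0, 5.0, 4.0])) == 0

    def test_invalid_frames_skipped(self):
        res = self._results([9.0, 5.0, 4.0], valid=[False, True, True])
        assert A.select_mid_systole(res) == 1

    def test_no_valid_frames(self):
        with pytest.raises(A.AnnulusFailure):
            A.select_mid_systole(self._results([1.0], valid=[False]))
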
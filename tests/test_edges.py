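"""Normal-profile extraction, step/peak fitting, outlier rejection and
variance normalization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from annulustrack import edges as E


def make_config(**kw):
    return E.EdgeConfig(**kw)


class TestExtractProfile:
    def test_constant_volume(self):
        vol = np.full((30, 30, 30), 7.0)
        cfg = make_config(search_length_mm=5.0, n_samples=11)
        prof = E.extract_profile(vol, [15.0, 15.0, 15.0], [1.0, 0.0, 0.0], cfg)
        assert prof.usable
        np.testing.assert_allclose(prof.intensities, 7.0)

    def test_half_space_step(self):
        # I = 100 * (x > 15.5) on the voxel grid, profile along +x
        x = np.arange(32)
        vol = np.where(x[:, None, None] > 15.5, 100.0, 0.0) * np.ones((1, 32, 32))
        cfg = make_config(search_length_mm=5.0, n_samples=11)
        prof = E.extract_profile(vol, [15.5, 16.0, 16.0], [1.0, 0.0, 0.0], cfg)
        expected = np.where(prof.offsets > 0, 100.0, 0.0)
        expected[prof.offsets == 0.0] = 50.0  # trilinear midpoint
        np.testing.assert_allclose(prof.intensities, expected)

    def test_offsets_cover_search_range(self):
        cfg = make_config(search_length_mm=14.0, n_samples=29)
        offs = cfg.offsets()
        assert offs[0] == -14.0 and offs[-1] == 14.0
        assert len(offs) == 29
        np.testing.assert_allclose(np.diff(offs), 1.0)

    def test_profile_outside_volume_unusable(self):
        vol = np.zeros((10, 10, 10))
        cfg = make_config(search_length_mm=12.0, n_samples=17)
        prof = E.extract_profile(vol, [0.0, 5.0, 5.0], [-1.0, 0.0, 0.0], cfg)
        assert not prof.usable


class TestFitEdge:
    def test_ideal_step_between_samples(self):
        cfg = make_config(search_length_mm=14.0, n_samples=29, fit_model="step")
        offs = cfg.offsets()
        prof = E.EdgeProfile(
            intensities=np.where(offs > 2.0, 100.0, 0.0),
            offsets=offs,
            origin=np.zeros(3),
            direction=np.array([1.0, 0.0, 0.0]),
        )
        v, res, height = E.fit_edge(prof, cfg)
        assert v == pytest.approx(2.5, abs=1e-9)
        assert res == pytest.approx(0.0, abs=1e-9)
        assert height == pytest.approx(100.0)

    def test_flat_profile_rejected(self):
        cfg = make_config(search_length_mm=5.0, n_samples=11)
        prof = E.EdgeProfile(
            intensities=np.full(11, 42.0),
            offsets=cfg.offsets(),
            origin=np.zeros(3),
            direction=np.array([1.0, 0.0, 0.0]),
        )
        assert E.fit_edge(prof, cfg) is None

    @pytest.mark.parametrize("d", [-10.0, -4.0, 0.0, 3.0, 9.0, 13.0])
    def test_step_sweep_within_half_sample(self, d):
        cfg = make_config(search_length_mm=14.0, n_samples=29, fit_model="step")
        offs = cfg.offsets()
        X = np.where(offs > d, 100.0, 0.0)[None, :]
        v, _, _, ok = E.fit_edges(X, offs, cfg)
        assert ok[0]
        assert abs(v[0] - d) <= 0.5 + 1e-9

    def test_noisy_step_monte_carlo(self):
        # exhaustive LS split fit is its own oracle; the mean detected
        # displacement must be unbiased at the 0.2 mm level
        rng = np.random.default_rng(17)
        cfg = make_config(search_length_mm=14.0, n_samples=29, fit_model="step")
        offs = cfg.offsets()
        clean = np.where(offs > -3.5, 100.0, 0.0)
        X = clean[None, :] + rng.normal(0, 5.0, size=(200, 29))
        v, res, h, ok = E.fit_edges(X, offs, cfg)
        assert ok.all()
        assert abs(v.mean() - (-3.5)) < 0.2
        # residual of the fit is close to the injected noise energy
        assert res.mean() == pytest.approx(29 * 25.0, rel=0.25)

    def test_peak_fit_centers_on_bump(self):
        cfg = make_config(
            search_length_mm=7.0, n_samples=15, fit_model="peak", peak_halfwidth=2
        )
        offs = cfg.offsets()
        X = 10.0 + 150.0 * np.exp(-0.5 * ((offs - 2.0) / 1.2) ** 2)[None, :]
        v, _, h, ok = E.fit_edges(X, offs, cfg)
        assert ok[0]
        assert abs(v[0] - 2.0) <= 0.5
        assert h[0] > 50


class TestOutlierRejection:
    def _edges(self, vs, heights, n_axial=1):
        return [
            E.EdgeMeasurement(
                v=v,
                r=1.0,
                h=np.zeros(2),
                step_height=h,
                residual=1.0,
                grid=(i // n_axial, i % n_axial),
            )
            for i, (v, h) in enumerate(zip(vs, heights))
        ]

    def test_homogeneous_set_kept(self):
        cfg = make_config(neighbor_max_delta_mm=3.0)
        edges = self._edges([1.0] * 8, [50.0] * 8)
        out = E.reject_outliers(edges, cfg, n_theta=8, n_axial=1, min_step_height=10.0)
        assert all(e.accepted for e in out)

    def test_single_outlier_rejected(self):
        # 4 x 2 grid: each edge has 3-4 neighbors, so the single outlier
        # cannot corrupt its neighbors' medians
        cfg = make_config(neighbor_max_delta_mm=3.0)
        vs = [0.0] * 8
        vs[2] = 10.0  # grid position (1, 0)
        out = E.reject_outliers(
            self._edges(vs, [50.0] * 8, n_axial=2), cfg, 4, 2, min_step_height=10.0
        )
        assert not out[2].accepted
        assert sum(e.accepted for e in out) == 7

    def test_weak_step_rejected(self):
        cfg = make_config()
        out = E.reject_outliers(
            self._edges([0.0] * 4, [5.0, 50.0, 50.0, 50.0]), cfg, 4, 1, 10.0
        )
        assert not out[0].accepted

    @given(st.lists(st.floats(-5, 5), min_size=4, max_size=12))
    @settings(deadline=None, derandomize=True, max_examples=30)
    def test_rejection_shrinks_monotonically(self, vs):
        # the accepted set is always a subset, and re-running on the kept
        # edges can only shrink it further (never re-accepts)
        cfg = make_config(neighbor_max_delta_mm=3.0)
        edges = self._edges(vs, [50.0] * len(vs))
        once = E.reject_outliers(edges, cfg, len(vs), 1, 10.0)
        assert len(once) == len(edges)
        kept = [e for e in once if e.accepted]
        assert len(kept) <= len(edges)
        twice = E.reject_outliers(kept, cfg, len(vs), 1, 10.0)
        kept2 = {e.grid for e in twice if e.accepted}
        assert kept2 <= {e.grid for e in kept}
        # a mutually consistent set is stable
        if max(vs) - min(vs) <= cfg.neighbor_max_delta_mm:
            assert len(kept2) == len(vs)

    def test_min_step_height_monotone(self):
        rng = np.random.default_rng(4)
        edges = self._edges(rng.normal(0, 1, 10), rng.uniform(5, 60, 10))
        cfg = make_config()
        sizes = []
        for thr in [0.0, 10.0, 30.0, 55.0]:
            out = E.reject_outliers(edges, cfg, 10, 1, thr)
            sizes.append(sum(e.accepted for e in out))
        assert sizes == sorted(sizes, reverse=True)


class TestVarianceNormalization:
    def test_proportional_scaling(self):
        r = E.normalized_variances(np.array([1.0, 3.0]), r_edge=8.0)
        np.testing.assert_allclose(r, [2.0, 6.0], rtol=1e-5)

    def test_zero_residuals_become_uniform(self):
        r = E.normalized_variances(np.zeros(4), r_edge=1.0)
        np.testing.assert_allclose(r, 0.25)

    @given(
        st.lists(st.floats(0, 1e4), min_size=1, max_size=50),
        st.floats(0.1, 100.0),
    )
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_sum_equals_r_edge(self, residuals, r_edge):
        r = E.normalized_variances(np.array(residuals), r_edge)
        assert abs(r.sum() - r_edge) < 1e-12 * max(1.0, r_edge)
        assert (r > 0).all()

    def test_empty_accepted_set_signals_skip(self):
        edges = [
            E.EdgeMeasurement(
                v=0.0, r=1.0, h=np.zeros(2), step_height=1.0, residual=1.0,
                accepted=False,
            )
        ]
        assert E.normalize_variances(edges, 1.0) == []

    def test_total_information_scales_inversely_with_r_edge(self):
        rng = np.random.default_rng(2)
        H = rng.normal(size=(20, 5))
        res = rng.uniform(0, 2, 20)
        info1 = (H.T / E.normalized_variances(res, 1.0)) @ H
        info2 = (H.T / E.normalized_variances(res, 2.0)) @ H
        np.testing.assert_allclose(info1, 2.0 * info2, rtol=1e-10)
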
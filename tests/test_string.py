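"""Finite-temperature string method: initialisation, relaxation, clustering."""

import numpy as np
import pytest

from tetrafes import string_method as sm, toy_systems as ts
from tetrafes.errors import InputError
from tetrafes.units import kbt


class TestInitialize:
    def test_linear_is_colinear_and_equally_spaced(self):
        p = sm.initialize_string([0, 0], [10, 0], M=10)
        assert p.n_images == 11
        assert np.allclose(p.images[:, 0], np.arange(11.0))
        assert np.allclose(p.images[:, 1], 0.0)
        assert np.allclose(p.arc_length, np.linspace(0, 1, 11))

    def test_waypoint_on_segment_equals_linear(self):
        lin = sm.initialize_string([0, 0], [4, 4], M=8)
        via = sm.initialize_string([0, 0], [4, 4], M=8, mode="through_point",
                                   waypoint=[2, 2])
        assert np.allclose(lin.images, via.images, atol=1e-12)

    def test_coincident_endpoints_rejected(self):
        with pytest.raises(InputError):
            sm.initialize_string([1, 1], [1, 1], M=10)

    def test_too_few_images_rejected(self):
        with pytest.raises(InputError):
            sm.initialize_string([0, 0], [1, 1], M=4)

    def test_reparameterization_preserves_straight_line(self):
        images = np.linspace([0, 0], [3, 4], 17)
        out = sm._reparameterize(images, 17)
        assert np.max(np.abs(out - images)) < 1e-8


class TestRelax:
    def test_single_basin_collapses_images(self):
        kappa = 4.0
        s = ts.make_surface("quad_bowl_nd", n=2, kappa=kappa)
        a, b = [-0.2, 0.0], [0.2, 0.0]  # both ends beside the minimum
        p = sm.initialize_string(a, b, M=10)
        out = sm.fts_relax(s, p, n_cell_samples=100, sampler_dt=2e-3, T=300.0,
                           alpha=0.2, smooth=0.1, max_iter=40, tol=1e-4,
                           seed=0, endpoint_mode="relaxed")
        radius = 3.0 * np.sqrt(kbt(300.0) / kappa)
        assert np.all(np.linalg.norm(out.images, axis=1) < radius)
        assert out.free_energy.max() - out.free_energy.min() < 3.0 * kbt(300.0)

    def test_same_seed_same_path(self):
        s = ts.make_surface("quad_bowl_nd", n=2, kappa=1.0)
        p = sm.initialize_string([-2, 0], [2, 0], M=8)
        kw = dict(n_cell_samples=50, sampler_dt=2e-3, T=300.0, max_iter=10,
                  tol=1e-6, seed=42)
        a = sm.fts_relax(s, p, **kw)
        b = sm.fts_relax(s, p, **kw)
        assert np.array_equal(a.images, b.images)

    def test_voronoi_restriction_holds_for_retained_samples(self):
        s = ts.make_surface("quad_bowl_nd", n=2, kappa=1.0)
        p = sm.initialize_string([-2, 0], [2, 0], M=8)
        out = sm.fts_relax(s, p, n_cell_samples=60, sampler_dt=2e-3, T=300.0,
                           max_iter=5, tol=1e-9, seed=1, collect_samples=True)
        images = out.cell_samples["images"]
        for i, samples in enumerate(out.cell_samples["samples"]):
            d = np.linalg.norm(samples[:, None, :] - images[None, :, :], axis=2)
            assert np.all(d.argmin(axis=1) == i)

    def test_endpoints_fixed_by_default(self):
        s = ts.make_surface("muller_brown")
        a, b = np.array([-0.558, 1.442]), np.array([0.623, 0.028])
        p = sm.initialize_string(a, b, M=12)
        out = sm.fts_relax(s, p, n_cell_samples=40, sampler_dt=2e-5, T=500.0,
                           max_iter=10, tol=1e-9, seed=2)
        assert np.array_equal(out.images[0], a)
        assert np.array_equal(out.images[-1], b)


class TestPathFreeEnergy:
    def test_constant_surface_gives_zero_profile(self):
        s = ts.QuadBowlND(n=2, kappa=1.0)
        s.energy = lambda x: np.zeros(np.asarray(x, float).shape[:-1])
        p = sm.initialize_string([0, 0], [1, 1], M=8)
        assert np.allclose(sm.path_free_energy(s, p), 0.0)

    def test_invariant_to_gauge_shift(self):
        s = ts.make_surface("quad_bowl_nd", n=2, kappa=1.0)
        shifted = ts.QuadBowlND(n=2, kappa=1.0)
        orig = shifted.energy
        shifted.energy = lambda x: orig(x) + 11.0
        p = sm.initialize_string([-2, 0], [2, 0], M=8)
        assert np.allclose(sm.path_free_energy(s, p),
                           sm.path_free_energy(shifted, p))

    def test_open_to_folded_gap_matches_fixture_depth(self):
        # string on the analytic 6-D benchmark: the folded endpoint sits
        # 2 kcal/mol below the open endpoint by construction
        s = ts.make_surface("sym6d_wells")
        p = sm.initialize_string(ts.SYM6D_OPEN, ts.SYM6D_FOLDED, M=16)
        out = sm.fts_relax(s, p, n_cell_samples=60, sampler_dt=5e-3, T=300.0,
                           max_iter=20, tol=1e-4, seed=3)
        assert out.free_energy[0] == 0.0
        assert out.free_energy[-1] == pytest.approx(-ts.SYM6D_DEPTH_GAP, abs=0.5)


class TestClusterPaths:
    def _path(self, images):
        return sm.StringPath(np.asarray(images, float))

    def test_duplicate_paths_form_one_group(self):
        imgs = np.linspace([0, 0], [1, 1], 9)
        assert sm.cluster_paths([self._path(imgs), self._path(imgs)], 0.5) == [[0, 1]]

    def test_threshold_extremes(self):
        a = self._path(np.linspace([0, 0], [1, 1], 9))
        b = self._path(np.linspace([0, 5], [1, 6], 9))
        assert sm.cluster_paths([a, b], np.inf) == [[0, 1]]
        assert sm.cluster_paths([a, b], 0.0) == [[0], [1]]

    def test_mixed_image_counts_rejected(self):
        a = self._path(np.linspace([0, 0], [1, 1], 9))
        b = self._path(np.linspace([0, 0], [1, 1], 11))
        with pytest.raises(InputError):
            sm.cluster_paths([a, b], 1.0)

    def test_engineered_channels_separate(self, two_channel_surface):
        surf = two_channel_surface
        a, b = np.array([-3.0, 0.0]), np.array([3.0, 0.0])
        paths = []
        for wp, seed in (([0, 2], 1), ([0, -2], 2), ([0, 2], 3), ([0, -2], 4)):
            init = sm.initialize_string(a, b, M=16, mode="through_point",
                                        waypoint=wp)
            paths.append(sm.fts_relax(surf, init, n_cell_samples=120,
                                      sampler_dt=2e-3, T=200.0, alpha=0.1,
                                      smooth=0.1, max_iter=60, tol=6e-3,
                                      seed=seed))
        D = np.array([[np.mean(np.linalg.norm(p.images - q.images, axis=1))
                       for q in paths] for p in paths])
        intra = max(D[0, 2], D[1, 3])
        inter = min(D[0, 1], D[0, 3], D[2, 1], D[2, 3])
        assert intra < inter
        groups = sm.cluster_paths(paths, 0.5 * (intra + inter))
        assert groups == [[0, 2], [1, 3]]
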
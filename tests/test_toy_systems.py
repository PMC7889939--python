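"""Benchmark surfaces: gradients, symmetry, sampling statistics, marginals."""

import numpy as np
import pytest
from scipy.optimize import minimize

from tetrafes import toy_systems as ts
from tetrafes.cvlib import reverse_order
from tetrafes.errors import DomainError, InputError
from tetrafes.units import kbt


def _random_interior(surface, rng, n=100):
    lo, hi = surface.bounds[:, 0], surface.bounds[:, 1]
    span = hi - lo
    return lo + span * (0.05 + 0.9 * rng.random((n, surface.dimension)))


class TestCatalog:
    def test_unknown_name_is_error(self):
        with pytest.raises(InputError, match="unknown surface"):
            ts.make_surface("no_such_surface")

    def test_double_well_minima_and_barrier(self):
        s = ts.make_surface("double_well_1d", h=5.0)
        e, g = ts.eval_surface(s, np.array([0.0]))
        assert e == pytest.approx(5.0) and g[0] == pytest.approx(0.0)
        for x in (-1.0, 1.0):
            e, g = ts.eval_surface(s, np.array([x]))
            assert e == pytest.approx(0.0) and g[0] == pytest.approx(0.0)

    def test_quad_bowl_minimum(self):
        s = ts.make_surface("quad_bowl_nd", n=3, kappa=2.0, center=[1, 2, 3])
        e, g = ts.eval_surface(s, np.array([1.0, 2.0, 3.0]))
        assert e == 0.0 and np.allclose(g, 0.0)

    def test_muller_brown_deepest_minimum_location(self):
        # independent oracle: numerical minimisation of the analytic form
        s = ts.make_surface("muller_brown")
        res = minimize(lambda x: s.energy(x[None])[0], [-0.5, 1.5],
                       jac=lambda x: s.gradient(x[None])[0], method="BFGS")
        assert np.allclose(res.x, [-0.558, 1.442], atol=5e-3)

    def test_out_of_domain_is_error(self):
        s = ts.make_surface("muller_brown")
        with pytest.raises(DomainError):
            ts.eval_surface(s, np.array([5.0, 5.0]))


@pytest.mark.parametrize("name,kwargs", [
    ("double_well_1d", {}),
    ("muller_brown", {}),
    ("quad_bowl_nd", {"n": 4, "kappa": 3.0}),
    ("sym6d_wells", {}),
])
def test_gradient_matches_finite_differences(name, kwargs, rng):
    surface = ts.make_surface(name, **kwargs)
    pts = _random_interior(surface, rng, n=100)
    h = 1e-5
    g = surface.gradient(pts)
    scale = np.abs(g).max() + 1.0
    for j in range(surface.dimension):
        e = np.zeros(surface.dimension)
        e[j] = h
        fd = (surface.energy(pts + e) - surface.energy(pts - e)) / (2 * h)
        assert np.allclose(fd, g[:, j], atol=1e-5 * scale, rtol=1e-5)


class TestSym6D:
    def test_exact_reversal_symmetry(self, rng):
        s = ts.make_surface("sym6d_wells")
        d = rng.uniform(3, 38, (1000, 6))
        dr = np.stack([np.asarray(reverse_order(x)) for x in d])
        assert np.allclose(s.energy(d), s.energy(dr), atol=1e-10)

    def test_basin_centers_recovered_by_descent(self, rng):
        s = ts.make_surface("sym6d_wells")
        for c in (ts.SYM6D_FOLDED, ts.SYM6D_OPEN):
            x0 = c + rng.uniform(-1.5, 1.5, 6)
            res = minimize(lambda x: s.energy(x[None])[0], x0,
                           jac=lambda x: s.gradient(x[None])[0], method="BFGS")
            assert np.allclose(res.x, c, atol=0.05)

    def test_folded_basin_deeper_by_depth_gap(self):
        s = ts.make_surface("sym6d_wells")
        gap = s.energy(ts.SYM6D_FOLDED[None])[0] - s.energy(ts.SYM6D_OPEN[None])[0]
        assert gap == pytest.approx(-ts.SYM6D_DEPTH_GAP, abs=1e-6)


class TestLangevin:
    def test_quad_bowl_stationary_variance(self):
        s = ts.make_surface("quad_bowl_nd", n=1, kappa=1.0)
        traj = ts.langevin_sample(s, T=300.0, n_steps=1_000_000, dt=5e-3,
                                  x0=[0.0], seed=42, save_stride=2)
        var = traj.samples[:, 0].var()
        assert var == pytest.approx(kbt(300.0), rel=0.05)

    def test_same_seed_is_bit_identical(self):
        s = ts.make_surface("double_well_1d")
        a = ts.langevin_sample(s, 300.0, 5000, 1e-3, x0=[-1.0], seed=3)
        b = ts.langevin_sample(s, 300.0, 5000, 1e-3, x0=[-1.0], seed=3)
        assert np.array_equal(a.samples, b.samples)

    def test_high_barrier_traps_unbiased_walker(self):
        # barrier 10 kcal/mol >> k_B T: no well-to-well crossing (spot check;
        # the 20-seed comparison against biased runs lives in the acceptance suite)
        s = ts.make_surface("double_well_1d", h=10.0)
        for seed in range(3):
            traj = ts.langevin_sample(s, 300.0, 100_000, 1e-3, x0=[-1.0], seed=seed)
            assert traj.samples[:, 0].max() < 0.0

    def test_trajectory_save_round_trip(self, tmp_path):
        s = ts.make_surface("double_well_1d")
        traj = ts.langevin_sample(s, 300.0, 1000, 1e-3, x0=[1.0], seed=0, save_stride=10)
        import json

        import pandas as pd

        traj.save(tmp_path / "t.csv", tmp_path / "t.json")
        back = pd.read_csv(tmp_path / "t.csv").to_numpy()
        assert np.allclose(back, traj.samples)
        side = json.loads((tmp_path / "t.json").read_text())
        assert side["seed"] == 0 and side["surface"] == "double_well_1d"


class _Separable2D(ts.ToySurface):
    """h(x^2-1)^2 + (kappa/2) y^2 — an exactly separable 2-D surface."""

    name = "separable"
    dimension = 2

    def __init__(self, h=2.0, kappa=3.0):
        super().__init__()
        self.h, self.kappa = h, kappa
        self.bounds = np.array([[-3.0, 3.0], [-6.0, 6.0]])

    def energy(self, x):
        x = np.asarray(x, float)
        return self.h * (x[..., 0] ** 2 - 1) ** 2 + 0.5 * self.kappa * x[..., 1] ** 2

    def gradient(self, x):
        x = np.asarray(x, float)
        return np.stack([4 * self.h * x[..., 0] * (x[..., 0] ** 2 - 1),
                         self.kappa * x[..., 1]], axis=-1)


class TestExactMarginal:
    def test_separable_marginal_is_the_component(self):
        s = _Separable2D()
        grid = np.linspace(-1.8, 1.8, 41)
        prof = ts.marginal_1d_exact(s, 0, grid, T=300.0)
        expected = s.h * (grid**2 - 1) ** 2
        expected -= expected.min()
        assert np.max(np.abs(prof.values - expected)) < 1e-3

    def test_separable_marginal_independent_of_temperature(self):
        s = _Separable2D()
        grid = np.linspace(-1.5, 1.5, 21)
        p1 = ts.marginal_1d_exact(s, 0, grid, T=300.0)
        p2 = ts.marginal_1d_exact(s, 0, grid, T=600.0)
        assert np.max(np.abs(p1.values - p2.values)) < 1e-3

    def test_quad_bowl_marginal_is_quadratic(self):
        s = ts.make_surface("quad_bowl_nd", n=2, kappa=4.0, center=[1.0, -2.0])
        grid = np.linspace(-1.0, 3.0, 31)
        prof = ts.marginal_1d_exact(s, 0, grid, T=300.0)
        expected = 0.5 * 4.0 * (grid - 1.0) ** 2
        expected -= expected.min()
        assert np.max(np.abs(prof.values - expected)) < 1e-6

    def test_closed_form_agrees_with_quadrature(self):
        # dual route: mixture closed form vs generic quadrature on a wrapper
        # that hides the mixture structure
        mix = ts.GaussianMixtureSurface(centers=[[0.0, 0.0], [2.0, 1.0]],
                                        widths=0.8, log_weights=[0.5, 0.0],
                                        T0=300.0)
        wrapper = ts.ToySurface()
        wrapper.dimension = 2
        wrapper.bounds = mix.bounds
        wrapper.energy = mix.energy
        wrapper.gradient = mix.gradient
        grid = np.linspace(-1.5, 3.5, 25)
        closed = ts.marginal_1d_exact(mix, 0, grid, T=300.0)
        quad = ts.marginal_1d_exact(wrapper, 0, grid, T=300.0)
        assert closed.meta["method"] == "closed_form"
        assert quad.meta["method"] == "quadrature"
        assert np.max(np.abs(closed.values - quad.values)) < 1e-6

    def test_monte_carlo_fallback_matches_closed_form(self):
        # 5-D bowl: 4 integrated dims forces the seeded MC path
        s = ts.make_surface("quad_bowl_nd", n=5, kappa=25.0)
        s.bounds = np.array([[-1.0, 1.0]] * 5)
        grid = np.linspace(-0.6, 0.6, 9)
        prof = ts.marginal_1d_exact(s, 0, grid, T=300.0, n_mc=200_000, seed=5)
        assert prof.meta["method"] == "monte_carlo"
        expected = 0.5 * 25.0 * grid**2
        expected -= expected.min()
        dev = np.abs(prof.values - expected)
        assert np.max(dev) < np.maximum(4 * prof.se, 0.05).max()
        assert np.all(prof.se > 0)
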
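"""Analytic benchmark potentials and an overdamped Langevin sampler.

These surfaces stand in for the microscopic potential U(r) (and for the
target free energy A(d)) so that every stage of the pipeline — biased
exploration, mean-force estimation, force matching, marginalisation, WHAM
and the string method — can be validated against exact energies, gradients
and marginals at desk scale.

The ``sym6d_wells`` fixture emulates the six-distance landscape of a
four-nucleosome array: a compact "folded" basin and an extended "open"
basin, exactly invariant under the nucleosome index reversal.  Its basin
centres, widths and depth gap are fixture constants chosen for the
benchmark, not measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cvlib import REVERSAL_PERM
from .errors import DomainError, InputError, InstabilityError
from .profiles import FreeEnergyProfile
from .units import kbt


class ToySurface:
    """An analytic potential with exact gradient on a rectangular domain.

    Subclasses implement ``energy`` and ``gradient`` for inputs of shape
    (..., n); ``bounds`` is an (n, 2) array of per-dimension domain limits.
    """

    name: str = "surface"
    dimension: int = 1
    symmetric: bool = False

    def __init__(self):
        self.params: dict = {}
        self.bounds = np.array([[-np.inf, np.inf]] * self.dimension)

    def energy(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def gradient(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def in_domain(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return np.all((x >= self.bounds[:, 0]) & (x <= self.bounds[:, 1]), axis=-1)

    def __repr__(self):  # pragma: no cover
        return f"<{type(self).__name__} {self.name} dim={self.dimension}>"


class DoubleWell1D(ToySurface):
    """A(x) = h (x^2 - 1)^2: minima at x = +/-1, barrier h at x = 0."""

    name = "double_well_1d"
    dimension = 1

    def __init__(self, h: float = 5.0):
        super().__init__()
        self.h = float(h)
        self.params = {"h": self.h}
        self.bounds = np.array([[-3.0, 3.0]])

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        return self.h * (x[..., 0] ** 2 - 1.0) ** 2

    def gradient(self, x):
        x = np.asarray(x, dtype=float)
        g = 4.0 * self.h * x[..., 0] * (x[..., 0] ** 2 - 1.0)
        return g[..., None]


class MullerBrown(ToySurface):
    """The standard four-Gaussian Muller-Brown potential (its own units)."""

    name = "muller_brown"
    dimension = 2

    A = np.array([-200.0, -100.0, -170.0, 15.0])
    a = np.array([-1.0, -1.0, -6.5, 0.7])
    b = np.array([0.0, 0.0, 11.0, 0.6])
    c = np.array([-10.0, -10.0, -6.5, 0.7])
    x0 = np.array([1.0, 0.0, -0.5, -1.0])
    y0 = np.array([0.0, 0.5, 1.5, 1.0])

    def __init__(self):
        super().__init__()
        self.params = {k: getattr(self, k).tolist() for k in ("A", "a", "b", "c", "x0", "y0")}
        self.bounds = np.array([[-1.8, 1.2], [-0.5, 2.3]])

    def _terms(self, x):
        dx = x[..., 0, None] - self.x0
        dy = x[..., 1, None] - self.y0
        return dx, dy, self.A * np.exp(self.a * dx**2 + self.b * dx * dy + self.c * dy**2)

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        return self._terms(x)[2].sum(axis=-1)

    def gradient(self, x):
        x = np.asarray(x, dtype=float)
        dx, dy, t = self._terms(x)
        gx = (t * (2.0 * self.a * dx + self.b * dy)).sum(axis=-1)
        gy = (t * (self.b * dx + 2.0 * self.c * dy)).sum(axis=-1)
        return np.stack([gx, gy], axis=-1)


class QuadBowlND(ToySurface):
    """Isotropic quadratic bowl A = (kappa/2) |x - c|^2 in n dimensions."""

    name = "quad_bowl_nd"

    def __init__(self, n: int = 2, kappa: float = 1.0, center=None):
        self.dimension = int(n)
        super().__init__()
        self.kappa = float(kappa)
        self.center = np.zeros(n) if center is None else np.asarray(center, dtype=float)
        if self.center.shape != (n,):
            raise InputError(f"center must have {n} components")
        self.params = {"n": n, "kappa": self.kappa, "center": self.center.tolist()}
        half = 20.0 / np.sqrt(self.kappa)
        self.bounds = np.stack([self.center - half, self.center + half], axis=1)

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        return 0.5 * self.kappa * np.sum((x - self.center) ** 2, axis=-1)

    def gradient(self, x):
        x = np.asarray(x, dtype=float)
        return self.kappa * (x - self.center)


class GaussianMixtureSurface(ToySurface):
    """A(x) = -k_B T0 ln sum_k exp(log_w_k) G(x; c_k, s_k) with isotropic G.

    The Boltzmann factor at the reference temperature T0 is an explicit
    Gaussian mixture, so marginals over any subset of coordinates have a
    closed form — the exact oracle the learned surface is validated against.
    """

    name = "gaussian_mixture"

    def __init__(self, centers, widths, log_weights, T0: float = 300.0,
                 bounds=None, name=None, symmetric=False):
        self.centers_ = np.atleast_2d(np.asarray(centers, dtype=float))
        self.dimension = self.centers_.shape[1]
        super().__init__()
        k = len(self.centers_)
        self.widths_ = np.broadcast_to(np.asarray(widths, dtype=float), (k,)).copy()
        self.log_weights_ = np.asarray(log_weights, dtype=float)
        if self.log_weights_.shape != (k,):
            raise InputError("one log weight per mixture component required")
        self.T0 = float(T0)
        self.symmetric = bool(symmetric)
        if name:
            self.name = name
        if bounds is None:
            lo = self.centers_.min(axis=0) - 5.0 * self.widths_.max()
            hi = self.centers_.max(axis=0) + 5.0 * self.widths_.max()
            bounds = np.stack([lo, hi], axis=1)
        self.bounds = np.asarray(bounds, dtype=float)
        self.params = {
            "centers": self.centers_.tolist(),
            "widths": self.widths_.tolist(),
            "log_weights": self.log_weights_.tolist(),
            "T0": self.T0,
        }

    def _log_terms(self, x):
        x = np.asarray(x, dtype=float)
        diff = x[..., None, :] - self.centers_  # (..., k, n)
        return self.log_weights_ - np.sum(diff**2, axis=-1) / (2.0 * self.widths_**2)

    def energy(self, x):
        lt = self._log_terms(x)
        m = lt.max(axis=-1)
        return -kbt(self.T0) * (m + np.log(np.sum(np.exp(lt - m[..., None]), axis=-1)))

    def gradient(self, x):
        x = np.asarray(x, dtype=float)
        lt = self._log_terms(x)
        m = lt.max(axis=-1, keepdims=True)
        p = np.exp(lt - m)
        p /= p.sum(axis=-1, keepdims=True)
        diff = x[..., None, :] - self.centers_
        pull = diff / self.widths_[:, None] ** 2
        return kbt(self.T0) * np.sum(p[..., None] * pull, axis=-2)

    def exact_marginal_logdensity(self, dims: tuple[int, ...], pts: np.ndarray) -> np.ndarray:
        """log of the (unnormalised) marginal Boltzmann factor at T0.

        ``pts`` has shape (..., len(dims)); all other coordinates are
        integrated out analytically over the full space.
        """
        dims = list(dims)
        n_out = self.dimension - len(dims)
        diff = np.asarray(pts, dtype=float)[..., None, :] - self.centers_[:, dims]
        lt = (
            self.log_weights_
            - np.sum(diff**2, axis=-1) / (2.0 * self.widths_**2)
            + 0.5 * n_out * np.log(2.0 * np.pi * self.widths_**2)
        )
        m = lt.max(axis=-1)
        return m + np.log(np.sum(np.exp(lt - m[..., None]), axis=-1))


#: Fixture constants of the reversal-symmetric 6-D two-basin benchmark
#: (design choices for the synthetic benchmark, in nm / kcal/mol).
SYM6D_FOLDED = np.array([9.0, 6.0, 12.0, 9.0, 6.0, 9.0])
SYM6D_OPEN = np.array([15.0, 25.0, 32.0, 15.0, 25.0, 15.0])
SYM6D_WIDTH = 3.0
SYM6D_DEPTH_GAP = 2.0  # kcal/mol, folded below open at 300 K


def _sym6d_wells(T0: float = 300.0) -> GaussianMixtureSurface:
    for c in (SYM6D_FOLDED, SYM6D_OPEN):
        assert np.allclose(c, c[REVERSAL_PERM]), "basin centres must be reversal symmetric"
    surf = GaussianMixtureSurface(
        centers=[SYM6D_FOLDED, SYM6D_OPEN],
        widths=SYM6D_WIDTH,
        log_weights=[SYM6D_DEPTH_GAP / kbt(T0), 0.0],
        T0=T0,
        bounds=np.array([[2.0, 40.0]] * 6),
        name="sym6d_wells",
        symmetric=True,
    )
    return surf


_CATALOG = {
    "double_well_1d": DoubleWell1D,
    "muller_brown": MullerBrown,
    "quad_bowl_nd": QuadBowlND,
    "sym6d_wells": _sym6d_wells,
}


def make_surface(name: str, **overrides) -> ToySurface:
    """Instantiate a catalogued benchmark surface.

    Known names: double_well_1d, muller_brown, quad_bowl_nd, sym6d_wells.
    Keyword overrides are passed to the surface constructor.
    """
    try:
        factory = _CATALOG[name]
    except KeyError:
        raise InputError(f"unknown surface {name!r}; known: {sorted(_CATALOG)}") from None
    return factory(**overrides)


def eval_surface(surface: ToySurface, x) -> tuple[np.ndarray, np.ndarray]:
    """Energy (kcal/mol) and exact gradient at x; errors if x leaves the domain."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    xb = np.atleast_2d(x)
    if not np.all(surface.in_domain(xb)):
        raise DomainError(f"point outside the domain of {surface.name}")
    e = surface.energy(xb)
    g = surface.gradient(xb)
    if single:
        return float(e[0]), g[0]
    return e, g


@dataclass
class Trajectory:
    """Samples from a (possibly biased) sampler, with its provenance."""

    samples: np.ndarray
    temperature: float
    dt: float
    friction: float
    seed: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))

    def __len__(self):
        return len(self.samples)

    def save(self, csv_path, json_path=None):
        import json

        import pandas as pd

        n = self.samples.shape[1]
        pd.DataFrame(self.samples, columns=[f"x{i}" for i in range(n)]).to_csv(
            csv_path, index=False
        )
        if json_path is not None:
            side = {
                "temperature": self.temperature,
                "dt": self.dt,
                "friction": self.friction,
                "seed": self.seed,
                **self.meta,
            }
            with open(json_path, "w") as fh:
                json.dump(side, fh, indent=1)


def _reflect(x: np.ndarray, bounds: np.ndarray) -> np.ndarray:
    lo, hi = bounds[:, 0], bounds[:, 1]
    for _ in range(4):
        out_lo = x < lo
        out_hi = x > hi
        if not (out_lo.any() or out_hi.any()):
            break
        x = np.where(out_lo, 2.0 * lo - x, x)
        x = np.where(out_hi, 2.0 * hi - x, x)
    return np.clip(x, lo, hi)


def langevin_sample(surface: ToySurface, T: float, n_steps: int, dt: float,
                    friction: float = 1.0, x0=None, seed: int = 0,
                    save_stride: int = 1) -> Trajectory:
    """Overdamped Euler-Maruyama sampling of exp(-A/k_B T).

    x <- x - (dt/gamma) grad A + sqrt(2 k_B T dt / gamma) xi, with reflecting
    boundaries at the surface's domain limits.  Bit-reproducible for a fixed
    seed.  Raises InstabilityError (naming dt) if the walker leaves the
    domain by more than 10x its extent.
    """
    n = surface.dimension
    bounds = surface.bounds
    finite = np.all(np.isfinite(bounds))
    if x0 is None:
        x = bounds.mean(axis=1) if finite else np.zeros(n)
    else:
        x = np.array(x0, dtype=float).reshape(n)
    rng = np.random.default_rng(seed)
    amp = np.sqrt(2.0 * kbt(T) * dt / friction)
    mob = dt / friction
    noise = rng.standard_normal((n_steps, n))
    extent = (bounds[:, 1] - bounds[:, 0]) if finite else np.full(n, np.inf)
    samples = np.empty((n_steps // save_stride, n))
    k = 0
    grad = surface.gradient
    for step in range(n_steps):
        x = x - mob * grad(x) + amp * noise[step]
        if finite:
            x = _reflect(x, bounds)
        elif np.any(np.abs(x) > 1e8):
            raise InstabilityError(f"sampler diverged at step {step} with dt={dt}")
        if not np.all(np.isfinite(x)):
            raise InstabilityError(f"sampler produced non-finite state with dt={dt}")
        if (step + 1) % save_stride == 0:
            samples[k] = x
            k += 1
    return Trajectory(
        samples[:k], T, dt, friction, seed,
        meta={"surface": surface.name, "n_steps": n_steps, "save_stride": save_stride},
    )


def marginal_1d_exact(surface: ToySurface, dim: int, grid: np.ndarray, T: float,
                      n_mc: int = 200_000, seed: int = 0) -> FreeEnergyProfile:
    """Exact/deterministic 1-D marginal free energy of an analytic surface.

    A_1(x) = -k_B T ln  integral  exp(-A/k_B T) d(other dims), min-shifted.

    Gaussian-mixture surfaces evaluated at their reference temperature are
    marginalised in closed form (exact, zero standard error).  Otherwise the
    integral uses tensor Gauss-Legendre quadrature for up to 3 integrated
    dimensions and seeded uniform Monte-Carlo (with reported standard error)
    above that.
    """
    grid = np.asarray(grid, dtype=float)
    n = surface.dimension
    if not (0 <= dim < n):
        raise InputError(f"dim {dim} out of range for dimension {n}")
    beta = 1.0 / kbt(T)
    other = [i for i in range(n) if i != dim]

    if isinstance(surface, GaussianMixtureSurface) and abs(T - surface.T0) < 1e-9:
        logm = surface.exact_marginal_logdensity((dim,), grid[:, None])
        vals = -logm / beta
        vals -= vals.min()
        return FreeEnergyProfile(grid, vals, np.zeros_like(vals), dims=(dim,),
                                 meta={"method": "closed_form", "T": T})

    if n == 1:
        vals = surface.energy(grid[:, None])
        vals = vals - vals.min()
        return FreeEnergyProfile(grid, vals, np.zeros_like(vals), dims=(dim,),
                                 meta={"method": "direct", "T": T})

    if len(other) <= 3:
        n_nodes = {1: 200, 2: 80, 3: 32}[len(other)]
        axes, wts = [], []
        for j in other:
            t, w = np.polynomial.legendre.leggauss(n_nodes)
            lo, hi = surface.bounds[j]
            if not np.isfinite(lo) or not np.isfinite(hi):
                raise InputError("quadrature requires finite domain bounds")
            axes.append(0.5 * (hi - lo) * t + 0.5 * (hi + lo))
            wts.append(0.5 * (hi - lo) * w)
        mesh = np.meshgrid(*axes, indexing="ij")
        wmesh = np.ones_like(mesh[0])
        for k, w in enumerate(wts):
            shape = [1] * len(other)
            shape[k] = -1
            wmesh = wmesh * w.reshape(shape)
        pts = np.empty(mesh[0].shape + (n,))
        for k, j in enumerate(other):
            pts[..., j] = mesh[k]
        vals = np.empty_like(grid)
        for gi, gx in enumerate(grid):
            pts[..., dim] = gx
            e = surface.energy(pts)
            if not np.all(np.isfinite(e)):
                raise InputError("non-finite integrand in marginalisation")
            emin = e.min()
            vals[gi] = emin - np.log(np.sum(wmesh * np.exp(-beta * (e - emin)))) / beta
        vals -= vals.min()
        return FreeEnergyProfile(grid, vals, np.zeros_like(vals), dims=(dim,),
                                 meta={"method": "quadrature", "T": T, "nodes": n_nodes})

    # seeded uniform Monte-Carlo fallback
    rng = np.random.default_rng(seed)
    lo = surface.bounds[other, 0]
    hi = surface.bounds[other, 1]
    vol = np.prod(hi - lo)
    u = lo + (hi - lo) * rng.random((n_mc, len(other)))
    pts = np.empty((n_mc, n))
    pts[:, other] = u
    vals = np.empty_like(grid)
    se = np.empty_like(grid)
    for gi, gx in enumerate(grid):
        pts[:, dim] = gx
        e = surface.energy(pts)
        emin = e.min()
        f = np.exp(-beta * (e - emin))
        mean = f.mean()
        vals[gi] = emin - np.log(vol * mean) / beta
        se[gi] = f.std(ddof=1) / np.sqrt(n_mc) / mean / beta
    shift = vals.min()
    return FreeEnergyProfile(grid, vals - shift, se, dims=(dim,),
                             meta={"method": "monte_carlo", "T": T, "n_mc": n_mc, "seed": seed})
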
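"""Biased conformational exploration: metadynamics combined with TAMD.

Two accelerations are layered on the overdamped sampler.  Metadynamics
deposits repulsive Gaussian hills at the visited collective-variable (CV)
values so the walker is pushed away from regions it has already seen.  TAMD
tethers each CV theta(x) to a fictitious extended variable z through a stiff
harmonic spring and evolves z at an elevated temperature, so rare barrier
crossings of the physical system are driven by the hot extended dynamics.
The hills act on z, not on x directly.

The combination produces the broad coverage of CV space from which
mean-force centres are later selected by K-means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError, InstabilityError
from .toy_systems import ToySurface, Trajectory, _reflect
from .units import kbt


class CoordinateCV:
    """The i-th coordinate as a collective variable (analytic gradient)."""

    def __init__(self, index: int):
        self.index = int(index)

    def value(self, x) -> float:
        return float(np.asarray(x)[self.index])

    def gradient(self, x) -> np.ndarray:
        g = np.zeros(len(np.asarray(x)))
        g[self.index] = 1.0
        return g

    def values(self, X) -> np.ndarray:
        return np.asarray(X)[:, self.index]


class FunctionCV:
    """A CV from a callable; gradient analytic if given, else central differences."""

    def __init__(self, fn, grad=None, fd_step: float = 1e-4):
        self.fn = fn
        self.grad = grad
        self.fd_step = float(fd_step)

    def value(self, x) -> float:
        return float(self.fn(np.asarray(x, dtype=float)))

    def gradient(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.grad is not None:
            return np.asarray(self.grad(x), dtype=float)
        h = self.fd_step
        g = np.empty_like(x)
        for i in range(len(x)):
            e = np.zeros_like(x)
            e[i] = h
            g[i] = (self.fn(x + e) - self.fn(x - e)) / (2.0 * h)
        return g

    def values(self, X) -> np.ndarray:
        return np.array([self.value(x) for x in np.asarray(X, dtype=float)])


@dataclass
class Hills:
    """Deposited metadynamics hills (centres, heights, widths, deposit steps)."""

    centers: np.ndarray
    heights: np.ndarray
    widths: np.ndarray
    steps: np.ndarray

    def __post_init__(self):
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.heights = np.asarray(self.heights, dtype=float).reshape(-1)
        self.widths = np.atleast_2d(np.asarray(self.widths, dtype=float))
        self.steps = np.asarray(self.steps, dtype=int).reshape(-1)
        if len(self.heights) and (np.any(self.heights < 0) or np.any(self.widths <= 0)):
            raise InputError("hill heights must be >= 0 and widths > 0")

    def __len__(self):
        return len(self.heights)

    @classmethod
    def empty(cls, n_cv: int) -> "Hills":
        return cls(np.empty((0, n_cv)), np.empty(0), np.empty((0, n_cv)), np.empty(0, int))

    def to_csv(self, path):
        m = self.centers.shape[1]
        cols = {"step": self.steps}
        for i in range(m):
            cols[f"center{i}"] = self.centers[:, i]
        cols["height"] = self.heights
        for i in range(m):
            cols[f"width{i}"] = self.widths[:, i]
        pd.DataFrame(cols).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Hills":
        df = pd.read_csv(path)
        m = sum(c.startswith("center") for c in df.columns)
        return cls(
            df[[f"center{i}" for i in range(m)]].to_numpy(),
            df["height"].to_numpy(),
            df[[f"width{i}" for i in range(m)]].to_numpy(),
            df["step"].to_numpy(),
        )


def bias_potential(hills: Hills, z) -> float:
    """Total metadynamics bias at CV point z (kcal/mol); 0 for no hills."""
    if len(hills) == 0:
        return 0.0
    z = np.asarray(z, dtype=float)
    expo = np.sum((z - hills.centers) ** 2 / (2.0 * hills.widths**2), axis=1)
    return float(np.sum(hills.heights * np.exp(-expo)))


def bias_gradient(hills: Hills, z) -> np.ndarray:
    """Gradient of the bias with respect to z."""
    z = np.asarray(z, dtype=float)
    if len(hills) == 0:
        return np.zeros_like(z)
    diff = z - hills.centers
    expo = np.sum(diff**2 / (2.0 * hills.widths**2), axis=1)
    w = hills.heights * np.exp(-expo)
    return -np.sum((w[:, None] * diff) / hills.widths**2, axis=0)


def run_tamd_metad(surface: ToySurface, cv_functions, *, kappa_ext: float = 50.0,
                   T: float = 300.0, T_bar: float = 1500.0, hill_height: float = 0.3,
                   hill_width: float = 0.3, deposit_stride: int = 500,
                   n_steps: int = 100_000, dt: float = 1e-3, friction: float = 1.0,
                   friction_z: float = 1.0, x0=None, seed: int = 0,
                   save_stride: int = 10, cv_bounds=None,
                   well_tempered_delta_T: float | None = None):
    """Coupled metadynamics + TAMD run on a toy surface.

    Per step:
      x <- Langevin at T under  -grad A(x) - kappa_ext (theta(x) - z) grad theta(x)
      z <- Langevin at T_bar under  kappa_ext (theta(x) - z) - grad V_bias(z)
    and every ``deposit_stride`` steps a hill is dropped at the current z
    (scaled by the well-tempered factor when ``well_tempered_delta_T`` is set).

    Returns ``(trajectory, hills)``; the trajectory carries the physical
    samples, with the matching CV and z series attached as ``cv_samples``
    and ``z_samples``.
    """
    if T_bar < T:
        raise InputError(f"extended temperature {T_bar} K must be >= physical {T} K")
    cvs = list(cv_functions)
    m = len(cvs)
    n = surface.dimension
    rng = np.random.default_rng(seed)
    bounds = surface.bounds
    finite = np.all(np.isfinite(bounds))
    x = (bounds.mean(axis=1) if finite else np.zeros(n)) if x0 is None else np.array(x0, dtype=float)

    if cv_bounds is None:
        cb = []
        for cv in cvs:
            if isinstance(cv, CoordinateCV) and finite:
                cb.append(bounds[cv.index])
            else:
                cb.append([-np.inf, np.inf])
        cv_bounds = np.array(cb, dtype=float)
    else:
        cv_bounds = np.asarray(cv_bounds, dtype=float)
    cv_finite = np.all(np.isfinite(cv_bounds))

    z = np.array([cv.value(x) for cv in cvs])
    amp_x = np.sqrt(2.0 * kbt(T) * dt / friction)
    amp_z = np.sqrt(2.0 * kbt(T_bar) * dt / friction_z)
    mob_x = dt / friction
    mob_z = dt / friction_z

    n_hills_max = n_steps // deposit_stride
    h_centers = np.empty((n_hills_max, m))
    h_heights = np.empty(n_hills_max)
    h_widths = np.empty((n_hills_max, m))
    h_steps = np.empty(n_hills_max, dtype=int)
    n_h = 0
    hills = Hills.empty(m)

    width_vec = np.broadcast_to(np.asarray(hill_width, dtype=float), (m,))
    noise_x = rng.standard_normal((n_steps, n))
    noise_z = rng.standard_normal((n_steps, m))
    n_save = n_steps // save_stride
    xs = np.empty((n_save, n))
    cvss = np.empty((n_save, m))
    zss = np.empty((n_save, m))
    k = 0

    for step in range(n_steps):
        theta = np.array([cv.value(x) for cv in cvs])
        gap = theta - z
        f_x = -surface.gradient(x)
        for j, cv in enumerate(cvs):
            f_x -= kappa_ext * gap[j] * cv.gradient(x)
        x = x + mob_x * f_x + amp_x * noise_x[step]
        if finite:
            x = _reflect(x, bounds)
        if not np.all(np.isfinite(x)):
            raise InstabilityError(f"physical walker diverged with dt={dt}")

        f_z = kappa_ext * gap
        if n_h:
            view = Hills(h_centers[:n_h], h_heights[:n_h], h_widths[:n_h], h_steps[:n_h])
            f_z = f_z - bias_gradient(view, z)
        z = z + mob_z * f_z + amp_z * noise_z[step]
        if cv_finite:
            z = _reflect(z, cv_bounds)
        if not np.all(np.isfinite(z)):
            raise InstabilityError(f"extended walker diverged with dt={dt}")

        if (step + 1) % deposit_stride == 0 and n_h < n_hills_max:
            h = hill_height
            if well_tempered_delta_T is not None and n_h:
                view = Hills(h_centers[:n_h], h_heights[:n_h], h_widths[:n_h], h_steps[:n_h])
                h = hill_height * np.exp(-bias_potential(view, z) / kbt(well_tempered_delta_T))
            h_centers[n_h] = z
            h_heights[n_h] = h
            h_widths[n_h] = width_vec
            h_steps[n_h] = step + 1
            n_h += 1

        if (step + 1) % save_stride == 0:
            xs[k] = x
            cvss[k] = theta
            zss[k] = z
            k += 1

    hills = Hills(h_centers[:n_h], h_heights[:n_h], h_widths[:n_h], h_steps[:n_h])
    traj = Trajectory(
        xs[:k], T, dt, friction, seed,
        meta={"surface": surface.name, "n_steps": n_steps, "save_stride": save_stride,
              "kappa_ext": kappa_ext, "T_bar": T_bar, "n_hills": n_h,
              "hill_height": hill_height, "deposit_stride": deposit_stride},
    )
    traj.cv_samples = cvss[:k]
    traj.z_samples = zss[:k]
    return traj, hills


def coverage_report(trajectory: Trajectory, cv_functions, bins: int = 20, box=None) -> float:
    """Fraction of occupied bins over a CV bounding box.

    ``box`` is an (m, 2) array; if omitted it is taken from the trajectory's
    own CV range (degenerate ranges are widened by a tiny epsilon).  A
    supplied zero-volume box is an error.
    """
    if len(trajectory) == 0:
        raise InputError("empty trajectory")
    cvs = list(cv_functions)
    vals = np.stack([cv.values(trajectory.samples) for cv in cvs], axis=1)
    if box is None:
        lo = vals.min(axis=0)
        hi = vals.max(axis=0)
        eps = np.where(hi - lo <= 0, 1e-12, 0.0)
        lo, hi = lo - eps, hi + eps
    else:
        box = np.asarray(box, dtype=float)
        lo, hi = box[:, 0], box[:, 1]
        if np.any(hi <= lo):
            raise InputError("CV bounding box has zero volume")
    edges = [np.linspace(lo[j], hi[j], bins + 1) for j in range(len(cvs))]
    hist, _ = np.histogramdd(vals, bins=edges)
    return float(np.count_nonzero(hist) / hist.size)
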
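"""Umbrella sampling and the weighted histogram analysis method (WHAM).

An independent route to a 1-D free energy profile used to cross-validate
the learned surface: harmonically biased windows are sampled along one
collective variable and recombined by the standard self-consistent WHAM
equations

    P(x)  proportional to  sum_i n_i(x) / sum_j N_j exp[(f_j - w_j(x))/k_B T]
    f_i = -k_B T ln sum_x P(x) exp(-w_i(x)/k_B T)

with w_i the window bias.  Empty bins are reported as missing rather than
regularised, so sparse sampling is visible instead of silently smoothed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError
from .toy_systems import ToySurface, langevin_sample
from .meanforce import _RestrainedSurface
from .units import kbt

logger = logging.getLogger(__name__)


@dataclass
class UmbrellaWindow:
    """One harmonic window: centre, spring and post-burn-in CV samples."""

    center: float
    spring: float
    samples: np.ndarray
    seed: int = 0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float).reshape(-1)
        if len(self.samples) < 100:
            raise InputError(
                f"window at {self.center} has {len(self.samples)} samples (need >= 100)"
            )
        if self.spring < 0:
            raise InputError("window spring must be non-negative")


@dataclass
class WHAMResult:
    """Recombined profile, per-window offsets and convergence state."""

    grid: np.ndarray
    free_energy: np.ndarray
    f_windows: np.ndarray
    iterations: int
    converged: bool
    overlap_ok: bool = True
    meta: dict = field(default_factory=dict)

    def to_csv(self, path):
        pd.DataFrame({"x": self.grid, "A": self.free_energy}).to_csv(path, index=False)


class _Restrained1DCV(ToySurface):
    """base surface + (k/2)(x_dim - c)^2: restraint on one coordinate only."""

    def __init__(self, base: ToySurface, dim: int, center: float, spring: float):
        self.base = base
        self.dimension = base.dimension
        super().__init__()
        self.name = f"{base.name}+umbrella"
        self.dim, self.center, self.spring = dim, center, spring
        self.bounds = base.bounds

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        return self.base.energy(x) + 0.5 * self.spring * (x[..., self.dim] - self.center) ** 2

    def gradient(self, x):
        x = np.asarray(x, dtype=float)
        g = self.base.gradient(x).copy()
        g[..., self.dim] += self.spring * (x[..., self.dim] - self.center)
        return g


def run_umbrella(surface: ToySurface, cv_dim: int, window_centers, spring: float,
                 T: float = 300.0, n_steps: int = 30_000, seed: int = 0,
                 dt: float = 1e-3, friction: float = 1.0,
                 burn_in: int | None = None, n_seeds: int = 3) -> list[UmbrellaWindow]:
    """One restrained Langevin run per window centre (sorted, seeded).

    ``n_seeds`` independent replicas per window are pooled — a hedge against
    a single replica being trapped in one basin of a rugged landscape.
    Per-window seeds are derived deterministically from the base seed.
    """
    centers = np.sort(np.asarray(window_centers, dtype=float))
    if spring <= 0:
        raise InputError("spring must be positive")
    if burn_in is None:
        burn_in = n_steps // 5
    windows = []
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(len(centers) * n_seeds)
    for i, c in enumerate(centers):
        restrained = _Restrained1DCV(surface, cv_dim, float(c), spring)
        x0 = surface.bounds.mean(axis=1).copy()
        if np.all(np.isfinite(x0)):
            x0[cv_dim] = np.clip(c, *surface.bounds[cv_dim])
        else:
            x0 = np.zeros(surface.dimension)
            x0[cv_dim] = c
        pooled = []
        for r in range(n_seeds):
            s = int(child[i * n_seeds + r].generate_state(1)[0] % (2**31 - 1))
            traj = langevin_sample(restrained, T, n_steps, dt, friction, x0=x0,
                                   seed=s, save_stride=1)
            pooled.append(traj.samples[burn_in:, cv_dim])
        windows.append(
            UmbrellaWindow(float(c), spring, np.concatenate(pooled), seed=i)
        )
    return windows


def wham_solve(windows: list[UmbrellaWindow], n_bins: int = 100, T: float = 300.0,
               tol: float = 1e-6, max_iter: int = 100_000,
               grid_range=None) -> WHAMResult:
    """Self-consistent WHAM solution over fixed-width bins.

    Bins span the union of window sample ranges (or ``grid_range``).
    Iterates until max |delta f_i| < tol (kcal/mol) or ``max_iter``.  The
    profile is -k_B T ln P, minimum-shifted; empty bins are NaN.  Windows
    whose adjacent histograms do not overlap are flagged (``overlap_ok``),
    not fatal.
    """
    if not windows:
        raise InputError("at least one window is required")
    beta = 1.0 / kbt(T)
    if grid_range is None:
        lo = min(w.samples.min() for w in windows)
        hi = max(w.samples.max() for w in windows)
    else:
        lo, hi = grid_range
    edges = np.linspace(lo, hi, n_bins + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])

    counts = np.stack([np.histogram(w.samples, bins=edges)[0] for w in windows])
    N = counts.sum(axis=1).astype(float)          # samples per window
    n_tot = counts.sum(axis=0).astype(float)      # samples per bin

    order = np.argsort([w.center for w in windows])
    overlap_ok = True
    for a, b in zip(order[:-1], order[1:]):
        if np.sum((counts[a] > 0) & (counts[b] > 0)) == 0:
            overlap_ok = False
            logger.warning(
                "no histogram overlap between windows at %.3g and %.3g",
                windows[a].center, windows[b].center,
            )

    bias = np.stack([0.5 * w.spring * (mids - w.center) ** 2 for w in windows])
    expw = np.exp(-beta * bias)                   # (n_windows, n_bins)

    f = np.zeros(len(windows))
    it = 0
    for it in range(1, max_iter + 1):
        denom = np.einsum("i,ij->j", N * np.exp(beta * f), expw)
        with np.errstate(divide="ignore", invalid="ignore"):
            P = np.where(denom > 0, n_tot / denom, 0.0)
        Z = expw @ P
        f_new = -np.log(Z) / beta
        f_new -= f_new[0]
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < tol:
            break
    converged = bool(delta < tol)
    with np.errstate(divide="ignore"):
        A = np.where(P > 0, -np.log(np.where(P > 0, P, 1.0)) / beta, np.nan)
    A -= np.nanmin(A)
    return WHAMResult(mids, A, f, it, converged, overlap_ok,
                      meta={"T": T, "tol": tol, "n_bins": n_bins})
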
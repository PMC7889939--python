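"""Finite-temperature string method (FTS) on a differentiable surface.

A folding pathway is represented by a string of M+1 images in collective-
variable space.  Each iteration (i) samples the surface at temperature T
inside every image's Voronoi cell — Langevin proposals whose nearest image
is not the current one are rejected, which samples the cell-restricted
Boltzmann law exactly — (ii) moves each image a fraction alpha toward its
cell's sample mean, (iii) smooths interior images, and (iv) reparameterises
the string to equal arc length.  The converged string is the principal
curve of the transition tube: it averages over k_B T-scale ruggedness and
connects the reactant with the product.

Several independently initialised strings (the multi-start protocol) are
clustered by mean image distance to report distinct transition channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError, SamplingFailure
from .units import kbt


@dataclass
class StringPath:
    """An ordered string of images with free energies and convergence history."""

    images: np.ndarray
    free_energy: np.ndarray | None = None
    arc_length: np.ndarray | None = None
    history: list = field(default_factory=list)
    seed: int = 0
    converged: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.images = np.atleast_2d(np.asarray(self.images, dtype=float))
        if self.arc_length is None:
            self.arc_length = _arc_parameters(self.images)

    @property
    def n_images(self) -> int:
        return len(self.images)

    def to_csv(self, path):
        import pandas as pd

        n = self.images.shape[1]
        cols = {"image": np.arange(self.n_images)}
        for i in range(n):
            cols[f"x{i}"] = self.images[:, i]
        if self.free_energy is not None:
            cols["A"] = self.free_energy
        pd.DataFrame(cols).to_csv(path, index=False)


def _arc_parameters(images: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(images, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    return s / s[-1] if s[-1] > 0 else np.linspace(0, 1, len(images))


def initialize_string(endpoint_a, endpoint_b, M: int = 32, mode: str = "linear",
                      waypoint=None) -> StringPath:
    """A string of M+1 images from a to b.

    mode 'linear': equal-spaced straight interpolation; 'through_point':
    piecewise linear via ``waypoint``, used to seed distinct channels.
    """
    a = np.asarray(endpoint_a, dtype=float)
    b = np.asarray(endpoint_b, dtype=float)
    if M < 8:
        raise InputError(f"M must be >= 8, got {M}")
    if np.allclose(a, b):
        raise InputError("endpoints coincide")
    if mode == "linear":
        t = np.linspace(0, 1, M + 1)[:, None]
        images = (1 - t) * a + t * b
    elif mode == "through_point":
        if waypoint is None:
            raise InputError("through_point mode requires a waypoint")
        w = np.asarray(waypoint, dtype=float)
        pts = np.stack([a, w, b])
        images = _reparameterize(pts, M + 1)
    else:
        raise InputError(f"unknown mode {mode!r}")
    return StringPath(images)


def _reparameterize(images: np.ndarray, n_out: int) -> np.ndarray:
    """Resample a polyline at n_out equally spaced arc-length positions."""
    seg = np.linalg.norm(np.diff(images, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] == 0:
        return np.repeat(images[:1], n_out, axis=0)
    s /= s[-1]
    t = np.linspace(0, 1, n_out)
    out = np.empty((n_out, images.shape[1]))
    for j in range(images.shape[1]):
        out[:, j] = np.interp(t, s, images[:, j])
    return out


def fts_relax(surface_or_model, path: StringPath, *, n_cell_samples: int = 200,
              sampler_dt: float = 1e-3, T: float = 300.0, friction: float = 1.0,
              alpha: float = 0.1, smooth: float = 0.1, max_iter: int = 100,
              tol: float = 1e-3, seed: int = 0, endpoint_mode: str = "fixed",
              collect_samples: bool = False) -> StringPath:
    """Relax a string on the surface with Voronoi-restricted sampling.

    Per iteration each image runs ``n_cell_samples`` overdamped Langevin
    steps; proposals leaving the image's Voronoi cell are rejected (the
    walker stays put), which leaves the cell-restricted Boltzmann measure
    invariant.  Images move by ``alpha`` toward the cell means, interior
    images are smoothed with strength ``smooth`` and the string is
    reparameterised to equal arc length.  Endpoints are held fixed
    (default) or relaxed within their own cells.  Convergence: maximum
    image displacement below ``tol`` (CV units).
    """
    if tol <= 0:
        raise InputError("tol must be positive")
    if endpoint_mode not in ("fixed", "relaxed"):
        raise InputError(f"unknown endpoint_mode {endpoint_mode!r}")
    surface = surface_or_model
    if hasattr(surface, "trusted"):
        flags = surface.trusted(path.images)
        if not np.all(flags):
            raise InputError("all initial images must lie in the trusted domain")
    images = path.images.copy()
    M1, n = images.shape
    rng = np.random.default_rng(seed)
    amp = np.sqrt(2.0 * kbt(T) * sampler_dt / friction)
    mob = sampler_dt / friction
    history = []
    walkers = images.copy()
    converged = False
    collected = None
    for it in range(max_iter):
        if collect_samples:
            collected = {"images": images.copy(),
                         "samples": [[] for _ in range(M1)]}
        means = np.empty_like(images)
        # keep walkers assigned to their own cells after image moves
        own = np.linalg.norm(walkers[:, None, :] - images[None, :, :], axis=2).argmin(axis=1)
        reset = own != np.arange(M1)
        walkers[reset] = images[reset]
        for i in range(M1):
            x = walkers[i]
            acc = np.zeros(n)
            n_acc = 0
            attempts = 0
            while n_acc < n_cell_samples:
                attempts += 1
                if attempts > 10 * n_cell_samples and n_acc == 0:
                    raise SamplingFailure(
                        f"image {i} captured no samples after {attempts} attempts"
                    )
                prop = x - mob * surface.gradient(x) + amp * rng.standard_normal(n)
                d2 = np.sum((images - prop) ** 2, axis=1)
                if d2.argmin() == i:
                    x = prop
                acc += x
                n_acc += 1
                if collect_samples:
                    collected["samples"][i].append(x.copy())
            walkers[i] = x
            means[i] = acc / n_cell_samples
        new = (1.0 - alpha) * images + alpha * means
        if endpoint_mode == "fixed":
            new[0] = images[0]
            new[-1] = images[-1]
        # smoothing of interior images
        if smooth > 0:
            interior = new[1:-1] + smooth * (new[2:] - 2.0 * new[1:-1] + new[:-2])
            new = np.vstack([new[:1], interior, new[-1:]])
        new = _reparameterize(new, M1)
        if endpoint_mode == "fixed":
            new[0] = images[0]
            new[-1] = images[-1]
        disp = float(np.max(np.linalg.norm(new - images, axis=1)))
        history.append(disp)
        images = new
        if disp < tol:
            converged = True
            break
    out = StringPath(images, history=list(path.history) + history, seed=seed,
                     converged=converged,
                     meta={"alpha": alpha, "smooth": smooth, "T": T,
                           "n_cell_samples": n_cell_samples, "tol": tol,
                           "endpoint_mode": endpoint_mode, "iterations": len(history)})
    if collected is not None:
        out.cell_samples = {
            "images": collected["images"],
            "samples": [np.array(s) for s in collected["samples"]],
        }
    out.free_energy = path_free_energy(surface, out)
    return out


def path_free_energy(surface_or_model, path: StringPath) -> np.ndarray:
    """Free energy at each image, shifted so the reactant endpoint is zero.

    Indexed by image number — the reaction coordinate index of the path
    profile.  For learned models, images outside the trusted domain are
    flagged NaN.
    """
    surface = surface_or_model
    vals = np.asarray(surface.energy(path.images), dtype=float)
    vals = vals - vals[0]
    if hasattr(surface, "trusted"):
        flags = np.asarray(surface.trusted(path.images))
        vals = np.where(flags, vals, np.nan)
    return vals


def cluster_paths(paths: list[StringPath], distance_threshold: float):
    """Group strings into distinct channels by single linkage.

    Pairwise distance = mean over image index of the Euclidean distance
    between corresponding images.  Paths joined below the threshold share a
    group; groups are ordered (and their members listed) by lowest path
    index.  All paths must share M and endpoints.
    """
    if not paths:
        return []
    M = paths[0].n_images
    for p in paths:
        if p.n_images != M:
            raise InputError("all paths must have the same number of images")
    k = len(paths)
    dist = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            dij = np.mean(np.linalg.norm(paths[i].images - paths[j].images, axis=1))
            dist[i, j] = dist[j, i] = dij
    # single linkage = connected components of the thresholded graph
    groups = []
    unassigned = set(range(k))
    while unassigned:
        root = min(unassigned)
        stack = [root]
        comp = set()
        while stack:
            u = stack.pop()
            if u in comp:
                continue
            comp.add(u)
            for v in unassigned:
                if v not in comp and dist[u, v] <= distance_threshold:
                    stack.append(v)
        unassigned -= comp
        groups.append(sorted(comp))
    groups.sort(key=lambda g: g[0])
    return groups
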
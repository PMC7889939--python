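"""Centre selection and mean-force estimation.

The free energy gradient at a point d_o is estimated from a harmonically
restrained simulation: with the restraint (k/2)|d - d_o|^2 added to the
potential, the mean force is

    F(d_o) = < k (d - d_o) >

averaged over the restrained ensemble.  On a quadratic surface of stiffness
kappa the estimator has the closed form F = -kappa (d_o - mu) * k/(k+kappa):
it is biased toward zero by the factor k/(k+kappa), vanishing as the
restraint stiffens — the property the tests exercise.

Centres are picked by K-means over the biased exploration samples, so they
trace the explored region without requiring overlap between neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .errors import InputError, TetraFESError
from .toy_systems import ToySurface, langevin_sample
from .units import kbt


@dataclass
class CenterSet:
    """K-means centres in CV space, with selection provenance."""

    centers: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))

    def __len__(self):
        return len(self.centers)


@dataclass
class MeanForceRecord:
    """A mean-force estimate at one centre."""

    center: np.ndarray
    force: np.ndarray
    se: np.ndarray
    spring: float
    temperature: float
    n_samples: int
    seed: int = 0

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float).reshape(-1)
        self.force = np.asarray(self.force, dtype=float).reshape(-1)
        self.se = np.asarray(self.se, dtype=float).reshape(-1)
        if self.n_samples <= 0:
            raise InputError("n_samples must be positive")
        if np.any(self.se < 0):
            raise InputError("standard errors must be non-negative")


def select_centers(samples: np.ndarray, n_centers: int, seed: int = 0,
                   max_iter: int = 100) -> CenterSet:
    """K-means centres (k-means++ initialisation, seeded, single restart)."""
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    distinct = np.unique(samples, axis=0)
    if n_centers > len(distinct):
        raise InputError(
            f"requested {n_centers} centers but only {len(distinct)} distinct samples"
        )
    if n_centers == len(distinct):
        centers = distinct
    else:
        km = KMeans(n_clusters=n_centers, init="k-means++", n_init=1,
                    random_state=seed, max_iter=max_iter)
        km.fit(samples)
        centers = km.cluster_centers_
    lo = samples.min(axis=0)
    hi = samples.max(axis=0)
    centers = np.clip(centers, lo, hi)
    return CenterSet(centers, provenance={"seed": seed, "k": n_centers,
                                          "n_samples": len(samples)})


def estimate_mean_force(surface: ToySurface, d_o, k: float, T: float = 300.0,
                        n_steps: int = 20_000, burn_in: int | None = None,
                        dt: float = 1e-3, friction: float = 1.0, seed: int = 0,
                        n_batches: int = 20) -> MeanForceRecord:
    """Mean force at d_o from a harmonically restrained Langevin run.

    Samples exp(-(A + (k/2)|d - d_o|^2)/k_B T) and returns the batch-means
    average of k (d - d_o) with per-component standard errors.
    """
    if k <= 0:
        raise InputError(f"spring constant must be positive, got {k}")
    d_o = np.asarray(d_o, dtype=float).reshape(-1)
    if burn_in is None:
        burn_in = n_steps // 5
    if burn_in >= n_steps:
        raise InputError("burn_in must be smaller than n_steps")

    restrained = _RestrainedSurface(surface, d_o, k)
    traj = langevin_sample(restrained, T, n_steps, dt, friction, x0=d_o,
                           seed=seed, save_stride=1)
    post = traj.samples[burn_in:]
    forces = k * (post - d_o)
    mean = forces.mean(axis=0)
    nb = min(n_batches, len(post))
    batches = np.array_split(forces, nb)
    bm = np.stack([b.mean(axis=0) for b in batches])
    se = bm.std(axis=0, ddof=1) / np.sqrt(nb)
    return MeanForceRecord(d_o, mean, se, k, T, len(post), seed)


class _RestrainedSurface(ToySurface):
    """surface + (k/2)|x - d_o|^2, restricted to the base surface's domain."""

    def __init__(self, base: ToySurface, d_o: np.ndarray, k: float):
        self.base = base
        self.dimension = base.dimension
        super().__init__()
        self.name = f"{base.name}+restraint"
        self.d_o = d_o
        self.k = k
        self.bounds = base.bounds

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        return self.base.energy(x) + 0.5 * self.k * np.sum((x - self.d_o) ** 2, axis=-1)

    def gradient(self, x):
        x = np.asarray(x, dtype=float)
        return self.base.gradient(x) + self.k * (x - self.d_o)


def batch_mean_forces(surface: ToySurface, centers: CenterSet | np.ndarray,
                      k: float = 100.0, T: float = 300.0, n_steps: int = 20_000,
                      burn_in: int | None = None, dt: float = 1e-3,
                      friction: float = 1.0, seeds=None, base_seed: int = 0
                      ) -> list[MeanForceRecord]:
    """Mean forces at every centre; per-centre failures are isolated.

    Seeds are taken from ``seeds`` (one per centre) or expanded
    deterministically from ``base_seed``.  More than 10% failed centres is a
    run-level error.
    """
    pts = centers.centers if isinstance(centers, CenterSet) else np.atleast_2d(centers)
    if len(pts) == 0:
        return []
    if seeds is None:
        seeds = [int(s) for s in
                 np.random.default_rng(base_seed).integers(0, 2**31 - 1, len(pts))]
    if len(seeds) != len(pts):
        raise InputError("one seed per centre required")
    records: list[MeanForceRecord] = []
    failures: list[tuple[int, str]] = []
    for i, (c, s) in enumerate(zip(pts, seeds)):
        try:
            records.append(
                estimate_mean_force(surface, c, k, T, n_steps, burn_in, dt,
                                    friction, seed=s)
            )
        except TetraFESError as exc:
            failures.append((i, str(exc)))
    if failures and len(failures) > 0.1 * len(pts):
        raise TetraFESError(
            f"{len(failures)}/{len(pts)} centres failed; first: {failures[0]}"
        )
    return records


# ---------------------------------------------------------------------------
# Interchange format: the CSV boundary where external MD output could be
# substituted for the toy sampler.
# ---------------------------------------------------------------------------

def records_to_csv(records: list[MeanForceRecord], path) -> None:
    if not records:
        pd.DataFrame().to_csv(path, index=False)
        return
    n = len(records[0].center)
    rows = {}
    for i in range(n):
        rows[f"d{i}"] = [r.center[i] for r in records]
    for i in range(n):
        rows[f"F{i}"] = [r.force[i] for r in records]
    for i in range(n):
        rows[f"se{i}"] = [r.se[i] for r in records]
    rows["k"] = [r.spring for r in records]
    rows["T"] = [r.temperature for r in records]
    rows["n_samples"] = [r.n_samples for r in records]
    rows["seed"] = [r.seed for r in records]
    pd.DataFrame(rows).to_csv(path, index=False)


def records_from_csv(path) -> list[MeanForceRecord]:
    df = pd.read_csv(path)
    if df.empty:
        return []
    n = sum(c.startswith("d") and c[1:].isdigit() for c in df.columns)
    recs = []
    for _, row in df.iterrows():
        recs.append(
            MeanForceRecord(
                center=[row[f"d{i}"] for i in range(n)],
                force=[row[f"F{i}"] for i in range(n)],
                se=[row[f"se{i}"] for i in range(n)],
                spring=float(row["k"]),
                temperature=float(row["T"]),
                n_samples=int(row["n_samples"]),
                seed=int(row["seed"]),
            )
        )
    return recs


def closed_form_restrained_force(kappa: float, mu: np.ndarray, k: float, d_o) -> np.ndarray:
    """Exact restrained mean force on a quadratic bowl (the estimator's oracle).

    For A = (kappa/2)|d - mu|^2 with restraint centre d_o and spring k the
    restrained ensemble is Gaussian and F = -kappa (d_o - mu) * k/(k+kappa).
    """
    d_o = np.asarray(d_o, dtype=float)
    mu = np.asarray(mu, dtype=float)
    return -kappa * (d_o - mu) * k / (k + kappa)
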
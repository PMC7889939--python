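"""End-to-end benchmark pipeline on the synthetic 6-D two-basin landscape.

The stages mirror the production workflow for a real chromatin system:

  fixture -> biased exploration -> K-means centres -> mean forces ->
  force-matched network -> marginal validation -> (WHAM, string method)

but run on the analytic ``sym6d_wells`` surface, whose exact gradients and
closed-form marginals provide the ground truth that a molecular system
cannot.  Mean forces are drawn around the analytic gradient with Gaussian
noise scaled to a fraction of the force RMS, emulating the statistical
error of restrained simulations while keeping the benchmark's truth known.

All stage seeds are derived deterministically from one base seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import explore, meanforce, profiles, string_method, toy_systems, wham
from .explore import CoordinateCV
from .fes_net import FESModel, TrainingReport, build_model, train_force_matching
from .meanforce import MeanForceRecord

logger = logging.getLogger(__name__)

#: Indices of d13 and d24 in the distance vector — the two distances that
#: both reach their minima in the stacked configuration, used as biasing CVs.
CV_D13, CV_D24 = 1, 4

EXPLORE_DEFAULTS = dict(
    kappa_ext=5.0, T=300.0, T_bar=3000.0, hill_height=1.0, hill_width=1.5,
    deposit_stride=500, n_steps=400_000, dt=0.01, friction=1.0,
    friction_z=1.0, save_stride=20,
)


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(n)]


def explore_benchmark(surface=None, seed: int = 0, **overrides):
    """Biased exploration of the 6-D benchmark along (d13, d24)."""
    if surface is None:
        surface = toy_systems.make_surface("sym6d_wells")
    params = dict(EXPLORE_DEFAULTS)
    params.update(overrides)
    cvs = [CoordinateCV(CV_D13), CoordinateCV(CV_D24)]
    cv_bounds = surface.bounds[[CV_D13, CV_D24]]
    traj, hills = explore.run_tamd_metad(
        surface, cvs, x0=toy_systems.SYM6D_FOLDED, seed=seed,
        cv_bounds=cv_bounds, **params,
    )
    return traj, hills


def noisy_mean_forces(surface, centers: np.ndarray, noise_frac: float = 0.05,
                      seed: int = 0, k: float = 100.0, T: float = 300.0
                      ) -> list[MeanForceRecord]:
    """Mean-force records around the analytic gradient with scaled noise.

    Noise SD = ``noise_frac`` times the pooled RMS of the true forces,
    mirroring the uncertainty of restrained-simulation estimates.
    """
    centers = np.atleast_2d(centers)
    F_true = -surface.gradient(centers)
    rms = float(np.sqrt(np.mean(F_true**2)))
    sd = noise_frac * rms
    rng = np.random.default_rng(seed)
    F = F_true + sd * rng.standard_normal(F_true.shape)
    se = np.full(centers.shape[1], sd)
    return [
        MeanForceRecord(c, f, se, spring=k, temperature=T, n_samples=1, seed=seed)
        for c, f in zip(centers, F)
    ]


@dataclass
class BenchmarkResult:
    """Artifacts and headline numbers of the force-matching benchmark."""

    model: FESModel
    report: TrainingReport
    surface: object
    centers: np.ndarray
    pearson_pooled: float
    marginal_max_dev: float
    marginal_mean_dev: float
    marginal_offset: float
    profile_model: profiles.FreeEnergyProfile
    profile_exact: profiles.FreeEnergyProfile
    n_samples: int
    extras: dict = field(default_factory=dict)


def run_force_matching_benchmark(seed: int = 0, n_centers: int = 2000,
                                 noise_frac: float = 0.05,
                                 split_fraction: float = 0.2,
                                 n_grid: int = 60, n_mc: int = 4000,
                                 explore_overrides: dict | None = None,
                                 hyperparams: dict | None = None) -> BenchmarkResult:
    """Full surrogate of the published validation, at desk scale.

    Biased exploration of the two-basin 6-D surface, 2,000 K-means centres,
    noisy analytic mean forces (SD = 5% of force RMS), symmetrised
    force-matching network with a 20% held-out split, then: pooled held-out
    Pearson correlation of predicted vs reference mean forces, and the
    offset-aligned maximum deviation of the learned d13 marginal from the
    exact one over the trusted range.
    """
    s_explore, s_centers, s_forces, s_train, s_marg, *_ = _stage_seeds(seed)
    surface = toy_systems.make_surface("sym6d_wells")

    logger.info("exploration (metadynamics + TAMD) ...")
    traj, hills = explore_benchmark(surface, seed=s_explore,
                                    **(explore_overrides or {}))
    logger.info("exploration produced %d samples, %d hills", len(traj), len(hills))

    cset = meanforce.select_centers(traj.samples, n_centers, seed=s_centers)
    records = noisy_mean_forces(surface, cset.centers, noise_frac, seed=s_forces)

    model = build_model(seed=s_train)
    model, report = train_force_matching(model, records,
                                         split_fraction=split_fraction,
                                         hyperparams=hyperparams, seed=s_train)
    logger.info("training stopped at epoch %d, held-out pooled r=%.4f",
                report.stopping_epoch, report.pearson_pooled)

    d13 = cset.centers[:, CV_D13]
    grid = np.linspace(np.percentile(d13, 2), np.percentile(d13, 98), n_grid)
    prof_model = profiles.marginal_profile(model, CV_D13, grid, T=300.0,
                                           n_mc=n_mc, seed=s_marg)
    prof_exact = toy_systems.marginal_1d_exact(surface, CV_D13, grid, T=300.0)
    offset, max_dev, mean_dev = profiles.compare_profiles(prof_model, prof_exact)
    logger.info("d13 marginal: max|dev|=%.3f kcal/mol after offset %.3f",
                max_dev, offset)

    return BenchmarkResult(
        model=model, report=report, surface=surface, centers=cset.centers,
        pearson_pooled=report.pearson_pooled, marginal_max_dev=max_dev,
        marginal_mean_dev=mean_dev, marginal_offset=offset,
        profile_model=prof_model, profile_exact=prof_exact,
        n_samples=len(traj),
        extras={"hills": len(hills), "stopping_epoch": report.stopping_epoch},
    )


def wham_double_well_barrier(seed: int = 0, h: float = 5.0, n_windows: int = 15,
                             spring: float = 50.0, n_steps: int = 40_000,
                             T: float = 300.0) -> dict:
    """Umbrella sampling + WHAM recovery of an analytic double-well barrier."""
    surface = toy_systems.make_surface("double_well_1d", h=h)
    centers = np.linspace(-1.6, 1.6, n_windows)
    windows = wham.run_umbrella(surface, 0, centers, spring, T=T,
                                n_steps=n_steps, seed=seed)
    res = wham.wham_solve(windows, n_bins=100, T=T)
    grid, A = res.grid, res.free_energy
    ok = np.isfinite(A)
    left = A[ok & (grid < -0.5)].min()
    right = A[ok & (grid > 0.5)].min()
    barrier = float(A[ok & (np.abs(grid) < 0.4)].max() - 0.5 * (left + right))
    return {"barrier": barrier, "expected": h, "converged": res.converged,
            "result": res}


def string_channels_on_model(model: FESModel, seed: int = 0, n_strings: int = 4,
                             M: int = 24, **fts_kwargs) -> dict:
    """Multi-start strings from the open to the folded basin on a model.

    Endpoints are the model's local minima obtained by descent from the
    fixture basin centres; strings start from linear and perturbed
    initialisations and are clustered into channels.
    """
    from scipy.optimize import minimize

    lo, hi = model.bounds[:, 0], model.bounds[:, 1]

    def descend(x0):
        r = minimize(lambda x: float(model.predict_energy(x)),
                     x0, jac=lambda x: -model.predict_force(x),
                     method="L-BFGS-B", bounds=list(zip(lo, hi)))
        return r.x

    a = descend(toy_systems.SYM6D_OPEN)
    b = descend(toy_systems.SYM6D_FOLDED)
    seeds = _stage_seeds(seed, n_strings)
    paths = []
    rng = np.random.default_rng(seed)
    kwargs = dict(n_cell_samples=100, sampler_dt=5e-3, T=300.0, alpha=0.1,
                  smooth=0.1, max_iter=60, tol=5e-3)
    kwargs.update(fts_kwargs)
    for i in range(n_strings):
        if i == 0:
            init = string_method.initialize_string(a, b, M=M)
        else:
            mid = 0.5 * (a + b) + rng.standard_normal(len(a)) * 3.0
            mid = np.clip(mid, lo, hi)
            init = string_method.initialize_string(a, b, M=M, mode="through_point",
                                                   waypoint=mid)
        paths.append(string_method.fts_relax(model, init, seed=seeds[i], **kwargs))
    dists = [
        np.mean(np.linalg.norm(p.images - q.images, axis=1))
        for i, p in enumerate(paths) for q in paths[i + 1:]
    ]
    thresh = float(np.median(dists)) if dists else 0.0
    groups = string_method.cluster_paths(paths, thresh)
    return {"paths": paths, "groups": groups, "endpoints": (a, b),
            "threshold": thresh}
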
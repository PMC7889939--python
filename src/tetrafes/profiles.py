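"""Marginal free energy profiles and profile comparison.

A free energy surface A(d) defined over six distances is summarised by 1-D
(or 2-D) marginals

    A_1(x) = -k_B T ln  integral  exp(-A(d)/k_B T)  d(other dims)

restricted, for a learned surface, to the trusted domain around its training
centres.  Profiles are defined up to an additive constant; comparisons are
made after removing the mean offset over the common support, mirroring how a
network-derived profile is validated against umbrella sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .units import kbt


@dataclass
class FreeEnergyProfile:
    """A free energy profile on a regular grid.

    grid    (n,) grid for 1-D profiles, or a tuple of two axes for 2-D
    values  free energies (kcal/mol), minimum shifted to 0; NaN = missing cell
    se      per-cell standard error (0 for exact/quadrature results)
    dims    index/indices of the retained coordinate(s)
    """

    grid: np.ndarray | tuple[np.ndarray, np.ndarray]
    values: np.ndarray
    se: np.ndarray | None = None
    dims: tuple[int, ...] = (0,)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.se is None:
            self.se = np.zeros_like(self.values)
        self.se = np.asarray(self.se, dtype=float)

    @property
    def ndim(self) -> int:
        return self.values.ndim

    def shifted(self) -> "FreeEnergyProfile":
        """Copy with the finite minimum moved to zero."""
        v = self.values - np.nanmin(self.values)
        return FreeEnergyProfile(self.grid, v, self.se.copy(), self.dims, dict(self.meta))

    def to_frame(self):
        import pandas as pd

        if self.ndim == 1:
            return pd.DataFrame({"x": np.asarray(self.grid), "A": self.values, "se": self.se})
        gx, gy = self.grid
        X, Y = np.meshgrid(gx, gy, indexing="ij")
        return pd.DataFrame(
            {"x": X.ravel(), "y": Y.ravel(), "A": self.values.ravel(), "se": self.se.ravel()}
        )

    @staticmethod
    def from_frame(df) -> "FreeEnergyProfile":
        if "y" in df.columns:
            gx = np.unique(df["x"].to_numpy())
            gy = np.unique(df["y"].to_numpy())
            vals = df["A"].to_numpy().reshape(len(gx), len(gy))
            se = df["se"].to_numpy().reshape(len(gx), len(gy))
            return FreeEnergyProfile((gx, gy), vals, se, dims=(0, 1))
        return FreeEnergyProfile(df["x"].to_numpy(), df["A"].to_numpy(), df["se"].to_numpy())


def compare_profiles(p: FreeEnergyProfile, q: FreeEnergyProfile):
    """Offset-aligned deviation between two 1-D profiles.

    q is linearly interpolated onto p's grid over the overlapping support;
    missing cells are excluded.  Returns (offset, max_abs_dev, mean_abs_dev)
    where offset = mean(p - q) over the common support and the deviations are
    computed after subtracting it.
    """
    if p.ndim != 1 or q.ndim != 1:
        raise InputError("compare_profiles expects 1-D profiles")
    gp = np.asarray(p.grid, dtype=float)
    gq = np.asarray(q.grid, dtype=float)
    ok_q = np.isfinite(q.values)
    if ok_q.sum() < 2:
        raise InputError("second profile has fewer than 2 finite cells")
    lo, hi = gq[ok_q].min(), gq[ok_q].max()
    mask = (gp >= lo) & (gp <= hi) & np.isfinite(p.values)
    if mask.sum() < 5:
        raise InputError(
            f"profiles overlap on only {int(mask.sum())} grid points (need >= 5)"
        )
    q_interp = np.interp(gp[mask], gq[ok_q], q.values[ok_q])
    diff = p.values[mask] - q_interp
    offset = float(np.mean(diff))
    dev = diff - offset
    return offset, float(np.max(np.abs(dev))), float(np.mean(np.abs(dev)))


def marginal_profile(model_or_surface, dims, grid, T: float, n_mc: int = 20000, seed: int = 0):
    """Marginal free energy profile of a learned model or an analytic surface.

    dims    one (1-D) or two (2-D) coordinate indices to retain
    grid    array of grid values (1-D) or tuple of two axes (2-D)

    Analytic surfaces are marginalised by the exact/quadrature machinery of
    the toy-system module.  Learned surfaces are marginalised by seeded
    importance sampling restricted to the trusted domain: the proposal over
    the integrated coordinates is a Gaussian mixture centred on the model's
    training centres, weighted by each centre's Boltzmann factor and by its
    proximity to the conditioning value, so samples land where the model both
    carries probability mass and is trusted.  Grid cells whose trusted volume
    yields no accepted sample are marked missing (NaN), not fatal.
    """
    dims = tuple(np.atleast_1d(dims).tolist())
    if len(dims) not in (1, 2):
        raise InputError(f"dims must select 1 or 2 coordinates, got {dims}")
    if hasattr(model_or_surface, "energy") and not hasattr(model_or_surface, "centers"):
        from .toy_systems import marginal_1d_exact

        if len(dims) == 1:
            return marginal_1d_exact(model_or_surface, dims[0], np.asarray(grid), T)
        raise InputError("2-D marginals of analytic surfaces are not implemented")
    return _marginal_model(model_or_surface, dims, grid, T, n_mc, seed)


def _marginal_model(model, dims, grid, T, n_mc, seed):
    """Importance-sampled marginal of a trained surface over its trusted domain."""
    beta = 1.0 / kbt(T)
    centers = np.asarray(model.centers, dtype=float)
    n_dim = centers.shape[1]
    other = [i for i in range(n_dim) if i not in dims]
    rng = np.random.default_rng(seed)

    # Mixture width: typical centre spacing, so the proposal tiles the
    # trusted region without leaving it too often.
    from scipy.spatial import cKDTree

    tree = cKDTree(centers)
    nn = tree.query(centers, k=2)[0][:, 1]
    tau = float(np.median(nn)) * 1.5

    center_energy = model.predict_energy(centers)
    log_w_center = -beta * center_energy
    log_w_center -= log_w_center.max()

    grids = [np.asarray(g, dtype=float) for g in (grid if len(dims) == 2 else (grid,))]
    shape = tuple(len(g) for g in grids)
    logI = np.full(shape, np.nan)
    se = np.full(shape, np.nan)

    for idx in np.ndindex(shape):
        xfix = np.array([grids[k][idx[k]] for k in range(len(dims))])
        # proximity weight of each centre to the conditioning slice
        d2 = np.sum((centers[:, dims] - xfix) ** 2, axis=1)
        logw = log_w_center - d2 / (2.0 * tau * tau)
        logw -= logw.max()
        w = np.exp(logw)
        wsum = w.sum()
        if wsum <= 0 or not np.isfinite(wsum):
            continue
        w /= wsum
        comp = rng.choice(len(centers), size=n_mc, p=w)
        pts = np.empty((n_mc, n_dim))
        pts[:, other] = centers[np.ix_(comp, other)] + rng.standard_normal(
            (n_mc, len(other))
        ) * tau
        pts[:, list(dims)] = xfix
        # mixture proposal density over the integrated coordinates
        dd = pts[:, None, other] - centers[None, :, other]
        log_comp = -np.sum(dd * dd, axis=2) / (2.0 * tau * tau)
        log_q = _logsumexp(log_comp + np.log(w)[None, :], axis=1) - 0.5 * len(other) * np.log(
            2.0 * np.pi * tau * tau
        )
        trusted = model.trusted(pts)
        if not np.any(trusted):
            continue
        energy = np.full(n_mc, np.inf)
        energy[trusted] = model.predict_energy(pts[trusted])
        log_f = -beta * energy - log_q
        m = log_f[trusted].max()
        ratios = np.where(trusted, np.exp(log_f - m), 0.0)
        mean = ratios.mean()
        if mean <= 0:
            continue
        logI[idx] = np.log(mean) + m
        se[idx] = ratios.std(ddof=1) / np.sqrt(n_mc) / mean / beta
    values = -logI / beta
    values -= np.nanmin(values)
    out_grid = grids[0] if len(dims) == 1 else (grids[0], grids[1])
    return FreeEnergyProfile(
        out_grid, values, se, dims=dims, meta={"T": T, "n_mc": n_mc, "seed": seed, "tau": tau}
    )


def _logsumexp(a, axis=None):
    m = np.max(a, axis=axis, keepdims=True)
    return np.squeeze(m, axis=axis) + np.log(np.sum(np.exp(a - m), axis=axis))


def contour_export(profile: FreeEnergyProfile, levels_interval: float = 1.0,
                   csv_path=None, figure_path=None):
    """Write a 2-D profile as gridded CSV and a contour figure.

    Contour levels are spaced ``levels_interval`` kcal/mol apart (default 1).
    Returns the matplotlib figure.
    """
    if profile.ndim != 2:
        raise InputError("contour_export expects a 2-D profile")
    if not np.any(np.isfinite(profile.values)):
        raise InputError("profile has no finite cells")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if csv_path is not None:
        profile.to_frame().to_csv(csv_path, index=False)
    gx, gy = profile.grid
    vmax = np.nanmax(profile.values)
    levels = np.arange(0.0, vmax + levels_interval, levels_interval)
    fig, ax = plt.subplots(figsize=(5, 4))
    cs = ax.contour(gx, gy, profile.values.T, levels=levels)
    ax.clabel(cs, inline=True, fontsize=7, fmt="%.0f")
    ax.set_xlabel(f"coordinate {profile.dims[0]}")
    ax.set_ylabel(f"coordinate {profile.dims[1]}")
    if figure_path is not None:
        fig.savefig(figure_path, dpi=120)
        plt.close(fig)
    return fig
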
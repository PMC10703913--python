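"""Posterior prediction surfaces: kriging of the latent field, gridded
prevalence with uncertainty, exceedance probabilities, and the
observed-versus-predicted validation used as a visual model check.

Prediction is by composition sampling: for every retained posterior draw of
(alpha, beta, sigma2, kappa, S at cluster sites), the latent field at new
locations is drawn from its exact Gaussian conditional, so hyperparameter
uncertainty propagates into the credible-interval maps.  Cells are summarized
marginally, so conditional draws are taken cellwise (the joint spatial
structure across cells within one draw is not needed for per-cell maps).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve, solve_triangular
from scipy.spatial.distance import cdist
from scipy.special import expit
from scipy.stats import pearsonr

from .matern import MaternTable, chol_with_jitter
from .models import PosteriorFit
from .raster import RasterGrid

__all__ = [
    "PredictionSurface",
    "kriging_moments",
    "predict_latent_field",
    "prevalence_surface",
    "exceedance_surface",
    "observed_vs_predicted",
]


@dataclass
class PredictionSurface:
    """Gridded posterior summaries of prevalence."""

    mean_prev: RasterGrid
    sd_prev: RasterGrid              # posterior SD, reported as the map "SE"
    ci_lower: RasterGrid
    ci_upper: RasterGrid
    ci_width: RasterGrid
    exceedance: dict[float, RasterGrid] = field(default_factory=dict)
    draws: np.ndarray | None = None  # optional (S, n_valid) prevalence draws
    valid_mask: np.ndarray | None = None

    def write(self, outdir, prefix: str = "prevalence", meta: dict | None = None) -> list[str]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        layers = {"mean": self.mean_prev, "sd": self.sd_prev, "ci_lower": self.ci_lower,
                  "ci_upper": self.ci_upper, "ci_width": self.ci_width}
        for thr, ras in self.exceedance.items():
            layers[f"exceedance_{thr:g}"] = ras
        for name, ras in layers.items():
            path = outdir / f"{prefix}_{name}.asc"
            ras.write_ascii(path, meta=meta)
            written.append(str(path))
        csv_path = outdir / f"{prefix}_surface.csv"
        self.to_dataframe().to_csv(csv_path, index=False)
        written.append(str(csv_path))
        return written

    def to_dataframe(self) -> pd.DataFrame:
        g = self.mean_prev
        centers = g.cell_centers()
        df = pd.DataFrame({
            "x": centers[:, 0], "y": centers[:, 1],
            "mean": g.values.ravel(), "sd": self.sd_prev.values.ravel(),
            "ci_lower": self.ci_lower.values.ravel(),
            "ci_upper": self.ci_upper.values.ravel(),
            "ci_width": self.ci_width.values.ravel(),
        })
        for thr, ras in self.exceedance.items():
            df[f"exceedance_{thr:g}"] = ras.values.ravel()
        return df.dropna(subset=["mean"]).reset_index(drop=True)


_corr_tables: dict[float, MaternTable] = {}


def _corr_table(nu: float) -> MaternTable:
    if nu not in _corr_tables:
        _corr_tables[nu] = MaternTable(nu)
    return _corr_tables[nu]


def kriging_moments(sites, s_values, sigma2: float, kappa: float, nu: float,
                    new_locations, jitter: float = 1e-8):
    """Conditional mean and (pointwise) variance of a Matérn GP at
    ``new_locations`` given field values ``s_values`` at ``sites``."""
    sites = np.atleast_2d(np.asarray(sites, dtype=float))
    new = np.atleast_2d(np.asarray(new_locations, dtype=float))
    s_values = np.asarray(s_values, dtype=float)
    if sigma2 <= 0:
        return np.zeros(new.shape[0]), np.zeros(new.shape[0])
    corr = _corr_table(nu)
    R, jit = chol_with_jitter(corr.corr_at(kappa * cdist(sites, sites)), jitter)
    a = cho_solve((R, True), s_values)
    c = corr.corr_at(kappa * cdist(new, sites))
    mean = c @ a
    half = solve_triangular(R, c.T, lower=True)
    var = sigma2 * np.maximum((1.0 + jit) - np.einsum("ij,ij->j", half, half), 0.0)
    return mean, var


def predict_latent_field(fit: PosteriorFit, new_locations, seed=None,
                         n_draws: int | None = None, batch_size: int = 4000) -> np.ndarray:
    """Conditional draws of the latent field S at ``new_locations``.

    For each posterior draw s, S(new) | S(sites), sigma2_s, kappa_s is Gaussian
    with the usual kriging mean and variance; one cellwise draw is taken per
    posterior draw.  Returns an (n_draws, n_new) array, deterministic given
    ``seed``.
    """
    if not fit.spatial:
        raise ValueError("latent-field prediction requires a spatial fit")
    new = np.atleast_2d(np.asarray(new_locations, dtype=float))
    rng = np.random.default_rng(seed)
    S_total = fit.n_samples
    idx = np.arange(S_total)
    if n_draws is not None and n_draws < S_total:
        idx = np.linspace(0, S_total - 1, n_draws).round().astype(int)
    sites = fit.coords
    out = np.empty((len(idx), new.shape[0]))
    for row, s in enumerate(idx):
        for start in range(0, new.shape[0], batch_size):
            blk = new[start:start + batch_size]
            mean, var = kriging_moments(sites, fit.latent[s], fit.sigma2[s],
                                        fit.kappa[s], fit.nu, blk, fit.jitter)
            out[row, start:start + batch_size] = mean + np.sqrt(var) * rng.standard_normal(len(blk))
    return out


def _linear_predictor_draws(fit: PosteriorFit, covs: np.ndarray, locations, seed, n_draws):
    """Prevalence draws (S, m) at arbitrary locations with covariates covs."""
    if fit.spatial:
        S_new = predict_latent_field(fit, locations, seed=seed, n_draws=n_draws)
        n_used = S_new.shape[0]
        idx = (np.linspace(0, fit.n_samples - 1, n_used).round().astype(int)
               if n_used < fit.n_samples else np.arange(fit.n_samples))
    else:
        idx = np.arange(fit.n_samples)
        if n_draws is not None and n_draws < fit.n_samples:
            idx = np.linspace(0, fit.n_samples - 1, n_draws).round().astype(int)
        S_new = 0.0
    eta = fit.alpha[idx, None] + fit.beta[idx] @ covs.T + S_new
    return expit(eta)


def prevalence_surface(fit: PosteriorFit, grid: RasterGrid, covariate_rasters: dict,
                       thresholds=(0.25,), seed=None, n_draws: int | None = None,
                       keep_draws: bool = False) -> PredictionSurface:
    """Posterior prevalence summaries on the geometry of ``grid``.

    ``covariate_rasters`` maps covariate name -> RasterGrid on the same
    geometry; every covariate of the fit must be present.  Cells where any
    covariate is nodata become nodata in all output layers.
    """
    missing = [c for c in fit.covariate_names if c not in covariate_rasters]
    if missing:
        raise ValueError(f"missing covariate rasters: {missing}")
    for name in fit.covariate_names:
        if not grid.same_grid(covariate_rasters[name]):
            raise ValueError(f"covariate raster {name!r} not on the prediction grid")

    centers = grid.cell_centers()
    if fit.covariate_names:
        covs = np.column_stack([covariate_rasters[c].values.ravel() for c in fit.covariate_names])
    else:
        covs = np.empty((len(centers), 0))
    valid = ~np.isnan(covs).any(axis=1)
    prev = _linear_predictor_draws(fit, covs[valid], centers[valid], seed, n_draws)

    def _layer(flat_vals):
        full = np.full(len(centers), np.nan)
        full[valid] = flat_vals
        return replace(grid, values=full.reshape(grid.values.shape), meta={})

    lo, hi = np.percentile(prev, [2.5, 97.5], axis=0)
    surf = PredictionSurface(
        mean_prev=_layer(prev.mean(axis=0)),
        sd_prev=_layer(prev.std(axis=0)),
        ci_lower=_layer(lo), ci_upper=_layer(hi), ci_width=_layer(hi - lo),
        draws=prev if keep_draws else None,
        valid_mask=valid,
    )
    for thr in thresholds:
        surf.exceedance[float(thr)] = _layer((prev > thr).mean(axis=0))
    return surf


def exceedance_surface(fit: PosteriorFit, grid: RasterGrid, covariate_rasters: dict,
                       threshold: float = 0.25, seed=None, n_draws: int | None = None) -> RasterGrid:
    """Per-cell posterior probability that prevalence exceeds ``threshold``."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    surf = prevalence_surface(fit, grid, covariate_rasters, thresholds=(threshold,),
                              seed=seed, n_draws=n_draws)
    return surf.exceedance[float(threshold)]


def observed_vs_predicted(fit: PosteriorFit, table: pd.DataFrame):
    """Cluster-level validation: observed y/n against posterior-mean fitted
    prevalence, with the Pearson correlation.

    Returns (validation DataFrame, correlation, p-value, n_excluded).  Clusters
    with n = 0 are excluded and counted; with fewer than 3 usable clusters or a
    constant series, the correlation is NaN (flagged, no crash).
    """
    n = table["n"].to_numpy(dtype=float)
    y = table["y_stunted"].to_numpy(dtype=float)
    if len(n) != fit.prevalence.shape[1]:
        raise ValueError("fit and table refer to different cluster sets")
    fitted = fit.prevalence.mean(axis=0)
    ok = n > 0
    n_excluded = int((~ok).sum())
    with np.errstate(invalid="ignore"):
        obs = np.where(ok, y / np.where(ok, n, 1.0), np.nan)
    df = pd.DataFrame({
        "cluster_id": table["cluster_id"].to_numpy(),
        "observed": obs, "predicted": fitted, "n": n,
    })
    o, f = obs[ok], fitted[ok]
    if ok.sum() < 3 or np.std(o) == 0 or np.std(f) == 0:
        return df, float("nan"), float("nan"), n_excluded
    r, pval = pearsonr(o, f)
    return df, float(r), float(pval), n_excluded
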
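"""Synthetic cluster surveys with the statistical structure the geostatistical
analysis assumes, with ground truth retained for recovery testing.

The generator emulates: a planar-km study domain; two-stage stratified cluster
sampling with urban clusters concentrated around a few town centers and rural
clusters spread uniformly; smooth standardized covariate fields standing in
for remote-sensed layers; a latent Matérn Gaussian process on the logit scale;
binomial outcomes; right-skewed survey weights; and GPS displacement of up to
2 km (urban) / 5 km (rural).

All randomness derives from ``SyntheticConfig.seed``; the full generator is a
deterministic function of the configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .matern import MaternParams, chol_with_jitter, matern_correlation
from .raster import BufferSpec, RasterGrid

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_covariate_fields",
    "sample_clusters",
    "simulate_spatial_field",
    "simulate_outcomes",
    "displace_coordinates",
    "generate_survey",
]

# fixed stream tags so each stage gets an independent, reproducible substream
_STREAM = {"fields": 1, "clusters": 2, "gp": 3, "outcomes": 4, "displace": 5}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAM[stage]])


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic survey.

    Defaults describe a Ghana-like 100x100 km study area: 400 clusters with a
    30% urban share, negative-binomial cluster sizes with mean 12 children
    (matching the ~11.7 children/cluster of a recent national survey) and
    dispersion 4, log-normal survey weights with CV 0.5 normalized to mean 1,
    one standardized covariate with log-odds effect 0.32, and a latent Matérn
    field with sigma2=0.3, kappa=0.1 per km (practical range ~28 km), nu=1.
    """

    domain_extent: tuple[float, float, float, float] = (0.0, 0.0, 100.0, 100.0)
    n_clusters: int = 400
    urban_fraction: float = 0.3
    children_mean: float = 12.0
    children_dispersion: float = 4.0
    true_alpha: float = -0.3
    true_beta: tuple[float, ...] = (0.32,)
    matern: MaternParams = field(default_factory=lambda: MaternParams(0.3, 0.1, 1.0))
    weight_cv: float = 0.5
    seed: int = 0
    grid_cellsize: float = 5.0
    buffers: BufferSpec = field(default_factory=BufferSpec)

    def __post_init__(self) -> None:
        xmin, ymin, xmax, ymax = self.domain_extent
        if xmax <= xmin or ymax <= ymin:
            raise ValueError("domain must have positive area")
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if not 0.0 <= self.urban_fraction <= 1.0:
            raise ValueError("urban_fraction must lie in [0, 1]")
        if self.weight_cv < 0:
            raise ValueError("weight_cv must be nonnegative")
        if self.children_mean <= 0 or self.children_dispersion <= 0:
            raise ValueError("children-per-cluster distribution needs positive mean and dispersion")
        if self.grid_cellsize <= 0:
            raise ValueError("grid cell size must be positive")

    @property
    def n_covariates(self) -> int:
        return len(self.true_beta)

    def grid_template(self) -> RasterGrid:
        xmin, ymin, xmax, ymax = self.domain_extent
        ncols = max(2, int(np.ceil((xmax - xmin) / self.grid_cellsize)))
        nrows = max(2, int(np.ceil((ymax - ymin) / self.grid_cellsize)))
        return RasterGrid(np.full((nrows, ncols), np.nan), xll=xmin, yll=ymin,
                          cellsize=self.grid_cellsize)


@dataclass
class SyntheticTruth:
    """Ground truth retained alongside a generated survey."""

    config: SyntheticConfig
    p_surface: RasterGrid          # true prevalence P(x) on the grid
    s_surface: RasterGrid          # true latent field on the grid
    s_sites: np.ndarray            # latent field at (true) cluster sites
    true_coords: np.ndarray        # pre-displacement cluster coordinates
    p_sites: np.ndarray            # true prevalence at cluster sites
    covariate_rasters: dict[str, RasterGrid] = field(default_factory=dict)

    def check_consistency(self, atol: float = 1e-8) -> None:
        """logit(P) minus the fixed effects must equal S at grid nodes."""
        cfg = self.config
        lin = np.full_like(self.p_surface.values, cfg.true_alpha)
        for b, (_, ras) in zip(cfg.true_beta, self.covariate_rasters.items()):
            lin = lin + b * ras.values
        resid = logit(self.p_surface.values) - lin - self.s_surface.values
        assert np.nanmax(np.abs(resid)) < atol


def generate_covariate_fields(config: SyntheticConfig, n_fields: int) -> list[RasterGrid]:
    """Smooth synthetic covariate rasters, each standardized to zero mean and
    unit SD over the grid.  Deterministic given the config seed.

    Each field is a sum of random cosine plane waves with wavelengths from
    ~1/16 up to ~1/2 of the domain extent: smooth enough to show positive
    short-range autocorrelation like real remote-sensed layers, but with
    fine-scale components well below a country-scale Matérn practical range,
    so covariate effects stay identifiable next to the latent field (as they
    are for real 5 km resolution layers).
    """
    if n_fields < 1:
        raise ValueError("n_fields must be >= 1")
    rng = _rng(config.seed, "fields")
    grid = config.grid_template()
    centers = grid.cell_centers()
    xmin, ymin, xmax, ymax = config.domain_extent
    extent = max(xmax - xmin, ymax - ymin)
    rasters = []
    for i in range(n_fields):
        vals = np.zeros(len(centers))
        for _ in range(12):
            wavelength = extent / np.exp(rng.uniform(np.log(2.0), np.log(16.0)))
            theta = rng.uniform(0.0, 2.0 * np.pi)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            amp = rng.standard_normal()
            k = 2.0 * np.pi / wavelength * np.array([np.cos(theta), np.sin(theta)])
            vals += amp * np.cos(centers @ k + phase)
        vals = (vals - vals.mean()) / vals.std()
        ras = replace(grid, values=vals.reshape(grid.values.shape),
                      meta={"synthetic": True, "field": i})
        rasters.append(ras)
    return rasters


def sample_clusters(config: SyntheticConfig) -> pd.DataFrame:
    """Cluster locations, strata and survey weights (no outcomes yet).

    Exactly round(n_clusters * urban_fraction) clusters are urban, scattered
    around a small number of town centers; rural clusters are uniform over the
    domain.  Weights are log-normal with the configured CV, normalized to
    sample mean 1.
    """
    rng = _rng(config.seed, "clusters")
    xmin, ymin, xmax, ymax = config.domain_extent
    n = config.n_clusters
    n_urban = int(round(n * config.urban_fraction))
    n_rural = n - n_urban

    coords = np.empty((n, 2))
    if n_urban:
        n_towns = max(1, int(round(np.sqrt(n_urban))))
        towns = np.column_stack([rng.uniform(xmin, xmax, n_towns),
                                 rng.uniform(ymin, ymax, n_towns)])
        assignment = rng.integers(0, n_towns, n_urban)
        scatter = 0.02 * max(xmax - xmin, ymax - ymin)
        pts = towns[assignment] + scatter * rng.standard_normal((n_urban, 2))
        coords[:n_urban, 0] = np.clip(pts[:, 0], xmin, xmax)
        coords[:n_urban, 1] = np.clip(pts[:, 1], ymin, ymax)
    coords[n_urban:, 0] = rng.uniform(xmin, xmax, n_rural)
    coords[n_urban:, 1] = rng.uniform(ymin, ymax, n_rural)

    if config.weight_cv > 0:
        s2 = np.log1p(config.weight_cv ** 2)
        w = rng.lognormal(mean=-s2 / 2.0, sigma=np.sqrt(s2), size=n)
        w = w / w.mean()
    else:
        w = np.ones(n)

    table = pd.DataFrame({
        "cluster_id": [f"c{i:04d}" for i in range(n)],
        "x": coords[:, 0], "y": coords[:, 1],
        "urban": np.arange(n) < n_urban,
        "weight": w,
    })
    return table.sample(frac=1.0, random_state=np.random.RandomState(config.seed % (2**31))).reset_index(drop=True)


def simulate_spatial_field(locations, params: MaternParams, seed=None,
                           rng: np.random.Generator | None = None,
                           jitter: float = 1e-8) -> np.ndarray:
    """One draw of the zero-mean Matérn Gaussian process at ``locations``."""
    locs = np.atleast_2d(np.asarray(locations, dtype=float))
    if rng is None:
        rng = np.random.default_rng(seed)
    n = locs.shape[0]
    if params.sigma2 == 0:
        return np.zeros(n)
    from scipy.spatial.distance import cdist

    R = matern_correlation(cdist(locs, locs), params.kappa, params.nu)
    L, _ = chol_with_jitter(R, jitter)
    return np.sqrt(params.sigma2) * (L @ rng.standard_normal(n))


def simulate_outcomes(clusters: pd.DataFrame, alpha: float, beta, s_values,
                      config: SyntheticConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Fill n (children sampled) and y_stunted via the binomial model.

    Requires covariate columns cov_1..cov_k in ``clusters``; the linear
    predictor is alpha + d(x)'beta + S(x) on the logit scale.
    """
    if rng is None:
        rng = _rng(config.seed, "outcomes")
    beta = np.asarray(beta, dtype=float)
    cov_cols = [f"cov_{j + 1}" for j in range(len(beta))]
    missing = [c for c in cov_cols if c not in clusters.columns]
    if missing:
        raise ValueError(f"covariate values missing at cluster sites: {missing}")
    D = clusters[cov_cols].to_numpy(dtype=float) if len(beta) else np.zeros((len(clusters), 0))
    eta = alpha + D @ beta + np.asarray(s_values, dtype=float)
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite linear predictor; check covariates and parameters")
    p = expit(eta)
    disp, mean = config.children_dispersion, config.children_mean
    n = rng.negative_binomial(disp, disp / (disp + mean), size=len(clusters))
    y = rng.binomial(n, p)
    out = clusters.copy()
    out["n"] = n
    out["y_stunted"] = y
    out["true_prevalence"] = p
    return out


def displace_coordinates(clusters: pd.DataFrame, seed=None, buffers: BufferSpec = BufferSpec(),
                         rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Jitter coordinates like DHS GPS displacement: uniform random angle,
    uniform distance up to 2 km (urban) or 5 km (rural)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    n = len(clusters)
    rmax = np.where(clusters["urban"].to_numpy(dtype=bool),
                    buffers.urban_radius_km, buffers.rural_radius_km)
    dist = rng.uniform(0.0, rmax)
    angle = rng.uniform(0.0, 2.0 * np.pi, n)
    out = clusters.copy()
    out["x"] = clusters["x"].to_numpy() + dist * np.cos(angle)
    out["y"] = clusters["y"].to_numpy() + dist * np.sin(angle)
    return out


def generate_survey(config: SyntheticConfig, displace: bool = True):
    """Full synthetic survey: returns (cluster table, SyntheticTruth).

    The latent field is drawn *jointly* at cluster sites and grid nodes so the
    stored truth surface and the site values are one coherent realization.
    The returned table's coordinates are displaced when ``displace`` is True;
    the truth keeps the original coordinates.  Covariate columns cov_1..cov_k
    hold the field values at the true cluster locations.
    """
    k = config.n_covariates
    rasters = generate_covariate_fields(config, max(k, 1))[:k] if k else []
    clusters = sample_clusters(config)
    coords = clusters[["x", "y"]].to_numpy()

    grid = config.grid_template()
    grid_pts = grid.cell_centers()
    all_pts = np.vstack([coords, grid_pts])
    s_all = simulate_spatial_field(all_pts, config.matern, rng=_rng(config.seed, "gp"))
    s_sites = s_all[: len(coords)]
    s_grid = s_all[len(coords):].reshape(grid.values.shape)

    cov_rasters = {}
    # clamp sampling points into the cell-center extent so edge clusters get
    # the nearest in-grid value instead of nodata
    xs, ys = grid.x_centers, grid.y_centers
    clamped = np.column_stack([
        np.clip(coords[:, 0], xs.min(), xs.max()),
        np.clip(coords[:, 1], ys.min(), ys.max()),
    ])
    for j, ras in enumerate(rasters):
        name = f"cov_{j + 1}"
        clusters[name] = ras.sample_bilinear(clamped)
        cov_rasters[name] = ras

    clusters = simulate_outcomes(clusters, config.true_alpha, config.true_beta,
                                 s_sites, config)

    lin = np.full_like(s_grid, config.true_alpha)
    for b, ras in zip(config.true_beta, rasters):
        lin = lin + b * ras.values
    p_grid = expit(lin + s_grid)

    truth = SyntheticTruth(
        config=config,
        p_surface=replace(grid, values=p_grid, meta={"synthetic": True, "layer": "true_prevalence"}),
        s_surface=replace(grid, values=s_grid, meta={"synthetic": True, "layer": "true_latent"}),
        s_sites=s_sites,
        true_coords=coords.copy(),
        p_sites=clusters["true_prevalence"].to_numpy(),
        covariate_rasters=cov_rasters,
    )
    if displace:
        clusters = displace_coordinates(clusters, buffers=config.buffers,
                                        rng=_rng(config.seed, "displace"))
    order = ["cluster_id", "x", "y", "urban", "n", "y_stunted", "weight"] + list(cov_rasters)
    return clusters[order + ["true_prevalence"]], truth
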
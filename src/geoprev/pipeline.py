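"""End-to-end orchestration: simulate/load -> extract covariates -> fit both
models -> predict surfaces -> report, as a configured, logged, reproducible run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from time import perf_counter

import numpy as np
import pandas as pd
import yaml

from .matern import MaternParams, practical_range
from .models import ModelSpec, PosteriorFit, PriorSpec, fit_nonspatial, fit_spatial
from .predict import observed_vs_predicted, prevalence_surface
from .raster import BufferSpec, RasterGrid, extract_buffered_many, resample_bilinear
from .survey import national_weighted_prevalence, validate_cluster_table, weighted_counts
from .synthetic import SyntheticConfig, generate_survey

logger = logging.getLogger("geoprev.pipeline")

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline", "summarize_fit"]


@dataclass
class PipelineConfig:
    """One reproducible run.  Exactly one of synthetic / real-input mode."""

    seed: int
    out_dir: str
    synthetic: bool = True
    synthetic_config: SyntheticConfig | None = None
    cluster_csv: str | None = None
    raster_paths: dict = field(default_factory=dict)   # covariate name -> .asc path
    covariates: list[str] = field(default_factory=list)
    nu: float = 1.0
    n_burn: int = 500
    n_samples: int = 1000
    thin: int = 1
    strict_convergence: bool = False
    grid_cellsize: float = 5.0
    grid_margin: float = 0.0
    thresholds: list[float] = field(default_factory=lambda: [0.25])
    prediction_draws: int | None = 200
    buffer_urban_km: float = 2.0
    buffer_rural_km: float = 5.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.synthetic == (self.cluster_csv is not None):
            raise ValueError("exactly one of synthetic mode / cluster_csv input is required")
        if self.synthetic and self.synthetic_config is None:
            self.synthetic_config = SyntheticConfig(seed=self.seed)
        if self.synthetic and not self.covariates:
            self.covariates = [f"cov_{j+1}" for j in range(self.synthetic_config.n_covariates)]

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        syn = raw.pop("synthetic_config", None)
        if syn is not None:
            mat = syn.pop("matern", None)
            if mat is not None:
                syn["matern"] = MaternParams(**mat)
            if "true_beta" in syn:
                syn["true_beta"] = tuple(syn["true_beta"])
            if "domain_extent" in syn:
                syn["domain_extent"] = tuple(syn["domain_extent"])
            syn.setdefault("seed", raw.get("seed", 0))
            raw["synthetic_config"] = SyntheticConfig(**syn)
        return cls(**raw)

    def config_hash(self) -> str:
        def _clean(o):
            if isinstance(o, dict):
                return {k: _clean(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [_clean(v) for v in o]
            return o
        blob = json.dumps(_clean(asdict(self)), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class ReportBundle:
    """Run-level report: model comparison, national prevalence, manifest."""

    model_summaries: dict[str, pd.DataFrame]
    waic: dict[str, float]
    preferred_model: str
    national_prevalence_pct: float
    diagnostics: dict[str, pd.DataFrame]
    validation: dict
    surfaces_manifest: list[str]
    config_hash: str
    seed: int

    def to_dict(self) -> dict:
        return {
            "waic": self.waic,
            "preferred_model": self.preferred_model,
            "national_prevalence_pct": self.national_prevalence_pct,
            "validation": self.validation,
            "surfaces_manifest": self.surfaces_manifest,
            "config_hash": self.config_hash,
            "seed": self.seed,
            "model_summaries": {k: v.to_dict(orient="records") for k, v in self.model_summaries.items()},
        }

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(self.to_dict(), indent=1, default=float))
        for name, df in self.model_summaries.items():
            df.to_csv(outdir / f"summary_{name}.csv", index=False)


def summarize_fit(fits: list[PosteriorFit], table: pd.DataFrame,
                  config_hash: str = "", seed: int = 0) -> ReportBundle:
    """Table-1-style report across fitted models plus the design-weighted
    national prevalence 100 * sum(y_eff) / sum(n_eff)."""
    if not fits:
        raise ValueError("need at least one fitted model")
    wc = weighted_counts(table)
    national = national_weighted_prevalence(wc["y_stunted"], wc["n"])
    summaries = {f.model: f.summary() for f in fits}
    waic = {f.model: f.waic for f in fits}
    preferred = min(waic, key=waic.get)
    return ReportBundle(
        model_summaries=summaries, waic=waic, preferred_model=preferred,
        national_prevalence_pct=national,
        diagnostics={f.model: f.diagnostics for f in fits},
        validation={}, surfaces_manifest=[], config_hash=config_hash, seed=seed)


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = perf_counter()
            logger.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done in %.1fs", name, perf_counter() - t0)
            return out
        return wrapper
    return deco


@_stage("extract")
def _extract_covariates(table: pd.DataFrame, rasters: dict[str, RasterGrid],
                        buffers: BufferSpec) -> pd.DataFrame:
    """Displacement-aware buffered extraction of every covariate layer."""
    pts = table[["x", "y"]].to_numpy()
    urban = table["urban"].to_numpy(dtype=bool)
    out = table.copy()
    for name, ras in rasters.items():
        out[name] = extract_buffered_many(ras, pts, urban, buffers)
    cov_cols = list(rasters)
    bad = out[cov_cols].isna().any(axis=1)
    if bad.any():
        logger.warning("dropping %d clusters with missing covariates after extraction",
                       int(bad.sum()))
        out = out[~bad].reset_index(drop=True)
    return out


def _prediction_grid(table: pd.DataFrame, cellsize: float, margin: float) -> RasterGrid:
    xmin, ymin = table[["x", "y"]].min() - margin
    xmax, ymax = table[["x", "y"]].max() + margin
    ncols = max(2, int(np.ceil((xmax - xmin) / cellsize)))
    nrows = max(2, int(np.ceil((ymax - ymin) / cellsize)))
    return RasterGrid(np.full((nrows, ncols), np.nan), xll=float(xmin), yll=float(ymin),
                      cellsize=float(cellsize))


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run every stage and write all artifacts under ``config.out_dir``."""
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(outdir / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("geoprev")
    root.addHandler(fh)
    root.setLevel(logging.INFO)
    chash = config.config_hash()
    meta = {"seed": config.seed, "config_hash": chash}
    logger.info("run start: seed=%d hash=%s", config.seed, chash)
    try:
        buffers = BufferSpec(config.buffer_urban_km, config.buffer_rural_km)

        # ---- stage: inputs ------------------------------------------------
        if config.synthetic:
            table, truth = generate_survey(config.synthetic_config)
            rasters = truth.covariate_rasters
            truth.p_surface.write_ascii(outdir / "true_prevalence.asc", meta=meta)
            for name, ras in rasters.items():
                ras.write_ascii(outdir / f"{name}.asc", meta=meta)
        else:
            table = pd.read_csv(config.cluster_csv)
            rasters = {name: RasterGrid.read_ascii(p) for name, p in config.raster_paths.items()}
        logger.info("inputs: %d clusters, %d covariate layers", len(table), len(rasters))

        # ---- stage: extract ----------------------------------------------
        use = {c: rasters[c] for c in config.covariates} if config.covariates else {}
        if use:
            table = _extract_covariates(table, use, buffers)
        table = weighted_counts(table)
        validate_cluster_table(table, config.covariates)
        table.to_csv(outdir / "clusters.csv", index=False)

        # ---- stage: fit ---------------------------------------------------
        priors = PriorSpec()
        base = dict(covariates=config.covariates, nu=config.nu, priors=priors,
                    n_burn=config.n_burn, n_samples=config.n_samples, thin=config.thin,
                    strict_convergence=config.strict_convergence)
        t0 = perf_counter()
        fit_ns = fit_nonspatial(table, ModelSpec(spatial=False, **base),
                                random_state=config.seed)
        logger.info("non-spatial fit: WAIC=%.2f (%.1fs)", fit_ns.waic, perf_counter() - t0)
        t0 = perf_counter()
        fit_sp = fit_spatial(table, ModelSpec(spatial=True, **base),
                             random_state=config.seed + 1)
        logger.info("spatial fit: WAIC=%.2f sigma2=%.3f range=%.2f (%.1fs)",
                    fit_sp.waic, float(np.mean(fit_sp.sigma2)),
                    practical_range(float(np.mean(fit_sp.kappa)), config.nu),
                    perf_counter() - t0)
        for f in (fit_ns, fit_sp):
            f.save(outdir)

        # ---- stage: predict -----------------------------------------------
        grid = _prediction_grid(table, config.grid_cellsize, config.grid_margin)
        cov_on_grid = {name: resample_bilinear(ras, grid) for name, ras in use.items()}
        fits = {"nonspatial": fit_ns, "spatial": fit_sp}
        preferred = min(fits, key=lambda k: fits[k].waic)
        surf = prevalence_surface(fits[preferred], grid, cov_on_grid,
                                  thresholds=config.thresholds,
                                  seed=config.seed + 2, n_draws=config.prediction_draws)
        manifest = surf.write(outdir, prefix=f"prevalence_{preferred}", meta=meta)

        # ---- stage: report ------------------------------------------------
        vdf, corr, pval, n_excl = observed_vs_predicted(fit_sp, table)
        vdf.to_csv(outdir / "observed_vs_predicted.csv", index=False)
        bundle = summarize_fit([fit_ns, fit_sp], table, config_hash=chash, seed=config.seed)
        bundle.validation = {"pearson_r": corr, "p_value": pval,
                             "n_excluded_zero_n": n_excl}
        bundle.surfaces_manifest = manifest
        bundle.write(outdir)
        logger.info("run complete: preferred=%s national=%.1f%%",
                    bundle.preferred_model, bundle.national_prevalence_pct)
        return bundle
    finally:
        root.removeHandler(fh)
        fh.close()
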
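"""Gridded raster layers: container, text I/O, resampling, derived covariates
and displacement-aware buffered extraction.

Rasters are square-celled, axis-aligned grids in the working coordinate system
(planar km for synthetic runs; lon/lat with a local equirectangular projection
for geographic data).  On disk they are ESRI ASCII grids (.asc), a plain-text
format readable by every GIS.  Missing data are carried as NaN in memory and as
the ``nodata`` sentinel on disk; no aggregation ever treats nodata as a value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.interpolate import RegularGridInterpolator

EARTH_RADIUS_KM = 6371.0


@dataclass
class RasterGrid:
    """A single-band georeferenced grid.

    ``values`` is a 2-D float array with row 0 the *northernmost* row (ESRI
    ASCII convention); NaN marks nodata.  ``xll``/``yll`` are the coordinates
    of the lower-left *corner*; ``cellsize`` is the square cell edge in the
    units of the working coordinate system.
    """

    values: np.ndarray
    xll: float
    yll: float
    cellsize: float
    nodata: float = -9999.0
    crs_label: str = "planar_km"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cellsize <= 0:
            raise ValueError(f"cellsize must be positive, got {self.cellsize}")

    # ---- geometry -------------------------------------------------------
    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def x_centers(self) -> np.ndarray:
        return self.xll + (np.arange(self.ncols) + 0.5) * self.cellsize

    @property
    def y_centers(self) -> np.ndarray:
        """Cell-center y coordinates for rows 0..nrows-1 (descending)."""
        top = self.yll + self.nrows * self.cellsize
        return top - (np.arange(self.nrows) + 0.5) * self.cellsize

    def cell_centers(self) -> np.ndarray:
        """(nrows*ncols, 2) array of (x, y) centers in row-major order."""
        xx, yy = np.meshgrid(self.x_centers, self.y_centers)
        return np.column_stack([xx.ravel(), yy.ravel()])

    def same_grid(self, other: "RasterGrid", tol: float = 1e-9) -> bool:
        return (
            self.values.shape == other.values.shape
            and abs(self.xll - other.xll) <= tol
            and abs(self.yll - other.yll) <= tol
            and abs(self.cellsize - other.cellsize) <= tol
        )

    def blank_like(self) -> "RasterGrid":
        return replace(self, values=np.full_like(self.values, np.nan), meta=dict(self.meta))

    # ---- interpolation --------------------------------------------------
    def interpolator(self) -> RegularGridInterpolator:
        # ascending y axis for the interpolator: flip rows
        return RegularGridInterpolator(
            (self.y_centers[::-1], self.x_centers),
            self.values[::-1, :],
            method="linear",
            bounds_error=False,
            fill_value=np.nan,
        )

    def sample_bilinear(self, points) -> np.ndarray:
        """Bilinear sample at (x, y) points; NaN outside the center extent."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return self.interpolator()(np.column_stack([pts[:, 1], pts[:, 0]]))

    # ---- I/O ------------------------------------------------------------
    def write_ascii(self, path, meta: dict | None = None) -> None:
        """Write as ESRI ASCII grid, with provenance in a JSON sidecar."""
        path = Path(path)
        vals = np.where(np.isnan(self.values), self.nodata, self.values)
        with open(path, "w") as fh:
            fh.write(f"ncols {self.ncols}\n")
            fh.write(f"nrows {self.nrows}\n")
            fh.write(f"xllcorner {self.xll:.10g}\n")
            fh.write(f"yllcorner {self.yll:.10g}\n")
            fh.write(f"cellsize {self.cellsize:.10g}\n")
            fh.write(f"NODATA_value {self.nodata:.10g}\n")
            for row in vals:
                fh.write(" ".join(f"{v:.8g}" for v in row) + "\n")
        sidecar = {"crs_label": self.crs_label, **self.meta, **(meta or {})}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def read_ascii(cls, path) -> "RasterGrid":
        path = Path(path)
        header: dict[str, float] = {}
        rows = []
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                if len(parts) == 2 and parts[0].lower() in {
                    "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
                }:
                    header[parts[0].lower()] = float(parts[1])
                else:
                    rows.append([float(v) for v in parts])
        values = np.asarray(rows, dtype=float)
        nodata = header.get("nodata_value", -9999.0)
        values[values == nodata] = np.nan
        meta: dict = {}
        crs = "planar_km"
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            crs = meta.pop("crs_label", crs)
        return cls(
            values=values,
            xll=header["xllcorner"],
            yll=header["yllcorner"],
            cellsize=header["cellsize"],
            nodata=nodata,
            crs_label=crs,
            meta=meta,
        )


@dataclass(frozen=True)
class BufferSpec:
    """Extraction buffer radii absorbing GPS displacement (km)."""

    urban_radius_km: float = 2.0
    rural_radius_km: float = 5.0

    def __post_init__(self) -> None:
        if self.urban_radius_km <= 0 or self.rural_radius_km <= 0:
            raise ValueError("buffer radii must be positive")
        if self.urban_radius_km > self.rural_radius_km:
            raise ValueError("urban radius must not exceed rural radius")

    def radius(self, urban: bool) -> float:
        return self.urban_radius_km if urban else self.rural_radius_km


def _check_same_grids(rasters) -> None:
    first = rasters[0]
    for r in rasters[1:]:
        if not first.same_grid(r):
            raise ValueError("rasters are not on an identical grid")


def temporal_aggregate(monthly, mode: str = "sum") -> RasterGrid:
    """Cellwise sum or mean across a monthly raster stack (nodata propagates)."""
    monthly = list(monthly)
    if not monthly:
        raise ValueError("empty raster list")
    if mode not in {"sum", "mean"}:
        raise ValueError(f"mode must be 'sum' or 'mean', got {mode!r}")
    _check_same_grids(monthly)
    stack = np.stack([r.values for r in monthly])
    agg = stack.sum(axis=0) if mode == "sum" else stack.mean(axis=0)
    return replace(monthly[0], values=agg, meta={"derived": f"temporal_{mode}", "n_months": len(monthly)})


def compute_aridity(precip_monthly, pet_monthly) -> RasterGrid:
    """Aridity index: mean monthly precipitation / mean monthly PET.

    Nodata wherever either input stack is nodata or the PET mean is zero.
    """
    precip_monthly, pet_monthly = list(precip_monthly), list(pet_monthly)
    if len(precip_monthly) != len(pet_monthly) or not precip_monthly:
        raise ValueError("precip and PET stacks must be nonempty and equal length")
    _check_same_grids(precip_monthly + pet_monthly)
    p_mean = temporal_aggregate(precip_monthly, "mean").values
    e_mean = temporal_aggregate(pet_monthly, "mean").values
    with np.errstate(divide="ignore", invalid="ignore"):
        aridity = np.where(e_mean == 0, np.nan, p_mean / e_mean)
    return replace(precip_monthly[0], values=aridity, meta={"derived": "aridity"})


def resample_bilinear(source: RasterGrid, target_grid: RasterGrid) -> RasterGrid:
    """Resample ``source`` onto the geometry of ``target_grid`` bilinearly.

    Target cell centers outside the source center extent become nodata.
    """
    pts = target_grid.cell_centers()
    vals = source.sample_bilinear(pts).reshape(target_grid.values.shape)
    if np.all(np.isnan(vals)):
        raise ValueError("target grid does not overlap source extent")
    out = target_grid.blank_like()
    out.values = vals
    out.crs_label = source.crs_label
    out.meta = {"derived": "resample_bilinear"}
    return out


def extract_buffered(raster: RasterGrid, point, urban: bool, buffers: BufferSpec = BufferSpec()) -> float:
    """Mean of non-nodata cells whose centers fall within the displacement
    buffer (2 km urban / 5 km rural) of ``point``.  NaN if no valid cell."""
    x0, y0 = float(point[0]), float(point[1])
    r = buffers.radius(urban)
    xs = raster.x_centers
    ys = raster.y_centers
    # bounding box prefilter, then exact circular test on centers
    ci = np.where(np.abs(xs - x0) <= r)[0]
    ri = np.where(np.abs(ys - y0) <= r)[0]
    if ci.size == 0 or ri.size == 0:
        return float("nan")
    sub = raster.values[np.ix_(ri, ci)]
    dx = xs[ci][None, :] - x0
    dy = ys[ri][:, None] - y0
    inside = dx * dx + dy * dy <= r * r
    vals = sub[inside & ~np.isnan(sub)]
    if vals.size == 0:
        return float("nan")
    return float(vals.mean())


def extract_buffered_many(raster: RasterGrid, points, urban_flags, buffers: BufferSpec = BufferSpec()) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    urban = np.asarray(urban_flags, dtype=bool)
    return np.array([
        extract_buffered(raster, p, bool(u), buffers) for p, u in zip(pts, urban)
    ])


def lonlat_to_local_km(lon, lat, lon0: float | None = None, lat0: float | None = None):
    """Project lon/lat (degrees) to planar km with a local equirectangular
    projection about (lon0, lat0), adequate for km-scale buffers."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if lon0 is None:
        lon0 = float(np.mean(lon))
    if lat0 is None:
        lat0 = float(np.mean(lat))
    kx = np.cos(np.deg2rad(lat0)) * np.pi / 180.0 * EARTH_RADIUS_KM
    ky = np.pi / 180.0 * EARTH_RADIUS_KM
    return (lon - lon0) * kx, (lat - lat0) * ky
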
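"""Shared geospatial containers and GeoTIFF / CSV input-output.

All coordinates are map units of a projected metric CRS (meters); the toolkit
performs no reprojection.  Rasters follow the usual north-up convention:
row 0 is the top of the grid, cell coordinates refer to cell centers, and
pixel extents are half-open.  GeoTIFFs are written single-band float32 with
an explicit nodata value and the standard geo tags (ModelPixelScale,
ModelTiepoint, GeoKeyDirectory, GDAL_NODATA).
"""

from __future__ import annotations

import dataclasses
import logging
import math
import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger("demdiff")

DEFAULT_NODATA = -9999.0
#: default CRS identifier (UTM zone 50N) — purely a label carried through I/O
DEFAULT_EPSG = 32650

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_KEY_DIRECTORY = 34735
_TAG_GDAL_NODATA = 42113
_GEOKEY_PROJECTED_CRS = 3072


class GeodataError(Exception):
    """Base class for data-layer failures."""


class MultiBandError(GeodataError):
    """Raster has more than one band where a single band is required."""


class MissingGeotransformError(GeodataError):
    """Raster lacks the tags needed to place it in map coordinates."""


class DuplicateSiteIdError(GeodataError):
    """Two site records share an id."""


class EmptySiteTableError(GeodataError):
    """No usable site records remain."""


# ---------------------------------------------------------------------------
# grid geometry
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class GridTransform:
    """North-up affine placement of a raster grid.

    ``x0``/``y0`` are the map coordinates of the grid's top-left *corner*;
    ``dx``/``dy`` are the (strictly positive) cell width and height.  The
    center of cell ``(row, col)`` sits at ``(x0 + (col+0.5)dx,
    y0 - (row+0.5)dy)``.
    """

    x0: float
    y0: float
    dx: float
    dy: float

    def __post_init__(self) -> None:
        if not (self.dx > 0 and self.dy > 0):
            raise GeodataError("cell sizes must be strictly positive")

    def x_centers(self, ncols: int) -> np.ndarray:
        return self.x0 + (np.arange(ncols) + 0.5) * self.dx

    def y_centers(self, nrows: int) -> np.ndarray:
        return self.y0 - (np.arange(nrows) + 0.5) * self.dy

    def cell_center(self, row, col):
        return (self.x0 + (np.asarray(col) + 0.5) * self.dx,
                self.y0 - (np.asarray(row) + 0.5) * self.dy)

    def rowcol(self, x, y):
        """Indices of the cells containing points ``(x, y)`` (half-open)."""
        col = np.floor((np.asarray(x, dtype=float) - self.x0) / self.dx)
        row = np.floor((self.y0 - np.asarray(y, dtype=float)) / self.dy)
        return row.astype(np.int64), col.astype(np.int64)


def _validate_grid(values: np.ndarray, mask: np.ndarray) -> None:
    if values.ndim != 2 or values.shape[0] < 1 or values.shape[1] < 1:
        raise GeodataError("grid must be 2-D with dimensions >= 1x1")
    if mask.shape != values.shape or mask.dtype != bool:
        raise GeodataError("nodata mask must be a boolean grid matching values")
    if not np.all(np.isfinite(values[~mask])):
        raise GeodataError("unmasked grid values must be finite")


@dataclasses.dataclass
class DemRaster:
    """Gridded elevation (meters) with placement and a nodata mask."""

    values: np.ndarray
    transform: GridTransform
    crs_id: int = DEFAULT_EPSG
    nodata_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        _validate_grid(self.values, self.nodata_mask)

    @property
    def shape(self):
        return self.values.shape

    @property
    def cell_size(self) -> float:
        return float(self.transform.dx)


@dataclasses.dataclass
class Surface:
    """Gridded concentration estimate (µg/m³), aligned to a DEM grid."""

    values: np.ndarray
    transform: GridTransform
    crs_id: int = DEFAULT_EPSG
    nodata_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        _validate_grid(self.values, self.nodata_mask)
        if np.any(self.values[~self.nodata_mask] < 0):
            raise GeodataError("unmasked surface values must be non-negative")

    @property
    def shape(self):
        return self.values.shape

    def sample(self, x, y) -> np.ndarray:
        """Values at the cells containing points ``(x, y)``; NaN off-grid
        and at nodata cells."""
        row, col = self.transform.rowcol(x, y)
        out = np.full(row.shape, np.nan)
        inside = ((row >= 0) & (row < self.shape[0])
                  & (col >= 0) & (col < self.shape[1]))
        r, c = row[inside], col[inside]
        vals = self.values[r, c].astype(float)
        vals[self.nodata_mask[r, c]] = np.nan
        out[inside] = vals
        return out


# ---------------------------------------------------------------------------
# site table
# ---------------------------------------------------------------------------

class SiteTable:
    """Monitoring-station records ``(id, x, y, value)``.

    ``value`` is the observed concentration for one time slice (µg/m³);
    negative observations are instrument artifacts and are rejected rather
    than clipped.  ``nonnegative=False`` relaxes the sign constraint for
    internal residual tables (e.g. detrended kriging inputs).
    """

    COLUMNS = ("id", "x", "y", "value")

    def __init__(self, frame: pd.DataFrame, nonnegative: bool = True):
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise GeodataError(f"site table missing columns: {missing}")
        frame = frame.loc[:, list(self.COLUMNS)].reset_index(drop=True).copy()
        frame["id"] = frame["id"].astype(str)
        for c in ("x", "y", "value"):
            frame[c] = pd.to_numeric(frame[c], errors="coerce").astype(float)
        if len(frame) < 1:
            raise EmptySiteTableError("site table has no records")
        if frame["id"].duplicated().any():
            dups = sorted(frame.loc[frame["id"].duplicated(), "id"].unique())
            raise DuplicateSiteIdError(f"duplicate site ids: {dups}")
        if not np.all(np.isfinite(frame[["x", "y", "value"]].to_numpy())):
            raise GeodataError("site coordinates and values must be finite")
        if nonnegative and (frame["value"] < 0).any():
            raise GeodataError("site values must be non-negative")
        self.frame = frame
        self.nonnegative = nonnegative

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def ids(self) -> np.ndarray:
        return self.frame["id"].to_numpy()

    @property
    def x(self) -> np.ndarray:
        return self.frame["x"].to_numpy()

    @property
    def y(self) -> np.ndarray:
        return self.frame["y"].to_numpy()

    @property
    def values(self) -> np.ndarray:
        return self.frame["value"].to_numpy()

    def coords(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def select_ids(self, ids: Iterable[str]) -> "SiteTable":
        wanted = set(str(i) for i in ids)
        mask = self.frame["id"].isin(wanted).to_numpy()
        return self.select_mask(mask)

    def select_mask(self, mask: np.ndarray) -> "SiteTable":
        return SiteTable(self.frame.loc[np.asarray(mask, dtype=bool)],
                         nonnegative=self.nonnegative)

    def with_values(self, values: np.ndarray,
                    nonnegative: bool | None = None) -> "SiteTable":
        frame = self.frame.copy()
        frame["value"] = np.asarray(values, dtype=float)
        if nonnegative is None:
            nonnegative = self.nonnegative
        return SiteTable(frame, nonnegative=nonnegative)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RunConfig:
    """Parameters of one interpolation / evaluation run.

    segmentation_scale
        merge-cost threshold of the region-merging segmentation
        (dimensionless; merging stops once the cheapest merge exceeds
        ``scale²``).  Not comparable across datasets — recalibrate per DEM.
    buffer_km
        window buffer radius around each region (km); default 100, the
        distance over which neighbouring stations are allowed to inform a
        region's estimate.
    output_resolution
        cell size of the estimate surface (map units); ``None`` means the
        DEM cell size.
    w_bins_max
        cap on the number of value-axis bins of the monitoring space.
    idw_power_grid
        candidate IDW power exponents for RMSE-optimal selection.
    """

    segmentation_scale: float = 500.0
    buffer_km: float = 100.0
    output_resolution: float | None = None
    w_bins_max: int = 40
    idw_power_grid: Sequence[float] = (1.0, 1.5, 2.0, 2.5, 3.0, 4.0)
    variogram_model: str = "spherical"
    rng_seed: int = 0
    folds: int = 10

    def __post_init__(self) -> None:
        if self.segmentation_scale <= 0:
            raise GeodataError("segmentation_scale must be positive")
        if self.buffer_km <= 0:
            raise GeodataError("buffer_km must be positive")
        if self.output_resolution is not None and self.output_resolution <= 0:
            raise GeodataError("output_resolution must be positive")
        if self.w_bins_max < 2:
            raise GeodataError("w_bins_max must be >= 2")
        if len(self.idw_power_grid) < 1 or min(self.idw_power_grid) <= 0:
            raise GeodataError("idw_power_grid must be positive values")
        if self.folds < 2:
            raise GeodataError("folds must be >= 2")

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        """Parse a plain ``key = value`` text file mirroring the field names."""
        kwargs = {}
        with open(path) as fh:
            for raw in fh:
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise GeodataError(f"bad config line: {raw.strip()!r}")
                key, val = (s.strip() for s in line.split("=", 1))
                if key not in {f.name for f in dataclasses.fields(cls)}:
                    raise GeodataError(f"unknown config key: {key!r}")
                if key == "idw_power_grid":
                    kwargs[key] = tuple(float(v) for v in val.split(","))
                elif key == "variogram_model":
                    kwargs[key] = val
                elif key in ("w_bins_max", "rng_seed", "folds"):
                    kwargs[key] = int(val)
                elif key == "output_resolution" and val.lower() == "none":
                    kwargs[key] = None
                else:
                    kwargs[key] = float(val)
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# GeoTIFF I/O
# ---------------------------------------------------------------------------

def _write_geotiff(values: np.ndarray, mask: np.ndarray,
                   transform: GridTransform, crs_id: int, path: str,
                   nodata: float = DEFAULT_NODATA) -> None:
    arr = np.asarray(values, dtype=np.float32).copy()
    arr[mask] = np.float32(nodata)
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3,
         (float(transform.dx), float(transform.dy), 0.0), True),
        (_TAG_MODEL_TIEPOINT, "d", 6,
         (0.0, 0.0, 0.0, float(transform.x0), float(transform.y0), 0.0), True),
        (_TAG_GEO_KEY_DIRECTORY, "H", 8,
         (1, 1, 0, 1, _GEOKEY_PROJECTED_CRS, 0, 1, int(crs_id)), True),
        (_TAG_GDAL_NODATA, "s", 0, str(nodata), True),
    ]
    tifffile.imwrite(path, arr, photometric="minisblack", extratags=extratags)


def _read_geotiff(path: str):
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        if len(tif.pages) > 1:
            raise MultiBandError(f"multi-band raster (pages): {path}")
        page = tif.pages[0]
        if page.samplesperpixel != 1:
            raise MultiBandError(f"multi-band raster: {path}")
        values = page.asarray()
        if values.ndim != 2:
            raise MultiBandError(f"multi-band raster: {path}")
        scale = page.tags.get(_TAG_MODEL_PIXEL_SCALE)
        tiepoint = page.tags.get(_TAG_MODEL_TIEPOINT)
        if scale is None or tiepoint is None:
            raise MissingGeotransformError(f"raster lacks geotransform: {path}")
        dx, dy = float(scale.value[0]), float(scale.value[1])
        # tiepoint maps raster (col, row) = (t0, t1) to map (t3, t4)
        t = tiepoint.value
        x0 = float(t[3]) - float(t[0]) * dx
        y0 = float(t[4]) + float(t[1]) * dy
        crs_id = DEFAULT_EPSG
        geokeys = page.tags.get(_TAG_GEO_KEY_DIRECTORY)
        if geokeys is not None:
            vals = list(geokeys.value)
            for k in range(4, len(vals) - 3, 4):
                if vals[k] == _GEOKEY_PROJECTED_CRS:
                    crs_id = int(vals[k + 3])
        nodata = None
        nd_tag = page.tags.get(_TAG_GDAL_NODATA)
        if nd_tag is not None:
            try:
                nodata = float(str(nd_tag.value))
            except ValueError:
                nodata = None
    values = np.asarray(values, dtype=np.float32)
    mask = ~np.isfinite(values)
    if nodata is not None:
        mask |= values == np.float32(nodata)
    return values, mask, GridTransform(x0, y0, dx, dy), crs_id


def read_dem(path: str) -> DemRaster:
    """Read a single-band elevation GeoTIFF (meters); nodata cells masked."""
    values, mask, transform, crs_id = _read_geotiff(path)
    if mask.all():
        raise GeodataError(f"DEM is entirely nodata: {path}")
    return DemRaster(values, transform, crs_id, mask)


def write_dem(dem: DemRaster, path: str,
              nodata: float = DEFAULT_NODATA) -> None:
    _write_geotiff(dem.values, dem.nodata_mask, dem.transform, dem.crs_id,
                   path, nodata)


def read_surface(path: str) -> Surface:
    values, mask, transform, crs_id = _read_geotiff(path)
    return Surface(values, transform, crs_id, mask)


def write_surface(surface: Surface, path: str,
                  nodata: float = DEFAULT_NODATA) -> None:
    """Write a Surface as GeoTIFF; unmasked values round-trip bit-exactly."""
    _write_geotiff(surface.values, surface.nodata_mask, surface.transform,
                   surface.crs_id, path, nodata)


# ---------------------------------------------------------------------------
# site CSV I/O
# ---------------------------------------------------------------------------

def read_sites(path: str) -> SiteTable:
    """Read a station CSV with header ``id,x,y,value`` (extra columns
    ignored); rows with non-finite or negative values are dropped with a
    logged count."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    frame = pd.read_csv(path)
    missing = [c for c in SiteTable.COLUMNS if c not in frame.columns]
    if missing:
        raise GeodataError(f"site CSV missing columns: {missing}")
    frame = frame.loc[:, list(SiteTable.COLUMNS)].copy()
    frame["value"] = pd.to_numeric(frame["value"], errors="coerce")
    frame["x"] = pd.to_numeric(frame["x"], errors="coerce")
    frame["y"] = pd.to_numeric(frame["y"], errors="coerce")
    ok = (np.isfinite(frame[["x", "y", "value"]].to_numpy()).all(axis=1)
          & (frame["value"].to_numpy() >= 0))
    dropped = int((~ok).sum())
    if dropped:
        logger.info("read_sites: dropped %d rows with non-finite or negative "
                    "values from %s", dropped, path)
    frame = frame.loc[ok]
    if len(frame) == 0:
        raise EmptySiteTableError(f"no valid site records in {path}")
    if frame["id"].astype(str).duplicated().any():
        dups = sorted(frame.loc[frame["id"].astype(str).duplicated(), "id"]
                      .astype(str).unique())
        raise DuplicateSiteIdError(f"duplicate site ids: {dups}")
    return SiteTable(frame)


def write_sites(sites: SiteTable, path: str) -> None:
    sites.frame.to_csv(path, index=False)
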
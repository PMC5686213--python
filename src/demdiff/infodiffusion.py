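"""Information-diffusion interpolation on a discrete monitoring space.

Each monitoring window is treated as a small-sample estimation problem.
The two spatial coordinates and the observed concentration are discretized
into an equal-interval monitoring space U×V×W; every sample (x_l, y_l, z_l)
spreads a separable 3-D Gaussian kernel ("information") over the space with
per-dimension bandwidths h set by the averaging model; the accumulated
information matrix Q is normalized per value-slice into a fuzzy relation r;
and the concentration estimate at each spatial node is the fuzzy-set
centroid of r along the value axis:

    est(u_i, v_j) = Σ_k w_k r_ijk / Σ_k r_ijk.

Windows come from the DEM segmentation; region edges are hard break lines —
a window's estimate is written only to its own region's cells, while its
sample pool includes buffered neighbouring stations.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import List, Sequence, Tuple

import numpy as np

from .geodata import DemRaster, GeodataError, RunConfig, SiteTable, Surface
from .segmentation import RegionMap, RegionWindow, build_windows, segment_dem

logger = logging.getLogger("demdiff")

SQRT_2PI = math.sqrt(2.0 * math.pi)

#: averaging-model coefficients c(n) of the diffusion factor h = c(n)·(b−a)
H_COEFFICIENTS = {5: 0.8146, 6: 0.5690, 7: 0.4560, 8: 0.3860,
                  9: 0.3362, 10: 0.2986}
#: numerator of the large-sample branch h = C·(b−a)/(n−1), n > 10
H_LARGE_N_NUMERATOR = 2.6851

#: value-axis step (µg/m³) used when every sample in a window shares one
#: value, so no data-derived step exists
DEGENERATE_W_STEP = 1.0


class DegenerateStepError(GeodataError):
    """All coordinates identical in a dimension: no pairwise step exists."""


# ---------------------------------------------------------------------------
# monitoring space
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class MonitoringSpace:
    """Equal-interval discretization of (x, y, value).

    ``u`` is the west→east axis (map units), ``v`` the node y-coordinates in
    raster row order (north→south), ``w`` the ascending value axis (µg/m³).
    ``col0``/``row0`` anchor the (u, v) nodes on the output raster lattice:
    node (i, j) is the center of raster cell (row0 + j, col0 + i), indices
    possibly outside the raster when padding extends past its edge.
    """

    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    col0: int = 0
    row0: int = 0

    def __post_init__(self) -> None:
        for ax in (self.u, self.w):
            if len(ax) < 2 or np.any(np.diff(ax) <= 0):
                raise GeodataError("space axes must be strictly increasing")
        if len(self.v) < 2 or np.any(np.diff(self.v) >= 0):
            raise GeodataError("v axis must be strictly decreasing "
                               "(raster row order)")

    @property
    def du(self) -> float:
        return float(self.u[1] - self.u[0])

    @property
    def dv(self) -> float:
        return float(abs(self.v[1] - self.v[0]))

    @property
    def dw(self) -> float:
        return float(self.w[1] - self.w[0])

    @property
    def shape(self) -> Tuple[int, int, int]:
        return (len(self.v), len(self.u), len(self.w))


@dataclasses.dataclass(frozen=True)
class DiffusionFactors:
    """Per-dimension Gaussian bandwidths from the averaging model."""

    h_x: float
    h_y: float
    h_z: float
    n: int
    range_x: Tuple[float, float]
    range_y: Tuple[float, float]
    range_z: Tuple[float, float]

    def __post_init__(self) -> None:
        if not (self.h_x > 0 and self.h_y > 0 and self.h_z > 0):
            raise GeodataError("diffusion factors must be positive")
        if self.n < 1:
            raise GeodataError("sample count must be >= 1")


def compute_steps(samples: np.ndarray) -> Tuple[float, float, float]:
    """Minimum absolute pairwise difference over distinct coordinates,
    per dimension of an (n, 3) sample array.

    A dimension whose coordinates are all identical has no step; it is
    reported as NaN and the caller substitutes a degenerate default.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[1] != 3 or samples.shape[0] < 2:
        raise GeodataError("compute_steps needs an (n>=2, 3) sample array")
    steps = []
    for d in range(3):
        uniq = np.unique(samples[:, d])
        steps.append(float(np.diff(uniq).min()) if len(uniq) > 1 else np.nan)
    return tuple(steps)  # type: ignore[return-value]


def compute_h(n: int, a: float, b: float,
              grid_step: float | None = None) -> float:
    """Diffusion factor from the averaging model.

    Piecewise in the sample count: tabulated coefficients times the data
    range (b − a) for n = 5..10 and 2.6851(b − a)/(n − 1) beyond; below
    n = 5 (where the model is undefined) the n = 5 coefficient is used.
    A zero range (b = a) falls back to half the dimension's grid step.
    """
    if n < 1:
        raise GeodataError("compute_h requires n >= 1")
    if b < a:
        raise GeodataError("compute_h requires b >= a")
    if b == a:
        if grid_step is None or grid_step <= 0:
            raise DegenerateStepError(
                "zero data range and no grid step to fall back to")
        return 0.5 * float(grid_step)
    if n > 10:
        return H_LARGE_N_NUMERATOR * (b - a) / (n - 1)
    coeff = H_COEFFICIENTS[max(n, 5)]
    return coeff * (b - a)


def compute_factors(samples: np.ndarray, resolution: float) -> DiffusionFactors:
    """Averaging-model bandwidths for one window's sample set."""
    samples = np.asarray(samples, dtype=float)
    n = samples.shape[0]
    ranges = [(float(samples[:, d].min()), float(samples[:, d].max()))
              for d in range(3)]
    grid_steps = (resolution, resolution, DEGENERATE_W_STEP)
    hs = [compute_h(n, a, b, grid_step=g)
          for (a, b), g in zip(ranges, grid_steps)]
    return DiffusionFactors(hs[0], hs[1], hs[2], n, *ranges)


def build_space(samples: np.ndarray, bbox: Tuple[float, float, float, float],
                resolution: float, w_bins_max: int,
                factors: DiffusionFactors,
                anchor: Tuple[float, float] = (0.0, 0.0)) -> MonitoringSpace:
    """Construct the monitoring space for one window.

    The u/v axes cover the region bounding box ``(xmin, xmax, ymin, ymax)``
    padded by 3·max(h_x, h_y), with nodes on the output raster lattice
    anchored at ``anchor`` = map coordinates of the raster's top-left corner
    and step equal to the output resolution.  The w axis covers the sample
    value range padded by 3·h_z, with step max(Δz, span/(w_bins_max − 1)) so
    the bin count never exceeds ``w_bins_max``.
    """
    samples = np.asarray(samples, dtype=float)
    xmin, xmax, ymin, ymax = bbox
    pad = 3.0 * max(factors.h_x, factors.h_y)
    x_corner, y_corner = anchor

    col0 = int(math.floor((xmin - pad - x_corner) / resolution))
    col1 = max(int(math.ceil((xmax + pad - x_corner) / resolution)), col0 + 2)
    u = x_corner + (np.arange(col0, col1) + 0.5) * resolution
    row0 = int(math.floor((y_corner - (ymax + pad)) / resolution))
    row1 = max(int(math.ceil((y_corner - (ymin - pad)) / resolution)),
               row0 + 2)
    v = y_corner - (np.arange(row0, row1) + 0.5) * resolution

    a_z, b_z = factors.range_z
    dz = compute_steps(samples)[2]
    if math.isnan(dz):
        dz = DEGENERATE_W_STEP
    w_start = a_z - 3.0 * factors.h_z
    w_end = b_z + 3.0 * factors.h_z
    span = w_end - w_start
    dw = max(dz, span / (w_bins_max - 1))
    n_steps = int(math.ceil(span / dw - 1e-9))
    w = w_start + np.arange(n_steps + 1) * dw
    if len(w) > w_bins_max:
        raise GeodataError("w axis exceeded w_bins_max")  # pragma: no cover
    return MonitoringSpace(u=u, v=v, w=w, col0=col0, row0=row0)


# ---------------------------------------------------------------------------
# diffusion, fuzzification, defuzzification
# ---------------------------------------------------------------------------

def _gauss(axis: np.ndarray, center: float, h: float) -> np.ndarray:
    return np.exp(-((axis - center) ** 2) / (2.0 * h * h)) / (h * SQRT_2PI)


def diffuse_sample(sample: Sequence[float], space: MonitoringSpace,
                   factors: DiffusionFactors) -> np.ndarray:
    """Information of one sample over the space: the separable product of
    three 1-D Gaussian kernels, shape (len(v), len(u), len(w))."""
    x, y, z = (float(s) for s in sample)
    gv = _gauss(space.v, y, factors.h_y)
    gu = _gauss(space.u, x, factors.h_x)
    gw = _gauss(space.w, z, factors.h_z)
    return gv[:, None, None] * gu[None, :, None] * gw[None, None, :]


def accumulate(samples: np.ndarray, space: MonitoringSpace,
               factors: DiffusionFactors) -> np.ndarray:
    """Original information matrix Q: the sum of every sample's diffusion."""
    samples = np.asarray(samples, dtype=float)
    if samples.shape[0] < 1:
        raise GeodataError("accumulate requires at least one sample")
    gu = _gauss(space.u[None, :], samples[:, 0:1], factors.h_x)
    gv = _gauss(space.v[None, :], samples[:, 1:2], factors.h_y)
    gw = _gauss(space.w[None, :], samples[:, 2:3], factors.h_z)
    return np.einsum("lv,lu,lw->vuw", gv, gu, gw, optimize=True)


def fuzzify(Q: np.ndarray) -> np.ndarray:
    """Fuzzy relation r: each value-slice of Q scaled by its spatial
    maximum S_k; all-zero slices stay zero."""
    if np.any(Q < 0):
        raise GeodataError("information matrix must be non-negative")
    S = Q.max(axis=(0, 1))
    R = np.zeros_like(Q)
    pos = S > 0
    R[:, :, pos] = Q[:, :, pos] / S[pos]
    return R


def defuzzify(R: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Fuzzy-set centroid along the value axis at every spatial node;
    NaN where the relation carries no mass."""
    den = R.sum(axis=2)
    num = R @ np.asarray(w, dtype=float)
    out = np.full(den.shape, np.nan)
    pos = den > 0
    out[pos] = num[pos] / den[pos]
    return out


# ---------------------------------------------------------------------------
# windowed interpolation
# ---------------------------------------------------------------------------

def _window_samples(window: RegionWindow, sites: SiteTable) -> np.ndarray:
    sub = sites.select_ids(window.buffered_sites)
    return np.column_stack([sub.x, sub.y, sub.values])


def interpolate_window(window: RegionWindow, sites: SiteTable,
                       regions: RegionMap, config: RunConfig
                       ) -> np.ndarray:
    """Estimate one region; returns a full-grid float array that is NaN
    everywhere except the window's own cells (hard break lines)."""
    samples = _window_samples(window, sites)
    if samples.shape[0] < 3:
        raise GeodataError(
            f"window {window.label} has fewer than 3 buffered sites")
    t = regions.transform
    resolution = config.output_resolution or t.dx
    factors = compute_factors(samples, resolution)

    rr, cc = np.nonzero(regions.labels == window.label)
    cx, cy = t.cell_center(rr, cc)
    bbox = (cx.min(), cx.max(), cy.min(), cy.max())
    space = build_space(samples, bbox, resolution, config.w_bins_max,
                        factors, anchor=(t.x0, t.y0))
    logger.debug("window %d: n=%d h=(%.1f, %.1f, %.3f) grid=%s",
                 window.label, factors.n, factors.h_x, factors.h_y,
                 factors.h_z, space.shape)
    Q = accumulate(samples, space, factors)
    R = fuzzify(Q)
    est = defuzzify(R, space.w)

    out = np.full(regions.labels.shape, np.nan)
    iv = rr - space.row0
    iu = cc - space.col0
    out[rr, cc] = np.maximum(est[iv, iu], 0.0)
    return out


def single_region_map(dem: DemRaster) -> RegionMap:
    """The trivial partition: one region covering every unmasked cell
    (the global, unwindowed variant of the estimator)."""
    from .segmentation import RegionStats
    labels = np.where(dem.nodata_mask, 0, 1).astype(np.int32)
    vals = dem.values[~dem.nodata_mask].astype(float)
    stats = {1: RegionStats(int(labels.sum()), float(vals.mean()),
                            float(vals.min()), float(vals.max()))}
    return RegionMap(labels, stats, dem.transform, dem.crs_id)


def interpolate_field(dem: DemRaster, sites: SiteTable, config: RunConfig,
                      windowed: bool = True,
                      regions: RegionMap | None = None) -> np.ndarray:
    """The mosaicked estimate grid in float64, NaN where no estimate
    (nodata DEM cells or value slices without mass)."""
    if regions is None:
        regions = (segment_dem(dem, config.segmentation_scale) if windowed
                   else single_region_map(dem))
    windows = build_windows(regions, sites, config.buffer_km)
    mosaic = np.full(dem.shape, np.nan)
    failures = []
    for window in windows:
        try:
            part = interpolate_window(window, sites, regions, config)
        except GeodataError as exc:
            failures.append((window.label, str(exc)))
            continue
        cells = ~np.isnan(part)
        mosaic[cells] = part[cells]
    if failures:
        raise GeodataError(
            "interpolation failed for regions: "
            + "; ".join(f"{lab}: {msg}" for lab, msg in failures))
    return mosaic


def interpolate(dem: DemRaster, sites: SiteTable, config: RunConfig,
                windowed: bool = True,
                regions: RegionMap | None = None) -> Surface:
    """Full pipeline: segment → window → diffuse per region → mosaic.

    ``windowed=False`` skips the segmentation and estimates the whole DEM
    as a single window (the comparison baseline for the windowing benefit).
    A precomputed ``regions`` partition may be passed to avoid re-running
    the segmentation, e.g. across cross-validation folds.
    """
    mosaic = interpolate_field(dem, sites, config, windowed, regions)
    mask = dem.nodata_mask | np.isnan(mosaic)
    values = np.where(mask, 0.0, mosaic)
    return Surface(values.astype(np.float32), dem.transform, dem.crs_id, mask)
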
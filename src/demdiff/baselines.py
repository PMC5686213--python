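"""Comparator interpolators: inverse-distance weighting and ordinary kriging.

IDW predicts Ẑ(S₀) = Σ λ_i Z(S_i) with convex weights λ_i ∝ d_i0^(−p); the
power p is chosen by minimum cross-validated RMSE over a candidate grid.
Ordinary kriging is the BLUP under a sum-to-one weight constraint, with the
covariance structure taken from a semivariogram model (spherical,
exponential or gaussian, practical-range parameterisation) fitted by
weighted least squares to the binned empirical semivariogram.  Kriging
inputs pass through the customary preprocessing contract: skewness-triggered
log1p transform, IQR outlier removal, and first-order trend removal, each
recorded and inverted after prediction.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import List, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit
from scipy.spatial.distance import cdist
from scipy.stats import skew

from .geodata import GeodataError, SiteTable

logger = logging.getLogger("demdiff")


# ---------------------------------------------------------------------------
# inverse distance weighting
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class IdwParams:
    """Power exponent and neighbour count (None = all sites)."""

    p: float = 2.0
    n_neighbors: int | None = None

    def __post_init__(self) -> None:
        if self.p <= 0:
            raise GeodataError("IDW power must be positive")
        if self.n_neighbors is not None and self.n_neighbors < 1:
            raise GeodataError("IDW neighbour count must be >= 1")


def idw_predict(sites: SiteTable, query_xy: np.ndarray,
                params: IdwParams = IdwParams()) -> np.ndarray:
    """IDW estimates at query points; a query coincident with a site
    returns that site's value exactly."""
    query_xy = np.atleast_2d(np.asarray(query_xy, dtype=float))
    dist = cdist(query_xy, sites.coords())
    values = sites.values
    if params.n_neighbors is not None and params.n_neighbors < len(sites):
        k = params.n_neighbors
        cut = np.partition(dist, k - 1, axis=1)[:, k - 1:k]
        far = dist > cut
    else:
        far = np.zeros_like(dist, dtype=bool)
    out = np.empty(len(query_xy))
    hit_rows, hit_cols = np.nonzero(dist == 0.0)
    with np.errstate(divide="ignore"):
        wts = dist ** (-params.p)
    wts[far] = 0.0
    wts[~np.isfinite(wts)] = 0.0
    coincident = np.zeros(len(query_xy), dtype=bool)
    coincident[hit_rows] = True
    denom = wts.sum(axis=1)
    safe = ~coincident
    out[safe] = (wts[safe] @ values) / denom[safe]
    for r, c in zip(hit_rows, hit_cols):
        out[r] = values[c]
    return out


def optimize_p(sites: SiteTable, candidates: Sequence[float],
               folds: int = 5, rng_seed: int = 0) -> IdwParams:
    """RMSE-optimal IDW power by k-fold cross-validation over a candidate
    grid; ties broken toward the smallest power."""
    if len(candidates) < 1:
        raise GeodataError("optimize_p needs at least one candidate power")
    cands = sorted(set(float(p) for p in candidates))
    if len(cands) == 1:
        return IdwParams(p=cands[0])
    from .evaluation import make_folds  # local import: avoids module cycle

    assignment = make_folds(sites, folds, rng_seed)
    fold_of = np.array([assignment.fold_of[i] for i in sites.ids])
    best_p, best_rmse = None, np.inf
    for p in cands:
        sq_sum, count = 0.0, 0
        for f in range(folds):
            val = fold_of == f
            train = sites.select_mask(~val)
            pred = idw_predict(train, sites.coords()[val], IdwParams(p=p))
            sq_sum += float(((pred - sites.values[val]) ** 2).sum())
            count += int(val.sum())
        rmse = np.sqrt(sq_sum / count)
        if rmse < best_rmse - 1e-12:
            best_p, best_rmse = p, rmse
    return IdwParams(p=best_p)


# ---------------------------------------------------------------------------
# variogram
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class VariogramModel:
    """Fitted semivariogram; ``sill`` is the total sill (nugget + partial),
    ``range_`` the practical range."""

    model: str
    nugget: float
    sill: float
    range_: float
    converged: bool = True

    def __post_init__(self) -> None:
        if self.model not in ("spherical", "exponential", "gaussian"):
            raise GeodataError(f"unknown variogram model: {self.model}")
        if self.nugget < 0 or self.sill < self.nugget or self.range_ <= 0:
            raise GeodataError("variogram parameters violate invariants")

    def gamma(self, h: np.ndarray) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        psill = self.sill - self.nugget
        r = self.range_
        if self.model == "spherical":
            inside = np.clip(h / r, 0.0, 1.0)
            struct = 1.5 * inside - 0.5 * inside ** 3
        elif self.model == "exponential":
            struct = 1.0 - np.exp(-3.0 * h / r)
        else:  # gaussian
            struct = 1.0 - np.exp(-3.0 * (h / r) ** 2)
        out = self.nugget + psill * struct
        return np.where(h == 0.0, 0.0, out)  # γ(0) = 0 by definition


def empirical_semivariogram(sites: SiteTable, n_bins: int = 15
                            ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Binned pairwise half-squared differences: (lag centers, γ̂, counts)."""
    xy = sites.coords()
    values = sites.values
    dist = cdist(xy, xy)
    iu = np.triu_indices(len(sites), k=1)
    d = dist[iu]
    g = 0.5 * (values[iu[0]] - values[iu[1]]) ** 2
    max_lag = d.max() / 2.0
    if max_lag <= 0:
        raise GeodataError("all site locations coincide")
    edges = np.linspace(0.0, max_lag, n_bins + 1)
    which = np.digitize(d, edges) - 1
    # pairs exactly at the maximum lag belong to the last bin
    which[(d <= max_lag) & (which == n_bins)] = n_bins - 1
    centers, gammas, counts = [], [], []
    for b in range(n_bins):
        sel = which == b
        if sel.sum() > 0:
            centers.append(0.5 * (edges[b] + edges[b + 1]))
            gammas.append(g[sel].mean())
            counts.append(int(sel.sum()))
    return np.array(centers), np.array(gammas), np.array(counts)


def fit_variogram(sites: SiteTable, model: str = "spherical",
                  n_bins: int = 15) -> VariogramModel:
    """Weighted least-squares fit of a semivariogram model to the empirical
    semivariogram (weights = pair counts).  A non-convergent fit falls back
    to exponential defaults from the data variance and extent."""
    if len(sites) < 5:
        raise GeodataError("fit_variogram requires >= 5 sites")
    lags, gammas, counts = empirical_semivariogram(sites, n_bins)
    var = float(np.var(sites.values))
    extent = float(cdist(sites.coords(), sites.coords()).max())
    if len(lags) < 3 or var == 0.0:
        # no structure to fit; flat (pure nugget-free, tiny-sill) model
        return VariogramModel(model, 0.0, max(var, 0.0) + 1e-12,
                              max(extent, 1.0) / 3.0, converged=False)

    def curve(h, nugget, psill, rng):
        return VariogramModel(model, nugget, nugget + psill, rng).gamma(h)

    p0 = (0.0, max(var, 1e-12), max(extent, 1.0) / 3.0)
    bounds = ([0.0, 0.0, 1e-9 * max(extent, 1.0)],
              [np.inf, np.inf, 10.0 * max(extent, 1.0)])
    try:
        popt, _ = curve_fit(curve, lags, gammas, p0=p0, bounds=bounds,
                            sigma=1.0 / np.sqrt(counts), maxfev=20000)
        nugget, psill, rng = (float(v) for v in popt)
        return VariogramModel(model, nugget, nugget + psill, rng)
    except (RuntimeError, ValueError):
        logger.warning("fit_variogram: %s fit failed, falling back to "
                       "exponential defaults", model)
        return VariogramModel("exponential", 0.0, var,
                              max(extent, 1.0) / 3.0, converged=False)


# ---------------------------------------------------------------------------
# ordinary kriging
# ---------------------------------------------------------------------------

def kriging_weights(sites: SiteTable, variogram: VariogramModel,
                    query_xy: np.ndarray) -> np.ndarray:
    """Ordinary-kriging weights per query (rows), sum-to-one enforced by
    the Lagrange multiplier of the constrained system."""
    xy = sites.coords()
    n = len(sites)
    dist = cdist(xy, xy)
    off_diag = dist[np.triu_indices(n, k=1)]
    if np.any(off_diag == 0.0):
        ii, jj = np.nonzero((dist == 0.0) & ~np.eye(n, dtype=bool))
        pairs = sorted({tuple(sorted((sites.ids[i], sites.ids[j])))
                        for i, j in zip(ii, jj)})
        raise GeodataError(f"duplicated site locations: {pairs}")
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = variogram.gamma(dist)
    A[n, :] = 1.0
    A[:, n] = 1.0
    A[n, n] = 0.0
    query_xy = np.atleast_2d(np.asarray(query_xy, dtype=float))
    B = np.empty((n + 1, len(query_xy)))
    B[:n, :] = variogram.gamma(cdist(xy, query_xy))
    B[n, :] = 1.0
    try:
        sol = np.linalg.solve(A, B)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise GeodataError(f"singular kriging system: {exc}") from exc
    return sol[:n, :].T


def kriging_predict(sites: SiteTable, variogram: VariogramModel,
                    query_xy: np.ndarray) -> np.ndarray:
    """Ordinary-kriging estimates at query points; exact at the sites
    when the nugget is zero."""
    return kriging_weights(sites, variogram, query_xy) @ sites.values


# ---------------------------------------------------------------------------
# kriging preprocessing contract
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class KrigingTransformRecord:
    """What was done to the data before kriging (to be inverted after)."""

    log_applied: bool
    outlier_ids: List[str]
    trend_coefs: Tuple[float, float, float]  # value ≈ b0 + bx·x + by·y

    def trend_at(self, query_xy: np.ndarray) -> np.ndarray:
        query_xy = np.atleast_2d(np.asarray(query_xy, dtype=float))
        b0, bx, by = self.trend_coefs
        return b0 + bx * query_xy[:, 0] + by * query_xy[:, 1]

    def invert(self, predictions: np.ndarray,
               query_xy: np.ndarray) -> np.ndarray:
        out = np.asarray(predictions, dtype=float) + self.trend_at(query_xy)
        if self.log_applied:
            out = np.expm1(out)
        return out


def preprocess_for_kriging(sites: SiteTable,
                           skew_threshold: float = 1.0,
                           iqr_factor: float = 3.0
                           ) -> Tuple[SiteTable, KrigingTransformRecord]:
    """Normality / outlier / trend contract before ordinary kriging.

    (i) values with |skewness| above the threshold get a log1p transform;
    (ii) values beyond ``iqr_factor`` interquartile ranges from the median
    are removed (count logged); (iii) a first-order polynomial trend is
    fitted and removed.  The returned record inverts all three after
    prediction.
    """
    if len(sites) < 5:
        raise GeodataError("preprocess_for_kriging requires >= 5 sites")
    values = sites.values.astype(float)
    log_applied = bool(abs(skew(values)) > skew_threshold) \
        if len(np.unique(values)) > 1 else False
    if log_applied:
        values = np.log1p(values)

    med = float(np.median(values))
    q1, q3 = np.percentile(values, [25, 75])
    iqr = float(q3 - q1)
    if iqr > 0:
        keep = np.abs(values - med) <= iqr_factor * iqr
    else:
        keep = np.ones(len(values), dtype=bool)
    outlier_ids = list(sites.ids[~keep])
    if len(outlier_ids):
        logger.info("preprocess_for_kriging: removed %d outliers: %s",
                    len(outlier_ids), outlier_ids)
    if not keep.any():
        raise GeodataError("all sites removed as outliers")
    kept = sites.select_mask(keep)
    values = values[keep]

    design = np.column_stack([np.ones(len(kept)), kept.x, kept.y])
    coefs, *_ = np.linalg.lstsq(design, values, rcond=None)
    residuals = values - design @ coefs
    record = KrigingTransformRecord(log_applied, outlier_ids,
                                    tuple(float(c) for c in coefs))
    return kept.with_values(residuals, nonnegative=False), record


def ok_predict(sites: SiteTable, query_xy: np.ndarray,
               model: str = "spherical") -> np.ndarray:
    """Full ordinary-kriging pipeline: preprocess → fit variogram on the
    residuals → krige → invert the preprocessing."""
    prepped, record = preprocess_for_kriging(sites)
    variogram = fit_variogram(prepped, model)
    raw = kriging_predict(prepped, variogram, query_xy)
    return record.invert(raw, query_xy)
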
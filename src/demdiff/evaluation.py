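"""Accuracy-assessment protocol: repeated k-fold CV and error metrics.

Sites are split into F equal-sized random folds; each fold in turn is the
validation set and the remainder the training set.  Every method under
comparison is fitted on the same training sets (shared fold assignment) and
scored at the held-out station coordinates with

    AE   = |O − S|            (absolute error, per site)
    MAE  = mean AE            (per fold)
    RMSE = sqrt(mean (O−S)²)  (per fold)
    RAE  = max AE − min AE    (per fold)

plus pooled observed-vs-estimated R² across folds (squared Pearson
correlation as the primary definition; 1 − SSE/SST also reported) and a
grade-distribution table over the standard PM2.5 concentration bins.
Validation points that fall on a method's nodata cells are excluded
pairwise for that method, with the exclusion count reported.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Dict, List, Sequence

import numpy as np

from .geodata import DemRaster, GeodataError, RunConfig, SiteTable
from .segmentation import RegionMap
from . import baselines, infodiffusion

logger = logging.getLogger("demdiff")

#: PM2.5 concentration grade edges (µg/m³), half-open [lo, hi) bins
DEFAULT_GRADE_EDGES = (0.0, 35.0, 75.0, 115.0, 150.0, 250.0, 350.0)

METHODS = ("infodiff", "infodiff-global", "idw", "ok")


@dataclasses.dataclass
class FoldAssignment:
    fold_of: Dict[str, int]
    folds: int
    rng_seed: int


@dataclasses.dataclass
class FoldMetrics:
    ae: List[float]
    mae: float
    rmse: float
    rae: float
    n_excluded: int = 0


@dataclasses.dataclass
class EvalReport:
    """Per-fold and aggregate accuracy of one method."""

    method: str
    fold_metrics: List[FoldMetrics]
    mae_mean: float
    mae_var: float
    rmse_mean: float
    rmse_var: float
    rae_mean: float
    rae_var: float
    r2_pearson: float
    r2_cod: float
    grade_observed: Dict[str, float]
    grade_estimated: Dict[str, float]
    n_excluded_total: int
    fold_assignment: Dict[str, int]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fold_metrics"] = [dataclasses.asdict(m) for m in self.fold_metrics]
        return d


def make_folds(sites: SiteTable, folds: int, rng_seed: int) -> FoldAssignment:
    """Uniform random partition into folds whose sizes differ by at most
    one; reproducible under the seed."""
    if folds < 2:
        raise GeodataError("folds must be >= 2")
    if len(sites) < folds:
        raise GeodataError("need at least as many sites as folds")
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(len(sites))
    fold_of = {}
    for pos, site_idx in enumerate(order):
        fold_of[str(sites.ids[site_idx])] = pos % folds
    return FoldAssignment(fold_of, folds, rng_seed)


def metrics(observed: Sequence[float], estimated: Sequence[float]
            ) -> FoldMetrics:
    observed = np.asarray(observed, dtype=float)
    estimated = np.asarray(estimated, dtype=float)
    if observed.shape != estimated.shape or observed.ndim != 1:
        raise GeodataError("observed and estimated must be equal-length 1-D")
    if len(observed) < 1:
        raise GeodataError("metrics require at least one pair")
    ae = np.abs(observed - estimated)
    rmse = float(np.sqrt(np.mean((observed - estimated) ** 2)))
    return FoldMetrics(ae=list(map(float, ae)), mae=float(ae.mean()),
                       rmse=rmse, rae=float(ae.max() - ae.min()))


def grade_distribution(values: Sequence[float],
                       edges: Sequence[float] = DEFAULT_GRADE_EDGES
                       ) -> Dict[str, float]:
    """Percentage of values per concentration grade (half-open bins);
    values at or above the top edge land in a flagged overflow bin."""
    values = np.asarray(values, dtype=float)
    if len(values) < 1:
        raise GeodataError("grade_distribution requires at least one value")
    edges = np.asarray(edges, dtype=float)
    out: Dict[str, float] = {}
    for lo, hi in zip(edges[:-1], edges[1:]):
        pct = 100.0 * np.mean((values >= lo) & (values < hi))
        out[f"{lo:g}-{hi:g}"] = float(pct)
    overflow = float(100.0 * np.mean(values >= edges[-1]))
    out[f">={edges[-1]:g}"] = overflow
    if overflow > 0:
        logger.warning("grade_distribution: %.2f%% of values above the top "
                       "edge %g", overflow, edges[-1])
    return out


# ---------------------------------------------------------------------------
# method dispatch
# ---------------------------------------------------------------------------

def _predict(method: str, dem: DemRaster, train: SiteTable,
             query_xy: np.ndarray, config: RunConfig,
             regions: RegionMap | None) -> np.ndarray:
    if method == "infodiff":
        surface = infodiffusion.interpolate(dem, train, config,
                                            windowed=True, regions=regions)
        return surface.sample(query_xy[:, 0], query_xy[:, 1])
    if method == "infodiff-global":
        surface = infodiffusion.interpolate(dem, train, config,
                                            windowed=False)
        return surface.sample(query_xy[:, 0], query_xy[:, 1])
    if method == "idw":
        params = baselines.optimize_p(train, config.idw_power_grid,
                                      folds=min(5, len(train)),
                                      rng_seed=config.rng_seed)
        return baselines.idw_predict(train, query_xy, params)
    if method == "ok":
        return baselines.ok_predict(train, query_xy, config.variogram_model)
    raise GeodataError(f"unknown method: {method!r}")


def _r2_pair(observed: np.ndarray, estimated: np.ndarray):
    if len(observed) < 2 or np.std(observed) == 0 or np.std(estimated) == 0:
        return 0.0, 0.0
    r = float(np.corrcoef(observed, estimated)[0, 1])
    sse = float(np.sum((observed - estimated) ** 2))
    sst = float(np.sum((observed - observed.mean()) ** 2))
    return r * r, 1.0 - sse / sst


def run_comparison(dem: DemRaster, sites: SiteTable, config: RunConfig,
                   methods: Sequence[str] = ("infodiff", "idw", "ok"),
                   regions: RegionMap | None = None
                   ) -> Dict[str, EvalReport]:
    """Shared-fold cross-validated comparison of interpolation methods.

    One fold assignment is drawn and reused by every method; per fold each
    method is fitted on the training sites and scored at the held-out
    station coordinates.  Per-method failures abort the run with the
    offending method named.
    """
    if len(methods) < 1:
        raise GeodataError("run_comparison needs at least one method")
    assignment = make_folds(sites, config.folds, config.rng_seed)
    fold_of = np.array([assignment.fold_of[i] for i in sites.ids])
    if regions is None and "infodiff" in methods:
        regions = infodiffusion.segment_dem(dem, config.segmentation_scale)

    reports: Dict[str, EvalReport] = {}
    for method in methods:
        per_fold: List[FoldMetrics] = []
        pooled_obs: List[float] = []
        pooled_est: List[float] = []
        try:
            for f in range(config.folds):
                val = fold_of == f
                train = sites.select_mask(~val)
                query_xy = sites.coords()[val]
                observed = sites.values[val]
                pred = np.asarray(
                    _predict(method, dem, train, query_xy, config, regions),
                    dtype=float)
                ok = np.isfinite(pred)
                excluded = int((~ok).sum())
                if excluded:
                    logger.info("%s fold %d: excluded %d nodata validation "
                                "points", method, f, excluded)
                if ok.sum() == 0:
                    raise GeodataError(
                        f"method {method} produced no valid estimates "
                        f"in fold {f}")
                m = metrics(observed[ok], pred[ok])
                m.n_excluded = excluded
                per_fold.append(m)
                pooled_obs.extend(observed[ok])
                pooled_est.extend(pred[ok])
        except GeodataError as exc:
            raise GeodataError(f"method {method!r} failed: {exc}") from exc

        pooled_obs_a = np.asarray(pooled_obs)
        pooled_est_a = np.asarray(pooled_est)
        r2p, r2c = _r2_pair(pooled_obs_a, pooled_est_a)
        maes = np.array([m.mae for m in per_fold])
        rmses = np.array([m.rmse for m in per_fold])
        raes = np.array([m.rae for m in per_fold])
        reports[method] = EvalReport(
            method=method,
            fold_metrics=per_fold,
            mae_mean=float(maes.mean()), mae_var=float(maes.var()),
            rmse_mean=float(rmses.mean()), rmse_var=float(rmses.var()),
            rae_mean=float(raes.mean()), rae_var=float(raes.var()),
            r2_pearson=r2p, r2_cod=r2c,
            grade_observed=grade_distribution(pooled_obs_a),
            grade_estimated=grade_distribution(pooled_est_a),
            n_excluded_total=int(sum(m.n_excluded for m in per_fold)),
            fold_assignment=dict(assignment.fold_of),
        )
    return reports


def cv_correlation_harness(config: RunConfig):
    """Harness for ``sweep_scales``: pooled CV Pearson² of the windowed
    estimator under a given precomputed partition."""
    def harness(dem: DemRaster, sites: SiteTable, regions: RegionMap
                ) -> float:
        reports = run_comparison(dem, sites, config, methods=("infodiff",),
                                 regions=regions)
        return reports["infodiff"].r2_pearson
    return harness
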
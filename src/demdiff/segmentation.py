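"""Homogeneous-elevation segmentation of the DEM and buffered station windows.

The DEM is partitioned by greedy bottom-up region merging on 4-connected
adjacency: starting from single pixels, the adjacent pair with the lowest
merge cost is merged until the cheapest remaining merge exceeds ``scale²``.
The cost is the single-band Baatz–Schäpe spectral heterogeneity increase

    cost(A, B) = (n_A + n_B)·σ_AB − (n_A·σ_A + n_B·σ_B)

with σ the (population) standard deviation of elevation inside a region and
n its area in cells — i.e. shape weight 0, elevation as the only band.

Two exact shortcuts keep this fast: (i) adjacent cells of identical
elevation are merged up front (their merge cost is exactly zero, the global
minimum, and zero-cost merges are order-independent, so greedy merging
would perform them first anyway); (ii) the greedy merge sequence does not
depend on the scale threshold — the threshold only truncates it — so a
single fully-merged dendrogram can be cut at many scales.  Consequently a
larger scale never yields more regions than a smaller one and partitions
are nested across scales.

Each resulting region becomes an interpolation window: the stations inside
it plus every station within a buffer distance of its cell set.  Region
boundaries act as hard break lines during interpolation; the buffer only
widens the *sample* pool of a window, never the cells it writes.
"""

from __future__ import annotations

import dataclasses
import heapq
import logging
import math
from typing import Callable, Dict, List, Sequence, Tuple

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .geodata import DemRaster, GeodataError, GridTransform, SiteTable

logger = logging.getLogger("demdiff")


@dataclasses.dataclass(frozen=True)
class RegionStats:
    area_cells: int
    mean_elevation: float
    min_elevation: float
    max_elevation: float


@dataclasses.dataclass
class RegionMap:
    """Integer-labelled partition of the DEM (labels 1..K, 0 = nodata)."""

    labels: np.ndarray
    region_stats: Dict[int, RegionStats]
    transform: GridTransform
    crs_id: int

    @property
    def n_regions(self) -> int:
        return len(self.region_stats)


@dataclasses.dataclass
class RegionWindow:
    """A region plus the buffered station set that informs its estimate."""

    label: int
    core_sites: List[str]
    buffered_sites: List[str]
    buffer_km_used: float


@dataclasses.dataclass
class MergeDendrogram:
    """Initial equal-elevation components and the ordered greedy merges."""

    comp_grid: np.ndarray        # int grid, -1 at nodata
    n_components: int
    area: np.ndarray             # per-component stats at the leaves
    total: np.ndarray
    total_sq: np.ndarray
    vmin: np.ndarray
    vmax: np.ndarray
    merges: List[Tuple[float, int, int]]  # (cost, keep, absorb), in order
    transform: GridTransform
    crs_id: int


def _sigma(n, s, ss):
    return np.sqrt(np.maximum(0.0, ss / n - (s / n) ** 2))


def _initial_components(dem: DemRaster):
    """Merge adjacent equal-elevation cells (exact zero-cost merges);
    components are numbered in raster order of first occurrence."""
    mask = dem.nodata_mask
    nrows, ncols = dem.shape
    values = dem.values.astype(np.float64)
    idx = -np.ones((nrows, ncols), dtype=np.int64)
    flat = np.flatnonzero(~mask.ravel())
    idx.ravel()[flat] = np.arange(flat.size)
    n_pix = flat.size

    pairs = []
    right = (~mask[:, :-1]) & (~mask[:, 1:])
    pairs.append((idx[:, :-1][right], idx[:, 1:][right],
                  values[:, :-1][right] == values[:, 1:][right]))
    down = (~mask[:-1, :]) & (~mask[1:, :])
    pairs.append((idx[:-1, :][down], idx[1:, :][down],
                  values[:-1, :][down] == values[1:, :][down]))
    a_all = np.concatenate([p[0] for p in pairs])
    b_all = np.concatenate([p[1] for p in pairs])
    equal = np.concatenate([p[2] for p in pairs])

    graph = coo_matrix((np.ones(equal.sum()), (a_all[equal], b_all[equal])),
                       shape=(n_pix, n_pix))
    _, comp_of_pix = connected_components(graph, directed=False)
    # renumber components in raster order of first occurrence
    _, first_pos = np.unique(comp_of_pix, return_index=True)
    order = np.argsort(first_pos)
    renum = np.empty_like(order)
    renum[order] = np.arange(len(order))
    comp_of_pix = renum[comp_of_pix]
    n_comp = len(order)

    comp_grid = -np.ones((nrows, ncols), dtype=np.int64)
    comp_grid.ravel()[flat] = comp_of_pix

    pix_values = values.ravel()[flat]
    area = np.bincount(comp_of_pix, minlength=n_comp).astype(np.float64)
    total = np.bincount(comp_of_pix, weights=pix_values, minlength=n_comp)
    total_sq = np.bincount(comp_of_pix, weights=pix_values ** 2,
                           minlength=n_comp)
    vmin = np.full(n_comp, np.inf)
    np.minimum.at(vmin, comp_of_pix, pix_values)
    vmax = np.full(n_comp, -np.inf)
    np.maximum.at(vmax, comp_of_pix, pix_values)

    ca, cb = comp_of_pix[a_all[~equal]], comp_of_pix[b_all[~equal]]
    lo, hi = np.minimum(ca, cb), np.maximum(ca, cb)
    edges = np.unique(np.stack([lo, hi], axis=1), axis=0)
    return comp_grid, n_comp, area, total, total_sq, vmin, vmax, edges


def build_dendrogram(dem: DemRaster,
                     stop_cost: float = math.inf) -> MergeDendrogram:
    """Run the greedy merge sequence, recording each merge and its cost.

    ``stop_cost`` truncates the run early (used by ``segment_dem``);
    ``math.inf`` merges down to one region per connected part of the DEM.
    Cost ties break on the lowest (label, label) pair; the merged region
    keeps the smaller label.  Deterministic for identical inputs.
    """
    if dem.nodata_mask.all():
        raise GeodataError("cannot segment an all-masked DEM")
    (comp_grid, n_comp, area0, total0, total_sq0,
     vmin0, vmax0, edges) = _initial_components(dem)
    area, total, total_sq = area0.copy(), total0.copy(), total_sq0.copy()
    vmin, vmax = vmin0.copy(), vmax0.copy()
    parent = np.arange(n_comp, dtype=np.int64)
    version = np.zeros(n_comp, dtype=np.int64)
    neighbors: List[set] = [set() for _ in range(n_comp)]
    for a, b in edges:
        neighbors[a].add(int(b))
        neighbors[b].add(int(a))

    def find(a: int) -> int:
        root = a
        while parent[root] != root:
            root = parent[root]
        while parent[a] != root:
            parent[a], a = root, parent[a]
        return root

    def merge_cost(a: int, b: int) -> float:
        na, nb = area[a], area[b]
        sa = math.sqrt(max(0.0, total_sq[a] / na - (total[a] / na) ** 2))
        sb = math.sqrt(max(0.0, total_sq[b] / nb - (total[b] / nb) ** 2))
        nab = na + nb
        sab = math.sqrt(max(0.0, (total_sq[a] + total_sq[b]) / nab
                            - ((total[a] + total[b]) / nab) ** 2))
        return nab * sab - (na * sa + nb * sb)

    heap: list = []
    for a, b in edges:
        heapq.heappush(heap, (merge_cost(int(a), int(b)),
                              int(a), int(b), 0, 0))

    merges: List[Tuple[float, int, int]] = []
    while heap:
        cost, a, b, va, vb = heapq.heappop(heap)
        if parent[a] != a or parent[b] != b:
            continue
        if version[a] != va or version[b] != vb:
            continue
        if cost > stop_cost:
            break
        parent[b] = a
        merges.append((cost, a, b))
        area[a] += area[b]
        total[a] += total[b]
        total_sq[a] += total_sq[b]
        vmin[a] = min(vmin[a], vmin[b])
        vmax[a] = max(vmax[a], vmax[b])
        version[a] += 1
        merged_nb = set()
        for nb_ in neighbors[a] | neighbors[b]:
            root = find(int(nb_))
            if root != a:
                merged_nb.add(root)
        neighbors[a] = merged_nb
        neighbors[b] = set()
        for nb_ in merged_nb:
            neighbors[nb_].discard(b)
            neighbors[nb_].add(a)
            lo, hi = (a, nb_) if a < nb_ else (nb_, a)
            heapq.heappush(heap, (merge_cost(lo, hi), lo, hi,
                                  int(version[lo]), int(version[hi])))
    return MergeDendrogram(
        comp_grid=comp_grid, n_components=n_comp,
        area=area0, total=total0, total_sq=total_sq0,
        vmin=vmin0, vmax=vmax0,
        merges=merges, transform=dem.transform, crs_id=dem.crs_id)


def cut_dendrogram(dendro: MergeDendrogram, scale: float) -> RegionMap:
    """Apply the recorded merges up to the first whose cost exceeds
    ``scale²`` and relabel the surviving regions 1..K in raster order."""
    if scale <= 0:
        raise GeodataError("segmentation scale must be positive")
    threshold = float(scale) ** 2
    n = dendro.n_components
    parent = np.arange(n, dtype=np.int64)
    area = dendro.area.copy()
    total = dendro.total.copy()
    total_sq = dendro.total_sq.copy()
    vmin = dendro.vmin.copy()
    vmax = dendro.vmax.copy()
    for cost, keep, absorb in dendro.merges:
        if cost > threshold:
            break
        parent[absorb] = keep
        area[keep] += area[absorb]
        total[keep] += total[absorb]
        total_sq[keep] += total_sq[absorb]
        vmin[keep] = min(vmin[keep], vmin[absorb])
        vmax[keep] = max(vmax[keep], vmax[absorb])

    root = np.arange(n, dtype=np.int64)
    changed = True
    while changed:
        nxt = parent[root]
        changed = bool(np.any(nxt != root))
        root = nxt

    labels = np.zeros(dendro.comp_grid.shape, dtype=np.int32)
    inside = dendro.comp_grid >= 0
    root_grid = root[dendro.comp_grid[inside]]
    uniq_roots, inverse = np.unique(root_grid, return_inverse=True)
    first_pos = np.full(len(uniq_roots), np.iinfo(np.int64).max)
    np.minimum.at(first_pos, inverse, np.arange(len(root_grid)))
    order = np.argsort(first_pos)
    relabel = np.empty(len(uniq_roots), dtype=np.int64)
    relabel[order] = np.arange(1, len(uniq_roots) + 1)
    labels[inside] = relabel[inverse]

    stats: Dict[int, RegionStats] = {}
    for pos, r in enumerate(uniq_roots):
        lab = int(relabel[pos])
        stats[lab] = RegionStats(
            area_cells=int(area[r]),
            mean_elevation=float(total[r] / area[r]),
            min_elevation=float(vmin[r]),
            max_elevation=float(vmax[r]),
        )
    return RegionMap(labels, dict(sorted(stats.items())),
                     dendro.transform, dendro.crs_id)


def segment_dem(dem: DemRaster, scale: float) -> RegionMap:
    """Partition the DEM into homogeneous-elevation regions at one scale."""
    if scale <= 0:
        raise GeodataError("segmentation scale must be positive")
    dendro = build_dendrogram(dem, stop_cost=float(scale) ** 2)
    regions = cut_dendrogram(dendro, scale)
    logger.info("segment_dem: scale=%g -> %d regions", scale,
                regions.n_regions)
    return regions


def build_windows(regions: RegionMap, sites: SiteTable, buffer_km: float,
                  min_sites: int = 3, growth_km: float = 50.0
                  ) -> List[RegionWindow]:
    """Attach station sets to regions.

    A station belongs to a region's buffered set iff it lies inside the
    region or within ``buffer_km`` of any of its cell centers.  Windows with
    fewer than ``min_sites`` buffered stations grow their buffer in
    ``growth_km`` increments until enough stations are captured (or the
    global set is reached).
    """
    labels = regions.labels
    nrows, ncols = labels.shape
    coords = sites.coords()
    ids = sites.ids
    row, col = regions.transform.rowcol(sites.x, sites.y)
    inside = (row >= 0) & (row < nrows) & (col >= 0) & (col < ncols)
    site_label = np.zeros(len(sites), dtype=np.int64)
    site_label[inside] = labels[row[inside], col[inside]]

    windows: List[RegionWindow] = []
    for lab in sorted(regions.region_stats):
        rr, cc = np.nonzero(labels == lab)
        cx, cy = regions.transform.cell_center(rr, cc)
        tree = cKDTree(np.column_stack([cx, cy]))
        dist, _ = tree.query(coords, k=1)
        core = list(ids[site_label == lab])
        buf = float(buffer_km)
        while True:
            sel = (site_label == lab) | (dist <= buf * 1000.0)
            if sel.sum() >= min_sites or sel.all():
                break
            buf += growth_km
        if sel.sum() < min_sites:
            sel = np.ones(len(sites), dtype=bool)  # global fallback
            logger.warning("build_windows: region %d fell back to the "
                           "global station set", lab)
        windows.append(RegionWindow(lab, core, list(ids[sel]), buf))
    return windows


def sweep_scales(dem: DemRaster, sites: SiteTable, scales: Sequence[float],
                 harness: Callable[[DemRaster, SiteTable, RegionMap], float]
                 ) -> List[dict]:
    """Evaluate a list of segmentation scales.

    ``harness(dem, sites, regions)`` returns the cross-validated correlation
    (or any scalar score) of the windowed estimator under that partition.
    The merge dendrogram is built once and cut per scale.  Returns one row
    per scale: ``{"scale", "n_regions", "correlation"}``.
    """
    if len(scales) < 1:
        raise GeodataError("sweep_scales requires at least one scale")
    dendro = build_dendrogram(dem)
    rows = []
    for scale in scales:
        regions = cut_dendrogram(dendro, scale)
        score = float(harness(dem, sites, regions))
        rows.append({"scale": float(scale),
                     "n_regions": regions.n_regions,
                     "correlation": score})
    return rows


def regions_to_geojson(regions: RegionMap) -> dict:
    """Region polygons (unions of cell boxes) as a GeoJSON FeatureCollection."""
    from shapely import to_geojson
    from shapely.geometry import box
    from shapely.ops import unary_union
    import json

    t = regions.transform
    features = []
    for lab, st in sorted(regions.region_stats.items()):
        rr, cc = np.nonzero(regions.labels == lab)
        boxes = [box(t.x0 + c * t.dx, t.y0 - (r + 1) * t.dy,
                     t.x0 + (c + 1) * t.dx, t.y0 - r * t.dy)
                 for r, c in zip(rr, cc)]
        geom = unary_union(boxes)
        features.append({
            "type": "Feature",
            "geometry": json.loads(to_geojson(geom)),
            "properties": {"label": int(lab),
                           "area_cells": st.area_cells,
                           "mean_elevation": st.mean_elevation},
        })
    return {"type": "FeatureCollection", "features": features}
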
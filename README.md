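# demdiff

Terrain-aware interpolation of ground PM2.5 concentration surfaces from
sparse monitoring stations.

National-scale station networks are sparse and strongly clustered in urban
lowlands, so classical spatial interpolators (inverse distance weighting,
ordinary kriging) produce unreliable, concentric artifacts in data-poor
terrain.  `demdiff` implements a DEM-assisted *information diffusion*
estimator: a digital elevation model is segmented into regions of
homogeneous elevation, each region (plus a buffered neighbourhood of
stations) becomes an independent small-sample estimation window, and a
fuzzy-set diffusion interpolator is run inside each window, with region
edges acting as hard break lines.  The package also provides the IDW and
ordinary-kriging comparators and a shared-fold cross-validation harness to
judge all three, plus a seeded synthetic DEM/station generator so that
every stage is testable without real data downloads.

It is aimed at exposure-assessment and environmental-health researchers
who need gridded concentration fields from station tables, and at anyone
who wants a reproducible, open implementation of diffusion-based
small-sample spatial estimation.

## The estimator

Within a window holding samples (xₗ, yₗ, zₗ), l = 1..n (z = observed
concentration, µg/m³):

1. **Monitoring space.**  The spatial coordinates and the value axis are
   discretized into an equal-interval grid U×V×W; spatial nodes coincide
   with output-raster cell centers, the value axis spans the sample range
   padded by three bandwidths.

2. **Diffusion.**  Each sample spreads a separable Gaussian kernel over
   the space,

   q_l(u_i, v_j, w_k) = Π_d (h_d √(2π))⁻¹ exp(−(·−·)²/2h_d²),

   with per-dimension bandwidths from the *averaging model*:
   h = c(n)·(b−a), where c(5..10) = 0.8146, 0.5690, 0.4560, 0.3860,
   0.3362, 0.2986 and h = 2.6851(b−a)/(n−1) for n > 10.

3. **Fuzzy relation.**  The accumulated information matrix
   Q_ijk = Σ_l q_l is normalized per value-slice by its spatial maximum
   S_k, giving membership values r_ijk ∈ [0, 1].

4. **Defuzzification.**  The estimate at each spatial node is the
   fuzzy-set centroid along the value axis,
   est(u_i, v_j) = Σ_k w_k r_ijk / Σ_k r_ijk.

Windows come from greedy bottom-up region merging of the DEM
(Baatz–Schäpe spectral heterogeneity cost, shape weight 0, single band =
elevation) thresholded at `scale²`; station pools are widened by a buffer
(default 100 km) around each region.  See `docs/methods.md` for the full
model description, parameter meanings and limitations.

## Worked example

```
$ demdiff simulate --seed 0 --out-dir demo          # synthetic fixture
$ demdiff segment demo/dem.tif --scale 500 --out demo/regions.tif
2 regions -> demo/regions.tif, demo/regions.tif.geojson
$ demdiff evaluate demo/dem.tif demo/sites.csv \
      --methods infodiff,idw,ok --folds 10 --seed 42 --out demo/report.json
```

The fixture is a 256×256 km two-plateau landscape (2-km cells) whose true
concentration field falls 0.05 µg/m³ per meter of elevation from an
80 µg/m³ baseline, with a +20 µg/m³ lowland offset, correlated field noise
and 60 noisy stations clustered at low elevation.  The report compares the
windowed diffusion estimator with IDW (RMSE-optimal power) and ordinary
kriging under one shared 10-fold split; for the run above it contains:

| method   | R²   | MAE (µg/m³) | RMSE (µg/m³) | RAE (µg/m³) |
|----------|------|-------------|--------------|-------------|
| infodiff | 0.64 | 10.47       | 15.28        | 30.39       |
| idw      | 0.74 | 9.34        | 12.85        | 23.06       |
| ok       | 0.41 | 14.69       | 23.15        | 46.10       |

R² is the squared Pearson correlation between observed and estimated
validation values pooled over folds; MAE/RMSE are fold means of the mean
absolute and root-mean-square errors; RAE is the fold-mean range
(max − min) of absolute errors.  `report.json.metrics.csv` and
`report.json.grades.csv` hold the same summary plus the concentration-grade
distribution table (bins 0–35–75–115–150–250–350 µg/m³).  On this
deliberately bimodal fixture the kriging preprocessing prunes the
high-plateau stations as outliers, which is why its scores trail — see
`docs/methods.md` for the analysis.

The library mirrors the CLI: `demdiff.interpolate(dem, sites, config)`
returns a `Surface`, `demdiff.run_comparison(...)` the evaluation
reports, and `demdiff.make_fixture(...)` the synthetic inputs.

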
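"""Monitoring-space construction, diffusion, defuzzification, and the
windowed pipeline's invariance properties."""

import math

import numpy as np
import pytest

from conftest import (make_plateau_dem, make_sites, random_micro_case,
                      triple_loop_pipeline)
from demdiff import (GeodataError, RunConfig, compute_h, compute_steps,
                     accumulate, build_space, defuzzify, diffuse_sample,
                     fuzzify, interpolate, interpolate_field, segment_dem)
from demdiff.infodiffusion import (DegenerateStepError, DiffusionFactors,
                                   MonitoringSpace, compute_factors)


def factors(hx=1.0, hy=1.0, hz=1.0, n=5, rx=(0, 1), ry=(0, 1), rz=(0, 1)):
    return DiffusionFactors(hx, hy, hz, n, rx, ry, rz)


class TestComputeSteps:
    def test_min_pairwise_difference(self):
        samples = np.array([[0.0, 5.0, 10.0],
                            [1.0, 5.0, 10.5],
                            [3.0, 5.0, 12.0]])
        dx, dy, dz = compute_steps(samples)
        assert dx == 1.0
        assert math.isnan(dy)  # all y identical: degenerate
        assert dz == 0.5

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 9))
            samples = rng.choice(np.arange(0, 50, 0.5), size=(n, 3))
            steps = compute_steps(samples)
            for d in range(3):
                col = samples[:, d]
                diffs = [abs(a - b) for i, a in enumerate(col)
                         for b in col[i + 1:] if a != b]
                if diffs:
                    assert steps[d] == min(diffs)
                else:
                    assert math.isnan(steps[d])

    def test_needs_two_samples(self):
        with pytest.raises(GeodataError):
            compute_steps(np.array([[0.0, 0.0, 0.0]]))


class TestComputeH:
    def test_small_sample_uses_n5_coefficient(self):
        assert compute_h(3, 0.0, 2.0) == pytest.approx(2 * 0.8146)

    def test_large_n_formula(self):
        assert compute_h(100, 0.0, 1.0) == pytest.approx(2.6851 / 99)

    def test_zero_range_falls_back_to_half_grid_step(self):
        assert compute_h(7, 5.0, 5.0, grid_step=2.0) == 1.0
        with pytest.raises(DegenerateStepError):
            compute_h(7, 5.0, 5.0)

    def test_invalid_inputs(self):
        with pytest.raises(GeodataError):
            compute_h(0, 0.0, 1.0)
        with pytest.raises(GeodataError):
            compute_h(5, 1.0, 0.0)


class TestBuildSpace:
    def test_w_axis_padding_and_step(self):
        # samples spanning z in [20, 80] with min pairwise gap 0.5, h_z=10:
        # w axis runs from -10 to 110 in steps of 0.5
        z = np.concatenate([[20.0, 20.5], np.linspace(25, 80, 10)])
        samples = np.column_stack([np.linspace(0, 1000, len(z)),
                                   np.linspace(0, 1000, len(z)), z])
        f = factors(hx=100.0, hy=100.0, hz=10.0, n=len(z),
                    rz=(20.0, 80.0))
        space = build_space(samples, (0, 1000, 0, 1000), resolution=100.0,
                            w_bins_max=400, factors=f, anchor=(0.0, 1000.0))
        assert space.w[0] == pytest.approx(-10.0)
        assert space.w[-1] == pytest.approx(110.0)
        assert space.dw == pytest.approx(0.5)

    def test_w_bins_capped(self):
        z = np.linspace(0, 100, 12)
        samples = np.column_stack([z * 10, z * 10, z])
        f = compute_factors(samples, resolution=50.0)
        space = build_space(samples, (0, 1000, 0, 1000), resolution=50.0,
                            w_bins_max=10, factors=f, anchor=(0.0, 1000.0))
        assert len(space.w) <= 10

    def test_uv_on_output_lattice(self):
        samples = np.array([[10.0, 10.0, 1.0], [500.0, 700.0, 2.0],
                            [900.0, 300.0, 3.0]])
        f = compute_factors(samples, resolution=100.0)
        space = build_space(samples, (50.0, 950.0, 50.0, 950.0),
                            resolution=100.0, w_bins_max=20, factors=f,
                            anchor=(0.0, 1000.0))
        # node coordinates are cell centers of the 100-unit output lattice
        assert np.allclose((space.u - 50.0) % 100.0, 0.0)
        assert np.allclose((space.v - 50.0) % 100.0, 0.0)
        assert space.du == 100.0


class TestDiffusion:
    def test_kernel_value_at_sample(self):
        space = MonitoringSpace(u=np.array([0.0, 1.0]),
                                v=np.array([1.0, 0.0]),
                                w=np.array([0.0, 1.0]))
        q = diffuse_sample((0.0, 0.0, 0.0), space, factors())
        assert q[1, 0, 0] == pytest.approx((2 * math.pi) ** -1.5, rel=1e-12)

    def test_kernel_ratio_three_bandwidths_out(self):
        space = MonitoringSpace(u=np.array([0.0, 3.0]),
                                v=np.array([1.0, 0.0]),
                                w=np.array([0.0, 1.0]))
        q = diffuse_sample((0.0, 0.0, 0.0), space, factors())
        assert q[1, 1, 0] / q[1, 0, 0] == pytest.approx(math.exp(-4.5),
                                                        rel=1e-12)

    def test_symmetric_about_on_node_sample(self):
        space = MonitoringSpace(u=np.linspace(-2, 2, 5),
                                v=np.linspace(2, -2, 5),
                                w=np.linspace(-1, 1, 3))
        q = diffuse_sample((0.0, 0.0, 0.0), space, factors())
        assert np.allclose(q, q[::-1, :, :])
        assert np.allclose(q, q[:, ::-1, :])

    def test_accumulate_additivity(self):
        space = MonitoringSpace(u=np.linspace(0, 10, 6),
                                v=np.linspace(10, 0, 6),
                                w=np.linspace(0, 5, 4))
        f = factors(2.0, 2.0, 1.0)
        s1 = np.array([[1.0, 2.0, 3.0]])
        s2 = np.array([[4.0, 5.0, 1.0], [8.0, 3.0, 2.0]])
        both = accumulate(np.vstack([s1, s2]), space, f)
        assert np.allclose(both, accumulate(s1, space, f)
                           + accumulate(s2, space, f), rtol=1e-12)
        assert np.allclose(accumulate(s1, space, f),
                           diffuse_sample(s1[0], space, f), rtol=1e-12)
        two_same = accumulate(np.vstack([s1, s1]), space, f)
        assert np.allclose(two_same, 2 * accumulate(s1, space, f), rtol=1e-12)

    def test_mass_captured_by_padded_axes(self):
        # axes extend >= 3h beyond the data with steps below h: the Riemann
        # sum of each kernel recovers its unit mass up to tail truncation
        rng = np.random.default_rng(5)
        samples = np.column_stack([rng.uniform(40, 60, 7),
                                   rng.uniform(40, 60, 7),
                                   rng.uniform(45, 55, 7)])
        f = factors(10.0, 10.0, 5.0, n=7)
        space = MonitoringSpace(u=np.arange(-20.0, 121.0, 5.0),
                                v=np.arange(120.0, -21.0, -5.0),
                                w=np.arange(0.0, 101.0, 2.5))
        Q = accumulate(samples, space, f)
        mass = Q.sum() * space.du * space.dv * space.dw
        assert 0.9 * 7 <= mass <= 1.0 * 7


class TestFuzzifyDefuzzify:
    def test_slice_max_is_one(self, rng):
        Q = rng.uniform(0, 5, (4, 5, 6))
        R = fuzzify(Q)
        assert np.allclose(R.max(axis=(0, 1)), 1.0)
        assert R.min() >= 0 and R.max() <= 1

    def test_zero_slice_stays_zero(self):
        Q = np.zeros((3, 3, 2))
        Q[:, :, 0] = 1.0
        R = fuzzify(Q)
        assert np.allclose(R[:, :, 0], 1.0)
        assert np.all(R[:, :, 1] == 0.0)

    def test_negative_mass_rejected(self):
        with pytest.raises(GeodataError):
            fuzzify(-np.ones((2, 2, 2)))

    def test_equal_split_centroid(self):
        R = np.zeros((1, 1, 2))
        R[0, 0, :] = 1.0
        assert defuzzify(R, np.array([10.0, 20.0]))[0, 0] == 15.0

    def test_empty_column_is_nan(self):
        R = np.zeros((2, 1, 3))
        R[0, 0, 1] = 0.7
        est = defuzzify(R, np.array([1.0, 2.0, 3.0]))
        assert est[0, 0] == 2.0
        assert np.isnan(est[1, 0])

    def test_matches_weighted_mean_oracle(self, rng):
        R = rng.uniform(0, 1, (4, 3, 7))
        w = np.sort(rng.uniform(0, 100, 7))
        est = defuzzify(R, w)
        for j in range(4):
            for i in range(3):
                expect = sum(w[k] * R[j, i, k] for k in range(7)) \
                    / sum(R[j, i, k] for k in range(7))
                assert est[j, i] == pytest.approx(expect, rel=1e-12)


class TestVectorizedAgainstTripleLoop:
    @pytest.mark.parametrize("case", range(5))
    def test_pipeline_matches_literal_loops(self, case):
        rng = np.random.default_rng(100 + case)
        samples, u, v, w, hx, hy, hz = random_micro_case(rng)
        space = MonitoringSpace(u=u, v=v, w=w)
        f = factors(hx, hy, hz, n=len(samples))
        Q = accumulate(samples, space, f)
        R = fuzzify(Q)
        est = defuzzify(R, w)
        Qo, Ro, eo = triple_loop_pipeline(samples, u, v, w, hx, hy, hz)
        assert np.allclose(Q, Qo, rtol=1e-10, atol=0)
        assert np.allclose(R, Ro, rtol=1e-10, atol=1e-300)
        assert np.allclose(est, eo, rtol=1e-10, equal_nan=True)


class TestWindowedPipeline:
    def test_constant_sites_recover_constant(self, plateau_dem, rng):
        sites = make_sites(rng.uniform(0, 32000, 12),
                           rng.uniform(0, 32000, 12), [55.0] * 12)
        cfg = RunConfig(segmentation_scale=300.0)
        est = interpolate_field(plateau_dem, sites, cfg)
        # degenerate value axis has dw = 1
        assert np.nanmax(np.abs(est - 55.0)) <= 0.5 + 1e-9

    def test_estimates_bounded_by_value_axis(self, canonical_fixture,
                                             canonical_regions):
        dem, _, sites = canonical_fixture
        cfg = RunConfig()
        est = interpolate_field(dem, sites, cfg, regions=canonical_regions)
        vmin, vmax = sites.values.min(), sites.values.max()
        pad = 3 * 0.8146 * (vmax - vmin)  # largest possible h_z padding
        assert np.nanmin(est) >= max(vmin - pad, 0.0) - 1e-9
        assert np.nanmax(est) <= vmax + pad + 1e-9

    def test_translation_invariance(self, rng):
        from demdiff import DemRaster, GridTransform
        dem = make_plateau_dem()
        sites = make_sites(rng.uniform(2000, 30000, 15),
                           rng.uniform(2000, 30000, 15),
                           rng.uniform(30, 90, 15))
        cfg = RunConfig(segmentation_scale=300.0)
        est = interpolate_field(dem, sites, cfg)
        shift = 50_000.0
        t = dem.transform
        dem2 = DemRaster(dem.values,
                         GridTransform(t.x0 + shift, t.y0 + shift,
                                       t.dx, t.dy))
        sites2 = make_sites(sites.x + shift, sites.y + shift, sites.values)
        est2 = interpolate_field(dem2, sites2, cfg)
        assert np.allclose(est, est2, atol=1e-8, equal_nan=True)

    def test_value_equivariance(self, canonical_fixture, canonical_regions):
        dem, _, sites = canonical_fixture
        cfg = RunConfig()
        alpha, beta = 2.5, 7.0
        est = interpolate_field(dem, sites, cfg, regions=canonical_regions)
        scaled = sites.with_values(alpha * sites.values + beta)
        est2 = interpolate_field(dem, scaled, cfg, regions=canonical_regions)
        assert np.allclose(est2, alpha * est + beta, atol=1e-8,
                           equal_nan=True)

    def test_single_region_reduces_to_one_window(self, rng):
        from demdiff.infodiffusion import single_region_map, \
            interpolate_window
        from demdiff.segmentation import build_windows
        dem = make_plateau_dem(high=0.0)  # constant: one region
        sites = make_sites(rng.uniform(0, 32000, 8),
                           rng.uniform(0, 32000, 8),
                           rng.uniform(30, 80, 8))
        cfg = RunConfig()
        whole = interpolate_field(dem, sites, cfg, windowed=False)
        regions = single_region_map(dem)
        window = build_windows(regions, sites, cfg.buffer_km)[0]
        part = interpolate_window(window, sites, regions, cfg)
        assert np.allclose(whole, part, equal_nan=True)

    def test_windows_partition_the_mosaic(self, canonical_fixture,
                                          canonical_regions):
        from demdiff.infodiffusion import interpolate_window
        from demdiff.segmentation import build_windows
        dem, _, sites = canonical_fixture
        cfg = RunConfig()
        windows = build_windows(canonical_regions, sites, cfg.buffer_km)
        covered = np.zeros(dem.shape, dtype=int)
        for w in windows:
            part = interpolate_window(w, sites, canonical_regions, cfg)
            covered += (~np.isnan(part)).astype(int)
        assert covered.max() <= 1  # disjoint writes
        assert (covered[~dem.nodata_mask] == 1).all()

    def test_hard_break_at_plateau_boundary(self):
        # zero-noise fixture with a 70 ug/m3 jump at the boundary: the
        # windowed estimate must keep the discontinuity sharp
        from demdiff.synthetic import SyntheticConfig, make_fixture
        cfg_s = SyntheticConfig(noise_amplitude=0.0, measurement_noise=0.0,
                                rng_seed=3)
        dem, truth, sites = make_fixture(cfg_s)
        cfg = RunConfig(buffer_km=1.0)
        est = interpolate_field(dem, sites, cfg)
        ncols = est.shape[1]
        left_edge = est[:, ncols // 2 - 1]
        right_edge = est[:, ncols // 2]
        jump = np.nanmean(left_edge) - np.nanmean(right_edge)
        true_jump = 100.0 - 30.0
        assert jump > 0.5 * true_jump
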
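"""Shared fixtures and independent brute-force oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from demdiff import (DemRaster, GridTransform, RunConfig, SiteTable,
                     SyntheticConfig, make_fixture)
from demdiff.synthetic import generate_dem

SQRT_2PI = math.sqrt(2.0 * math.pi)


# ---------------------------------------------------------------------------
# brute-force oracles (deliberately scalar / loop-based)
# ---------------------------------------------------------------------------

def triple_loop_pipeline(samples, u, v, w, hx, hy, hz):
    """Literal loop transcription of the diffusion → fuzzify → centroid
    chain, kept independent of the vectorized implementation."""
    nv, nu, nw = len(v), len(u), len(w)
    Q = np.zeros((nv, nu, nw))
    for xl, yl, zl in samples:
        for j in range(nv):
            gy = math.exp(-(v[j] - yl) ** 2 / (2 * hy * hy)) / (hy * SQRT_2PI)
            for i in range(nu):
                gx = math.exp(-(u[i] - xl) ** 2
                              / (2 * hx * hx)) / (hx * SQRT_2PI)
                for k in range(nw):
                    gz = math.exp(-(w[k] - zl) ** 2
                                  / (2 * hz * hz)) / (hz * SQRT_2PI)
                    Q[j, i, k] += gx * gy * gz
    R = np.zeros_like(Q)
    for k in range(nw):
        S = Q[:, :, k].max()
        if S > 0:
            R[:, :, k] = Q[:, :, k] / S
    est = np.full((nv, nu), np.nan)
    for j in range(nv):
        for i in range(nu):
            den = sum(R[j, i, k] for k in range(nw))
            if den > 0:
                est[j, i] = sum(w[k] * R[j, i, k] for k in range(nw)) / den
    return Q, R, est


def dense_kriging_oracle(xy, values, gamma_fn, query):
    """Independent dense solve of the ordinary-kriging system for one
    query point: full matrix assembly with explicit loops."""
    n = len(xy)
    A = np.zeros((n + 1, n + 1))
    for i in range(n):
        for j in range(n):
            d = math.dist(xy[i], xy[j])
            A[i, j] = gamma_fn(d) if d > 0 else 0.0
        A[i, n] = 1.0
        A[n, i] = 1.0
    b = np.zeros(n + 1)
    for i in range(n):
        d = math.dist(xy[i], query)
        b[i] = gamma_fn(d) if d > 0 else 0.0
    b[n] = 1.0
    sol = np.linalg.solve(A, b)
    return float(sol[:n] @ values), sol[:n]


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def make_plateau_dem(nrows=16, ncols=16, cell=2000.0, low=0.0, high=1000.0):
    """West half at ``low`` m, east half at ``high`` m."""
    values = np.full((nrows, ncols), low, dtype=np.float32)
    values[:, ncols // 2:] = high
    t = GridTransform(0.0, nrows * cell, cell, cell)
    return DemRaster(values, t)


def make_sites(xs, ys, values, prefix="s"):
    return SiteTable(pd.DataFrame({
        "id": [f"{prefix}{i}" for i in range(len(xs))],
        "x": xs, "y": ys, "value": values,
    }))


@pytest.fixture(scope="session")
def plateau_dem():
    return make_plateau_dem()


@pytest.fixture(scope="session")
def canonical_fixture():
    """The default two-plateau study fixture (128×128, 60 sites, seed 0)."""
    return make_fixture(SyntheticConfig(rng_seed=0))


@pytest.fixture(scope="session")
def canonical_regions(canonical_fixture):
    from demdiff import segment_dem
    dem, _, _ = canonical_fixture
    return segment_dem(dem, 500.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_micro_case(rng, max_sites=6, max_axis=15):
    """Random small diffusion problem for oracle-equivalence checks."""
    n = int(rng.integers(3, max_sites + 1))
    samples = np.column_stack([
        rng.uniform(0.0, 100.0, n),
        rng.uniform(0.0, 100.0, n),
        rng.uniform(10.0, 90.0, n),
    ])
    nu = int(rng.integers(4, max_axis + 1))
    nv = int(rng.integers(4, max_axis + 1))
    nw = int(rng.integers(4, max_axis + 1))
    u = np.linspace(-20.0, 120.0, nu)
    v = np.linspace(120.0, -20.0, nv)
    w = np.linspace(0.0, 100.0, nw)
    hx, hy = rng.uniform(5.0, 40.0, 2)
    hz = rng.uniform(5.0, 30.0)
    return samples, u, v, w, float(hx), float(hy), float(hz)
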
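import numpy as np
import pytest

import hetcakit as hk


@pytest.fixture
def small_axis() -> hk.PpmAxis:
    """Descending 0–10 ppm axis at 0.01 ppm/point (1001 points)."""
    return hk.PpmAxis(np.linspace(10.0, 0.0, 1001))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def small_set(small_axis, rng) -> hk.SpectrumSet:
    mat = rng.uniform(0.0, 2.0, size=(5, len(small_axis)))
    ids = [f"Fr{k}" for k in range(1, 6)]
    return hk.SpectrumSet.from_matrix(small_axis.values, mat, ids)


def make_buckets(values: np.ndarray, width: float = 0.001) -> hk.BucketTable:
    """Wrap an n x p matrix as a bucket table with synthetic ppm intervals."""
    n, p = values.shape
    starts = 0.5 + width * np.arange(p)
    edges = np.column_stack([starts, starts + width])
    ids = tuple(f"Fr{k:02d}" for k in range(1, n + 1))
    return hk.BucketTable(ids, edges, values)


def make_activity(y: np.ndarray, ids=None) -> hk.ActivityTable:
    ids = ids or tuple(f"Fr{k:02d}" for k in range(1, len(y) + 1))
    return hk.ActivityTable(
        tuple(ids), np.asarray(y, float), np.zeros(len(y)), np.ones(len(y), int)
    )
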
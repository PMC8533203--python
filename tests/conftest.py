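import numpy as np
import pytest

from poincarehrv import rr_io
from poincarehrv.plot2d import GridSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def grid():
    return GridSpec()


def make_series(rr, labels=None, meta=None):
    return rr_io.RRSeries(np.asarray(rr, dtype=float), labels, meta)


@pytest.fixture
def series_factory():
    return make_series


def random_bool_grid(rng, max_side=50, p=None):
    """Random boolean image, 1..max_side per side, random density."""
    rows = int(rng.integers(1, max_side + 1))
    cols = int(rng.integers(1, max_side + 1))
    p = p if p is not None else float(rng.uniform(0.05, 0.7))
    return rng.random((rows, cols)) < p


def random_counts_grid(rng, max_side=30, max_count=50):
    rows = int(rng.integers(1, max_side + 1))
    cols = int(rng.integers(1, max_side + 1))
    counts = rng.integers(0, max_count + 1, size=(rows, cols))
    if counts.max() == 0:
        counts[rng.integers(rows), rng.integers(cols)] = 1
    return counts.astype(np.int64)
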
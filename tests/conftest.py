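import numpy as np
import pytest

from boxid.pipeline import RunConfig, run_pipeline
from boxid.preprocess import preprocess
from boxid.synthetic import gen_shed_like


def grid_occupancy(points: np.ndarray, level: int) -> int:
    """Independent box-counting oracle: bin points into a uniform grid of
    2**level cells per axis using the half-open (a, b] convention (cell 0 is
    closed below) and count occupied cells."""
    arr = np.asarray(points, dtype=float)
    idx = np.ceil(arr * 2.0**level).astype(np.int64) - 1
    idx[idx < 0] = 0
    return len(np.unique(idx, axis=0))


@pytest.fixture(scope="session")
def shed_small():
    """A small raw sensor log: 3 participants over 2 days."""
    return gen_shed_like(3, 2, seed=7)


@pytest.fixture(scope="session")
def shed_small_ds(shed_small):
    return preprocess(shed_small)


@pytest.fixture(scope="session")
def full_report(tmp_path_factory):
    """One full-scale pipeline run (20 participants x 14 days, fixed seed),
    shared by the end-to-end assertions."""
    out = tmp_path_factory.mktemp("full_run")
    return run_pipeline(RunConfig(seed=1), out)
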
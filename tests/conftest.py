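import numpy as np
import pytest

from specfx import (
    BatchSimConfig,
    detect_peaks,
    match_common_peaks,
    simulate_batch_set,
)


@pytest.fixture(scope="session")
def batch_set():
    """Default 15-batch / 20-common-peak synthetic set (seed 1) with truth."""
    cfg = BatchSimConfig(seed=1)
    chroms, truth = simulate_batch_set(cfg)
    return cfg, chroms, truth


@pytest.fixture(scope="session")
def matched(batch_set):
    """Peak tables and the matched common-peak matrix for the default set."""
    _, chroms, _ = batch_set
    tables = [detect_peaks(c, min_prominence=10.0) for c in chroms]
    matrix = match_common_peaks(tables, rt_tolerance=0.3)
    return tables, matrix


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
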
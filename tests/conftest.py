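import numpy as np
import pytest

from chw_access import LandscapeSpec, generate, run_pipeline
from chw_access.geodata import make_grid


SMALL_SPEC = dict(shape=(60, 60), n_settlements=8, n_communes=3, seed=1)


@pytest.fixture(scope="session")
def small_land():
    """One modest synthetic landscape shared across test modules."""
    return generate(LandscapeSpec(**SMALL_SPEC))


@pytest.fixture(scope="session")
def small_result(small_land):
    return run_pipeline(small_land)


@pytest.fixture
def flat_grid():
    """5x5 all-zero grid at 100 m cells."""
    return make_grid(np.zeros((5, 5)), 100.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
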
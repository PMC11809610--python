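import numpy as np
import pytest

from oligoquant import celfis, synth


@pytest.fixture(scope="session")
def grid():
    return synth.default_grid(n_bins=256, period=25.0)


@pytest.fixture(scope="session")
def profiles(grid):
    return synth.gaussian_irf_profiles(grid)


@pytest.fixture(scope="session")
def library():
    return celfis.PatternLibrary.default()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
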
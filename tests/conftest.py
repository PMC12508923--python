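import numpy as np
import pytest
from hypothesis import settings

from sersdemux.simulate import make_background, make_reference_pfos
from sersdemux.spectra import DEFAULT_GRID, GridSpec

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def grid():
    return DEFAULT_GRID


@pytest.fixture(scope="session")
def small_grid():
    """Coarse grid covering both marker peaks; cheap for per-test math."""
    return GridSpec(400.0, 1800.0, 256)


@pytest.fixture(scope="session")
def pfos(grid):
    return make_reference_pfos(grid=grid)


@pytest.fixture(scope="session")
def bkg(grid):
    return make_background(grid=grid)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
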
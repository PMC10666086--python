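import numpy as np
import pytest

from ir2dscreen import RunConfig, generate_screening_set, preprocess_dataset
from ir2dscreen.gridmap import AxisGrid, default_grid


@pytest.fixture(scope="session")
def config():
    return RunConfig()


@pytest.fixture(scope="session")
def grid(config):
    return default_grid(**vars(config.grid))


@pytest.fixture(scope="session")
def small_grid():
    """A coarse grid for cheap lineshape tests."""
    return AxisGrid(np.arange(1600.0, 1701.0, 4.0), np.arange(1580.0, 1701.0, 4.0))


@pytest.fixture(scope="session")
def screening(config):
    """Default screening dataset, seed 1."""
    return generate_screening_set(config, seed=1)


@pytest.fixture(scope="session")
def processed(screening):
    return preprocess_dataset(screening)


@pytest.fixture(scope="session")
def noiseless_config():
    return RunConfig(noise_sigma=0.0)


@pytest.fixture(scope="session")
def noiseless_screening(noiseless_config):
    return generate_screening_set(noiseless_config, seed=1)
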
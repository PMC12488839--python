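import numpy as np
import pytest

from hdemg_hypoxia.core import GridGeometry


@pytest.fixture(scope="session")
def geometry():
    """Default 13 x 5 grid, 8 mm IED, 2048 Hz."""
    return GridGeometry()


@pytest.fixture(scope="session")
def small_geometry():
    """Reduced grid for cheap tests."""
    return GridGeometry(n_rows=7, n_cols=3, ied=8.0, fs=2048.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
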
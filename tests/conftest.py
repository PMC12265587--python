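import numpy as np
import pytest

from spt_audit.imaging import CameraParams, EmissionParams, OpticsParams
from spt_audit.io import default_config
from spt_audit.trajectories import InitialPositionPrior, TimeGrid


@pytest.fixture(scope="session")
def reference_config():
    return default_config()


@pytest.fixture(scope="session")
def optics():
    return OpticsParams()


@pytest.fixture(scope="session")
def camera():
    return CameraParams()


@pytest.fixture(scope="session")
def emission():
    return EmissionParams()


@pytest.fixture(scope="session")
def prior():
    c = CameraParams().pixels_per_side * CameraParams().pixel_size_um / 2.0
    return InitialPositionPrior((c, c, 0.0), 0.0963, 0.3738)


@pytest.fixture
def uniform_grid():
    """100 uniform steps of 0.1 s (no dead time)."""
    return TimeGrid(100, 1, 0.1, 0.1)


@pytest.fixture
def small_grid():
    """Reference-timing grid small enough for fast rendering."""
    return TimeGrid(5, 4)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
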
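import numpy as np
import pytest

from ecopattern.grid import Raster
from ecopattern.synth import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def small_scene():
    """80x80 scene shared by the stage tests (fast, deterministic)."""
    return generate_scene(SceneConfig(nrows=80, ncols=80, seed=1))


@pytest.fixture(scope="session")
def default_scene():
    """The default 200x200 scene used by end-to-end checks."""
    return generate_scene(SceneConfig(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def flat_raster():
    return Raster(np.zeros((10, 10)), cell_size=0.5)


def make_raster(values, cell_size=1.0, nodata=-9999.0):
    return Raster(np.asarray(values, dtype=float), cell_size=cell_size,
                  nodata=nodata)
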
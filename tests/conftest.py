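import numpy as np
import pytest
from hypothesis import settings

from pondnet.raster import CLASS_CODES, Raster
from pondnet.resistance import ResistanceRaster

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def uniform_landcover():
    """A 6x6 all-wetlands land-cover raster at 10 m resolution."""

    def _make(cls="wetlands", shape=(6, 6)):
        return Raster(np.full(shape, CLASS_CODES[cls], dtype=int), cell_size=10.0)

    return _make


@pytest.fixture
def small_resistance():
    """5x5 uniform medium-resistance raster with full study mask."""
    ras = Raster(np.full((5, 5), 10.0), cell_size=10.0)
    return ResistanceRaster(ras, np.ones((5, 5), bool))


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
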
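import numpy as np
import pytest

from shadowimg.core import ImageStack, PixelGeometry


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def geometry():
    return PixelGeometry(dx=0.1)


@pytest.fixture
def random_stack(rng, geometry):
    """32x32 random single-frame stack with values in [0, 10)."""
    return ImageStack(rng.uniform(0, 10, (32, 32)), geometry=geometry)
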
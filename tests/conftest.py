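import numpy as np
import pytest

from sliscat.geometry import DisplayGeometry
from sliscat.synthetic import FiberBundle, render_pattern


@pytest.fixture
def paper_geom() -> DisplayGeometry:
    """The published instrument layout: 256 LEDs, 1.8 mm pitch, H = 13 cm."""
    return DisplayGeometry()


@pytest.fixture
def small_geom() -> DisplayGeometry:
    """Compact scan geometry used by most synthetic fixtures."""
    return DisplayGeometry(kernel_size=4, kernels_per_side=49)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20211129)


def render_centered(constellation, size=49, **kwargs):
    """Noiseless pattern centred on the middle of an odd-sized grid."""
    center = ((size - 1) / 2.0, (size - 1) / 2.0)
    if isinstance(constellation, FiberBundle):
        constellation = [constellation]
    return render_pattern(constellation, size=size, center=center, **kwargs)
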
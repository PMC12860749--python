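import numpy as np
import pytest

from marrowquant.grids import LabelMask, VolumeGrid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_grid(data, spacing=(1.0, 1.0, 1.0)):
    return VolumeGrid(data=np.asarray(data, dtype=float), spacing=spacing)


def make_mask(data, spacing=(1.0, 1.0, 1.0), label=""):
    return LabelMask(data=np.asarray(data, dtype=bool), spacing=spacing, label=label)


@pytest.fixture
def uniform_cavity():
    """A 16^3 grid, constant -80 HU, with a 10^3 central cavity mask."""
    data = np.full((16, 16, 16), -80.0)
    mask = np.zeros((16, 16, 16), dtype=bool)
    mask[3:13, 3:13, 3:13] = True
    return make_grid(data), make_mask(mask, label="medullary_cavity")
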
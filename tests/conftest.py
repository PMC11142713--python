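import numpy as np
import pytest

from snakerisk.raster import RasterGrid
from snakerisk.stack import PredictorStack


@pytest.fixture
def unit_grid():
    """4x4 grid over [0,4]x[0,4] with cell size 1, values = row*4+col."""
    values = np.arange(16, dtype=float).reshape(4, 4)
    return RasterGrid(values=values, mask=np.zeros((4, 4), bool),
                      origin_x=0.0, origin_y=4.0, cell_size=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_grid(values, origin_x=0.0, origin_y=None, cell_size=1.0, mask=None):
    values = np.asarray(values, dtype=float)
    if origin_y is None:
        origin_y = values.shape[0] * cell_size
    if mask is None:
        mask = np.zeros(values.shape, bool)
    return RasterGrid(values=values, mask=mask, origin_x=origin_x,
                      origin_y=origin_y, cell_size=cell_size)


def make_stack(layer_values: dict, **kwargs) -> PredictorStack:
    return PredictorStack({name: make_grid(v, **kwargs) for name, v in layer_values.items()})
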
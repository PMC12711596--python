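import numpy as np
import pytest

from esdm.grid import RasterGrid
from esdm.stack import PredictorStack
from esdm.synthetic import LandscapeSpec, make_stack


@pytest.fixture
def template():
    """10x10 grid of 1-km cells anchored at the origin."""
    return RasterGrid(np.zeros((10, 10)), 0.0, 10.0, 1.0)


@pytest.fixture(scope="session")
def stack_100():
    """100x100-cell stack, 5 layers with an engineered rho=0.9 pair."""
    spec = LandscapeSpec(extent=(0, 0, 100, 100), cell_size=1.0, n_predictors=5,
                         collinear_pairs=[(0, 1, 0.9)], smoothness=3.0, seed=42)
    return make_stack(spec)


def constant_grid(value, shape=(10, 10), cell=1.0):
    return RasterGrid(np.full(shape, float(value)), 0.0, shape[0] * cell, cell)


def stack_from_arrays(cell=1.0, **arrays) -> PredictorStack:
    layers = {}
    for name, arr in arrays.items():
        arr = np.asarray(arr, dtype=float)
        layers[name] = RasterGrid(arr, 0.0, arr.shape[0] * cell, cell)
    return PredictorStack(layers)
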
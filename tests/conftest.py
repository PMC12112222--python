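import numpy as np
import pytest

from enmkit.grids import GridHeader, Raster, RasterStack
from enmkit.synthetic import default_scenario, make_stack, make_truth, sample_occurrences


@pytest.fixture(scope="session")
def scenario():
    """The package's reference synthetic study system (seed 42)."""
    return default_scenario()


@pytest.fixture(scope="session")
def small_scenario():
    """A compact scenario for fast fitting tests: 3 layers, 60x60 cells."""
    stack = make_stack(
        3,
        nrows=60,
        ncols=60,
        corr_length_cells=5.0,
        seed=7,
        layer_names=["temp", "wet", "noise"],
        lat_gradient={"temp": -1.0},
    )
    truth = make_truth(stack, intercept=1.0, linear={"wet": 1.0}, quadratic={"temp": (-1.0, 0.0)})
    occ = sample_occurrences(truth, 120, seed=8)
    return stack, truth, occ


@pytest.fixture
def header3():
    return GridHeader(ncols=3, nrows=3, xll=100.0, yll=20.0, cellsize=0.5)


@pytest.fixture
def raster3(header3):
    return Raster(header3, np.arange(1.0, 10.0).reshape(3, 3))
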
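import numpy as np
import pandas as pd
import pytest

from nichekit import synth
from nichekit.grids import GridSpec, Raster


@pytest.fixture(scope="session")
def small_spec():
    return GridSpec(ncols=40, nrows=30, xll=105.0, yll=26.0, cellsize=0.05)


@pytest.fixture(scope="session")
def desk_spec():
    return synth.DEFAULT_SPEC


@pytest.fixture(scope="session")
def env_stack(desk_spec):
    return synth.make_env_stack(11, desk_spec, n_vars=4, corr_pairs=[(0, 1, 0.9)])


@pytest.fixture(scope="session")
def truth_model():
    return synth.TruthModel({"Bio1": (1.5, -1.0), "Bio3": (1.0, 0.0)})


@pytest.fixture(scope="session")
def base_suitability(env_stack, truth_model):
    return truth_model.suitability(env_stack)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def uniform_background():
    """Two independent uniform variables as a background table."""
    r = np.random.default_rng(7)
    return pd.DataFrame({"x1": r.uniform(0, 1, 1000), "x2": r.uniform(0, 1, 1000)})


def checkerboard_raster(spec, fill=0.6, nodata_cells=()):
    vals = np.full((spec.nrows, spec.ncols), fill)
    mask = np.zeros_like(vals, dtype=bool)
    for r, c in nodata_cells:
        mask[r, c] = True
    return Raster(spec, np.where(mask, spec.nodata, vals), mask)
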
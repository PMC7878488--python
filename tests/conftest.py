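import numpy as np
import pytest

from grazecap import synthetic
from grazecap.config import load_config
from grazecap.grid import GridSpec, Raster
from grazecap.pipeline import run_all


@pytest.fixture(scope="session")
def default_county():
    """The default synthetic county (seed 0), shared read-only."""
    return synthetic.make_county(synthetic.CountySpec(seed=0))


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run at the default configuration (seed 0)."""
    outdir = tmp_path_factory.mktemp("default_run")
    cfg = load_config()
    report = run_all(cfg, outdir)
    return outdir, report


@pytest.fixture
def small_grid():
    """4x4 grid of 5 km cells, 20x20 km extent."""
    return GridSpec(xmin=0.0, ymax=20.0, cell_size=5.0, nrows=4, ncols=4)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def raster_of(grid, values):
    return Raster(grid, np.asarray(values, dtype=float))
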
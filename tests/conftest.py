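import numpy as np
import pytest

from seaniche import (GridSpec, Raster, SeascapeParams, default_effort,
                      default_truths, make_seascape, simulate_occurrences)


@pytest.fixture(scope="session")
def small_params():
    return SeascapeParams(n_rows=40, n_cols=40, n_sst_dates_per_season=6,
                          n_bathy_points=150, seed=11)


@pytest.fixture(scope="session")
def small_scape(small_params):
    return make_seascape(small_params)


@pytest.fixture(scope="session")
def small_stacks(small_scape):
    return small_scape.env_stacks()


@pytest.fixture(scope="session")
def small_occurrences(small_scape, small_stacks):
    truths = default_truths(120)
    effort = default_effort(small_scape.grid)
    return simulate_occurrences(small_stacks, truths, effort, seed=21)


@pytest.fixture
def open_sea_grid():
    """A 12x12 all-marine grid except a land rim on the western edge."""
    mask = np.ones((12, 12), dtype=bool)
    mask[:, 0] = False
    return GridSpec(12, 12, 1000.0, origin_x=0.0, origin_y=12000.0, mask=mask)


def make_raster(values, cell_size=1000.0, mask=None, name="layer"):
    values = np.asarray(values, dtype=float)
    n_rows, n_cols = values.shape
    grid = GridSpec(n_rows, n_cols, cell_size, origin_x=0.0,
                    origin_y=n_rows * cell_size, mask=mask)
    return Raster(grid, values, name=name)
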
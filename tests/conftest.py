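import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from ozcrop import (
    County,
    CountySet,
    ExposureWindow,
    HourlyO3Grid,
    make_grid,
)


@pytest.fixture
def grid3():
    """3 x 3 unit-cell grid at the origin."""
    return make_grid(3, 3, 1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def hourly_times(n_hours, start="2020-05-01"):
    return pd.date_range(start, periods=n_hours, freq="h")


@pytest.fixture
def random_cube(grid3, rng):
    """48-hour random cube on the 3 x 3 grid, values in [0, 0.08] ppmV."""
    vals = rng.uniform(0.0, 0.08, size=(48, 3, 3))
    return HourlyO3Grid(values=vals, times=hourly_times(48), grid=grid3)


@pytest.fixture
def window48():
    return ExposureWindow(start="2020-05-01", end="2020-05-03")


@pytest.fixture
def quadrant_counties():
    """Four equal counties tiling a 2 x 2 domain, with production."""
    return CountySet(
        [
            County("C00", box(0, 0, 1, 1), "Southeast", 1000.0),
            County("C01", box(1, 0, 2, 1), "Southeast", 2000.0),
            County("C10", box(0, 1, 1, 2), "Midwest", 3000.0),
            County("C11", box(1, 1, 2, 2), "Midwest", 4000.0),
        ]
    )


def make_impact_table(county_ids, regions, aot40, production, a=0.0113,
                      convention="compensated", price=9.0075):
    """Build a county impact table the way the pipeline does, from raw
    exposures and production, for use in scenario-level tests."""
    from ozcrop import economic_loss_usd, production_loss_bu, relative_yield_loss

    aot40 = np.asarray(aot40, dtype=float)
    production = np.asarray(production, dtype=float)
    ryl = relative_yield_loss(aot40, a)
    loss_bu = production_loss_bu(production, ryl, convention)
    return pd.DataFrame(
        {
            "county_id": county_ids,
            "region": regions,
            "aot40": aot40,
            "ryl": ryl,
            "production_bu": production,
            "loss_bu": loss_bu,
            "loss_usd": economic_loss_usd(loss_bu, price),
        }
    )
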
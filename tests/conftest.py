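import numpy as np
import pandas as pd
import pytest
import xarray as xr

from wavecatch.grid import monthly_axis
from wavecatch.synthetic import GridConfig, ScenarioConfig, WaveConfig


def make_field(
    values=None,
    n_time=36,
    lats=(30.0, 30.5, 31.0, 31.5),
    lons=(130.0, 130.5, 131.0, 131.5, 132.0),
    start="2000-01",
    name="ssh",
    units="cm",
):
    """A small gridded field; values default to zeros."""
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    time = monthly_axis(start, n_time)
    if values is None:
        values = np.zeros((n_time, lats.size, lons.size))
    da = xr.DataArray(
        np.asarray(values, dtype=float),
        coords={"time": time, "lat": lats, "lon": lons},
        dims=("time", "lat", "lon"),
        name=name,
    )
    da.attrs["units"] = units
    return da


@pytest.fixture
def small_field():
    return make_field()


def tiny_scenario(seed=0, **overrides) -> ScenarioConfig:
    """A desk-scale scenario on a 1-degree grid; fast enough for loops."""
    kwargs = dict(
        grid=GridConfig(lat_min=28, lat_max=33, lon_min=130, lon_max=160, spacing=1.0),
        seed=seed,
    )
    kwargs.update(overrides)
    return ScenarioConfig(**kwargs)


@pytest.fixture
def scenario_config():
    return tiny_scenario()


@pytest.fixture(scope="session")
def default_scenario():
    """One generated default (paper-mimic) scenario, shared across tests."""
    from wavecatch.synthetic import generate

    return generate(ScenarioConfig(seed=0))


def winter_series(values, first_winter=2000, name="index"):
    """SeasonalSeries from a plain list of winter values."""
    from wavecatch.cpue import SeasonalSeries

    idx = pd.Index(range(first_winter, first_winter + len(values)), name="winter")
    return SeasonalSeries(value=pd.Series(np.asarray(values, dtype=float), index=idx, name=name))
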
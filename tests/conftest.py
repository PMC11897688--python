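import numpy as np
import pandas as pd
import pytest

from laiproj import DataCube, DatasetBundle, Grid


@pytest.fixture
def rng():
    return np.random.default_rng(20250925)


def make_grid(lats, lons, resolution=1.0):
    return Grid(lats=np.asarray(lats, float), lons=np.asarray(lons, float),
                resolution=resolution)


def make_cube(values, lats=None, lons=None, times=None, variable="LAI",
              units="m2 m-2", resolution=1.0):
    values = np.asarray(values, dtype=float)
    nt, nlat, nlon = values.shape
    if lats is None:
        lats = np.arange(nlat, dtype=float)
    if lons is None:
        lons = np.arange(nlon, dtype=float)
    if times is None:
        times = pd.date_range("2000-01-01", periods=nt, freq="MS")
    return DataCube(variable=variable, units=units, times=pd.DatetimeIndex(times),
                    grid=make_grid(lats, lons, resolution), values=values)


def make_bundle(dataset_id, factor_values, **kw):
    """Bundle from a dict factor-name -> (t, lat, lon) array."""
    return DatasetBundle(
        dataset_id=dataset_id,
        factors={name: make_cube(vals, variable=name, units="", **kw)
                 for name, vals in factor_values.items()},
    )


@pytest.fixture
def cube_factory():
    return make_cube


@pytest.fixture
def bundle_factory():
    return make_bundle
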
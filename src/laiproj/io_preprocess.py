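"""Gridded monthly data containers and the LAI preprocessing chain.

The pipeline mirrors how long-term satellite LAI records are prepared for
regional climate--vegetation modelling: sub-monthly fields are composited to
monthly maxima (MVC), resampled to a common grid by bilinear interpolation,
several products are averaged into one observational record, climate factors
are aggregated to monthly sums or means depending on the variable, and
area-weighted regional mean series are extracted for latitude-band regions.

Missing data are represented as NaN throughout; every statistic here is
mask-safe (a masked value never contributes to an output).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr
from scipy.interpolate import RegularGridInterpolator

from .errors import (
    AlignmentError,
    ArgumentError,
    EmptyRegionError,
    FormatError,
)

#: Canonical climate factor names, in the order used for subset enumeration.
FACTORS: tuple[str, ...] = ("ET", "SM", "Pre", "Tmp", "CO2")

#: Factors accumulated to monthly totals; the rest are averaged.
SUM_FACTORS: frozenset[str] = frozenset({"Pre", "ET", "CO2"})


@dataclass(frozen=True)
class Grid:
    """A regular latitude/longitude grid (cell-center registration).

    Latitudes are degrees north and strictly ascending; longitudes are degrees
    east in [-180, 180). ``resolution`` is the nominal cell size in degrees.
    """

    lats: np.ndarray
    lons: np.ndarray
    resolution: float

    def __post_init__(self) -> None:
        lats = np.asarray(self.lats, dtype=float)
        lons = np.asarray(self.lons, dtype=float)
        object.__setattr__(self, "lats", lats)
        object.__setattr__(self, "lons", lons)
        if self.resolution <= 0:
            raise ArgumentError("grid resolution must be positive")
        if lats.ndim != 1 or lons.ndim != 1:
            raise ArgumentError("grid coordinate vectors must be 1-D")
        if len(lats) > 1 and not np.all(np.diff(lats) > 0):
            raise ArgumentError("latitudes must be strictly ascending")
        if len(lons) > 1 and not np.all(np.diff(lons) > 0):
            raise ArgumentError("longitudes must be strictly ascending")
        if lats.min() < -90 or lats.max() > 90:
            raise ArgumentError("latitudes must lie in [-90, 90]")

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.lats), len(self.lons)

    def __eq__(self, other: object) -> bool:  # value equality on coords
        if not isinstance(other, Grid):
            return NotImplemented
        return (
            self.lats.shape == other.lats.shape
            and self.lons.shape == other.lons.shape
            and np.allclose(self.lats, other.lats)
            and np.allclose(self.lons, other.lons)
        )

    @classmethod
    def global_grid(cls, resolution: float) -> "Grid":
        """Global grid at ``resolution`` degrees, cell-center registered."""
        half = resolution / 2.0
        lats = np.arange(-90 + half, 90, resolution)
        lons = np.arange(-180 + half, 180, resolution)
        return cls(lats=lats, lons=lons, resolution=resolution)


@dataclass
class DataCube:
    """One variable's gridded time series (time x lat x lon, NaN-masked)."""

    variable: str
    units: str
    times: pd.DatetimeIndex
    grid: Grid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = pd.DatetimeIndex(self.times)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) == 0:
            raise ArgumentError("cube must have at least one time step")
        if not self.times.is_monotonic_increasing or self.times.has_duplicates:
            raise ArgumentError("times must be strictly increasing")
        expected = (len(self.times),) + self.grid.shape
        if self.values.shape != expected:
            raise ArgumentError(
                f"values shape {self.values.shape} != (time, lat, lon) {expected}"
            )

    @property
    def mask(self) -> np.ndarray:
        """Boolean missing-value indicator, congruent with ``values``."""
        return np.isnan(self.values)

    def copy_with(self, **kw) -> "DataCube":
        return replace(self, **kw)


@dataclass
class DatasetBundle:
    """The five climate-factor cubes of one dataset on one grid/time index."""

    dataset_id: str
    factors: dict[str, DataCube] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.factors) - set(FACTORS)
        if unknown:
            raise ArgumentError(f"unknown factor names: {sorted(unknown)}")
        cubes = list(self.factors.values())
        for cube in cubes[1:]:
            if cube.grid != cubes[0].grid or not cube.times.equals(cubes[0].times):
                raise AlignmentError(
                    f"factor cubes of {self.dataset_id!r} are not aligned"
                )

    @property
    def grid(self) -> Grid:
        return next(iter(self.factors.values())).grid

    @property
    def times(self) -> pd.DatetimeIndex:
        return next(iter(self.factors.values())).times


@dataclass(frozen=True)
class RegionDefinition:
    """A latitude band (degrees north); the study regions are bands."""

    name: str
    lat_min: float
    lat_max: float

    def __post_init__(self) -> None:
        if not self.lat_min < self.lat_max:
            raise ArgumentError("lat_min must be below lat_max")


#: The five study regions: the globe plus four latitude bands. Cells south of
#: 60 degrees S belong to Global but to no sub-region.
REGIONS: tuple[RegionDefinition, ...] = (
    RegionDefinition("Global", -90.0, 90.0),
    RegionDefinition("N-High", 60.0, 90.0),
    RegionDefinition("N-Mid", 30.0, 60.0),
    RegionDefinition("Trop", -30.0, 30.0),
    RegionDefinition("S-Mid", -60.0, -30.0),
)

REGIONS_BY_NAME: dict[str, RegionDefinition] = {r.name: r for r in REGIONS}


# ---------------------------------------------------------------------------
# NetCDF I/O
# ---------------------------------------------------------------------------

def write_cube(cube: DataCube, path) -> None:
    """Write a cube to a CF-style NetCDF file (classic format).

    Units and fill-value attributes are recorded; NaN cells are stored as the
    fill value.
    """
    da = xr.DataArray(
        cube.values,
        dims=("time", "lat", "lon"),
        coords={"time": cube.times, "lat": cube.grid.lats, "lon": cube.grid.lons},
        name=cube.variable,
        attrs={"units": cube.units},
    )
    da["lat"].attrs.update(units="degrees_north", standard_name="latitude")
    da["lon"].attrs.update(units="degrees_east", standard_name="longitude")
    ds = da.to_dataset()
    ds.attrs["grid_resolution_deg"] = float(cube.grid.resolution)
    enc = {cube.variable: {"_FillValue": np.float64(-9.999e36), "dtype": "f8"}}
    ds.to_netcdf(path, engine="scipy", encoding=enc)


def read_cube(path, variable: str) -> DataCube:
    """Read one variable from a CF-style NetCDF file into a :class:`DataCube`.

    Latitude is normalised to ascending order; the file's fill value becomes
    the NaN mask. Raises :class:`FormatError` if the variable is missing or
    does not have (time, lat, lon) dimensions.
    """
    with xr.open_dataset(path, engine="scipy") as ds:
        if variable not in ds:
            raise FormatError(f"{path}: variable {variable!r} not found")
        da = ds[variable]
        dims = set(da.dims)
        lat_name = "lat" if "lat" in dims else "latitude" if "latitude" in dims else None
        lon_name = "lon" if "lon" in dims else "longitude" if "longitude" in dims else None
        if "time" not in dims or lat_name is None or lon_name is None:
            raise FormatError(
                f"{path}: variable {variable!r} must have (time, lat, lon) dims,"
                f" got {tuple(da.dims)}"
            )
        da = da.transpose("time", lat_name, lon_name)
        lats = np.asarray(da[lat_name].values, dtype=float)
        if len(lats) > 1 and lats[0] > lats[-1]:
            da = da.isel({lat_name: slice(None, None, -1)})
            lats = lats[::-1]
        lons = np.asarray(da[lon_name].values, dtype=float)
        res = float(ds.attrs.get("grid_resolution_deg", 0) or 0)
        if res <= 0:
            res = float(np.median(np.abs(np.diff(lats)))) if len(lats) > 1 else 1.0
        values = np.asarray(da.values, dtype=float)
        units = str(da.attrs.get("units", ""))
        times = pd.DatetimeIndex(da["time"].values)
    return DataCube(
        variable=variable,
        units=units,
        times=times,
        grid=Grid(lats=lats, lons=lons, resolution=res),
        values=values,
    )


# ---------------------------------------------------------------------------
# Compositing and aggregation
# ---------------------------------------------------------------------------

def _month_groups(times: pd.DatetimeIndex):
    """Yield ((year, month), integer index array) in chronological order."""
    periods = times.to_period("M")
    for per in periods.unique():
        idx = np.flatnonzero(periods == per)
        yield per, idx


def _reduce_monthly(cube: DataCube, how: str) -> DataCube:
    out_times = []
    out_vals = []
    for per, idx in _month_groups(cube.times):
        chunk = cube.values[idx]
        valid = ~np.isnan(chunk)
        any_valid = valid.any(axis=0)
        if how == "max":
            filled = np.where(valid, chunk, -np.inf)
            red = filled.max(axis=0)
        elif how == "sum":
            red = np.where(valid, chunk, 0.0).sum(axis=0)
        elif how == "mean":
            red = np.where(valid, chunk, 0.0).sum(axis=0) / np.maximum(
                valid.sum(axis=0), 1
            )
        else:  # pragma: no cover - internal
            raise ValueError(how)
        red = np.where(any_valid, red, np.nan)
        out_times.append(per.to_timestamp())
        out_vals.append(red)
    return cube.copy_with(
        times=pd.DatetimeIndex(out_times), values=np.stack(out_vals)
    )


def mvc_composite(cube: DataCube) -> DataCube:
    """Maximum-value composite: per calendar month, the cell-wise maximum.

    A cell is masked in a month only if every contributing value is masked.
    Idempotent on already-monthly input.
    """
    if cube.values.size == 0:
        raise ArgumentError("empty cube")
    return _reduce_monthly(cube, "max")


def monthly_aggregate(cube: DataCube, factor: str) -> DataCube:
    """Aggregate a sub-monthly factor cube to monthly resolution.

    Precipitation, evapotranspiration and the CO2 proxy (NBP) accumulate to
    monthly totals; temperature and soil moisture are averaged.
    """
    if factor not in FACTORS:
        raise ArgumentError(f"unknown factor {factor!r}; expected one of {FACTORS}")
    how = "sum" if factor in SUM_FACTORS else "mean"
    return _reduce_monthly(cube, how)


def ensemble_mean_products(cubes: Sequence[DataCube]) -> DataCube:
    """Cell-wise mean over unmasked members of several aligned products."""
    if len(cubes) == 0:
        raise ArgumentError("need at least one cube")
    first = cubes[0]
    for c in cubes[1:]:
        if c.grid != first.grid:
            raise AlignmentError("product grids do not match")
        if not c.times.equals(first.times):
            raise AlignmentError("product time indexes do not match")
    stack = np.stack([c.values for c in cubes])
    valid = ~np.isnan(stack)
    n = valid.sum(axis=0)
    total = np.where(valid, stack, 0.0).sum(axis=0)
    mean = np.where(n > 0, total / np.maximum(n, 1), np.nan)
    return first.copy_with(values=mean)


# ---------------------------------------------------------------------------
# Regridding
# ---------------------------------------------------------------------------

def regrid_bilinear(cube: DataCube, target: Grid, wrap_lon: bool = False) -> DataCube:
    """Bilinear interpolation of every time slice onto ``target``.

    Exact (to rounding) for fields of the form a + b*lat + c*lon + d*lat*lon.
    Target points outside the source cell-center hull come back masked rather
    than raising; with ``wrap_lon`` the source is padded periodically in
    longitude.
    """
    src_lats = cube.grid.lats
    src_lons = cube.grid.lons
    vals = cube.values
    if wrap_lon:
        src_lons = np.concatenate(
            ([src_lons[-1] - 360.0], src_lons, [src_lons[0] + 360.0])
        )
        vals = np.concatenate((vals[:, :, -1:], vals, vals[:, :, :1]), axis=2)
    tlat, tlon = np.meshgrid(target.lats, target.lons, indexing="ij")
    pts = np.column_stack([tlat.ravel(), tlon.ravel()])
    out = np.empty((len(cube.times),) + target.shape)
    for t in range(len(cube.times)):
        interp = RegularGridInterpolator(
            (src_lats, src_lons),
            vals[t],
            method="linear",
            bounds_error=False,
            fill_value=np.nan,
        )
        out[t] = interp(pts).reshape(target.shape)
    return cube.copy_with(grid=target, values=out)


# ---------------------------------------------------------------------------
# Regional extraction
# ---------------------------------------------------------------------------

def vegetated_mask(lai_cube: DataCube, threshold: float = 0.1) -> np.ndarray:
    """Default vegetated-cell mask: historical-mean LAI above ``threshold``.

    ``threshold`` is in the LAI unit (m^2 m^-2).
    """
    with np.errstate(invalid="ignore"):
        valid = ~np.isnan(lai_cube.values)
        total = np.where(valid, lai_cube.values, 0.0).sum(axis=0)
        n = valid.sum(axis=0)
        mean = np.where(n > 0, total / np.maximum(n, 1), np.nan)
    return np.nan_to_num(mean, nan=-np.inf) > threshold


def extract_region(
    cube: DataCube,
    region: RegionDefinition,
    veg_mask: np.ndarray | None = None,
    area_weighted: bool = True,
) -> pd.Series:
    """Area-weighted regional mean series over a latitude band.

    Weights are cos(latitude) by default (``area_weighted=False`` gives an
    unweighted mean). Masked cells are excluded per time step; cells outside
    ``veg_mask`` (if given) are excluded entirely. Raises
    :class:`EmptyRegionError` when no cell is ever eligible.
    """
    lats = cube.grid.lats
    in_band = (lats >= region.lat_min) & (lats <= region.lat_max)
    if not in_band.any():
        raise EmptyRegionError(
            f"region {region.name!r} does not overlap the cube grid"
        )
    vals = cube.values[:, in_band, :]
    if veg_mask is not None:
        if veg_mask.shape != cube.grid.shape:
            raise ArgumentError("veg_mask shape does not match the cube grid")
        sub = veg_mask[in_band, :]
        vals = np.where(sub[None, :, :], vals, np.nan)
    if area_weighted:
        w = np.cos(np.deg2rad(lats[in_band]))
    else:
        w = np.ones(in_band.sum())
    w2d = np.broadcast_to(w[:, None], vals.shape[1:])
    valid = ~np.isnan(vals)
    if not valid.any():
        raise EmptyRegionError(f"region {region.name!r} has no eligible cells")
    wsum = (np.where(valid, vals, 0.0) * w2d).sum(axis=(1, 2))
    wtot = (valid * w2d).sum(axis=(1, 2))
    out = np.where(wtot > 0, wsum / np.where(wtot > 0, wtot, 1.0), np.nan)
    return pd.Series(out, index=cube.times, name=f"{cube.variable}:{region.name}")


def extract_region_frame(
    bundle: DatasetBundle,
    region: RegionDefinition,
    veg_mask: np.ndarray | None = None,
    area_weighted: bool = True,
) -> pd.DataFrame:
    """Regional mean series for every factor of a bundle, as one DataFrame."""
    cols = {
        name: extract_region(cube, region, veg_mask, area_weighted)
        for name, cube in bundle.factors.items()
    }
    return pd.DataFrame(cols)
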
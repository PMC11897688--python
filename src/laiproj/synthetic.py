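"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

The generator emulates the shape of the real study inputs — two pseudo-ESM
climate datasets (five monthly gridded factors, historical 1982-2014 plus
four future scenarios with increasing trend multipliers), an observed LAI
cube generated from a *known* factor subset through a recorded link function,
daily LAI for compositing tests, and three pseudo-LAI products at mixed
native resolutions — so that every stage of the framework, including
ground-truth recovery by the model sweep, is testable without any download.

Each climate factor is a latitude-dependent mean + seasonal cycle + linear
trend (scenario-scaled) + AR(1) red noise; each pseudo-ESM observes that
shared truth through its own bias and noise. Everything is reproducible from
the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ArgumentError
from .io_preprocess import FACTORS, DataCube, DatasetBundle, Grid

#: Per-factor climatology: (base, latitude gradient, seasonal amplitude,
#: trend per year, AR(1) noise SD, units).
_FACTOR_PARAMS = {
    "Tmp": dict(base=22.0, lat_grad=-18.0, amp=8.0, trend=0.030, sd=0.6, units="degC"),
    "Pre": dict(base=80.0, lat_grad=-30.0, amp=30.0, trend=0.20, sd=8.0, units="mm"),
    "ET": dict(base=60.0, lat_grad=-25.0, amp=20.0, trend=0.15, sd=6.0, units="mm"),
    "SM": dict(base=0.25, lat_grad=0.05, amp=0.05, trend=5e-4, sd=0.012, units="m3 m-3"),
    "CO2": dict(base=1.0, lat_grad=0.2, amp=0.0, trend=0.045, sd=0.02, units="kg C m-2"),
}

DEFAULT_SCENARIOS = ("SSP126", "SSP245", "SSP370", "SSP585")


@dataclass(frozen=True)
class SynthConfig:
    """Conditions of the synthetic study; equal configs give equal outputs."""

    seed: int = 0
    n_lat: int = 20
    n_lon: int = 40
    hist_start: str = "1982-01"
    hist_end: str = "2014-12"
    scen_start: str = "2015-01"
    scen_end: str = "2100-12"
    scenarios: tuple[str, ...] = DEFAULT_SCENARIOS
    trend_multipliers: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0)
    #: additive bias and extra noise SD (as multiples of the factor's own
    #: noise SD) for each pseudo-ESM
    dataset_specs: tuple[tuple[str, float, float], ...] = (
        ("ESM-A", 0.0, 0.6),
        ("ESM-B", 0.4, 1.2),
    )
    ar1: float = 0.3
    noise_frac: float = 0.10
    #: generating factor subset per region band; 'default' covers the rest
    region_combos: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: {"default": ("SM", "CO2")}
    )
    link: str = "linear"

    def __post_init__(self) -> None:
        if self.noise_frac < 0:
            raise ArgumentError("noise fraction must be nonnegative")
        if len(self.scenarios) != len(self.trend_multipliers):
            raise ArgumentError("one trend multiplier per scenario required")

    def grid(self) -> Grid:
        res = 180.0 / self.n_lat
        lats = -90 + res * (np.arange(self.n_lat) + 0.5)
        lons = -180 + (360.0 / self.n_lon) * (np.arange(self.n_lon) + 0.5)
        return Grid(lats=lats, lons=lons, resolution=res)

    def hist_times(self) -> pd.DatetimeIndex:
        return pd.period_range(self.hist_start, self.hist_end, freq="M").to_timestamp()

    def scen_times(self) -> pd.DatetimeIndex:
        idx = pd.period_range(self.scen_start, self.scen_end, freq="M").to_timestamp()
        if len(idx) == 0:
            raise ArgumentError("empty scenario window")
        return idx


@dataclass
class GroundTruth:
    """Everything needed to regenerate the noise-free LAI exactly."""

    region_combos: dict[str, tuple[str, ...]]
    coefficients: dict[str, dict[str, float]]
    intercept: float
    link: str
    seed: int
    band_of_row: np.ndarray  # region-band key per latitude row


@dataclass
class SimulatedClimate:
    """Pseudo-ESM bundles plus the underlying noise-free factor truth."""

    historical: list[DatasetBundle]
    scenarios: dict[str, list[DatasetBundle]]
    truth_historical: DatasetBundle
    truth_scenarios: dict[str, DatasetBundle]
    config: SynthConfig


def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    eps = rng.standard_normal(n) * sd * np.sqrt(max(1 - phi**2, 1e-12))
    out = np.empty(n)
    out[0] = rng.standard_normal() * sd
    for t in range(1, n):
        out[t] = phi * out[t - 1] + eps[t]
    return out


def _factor_truth(
    factor: str,
    grid: Grid,
    times: pd.DatetimeIndex,
    years_since_hist_start: np.ndarray,
    trend_multiplier: float,
    hist_years_span: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Noise-free-ish shared truth field (the AR(1) weather is part of the
    truth; dataset-specific noise is added on top)."""
    p = _FACTOR_PARAMS[factor]
    lat_r = np.deg2rad(grid.lats)
    base = p["base"] + p["lat_grad"] * np.abs(np.sin(lat_r))  # (nlat,)
    month = times.month.to_numpy()
    # hemisphere-phased seasonal cycle
    phase = np.cos(2 * np.pi * (month - 7) / 12.0)  # peaks in July
    seas = p["amp"] * np.sin(lat_r)[None, :] * phase[:, None]  # (t, nlat)
    # trend: continuous across the historical/scenario boundary
    tyr = years_since_hist_start
    if trend_multiplier == 1.0:
        trend = p["trend"] * tyr
    else:
        trend = p["trend"] * (
            hist_years_span + trend_multiplier * (tyr - hist_years_span)
        )
    weather = _ar1(rng, len(times), 0.3, p["sd"])
    static = 0.1 * p["sd"] * rng.standard_normal(grid.shape)  # cell texture
    vals = (
        base[None, :, None]
        + seas[:, :, None]
        + (trend + weather)[:, None, None]
        + static[None, :, :]
    )
    return vals


def _years_since(times: pd.DatetimeIndex, origin: pd.Timestamp) -> np.ndarray:
    return (
        (times.year - origin.year) + (times.month - origin.month) / 12.0
    ).to_numpy(dtype=float)


def simulate_factor_bundles(config: SynthConfig) -> SimulatedClimate:
    """Generate the pseudo-ESM factor bundles for history and all scenarios."""
    grid = config.grid()
    hist_times = config.hist_times()
    scen_times = config.scen_times()
    origin = hist_times[0]
    hist_span = _years_since(hist_times, origin)[-1]
    root = np.random.default_rng(config.seed)
    truth_rngs = {f: np.random.default_rng(root.integers(2**31)) for f in FACTORS}
    ds_rngs = {
        ds_id: np.random.default_rng(root.integers(2**31))
        for ds_id, _, _ in config.dataset_specs
    }

    def build_truth(times, mult) -> DatasetBundle:
        factors = {}
        for f in FACTORS:
            rng = np.random.default_rng(truth_rngs[f].integers(2**31))
            vals = _factor_truth(
                f, grid, times, _years_since(times, origin), mult, hist_span, rng
            )
            factors[f] = DataCube(
                variable=f,
                units=_FACTOR_PARAMS[f]["units"],
                times=times,
                grid=grid,
                values=vals,
            )
        return DatasetBundle(dataset_id="TRUTH", factors=factors)

    truth_hist = build_truth(hist_times, 1.0)
    truth_scen = {
        s: build_truth(scen_times, m)
        for s, m in zip(config.scenarios, config.trend_multipliers)
    }

    def observe(truth: DatasetBundle, ds_id, bias, noise_mult, rng) -> DatasetBundle:
        factors = {}
        for f, cube in truth.factors.items():
            p = _FACTOR_PARAMS[f]
            noise = _ar1(rng, len(cube.times), config.ar1, noise_mult * p["sd"])
            vals = cube.values + bias * p["sd"] + noise[:, None, None]
            factors[f] = cube.copy_with(values=vals)
        return DatasetBundle(dataset_id=ds_id, factors=factors)

    historical = []
    scen_bundles: dict[str, list[DatasetBundle]] = {s: [] for s in config.scenarios}
    for ds_id, bias, noise_mult in config.dataset_specs:
        rng = ds_rngs[ds_id]
        historical.append(observe(truth_hist, ds_id, bias, noise_mult, rng))
        for s in config.scenarios:
            scen_bundles[s].append(observe(truth_scen[s], ds_id, bias, noise_mult, rng))
    return SimulatedClimate(
        historical=historical,
        scenarios=scen_bundles,
        truth_historical=truth_hist,
        truth_scenarios=truth_scen,
        config=config,
    )


def _band_key(lat: float, combos: Mapping[str, tuple[str, ...]]) -> str:
    if 60 <= lat <= 90 and "N-High" in combos:
        return "N-High"
    if 30 <= lat < 60 and "N-Mid" in combos:
        return "N-Mid"
    if -30 <= lat < 30 and "Trop" in combos:
        return "Trop"
    if -60 <= lat < -30 and "S-Mid" in combos:
        return "S-Mid"
    return "default"


def simulate_lai(
    climate: SimulatedClimate, config: SynthConfig | None = None
) -> tuple[DataCube, GroundTruth]:
    """Observed-LAI cube generated from the truth bundle's factor subset.

    LAI = link(standardised generating factors) + Gaussian noise whose SD is
    ``noise_frac`` of the noise-free signal SD, clipped at zero. The link is
    linear by default; ``link="quadratic"`` adds a squared term in the first
    generating factor.
    """
    config = config or climate.config
    if config.link not in ("linear", "quadratic"):
        raise ArgumentError(f"unknown link {config.link!r}")
    truth = climate.truth_historical
    times = truth.times
    grid = truth.grid
    rng = np.random.default_rng(config.seed + 777)
    combos = dict(config.region_combos)
    if "default" not in combos:
        combos["default"] = ("SM", "CO2")
    band_of_row = np.array([_band_key(lat, combos) for lat in grid.lats])

    # per-cell standardisation over the historical truth: LAI responds to each
    # factor's local temporal anomalies, not to its spatial climatology
    stats_ = {}
    for f in FACTORS:
        v = truth.factors[f].values
        mu = v.mean(axis=0)
        sd = v.std(axis=0)
        stats_[f] = (mu, np.where(sd == 0, 1.0, sd))
    coefficients: dict[str, dict[str, float]] = {}
    for band, members in combos.items():
        bad = set(members) - set(FACTORS)
        if bad:
            raise ArgumentError(f"unknown generating factors {sorted(bad)}")
        coefficients[band] = {m: 1.0 / np.sqrt(len(members)) for m in members}

    intercept = 2.0
    signal = np.zeros((len(times),) + grid.shape)
    for row, band in enumerate(band_of_row):
        for m, c in coefficients[band].items():
            mu, sd = stats_[m]
            z = (truth.factors[m].values[:, row, :] - mu[row, :]) / sd[row, :]
            signal[:, row, :] += c * z
            if config.link == "quadratic" and m == list(coefficients[band])[0]:
                signal[:, row, :] += 0.3 * c * z**2
    signal += intercept
    noise_sd = config.noise_frac * signal.std()
    lai = np.clip(signal + rng.standard_normal(signal.shape) * noise_sd, 0.0, None)
    cube = DataCube(
        variable="LAI", units="m2 m-2", times=times, grid=grid, values=lai
    )
    gt = GroundTruth(
        region_combos={k: tuple(v) for k, v in combos.items()},
        coefficients=coefficients,
        intercept=intercept,
        link=config.link,
        seed=config.seed,
        band_of_row=band_of_row,
    )
    return cube, gt


def simulate_daily_lai(
    config: SynthConfig,
    n_months: int = 3,
    n_lat: int = 4,
    n_lon: int = 6,
    start: str = "2000-01",
) -> tuple[DataCube, DataCube]:
    """Daily LAI whose per-month maximum is known by construction.

    Returns (daily cube, expected monthly-maximum cube). Roughly 10% of days
    are masked (never the day carrying the maximum), and the second month of
    the first cell is fully masked to exercise mask propagation.
    """
    rng = np.random.default_rng(config.seed + 1234)
    res = 180.0 / n_lat
    grid = Grid(
        lats=-90 + res * (np.arange(n_lat) + 0.5),
        lons=-180 + (360.0 / n_lon) * (np.arange(n_lon) + 0.5),
        resolution=res,
    )
    months = pd.period_range(start, periods=n_months, freq="M")
    daily_times = pd.date_range(
        months[0].to_timestamp(), months[-1].to_timestamp(how="end").normalize(), freq="D"
    )
    daily = np.empty((len(daily_times),) + grid.shape)
    monthly = np.empty((n_months,) + grid.shape)
    month_of_day = pd.PeriodIndex(daily_times, freq="M")
    for mi, per in enumerate(months):
        idx = np.flatnonzero(month_of_day == per)
        ndays = len(idx)
        maxima = rng.uniform(1.0, 4.0, size=grid.shape)
        monthly[mi] = maxima
        max_day = rng.integers(0, ndays, size=grid.shape)
        for k, day in enumerate(idx):
            drop = rng.uniform(0.1, 0.9, size=grid.shape)
            vals = np.where(max_day == k, maxima, maxima - drop)
            masked = (rng.random(grid.shape) < 0.1) & (max_day != k)
            daily[day] = np.where(masked, np.nan, vals)
        if mi == 1:  # fully masked month at one cell
            daily[idx, 0, 0] = np.nan
            monthly[mi, 0, 0] = np.nan
    daily_cube = DataCube(
        variable="LAI", units="m2 m-2", times=daily_times, grid=grid, values=daily
    )
    expected = DataCube(
        variable="LAI",
        units="m2 m-2",
        times=pd.DatetimeIndex([p.to_timestamp() for p in months]),
        grid=grid,
        values=monthly,
    )
    return daily_cube, expected


@dataclass
class ThreeProducts:
    """Three pseudo-LAI products plus the shared base field they perturb."""

    products: list[DataCube]
    base: DataCube
    perturbation_sd: float


def simulate_three_products(
    config: SynthConfig,
    n_months: int = 12,
    perturbation_sd: float = 0.1,
) -> ThreeProducts:
    """Three monthly LAI products at mixed native resolutions.

    The underlying field is linear in latitude and longitude (so bilinear
    regridding is exact); each product samples it on its own grid and adds
    seeded noise of SD ``perturbation_sd`` (0 gives three exact copies).
    The base cube is on the config grid.
    """
    rng = np.random.default_rng(config.seed + 4321)
    times = pd.period_range("2000-01", periods=n_months, freq="M").to_timestamp()
    seasonal = 0.3 * np.cos(2 * np.pi * (times.month.to_numpy() - 7) / 12.0)

    def field_on(grid: Grid) -> np.ndarray:
        lat, lon = np.meshgrid(grid.lats, grid.lons, indexing="ij")
        base2d = 2.0 + 0.01 * lat + 0.002 * lon
        return base2d[None, :, :] + seasonal[:, None, None]

    base_grid = config.grid()
    grids = [base_grid]
    for factor in (2, 3):  # finer native grids for the other two products
        res = base_grid.resolution / factor
        lats = -90 + res * (np.arange(config.n_lat * factor) + 0.5)
        lons = -180 + (360.0 / (config.n_lon * factor)) * (
            np.arange(config.n_lon * factor) + 0.5
        )
        grids.append(Grid(lats=lats, lons=lons, resolution=res))
    products = []
    for i, g in enumerate(grids):
        vals = field_on(g)
        if perturbation_sd > 0:
            vals = vals + rng.standard_normal(vals.shape) * perturbation_sd
        products.append(
            DataCube(
                variable="LAI", units="m2 m-2", times=times, grid=g, values=vals
            )
        )
    base = DataCube(
        variable="LAI",
        units="m2 m-2",
        times=times,
        grid=base_grid,
        values=field_on(base_grid),
    )
    return ThreeProducts(
        products=products, base=base, perturbation_sd=perturbation_sd
    )
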
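"""Monotone-trend statistics and greening-rate arithmetic.

Trends are assessed with the nonparametric Mann-Kendall test — the sign
statistic S = sum over pairs i<j of sign(x_j - x_i), with the tie-corrected
variance and a continuity-corrected normal deviate Z — and rates with Sen's
slope, the median of all pairwise slopes. Grid-cell trend maps, area-weighted
greening/browning fractions over vegetated cells, per-period rates and
future-vs-historical rate ratios are built on these two primitives.

Monthly series are annualised (calendar-year means) before trend fitting, so
reported slopes are per year.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ArgumentError, EmptyRegionError, SampleSizeError
from .io_preprocess import DataCube


@dataclass(frozen=True)
class TrendResult:
    """Mann-Kendall statistics and Sen's slope for one series."""

    S: int
    var_S: float
    Z: float
    p: float
    slope: float
    significant: bool
    alpha: float = 0.05


@dataclass(frozen=True)
class RateChange:
    """Future rate relative to a historical rate (x100 = percent)."""

    rate_hist: float
    rate_future: float
    percent: float
    times: float


def _clean(series) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(series, pd.Series):
        t = np.arange(len(series), dtype=float)
        x = series.to_numpy(dtype=float)
    else:
        x = np.asarray(series, dtype=float)
        t = np.arange(len(x), dtype=float)
    keep = ~np.isnan(x)
    return x[keep], t[keep]


def mann_kendall(series, alpha: float = 0.05) -> TrendResult:
    """Mann-Kendall monotone-trend test on a (possibly masked) series.

    S counts concordant minus discordant pairs; ties reduce the variance via
    the standard correction; Z applies the +/-1 continuity correction; p is
    the two-sided normal tail probability.
    """
    x, t = _clean(series)
    n = len(x)
    if n < 4:
        raise SampleSizeError(f"Mann-Kendall needs >= 4 values, got {n}")
    diff = np.sign(x[None, :] - x[:, None])
    S = int(np.triu(diff, k=1).sum())
    _, counts = np.unique(x, return_counts=True)
    tie_term = float(np.sum(counts * (counts - 1) * (2 * counts + 5)))
    var_S = (n * (n - 1) * (2 * n + 5) - tie_term) / 18.0
    if S > 0:
        Z = (S - 1) / np.sqrt(var_S) if var_S > 0 else 0.0
    elif S < 0:
        Z = (S + 1) / np.sqrt(var_S) if var_S > 0 else 0.0
    else:
        Z = 0.0
    p = float(2 * stats.norm.sf(abs(Z)))
    slope = sen_slope(x, t)
    return TrendResult(
        S=S, var_S=var_S, Z=float(Z), p=p, slope=slope,
        significant=p < alpha, alpha=alpha,
    )


def sen_slope(series, times=None) -> float:
    """Sen's slope: the median of all pairwise slopes (x_j - x_i)/(t_j - t_i)."""
    x = np.asarray(series, dtype=float)
    if times is None:
        t = np.arange(len(x), dtype=float)
    else:
        t = np.asarray(times, dtype=float)
    keep = ~np.isnan(x)
    x, t = x[keep], t[keep]
    if len(x) < 2:
        raise SampleSizeError(f"Sen's slope needs >= 2 values, got {len(x)}")
    if len(np.unique(t)) < 2:
        raise ArgumentError("degenerate time axis: all times equal")
    res = stats.theilslopes(x, t)
    return float(res.slope)


def ols_slope(series, times=None) -> float:
    """Ordinary least-squares slope, as an alternative rate estimator."""
    x = np.asarray(series, dtype=float)
    t = np.arange(len(x), dtype=float) if times is None else np.asarray(times, float)
    keep = ~np.isnan(x)
    if keep.sum() < 2:
        raise SampleSizeError("OLS slope needs >= 2 values")
    return float(np.polyfit(t[keep], x[keep], 1)[0])


def annualize(series: pd.Series) -> pd.Series:
    """Calendar-year means of a monthly series (index becomes the year)."""
    grouped = series.groupby(series.index.year).mean()
    grouped.index.name = "year"
    return grouped


def trend_map(cube: DataCube, alpha: float = 0.05) -> dict[str, np.ndarray]:
    """Cell-wise Mann-Kendall + Sen's slope over an annual cube.

    Returns arrays ``slope``, ``Z``, ``p``, ``S`` and boolean ``significant``
    on the cube grid; cells with fewer than 4 valid years are NaN-masked.
    """
    nt = len(cube.times)
    if nt < 4:
        raise SampleSizeError("trend map needs >= 4 annual slices")
    nlat, nlon = cube.grid.shape
    out = {
        "slope": np.full((nlat, nlon), np.nan),
        "Z": np.full((nlat, nlon), np.nan),
        "p": np.full((nlat, nlon), np.nan),
        "S": np.full((nlat, nlon), np.nan),
        "significant": np.zeros((nlat, nlon), dtype=bool),
    }
    for i in range(nlat):
        for j in range(nlon):
            x = cube.values[:, i, j]
            if (~np.isnan(x)).sum() < 4:
                continue
            tr = mann_kendall(x, alpha=alpha)
            out["slope"][i, j] = tr.slope
            out["Z"][i, j] = tr.Z
            out["p"][i, j] = tr.p
            out["S"][i, j] = tr.S
            out["significant"][i, j] = tr.significant
    return out


def greening_fraction(
    tmap: Mapping[str, np.ndarray],
    lats: np.ndarray,
    veg_mask: np.ndarray | None = None,
) -> dict[str, float]:
    """Area-weighted greening/browning percentages over vegetated cells.

    Greening means a positive Sen's slope; 'significant' additionally
    requires p below the map's alpha. Weights are cos(latitude). Returned
    percentages are out of the vegetated area with a defined trend.
    """
    slope = tmap["slope"]
    sig = tmap["significant"]
    valid = ~np.isnan(slope)
    if veg_mask is not None:
        valid &= veg_mask
    if not valid.any():
        raise EmptyRegionError("no vegetated cells with a defined trend")
    w = np.cos(np.deg2rad(np.asarray(lats, float)))[:, None]
    w2d = np.broadcast_to(w, slope.shape)
    total = float((w2d * valid).sum())

    def pct(cond):
        return 100.0 * float((w2d * (valid & cond)).sum()) / total

    return {
        "greening": pct(slope > 0),
        "significant_greening": pct((slope > 0) & sig),
        "browning": pct(slope < 0),
        "significant_browning": pct((slope < 0) & sig),
    }


def period_rates(
    annual: pd.Series,
    periods: Sequence[tuple[int, int]] = (
        (2015, 2100),
        (2021, 2040),
        (2041, 2060),
        (2061, 2080),
        (2081, 2100),
    ),
    estimator: str = "sen",
) -> dict[tuple[int, int], float]:
    """Trend rate (units per year) within each (start, end) year window."""
    est = {"sen": sen_slope, "ols": ols_slope}.get(estimator)
    if est is None:
        raise ArgumentError(f"unknown estimator {estimator!r}")
    years = np.asarray(annual.index, dtype=int)
    out: dict[tuple[int, int], float] = {}
    for start, end in periods:
        sel = (years >= start) & (years <= end)
        if sel.sum() < 2:
            raise ArgumentError(
                f"period {start}-{end} has fewer than 2 covered years"
            )
        out[(start, end)] = est(annual.to_numpy()[sel], years[sel].astype(float))
    return out


def rate_ratio(rate_hist: float, rate_future: float) -> RateChange:
    """Future rate as a percentage (and multiple) of the historical rate."""
    if rate_hist == 0:
        raise ArgumentError(
            "historical rate is zero; the rate ratio is undefined"
        )
    percent = 100.0 * rate_future / rate_hist
    return RateChange(
        rate_hist=rate_hist,
        rate_future=rate_future,
        percent=percent,
        times=percent / 100.0,
    )
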
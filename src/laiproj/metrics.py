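"""The DISO composite model-skill metric.

A model's skill is summarised by three indicators — the coefficient of
determination R^2, the mean absolute error and the root-mean-square error —
and collapsed into a single score: the Euclidean distance between the
normalised indicator vector (R^2, norMAE, norRMSE) and the ideal point
(1, 0, 0),

    DISO = sqrt((R^2 - 1)^2 + norMAE^2 + norRMSE^2).

Smaller is better; a perfect simulation scores exactly zero. MAE and RMSE are
normalised by the mean absolute observation over the evaluation window, so
DISO is dimensionless and comparable across variables. A min-max
normalisation across a candidate set is available as an alternative for the
error terms (``normalization="minmax"`` in :func:`normalize_indicator_sets`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ArgumentError, DegenerateObservationsError, SampleSizeError


@dataclass(frozen=True)
class IndicatorSet:
    """R^2, MAE, RMSE and the normalised error terms for one model."""

    r2: float
    mae: float
    rmse: float
    nor_mae: float
    nor_rmse: float
    n: int


@dataclass(frozen=True)
class DisoScore:
    """A DISO distance together with the indicators it was computed from."""

    value: float
    indicators: IndicatorSet | None = None

    def __lt__(self, other: "DisoScore") -> bool:
        return self.value < other.value


def _paired(sim, obs) -> tuple[np.ndarray, np.ndarray]:
    sim = np.asarray(sim, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if sim.shape != obs.shape:
        raise ArgumentError(
            f"sim and obs lengths differ: {sim.shape} vs {obs.shape}"
        )
    keep = ~(np.isnan(sim) | np.isnan(obs))
    return sim[keep], obs[keep]


def compute_indicators(sim, obs, r2_kind: str = "nse") -> IndicatorSet:
    """Skill indicators of ``sim`` against ``obs`` after pairwise masking.

    ``r2_kind`` selects the R^2 definition: ``"nse"`` (1 - SS_res/SS_tot; may
    be negative for worse-than-mean models, which correctly inflates DISO) or
    ``"pearson2"`` (squared Pearson correlation).
    """
    sim, obs = _paired(sim, obs)
    n = len(obs)
    if n < 2:
        raise SampleSizeError(f"need >= 2 paired samples, got {n}")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise DegenerateObservationsError("observations are constant")
    err = sim - obs
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    if r2_kind == "nse":
        r2 = 1.0 - float(np.sum(err**2)) / ss_tot
    elif r2_kind == "pearson2":
        r2 = float(np.corrcoef(sim, obs)[0, 1]) ** 2
    else:
        raise ArgumentError(f"unknown r2_kind {r2_kind!r}")
    denom = float(np.mean(np.abs(obs)))
    if denom == 0.0:
        raise DegenerateObservationsError("mean(|obs|) is zero; cannot normalise")
    return IndicatorSet(
        r2=r2, mae=mae, rmse=rmse, nor_mae=mae / denom, nor_rmse=rmse / denom, n=n
    )


def diso(indicators: IndicatorSet) -> DisoScore:
    """Euclidean distance of (R^2, norMAE, norRMSE) from the ideal (1, 0, 0)."""
    value = math.sqrt(
        (indicators.r2 - 1.0) ** 2
        + indicators.nor_mae**2
        + indicators.nor_rmse**2
    )
    return DisoScore(value=value, indicators=indicators)


def diso_from_series(sim, obs, r2_kind: str = "nse") -> DisoScore:
    """Convenience composition: indicators then DISO in one call."""
    return diso(compute_indicators(sim, obs, r2_kind=r2_kind))


def normalize_indicator_sets(sets: Sequence[IndicatorSet]) -> list[IndicatorSet]:
    """Re-normalise the error terms of a candidate set by min-max scaling.

    Alternative to the per-model mean(|obs|) normalisation: each model's MAE
    and RMSE are rescaled to [0, 1] across the candidates. With a single
    candidate (or zero spread) the scaled errors are 0.
    """
    if not sets:
        raise ArgumentError("empty indicator list")
    maes = np.array([s.mae for s in sets])
    rmses = np.array([s.rmse for s in sets])

    def scale(v, lo, hi):
        return 0.0 if hi == lo else (v - lo) / (hi - lo)

    return [
        IndicatorSet(
            r2=s.r2,
            mae=s.mae,
            rmse=s.rmse,
            nor_mae=scale(s.mae, maes.min(), maes.max()),
            nor_rmse=scale(s.rmse, rmses.min(), rmses.max()),
            n=s.n,
        )
        for s in sets
    ]


def indicators_table(scores: dict[str, DisoScore]) -> pd.DataFrame:
    """Tabulate DISO scores and indicators keyed by model identifier."""
    rows = []
    for key, sc in scores.items():
        ind = sc.indicators
        rows.append(
            {
                "model": key,
                "diso": sc.value,
                "r2": ind.r2 if ind else np.nan,
                "mae": ind.mae if ind else np.nan,
                "rmse": ind.rmse if ind else np.nan,
                "nor_mae": ind.nor_mae if ind else np.nan,
                "nor_rmse": ind.nor_rmse if ind else np.nan,
                "n": ind.n if ind else 0,
            }
        )
    return pd.DataFrame(rows).set_index("model")
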
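"""Exhaustive optimal-model selection and scenario projection.

For one region, the engine crosses every nonempty subset of the five climate
factors (31 combinations) with every candidate climate dataset (two ESMs plus
their MME and DISO-W combinations, 124 data choices) and every algorithm
(six, giving 744 candidate models), scores each candidate with the DISO
metric on a chronological holdout, and then selects hierarchically:

1. per (combination, algorithm), the best dataset        -> 186 models;
2. per combination, the best algorithm                    -> 31 models;
3. overall, the minimum-DISO model                        -> the optimum.

The regional optimum is refit on the full historical window and driven with
scenario climate to project the target variable to the end of the horizon.
All ties break deterministically: fewer factors first, then canonical
algorithm order, then dataset order.
"""

from __future__ import annotations

import itertools
import math
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import learners
from .ensembles import (
    DISOW_ID,
    MME_ID,
    EnsembleWeights,
    combine_frames,
    diso_weights,
    mme_frames,
)
from .errors import AlignmentError, ArgumentError, ContractError
from .io_preprocess import FACTORS
from .metrics import DisoScore, diso_from_series


@dataclass(frozen=True)
class FactorCombination:
    """A nonempty ordered subset of the climate factors, with its 1-based
    position in the canonical enumeration (by size, then positionally)."""

    members: tuple[str, ...]
    index: int

    def __post_init__(self) -> None:
        if not self.members:
            raise ArgumentError("factor combination must be nonempty")
        if len(set(self.members)) != len(self.members):
            raise ArgumentError("duplicate factors in combination")


def enumerate_combinations(
    factors: Sequence[str] = FACTORS,
) -> list[FactorCombination]:
    """All 2^k - 1 nonempty subsets, ordered by size then position.

    For the five canonical factors this is the standard 31-row enumeration:
    singletons 1-5, pairs 6-15, triples 16-25, quadruples 26-30, the full
    quintuple 31.
    """
    factors = tuple(factors)
    if not factors:
        raise ArgumentError("empty factor list")
    if len(factors) > 10:
        raise ArgumentError("more than 10 factors is not supported")
    combos: list[FactorCombination] = []
    idx = 1
    for size in range(1, len(factors) + 1):
        for members in itertools.combinations(factors, size):
            combos.append(FactorCombination(members=members, index=idx))
            idx += 1
    return combos


@dataclass(frozen=True)
class ModelSpec:
    """One point of the sweep: region x dataset x combination x algorithm."""

    region: str
    dataset_id: str
    combination: FactorCombination
    algorithm_id: str


@dataclass
class EvaluatedModel:
    """A swept model with its fitted state (None on fit failure) and score."""

    spec: ModelSpec
    model: learners.FittedModel | None
    score: DisoScore


@dataclass
class SelectionResult:
    """The full sweep plus the hierarchical selections for one region."""

    region: str
    all_models: list[EvaluatedModel]
    per_combo_algo_best: list[EvaluatedModel]
    per_combo_best: list[EvaluatedModel]
    optimum: EvaluatedModel
    dataset_order: tuple[str, ...]
    algorithm_order: tuple[str, ...]
    weights_by_algorithm: dict[str, EnsembleWeights] = field(default_factory=dict)
    n_failures: int = 0

    def to_frame(self, which: str = "all") -> pd.DataFrame:
        models = {
            "all": self.all_models,
            "per_combo_algo": self.per_combo_algo_best,
            "per_combo": self.per_combo_best,
            "optimum": [self.optimum],
        }[which]
        rows = []
        for em in models:
            ind = em.score.indicators
            rows.append(
                {
                    "region": em.spec.region,
                    "combo_index": em.spec.combination.index,
                    "factors": "+".join(em.spec.combination.members),
                    "dataset": em.spec.dataset_id,
                    "algorithm": em.spec.algorithm_id,
                    "diso": em.score.value,
                    "r2": ind.r2 if ind else np.nan,
                    "rmse": ind.rmse if ind else np.nan,
                }
            )
        return pd.DataFrame(rows)


def _model_seed(master_seed: int, spec: ModelSpec) -> int:
    key = f"{master_seed}|{spec.region}|{spec.dataset_id}|{spec.combination.index}|{spec.algorithm_id}"
    return zlib.crc32(key.encode()) % (2**31)


def _split_index(n: int, split: float) -> int:
    k = int(math.floor(n * split))
    return min(max(k, 2), n - 2)


def _fit_and_score(
    spec: ModelSpec,
    frame: pd.DataFrame,
    obs: pd.Series,
    split: float,
    master_seed: int,
    protocol: str,
) -> EvaluatedModel:
    members = list(spec.combination.members)
    missing = [m for m in members if m not in frame.columns]
    if missing:
        raise ArgumentError(f"dataset {spec.dataset_id!r} lacks factors {missing}")
    X = frame[members]
    seed = _model_seed(master_seed, spec)
    lspec = learners.LearnerSpec(algorithm_id=spec.algorithm_id, seed=seed)
    try:
        if protocol == "holdout":
            k = _split_index(len(X), split)
            model = learners.fit(
                lspec,
                X.iloc[:k],
                obs.iloc[:k],
                factor_names=members,
                training_window=(obs.index[0], obs.index[k - 1]),
            )
            ctx = X.iloc[:k] if spec.algorithm_id in learners.SEQUENCE_ALGORITHMS else None
            sim = learners.predict(model, X.iloc[k:], context=ctx)
            score = diso_from_series(sim, obs.iloc[k:].to_numpy())
        elif protocol == "insample":
            model = learners.fit(lspec, X, obs, factor_names=members)
            sim = learners.predict(model, X)
            score = diso_from_series(sim, obs.to_numpy())
        else:
            raise ArgumentError(f"unknown evaluation protocol {protocol!r}")
    except (ArgumentError, AlignmentError):
        raise  # misuse of the sweep itself, not a model-level failure
    except Exception:
        return EvaluatedModel(spec=spec, model=None, score=DisoScore(math.inf))
    return EvaluatedModel(spec=spec, model=model, score=score)


def evaluate_all(
    obs: pd.Series,
    datasets: Mapping[str, pd.DataFrame] | None,
    algorithms: Sequence[str] = learners.ALGORITHMS,
    region: str = "Global",
    combinations: Sequence[FactorCombination] | None = None,
    split: float = 0.8,
    master_seed: int = 0,
    protocol: str = "holdout",
    datasets_by_algorithm: Mapping[str, Mapping[str, pd.DataFrame]] | None = None,
) -> tuple[list[EvaluatedModel], int]:
    """Score every (combination, dataset, algorithm) model for one region.

    ``datasets`` maps dataset id to an aligned factor DataFrame; when the
    dataset pool depends on the algorithm (the DISO-W dataset does),
    ``datasets_by_algorithm`` supersedes it. Individual fit failures score
    +inf rather than aborting the sweep; the failure count is returned.
    """
    if datasets_by_algorithm is None:
        if datasets is None:
            raise ArgumentError("either datasets or datasets_by_algorithm required")
        datasets_by_algorithm = {a: datasets for a in algorithms}
    first = next(iter(datasets_by_algorithm.values()))
    factors = [f for f in FACTORS if f in next(iter(first.values())).columns]
    combos = list(combinations) if combinations is not None else enumerate_combinations(factors)
    results: list[EvaluatedModel] = []
    failures = 0
    for combo in combos:
        for algo in algorithms:
            for ds_id, frame in datasets_by_algorithm[algo].items():
                if not frame.index.equals(obs.index):
                    raise ArgumentError(
                        f"dataset {ds_id!r} is not aligned with the observations"
                    )
                spec = ModelSpec(
                    region=region,
                    dataset_id=ds_id,
                    combination=combo,
                    algorithm_id=algo,
                )
                em = _fit_and_score(spec, frame, obs, split, master_seed, protocol)
                if not math.isfinite(em.score.value):
                    failures += 1
                results.append(em)
    return results, failures


def _ordered_min(
    candidates: list[EvaluatedModel], key_orders: list
) -> EvaluatedModel:
    """Minimum DISO; ties broken by the provided ordering functions."""
    return min(candidates, key=lambda em: (em.score.value, *[k(em) for k in key_orders]))


def best_per_combo_algo(
    all_models: Sequence[EvaluatedModel],
    dataset_order: Sequence[str],
) -> list[EvaluatedModel]:
    """Best dataset per (combination, algorithm): the 186-model table."""
    ds_rank = {d: i for i, d in enumerate(dataset_order)}
    grouped: dict[tuple[int, str], list[EvaluatedModel]] = {}
    for em in all_models:
        grouped.setdefault(
            (em.spec.combination.index, em.spec.algorithm_id), []
        ).append(em)
    out = []
    for key in sorted(
        grouped,
        key=lambda k: (k[0], learners.ALGORITHMS.index(k[1]) if k[1] in learners.ALGORITHMS else 99),
    ):
        out.append(
            _ordered_min(grouped[key], [lambda em: ds_rank.get(em.spec.dataset_id, 99)])
        )
    return out


def best_per_combo(
    per_combo_algo_best: Sequence[EvaluatedModel],
    algorithm_order: Sequence[str] = learners.ALGORITHMS,
) -> list[EvaluatedModel]:
    """Best algorithm per combination: the 31-model table."""
    algo_rank = {a: i for i, a in enumerate(algorithm_order)}
    grouped: dict[int, list[EvaluatedModel]] = {}
    for em in per_combo_algo_best:
        grouped.setdefault(em.spec.combination.index, []).append(em)
    return [
        _ordered_min(grouped[idx], [lambda em: algo_rank.get(em.spec.algorithm_id, 99)])
        for idx in sorted(grouped)
    ]


def select_optimum(
    per_combo_best: Sequence[EvaluatedModel],
    algorithm_order: Sequence[str] = learners.ALGORITHMS,
    dataset_order: Sequence[str] = (),
) -> EvaluatedModel:
    """The regional optimum: global minimum DISO.

    Exact ties prefer fewer factors, then canonical algorithm order, then
    dataset order, so the choice is deterministic.
    """
    if not per_combo_best:
        raise ArgumentError("empty model table")
    algo_rank = {a: i for i, a in enumerate(algorithm_order)}
    ds_rank = {d: i for i, d in enumerate(dataset_order)}
    return _ordered_min(
        list(per_combo_best),
        [
            lambda em: len(em.spec.combination.members),
            lambda em: algo_rank.get(em.spec.algorithm_id, 99),
            lambda em: ds_rank.get(em.spec.dataset_id, 99),
        ],
    )


def project(
    optimum: EvaluatedModel,
    scenario_frame: pd.DataFrame,
    context: pd.DataFrame | None = None,
) -> pd.Series:
    """Drive the (refit) optimum with scenario climate over its horizon.

    ``context`` supplies the historical factor rows preceding the horizon for
    sequence learners. Returns one value per horizon month.
    """
    if optimum.model is None:
        raise ContractError("optimum has no fitted model (fit failed)")
    members = list(optimum.spec.combination.members)
    missing = [m for m in members if m not in scenario_frame.columns]
    if missing:
        raise ContractError(f"scenario data lacks factors {missing}")
    ctx = None
    if optimum.spec.algorithm_id in learners.SEQUENCE_ALGORITHMS and context is not None:
        ctx = context[members]
    sim = learners.predict(optimum.model, scenario_frame[members], context=ctx)
    return pd.Series(sim, index=scenario_frame.index, name="LAI_projected")


@dataclass
class RegionOutcome:
    """run_region output: the selection plus per-scenario projections."""

    selection: SelectionResult
    refit_optimum: EvaluatedModel
    projections: dict[str, pd.Series]


def run_region(
    region: str,
    obs: pd.Series,
    esm_frames: Mapping[str, pd.DataFrame],
    scenario_frames: Mapping[str, Mapping[str, pd.DataFrame]] | None = None,
    algorithms: Sequence[str] = learners.ALGORITHMS,
    split: float = 0.8,
    master_seed: int = 0,
    protocol: str = "holdout",
    reference_combination: Sequence[str] | None = None,
) -> RegionOutcome:
    """The full per-region procedure: weights, sweep, selection, projection.

    ``esm_frames`` maps the candidate ESM dataset ids to aligned historical
    factor DataFrames; MME and DISO-W are built here. ``scenario_frames``
    maps scenario name -> ESM id -> future factor DataFrame. Inverse-DISO
    weights are computed per algorithm from a reference model fitted on each
    ESM with the full factor set (configurable via
    ``reference_combination``).
    """
    if len(esm_frames) < 2:
        raise ArgumentError("need at least two candidate ESM datasets")
    esm_ids = list(esm_frames)
    factors = [f for f in FACTORS if f in esm_frames[esm_ids[0]].columns]
    ref_members = tuple(reference_combination) if reference_combination else tuple(factors)
    combos = enumerate_combinations(factors)
    ref_combo = next(c for c in combos if c.members == ref_members)

    # Per-algorithm inverse-DISO weights from the reference models (Eq. 3
    # context: dataset l with algorithm i), then the DISO-W dataset per
    # algorithm; MME is algorithm-independent.
    mme_frame = mme_frames(esm_frames)
    weights_by_algorithm: dict[str, EnsembleWeights] = {}
    datasets_by_algorithm: dict[str, dict[str, pd.DataFrame]] = {}
    for algo in algorithms:
        ref_scores = {}
        for ds_id in esm_ids:
            spec = ModelSpec(
                region=region,
                dataset_id=ds_id,
                combination=ref_combo,
                algorithm_id=algo,
            )
            em = _fit_and_score(spec, esm_frames[ds_id], obs, split, master_seed, protocol)
            ref_scores[ds_id] = em.score
        if all(math.isfinite(s.value) for s in ref_scores.values()):
            w = diso_weights(ref_scores, context=(region, algo))
        else:  # degenerate: fall back to equal weights
            w = EnsembleWeights(
                weights={d: 1.0 / len(esm_ids) for d in esm_ids},
                context=(region, algo),
            )
        weights_by_algorithm[algo] = w
        disow_frame = combine_frames(esm_frames, w.weights)
        datasets_by_algorithm[algo] = {
            **{d: esm_frames[d] for d in esm_ids},
            MME_ID: mme_frame,
            DISOW_ID: disow_frame,
        }

    dataset_order = tuple(esm_ids) + (MME_ID, DISOW_ID)
    all_models, n_failures = evaluate_all(
        obs,
        None,
        algorithms=algorithms,
        region=region,
        combinations=combos,
        split=split,
        master_seed=master_seed,
        protocol=protocol,
        datasets_by_algorithm=datasets_by_algorithm,
    )
    table186 = best_per_combo_algo(all_models, dataset_order)
    table31 = best_per_combo(table186, algorithms)
    optimum = select_optimum(table31, algorithms, dataset_order)
    selection = SelectionResult(
        region=region,
        all_models=all_models,
        per_combo_algo_best=table186,
        per_combo_best=table31,
        optimum=optimum,
        dataset_order=dataset_order,
        algorithm_order=tuple(algorithms),
        weights_by_algorithm=weights_by_algorithm,
        n_failures=n_failures,
    )

    # Refit the optimum on the full historical window before projecting.
    members = list(optimum.spec.combination.members)
    hist_frame = datasets_by_algorithm[optimum.spec.algorithm_id][optimum.spec.dataset_id]
    seed = _model_seed(master_seed, optimum.spec)
    refit = learners.fit(
        learners.LearnerSpec(algorithm_id=optimum.spec.algorithm_id, seed=seed),
        hist_frame[members],
        obs,
        factor_names=members,
        training_window=(obs.index[0], obs.index[-1]),
    )
    refit_optimum = EvaluatedModel(spec=optimum.spec, model=refit, score=optimum.score)

    projections: dict[str, pd.Series] = {}
    if scenario_frames:
        for scen, per_ds in scenario_frames.items():
            ds = optimum.spec.dataset_id
            if ds in per_ds:
                frame = per_ds[ds]
            elif ds == MME_ID:
                frame = mme_frames(per_ds)
            elif ds == DISOW_ID:
                frame = combine_frames(
                    per_ds, weights_by_algorithm[optimum.spec.algorithm_id].weights
                )
            else:
                raise ContractError(f"scenario {scen!r} lacks dataset {ds!r}")
            projections[scen] = project(refit_optimum, frame, context=hist_frame)
    return RegionOutcome(
        selection=selection, refit_optimum=refit_optimum, projections=projections
    )
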
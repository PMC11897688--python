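"""Equal-weight (MME) and inverse-DISO weighted (DISO-W) dataset ensembles.

Candidate climate datasets (e.g. two earth-system models) are combined two
ways: the multi-model ensemble mean (MME), which weights members equally, and
DISO-W, which weights each dataset l by the reciprocal of its DISO score,

    w_l = (1 / DISO_l) / sum_k (1 / DISO_k),

so that better-performing datasets contribute more. The same weight is
applied to all five climate factors of a dataset. Weights live in a
(region, algorithm) context because the DISO feeding them comes from the
model fitted on that dataset with that algorithm in that region.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, ArgumentError
from .io_preprocess import DataCube, DatasetBundle
from .metrics import DisoScore

MME_ID = "MME"
DISOW_ID = "DISO-W"


@dataclass(frozen=True)
class EnsembleWeights:
    """Per-dataset weights w_l in a (region, algorithm) context; sum to 1."""

    weights: dict[str, float]
    context: tuple[str, str] | None = None  # (region, algorithm_id)

    def __post_init__(self) -> None:
        if not self.weights:
            raise ArgumentError("weights map is empty")
        vals = np.array(list(self.weights.values()), dtype=float)
        if (vals < 0).any():
            raise ArgumentError("weights must be nonnegative")
        if abs(vals.sum() - 1.0) > 1e-12:
            raise ArgumentError(f"weights must sum to 1, got {vals.sum()!r}")


def diso_weights(
    scores: Mapping[str, DisoScore | float],
    context: tuple[str, str] | None = None,
) -> EnsembleWeights:
    """Inverse-DISO weights, normalised to sum to 1.

    A DISO of exactly zero means a perfect dataset; in that limit the total
    weight is split equally among the zero-scoring datasets.
    """
    if not scores:
        raise ArgumentError("empty score map")
    vals = {
        k: (s.value if isinstance(s, DisoScore) else float(s))
        for k, s in scores.items()
    }
    if any(v < 0 for v in vals.values()):
        raise ArgumentError("DISO values must be nonnegative")
    zeros = [k for k, v in vals.items() if v == 0.0]
    if zeros:
        w = {k: (1.0 / len(zeros) if k in zeros else 0.0) for k in vals}
    else:
        inv = {k: 1.0 / v for k, v in vals.items()}
        total = sum(inv.values())
        w = {k: v / total for k, v in inv.items()}
    return EnsembleWeights(weights=w, context=context)


def _check_alignment(bundles: Sequence[DatasetBundle]) -> None:
    first = bundles[0]
    for b in bundles[1:]:
        if set(b.factors) != set(first.factors):
            raise AlignmentError("bundles carry different factor sets")
        if b.grid != first.grid:
            raise AlignmentError("bundle grids do not match")
        if not b.times.equals(first.times):
            raise AlignmentError("bundle time indexes do not match")


def combine_bundles(
    bundles: Sequence[DatasetBundle],
    weights: Sequence[float],
    dataset_id: str,
) -> DatasetBundle:
    """Weighted cell-wise combination of aligned bundles, factor by factor."""
    if len(bundles) != len(weights):
        raise ArgumentError("one weight per bundle required")
    _check_alignment(bundles)
    w = np.asarray(weights, dtype=float)
    factors: dict[str, DataCube] = {}
    for name, ref in bundles[0].factors.items():
        stack = np.stack([b.factors[name].values for b in bundles])
        combined = np.tensordot(w, stack, axes=(0, 0))
        factors[name] = ref.copy_with(values=combined)
    return DatasetBundle(dataset_id=dataset_id, factors=factors)


def mme(bundles: Sequence[DatasetBundle]) -> DatasetBundle:
    """Equal-weight multi-model ensemble mean of >= 2 aligned bundles."""
    if len(bundles) < 2:
        raise ArgumentError("MME needs at least two bundles")
    n = len(bundles)
    return combine_bundles(bundles, [1.0 / n] * n, MME_ID)


def diso_weighted_bundle(
    bundles: Sequence[DatasetBundle], weights: EnsembleWeights
) -> DatasetBundle:
    """DISO-W: each factor is sum_l w_l * x_l, cell-wise.

    ``weights`` must cover exactly the given bundles' dataset ids.
    """
    ids = [b.dataset_id for b in bundles]
    if set(ids) != set(weights.weights) or len(ids) != len(weights.weights):
        raise ArgumentError(
            f"weights keys {sorted(weights.weights)} do not match bundles {ids}"
        )
    return combine_bundles(bundles, [weights.weights[i] for i in ids], DISOW_ID)


def combine_frames(
    frames: Mapping[str, pd.DataFrame], weights: Mapping[str, float]
) -> pd.DataFrame:
    """The same weighted combination on regional-mean factor DataFrames.

    Regional averaging is linear, so combining the extracted series with the
    dataset weights equals extracting from the combined cubes.
    """
    if set(frames) != set(weights):
        raise ArgumentError("weights keys do not match frame keys")
    items = list(frames.items())
    first = items[0][1]
    for _, f in items[1:]:
        if not f.index.equals(first.index) or list(f.columns) != list(first.columns):
            raise AlignmentError("frames are not aligned")
    out = sum(weights[k] * f for k, f in items)
    return out


def mme_frames(frames: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    if len(frames) < 2:
        raise ArgumentError("MME needs at least two datasets")
    w = 1.0 / len(frames)
    return combine_frames(frames, {k: w for k in frames})


def save_weights(weights_by_context: Mapping, path) -> None:
    """Persist weights as JSON keyed by 'region/algorithm'."""
    payload = {
        "/".join(ctx): ew.weights for ctx, ew in weights_by_context.items()
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
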
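"""Six regression algorithm families behind one fit/predict contract.

The sweep crosses every factor combination and dataset with six learners:

* ``LR`` — ordinary least squares with intercept.
* ``SVR`` — RBF-kernel support vector regression on standardised inputs.
* ``RF`` — random forest (200 trees, fixed seed).
* ``CNN`` — a one-layer 1-D convolutional feature extractor over a sliding
  12-month window (16 seeded random filters, kernel 3, tanh, average pooling)
  with a closed-form ridge readout.
* ``LSTM`` — an echo-state recurrent network: a fixed seeded tanh recurrence
  (32 units, spectral radius 0.8) driven by the standardised factors, with a
  ridge readout on the hidden state.
* ``Transformer`` — one seeded random multi-head self-attention block
  (2 heads, model width 32, sinusoidal positions) over the 12-month window,
  with a ridge readout on the attended representation.

The three sequence learners train only their linear readout (their random
feature maps are fixed by the seed), which makes every learner exactly
deterministic under a fixed seed and keeps a full model sweep at desk scale
on one CPU. Tabular learners see only the current month's factors; sequence
learners see a lookback window and therefore need lookback context when
predicting beyond their training matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR as SkSVR

from .errors import ArgumentError, ContractError, SampleSizeError

#: Canonical algorithm identifiers, in canonical order.
ALGORITHMS: tuple[str, ...] = ("LR", "SVR", "RF", "CNN", "LSTM", "Transformer")

#: Learners that consume a sliding window of consecutive months.
SEQUENCE_ALGORITHMS: frozenset[str] = frozenset({"CNN", "LSTM", "Transformer"})

_DEFAULTS: dict[str, dict] = {
    "LR": {},
    "SVR": {"C": 10.0, "epsilon": 0.1, "kernel": "rbf"},
    "RF": {"n_estimators": 200, "max_depth": None},
    "CNN": {"lookback": 12, "n_filters": 16, "kernel_size": 3, "alpha": 1e-2},
    "LSTM": {
        "lookback": 12,
        "units": 32,
        "spectral_radius": 0.8,
        "input_scale": 0.5,
        "alpha": 1e-2,
    },
    "Transformer": {
        "lookback": 12,
        "d_model": 32,
        "n_heads": 2,
        "alpha": 1e-2,
    },
}


def list_algorithms() -> tuple[str, ...]:
    """The six algorithm identifiers, in stable canonical order."""
    return ALGORITHMS


@dataclass(frozen=True)
class LearnerSpec:
    """Algorithm choice, hyperparameter overrides and the master seed."""

    algorithm_id: str
    hyperparams: Mapping = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm_id not in ALGORITHMS:
            raise ArgumentError(
                f"unknown algorithm {self.algorithm_id!r}; expected one of {ALGORITHMS}"
            )

    def params(self) -> dict:
        merged = dict(_DEFAULTS[self.algorithm_id])
        merged.update(self.hyperparams)
        return merged


@dataclass
class FittedModel:
    """A fitted learner plus the factor set it is contractually bound to."""

    spec: LearnerSpec
    factors: tuple[str, ...] | None
    state: dict
    training_window: tuple | None = None

    @property
    def lookback(self) -> int:
        return int(self.state.get("lookback", 1))

    @property
    def is_sequence(self) -> bool:
        return self.spec.algorithm_id in SEQUENCE_ALGORITHMS


# ---------------------------------------------------------------------------
# Shared numerics
# ---------------------------------------------------------------------------

def _as_matrix(X, factors: tuple[str, ...] | None) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        if factors is not None:
            missing = [f for f in factors if f not in X.columns]
            if missing:
                raise ContractError(f"missing predictor columns: {missing}")
            X = X.loc[:, list(factors)]
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X


def _standardize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return mu, sd


def _ridge_fit(F: np.ndarray, y: np.ndarray, alpha: float):
    """Ridge with unpenalised intercept, via centred normal equations."""
    fm = F.mean(axis=0)
    ym = y.mean()
    Fc = F - fm
    A = Fc.T @ Fc + alpha * np.eye(F.shape[1])
    w = np.linalg.solve(A, Fc.T @ (y - ym))
    b = ym - fm @ w
    return w, b


def _windows(X: np.ndarray, lookback: int, context: np.ndarray | None) -> np.ndarray:
    """(T, lookback, n_factors) causal windows ending at each row of X.

    ``context`` supplies the rows immediately preceding X; without it the
    first row of X is replicated (left-edge padding), so training matrices
    never need external context.
    """
    L = lookback
    if context is not None:
        context = np.asarray(context, dtype=float)
        if context.ndim == 1:
            context = context[:, None]
        if len(context) < L - 1:
            raise ContractError(
                f"insufficient lookback context: need >= {L - 1} rows, "
                f"got {len(context)}"
            )
        pad = context[-(L - 1):] if L > 1 else context[:0]
    else:
        pad = np.repeat(X[:1], L - 1, axis=0)
    full = np.vstack([pad, X])
    win = sliding_window_view(full, L, axis=0)  # (T, nf, L)
    return np.ascontiguousarray(np.swapaxes(win, 1, 2))


def _sinusoidal_positions(length: int, dim: int) -> np.ndarray:
    pos = np.arange(length)[:, None]
    i = np.arange(dim)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / dim)
    enc = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return enc


# ---------------------------------------------------------------------------
# Sequence feature maps (fixed by the seed; only the readout is trained)
# ---------------------------------------------------------------------------

def _cnn_features(Xs: np.ndarray, state: dict, context: np.ndarray | None) -> np.ndarray:
    win = _windows(Xs, state["lookback"], context)  # (T, L, nf)
    K = state["filters"].shape[1]
    sub = sliding_window_view(win, K, axis=1)  # (T, L-K+1, nf, K)
    conv = np.einsum("tpck,fkc->tpf", sub, state["filters"])
    pooled = np.tanh(conv).mean(axis=1)  # (T, n_filters)
    return np.hstack([pooled, Xs])


def _esn_features(Xs: np.ndarray, state: dict, context: np.ndarray | None) -> np.ndarray:
    W_in, W, b = state["W_in"], state["W"], state["b"]
    if context is not None:
        context = np.asarray(context, dtype=float)
        if context.ndim == 1:
            context = context[:, None]
        if len(context) < state["lookback"] - 1:
            raise ContractError(
                "insufficient lookback context for the recurrent warm-up"
            )
        run = np.vstack([context, Xs])  # context arrives already standardised
        skip = len(context)
    else:
        run, skip = Xs, 0
    h = np.zeros(W.shape[0])
    states = np.empty((len(run), W.shape[0]))
    for t in range(len(run)):
        h = np.tanh(W_in @ run[t] + W @ h + b)
        states[t] = h
    states = states[skip:]
    return np.hstack([states, Xs])


def _attention_features(
    Xs: np.ndarray, state: dict, context: np.ndarray | None
) -> np.ndarray:
    win = _windows(Xs, state["lookback"], context)  # (T, L, nf)
    Z = np.einsum("tlc,cd->tld", win, state["W_e"]) + state["pos"][None]
    heads = []
    for Wq, Wk, Wv in state["heads"]:
        Q = Z @ Wq
        Kh = Z @ Wk
        V = Z @ Wv
        logits = np.einsum("tld,tmd->tlm", Q, Kh) / np.sqrt(Q.shape[-1])
        logits -= logits.max(axis=-1, keepdims=True)
        attn = np.exp(logits)
        attn /= attn.sum(axis=-1, keepdims=True)
        heads.append(np.einsum("tlm,tmd->tld", attn, V)[:, -1, :])
    rep = np.tanh(np.hstack(heads))
    return np.hstack([rep, Xs])


_FEATURE_MAPS = {
    "CNN": _cnn_features,
    "LSTM": _esn_features,
    "Transformer": _attention_features,
}


def _init_sequence_state(spec: LearnerSpec, n_factors: int) -> dict:
    p = spec.params()
    rng = np.random.default_rng(spec.seed)
    state: dict = {"lookback": int(p["lookback"]), "alpha": float(p["alpha"])}
    if spec.algorithm_id == "CNN":
        k, nf = int(p["kernel_size"]), int(p["n_filters"])
        state["filters"] = rng.standard_normal((nf, k, n_factors)) / np.sqrt(
            k * n_factors
        )
    elif spec.algorithm_id == "LSTM":
        units = int(p["units"])
        W = rng.standard_normal((units, units))
        radius = max(abs(np.linalg.eigvals(W)))
        state["W"] = W * (float(p["spectral_radius"]) / radius)
        state["W_in"] = (
            rng.standard_normal((units, n_factors)) * float(p["input_scale"])
        )
        state["b"] = rng.standard_normal(units) * 0.1
    else:  # Transformer
        d, h = int(p["d_model"]), int(p["n_heads"])
        dh = d // h
        state["W_e"] = rng.standard_normal((n_factors, d)) / np.sqrt(n_factors)
        state["pos"] = _sinusoidal_positions(state["lookback"], d)
        state["heads"] = [
            tuple(rng.standard_normal((d, dh)) / np.sqrt(d) for _ in range(3))
            for _ in range(h)
        ]
    return state


# ---------------------------------------------------------------------------
# fit / predict
# ---------------------------------------------------------------------------

def fit(
    spec: LearnerSpec,
    X,
    y,
    factor_names: Sequence[str] | None = None,
    training_window: tuple | None = None,
) -> FittedModel:
    """Fit one learner; deterministic given (spec, X, y).

    ``X`` is a time-by-factor matrix (rows in chronological order for the
    sequence learners) with no masked rows; ``y`` the target series.
    """
    factors = tuple(factor_names) if factor_names is not None else None
    Xm = _as_matrix(X, factors)
    yv = np.asarray(y, dtype=float).ravel()
    if len(Xm) != len(yv):
        raise ArgumentError("X and y lengths differ")
    if not (np.isfinite(Xm).all() and np.isfinite(yv).all()):
        raise ArgumentError("non-finite values in training data")
    n, nf = Xm.shape
    if n < max(8, 2 * nf):
        raise SampleSizeError(
            f"need >= {max(8, 2 * nf)} samples for {nf} factors, got {n}"
        )
    algo = spec.algorithm_id
    params = spec.params()
    if algo == "LR":
        est = LinearRegression().fit(Xm, yv)
        state = {"estimator": est}
    elif algo == "SVR":
        est = make_pipeline(
            StandardScaler(),
            SkSVR(kernel=params["kernel"], C=params["C"], epsilon=params["epsilon"]),
        ).fit(Xm, yv)
        state = {"estimator": est}
    elif algo == "RF":
        est = RandomForestRegressor(
            n_estimators=params["n_estimators"],
            max_depth=params["max_depth"],
            random_state=spec.seed % (2**31),
            n_jobs=1,
        ).fit(Xm, yv)
        state = {"estimator": est}
    else:
        state = _init_sequence_state(spec, nf)
        mu, sd = _standardize_fit(Xm)
        state["mu"], state["sd"] = mu, sd
        Xs = (Xm - mu) / sd
        F = _FEATURE_MAPS[algo](Xs, state, None)
        w, b = _ridge_fit(F, yv, state["alpha"])
        state["w"], state["b_out"] = w, b
    return FittedModel(
        spec=spec, factors=factors, state=state, training_window=training_window
    )


def predict(model: FittedModel, X, context=None) -> np.ndarray:
    """One prediction per row of ``X``.

    For sequence learners, ``context`` supplies the rows immediately
    preceding ``X`` (at least lookback - 1 of them); without it the window is
    left-padded from the first row of ``X``. Tabular learners ignore
    ``context``. Raises :class:`ContractError` on factor-set mismatch or
    insufficient context.
    """
    Xm = _as_matrix(X, model.factors)
    if model.factors is not None and Xm.shape[1] != len(model.factors):
        raise ContractError(
            f"expected {len(model.factors)} predictors, got {Xm.shape[1]}"
        )
    if len(Xm) == 0:
        raise ContractError("empty prediction matrix")
    algo = model.spec.algorithm_id
    if algo in ("LR", "SVR", "RF"):
        return np.asarray(model.state["estimator"].predict(Xm), dtype=float)
    state = model.state
    if context is not None and isinstance(context, pd.DataFrame):
        context = _as_matrix(context, model.factors)
    Xs = (Xm - state["mu"]) / state["sd"]
    ctx = None
    if context is not None:
        ctx = (np.asarray(context, dtype=float) - state["mu"]) / state["sd"]
    F = _FEATURE_MAPS[algo](Xs, state, ctx)
    return F @ state["w"] + state["b_out"]
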
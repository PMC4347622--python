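"""Single-hidden-layer feed-forward network base learner.

The network maps a descriptor vector x to a predicted binding affinity

    yhat = w_{0,o} + sum_{h=1..H} w_{h,o} * S( sum_{i=0..|p|} w_{i,h} * x_i ),

with logistic-sigmoid hidden units S(u) = e^u / (1 + e^u), a linear output
neuron, and the bias convention x_0 = 1 / S(.) = 1 for h = 0.  ``hidden``
counts of H + 1 therefore include the constant bias unit: a net with
``hidden=20`` has 19 sigmoid units.

Weights are fitted by minimizing the weight-decay-regularized squared-error
criterion

    E = sum_n (y_n - yhat_n)^2 + lambda * sum_{all weights} w^2

with a full-batch quasi-Newton optimizer (L-BFGS) and analytic gradients;
``epochs`` caps the optimizer iterations, and training stops early once E
falls below ``abstol``.  Inputs are min-max scaled to [0, 1] on the training
rows; test-time inputs reuse the training scaler without clipping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .datamodel import FeatureDataset
from .errors import NumericError, SchemaError, UsageError

FORMAT_VERSION = 1


def spawn_seed(root: int, *path: int) -> int:
    """Derive a child seed from a root seed and a counter path.

    Deterministic and collision-resistant (via ``numpy.random.SeedSequence``),
    so one root seed expands to independent per-network init seeds.  The
    result fits in a signed 32-bit integer.
    """
    ss = np.random.SeedSequence([int(root)] + [int(p) for p in path])
    return int(ss.generate_state(1)[0] % (2**31))


def sigmoid(u):
    """Logistic activation S(u) = e^u / (1 + e^u); S(0) = 0.5, range (0, 1)."""
    return expit(u)


def linear_output(u):
    """Output-neuron activation O(u) = u."""
    return u


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters with the reference defaults.

    epochs : iteration cap for the optimizer (default 3000)
    weight_decay : quadratic penalty lambda on all weights (default 0.005)
    abstol : early-stop threshold on the fitting criterion E (default 1e-4)
    init_range : weights start uniform in [-init_range, +init_range] (0.7)
    seed : initialization seed
    """

    epochs: int = 3000
    weight_decay: float = 0.005
    abstol: float = 1e-4
    init_range: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise UsageError("epochs must be >= 1")
        if self.weight_decay < 0:
            raise UsageError("weight_decay must be >= 0")
        if self.abstol <= 0:
            raise UsageError("abstol must be > 0")
        if self.init_range <= 0:
            raise UsageError("init_range must be > 0")


@dataclass
class FeatureScaler:
    """Per-feature min-max scaling state fitted on training rows.

    A constant column gets range 1, so its scaled value is exactly 0.
    Out-of-range test inputs extrapolate linearly; they are not clipped,
    because clipping would distort the ranking of extreme complexes.
    """

    mins: np.ndarray
    ranges: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mins) / self.ranges


def fit_scaler(X: np.ndarray | FeatureDataset, subset: Sequence[int] | None = None) -> FeatureScaler:
    """Fit [0, 1] min-max scaling on the given columns of training data."""
    if isinstance(X, FeatureDataset):
        X = X.X
    X = np.asarray(X, dtype=float)
    if subset is not None:
        X = X[:, list(subset)]
    mins = X.min(axis=0)
    ranges = X.max(axis=0) - mins
    ranges[ranges == 0] = 1.0
    return FeatureScaler(mins=mins, ranges=ranges)


@dataclass
class NetworkModel:
    """One trained network plus everything needed to score new complexes.

    input_weights : (|p|+1, H) matrix w_{i,h}; row 0 is the input bias.
    output_weights : (H+1,) vector w_{h,o}; entry 0 is the hidden bias,
        paired with S(.) = 1.
    feature_subset : column indices p_l into the parent feature space.
    feature_names : names of those columns, for alignment against tables.
    scaler : training-time min-max state for the subset columns.
    """

    input_weights: np.ndarray
    output_weights: np.ndarray
    feature_subset: np.ndarray
    feature_names: list[str]
    scaler: FeatureScaler
    config: TrainConfig = field(default_factory=TrainConfig)

    @property
    def hidden(self) -> int:
        """Total hidden neurons H + 1, including the bias unit."""
        return len(self.output_weights)

    # -- scoring ------------------------------------------------------------

    def _scaled_design(self, X_parent: np.ndarray) -> np.ndarray:
        X_parent = np.atleast_2d(np.asarray(X_parent, dtype=float))
        if X_parent.shape[1] <= int(self.feature_subset.max(initial=0)):
            raise SchemaError(
                f"input has {X_parent.shape[1]} features; model needs index "
                f"{int(self.feature_subset.max())}"
            )
        Xs = self.scaler.transform(X_parent[:, self.feature_subset])
        return np.column_stack([np.ones(len(Xs)), Xs])

    def predict_matrix(self, X_parent: np.ndarray) -> np.ndarray:
        """Predict affinities for rows of a parent-space feature matrix."""
        Xd = self._scaled_design(X_parent)
        Z = sigmoid(Xd @ self.input_weights)
        return self.output_weights[0] + Z @ self.output_weights[1:]

    def predict(self, ds: FeatureDataset) -> np.ndarray:
        """Predict affinities for a dataset, aligning columns by name."""
        cols = ds.feature_index(self.feature_names)
        Xs = self.scaler.transform(ds.X[:, cols])
        Xd = np.column_stack([np.ones(len(Xs)), Xs])
        Z = sigmoid(Xd @ self.input_weights)
        return self.output_weights[0] + Z @ self.output_weights[1:]

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format_version": FORMAT_VERSION,
            "kind": "network",
            "input_weights": self.input_weights.tolist(),
            "output_weights": self.output_weights.tolist(),
            "feature_subset": self.feature_subset.tolist(),
            "feature_names": self.feature_names,
            "scaler": {
                "mins": self.scaler.mins.tolist(),
                "ranges": self.scaler.ranges.tolist(),
            },
            "config": self.config.__dict__,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkModel":
        return cls(
            input_weights=np.asarray(d["input_weights"], dtype=float),
            output_weights=np.asarray(d["output_weights"], dtype=float),
            feature_subset=np.asarray(d["feature_subset"], dtype=int),
            feature_names=list(d["feature_names"]),
            scaler=FeatureScaler(
                mins=np.asarray(d["scaler"]["mins"], dtype=float),
                ranges=np.asarray(d["scaler"]["ranges"], dtype=float),
            ),
            config=TrainConfig(**d["config"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "NetworkModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def forward(net: NetworkModel, x: Sequence[float]) -> float:
    """Score a single complex given its parent-space feature vector."""
    return float(net.predict_matrix(np.asarray(x, dtype=float)[None, :])[0])


def objective(net: NetworkModel, ds: FeatureDataset, targets: np.ndarray | None = None) -> float:
    """The regularized fitting criterion E on a dataset.

    E = sum of squared residuals + lambda * sum of squared weights, the
    penalty running over both layers including bias weights.
    """
    y = ds.y if targets is None else np.asarray(targets, dtype=float)
    resid = y - net.predict_matrix(ds.X)
    penalty = float(np.sum(net.input_weights**2) + np.sum(net.output_weights**2))
    return float(resid @ resid + net.config.weight_decay * penalty)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _unpack(w: np.ndarray, d: int, H: int) -> tuple[np.ndarray, np.ndarray]:
    W1 = w[: (d + 1) * H].reshape(d + 1, H)
    w2 = w[(d + 1) * H :]
    return W1, w2


def _objective_and_grad(w, Xd, y, lam, d, H):
    W1, w2 = _unpack(w, d, H)
    Z = expit(Xd @ W1)                      # (N, H)
    yhat = w2[0] + Z @ w2[1:]
    r = yhat - y
    E = r @ r + lam * (w @ w)

    g2 = np.empty_like(w2)
    g2[0] = 2.0 * r.sum()
    g2[1:] = 2.0 * (Z.T @ r)
    delta = (2.0 * r)[:, None] * (w2[1:][None, :] * Z * (1.0 - Z))
    g1 = Xd.T @ delta
    grad = np.concatenate([g1.ravel(), g2]) + 2.0 * lam * w
    return E, grad


class _EarlyStop(Exception):
    pass


def train_network(
    ds: FeatureDataset,
    subset: Sequence[int],
    hidden: int = 20,
    cfg: TrainConfig | None = None,
    targets: np.ndarray | None = None,
) -> NetworkModel:
    """Train one network on the given feature-subset columns of a dataset.

    ``hidden`` is the total H + 1 hidden-neuron count including the bias
    unit.  ``targets`` overrides the dataset affinities (used by boosting to
    fit residuals).  The result is bit-reproducible from (data, subset,
    config): initialization comes from ``cfg.seed`` and the optimizer is
    deterministic.
    """
    cfg = cfg or TrainConfig()
    subset = np.asarray(list(subset), dtype=int)
    if subset.size == 0:
        raise UsageError("feature subset must be non-empty")
    if hidden < 2:
        raise UsageError("hidden must be >= 2 (bias unit plus >= 1 sigmoid unit)")
    if ds.n < 2:
        raise UsageError("need at least 2 training rows")
    y = ds.y if targets is None else np.asarray(targets, dtype=float)
    if y.shape != (ds.n,):
        raise UsageError("targets length must match dataset rows")

    d = subset.size
    H = hidden - 1  # sigmoid units
    scaler = fit_scaler(ds.X, subset)
    Xs = scaler.transform(ds.X[:, subset])
    Xd = np.column_stack([np.ones(ds.n), Xs])
    lam = cfg.weight_decay

    rng = np.random.default_rng(cfg.seed)
    w0 = rng.uniform(-cfg.init_range, cfg.init_range, size=(d + 1) * H + H + 1)

    def fun(w):
        E, g = _objective_and_grad(w, Xd, y, lam, d, H)
        if not np.isfinite(E):
            raise NumericError("non-finite fitting criterion during training")
        return E, g

    def callback(wk):
        E, _ = _objective_and_grad(wk, Xd, y, lam, d, H)
        if E < cfg.abstol:
            raise StopIteration

    res = minimize(
        fun,
        w0,
        jac=True,
        method="L-BFGS-B",
        callback=callback,
        options={"maxiter": cfg.epochs, "maxfun": max(15000, 2 * cfg.epochs)},
    )
    w = res.x
    if not np.all(np.isfinite(w)):
        raise NumericError("non-finite weights after training")
    W1, w2 = _unpack(w, d, H)
    return NetworkModel(
        input_weights=W1,
        output_weights=w2,
        feature_subset=subset,
        feature_names=[ds.feature_names[j] for j in subset],
        scaler=scaler,
        config=cfg,
    )
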
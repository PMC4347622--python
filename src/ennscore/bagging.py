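"""Bagged ensemble of networks (bootstrap aggregation with random subspaces).

Each of the L members is trained on a bootstrap resample of the N training
complexes (drawn with replacement, size N), using its own random subset p_l
of the descriptor columns drawn without replacement.  The ensemble scores a
complex with the arithmetic mean of the member outputs

    yhat = (1/L) * sum_l f_l(x^{p_l}).

Rows absent from a member's bootstrap are that member's out-of-bag (OOB)
complexes — about (1 - 1/N)^N ~= 34% of the training set on average — and
provide validation predictions without a held-out split.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .datamodel import FeatureDataset
from .errors import NumericError, UsageError
from .network import FORMAT_VERSION, NetworkModel, TrainConfig, spawn_seed, train_network

_MAX_RETRIES = 3


def bootstrap_draw(
    n_rows: int, n_features: int, subset_size: int, seed: int, member_index: int
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one member's bootstrap rows and feature subset.

    Rows are sampled with replacement (size ``n_rows``, classical bagging);
    the feature subset is drawn uniformly without replacement.  This is the
    exact sampling path :func:`fit_bagging` uses for member
    ``member_index`` (1-based) under root ``seed``.
    """
    rng = np.random.default_rng(spawn_seed(seed, 0, member_index))
    rows = rng.integers(0, n_rows, size=n_rows)
    subset = rng.choice(n_features, size=subset_size, replace=False)
    return rows, subset


@dataclass
class BaggedEnsemble:
    """Ordered collection of networks with their bootstrap bookkeeping."""

    members: list[NetworkModel]
    bootstrap_index_sets: list[np.ndarray]
    subset_size: int
    seed: int
    feature_names: list[str]

    @property
    def L(self) -> int:
        return len(self.members)

    def predict(self, ds: FeatureDataset) -> np.ndarray:
        """Mean member prediction for each row of a dataset."""
        preds = np.stack([m.predict(ds) for m in self.members])
        return preds.mean(axis=0)

    def predict_matrix(self, X_parent: np.ndarray) -> np.ndarray:
        preds = np.stack([m.predict_matrix(X_parent) for m in self.members])
        return preds.mean(axis=0)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format_version": FORMAT_VERSION,
            "kind": "bagged_ensemble",
            "subset_size": self.subset_size,
            "seed": self.seed,
            "feature_names": self.feature_names,
            "bootstrap_index_sets": [b.tolist() for b in self.bootstrap_index_sets],
            "members": [m.to_dict() for m in self.members],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BaggedEnsemble":
        return cls(
            members=[NetworkModel.from_dict(m) for m in d["members"]],
            bootstrap_index_sets=[
                np.asarray(b, dtype=int) for b in d["bootstrap_index_sets"]
            ],
            subset_size=int(d["subset_size"]),
            seed=int(d["seed"]),
            feature_names=list(d["feature_names"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "BaggedEnsemble":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_bagging(
    ds: FeatureDataset,
    L: int = 3000,
    subset_size: int = 10,
    hidden: int = 20,
    cfg: TrainConfig | None = None,
) -> BaggedEnsemble:
    """Fit a bagged network ensemble.

    For each member: bootstrap N rows with replacement, draw ``subset_size``
    feature columns uniformly without replacement, and train a network on
    the resampled rows restricted to that subset.  Everything is
    reproducible from ``cfg.seed``.  Members whose training produces
    non-finite weights are retrained with a bumped seed (at most three
    retries); members that merely converge poorly are kept, since imperfect
    weight tuning adds diversity to the ensemble.
    """
    cfg = cfg or TrainConfig()
    if L < 1:
        raise UsageError("L must be >= 1")
    if not 1 <= subset_size <= ds.n_features:
        raise UsageError(
            f"subset_size must be in [1, {ds.n_features}], got {subset_size}"
        )
    if ds.n < 2:
        raise UsageError("need at least 2 training rows")

    root = cfg.seed
    members: list[NetworkModel] = []
    bootstraps: list[np.ndarray] = []
    for l in range(1, L + 1):
        rows, subset = bootstrap_draw(ds.n, ds.n_features, subset_size, root, l)
        sample = ds.subset_rows(rows, allow_duplicates=True)
        for attempt in range(_MAX_RETRIES + 1):
            member_cfg = TrainConfig(
                epochs=cfg.epochs,
                weight_decay=cfg.weight_decay,
                abstol=cfg.abstol,
                init_range=cfg.init_range,
                seed=spawn_seed(root, 1, l, attempt),
            )
            try:
                member = train_network(sample, subset, hidden, member_cfg)
                break
            except NumericError:
                if attempt == _MAX_RETRIES:
                    raise
        members.append(member)
        bootstraps.append(rows)
    return BaggedEnsemble(
        members=members,
        bootstrap_index_sets=bootstraps,
        subset_size=subset_size,
        seed=root,
        feature_names=list(ds.feature_names),
    )


def predict_bagging(ens: BaggedEnsemble, x: Sequence[float]) -> float:
    """Score one complex from its parent-space feature vector."""
    return float(ens.predict_matrix(np.asarray(x, dtype=float)[None, :])[0])


def oob_predictions(ens: BaggedEnsemble, ds: FeatureDataset) -> np.ndarray:
    """Per-row out-of-bag prediction, averaged over excluding members.

    Row ``i`` is scored only by members whose bootstrap did not contain it;
    the result is NaN for rows every member saw.  With L large every row is
    covered with probability approaching one.
    """
    sums = np.zeros(ds.n)
    counts = np.zeros(ds.n)
    for member, rows in zip(ens.members, ens.bootstrap_index_sets):
        inbag = np.zeros(ds.n, dtype=bool)
        inbag[rows] = True
        oob = ~inbag
        if oob.any():
            preds = member.predict(ds.subset_rows(np.flatnonzero(oob)))
            sums[oob] += preds
            counts[oob] += 1
    out = np.full(ds.n, np.nan)
    covered = counts > 0
    out[covered] = sums[covered] / counts[covered]
    return out


def oob_rmse(ens: BaggedEnsemble, ds: FeatureDataset) -> float:
    """RMSE of the out-of-bag predictions over the covered rows."""
    preds = oob_predictions(ens, ds)
    mask = np.isfinite(preds)
    if not mask.any():
        raise NumericError("no out-of-bag coverage; increase L")
    resid = ds.y[mask] - preds[mask]
    return float(np.sqrt(np.mean(resid**2)))
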
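"""Boosted ensemble of networks (stage-wise residual fitting with shrinkage).

The first network is fitted to all N training complexes on a random feature
subset p_1, and the working residuals are initialized as R^1 = Y - nu*yhat_1.
Every later stage l draws a bootstrap sample of rows, trains a network on the
sampled rows' *current* residuals (duplicated rows carry duplicate residual
targets), predicts on all N rows, and updates R^l = R^{l-1} - nu*yhat_l.
The shrinkage parameter nu < 1 slows learning to resist overfitting.

A complex is scored by the nu-shrunk sum over all stages,

    yhat = sum_{l=1..L} nu * f_l(x^{p_l}).

Every stage is shrunk, including the first, so the model's total weight is
L*nu: with the reference shrinkage nu = 0.001 a matching stage count
(L = 3000) is needed; a small L combined with a small nu systematically
under-predicts.  Each stage refits its own input scaler on its bootstrap
sample, keeping members self-contained.  No intercept/base-score term is
added.  Only the squared-error loss is supported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import FeatureDataset, kfold_indices
from .errors import NumericError, UsageError
from .network import FORMAT_VERSION, NetworkModel, TrainConfig, spawn_seed, train_network


@dataclass
class BoostedEnsemble:
    """Stage-ordered networks, the shrinkage nu, and the residual trace.

    ``residual_trace[l-1]`` is the residual sum of squares ||R^l||^2 on the
    full training set after stage l.
    """

    members: list[NetworkModel]
    nu: float
    residual_trace: np.ndarray
    seed: int
    subset_size: int
    feature_names: list[str]

    @property
    def L(self) -> int:
        return len(self.members)

    def predict(self, ds: FeatureDataset) -> np.ndarray:
        out = np.zeros(ds.n)
        for m in self.members:
            out += self.nu * m.predict(ds)
        return out

    def predict_matrix(self, X_parent: np.ndarray) -> np.ndarray:
        X_parent = np.atleast_2d(X_parent)
        out = np.zeros(len(X_parent))
        for m in self.members:
            out += self.nu * m.predict_matrix(X_parent)
        return out

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format_version": FORMAT_VERSION,
            "kind": "boosted_ensemble",
            "nu": self.nu,
            "seed": self.seed,
            "subset_size": self.subset_size,
            "feature_names": self.feature_names,
            "residual_trace": self.residual_trace.tolist(),
            "members": [m.to_dict() for m in self.members],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BoostedEnsemble":
        return cls(
            members=[NetworkModel.from_dict(m) for m in d["members"]],
            nu=float(d["nu"]),
            residual_trace=np.asarray(d["residual_trace"], dtype=float),
            seed=int(d["seed"]),
            subset_size=int(d["subset_size"]),
            feature_names=list(d["feature_names"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "BoostedEnsemble":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_boosting(
    ds: FeatureDataset,
    L: int = 3000,
    subset_size: int = 10,
    hidden: int = 20,
    nu: float = 0.001,
    cfg: TrainConfig | None = None,
) -> BoostedEnsemble:
    """Fit a boosted network ensemble by stage-wise residual fitting."""
    cfg = cfg or TrainConfig()
    if L < 1:
        raise UsageError("L must be >= 1")
    if not 0.0 < nu < 1.0:
        raise UsageError(f"shrinkage nu must be in (0, 1), got {nu}")
    if not 1 <= subset_size <= ds.n_features:
        raise UsageError(
            f"subset_size must be in [1, {ds.n_features}], got {subset_size}"
        )
    if ds.n < 2:
        raise UsageError("need at least 2 training rows")

    root = cfg.seed
    members: list[NetworkModel] = []
    trace = np.empty(L)

    def stage_cfg(l: int) -> TrainConfig:
        return TrainConfig(
            epochs=cfg.epochs,
            weight_decay=cfg.weight_decay,
            abstol=cfg.abstol,
            init_range=cfg.init_range,
            seed=spawn_seed(root, 1, l),
        )

    # Stage 1: fit to all complexes, random subset p_1.
    rng = np.random.default_rng(spawn_seed(root, 0, 1))
    subset = rng.choice(ds.n_features, size=subset_size, replace=False)
    f1 = train_network(ds, subset, hidden, stage_cfg(1))
    members.append(f1)
    residuals = ds.y - nu * f1.predict_matrix(ds.X)
    trace[0] = float(residuals @ residuals)

    # Stages 2..L: bootstrap rows, fit to their current residuals.
    for l in range(2, L + 1):
        rng = np.random.default_rng(spawn_seed(root, 0, l))
        rows = rng.integers(0, ds.n, size=ds.n)
        subset = rng.choice(ds.n_features, size=subset_size, replace=False)
        sample = ds.subset_rows(rows, allow_duplicates=True)
        fl = train_network(sample, subset, hidden, stage_cfg(l), targets=residuals[rows])
        members.append(fl)
        residuals = residuals - nu * fl.predict_matrix(ds.X)
        if not np.all(np.isfinite(residuals)):
            raise NumericError(f"non-finite residuals after boosting stage {l}")
        trace[l - 1] = float(residuals @ residuals)

    return BoostedEnsemble(
        members=members,
        nu=nu,
        residual_trace=trace,
        seed=root,
        subset_size=subset_size,
        feature_names=list(ds.feature_names),
    )


def predict_boosting(ens: BoostedEnsemble, x: Sequence[float]) -> float:
    """Score one complex from its parent-space feature vector."""
    return float(ens.predict_matrix(np.asarray(x, dtype=float)[None, :])[0])


# ---------------------------------------------------------------------------
# Cross-validated hyperparameter selection
# ---------------------------------------------------------------------------

def tune_by_cv(
    ds: FeatureDataset,
    grid: Sequence[Mapping],
    k: int = 10,
    seed: int = 0,
) -> tuple[dict, pd.DataFrame]:
    """Select a boosting configuration by k-fold cross-validation.

    Each grid entry is a mapping of :func:`fit_boosting` keyword overrides
    (``L``, ``subset_size``, ``hidden``, ``nu``, plus :class:`TrainConfig`
    fields ``epochs``, ``weight_decay``, ``abstol``, ``init_range``).  The
    candidate with the lowest mean held-out RMSE wins; ties go to the
    simpler configuration (fewer stages, then smaller subset).

    Returns the winning configuration and a table with one row per
    candidate and its per-fold and mean RMSEs.
    """
    if not grid:
        raise UsageError("hyperparameter grid is empty")
    folds = kfold_indices(ds.n, k, seed)
    all_idx = np.arange(ds.n)
    rows = []
    for ci, cand in enumerate(grid):
        cand = dict(cand)
        cfg = TrainConfig(
            epochs=cand.pop("epochs", TrainConfig.epochs),
            weight_decay=cand.pop("weight_decay", TrainConfig.weight_decay),
            abstol=cand.pop("abstol", TrainConfig.abstol),
            init_range=cand.pop("init_range", TrainConfig.init_range),
            seed=spawn_seed(seed, 100, ci),
        )
        fold_rmses = []
        for fold in folds:
            hold = np.zeros(ds.n, dtype=bool)
            hold[fold] = True
            train = ds.subset_rows(all_idx[~hold])
            test = ds.subset_rows(all_idx[hold])
            ens = fit_boosting(train, cfg=cfg, **cand)
            resid = test.y - ens.predict(test)
            fold_rmses.append(float(np.sqrt(np.mean(resid**2))))
        rows.append(
            {
                "candidate": ci,
                **cand,
                "mean_rmse": float(np.mean(fold_rmses)),
                **{f"fold{j}_rmse": r for j, r in enumerate(fold_rmses)},
            }
        )
    table = pd.DataFrame(rows)

    def sort_key(row):
        g = dict(grid[row["candidate"]])
        return (
            row["mean_rmse"],
            g.get("L", 3000),
            g.get("subset_size", 10),
        )

    best_row = min(rows, key=sort_key)
    return dict(grid[best_row["candidate"]]), table
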
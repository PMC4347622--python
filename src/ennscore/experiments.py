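"""Desk-scale experiments: recovery benchmarks and resampling diagnostics.

These are the package's standard self-contained studies on the synthetic
generator.  Problem sizes are deliberately modest — 600/200 train/test
complexes, ensembles of 100 networks trained with a 150-iteration budget —
so a study runs in minutes on one core while preserving the qualitative
structure of the full protocol (thousands of networks on a ~1100-complex
refined set).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bagging import bootstrap_draw, fit_bagging
from .boosting import fit_boosting
from .datamodel import FeatureDataset
from .evaluation import pearson
from .network import TrainConfig, spawn_seed, train_network
from .synthetic import SyntheticSpec, generate

#: Desk-scale training budget for experiment networks.
DESK_EPOCHS = 150


@dataclass
class RecoveryResult:
    """Per-seed test-set Pearson correlations of the three scoring functions."""

    seeds: list[int]
    bgn_rp: list[float] = field(default_factory=list)
    bsn_rp: list[float] = field(default_factory=list)
    snn_rp: list[float] = field(default_factory=list)

    @property
    def mean_bgn(self) -> float:
        return float(np.mean(self.bgn_rp))

    @property
    def mean_bsn(self) -> float:
        return float(np.mean(self.bsn_rp))

    @property
    def mean_snn(self) -> float:
        return float(np.mean(self.snn_rp))

    def wins(self, model: str) -> int:
        """Seeds on which an ensemble beats the single network."""
        values = self.bgn_rp if model == "bgn" else self.bsn_rp
        return sum(v > s for v, s in zip(values, self.snn_rp))


def _noisy_split(seed: int, n: int, train_n: int, noise_over_signal: float):
    """Generate one table with noise scaled to the signal's spread."""
    base = SyntheticSpec(n=n, seed=seed, noise_sd=0.0)
    ds0, g = generate(base)
    sd_g = float(np.std(g(ds0.X)))
    ds, _ = generate(
        SyntheticSpec(n=n, seed=seed, noise_sd=noise_over_signal * sd_g)
    )
    return ds.subset_rows(range(train_n)), ds.subset_rows(range(train_n, n))


def recovery_benchmark(
    root_seed: int,
    n_seeds: int = 10,
    n: int = 800,
    train_n: int = 600,
    L: int = 100,
    subset_size: int = 10,
    hidden: int = 20,
    nu: float = 0.01,
    epochs: int = DESK_EPOCHS,
    noise_over_signal: float = 0.8,
) -> RecoveryResult:
    """Ensemble-vs-single-network comparison on seeded synthetic replicates.

    For each replicate: generate a table whose additive noise has standard
    deviation ``noise_over_signal`` times the signal spread, train the
    bagged and boosted ensembles (random subsets of ``subset_size``
    features) and a single network on all features, and record each model's
    test-set Pearson correlation.
    """
    seeds = [spawn_seed(root_seed, 20, i) for i in range(n_seeds)]
    result = RecoveryResult(seeds=seeds)
    for seed in seeds:
        train, test = _noisy_split(seed, n, train_n, noise_over_signal)
        cfg = TrainConfig(epochs=epochs, seed=spawn_seed(seed, 9))
        bgn = fit_bagging(train, L=L, subset_size=subset_size, hidden=hidden, cfg=cfg)
        bsn = fit_boosting(
            train, L=L, subset_size=subset_size, hidden=hidden, nu=nu, cfg=cfg
        )
        snn = train_network(train, np.arange(train.n_features), hidden=hidden, cfg=cfg)
        result.bgn_rp.append(pearson(test.y, bgn.predict(test)))
        result.bsn_rp.append(pearson(test.y, bsn.predict(test)))
        result.snn_rp.append(pearson(test.y, snn.predict(test)))
    return result


def mean_oob_fraction(seed: int, n_bootstraps: int = 2000, n_rows: int = 100) -> float:
    """Mean out-of-bag fraction over repeated bootstrap draws.

    Uses the ensemble's own sampling path; the analytic value is
    (1 - 1/N)^N, about 0.366 for N = 100.
    """
    fractions = np.empty(n_bootstraps)
    for l in range(1, n_bootstraps + 1):
        rows, _ = bootstrap_draw(n_rows, 2, 1, seed, l)
        fractions[l - 1] = 1.0 - len(np.unique(rows)) / n_rows
    return float(fractions.mean())


def constant_target_decay(
    seed: int,
    L: int = 200,
    nu: float = 0.01,
    n_rows: int = 25,
    target: float = 5.0,
) -> tuple[float, float]:
    """Boosting residual decay on a noiseless constant-target fixture.

    Returns (stage-1 training RMSE, stage-L training RMSE).  When every
    network fits its (constant) target well, residuals shrink by roughly
    (1 - nu) per stage, so the stage-L RMSE is bounded near
    (1 - nu)^(L-1) times the stage-1 value.
    """
    rng = np.random.default_rng(spawn_seed(seed, 30))
    X = rng.normal(size=(n_rows, 3))
    ds = FeatureDataset(
        ids=[f"c{i}" for i in range(n_rows)],
        affinities=np.full(n_rows, target),
        features=X,
        feature_names=["X.f1", "X.f2", "X.f3"],
    )
    cfg = TrainConfig(epochs=40, weight_decay=0.0, seed=spawn_seed(seed, 31))
    ens = fit_boosting(ds, L=L, subset_size=2, hidden=3, nu=nu, cfg=cfg)
    rmse_trace = np.sqrt(ens.residual_trace / n_rows)
    return float(rmse_trace[0]), float(rmse_trace[-1])


def bagging_variance_across_seeds(
    root_seed: int,
    n_replicates: int = 20,
    L_values: tuple[int, ...] = (1, 50),
    n: int = 120,
    train_n: int = 90,
) -> dict[int, float]:
    """Seed-to-seed variance of bagged test predictions, by ensemble size.

    Trains ``n_replicates`` ensembles per L (differing only in seed) on the
    same table and measures the variance of each test complex's prediction
    across replicates, averaged over complexes.  Averaging more networks
    must damp the prediction's dependence on the training randomness.
    """
    ds, _ = generate(SyntheticSpec(n=n, seed=spawn_seed(root_seed, 40)))
    train = ds.subset_rows(range(train_n))
    test = ds.subset_rows(range(train_n, n))
    out: dict[int, float] = {}
    for L in L_values:
        preds = []
        for r in range(n_replicates):
            cfg = TrainConfig(epochs=40, seed=spawn_seed(root_seed, 41, L, r))
            ens = fit_bagging(train, L=L, subset_size=5, hidden=5, cfg=cfg)
            preds.append(ens.predict(test))
        out[L] = float(np.var(np.stack(preds), axis=0, ddof=1).mean())
    return out
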
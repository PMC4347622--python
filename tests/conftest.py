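import numpy as np
import pytest

from ennscore import FeatureDataset


def make_dataset(n=30, block_sizes=None, seed=0, families=None, y=None):
    """Random dataset with prefix-tagged feature columns."""
    block_sizes = block_sizes or {"X": 3, "A": 2, "R": 2, "G": 1}
    rng = np.random.default_rng(seed)
    names = [f"{b}.f{j + 1}" for b in ("X", "A", "R", "G") if b in block_sizes
             for j in range(block_sizes[b])]
    X = rng.normal(size=(n, len(names)))
    if y is None:
        y = X[:, 0] + 0.5 * X[:, 1] ** 2 + rng.normal(0, 0.3, n) + 5.0
    fam = None
    if families:
        fam = [f"F{i % families + 1}" for i in range(n)]
    return FeatureDataset(
        ids=[f"cpx{i:03d}" for i in range(n)],
        affinities=y,
        features=X,
        feature_names=names,
        families=fam,
    )


@pytest.fixture
def toy_ds():
    """30 complexes, 8 features in 4 blocks, 5 families."""
    return make_dataset(n=30, families=5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
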
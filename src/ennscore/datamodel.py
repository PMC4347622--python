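"""Feature-table data model, CSV I/O, feature-block selection and dataset splits.

A *feature table* holds one row per protein-ligand complex: a complex
identifier, an optional protein-family label, the measured binding affinity
(in -log Kd / -log Ki units, stored as given), and numeric descriptor
columns.  Descriptors come in four blocks named after the software families
that produce them in practice:

* ``X`` — empirical terms (6 columns by convention),
* ``A`` — AffiScore/SLIDE terms (30),
* ``R`` — element-pair contact counts (36),
* ``G`` — GOLD descriptors (14).

Columns are tagged with their block through the name prefix ``"X."``,
``"A."``, ``"R."`` or ``"G."``; anything else is tagged ``OTHER``.  An
explicit schema can override the prefix convention.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, IntegrityError, SchemaError, TableParseError, UsageError

#: The four descriptor blocks, in the display order used for model labels.
BLOCKS: tuple[str, ...] = ("X", "A", "R", "G")

#: Conventional number of columns per block in the full descriptor table.
DEFAULT_BLOCK_SIZES: dict[str, int] = {"X": 6, "A": 30, "R": 36, "G": 14}


def infer_block_tag(name: str) -> str:
    """Return the block tag implied by a column-name prefix (``OTHER`` if none)."""
    for b in BLOCKS:
        if name.startswith(b + "."):
            return b
    return "OTHER"


@dataclass(frozen=True)
class ColumnSchema:
    """Column-role mapping for :func:`read_feature_table`.

    ``block_overrides`` maps feature-column names to block tags, taking
    precedence over the prefix convention.
    """

    id_col: str = "id"
    family_col: str = "family"
    affinity_col: str = "affinity"
    block_overrides: Mapping[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class ComplexRecord:
    """One protein-ligand complex: identifier, optional family, affinity, features."""

    complex_id: str
    family: str | None
    affinity: float
    features: dict[str, float]

    def __post_init__(self) -> None:
        if not np.isfinite(self.affinity):
            raise IntegrityError(
                f"complex {self.complex_id!r}: affinity must be finite"
            )


@dataclass(frozen=True)
class FeatureCombination:
    """A non-empty subset of the four descriptor blocks."""

    blocks: frozenset[str]

    def __post_init__(self) -> None:
        blocks = frozenset(self.blocks)
        if not blocks:
            raise UsageError("feature combination must be non-empty")
        unknown = blocks - set(BLOCKS)
        if unknown:
            raise UsageError(f"unknown feature blocks: {sorted(unknown)}")
        object.__setattr__(self, "blocks", blocks)

    @classmethod
    def from_label(cls, label: str) -> "FeatureCombination":
        """Parse a label such as ``"XARG"`` or ``"xa"``."""
        return cls(frozenset(c.upper() for c in label))

    @property
    def label(self) -> str:
        """Blocks concatenated in canonical ``X, A, R, G`` order (e.g. ``"XAR"``)."""
        return "".join(b for b in BLOCKS if b in self.blocks)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


class FeatureDataset:
    """An in-memory feature table: matrix + affinities + block tags.

    Parameters
    ----------
    ids :
        Complex identifiers, unique, one per row.
    affinities :
        Measured binding affinities in -log Kd / -log Ki units.
    features :
        ``(n, d)`` matrix of descriptor values.
    feature_names :
        Column names, unique, length ``d``.
    families :
        Optional per-row protein-family labels.
    block_tags :
        Feature name -> block tag; inferred from prefixes when omitted.
    """

    def __init__(
        self,
        ids: Sequence[str],
        affinities: Sequence[float],
        features: np.ndarray,
        feature_names: Sequence[str],
        families: Sequence[str] | None = None,
        block_tags: Mapping[str, str] | None = None,
    ) -> None:
        self.ids = [str(i) for i in ids]
        self.y = np.asarray(affinities, dtype=float)
        X = np.asarray(features, dtype=float)
        self.X = (
            X.reshape(len(self.ids), 0) if X.size == 0 else X.reshape(len(self.ids), -1)
        )
        self.feature_names = list(feature_names)
        self.families = list(families) if families is not None else None
        if block_tags is None:
            block_tags = {}
        self.block_tags = {
            name: block_tags.get(name, infer_block_tag(name))
            for name in self.feature_names
        }
        self._validate()

    # -- invariants ---------------------------------------------------------

    def _validate(self) -> None:
        n = len(self.ids)
        if n < 1:
            raise IntegrityError("dataset must contain at least one complex")
        if len(set(self.ids)) != n:
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise IntegrityError(f"duplicate complex ids: {dupes[:5]}")
        if self.y.shape != (n,):
            raise IntegrityError("affinity vector length does not match row count")
        if not np.all(np.isfinite(self.y)):
            bad = self.ids[int(np.flatnonzero(~np.isfinite(self.y))[0])]
            raise IntegrityError(f"non-finite affinity for complex {bad!r}")
        if self.X.shape != (n, len(self.feature_names)):
            raise IntegrityError("feature matrix shape does not match names")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise IntegrityError("duplicate feature names")
        if self.families is not None and len(self.families) != n:
            raise IntegrityError("family labels length does not match row count")

    # -- basic accessors ----------------------------------------------------

    @property
    def n(self) -> int:
        """Number of complexes N."""
        return len(self.ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def records(self) -> Iterator[ComplexRecord]:
        """Yield rows as :class:`ComplexRecord` objects."""
        for i, cid in enumerate(self.ids):
            yield ComplexRecord(
                complex_id=cid,
                family=self.families[i] if self.families is not None else None,
                affinity=float(self.y[i]),
                features=dict(zip(self.feature_names, self.X[i])),
            )

    def subset_rows(
        self, indices: Sequence[int], allow_duplicates: bool = False
    ) -> "FeatureDataset":
        """New dataset restricted to the given row indices (order preserved).

        With ``allow_duplicates`` (bootstrap resamples are multisets),
        repeated rows get a ``#k`` suffix on their id to keep ids unique.
        """
        idx = list(indices)
        ids = [self.ids[i] for i in idx]
        if allow_duplicates:
            seen: dict[str, int] = {}
            out = []
            for cid in ids:
                k = seen.get(cid, 0)
                seen[cid] = k + 1
                out.append(cid if k == 0 else f"{cid}#{k}")
            ids = out
        return FeatureDataset(
            ids=ids,
            affinities=self.y[idx],
            features=self.X[idx],
            feature_names=self.feature_names,
            families=[self.families[i] for i in idx] if self.families else None,
            block_tags=self.block_tags,
        )

    def feature_index(self, names: Sequence[str]) -> np.ndarray:
        """Column indices for the given feature names (error if missing)."""
        pos = {name: j for j, name in enumerate(self.feature_names)}
        missing = [n for n in names if n not in pos]
        if missing:
            raise SchemaError(f"features not in table: {missing[:5]}")
        return np.array([pos[n] for n in names], dtype=int)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"FeatureDataset(n={self.n}, features={self.n_features}, "
            f"families={'yes' if self.families else 'no'})"
        )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_feature_table(
    path: str | Path, schema: ColumnSchema | None = None
) -> FeatureDataset:
    """Read a CSV feature table into a :class:`FeatureDataset`.

    The file must have a header row, one affinity column and at least one
    feature column.  The family column is optional.  Numeric cells that do
    not parse raise :class:`TableParseError` naming the row and column.
    """
    schema = schema or ColumnSchema()
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except (OSError, pd.errors.ParserError) as exc:
        raise DataError(f"cannot read feature table {path}: {exc}") from exc
    if schema.id_col not in df.columns:
        raise SchemaError(f"missing id column {schema.id_col!r} in {path}")
    if schema.affinity_col not in df.columns:
        raise SchemaError(f"missing affinity column {schema.affinity_col!r} in {path}")
    if len(df) == 0:
        raise DataError(f"feature table {path} has no rows")

    reserved = {schema.id_col, schema.affinity_col, schema.family_col}
    feature_cols = [c for c in df.columns if c not in reserved]
    if not feature_cols:
        raise SchemaError(f"feature table {path} has no feature columns")

    def _numeric(col: str) -> np.ndarray:
        values = df[col].to_numpy()
        try:
            return values.astype(float)
        except ValueError:
            for i, v in enumerate(values):
                try:
                    float(v)
                except ValueError:
                    raise TableParseError(
                        f"non-numeric value {v!r} in column {col!r}, row {i + 2} "
                        f"of {path}"
                    ) from None
            raise  # pragma: no cover - unreachable

    affinities = _numeric(schema.affinity_col)
    if not np.all(np.isfinite(affinities)):
        i = int(np.flatnonzero(~np.isfinite(affinities))[0])
        raise TableParseError(
            f"non-finite affinity in row {i + 2} of {path}"
        )
    features = np.column_stack([_numeric(c) for c in feature_cols])
    families = (
        df[schema.family_col].tolist() if schema.family_col in df.columns else None
    )
    return FeatureDataset(
        ids=df[schema.id_col].tolist(),
        affinities=affinities,
        features=features,
        feature_names=feature_cols,
        families=families,
        block_tags=dict(schema.block_overrides),
    )


def write_feature_table(
    ds: FeatureDataset, path: str | Path, schema: ColumnSchema | None = None
) -> None:
    """Write a dataset as CSV, losslessly round-trippable by ``read_feature_table``.

    Floats are rendered with 17 significant digits, which reproduces IEEE
    doubles bit-for-bit on re-parse.
    """
    schema = schema or ColumnSchema()
    data: dict[str, object] = {schema.id_col: ds.ids}
    if ds.families is not None:
        data[schema.family_col] = ds.families
    data[schema.affinity_col] = ds.y
    for j, name in enumerate(ds.feature_names):
        data[name] = ds.X[:, j]
    try:
        pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")
    except OSError as exc:
        raise DataError(f"cannot write feature table {path}: {exc}") from exc


def read_id_list(path: str | Path) -> list[str]:
    """Read a one-identifier-per-line file (blank lines ignored)."""
    try:
        text = Path(path).read_text()
    except OSError as exc:
        raise DataError(f"cannot read id list {path}: {exc}") from exc
    return [line.strip() for line in text.splitlines() if line.strip()]


# ---------------------------------------------------------------------------
# Feature-block combinations
# ---------------------------------------------------------------------------

def enumerate_feature_combinations(
    available_blocks: Sequence[str] | set[str],
) -> list[FeatureCombination]:
    """All non-empty subsets of the available blocks.

    Ordered by subset size, then lexicographically by label, so reports are
    stable across runs.  Four blocks yield the full set of 15 combinations.
    """
    blocks = sorted(set(available_blocks), key=BLOCKS.index)
    if not blocks:
        raise UsageError("no feature blocks available")
    combos = [
        FeatureCombination(frozenset(subset))
        for r in range(1, len(blocks) + 1)
        for subset in itertools.combinations(blocks, r)
    ]
    combos.sort(key=lambda c: (len(c.blocks), c.label))
    return combos


def select_features(ds: FeatureDataset, combo: FeatureCombination) -> FeatureDataset:
    """Restrict a dataset to the columns tagged with the combination's blocks."""
    keep = [n for n in ds.feature_names if ds.block_tags[n] in combo.blocks]
    present = {ds.block_tags[n] for n in keep}
    empty = sorted(combo.blocks - present)
    if empty:
        raise SchemaError(f"no columns tagged with block(s) {empty}")
    cols = ds.feature_index(keep)
    return FeatureDataset(
        ids=ds.ids,
        affinities=ds.y,
        features=ds.X[:, cols],
        feature_names=keep,
        families=ds.families,
        block_tags=ds.block_tags,
    )


# ---------------------------------------------------------------------------
# Dataset splits
# ---------------------------------------------------------------------------

def split_refined_core(
    ds: FeatureDataset, core_ids: set[str] | Sequence[str]
) -> tuple[FeatureDataset | None, FeatureDataset | None]:
    """Split into a training partition and a designated core test set.

    The test side contains exactly the rows whose id is in ``core_ids``; the
    training side is the complement.  Mirrors the benchmark practice of
    carving a family-balanced core set out of a refined set of complexes.
    Either side may be ``None`` when empty.
    """
    core = set(core_ids)
    unknown = core - set(ds.ids)
    if unknown:
        raise DataError(f"core ids not present in table: {sorted(unknown)[:5]}")
    test_idx = [i for i, cid in enumerate(ds.ids) if cid in core]
    train_idx = [i for i, cid in enumerate(ds.ids) if cid not in core]
    train = ds.subset_rows(train_idx) if train_idx else None
    test = ds.subset_rows(test_idx) if test_idx else None
    return train, test


def family_holdout_split(
    ds: FeatureDataset, family: str
) -> tuple[FeatureDataset, FeatureDataset]:
    """Hold out every complex of one protein family as the test set.

    Emulates evaluation on a homogeneous test set: the model never sees any
    complex of the held-out family during training.
    """
    if ds.families is None:
        raise SchemaError("dataset has no family labels")
    test_idx = [i for i, f in enumerate(ds.families) if f == family]
    if not test_idx:
        raise DataError(f"family {family!r} not present in dataset")
    train_idx = [i for i, f in enumerate(ds.families) if f != family]
    if not train_idx:
        raise DataError(
            f"family {family!r} is the only family; training side would be empty"
        )
    return ds.subset_rows(train_idx), ds.subset_rows(test_idx)


def kfold_indices(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Partition ``range(n)`` into ``k`` disjoint folds of near-equal size.

    Indices are shuffled with the given seed and dealt round-robin, so fold
    sizes differ by at most one and the partition is reproducible.
    """
    if not 2 <= k <= n:
        raise UsageError(f"need 2 <= k <= n, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    return [order[f::k].copy() for f in range(k)]
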
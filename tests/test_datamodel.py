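"""Feature-table I/O, block combinations and splitting protocols."""

import numpy as np
import pytest

from ennscore import (
    DataError,
    FeatureCombination,
    IntegrityError,
    SchemaError,
    TableParseError,
    UsageError,
    enumerate_feature_combinations,
    family_holdout_split,
    kfold_indices,
    read_feature_table,
    select_features,
    split_refined_core,
    write_feature_table,
)
from conftest import make_dataset


class TestCsvIO:
    def test_small_table_readback(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(
            "id,family,affinity,X.f1,R.f1\n"
            "c1,F1,5.2,0.1,3\n"
            "c2,F1,6.0,0.2,4\n"
            "c3,F2,4.1,0.3,5\n"
        )
        ds = read_feature_table(p)
        assert ds.n == 3
        assert ds.block_tags == {"X.f1": "X", "R.f1": "R"}
        assert ds.families == ["F1", "F1", "F2"]
        assert np.allclose(ds.y, [5.2, 6.0, 4.1])

    def test_non_numeric_affinity_is_parse_error(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("id,affinity,X.f1\nc1,NA,0.1\nc2,5.0,0.2\n")
        with pytest.raises(TableParseError, match="affinity"):
            read_feature_table(p)

    def test_non_numeric_feature_names_row_and_column(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("id,affinity,X.f1\nc1,5.0,0.1\nc2,5.0,oops\n")
        with pytest.raises(TableParseError, match=r"X\.f1.*row 3"):
            read_feature_table(p)

    def test_missing_affinity_column_is_schema_error(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("id,X.f1\nc1,0.1\n")
        with pytest.raises(SchemaError, match="affinity"):
            read_feature_table(p)

    def test_duplicate_ids_rejected(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("id,affinity,X.f1\nc1,5.0,0.1\nc1,6.0,0.2\n")
        with pytest.raises(IntegrityError, match="duplicate"):
            read_feature_table(p)

    def test_round_trip_is_lossless(self, tmp_path, rng):
        ds = make_dataset(n=50, block_sizes={"X": 10, "A": 10}, seed=7)
        p = tmp_path / "rt.csv"
        write_feature_table(ds, p)
        back = read_feature_table(p)
        assert back.ids == ds.ids
        assert np.array_equal(back.y, ds.y)
        assert np.array_equal(back.X, ds.X)
        assert back.feature_names == ds.feature_names

    def test_featureless_table_written_as_two_columns(self, tmp_path):
        from ennscore import FeatureDataset

        ds = FeatureDataset(
            ids=["a", "b"], affinities=[1.0, 2.0],
            features=np.zeros((2, 0)), feature_names=[],
        )
        p = tmp_path / "empty.csv"
        write_feature_table(ds, p)
        header = p.read_text().splitlines()[0]
        assert header == "id,affinity"

    def test_family_labels_survive_round_trip(self, tmp_path):
        ds = make_dataset(n=10, families=3)
        p = tmp_path / "fam.csv"
        write_feature_table(ds, p)
        assert read_feature_table(p).families == ds.families


class TestFeatureCombinations:
    def test_four_blocks_give_fifteen(self):
        combos = enumerate_feature_combinations({"X", "A", "R", "G"})
        assert len(combos) == 15
        labels = [c.label for c in combos]
        assert labels[0:4] == ["A", "G", "R", "X"]  # size then lexicographic
        assert labels[-1] == "XARG"
        assert len(set(labels)) == 15

    @pytest.mark.parametrize(
        "blocks,expected",
        [({"X"}, 1), ({"X", "A"}, 3), ({"X", "A", "R"}, 7), ({"X", "A", "R", "G"}, 15)],
    )
    def test_powerset_minus_empty_count(self, blocks, expected):
        assert len(enumerate_feature_combinations(blocks)) == 2 ** len(blocks) - 1

    def test_empty_input_rejected(self):
        with pytest.raises(UsageError):
            enumerate_feature_combinations(set())
        with pytest.raises(UsageError):
            FeatureCombination(frozenset())

    def test_label_parsing_and_canonical_order(self):
        assert FeatureCombination.from_label("grx").label == "XRG"


class TestSelectFeatures:
    def test_single_block_selection(self):
        ds = make_dataset(block_sizes={"X": 6, "R": 36})
        sub = select_features(ds, FeatureCombination.from_label("X"))
        assert sub.n_features == 6
        assert all(n.startswith("X.") for n in sub.feature_names)
        assert np.array_equal(sub.y, ds.y)
        assert sub.ids == ds.ids

    def test_all_blocks_is_identity_and_idempotent(self, toy_ds):
        combo = FeatureCombination.from_label("XARG")
        once = select_features(toy_ds, combo)
        twice = select_features(once, combo)
        assert once.feature_names == toy_ds.feature_names
        assert np.array_equal(once.X, toy_ds.X)
        assert twice.feature_names == once.feature_names

    def test_block_with_no_columns_rejected(self):
        ds = make_dataset(block_sizes={"X": 3})
        with pytest.raises(SchemaError):
            select_features(ds, FeatureCombination.from_label("XG"))


class TestSplits:
    def test_refined_core_partition(self):
        ds = make_dataset(n=100)
        core = set(ds.ids[10:30])
        train, test = split_refined_core(ds, core)
        assert test.n == 20 and train.n == 80
        assert set(test.ids) == core
        assert set(train.ids) | set(test.ids) == set(ds.ids)
        assert not set(train.ids) & set(test.ids)

    def test_empty_and_full_core(self):
        ds = make_dataset(n=10)
        train, test = split_refined_core(ds, set())
        assert test is None and train.n == 10
        train, test = split_refined_core(ds, set(ds.ids))
        assert train is None and test.n == 10

    def test_unknown_core_id_named_in_error(self):
        ds = make_dataset(n=5)
        with pytest.raises(DataError, match="nope"):
            split_refined_core(ds, {"nope"})

    def test_family_holdout(self):
        ds = make_dataset(n=15, families=3)  # F1 x5, F2 x5, F3 x5
        train, test = family_holdout_split(ds, "F2")
        assert test.n == 5 and train.n == 10
        assert all(f == "F2" for f in test.families)
        assert "F2" not in train.families

    def test_family_holdout_union_covers_all(self):
        ds = make_dataset(n=20, families=4)
        for fam in sorted(set(ds.families)):
            train, test = family_holdout_split(ds, fam)
            assert sorted(train.ids + test.ids) == sorted(ds.ids)

    def test_family_holdout_errors(self):
        ds = make_dataset(n=10, families=1)
        with pytest.raises(DataError, match="only family"):
            family_holdout_split(ds, "F1")
        ds2 = make_dataset(n=10, families=2)
        with pytest.raises(DataError, match="absent|not present"):
            family_holdout_split(ds2, "F99")


class TestKfold:
    def test_singleton_folds(self):
        folds = kfold_indices(10, 10, seed=0)
        assert sorted(len(f) for f in folds) == [1] * 10

    def test_near_equal_sizes(self):
        folds = kfold_indices(7, 3, seed=0)
        assert sorted(len(f) for f in folds) == [2, 2, 3]

    def test_partition_and_reproducibility(self):
        a = kfold_indices(53, 10, seed=42)
        b = kfold_indices(53, 10, seed=42)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))
        assert sorted(np.concatenate(a).tolist()) == list(range(53))

    def test_different_seeds_differ(self):
        same = sum(
            all(
                np.array_equal(x, y)
                for x, y in zip(kfold_indices(20, 4, s), kfold_indices(20, 4, s + 1000))
            )
            for s in range(100)
        )
        assert same < 5

    def test_k_out_of_range(self):
        with pytest.raises(UsageError):
            kfold_indices(5, 6, seed=0)
        with pytest.raises(UsageError):
            kfold_indices(5, 1, seed=0)
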
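import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from arborview.dataset_split import (
    SplitManifest,
    assemble_datasets,
    grouped_split,
    study_image_table,
)
from arborview.pointcloud_io import TreeRecord
from arborview.projection import GrayImage


def make_records(counts):
    return [
        TreeRecord(f"{sp}_{i}", sp, "") for sp, n in counts.items() for i in range(n)
    ]


def make_image(tree_id, view_index=0, augmented=False):
    return GrayImage(
        pixels=np.zeros((8, 8), dtype=np.uint8),
        tree_id=tree_id,
        view_index=view_index,
        augmented=augmented,
    )


class TestGroupedSplit:
    def test_explicit_count_ash_design(self):
        records = make_records({"ash": 39})
        split = grouped_split(records, per_species_test_counts={"ash": 7}, seed=0)
        assert len(split.test_tree_ids) == 7
        assert len(split.train_tree_ids) == 32
        # 10 views per tree: 70 test images
        assert 10 * len(split.test_tree_ids) == 70

    def test_partitions_disjoint_and_exhaustive(self):
        records = make_records({"a": 11, "b": 7})
        split = grouped_split(records, seed=3)
        all_ids = {r.tree_id for r in records}
        assert split.train_tree_ids | split.test_tree_ids == all_ids
        assert not split.train_tree_ids & split.test_tree_ids

    def test_fraction_rounding(self):
        split = grouped_split(make_records({"a": 10, "b": 10}), test_fraction=0.2, seed=0)
        assert split.per_species_test_counts == {"a": 2, "b": 2}

    def test_minimum_one_test_tree(self):
        split = grouped_split(make_records({"a": 3, "b": 3}), test_fraction=0.1, seed=0)
        assert split.per_species_test_counts == {"a": 1, "b": 1}

    def test_round_half_away_from_zero(self):
        # 0.2 * 22 = 4.4 -> 4 ; 0.2 * 38 = 7.6 -> 8 ; 0.5 * 5 = 2.5 -> 3
        split = grouped_split(make_records({"a": 22, "b": 38}), 0.2, seed=0)
        assert split.per_species_test_counts == {"a": 4, "b": 8}
        split = grouped_split(make_records({"c": 5}), 0.5, seed=0)
        assert split.per_species_test_counts == {"c": 3}

    def test_excessive_test_count_rejected(self):
        with pytest.raises(ValueError, match="test count"):
            grouped_split(make_records({"a": 5}), per_species_test_counts={"a": 5})

    def test_single_tree_species_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            grouped_split(make_records({"a": 1, "b": 5}), seed=0)

    def test_seeded_determinism(self):
        records = make_records({"a": 20, "b": 15})
        a = grouped_split(records, seed=9)
        b = grouped_split(records, seed=9)
        assert a.test_tree_ids == b.test_tree_ids

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        counts=st.dictionaries(
            st.sampled_from(["s1", "s2", "s3", "s4"]),
            st.integers(min_value=2, max_value=40),
            min_size=1,
        ),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
        frac=st.floats(min_value=0.05, max_value=0.45),
    )
    def test_zero_leakage_property(self, counts, seed, frac):
        split = grouped_split(make_records(counts), test_fraction=frac, seed=seed)
        assert not split.train_tree_ids & split.test_tree_ids
        for sp, k in split.per_species_test_counts.items():
            assert 1 <= k < counts[sp]


class TestAssembleDatasets:
    def test_routes_by_tree_and_conserves_images(self):
        records = make_records({"a": 5, "b": 5})
        split = grouped_split(records, per_species_test_counts={"a": 1, "b": 2}, seed=0)
        images = [
            make_image(r.tree_id, v) for r in records for v in range(10)
        ]
        species = {r.tree_id: r.species for r in records}
        train, test = assemble_datasets(images, split, species)
        assert len(train) + len(test) == len(images)
        assert len(test) == 30  # (1 + 2) test trees x 10 views
        assert {img.tree_id for img, _ in test} == set(split.test_tree_ids)

    def test_augmented_image_of_test_tree_rejected(self):
        records = make_records({"a": 4})
        split = grouped_split(records, per_species_test_counts={"a": 2}, seed=1)
        bad_tree = sorted(split.test_tree_ids)[0]
        images = [make_image(bad_tree, 1000, augmented=True)]
        with pytest.raises(AssertionError, match="augmented"):
            assemble_datasets(images, split, {r.tree_id: r.species for r in records})

    def test_unknown_tree_rejected(self):
        records = make_records({"a": 4})
        split = grouped_split(records, per_species_test_counts={"a": 1}, seed=1)
        with pytest.raises(KeyError):
            assemble_datasets([make_image("ghost")], split, {"ghost": "a"})


def test_manifest_json_roundtrip(tmp_path):
    split = grouped_split(make_records({"a": 8, "b": 6}), seed=4)
    path = tmp_path / "split.json"
    split.to_json(path)
    back = SplitManifest.from_json(path)
    assert back == split


def test_overlapping_manifest_rejected():
    with pytest.raises(ValueError, match="both partitions"):
        SplitManifest(frozenset({"t1", "t2"}), frozenset({"t2"}))


class TestStudyImageTable:
    def test_reference_design_bookkeeping(self):
        tree_counts = {
            "beech": 163, "red_oak": 100, "ash": 39, "oak": 22,
            "douglas_fir": 183, "spruce": 158, "pine": 25,
        }
        test_trees = {
            "beech": 35, "red_oak": 19, "ash": 7, "oak": 4,
            "douglas_fir": 37, "spruce": 31, "pine": 5,
        }
        table = study_image_table(tree_counts, test_trees)
        expected = {
            # species: (base, after_aug, train, test)
            "beech": (1630, 1630, 1280, 350),
            "red_oak": (1000, 1000, 810, 190),
            "ash": (390, 790, 720, 70),
            "oak": (220, 620, 580, 40),
            "douglas_fir": (1830, 1830, 1460, 370),
            "spruce": (1580, 1580, 1270, 310),
            "pine": (250, 650, 600, 50),
        }
        for sp, (base, after, train, test) in expected.items():
            row = table.loc[sp]
            assert row["base_images"] == base
            assert row["images_after_augmentation"] == after
            assert row["train_images"] == train
            assert row["test_images"] == test

    def test_image_conservation(self):
        table = study_image_table({"a": 12, "b": 140}, {"a": 2, "b": 28})
        assert (
            table["train_images"] + table["test_images"]
        ).equals(table["images_after_augmentation"])
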
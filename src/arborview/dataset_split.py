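"""Strict per-tree train/test partitioning and dataset assembly.

The split is grouped at the tree level: every image of a tree lands in
exactly one partition, so the test set never contains views (augmented or
not) of a training tree.  Splitting happens *before* augmentation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pointcloud_io import TreeRecord
from .projection import GrayImage

__all__ = [
    "SplitManifest",
    "grouped_split",
    "assemble_datasets",
    "study_image_table",
]


@dataclass(frozen=True)
class SplitManifest:
    """Per-tree train/test assignment with its generating seed."""

    train_tree_ids: frozenset[str]
    test_tree_ids: frozenset[str]
    per_species_test_counts: dict[str, int] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        overlap = self.train_tree_ids & self.test_tree_ids
        if overlap:
            raise ValueError(f"trees in both partitions: {sorted(overlap)[:5]}")

    def partition_of(self, tree_id: str) -> str:
        if tree_id in self.train_tree_ids:
            return "train"
        if tree_id in self.test_tree_ids:
            return "test"
        raise KeyError(f"tree {tree_id!r} not in split manifest")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "train_tree_ids": sorted(self.train_tree_ids),
            "test_tree_ids": sorted(self.test_tree_ids),
            "per_species_test_counts": self.per_species_test_counts,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitManifest":
        payload = json.loads(Path(path).read_text())
        return cls(
            train_tree_ids=frozenset(payload["train_tree_ids"]),
            test_tree_ids=frozenset(payload["test_tree_ids"]),
            per_species_test_counts={
                k: int(v) for k, v in payload["per_species_test_counts"].items()
            },
            seed=int(payload["seed"]),
        )


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def grouped_split(
    records: Sequence[TreeRecord],
    test_fraction: float = 0.2,
    per_species_test_counts: Mapping[str, int] | None = None,
    seed: int = 0,
) -> SplitManifest:
    """Randomly assign whole trees to train/test, stratified by species.

    Without explicit counts, each species contributes
    ``round(test_fraction * n_trees)`` test trees (half-away-from-zero, floor
    of one).  Explicit ``per_species_test_counts`` reproduce a given design
    exactly.  Reproducible for a fixed seed.
    """
    if not records:
        raise ValueError("no records to split")
    if per_species_test_counts is None and not 0 < test_fraction < 1:
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")

    by_species: dict[str, list[TreeRecord]] = {}
    for r in records:
        by_species.setdefault(r.species, []).append(r)

    rng = np.random.default_rng(seed)
    train: set[str] = set()
    test: set[str] = set()
    test_counts: dict[str, int] = {}
    for species in sorted(by_species):
        group = by_species[species]
        n = len(group)
        if n < 2:
            raise ValueError(f"species {species!r} has {n} tree(s); need >= 2 to split")
        if per_species_test_counts is not None:
            if species not in per_species_test_counts:
                raise ValueError(f"no test count given for species {species!r}")
            k = int(per_species_test_counts[species])
        else:
            k = max(1, _round_half_away(test_fraction * n))
        if not 1 <= k < n:
            raise ValueError(
                f"species {species!r}: test count {k} must be in [1, {n - 1}]"
            )
        order = rng.permutation(n)
        ids = [group[i].tree_id for i in order]
        test.update(ids[:k])
        train.update(ids[k:])
        test_counts[species] = k

    return SplitManifest(
        train_tree_ids=frozenset(train),
        test_tree_ids=frozenset(test),
        per_species_test_counts=test_counts,
        seed=seed,
    )


def assemble_datasets(
    images: Sequence[GrayImage],
    manifest: SplitManifest,
    species_by_tree: Mapping[str, str],
) -> tuple[list[tuple[GrayImage, str]], list[tuple[GrayImage, str]]]:
    """Route labeled images into (train, test) lists by tree membership.

    Every image's tree must appear in the manifest; augmented images are
    asserted to land in the training partition only.
    """
    train: list[tuple[GrayImage, str]] = []
    test: list[tuple[GrayImage, str]] = []
    for img in images:
        part = manifest.partition_of(img.tree_id)  # KeyError if unknown
        species = species_by_tree[img.tree_id]
        if part == "train":
            train.append((img, species))
        else:
            if img.augmented:
                raise AssertionError(
                    f"augmented image of test tree {img.tree_id!r}: "
                    "augmentation must happen after the split, on training trees"
                )
            test.append((img, species))
    return train, test


def study_image_table(
    tree_counts: Mapping[str, int],
    test_tree_counts: Mapping[str, int] | None = None,
    n_views: int = 10,
    minority_threshold_images: int = 1000,
    n_aug_per_minority: int = 400,
) -> pd.DataFrame:
    """Image bookkeeping for a study design (no rendering involved).

    For each species: tree count, base images (``n_views`` per tree), images
    after the minority balancing policy, and — when test-tree counts are
    given — training/test image counts under a grouped split (augmented
    images all belong to training).
    """
    rows = []
    for sp, n_trees in tree_counts.items():
        base = n_views * n_trees
        aug = n_aug_per_minority if base < minority_threshold_images else 0
        row: dict[str, object] = {
            "species": sp,
            "n_trees": n_trees,
            "base_images": base,
            "images_after_augmentation": base + aug,
        }
        if test_tree_counts is not None:
            k = int(test_tree_counts[sp])
            if not 1 <= k < n_trees:
                raise ValueError(f"species {sp!r}: bad test tree count {k}")
            row["test_images"] = n_views * k
            row["train_images"] = base + aug - n_views * k
        rows.append(row)
    return pd.DataFrame(rows).set_index("species")
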
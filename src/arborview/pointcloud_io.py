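"""Reading, validation, centering and subsampling of single-tree point clouds.

Clouds are plain-text xyz files (whitespace- or comma-delimited, optionally
gzipped), one point per row in meters, with z as the vertical axis.  A stand
is described by a manifest CSV with columns ``tree_id, species, cloud_path``.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PointCloud",
    "TreeRecord",
    "DEFAULT_SPECIES",
    "EmptyCloudError",
    "XyzParseError",
    "read_xyz",
    "write_xyz",
    "center_cloud",
    "subsample",
    "read_manifest",
    "write_manifest",
]

#: Species label set of the reference seven-species temperate-forest study.
DEFAULT_SPECIES = (
    "beech",
    "red_oak",
    "ash",
    "oak",
    "douglas_fir",
    "spruce",
    "pine",
)


class EmptyCloudError(ValueError):
    """Raised when an operation receives or would produce an empty cloud."""


class XyzParseError(ValueError):
    """Raised when an xyz file contains a malformed line."""


@dataclass(frozen=True)
class PointCloud:
    """An ordered set of 3D points (meters) belonging to one tree.

    ``points`` is an (N, 3) float array with columns x, y, z; z is the
    vertical axis, so ``height`` is the z-extent of the cloud.
    """

    points: np.ndarray
    tree_id: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"points must be (N, 3), got shape {pts.shape}")
        if pts.shape[0] == 0:
            raise EmptyCloudError(f"point cloud {self.tree_id!r} is empty")
        if not np.isfinite(pts).all():
            raise ValueError(f"point cloud {self.tree_id!r} has non-finite coordinates")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def height(self) -> float:
        """Vertical extent max(z) - min(z) in meters."""
        z = self.points[:, 2]
        return float(z.max() - z.min())

    def with_points(self, points: np.ndarray) -> "PointCloud":
        return PointCloud(points=points, tree_id=self.tree_id)


@dataclass(frozen=True)
class TreeRecord:
    """Manifest entry: one tree, its species label, and its cloud file."""

    tree_id: str
    species: str
    cloud_path: str = ""

    def validate(self, species_set: Sequence[str] = DEFAULT_SPECIES) -> None:
        if self.species not in species_set:
            raise ValueError(
                f"species {self.species!r} of tree {self.tree_id!r} not in "
                f"configured label set {list(species_set)}"
            )


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "r")


def read_xyz(path: str | Path, tree_id: str | None = None) -> PointCloud:
    """Read a plain-text xyz point cloud.

    Each non-empty, non-comment (``#``) line must hold at least three numeric
    fields (x, y, z in meters); extra fields such as intensity or RGB are
    ignored.  Fields may be separated by whitespace and/or commas.

    Raises
    ------
    FileNotFoundError / OSError
        if the file cannot be read.
    XyzParseError
        naming the offending line number if a line has fewer than three
        numeric fields.
    EmptyCloudError
        if the file contains no points.
    """
    path = Path(path)
    rows: list[tuple[float, float, float]] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            fields = text.replace(",", " ").split()
            if len(fields) < 3:
                raise XyzParseError(
                    f"{path}: line {lineno}: expected >= 3 numeric fields, "
                    f"got {len(fields)}: {text!r}"
                )
            try:
                x, y, z = float(fields[0]), float(fields[1]), float(fields[2])
            except ValueError as exc:
                raise XyzParseError(
                    f"{path}: line {lineno}: non-numeric coordinate in {text!r}"
                ) from exc
            rows.append((x, y, z))
    if not rows:
        raise EmptyCloudError(f"{path}: no points found")
    tid = tree_id if tree_id is not None else path.name.removesuffix(".gz").rsplit(".", 1)[0]
    return PointCloud(points=np.array(rows, dtype=float), tree_id=tid)


def write_xyz(cloud: PointCloud, path: str | Path) -> None:
    """Write a cloud as whitespace-delimited xyz text (gzip if *.gz)."""
    path = Path(path)
    opener = gzip.open(path, "wt") if path.suffix == ".gz" else open(path, "w")
    with opener as fh:
        np.savetxt(fh, cloud.points, fmt="%.6f")


def center_cloud(cloud: PointCloud) -> PointCloud:
    """Translate a cloud so the xy-centroid is (0, 0) and min(z) = 0.

    A rigid translation: pairwise distances and the cloud's shape are
    unchanged.  Idempotent.
    """
    pts = cloud.points
    offset = np.array([pts[:, 0].mean(), pts[:, 1].mean(), pts[:, 2].min()])
    return cloud.with_points(pts - offset)


def subsample(cloud: PointCloud, n: int = 6000, seed: int = 0) -> PointCloud:
    """Draw n distinct points uniformly without replacement (seeded).

    Clouds with fewer than n points are returned whole with a warning;
    sampling with replacement would fabricate duplicate markers.
    """
    if n < 1:
        raise ValueError(f"subsample size must be >= 1, got {n}")
    m = len(cloud)
    if m < n:
        warnings.warn(
            f"cloud {cloud.tree_id!r} has {m} < {n} points; using the whole cloud",
            stacklevel=2,
        )
        return cloud
    if m == n:
        return cloud
    rng = np.random.default_rng(seed)
    idx = rng.choice(m, size=n, replace=False)
    return cloud.with_points(cloud.points[np.sort(idx)])


def read_manifest(
    path: str | Path, species_set: Sequence[str] | None = None
) -> list[TreeRecord]:
    """Read a manifest CSV (tree_id, species, cloud_path) into TreeRecords.

    tree_ids must be unique; species must belong to ``species_set`` when one
    is given.
    """
    df = pd.read_csv(path, dtype=str)
    required = {"tree_id", "species", "cloud_path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
    records = [
        TreeRecord(tree_id=r.tree_id, species=r.species, cloud_path=r.cloud_path)
        for r in df.itertuples()
    ]
    ids = [r.tree_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"{path}: duplicate tree_ids {dupes}")
    if species_set is not None:
        for r in records:
            r.validate(species_set)
    return records


def write_manifest(records: Iterable[TreeRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.tree_id, r.species, r.cloud_path) for r in records],
        columns=["tree_id", "species", "cloud_path"],
    )
    df.to_csv(path, index=False)
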
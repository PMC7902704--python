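"""Input preparation for point-set (PointNet-style) classification.

Only the data preparation is provided, not the network: the lowest 30% of
points — mostly dense stem returns carrying little species signal — are cut,
then fixed-size random samples (2,048 points, ten repeats per tree) are
drawn.  Because TLS point density is much higher near the ground, cutting
30% of points removes only a small fraction of tree height.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .pointcloud_io import EmptyCloudError, PointCloud, write_xyz

__all__ = [
    "PointSample",
    "trim_lowest_points",
    "make_pointnet_samples",
    "samples_to_table",
]


@dataclass(frozen=True)
class PointSample:
    """A fixed-size point sample: one network input."""

    points: np.ndarray
    tree_id: str
    repeat_index: int

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"points must be (n, 3), got {pts.shape}")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return self.points.shape[0]


def trim_lowest_points(cloud: PointCloud, fraction: float = 0.3) -> PointCloud:
    """Remove the floor(fraction * N) points with smallest z.

    Ties in z are broken by input order (earlier rows cut first); the kept
    points preserve their original order.  fraction = 0 is the identity.
    """
    if not 0 <= fraction < 1:
        raise ValueError(f"fraction must be in [0, 1), got {fraction}")
    n = len(cloud)
    k = int(np.floor(fraction * n))
    if k == 0:
        return cloud
    if k >= n:
        raise EmptyCloudError("trim would remove every point")
    order = np.argsort(cloud.points[:, 2], kind="stable")
    keep = np.sort(order[k:])
    return cloud.with_points(cloud.points[keep])


def make_pointnet_samples(
    cloud: PointCloud,
    n_points: int = 2048,
    n_repeats: int = 10,
    fraction: float = 0.3,
    seed: int = 0,
) -> list[PointSample]:
    """Trim once, then draw ``n_repeats`` seeded samples of ``n_points``.

    Samples are drawn without replacement from the trimmed cloud; if the
    trimmed cloud is smaller than ``n_points``, sampling falls back to
    replacement with a warning.
    """
    if n_points < 1 or n_repeats < 1:
        raise ValueError("n_points and n_repeats must be >= 1")
    trimmed = trim_lowest_points(cloud, fraction)
    m = len(trimmed)
    replace = m < n_points
    if replace:
        warnings.warn(
            f"trimmed cloud {cloud.tree_id!r} has {m} < {n_points} points; "
            "sampling with replacement",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    samples = []
    for rep in range(n_repeats):
        idx = rng.choice(m, size=n_points, replace=replace)
        samples.append(
            PointSample(
                points=trimmed.points[idx], tree_id=cloud.tree_id, repeat_index=rep
            )
        )
    return samples


def samples_to_table(samples: Sequence[PointSample]) -> pd.DataFrame:
    """Pack samples into one long table (tree_id, repeat_index, x, y, z)."""
    frames = []
    for s in samples:
        df = pd.DataFrame(s.points, columns=["x", "y", "z"])
        df.insert(0, "repeat_index", s.repeat_index)
        df.insert(0, "tree_id", s.tree_id)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def export_samples(samples: Sequence[PointSample], out_dir: str | Path) -> None:
    """Write each sample as an xyz file <tree_id>_s<repeat>.xyz."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in samples:
        write_xyz(
            PointCloud(points=s.points, tree_id=s.tree_id),
            out / f"{s.tree_id}_s{s.repeat_index}.xyz",
        )
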
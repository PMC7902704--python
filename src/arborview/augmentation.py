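"""Class-balancing image augmentation for underrepresented species.

Augmented images are produced from *training* trees only, after the grouped
split, so no augmented copy of a test tree can leak into training.  Each
augmented image applies, in order: small random rotations of the point cloud
about all three axes, a fresh render, then image-space perturbations (shift,
Gaussian pixel noise, unsharp-mask sharpening, contrast change).

The balancing policy mirrors the reference study's bookkeeping: a species
whose base image pool (views x total tree count) falls below
``minority_threshold_images`` receives exactly ``n_aug_per_minority``
additional training images; all other species are left untouched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .pointcloud_io import PointCloud, TreeRecord, center_cloud, read_xyz, subsample
from .projection import GrayImage, RenderConfig, render_view

__all__ = [
    "AugmentConfig",
    "rotate_xyz",
    "augment_once",
    "balance_training_set",
    "needs_augmentation",
    "plan_balance",
]

#: view_index offset marking augmented images; keeps provenance unambiguous.
AUGMENTED_VIEW_BASE = 1000


@dataclass(frozen=True)
class AugmentConfig:
    """Magnitudes of the augmentation transforms and the balancing policy.

    Tilts about the horizontal axes are kept weak (default 10 degrees) so an
    augmented tree still stands upright; the z-rotation is unconstrained
    because azimuth carries no species information.  Image-space magnitudes
    are conservative so augmented images remain plausible renders.
    """

    max_tilt_deg: float = 10.0
    max_z_rot_deg: float = 360.0
    max_shift_frac: float = 0.05
    noise_sigma_gray: float = 5.0
    sharpen_amount: float = 0.5
    contrast_factor_range: tuple[float, float] = (0.8, 1.2)
    n_aug_per_minority: int = 400
    minority_threshold_images: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("max_tilt_deg", "max_z_rot_deg", "max_shift_frac", "noise_sigma_gray"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.sharpen_amount <= 1:
            raise ValueError("sharpen_amount must be in [0, 1]")
        lo, hi = self.contrast_factor_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid contrast_factor_range ({lo}, {hi})")
        if self.n_aug_per_minority < 0:
            raise ValueError("n_aug_per_minority must be >= 0")


def rotate_xyz(
    cloud: PointCloud, ax_deg: float, ay_deg: float, az_deg: float
) -> PointCloud:
    """Rigid rotation about the cloud centroid: x-tilt, then y-tilt, then z."""
    if ax_deg == ay_deg == az_deg == 0.0:
        return cloud
    a, b, c = np.deg2rad([ax_deg, ay_deg, az_deg])
    rx = np.array(
        [[1, 0, 0], [0, np.cos(a), -np.sin(a)], [0, np.sin(a), np.cos(a)]]
    )
    ry = np.array(
        [[np.cos(b), 0, np.sin(b)], [0, 1, 0], [-np.sin(b), 0, np.cos(b)]]
    )
    rz = np.array(
        [[np.cos(c), -np.sin(c), 0], [np.sin(c), np.cos(c), 0], [0, 0, 1]]
    )
    rot = rz @ ry @ rx
    centroid = cloud.points.mean(axis=0)
    return cloud.with_points((cloud.points - centroid) @ rot.T + centroid)


def _shift_image(px: np.ndarray, drow: int, dcol: int, fill: int) -> np.ndarray:
    """Integer shift with background fill (no wrap-around)."""
    if drow == 0 and dcol == 0:
        return px
    out = np.full_like(px, fill)
    H, W = px.shape
    rs, re = max(drow, 0), min(H + drow, H)
    cs, ce = max(dcol, 0), min(W + dcol, W)
    out[rs:re, cs:ce] = px[rs - drow : re - drow, cs - dcol : ce - dcol]
    return out


def augment_once(
    cloud: PointCloud,
    render_config: RenderConfig = RenderConfig(),
    aug_config: AugmentConfig = AugmentConfig(),
    seed: int = 0,
    subsample_n: int = 6000,
    view_index: int = AUGMENTED_VIEW_BASE,
) -> GrayImage:
    """Produce one augmented view of a tree.

    With every magnitude zero (and contrast range (1, 1)) the output equals
    the plain 0-degree render bit-for-bit, which pins down the transform
    order and guards against drift in the implementation.
    """
    rng = np.random.default_rng(seed)
    cfg = aug_config

    ax = rng.uniform(-cfg.max_tilt_deg, cfg.max_tilt_deg) if cfg.max_tilt_deg else 0.0
    ay = rng.uniform(-cfg.max_tilt_deg, cfg.max_tilt_deg) if cfg.max_tilt_deg else 0.0
    az = rng.uniform(0.0, cfg.max_z_rot_deg) if cfg.max_z_rot_deg else 0.0
    sampled = subsample(cloud, n=subsample_n, seed=int(rng.integers(2**31)))
    rotated = rotate_xyz(sampled, ax, ay, az)
    base = render_view(rotated, render_config, view_index=view_index)

    px = base.pixels.astype(np.float64)
    H, W = px.shape
    max_dr = int(round(cfg.max_shift_frac * H))
    max_dc = int(round(cfg.max_shift_frac * W))
    drow = int(rng.integers(-max_dr, max_dr + 1)) if max_dr else 0
    dcol = int(rng.integers(-max_dc, max_dc + 1)) if max_dc else 0
    px = _shift_image(px, drow, dcol, render_config.background)

    if cfg.noise_sigma_gray > 0:
        px = px + rng.normal(0.0, cfg.noise_sigma_gray, size=px.shape)
    if cfg.sharpen_amount > 0:
        px = px + cfg.sharpen_amount * (px - gaussian_filter(px, sigma=1.0))
    factor = rng.uniform(*cfg.contrast_factor_range)
    px = 127.5 + factor * (px - 127.5)

    px = np.clip(np.rint(px), 0, 255).astype(np.uint8)
    return GrayImage(
        pixels=px, tree_id=cloud.tree_id, view_index=view_index, augmented=True
    )


def needs_augmentation(base_image_count: int, config: AugmentConfig) -> bool:
    """Minority rule: augment species with fewer base images than threshold."""
    return base_image_count < config.minority_threshold_images


def plan_balance(
    base_image_counts: Mapping[str, int], config: AugmentConfig = AugmentConfig()
) -> dict[str, int]:
    """Per-species image totals after applying the balancing policy.

    Pure bookkeeping (no rendering): species below the minority threshold
    gain exactly ``n_aug_per_minority`` images, others are unchanged.
    """
    return {
        sp: n + (config.n_aug_per_minority if needs_augmentation(n, config) else 0)
        for sp, n in base_image_counts.items()
    }


def _default_loader(record: TreeRecord) -> PointCloud:
    return center_cloud(read_xyz(record.cloud_path, tree_id=record.tree_id))


def balance_training_set(
    train_images_by_species: Mapping[str, Sequence[GrayImage]],
    train_records_by_species: Mapping[str, Sequence[TreeRecord]],
    base_image_counts: Mapping[str, int],
    render_config: RenderConfig = RenderConfig(),
    aug_config: AugmentConfig = AugmentConfig(),
    subsample_n: int = 6000,
    load_cloud: Callable[[TreeRecord], PointCloud] = _default_loader,
) -> dict[str, list[GrayImage]]:
    """Append augmented images to the training pools of minority species.

    ``base_image_counts`` maps species to its full (train + test) base image
    count, which decides minority status; only training trees are drawn from
    to build the new images.  Species at or above the threshold are returned
    unchanged.  Test pools are never touched by construction.
    """
    missing = set(train_images_by_species) - set(train_records_by_species)
    if missing:
        raise ValueError(f"species missing from training records: {sorted(missing)}")
    rng = np.random.default_rng(aug_config.seed)
    out: dict[str, list[GrayImage]] = {}
    for species in train_images_by_species:
        pool = list(train_images_by_species[species])
        base_count = base_image_counts[species]
        if needs_augmentation(base_count, aug_config):
            records = list(train_records_by_species[species])
            if not records:
                raise ValueError(
                    f"species {species!r} needs augmentation but has no training trees"
                )
            cache: dict[str, PointCloud] = {}
            for i in range(aug_config.n_aug_per_minority):
                rec = records[int(rng.integers(len(records)))]
                if rec.tree_id not in cache:
                    cache[rec.tree_id] = load_cloud(rec)
                img = augment_once(
                    cache[rec.tree_id],
                    render_config,
                    aug_config,
                    seed=int(rng.integers(2**31)),
                    subsample_n=subsample_n,
                    view_index=AUGMENTED_VIEW_BASE + i,
                )
                pool.append(img)
        out[species] = pool
    return out
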
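"""Multi-view depth-encoded grayscale rendering of tree point clouds.

Each tree is rendered as ``n_views`` orthographic side views, evenly spaced
in azimuth about the vertical axis.  A view projects the cloud along y onto
the x-z plane; the point's y-coordinate (viewing depth) is encoded as gray
level — nearest point darkest (``gray_near``), farthest lightest
(``gray_far``) — so depth survives the drop from 3D to 2D.  Where markers
overlap the nearer point wins (painter's order).  The cloud's bounding box
is fitted inside the raster preserving aspect ratio, so absolute tree size
is not encoded in pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .pointcloud_io import EmptyCloudError, PointCloud, subsample

__all__ = [
    "RenderConfig",
    "GrayImage",
    "rotate_z",
    "render_view",
    "generate_views",
    "save_images",
    "load_images",
]


@dataclass(frozen=True)
class RenderConfig:
    """Geometry and gray-mapping parameters of the view renderer.

    Defaults: 150 x 100 px 8-bit rasters, ten views 36 degrees apart,
    3x3 disc markers, depth mapped to gray 0 (near) .. 200 (far) on white
    (255) background so the farthest markers stay distinguishable from it.
    """

    width_px: int = 100
    height_px: int = 150
    n_views: int = 10
    marker_radius_px: int = 1
    gray_near: int = 0
    gray_far: int = 200
    background: int = 255
    margin_frac: float = 0.05

    def __post_init__(self) -> None:
        if not (0 <= self.gray_near < self.gray_far <= 255):
            raise ValueError(
                f"need 0 <= gray_near < gray_far <= 255, got "
                f"({self.gray_near}, {self.gray_far})"
            )
        if self.gray_near <= self.background <= self.gray_far:
            raise ValueError("background gray must lie outside [gray_near, gray_far]")
        if self.n_views < 1:
            raise ValueError("n_views must be >= 1")
        if self.width_px < 8 or self.height_px < 8:
            raise ValueError("raster must be at least 8 x 8 pixels")
        if not 0 <= self.margin_frac < 0.5:
            raise ValueError("margin_frac must be in [0, 0.5)")
        if self.marker_radius_px < 0:
            raise ValueError("marker_radius_px must be >= 0")


@dataclass(frozen=True)
class GrayImage:
    """A single 8-bit grayscale view with provenance."""

    pixels: np.ndarray
    tree_id: str
    view_index: int
    augmented: bool = False

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"pixels must be 2D, got shape {px.shape}")
        if px.dtype != np.uint8:
            raise ValueError(f"pixels must be uint8, got {px.dtype}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def rotate_z(cloud: PointCloud, angle_deg: float) -> PointCloud:
    """Rigidly rotate a cloud about the vertical axis through its xy-centroid."""
    if not np.isfinite(angle_deg):
        raise ValueError(f"angle must be finite, got {angle_deg}")
    theta = np.deg2rad(angle_deg)
    c, s = np.cos(theta), np.sin(theta)
    pts = cloud.points
    cx, cy = pts[:, 0].mean(), pts[:, 1].mean()
    x = pts[:, 0] - cx
    y = pts[:, 1] - cy
    out = pts.copy()
    out[:, 0] = c * x - s * y + cx
    out[:, 1] = s * x + c * y + cy
    return cloud.with_points(out)


def _disc_offsets(radius: int) -> tuple[np.ndarray, np.ndarray]:
    """Integer pixel offsets of a filled disc; radius 1 gives the full 3x3."""
    r = np.arange(-radius, radius + 1)
    dr, dc = np.meshgrid(r, r, indexing="ij")
    keep = dr**2 + dc**2 <= (radius + 0.5) ** 2
    return dr[keep], dc[keep]


def render_view(
    cloud: PointCloud, config: RenderConfig = RenderConfig(), view_index: int = 0
) -> GrayImage:
    """Render one orthographic depth-encoded view of a cloud.

    The x-z bounding box is fitted inside the raster (aspect preserved,
    ``margin_frac`` border); each point becomes a filled disc whose gray is a
    linear map of its y-coordinate over the cloud's per-view depth range.
    Overlaps resolve to the nearer (darker) point.  Row 0 is the top of the
    tree.  A degenerate depth range (all y equal) renders at ``gray_near``.
    """
    pts = cloud.points
    if pts.shape[0] == 0:
        raise EmptyCloudError("cannot render an empty cloud")
    H, W = config.height_px, config.width_px
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]

    xmin, xmax = x.min(), x.max()
    zmin, zmax = z.min(), z.max()
    xrange = max(xmax - xmin, 1e-12)
    zrange = max(zmax - zmin, 1e-12)
    avail_w = W * (1.0 - 2.0 * config.margin_frac)
    avail_h = H * (1.0 - 2.0 * config.margin_frac)
    scale = min(avail_w / xrange, avail_h / zrange)

    col = np.rint((x - (xmin + xmax) / 2.0) * scale + (W - 1) / 2.0).astype(np.int64)
    row = np.rint((H - 1) / 2.0 - (z - (zmin + zmax) / 2.0) * scale).astype(np.int64)

    ymin, ymax = y.min(), y.max()
    if ymax - ymin <= 0:
        gray = np.full(pts.shape[0], config.gray_near, dtype=np.int64)
    else:
        frac = (y - ymin) / (ymax - ymin)
        gray = np.rint(
            config.gray_near + frac * (config.gray_far - config.gray_near)
        ).astype(np.int64)

    img = np.full((H, W), config.background, dtype=np.int64)
    dr, dc = _disc_offsets(config.marker_radius_px)
    rows = (row[:, None] + dr[None, :]).ravel()
    cols = (col[:, None] + dc[None, :]).ravel()
    grays = np.broadcast_to(gray[:, None], (pts.shape[0], dr.size)).ravel()
    inside = (rows >= 0) & (rows < H) & (cols >= 0) & (cols < W)
    # nearer point = strictly smaller gray, so painter's far-to-near order
    # is equivalent to a per-pixel minimum over covering discs
    np.minimum.at(img, (rows[inside], cols[inside]), grays[inside])

    return GrayImage(
        pixels=img.astype(np.uint8),
        tree_id=cloud.tree_id,
        view_index=view_index,
        augmented=False,
    )


def generate_views(
    cloud: PointCloud,
    config: RenderConfig = RenderConfig(),
    subsample_n: int = 6000,
    seed: int = 0,
) -> list[GrayImage]:
    """Render the evenly spaced rotational views of one tree.

    The cloud is subsampled once (``subsample_n`` points, seeded) and then
    rendered at ``n_views`` azimuths 360/n_views degrees apart starting at 0.
    """
    sampled = subsample(cloud, n=subsample_n, seed=seed)
    step = 360.0 / config.n_views
    views = []
    for k in range(config.n_views):
        rotated = rotate_z(sampled, k * step) if k else sampled
        img = render_view(rotated, config, view_index=k)
        views.append(img)
    return views


def image_filename(img: GrayImage) -> str:
    return f"{img.tree_id}_v{img.view_index}.png"


def save_images(
    images: Iterable[GrayImage],
    out_dir: str | Path,
    species_by_tree: Mapping[str, str] | None = None,
    index_name: str = "index.csv",
) -> pd.DataFrame:
    """Write images as 8-bit PNGs plus a CSV index.

    Index columns: image_path, tree_id, species, view_index, augmented.
    Returns the index as a DataFrame.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for img in images:
        name = image_filename(img)
        Image.fromarray(img.pixels, mode="L").save(out_dir / name)
        species = species_by_tree.get(img.tree_id, "") if species_by_tree else ""
        rows.append((name, img.tree_id, species, img.view_index, img.augmented))
    index = pd.DataFrame(
        rows, columns=["image_path", "tree_id", "species", "view_index", "augmented"]
    )
    index.to_csv(out_dir / index_name, index=False)
    return index


def load_images(
    image_dir: str | Path, index: pd.DataFrame | str | Path
) -> list[GrayImage]:
    """Load images listed in an index CSV back into GrayImage objects."""
    image_dir = Path(image_dir)
    if not isinstance(index, pd.DataFrame):
        index = pd.read_csv(index)
    out = []
    for r in index.itertuples():
        px = np.asarray(Image.open(image_dir / r.image_path), dtype=np.uint8)
        out.append(
            GrayImage(
                pixels=px,
                tree_id=str(r.tree_id),
                view_index=int(r.view_index),
                augmented=bool(r.augmented),
            )
        )
    return out
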
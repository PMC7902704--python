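"""Shared test utilities, including the brute-force rendering oracle."""

from __future__ import annotations

import numpy as np

from arborview.pointcloud_io import PointCloud
from arborview.projection import GrayImage, RenderConfig


def cloud_from(points, tree_id="t") -> PointCloud:
    return PointCloud(points=np.asarray(points, dtype=float), tree_id=tree_id)


def random_cloud(rng: np.random.Generator, n: int, tree_id="t") -> PointCloud:
    pts = rng.uniform(-3, 3, size=(n, 3))
    pts[:, 2] = rng.uniform(0, 10, size=n)
    return PointCloud(points=pts, tree_id=tree_id)


def brute_force_render(cloud: PointCloud, config: RenderConfig) -> np.ndarray:
    """Per-pixel minimum-depth rasterizer: for every pixel, scan all discs
    and keep the cover of smallest depth.  Independent of painter's order."""
    pts = cloud.points
    H, W = config.height_px, config.width_px
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]

    xmin, xmax = x.min(), x.max()
    zmin, zmax = z.min(), z.max()
    xrange = max(xmax - xmin, 1e-12)
    zrange = max(zmax - zmin, 1e-12)
    scale = min(
        W * (1 - 2 * config.margin_frac) / xrange,
        H * (1 - 2 * config.margin_frac) / zrange,
    )
    col = np.rint((x - (xmin + xmax) / 2) * scale + (W - 1) / 2).astype(int)
    row = np.rint((H - 1) / 2 - (z - (zmin + zmax) / 2) * scale).astype(int)
    ymin, ymax = y.min(), y.max()
    if ymax - ymin <= 0:
        gray = np.full(len(pts), config.gray_near, dtype=float)
    else:
        gray = np.rint(
            config.gray_near
            + (y - ymin) / (ymax - ymin) * (config.gray_far - config.gray_near)
        )

    rr, cc = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    rr = rr.reshape(-1, 1)
    cc = cc.reshape(-1, 1)
    dist2 = (rr - row[None, :]) ** 2 + (cc - col[None, :]) ** 2
    covered = dist2 <= (config.marker_radius_px + 0.5) ** 2
    candidate = np.where(covered, gray[None, :], np.inf)
    best = candidate.min(axis=1)
    img = np.where(np.isinf(best), config.background, best)
    return img.reshape(H, W).astype(np.uint8)
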
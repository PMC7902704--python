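"""Procedural generator of labeled single-tree point clouds.

Emulates the gross morphology that separates conifer and broadleaf crowns in
terrestrial laser scans of adult trees: a tapered trunk, branch segments
(regular whorls for conifers, irregular upswept branches for broadleaves),
and a crown envelope (cone vs. ellipsoid) with surface-biased points.  Point
density increases toward the ground, as in real TLS clouds where the lower
stem is covered by every scan position: with default settings the lowest 30%
of points span only about a fifth of total tree height.

The generator is a study stand-in, not a botanical model — no leaves, bark
microstructure, or occlusion; see the methods note for what that implies.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from .pointcloud_io import PointCloud, TreeRecord, write_manifest, write_xyz

__all__ = [
    "ArchetypeParams",
    "CONIFER",
    "BROADLEAF",
    "INTERMEDIATE",
    "STUDY_TREE_COUNTS",
    "STUDY_TEST_TREE_COUNTS",
    "generate_tree",
    "generate_study",
    "reference_study_design",
]

#: Tree counts per species of the reference seven-species stand design.
STUDY_TREE_COUNTS: dict[str, int] = {
    "beech": 163,
    "red_oak": 100,
    "ash": 39,
    "oak": 22,
    "douglas_fir": 183,
    "spruce": 158,
    "pine": 25,
}

#: Test-tree counts implied by the reference design's per-species test image
#: pools at ten views per tree (350/190/70/40/370/310/50 images).
STUDY_TEST_TREE_COUNTS: dict[str, int] = {
    "beech": 35,
    "red_oak": 19,
    "ash": 7,
    "oak": 4,
    "douglas_fir": 37,
    "spruce": 31,
    "pine": 5,
}

DECIDUOUS = ("beech", "red_oak", "ash", "oak")
CONIFEROUS = ("douglas_fir", "spruce", "pine")


@dataclass(frozen=True)
class ArchetypeParams:
    """Morphological template of a synthetic tree species.

    ``archetype`` selects the crown envelope (cone for conifer, ellipsoid
    for broadleaf); ``crown_width_ratio`` is crown diameter over tree
    height; ``vertical_density_gradient`` g biases trunk point heights as
    z ~ H * u^(1+g), concentrating points near the ground.
    """

    archetype: str = "conifer"
    height_range: tuple[float, float] = (22.0, 32.0)
    trunk_taper: float = 0.85
    crown_base_frac: float = 0.2
    crown_width_ratio: float = 0.25
    branch_count_range: tuple[int, int] = (40, 60)
    branch_angle_range: tuple[float, float] = (70.0, 95.0)
    whorled: bool = True
    points_total: int = 20_000
    noise_sigma_m: float = 0.02
    vertical_density_gradient: float = 3.0

    def __post_init__(self) -> None:
        if self.archetype not in ("conifer", "broadleaf"):
            raise ValueError(f"unknown archetype {self.archetype!r}")
        lo, hi = self.height_range
        if not 0 < lo <= hi:
            raise ValueError(f"invalid height_range ({lo}, {hi})")
        if not 0 < self.crown_base_frac < 1:
            raise ValueError("crown_base_frac must be in (0, 1)")
        if self.crown_width_ratio <= 0:
            raise ValueError("crown_width_ratio must be > 0")
        if self.points_total < 100:
            raise ValueError("points_total must be >= 100")
        if self.vertical_density_gradient < 0:
            raise ValueError("vertical_density_gradient must be >= 0")
        b_lo, b_hi = self.branch_count_range
        if not 0 < b_lo <= b_hi:
            raise ValueError("invalid branch_count_range")


#: Conical whorled conifer (spruce/fir-like): narrow deep crown.
CONIFER = ArchetypeParams()

#: Spreading broadleaf (beech/oak-like): wide ellipsoidal crown, high crown base.
BROADLEAF = ArchetypeParams(
    archetype="broadleaf",
    height_range=(20.0, 30.0),
    trunk_taper=0.7,
    crown_base_frac=0.45,
    crown_width_ratio=0.6,
    branch_count_range=(15, 25),
    branch_angle_range=(30.0, 60.0),
    whorled=False,
)

#: Intermediate archetype (pine-like): conical but broader crown, irregular
#: branching; used for three-class tests.
INTERMEDIATE = ArchetypeParams(
    archetype="conifer",
    height_range=(20.0, 30.0),
    trunk_taper=0.8,
    crown_base_frac=0.35,
    crown_width_ratio=0.45,
    branch_count_range=(25, 40),
    branch_angle_range=(50.0, 75.0),
    whorled=False,
)


def _crown_radius(params: ArchetypeParams, z: np.ndarray, height: float) -> np.ndarray:
    """Crown envelope radius at height z (cone or ellipsoid profile)."""
    zb = params.crown_base_frac * height
    r_max = params.crown_width_ratio * height / 2.0
    if params.archetype == "conifer":
        prof = np.clip((height - z) / max(height - zb, 1e-9), 0.0, 1.0)
        return r_max * prof
    zc = (zb + height) / 2.0
    b = (height - zb) / 2.0
    inside = np.clip(1.0 - ((z - zc) / b) ** 2, 0.0, None)
    return r_max * np.sqrt(inside)


def generate_tree(
    params: ArchetypeParams, seed: int = 0, tree_id: str = "", label: str | None = None
) -> tuple[PointCloud, str]:
    """Generate one synthetic tree cloud; reproducible per seed.

    Points are allocated 45% trunk, 25% branches, 30% crown surface; the
    trunk share is height-biased toward the ground by the density gradient.
    Returns the cloud and its species label (the archetype name by default).
    """
    rng = np.random.default_rng(seed)
    H = rng.uniform(*params.height_range)
    width_jitter = rng.uniform(0.92, 1.08)
    p = replace(
        params,
        crown_width_ratio=params.crown_width_ratio * width_jitter,
    )
    zb = p.crown_base_frac * H
    n = p.points_total
    n_trunk = int(0.45 * n)
    n_branch = int(0.25 * n)
    n_crown = n - n_trunk - n_branch

    # trunk: tapered stack of noisy circular cross sections, ground-biased
    g = p.vertical_density_gradient
    zt = H * rng.random(n_trunk) ** (1.0 + g)
    r0 = 0.012 * H
    rt = r0 * (1.0 - p.trunk_taper * zt / H)
    phi = rng.uniform(0.0, 2.0 * np.pi, n_trunk)
    trunk = np.column_stack((rt * np.cos(phi), rt * np.sin(phi), zt))

    # branches: straight segments from the trunk inside the crown envelope
    n_br = int(rng.integers(p.branch_count_range[0], p.branch_count_range[1] + 1))
    if p.whorled:
        n_whorls = max(-(-n_br // 5), 1)
        whorl_z = np.linspace(zb, 0.95 * H, n_whorls)
        ins_z = np.repeat(whorl_z, 5)[:n_br]
        az = np.concatenate(
            [
                (2 * np.pi * np.arange(5) / 5 + rng.uniform(0, 2 * np.pi))
                for _ in range(n_whorls)
            ]
        )[:n_br]
    else:
        ins_z = rng.uniform(zb, 0.95 * H, n_br)
        az = rng.uniform(0.0, 2.0 * np.pi, n_br)
    polar = np.deg2rad(rng.uniform(*p.branch_angle_range, n_br))
    env_r = _crown_radius(p, ins_z, H)
    length = env_r * rng.uniform(0.7, 1.0, n_br) / np.maximum(np.sin(polar), 0.3)
    per_branch = np.full(n_br, n_branch // n_br)
    per_branch[: n_branch - per_branch.sum()] += 1
    t = rng.random(n_branch)
    branch_idx = np.repeat(np.arange(n_br), per_branch)
    dirs = np.column_stack(
        (
            np.sin(polar) * np.cos(az),
            np.sin(polar) * np.sin(az),
            np.cos(polar),
        )
    )
    starts = np.column_stack((np.zeros(n_br), np.zeros(n_br), ins_z))
    branch = starts[branch_idx] + (t * length[branch_idx])[:, None] * dirs[branch_idx]

    # crown: surface-biased points on the envelope
    if p.archetype == "conifer":
        zc = zb + (H - zb) * rng.random(n_crown) ** 1.3
        rc = _crown_radius(p, zc, H) * (0.85 + 0.15 * rng.random(n_crown))
        phic = rng.uniform(0.0, 2.0 * np.pi, n_crown)
        crown = np.column_stack((rc * np.cos(phic), rc * np.sin(phic), zc))
    else:
        center_z = (zb + H) / 2.0
        a = p.crown_width_ratio * H / 2.0
        b = (H - zb) / 2.0
        v = rng.normal(size=(n_crown, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        f = (0.85 + 0.15 * rng.random(n_crown))[:, None]
        crown = v * f * np.array([a, a, b])
        crown[:, 2] += center_z

    pts = np.vstack((trunk, branch, crown))
    pts += rng.normal(0.0, p.noise_sigma_m, size=pts.shape)
    pts[:, 2] -= pts[:, 2].min()
    lab = label if label is not None else params.archetype
    tid = tree_id or f"{lab}_{seed}"
    return PointCloud(points=pts, tree_id=tid), lab


def generate_study(
    per_species: Mapping[str, tuple[ArchetypeParams, int]],
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[list[TreeRecord], dict[str, PointCloud]]:
    """Generate a labeled multi-species stand of synthetic trees.

    Per-tree parameters are jittered via per-tree seeds spawned from the
    study seed.  With ``out_dir`` set, xyz files and a ``manifest.csv`` in
    the package's standard formats are written there.
    """
    if len(per_species) < 2:
        raise ValueError(f"need >= 2 species, got {len(per_species)}")
    rng = np.random.default_rng(seed)
    records: list[TreeRecord] = []
    clouds: dict[str, PointCloud] = {}
    for species in per_species:
        params, n_trees = per_species[species]
        if n_trees < 1:
            raise ValueError(f"species {species!r}: n_trees must be >= 1")
        for i in range(n_trees):
            tid = f"{species}_{i:03d}"
            tree_seed = int(rng.integers(2**31))
            cloud, _ = generate_tree(params, seed=tree_seed, tree_id=tid, label=species)
            clouds[tid] = cloud
            path = ""
            if out_dir is not None:
                path = str(Path(out_dir) / f"{tid}.xyz")
            records.append(TreeRecord(tree_id=tid, species=species, cloud_path=path))
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for rec in records:
            write_xyz(clouds[rec.tree_id], rec.cloud_path)
        write_manifest(records, out / "manifest.csv")
    return records, clouds


def reference_study_design(
    points_total: int = 8000,
) -> dict[str, tuple[ArchetypeParams, int]]:
    """Synthetic stand-in for the reference seven-species design.

    Deciduous species map to broadleaf-derived archetypes, conifers to
    conifer-derived ones, with tree counts from ``STUDY_TREE_COUNTS``.
    """
    base = {
        "beech": BROADLEAF,
        "red_oak": replace(BROADLEAF, crown_width_ratio=0.55),
        "ash": replace(BROADLEAF, crown_width_ratio=0.5, crown_base_frac=0.5),
        "oak": replace(BROADLEAF, crown_width_ratio=0.65, crown_base_frac=0.4),
        "douglas_fir": CONIFER,
        "spruce": replace(CONIFER, crown_width_ratio=0.3),
        "pine": INTERMEDIATE,
    }
    return {
        sp: (replace(base[sp], points_total=points_total), STUDY_TREE_COUNTS[sp])
        for sp in STUDY_TREE_COUNTS
    }
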
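"""Synthetic root-in-soil CT phantoms with voxel-level ground truth.

The generator reproduces the imaging properties that make real root scans
hard: root and soil grey values that overlap (a configurable fraction of
soil voxels is drawn from the root intensity distribution, standing in for
organic matter), root attenuation that drifts with depth, dark air-filled
pores, and branched geometries including upward-growing laterals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from rootvox.traits import (
    TraitReport,
    count_direction_changes,
    measure_convex_hull_volume,
    measure_max_width,
    measure_surface_area,
    measure_volume,
)
from rootvox.volume_io import ImageStack, Segmentation

__all__ = [
    "BranchSpec",
    "PhantomSpec",
    "rasterize_branches",
    "render_greyscale",
    "builtin_phantoms",
    "true_traits",
    "BUILTIN_NAMES",
]

BUILTIN_NAMES = ("gravitropic", "y_branch", "one_upward_lateral", "fig2_like")


@dataclass
class BranchSpec:
    """One root branch: a tapered tube swept along a piecewise-linear path.

    ``plagiotropic`` (any segment of the centerline decreasing in slice
    index, i.e. growing upward) is derived from the control points.
    """

    control_points: list[tuple[float, float, float]]  # (slice, row, col)
    radius_start: float
    radius_end: float
    parent: Optional[int] = None
    plagiotropic: bool = field(init=False)

    def __post_init__(self) -> None:
        if len(self.control_points) < 2:
            raise ValueError("branch needs >= 2 control points")
        if self.radius_start <= 0 or self.radius_end <= 0:
            raise ValueError("radii must be > 0")
        pts = np.asarray(self.control_points, dtype=float)
        self.plagiotropic = bool(np.any(np.diff(pts[:, 0]) < 0))

    def point_at(self, t: float) -> tuple[float, float, float]:
        """Point at arc-length fraction t in [0, 1] along the centerline."""
        pts = np.asarray(self.control_points, dtype=float)
        seg_len = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg_len)])
        s = t * cum[-1]
        i = int(np.searchsorted(cum[1:], s, side="right"))
        i = min(i, len(seg_len) - 1)
        local = (s - cum[i]) / seg_len[i] if seg_len[i] > 0 else 0.0
        p = pts[i] + local * (pts[i + 1] - pts[i])
        return (float(p[0]), float(p[1]), float(p[2]))


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int]  # (slices, rows, cols)
    branches: list[BranchSpec]
    root_mu_top: float = 180.0
    root_mu_bottom: float = 140.0
    root_sigma: float = 8.0
    soil_mu: float = 90.0
    soil_sigma: float = 12.0
    organic_fraction: float = 0.02
    pore_fraction: float = 0.05
    blur_sigma: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("organic_fraction", "pore_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.organic_fraction + self.pore_fraction > 1.0:
            raise ValueError("organic_fraction + pore_fraction must be <= 1")


def rasterize_branches(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize every branch as a tapered capsule along its centerline.

    A voxel belongs to a branch when its centre lies within the local
    (linearly interpolated) radius of one of the centerline segments, which
    is equivalent to a dense ball sweep but exact.  Returns (mask,
    branch_labels): the union mask and a per-voxel branch id stack (1-based
    branch ids in list order; the lowest id wins at overlaps, so junction
    voxels belong to the parent when parents are listed first).
    """
    mask = np.zeros(spec.shape, dtype=bool)
    labels = np.zeros(spec.shape, dtype=np.int16)
    shape = np.asarray(spec.shape)
    for bid, branch in enumerate(spec.branches, start=1):
        pts = np.asarray(branch.control_points, dtype=float)
        seg_len = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg_len)])
        total = max(float(cum[-1]), 1e-12)
        rmax = max(branch.radius_start, branch.radius_end)
        # centerline must stay inside the stack; lateral overhang is an
        # error, top/bottom overhang is clipped (taproots span full depth)
        if pts[:, 0].min() < -0.5 or pts[:, 0].max() > shape[0] - 0.5:
            raise ValueError(f"branch {bid} centerline exits the volume (slice axis)")
        if (
            (pts[:, 1] - rmax).min() < -0.5 or (pts[:, 1] + rmax).max() > shape[1] - 0.5
            or (pts[:, 2] - rmax).min() < -0.5 or (pts[:, 2] + rmax).max() > shape[2] - 0.5
        ):
            raise ValueError(f"branch {bid} exits the volume")
        bmask = np.zeros(spec.shape, dtype=bool)
        for i in range(len(pts) - 1):
            p0, p1 = pts[i], pts[i + 1]
            lo = np.maximum(np.floor(np.minimum(p0, p1) - rmax - 1).astype(int), 0)
            hi = np.minimum(np.ceil(np.maximum(p0, p1) + rmax + 1).astype(int) + 1, shape)
            if np.any(hi <= lo):
                continue
            zz, yy, xx = np.meshgrid(
                np.arange(lo[0], hi[0]),
                np.arange(lo[1], hi[1]),
                np.arange(lo[2], hi[2]),
                indexing="ij",
            )
            q = np.stack([zz, yy, xx], axis=-1).astype(float)
            v = p1 - p0
            vv = float(v @ v)
            t = np.clip(((q - p0) @ v) / max(vv, 1e-12), 0.0, 1.0)
            closest = p0 + t[..., None] * v
            d2 = np.sum((q - closest) ** 2, axis=-1)
            arc = (cum[i] + t * seg_len[i]) / total
            radius = branch.radius_start + arc * (branch.radius_end - branch.radius_start)
            bmask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= d2 <= radius**2
        labels[bmask & (labels == 0)] = bid
        mask |= bmask
    return mask, labels


def render_greyscale(mask: np.ndarray, spec: PhantomSpec) -> ImageStack:
    """Render the ground-truth mask into a noisy 8-bit greyscale stack.

    Root voxels draw from N(mu(z), root_sigma) with mu interpolated from
    root_mu_top to root_mu_bottom; soil voxels are a pore / organic-matter /
    mineral mixture, where "organic" voxels draw from the root distribution
    at their depth (creating the root/soil overlap).  Fully deterministic
    under spec.rng_seed.
    """
    if mask.shape != spec.shape:
        raise ValueError("mask shape differs from spec.shape")
    rng = np.random.default_rng(spec.rng_seed)
    n_slices = spec.shape[0]
    z = np.arange(n_slices, dtype=float)
    frac = z / max(n_slices - 1, 1)
    mu_z = spec.root_mu_top + frac * (spec.root_mu_bottom - spec.root_mu_top)
    mu_vol = mu_z[:, None, None]

    root_noise = rng.normal(0.0, spec.root_sigma, size=spec.shape)
    soil_base = rng.normal(spec.soil_mu, spec.soil_sigma, size=spec.shape)
    pore_vals = rng.normal(10.0, 3.0, size=spec.shape)
    organic_vals = mu_vol + rng.normal(0.0, spec.root_sigma, size=spec.shape)
    u = rng.random(size=spec.shape)

    img = np.where(u < spec.pore_fraction, pore_vals, soil_base)
    img = np.where(
        (u >= spec.pore_fraction) & (u < spec.pore_fraction + spec.organic_fraction),
        organic_vals,
        img,
    )
    img = np.where(mask, mu_vol + root_noise, img)
    if spec.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, spec.blur_sigma)
    return ImageStack(
        voxels=np.clip(img, 0, 255).astype(np.uint8), voxel_size_um=100.0
    )


def _scaled_radius(r: float, s: float) -> float:
    return max(r * s, 2.5)


def builtin_phantoms(name: str, size_scale: float = 1.0, **overrides) -> PhantomSpec:
    """Parameterized phantom geometries used throughout testing.

    gravitropic         — taproot plus one downward lateral; nothing upward.
    y_branch            — taproot splitting into two downward branches.
    one_upward_lateral  — taproot with a single upward-growing lateral
                          joining it mid-stack (~10% of root volume).
    fig2_like           — taproot with an upward lateral that itself carries
                          a downward sub-lateral, forcing at least three
                          tracking passes (down, up, down).
    """
    s = size_scale
    S, R, C = round(200 * s), round(128 * s), round(128 * s)
    cy, cx = 0.5 * R, 0.5 * C

    def pt(z, y, x):
        return (float(z), float(y), float(x))

    if name == "gravitropic":
        branches = [
            BranchSpec(
                [pt(0, cy, cx), pt(0.5 * (S - 1), cy + 0.04 * R, cx), pt(S - 1, cy, cx + 0.04 * C)],
                _scaled_radius(6, s), _scaled_radius(4.5, s),
            ),
            BranchSpec(
                [pt(0.3 * (S - 1), cy + 0.028 * R, cx), pt(0.85 * (S - 1), 0.75 * R, 0.68 * C)],
                _scaled_radius(4, s), _scaled_radius(3, s), parent=0,
            ),
        ]
    elif name == "y_branch":
        zsplit = 0.5 * (S - 1)
        branches = [
            BranchSpec([pt(0, cy, cx), pt(zsplit, cy, cx)],
                       _scaled_radius(6, s), _scaled_radius(5, s)),
            BranchSpec([pt(zsplit, cy, cx), pt(S - 1, 0.3 * R, 0.38 * C)],
                       _scaled_radius(4.5, s), _scaled_radius(3.5, s), parent=0),
            BranchSpec([pt(zsplit, cy, cx), pt(S - 1, 0.7 * R, 0.62 * C)],
                       _scaled_radius(4.5, s), _scaled_radius(3.5, s), parent=0),
        ]
    elif name == "one_upward_lateral":
        zjoin = 0.6 * (S - 1)
        branches = [
            BranchSpec([pt(0, cy, cx), pt(S - 1, cy, cx)],
                       _scaled_radius(6, s), _scaled_radius(4.5, s)),
            BranchSpec([pt(zjoin, cy, cx), pt(0.3 * (S - 1), 0.73 * R, 0.68 * C)],
                       _scaled_radius(3.5, s), _scaled_radius(3, s), parent=0),
        ]
    elif name == "fig2_like":
        zjoin = 0.6 * (S - 1)
        up_top = pt(0.25 * (S - 1), 0.72 * R, 0.66 * C)
        up_branch = BranchSpec(
            [pt(zjoin, cy, cx), up_top],
            _scaled_radius(4, s), _scaled_radius(3, s), parent=0,
        )
        # sub-lateral starts on the upward branch's centerline and descends
        sub_start = up_branch.point_at(0.55)
        branches = [
            BranchSpec([pt(0, cy, cx), pt(S - 1, cy, cx)],
                       _scaled_radius(6, s), _scaled_radius(4.5, s)),
            up_branch,
            BranchSpec([sub_start, pt(0.8 * (S - 1), 0.9 * R, 0.85 * C)],
                       _scaled_radius(3, s), _scaled_radius(2.5, s), parent=1),
        ]
    else:
        raise ValueError(f"unknown phantom {name!r}; choose from {BUILTIN_NAMES}")
    return PhantomSpec(shape=(S, R, C), branches=branches, **overrides)


def true_traits(
    mask: np.ndarray,
    per_branch: np.ndarray,
    spec: PhantomSpec,
    voxel_size_um: float,
) -> TraitReport:
    """Traits computed directly on the ground-truth mask.

    upward_fraction uses the per-branch labels: voxels of plagiotropic
    branches over all root voxels (junction voxels belong to the parent).
    direction_changes counts branches whose growth sense differs from their
    parent's — each such junction is one point where direction changes.
    """
    plag_ids = {
        i for i, b in enumerate(spec.branches, start=1) if b.plagiotropic
    }
    total = int(np.count_nonzero(mask))
    upward = int(np.count_nonzero(np.isin(per_branch, list(plag_ids)))) if plag_ids else 0

    changes = 0
    for b in spec.branches:
        parent_plag = (
            spec.branches[b.parent].plagiotropic if b.parent is not None else False
        )
        if b.plagiotropic != parent_plag:
            changes += 1

    direction = np.zeros(spec.shape, dtype=np.uint8)
    direction[mask] = 1
    if plag_ids:
        direction[np.isin(per_branch, list(plag_ids))] = 2
    seg = Segmentation(mask=mask, direction_label=direction)
    if total == 0:
        return TraitReport(0, 0.0, 0.0, 0.0, 0.0, 0.0, 0)
    area, _, _ = measure_surface_area(seg, voxel_size_um)
    width, _ = measure_max_width(seg, voxel_size_um)
    hull = measure_convex_hull_volume(seg, voxel_size_um, n_samples=200_000)
    return TraitReport(
        voxel_count=total,
        volume_mm3=measure_volume(seg, voxel_size_um),
        surface_area_mm2=area,
        max_width_mm=width,
        convex_hull_mm3=hull.exact_mm3,
        upward_fraction=(upward / total),
        direction_changes=changes,
    )
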
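"""Root-system trait measurements from a segmentation.

Traits mirror the standard whole-system descriptors: voxel-count volume,
iso-surface triangle-sum surface area, maximum width as the diameter of the
minimum enclosing circle of the x-y projection (Welzl's algorithm), convex
hull volume (QuickHull, with a seeded Monte Carlo estimate), plus the
direction-aware traits enabled by the two-stage tracker: the fraction of the
root system discovered while tracking upward, and the number of detected
direction-of-growth changes.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import NamedTuple, Optional

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage import measure

from rootvox.volume_io import Segmentation

__all__ = [
    "TraitReport",
    "HullVolume",
    "EnclosingCircle",
    "measure_volume",
    "measure_surface_area",
    "measure_max_width",
    "measure_convex_hull_volume",
    "measure_upward_fraction",
    "count_direction_changes",
    "percent_change",
    "minimum_enclosing_circle",
    "compute_traits",
    "write_trait_csv",
]


@dataclass
class TraitReport:
    voxel_count: int
    volume_mm3: float
    surface_area_mm2: float
    max_width_mm: float
    convex_hull_mm3: float
    upward_fraction: float
    direction_changes: int

    def as_dict(self) -> dict:
        return asdict(self)


class HullVolume(NamedTuple):
    mc_mm3: float
    exact_mm3: float
    n_samples: int


class EnclosingCircle(NamedTuple):
    center: tuple[float, float]
    radius: float


def measure_volume(seg: Segmentation, voxel_size_um: float) -> float:
    """Root volume in mm^3: voxel count times voxel size cubed (exact)."""
    v_mm = voxel_size_um / 1000.0
    return seg.voxel_count * v_mm**3


def measure_surface_area(
    seg: Segmentation, voxel_size_um: float, smooth_sigma: float = 0.8
) -> tuple[float, np.ndarray, np.ndarray]:
    """Surface area in mm^2 from a marching-cubes iso-surface of the mask.

    The mask is zero-padded on every face so the surface closes at the
    stack boundary, and lightly Gaussian-smoothed (``smooth_sigma`` in
    voxels; 0 disables) before extracting the level-0.5 iso-surface —
    marching cubes on a raw binary volume overestimates areas by ~8% from
    staircase facets.  Returns (area_mm2, vertices, triangles); vertices
    are in mm.
    """
    if seg.voxel_count == 0:
        return 0.0, np.zeros((0, 3)), np.zeros((0, 3), dtype=np.int64)
    v_mm = voxel_size_um / 1000.0
    padded = np.pad(seg.mask, 2).astype(float)
    if smooth_sigma > 0:
        padded = ndimage.gaussian_filter(padded, smooth_sigma)
    verts, faces, _, _ = measure.marching_cubes(
        padded, level=0.5, spacing=(v_mm, v_mm, v_mm)
    )
    area = float(measure.mesh_surface_area(verts, faces))
    return area, verts, faces


# ---------------------------------------------------------------------------
# minimum enclosing circle (Welzl's randomized incremental algorithm)
# ---------------------------------------------------------------------------

def _circle_two(a: np.ndarray, b: np.ndarray) -> EnclosingCircle:
    center = (a + b) / 2.0
    radius = float(np.linalg.norm(a - b) / 2.0)
    return EnclosingCircle((float(center[0]), float(center[1])), radius)


def _circle_three(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> Optional[EnclosingCircle]:
    """Circumcircle of three points; None when (near-)collinear."""
    d = 2.0 * (a[0] * (b[1] - c[1]) + b[0] * (c[1] - a[1]) + c[0] * (a[1] - b[1]))
    if abs(d) < 1e-12:
        return None
    ux = (
        (a @ a) * (b[1] - c[1]) + (b @ b) * (c[1] - a[1]) + (c @ c) * (a[1] - b[1])
    ) / d
    uy = (
        (a @ a) * (c[0] - b[0]) + (b @ b) * (a[0] - c[0]) + (c @ c) * (b[0] - a[0])
    ) / d
    center = np.array([ux, uy])
    radius = float(np.linalg.norm(a - center))
    return EnclosingCircle((float(ux), float(uy)), radius)


def _in_circle(circle: EnclosingCircle, p: np.ndarray, eps: float = 1e-9) -> bool:
    dx = p[0] - circle.center[0]
    dy = p[1] - circle.center[1]
    return dx * dx + dy * dy <= (circle.radius + eps) ** 2


def _circle_with_two_boundary(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> EnclosingCircle:
    circle = _circle_two(a, b)
    for p in points:
        if not _in_circle(circle, p):
            c3 = _circle_three(a, b, p)
            if c3 is not None:
                circle = c3
    return circle


def _circle_with_one_boundary(points: np.ndarray, a: np.ndarray) -> EnclosingCircle:
    circle = EnclosingCircle((float(a[0]), float(a[1])), 0.0)
    for i, p in enumerate(points):
        if not _in_circle(circle, p):
            circle = _circle_with_two_boundary(points[:i], a, p)
    return circle


def minimum_enclosing_circle(
    points: np.ndarray, rng_seed: int = 0
) -> EnclosingCircle:
    """Exact minimum enclosing circle of 2D points.

    Welzl's randomized incremental construction (move-to-front variant,
    expected linear time).  The shuffle is seeded for reproducibility but the
    resulting circle is the same for any permutation.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(points) == 0:
        raise ValueError("need at least one point")
    points = np.unique(points, axis=0)
    rng = np.random.default_rng(rng_seed)
    points = points[rng.permutation(len(points))]
    circle = EnclosingCircle((float(points[0][0]), float(points[0][1])), 0.0)
    for i, p in enumerate(points):
        if not _in_circle(circle, p):
            circle = _circle_with_one_boundary(points[:i], p)
    return circle


def measure_max_width(
    seg: Segmentation, voxel_size_um: float, rng_seed: int = 0
) -> tuple[float, EnclosingCircle]:
    """Maximum width in mm: diameter of the minimum enclosing circle of all
    root voxels projected onto one x-y plane (voxel centres)."""
    if seg.voxel_count == 0:
        raise ValueError("empty mask has no width")
    projected = seg.mask.any(axis=0)
    points = np.column_stack(np.nonzero(projected)).astype(float)
    circle = minimum_enclosing_circle(points, rng_seed=rng_seed)
    return 2.0 * circle.radius * voxel_size_um / 1000.0, circle


def measure_convex_hull_volume(
    seg: Segmentation,
    voxel_size_um: float,
    n_samples: int = 1_000_000,
    rng_seed: int = 0,
) -> HullVolume:
    """Convex hull volume of the root voxel centres, in mm^3.

    The hull is built with QuickHull; the reported volume is a Monte Carlo
    estimate — uniform samples in the hull's bounding box, scaled by the hit
    fraction — with the exact facet-decomposition volume exposed alongside
    for verification.  Degenerate (coplanar/collinear) inputs yield 0.
    """
    v_mm = voxel_size_um / 1000.0
    points = np.column_stack(np.nonzero(seg.mask)).astype(float)
    if len(points) < 4:
        warnings.warn("fewer than 4 root voxels: hull volume 0")
        return HullVolume(0.0, 0.0, n_samples)
    try:
        hull = ConvexHull(points)
    except QhullError:
        warnings.warn("degenerate (coplanar/collinear) voxel set: hull volume 0")
        return HullVolume(0.0, 0.0, n_samples)
    exact = float(hull.volume) * v_mm**3

    rng = np.random.default_rng(rng_seed)
    lo = points.min(axis=0)
    hi = points.max(axis=0)
    bbox_vol = float(np.prod(hi - lo)) * v_mm**3
    samples = rng.uniform(lo, hi, size=(n_samples, 3))
    # inside test via the hull's half-space equations A x + b <= 0
    a = hull.equations[:, :3]
    b = hull.equations[:, 3]
    inside = np.all(samples @ a.T + b <= 1e-9, axis=1)
    estimate = float(inside.mean()) * bbox_vol
    return HullVolume(estimate, exact, n_samples)


def measure_upward_fraction(seg: Segmentation) -> float:
    """Fraction of root voxels first discovered while tracking upward."""
    total = seg.voxel_count
    if total == 0:
        return 0.0
    upward = int(np.count_nonzero(seg.direction_label == 2))
    return upward / total


def count_direction_changes(seg: Segmentation) -> int:
    """Number of points where growth direction changed: consumed markers."""
    return sum(1 for m in seg.marker_log if m.status == "consumed")


def percent_change(before: float, after: float) -> float:
    """Percentage change 100*(after-before)/before; ``before`` must be > 0."""
    if not (before > 0):
        raise ValueError(f"before must be > 0, got {before}")
    return 100.0 * (after - before) / before


def compute_traits(
    seg: Segmentation,
    voxel_size_um: float,
    n_samples: int = 1_000_000,
    rng_seed: int = 0,
) -> TraitReport:
    """All traits for one segmentation; zeros for an empty mask."""
    if seg.voxel_count == 0:
        warnings.warn("empty segmentation: all traits zero")
        return TraitReport(0, 0.0, 0.0, 0.0, 0.0, 0.0, count_direction_changes(seg))
    area, _, _ = measure_surface_area(seg, voxel_size_um)
    width, _ = measure_max_width(seg, voxel_size_um, rng_seed=rng_seed)
    hull = measure_convex_hull_volume(
        seg, voxel_size_um, n_samples=n_samples, rng_seed=rng_seed
    )
    return TraitReport(
        voxel_count=seg.voxel_count,
        volume_mm3=measure_volume(seg, voxel_size_um),
        surface_area_mm2=area,
        max_width_mm=width,
        convex_hull_mm3=hull.mc_mm3,
        upward_fraction=measure_upward_fraction(seg),
        direction_changes=count_direction_changes(seg),
    )


def write_trait_csv(reports: list[TraitReport], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fields = [
        "voxel_count",
        "volume_mm3",
        "surface_area_mm2",
        "max_width_mm",
        "convex_hull_mm3",
        "upward_fraction",
        "direction_changes",
    ]
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields)
        writer.writeheader()
        for r in reports:
            writer.writerow(r.as_dict())
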
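"""Reading and writing image stacks, segmentations, meshes and marker logs.

Conventions
-----------
* A stack is indexed ``(slice, row, col)``; slice 0 is the top of the soil
  column when ``slice_axis_down`` is true.
* Voxel indices are 0-based and a voxel's centre sits at ``index * voxel_size``.
* Directories of single-slice images are read in lexicographic filename
  order; this order defines the slice index.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = [
    "ImageStack",
    "Segmentation",
    "StackReadError",
    "read_stack",
    "write_stack",
    "write_segmentation",
    "read_segmentation",
    "write_mesh",
    "read_mesh",
]

_SLICE_SUFFIXES = {".tif", ".tiff", ".png"}


class StackReadError(ValueError):
    """Raised when an on-disk stack cannot be interpreted."""


@dataclass
class ImageStack:
    """A 3D greyscale volume plus its physical voxel size.

    Attributes
    ----------
    voxels : ndarray, shape (slices, rows, cols)
        Grey intensities, kept in their stored range (no normalisation).
    voxel_size_um : float
        Isotropic voxel edge length in micrometres.
    slice_axis_down : bool
        True if increasing slice index means deeper in the soil column.
    """

    voxels: np.ndarray
    voxel_size_um: float
    slice_axis_down: bool = True

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"stack must be 3D, got ndim={self.voxels.ndim}")
        if any(d < 1 for d in self.voxels.shape):
            raise ValueError(f"all dimensions must be >= 1, got {self.voxels.shape}")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            if not np.all(np.isfinite(self.voxels)):
                raise ValueError("intensities must be finite")
        if np.min(self.voxels) < 0:
            raise ValueError("intensities must be non-negative")
        if not (self.voxel_size_um > 0):
            raise ValueError(f"voxel_size_um must be > 0, got {self.voxel_size_um}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def voxel_size_mm(self) -> float:
        return self.voxel_size_um / 1000.0

    def intensity_range(self) -> tuple[float, float]:
        """Global (min, max) used to bin appearance histograms."""
        lo = float(np.min(self.voxels))
        hi = float(np.max(self.voxels))
        if hi <= lo:
            hi = lo + 1.0
        return lo, hi


@dataclass
class Segmentation:
    """Binary root mask with per-voxel direction-of-discovery labels.

    ``direction_label`` is 0 outside the mask, 1 where a voxel was first
    labelled on a downward pass and 2 where it was first labelled on an
    upward pass.  ``marker_log`` records every direction-change marker the
    tracker created (see :mod:`rootvox.tracking`).
    """

    mask: np.ndarray
    direction_label: np.ndarray
    marker_log: list = field(default_factory=list)
    pass_count: int = 0
    slice_visits: int = 0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.direction_label = np.asarray(self.direction_label, dtype=np.uint8)
        if self.mask.shape != self.direction_label.shape:
            raise ValueError("mask and direction_label shapes differ")

    def validate(self) -> None:
        if not np.array_equal(self.direction_label > 0, self.mask):
            raise ValueError("direction_label must be > 0 exactly where mask is true")

    @property
    def voxel_count(self) -> int:
        return int(np.count_nonzero(self.mask))


def read_stack(path: str | Path, voxel_size_um: float) -> ImageStack:
    """Read a stack from a directory of slices or a multipage TIFF.

    Directory slices are ordered by lexicographic filename; 16-bit data is
    preserved without rescaling.
    """
    path = Path(path)
    if not path.exists():
        raise StackReadError(f"no such path: {path}")
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in _SLICE_SUFFIXES)
        if not files:
            raise StackReadError(f"no slice images (tif/png) found in {path}")
        slices = []
        for f in files:
            img = iio.imread(f)
            if img.ndim == 3:  # RGB(A) PNG: collapse identical channels to grey
                img = img[..., 0]
            slices.append(img)
        shapes = {s.shape for s in slices}
        if len(shapes) != 1:
            raise StackReadError(f"inconsistent slice dimensions: {sorted(shapes)}")
        voxels = np.stack(slices, axis=0)
    else:
        voxels = tifffile.imread(path)
        if voxels.ndim == 2:
            voxels = voxels[None]
        if voxels.ndim != 3:
            raise StackReadError(f"expected 2D/3D TIFF, got ndim={voxels.ndim}")
    if voxels.shape[0] < 1:
        raise StackReadError("zero slices")
    return ImageStack(voxels=voxels, voxel_size_um=voxel_size_um)


def write_stack(stack: ImageStack | np.ndarray, path: str | Path) -> None:
    """Write a stack as a multipage TIFF (one page per slice)."""
    voxels = stack.voxels if isinstance(stack, ImageStack) else np.asarray(stack)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, voxels, photometric="minisblack")


def write_segmentation(seg: Segmentation, path: str | Path) -> None:
    """Write a segmentation to a directory.

    Produces ``mask.tif`` (0/255 per slice), ``direction.tif`` (0/1/2) and
    ``markers.csv`` with columns slice_index, n_pixels, direction, pass_id,
    status.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        path / "mask.tif", seg.mask.astype(np.uint8) * 255, photometric="minisblack"
    )
    tifffile.imwrite(
        path / "direction.tif",
        seg.direction_label.astype(np.uint8),
        photometric="minisblack",
    )
    with open(path / "markers.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["slice_index", "n_pixels", "direction", "pass_id", "status"])
        for m in seg.marker_log:
            writer.writerow(
                [m.slice_index, len(m.pixels), m.direction, m.source_pass, m.status]
            )


def read_segmentation(path: str | Path) -> Segmentation:
    """Read a segmentation written by :func:`write_segmentation`.

    The marker log is restored as lightweight records sufficient for trait
    measurement (slice index, pixel count, direction, pass id, status).
    """
    from rootvox.tracking import Marker  # deferred: avoid import cycle

    path = Path(path)
    mask = tifffile.imread(path / "mask.tif") > 0
    if mask.ndim == 2:
        mask = mask[None]
    direction = tifffile.imread(path / "direction.tif").astype(np.uint8)
    if direction.ndim == 2:
        direction = direction[None]
    markers = []
    csv_path = path / "markers.csv"
    if csv_path.exists():
        with open(csv_path, newline="") as fh:
            for row in csv.DictReader(fh):
                n = int(row["n_pixels"])
                markers.append(
                    Marker(
                        slice_index=int(row["slice_index"]),
                        pixels=np.zeros((n, 2), dtype=np.int64),
                        direction=row["direction"],
                        source_pass=int(row["pass_id"]),
                        status=row["status"],
                    )
                )
    return Segmentation(mask=mask, direction_label=direction, marker_log=markers)


def write_mesh(
    vertices: Sequence[Sequence[float]],
    triangles: Sequence[Sequence[int]],
    path: str | Path,
) -> None:
    """Write a triangle mesh as ascii PLY."""
    vertices = np.asarray(vertices, dtype=float).reshape(-1, 3)
    triangles = np.asarray(triangles, dtype=np.int64).reshape(-1, 3)
    if triangles.size and (triangles.min() < 0 or triangles.max() >= len(vertices)):
        raise ValueError("triangle index out of range")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [
        "ply",
        "format ascii 1.0",
        f"element vertex {len(vertices)}",
        "property float x",
        "property float y",
        "property float z",
        f"element face {len(triangles)}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    for v in vertices:
        lines.append(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}")
    for t in triangles:
        lines.append(f"3 {t[0]} {t[1]} {t[2]}")
    path.write_text("\n".join(lines) + "\n")


def read_mesh(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read an ascii PLY triangle mesh back into (vertices, triangles)."""
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].strip() != "ply":
        raise ValueError("not a PLY file")
    n_vert = n_face = 0
    i = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if parts[:2] == ["element", "vertex"]:
            n_vert = int(parts[2])
        elif parts[:2] == ["element", "face"]:
            n_face = int(parts[2])
        elif parts[:1] == ["end_header"]:
            break
    body = lines[i + 1 :]
    verts = np.array(
        [[float(x) for x in body[j].split()[:3]] for j in range(n_vert)], dtype=float
    ).reshape(n_vert, 3)
    faces = np.array(
        [[int(x) for x in body[n_vert + j].split()[1:4]] for j in range(n_face)],
        dtype=np.int64,
    ).reshape(n_face, 3)
    return verts, faces
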
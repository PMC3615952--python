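"""Per-slice local segmentation with a grey-level appearance model.

The segmenter evolves a narrow-band level set whose speed combines an
appearance data term with a curvature regulariser:

    F(x) = alpha * (2 * p_root(I(x)) - 1) - (1 - alpha) * kappa(x)

``p_root(g) = h_root(g) / (h_root(g) + h_bg(g))`` compares the tracked
object's grey-level histogram ``h_root`` against a background histogram
``h_bg`` estimated from an annulus surrounding the initial region, so the
segmentation is local in both space and appearance.  ``alpha`` weighs data
against smoothness; ``beta`` gates appearance-model updates (see
:func:`update_model`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np
from scipy import ndimage

__all__ = [
    "AppearanceModel",
    "TrackerConfig",
    "RootObject",
    "SeedRejectedError",
    "pixels_to_mask",
    "mask_to_pixels",
    "init_from_click",
    "evolve_levelset",
    "connected_components",
    "similarity",
    "update_model",
]


class SeedRejectedError(ValueError):
    """The region grown from the user's seed point is too small to track."""


# ---------------------------------------------------------------------------
# pixel-set helpers: the canonical pixel-set representation is a (N, 2) int
# array of (row, col) coordinates in lexicographic order.
# ---------------------------------------------------------------------------

def mask_to_pixels(mask: np.ndarray) -> np.ndarray:
    rows, cols = np.nonzero(mask)
    return np.column_stack([rows, cols]).astype(np.int64)


def pixels_to_mask(pixels: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    pixels = np.asarray(pixels, dtype=np.int64).reshape(-1, 2)
    if len(pixels):
        mask[pixels[:, 0], pixels[:, 1]] = True
    return mask


@dataclass(frozen=True)
class AppearanceModel:
    """Normalised grey-level histogram of a tracked root cross-section.

    Bins are laid over the fixed intensity range ``[lo, hi]`` of the source
    stack so that models from different slices are comparable.
    """

    hist: np.ndarray
    n_pixels: int
    lo: float
    hi: float

    def __post_init__(self) -> None:
        h = np.asarray(self.hist, dtype=float)
        object.__setattr__(self, "hist", h)
        if self.n_pixels > 0:
            s = h.sum()
            if not np.isclose(s, 1.0, atol=1e-9):
                raise ValueError(f"histogram must sum to 1, got {s}")
            if np.any(h < 0):
                raise ValueError("histogram entries must be >= 0")

    @property
    def bins(self) -> int:
        return len(self.hist)

    @classmethod
    def from_values(
        cls, values: np.ndarray, bins: int, lo: float, hi: float
    ) -> "AppearanceModel":
        values = np.asarray(values, dtype=float).ravel()
        idx = _bin_indices(values, bins, lo, hi)
        hist = np.bincount(idx, minlength=bins).astype(float)
        n = len(values)
        if n:
            hist /= n
        return cls(hist=hist, n_pixels=n, lo=lo, hi=hi)

    @classmethod
    def from_pixels(
        cls,
        image: np.ndarray,
        pixels: np.ndarray,
        bins: int,
        lo: float,
        hi: float,
    ) -> "AppearanceModel":
        pixels = np.asarray(pixels, dtype=np.int64).reshape(-1, 2)
        return cls.from_values(image[pixels[:, 0], pixels[:, 1]], bins, lo, hi)


def _bin_indices(values: np.ndarray, bins: int, lo: float, hi: float) -> np.ndarray:
    scaled = (np.asarray(values, dtype=float) - lo) / (hi - lo) * bins
    return np.clip(scaled.astype(np.int64), 0, bins - 1)


@dataclass
class TrackerConfig:
    """Parameters of the slice tracker.

    ``alpha`` weighs the appearance data term against curvature smoothing;
    ``beta`` is the minimum appearance similarity for accepting a model
    update.  Published example settings for real scans are alpha=0.606,
    beta=0.246.
    """

    alpha: float = 0.6
    beta: float = 0.25
    bins: int = 64
    max_iter: int = 200
    band_width: int = 6
    min_area: int = 10
    connectivity_2d: int = 8
    rng_seed: int = 0
    forward_only: bool = False
    overlap_threshold: int = 1
    annulus_width: int = 5
    seed_radius: int = 3
    reinit_interval: int = 20
    convergence_patience: int = 25
    dt: float = 0.5
    hist_smooth_sigma: float = 1.0
    p_smooth_sigma: float = 0.5
    curvature_sigma: float = 0.5
    mc_samples: int = 1_000_000

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha must be in [0,1], got {self.alpha}")
        if not (0.0 <= self.beta <= 1.0):
            raise ValueError(f"beta must be in [0,1], got {self.beta}")
        if self.min_area < 1:
            raise ValueError("min_area must be >= 1")
        if self.connectivity_2d not in (4, 8):
            raise ValueError("connectivity_2d must be 4 or 8")


@dataclass
class RootObject:
    """One connected root cross-section on one slice.

    ``direction`` records the traversal direction ("down" or "up") of the
    pass that found the object; ``parent_id`` links it to the object on the
    adjacent slice it was grown from.
    """

    slice_index: int
    pixels: np.ndarray
    model: AppearanceModel
    centroid: tuple[float, float] = (0.0, 0.0)
    parent_id: Optional[int] = None
    direction: str = "down"
    id: int = -1

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.int64).reshape(-1, 2)
        if len(self.pixels) == 0:
            raise ValueError("RootObject requires a non-empty pixel set")
        order = np.lexsort((self.pixels[:, 1], self.pixels[:, 0]))
        self.pixels = self.pixels[order]
        self.centroid = (float(self.pixels[:, 0].mean()), float(self.pixels[:, 1].mean()))

    @property
    def area(self) -> int:
        return len(self.pixels)

    def footprint(self, shape: tuple[int, int]) -> np.ndarray:
        return pixels_to_mask(self.pixels, shape)


# ---------------------------------------------------------------------------
# appearance similarity and model updating
# ---------------------------------------------------------------------------

def similarity(a: AppearanceModel, b: AppearanceModel) -> float:
    """Bhattacharyya coefficient between two appearance histograms."""
    if a.bins != b.bins:
        raise ValueError(f"bin-count mismatch: {a.bins} vs {b.bins}")
    return float(np.clip(np.sum(np.sqrt(a.hist * b.hist)), 0.0, 1.0))


def update_model(
    current: AppearanceModel, observed: AppearanceModel, beta: float
) -> AppearanceModel:
    """Replace the model with the observation iff it is reliable.

    The observation is accepted when its Bhattacharyya similarity to the
    current model is >= beta (inclusive); otherwise the current model is kept
    so a single bad object cannot corrupt tracking.
    """
    if similarity(current, observed) >= beta:
        return observed
    return current


# ---------------------------------------------------------------------------
# connected components
# ---------------------------------------------------------------------------

_STRUCT_4 = ndimage.generate_binary_structure(2, 1)
_STRUCT_8 = ndimage.generate_binary_structure(2, 2)


def connected_components(mask: np.ndarray, connectivity: int = 8) -> list[np.ndarray]:
    """Partition a 2D boolean mask into maximal connected pixel sets.

    Output order is deterministic: components sorted by their minimum
    (row, col) pixel, lexicographically.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return []
    struct = _STRUCT_4 if connectivity == 4 else _STRUCT_8
    labels, n = ndimage.label(mask, structure=struct)
    comps = []
    for lab in range(1, n + 1):
        comps.append(mask_to_pixels(labels == lab))
    comps.sort(key=lambda p: (int(p[0, 0]), int(p[0, 1])))
    return comps


# ---------------------------------------------------------------------------
# level-set evolution
# ---------------------------------------------------------------------------

def _signed_distance(region: np.ndarray) -> np.ndarray:
    """Signed distance, negative inside the region."""
    inside = ndimage.distance_transform_edt(region)
    outside = ndimage.distance_transform_edt(~region)
    return outside - inside


def _smooth_hist(hist: np.ndarray, sigma: float) -> np.ndarray:
    if sigma <= 0:
        return hist
    return ndimage.gaussian_filter1d(hist.astype(float), sigma, mode="constant")


def _foreground_probability(
    image: np.ndarray,
    model: AppearanceModel,
    bg_hist: np.ndarray,
    cfg: TrackerConfig,
) -> np.ndarray:
    """Per-pixel p_root(I(x)) from smoothed root/background histograms."""
    h_root = _smooth_hist(model.hist, cfg.hist_smooth_sigma)
    h_bg = _smooth_hist(bg_hist, cfg.hist_smooth_sigma)
    denom = h_root + h_bg
    p_of_bin = np.where(denom > 0, h_root / np.where(denom > 0, denom, 1.0), 0.5)
    idx = _bin_indices(image.ravel(), model.bins, model.lo, model.hi)
    p = p_of_bin[idx].reshape(image.shape)
    if cfg.p_smooth_sigma > 0:
        # spatial smoothing: isolated noisy pixels cannot puncture the region
        p = ndimage.gaussian_filter(p, cfg.p_smooth_sigma)
    return p


def background_histogram(
    image: np.ndarray,
    region: np.ndarray,
    cfg: TrackerConfig,
    lo: float,
    hi: float,
    exclude: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Histogram of an annulus around ``region``, excluding other objects.

    Falls back to the whole-image histogram if the annulus is empty (e.g.
    region touching all borders).
    """
    dilated = ndimage.binary_dilation(region, _STRUCT_8, iterations=cfg.annulus_width)
    annulus = dilated & ~region
    if exclude is not None:
        annulus &= ~exclude
    values = image[annulus] if annulus.any() else image.ravel()
    return AppearanceModel.from_values(values, cfg.bins, lo, hi).hist


def _upwind_gradnorms(phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Godunov upwind gradient norms for expansion (plus) / contraction (minus)."""
    dmy = np.diff(phi, axis=0, prepend=phi[:1])
    dpy = np.diff(phi, axis=0, append=phi[-1:])
    dmx = np.diff(phi, axis=1, prepend=phi[:, :1])
    dpx = np.diff(phi, axis=1, append=phi[:, -1:])
    grad_plus = np.sqrt(
        np.maximum(dmy, 0) ** 2 + np.minimum(dpy, 0) ** 2
        + np.maximum(dmx, 0) ** 2 + np.minimum(dpx, 0) ** 2
    )
    grad_minus = np.sqrt(
        np.minimum(dmy, 0) ** 2 + np.maximum(dpy, 0) ** 2
        + np.minimum(dmx, 0) ** 2 + np.maximum(dpx, 0) ** 2
    )
    return grad_plus, grad_minus


def _prune_disconnected(region: np.ndarray, anchor: np.ndarray) -> np.ndarray:
    """Drop foreground components that do not touch the anchor region.

    The contour may only move, not jump: without this, the narrow band lets
    new foreground appear across a background gap, which would give the
    forward pass the same reach as the look-back step and defeat marker
    detection.
    """
    if not region.any():
        return region
    labels, n = ndimage.label(region, structure=_STRUCT_8)
    if n == 1:
        return region
    keep = np.unique(labels[anchor & region])
    keep = keep[keep > 0]
    return np.isin(labels, keep)


def _roi_bounds(
    region: np.ndarray, shape: tuple[int, int], margin: int
) -> tuple[int, int, int, int]:
    rows = np.flatnonzero(region.any(axis=1))
    cols = np.flatnonzero(region.any(axis=0))
    r0 = max(int(rows[0]) - margin, 0)
    r1 = min(int(rows[-1]) + margin + 1, shape[0])
    c0 = max(int(cols[0]) - margin, 0)
    c1 = min(int(cols[-1]) + margin + 1, shape[1])
    return r0, r1, c0, c1


def evolve_levelset(
    slice_img: np.ndarray,
    init_region: np.ndarray,
    model: AppearanceModel,
    cfg: TrackerConfig,
    bg_hist: Optional[np.ndarray] = None,
    exclude: Optional[np.ndarray] = None,
    area_trace: Optional[list] = None,
) -> np.ndarray:
    """Narrow-band level-set evolution of an initial region on one slice.

    Parameters
    ----------
    slice_img : 2D grey image.
    init_region : (N, 2) pixel array or 2D boolean mask, the initial region.
    model : appearance model providing the foreground histogram.
    bg_hist : optional pre-computed background histogram; estimated from an
        annulus around the initial region when omitted.
    exclude : optional boolean mask of pixels belonging to other tracked
        objects, kept out of the background estimate.
    area_trace : optional list collecting the region area after every
        iteration (diagnostics / tests).

    Returns
    -------
    (N, 2) pixel array of the stabilised foreground; empty when the region
    collapses (target loss).
    """
    slice_img = np.asarray(slice_img)
    if init_region.ndim == 2 and init_region.dtype == bool:
        region_full = init_region.copy()
    else:
        region_full = pixels_to_mask(init_region, slice_img.shape)
    if not region_full.any():
        raise ValueError("init_region must be non-empty")

    if bg_hist is None:
        lo, hi = model.lo, model.hi
        bg_hist = background_histogram(slice_img, region_full, cfg, lo, hi, exclude)
    p_full = _foreground_probability(slice_img.astype(float), model, bg_hist, cfg)
    speed_data_full = cfg.alpha * (2.0 * p_full - 1.0)

    anchor_full = region_full.copy()
    margin = cfg.band_width + 2
    r0, r1, c0, c1 = _roi_bounds(region_full, slice_img.shape, margin)
    region = region_full[r0:r1, c0:c1].copy()
    phi = _signed_distance(region)

    unchanged = 0
    prev = region.copy()
    for it in range(cfg.max_iter):
        band = np.abs(phi) <= cfg.band_width
        f_data = speed_data_full[r0:r1, c0:c1]
        grad_plus, grad_minus = _upwind_gradnorms(phi)
        dphi = (
            np.maximum(f_data, 0.0) * grad_plus + np.minimum(f_data, 0.0) * grad_minus
        )
        phi = np.where(band, phi - cfg.dt * dphi, phi)
        if cfg.alpha < 1.0:
            # curvature motion via heat flow on phi: G_sigma*phi - phi is
            # ~ (sigma^2/2) * kappa * |grad phi| for a signed distance field,
            # a stable substitute for an explicit (clipped) kappa term.
            # Applied only in a thin shell around the contour so the medial
            # ridge of thin tubes is untouched (smoothing the ridge would
            # evaporate any structure narrower than the band).
            smooth = ndimage.gaussian_filter(phi, cfg.curvature_sigma)
            shell = np.abs(phi) <= 2.0
            phi = np.where(
                shell, phi + (1.0 - cfg.alpha) * cfg.dt * (smooth - phi), phi
            )

        region = phi < 0
        if area_trace is not None:
            area_trace.append(int(region.sum()))
        if np.array_equal(region, prev):
            unchanged += 1
            if unchanged >= cfg.convergence_patience:
                break
        else:
            unchanged = 0
        prev = region.copy()

        if (it + 1) % cfg.reinit_interval == 0:
            if not region.any():
                break
            # prune gap-jumping components, re-anchor the ROI, rebuild phi
            region_full[:] = False
            region_full[r0:r1, c0:c1] = region
            region_full = _prune_disconnected(region_full, anchor_full)
            if not region_full.any():
                break
            r0, r1, c0, c1 = _roi_bounds(region_full, slice_img.shape, margin)
            region = region_full[r0:r1, c0:c1].copy()
            phi = _signed_distance(region)
            prev = region.copy()
        elif not region.any():
            break

    out = np.zeros(slice_img.shape, dtype=bool)
    out[r0:r1, c0:c1] = region
    out = _prune_disconnected(out, anchor_full)
    return mask_to_pixels(out)


def init_from_click(
    stack,
    seed: tuple[int, int],
    cfg: TrackerConfig,
) -> RootObject:
    """Grow the first root object from a user seed point on slice 0.

    A small disc around the seed provides the initial appearance estimate;
    the level set then grows the region of sufficiently similar grey values,
    and the final histogram is recorded as the object's model.
    """
    img = stack.voxels[0]
    r, c = int(seed[0]), int(seed[1])
    if not (0 <= r < img.shape[0] and 0 <= c < img.shape[1]):
        raise ValueError(f"seed {seed} outside slice 0 of shape {img.shape}")
    lo, hi = stack.intensity_range()

    yy, xx = np.ogrid[: img.shape[0], : img.shape[1]]
    disc = (yy - r) ** 2 + (xx - c) ** 2 <= cfg.seed_radius**2
    model = AppearanceModel.from_pixels(
        img, mask_to_pixels(disc), cfg.bins, lo, hi
    )
    # two deterministic refinement rounds: evolve, re-estimate the histogram
    region = mask_to_pixels(disc)
    for _ in range(2):
        region = evolve_levelset(img, region, model, cfg)
        if len(region) == 0:
            raise SeedRejectedError("seed rejected: region collapsed")
        model = AppearanceModel.from_pixels(img, region, cfg.bins, lo, hi)

    # keep only the component containing (or nearest to) the seed
    comps = connected_components(pixels_to_mask(region, img.shape), cfg.connectivity_2d)
    best = None
    for comp in comps:
        if ((comp[:, 0] == r) & (comp[:, 1] == c)).any():
            best = comp
            break
    if best is None:
        dists = [np.min((comp[:, 0] - r) ** 2 + (comp[:, 1] - c) ** 2) for comp in comps]
        best = comps[int(np.argmin(dists))]
    if len(best) < cfg.min_area:
        raise SeedRejectedError(
            f"seed rejected: region of {len(best)} px below min_area={cfg.min_area}"
        )
    model = AppearanceModel.from_pixels(img, best, cfg.bins, lo, hi)
    return RootObject(slice_index=0, pixels=best, model=model, direction="down", id=0)
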
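"""Stack traversal: slice-to-slice tracking, look-back marker detection and
alternating-direction pass scheduling.

A first downward pass tracks the root from the user's seed, splitting as the
root branches.  After identifying the objects on slice n (and before moving
on), the tracker revisits the slice behind it, re-segmenting it from the
current objects; connected components seen on this second visit that were
*not* labelled on the first visit are recorded as markers — candidate roots
growing against the pass direction.  Once a pass ends, pending markers are
consumed lowest-slice-first, each spawning a new pass in its own direction;
those passes look back too, so downward roots hanging off upward segments
are found in turn.  The scheduler alternates until no markers remain.

Each voxel keeps the direction (down=1 / up=2) of the pass that first
labelled it, which is what makes the upward-grown fraction measurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from rootvox.segmentation import (
    AppearanceModel,
    RootObject,
    TrackerConfig,
    background_histogram,
    connected_components,
    evolve_levelset,
    init_from_click,
    mask_to_pixels,
    pixels_to_mask,
    similarity,
    update_model,
)
from rootvox.volume_io import ImageStack, Segmentation

__all__ = ["Marker", "PassResult", "advance", "look_back", "run_pass", "extract_root_system"]

_STRUCT_8 = ndimage.generate_binary_structure(2, 2)


@dataclass
class Marker:
    """A candidate root detected on a look-back step.

    ``direction`` is the direction the spawned pass must travel ("up" for
    markers found while tracking down, "down" for the converse).  ``status``
    moves pending -> consumed when the marker spawns a pass, or
    pending -> discarded when its pixels were already labelled by the time
    it is examined.
    """

    slice_index: int
    pixels: np.ndarray
    direction: str
    source_pass: int
    status: str = "pending"
    model: Optional[AppearanceModel] = None
    created_order: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.int64).reshape(-1, 2)


@dataclass
class PassResult:
    """Summary of one tracking pass."""

    objects_by_slice: dict = field(default_factory=dict)
    new_markers: list = field(default_factory=list)
    slices_visited: int = 0


def _step(direction: str) -> int:
    if direction == "down":
        return 1
    if direction == "up":
        return -1
    raise ValueError(f"direction must be 'down' or 'up', got {direction!r}")


def _evolve_onto_slice(
    objects: list[RootObject],
    target_index: int,
    stack: ImageStack,
    seg: Segmentation,
    cfg: TrackerConfig,
) -> list[tuple[np.ndarray, RootObject, AppearanceModel]]:
    """Evolve every object's footprint onto a target slice and decompose.

    Each object is evolved separately with its own appearance model; the
    union of the results is split into connected components and every
    component >= min_area is assigned to the parent whose model is most
    similar to the component's observed histogram (ties: lowest parent id).
    Components not 8-adjacent to any parent footprint are dropped, which
    keeps the growing segmentation 26-connected to the seed.

    Returns a list of (component_pixels, parent_object, observed_model).
    """
    img = stack.voxels[target_index]
    shape = img.shape
    lo, hi = stack.intensity_range()
    labelled_here = seg.mask[target_index]

    union = np.zeros(shape, dtype=bool)
    evolved: list[np.ndarray] = []
    for obj in objects:
        footprint = obj.footprint(shape)
        bg = background_histogram(img, footprint, cfg, lo, hi, exclude=labelled_here)
        pix = evolve_levelset(img, footprint, obj.model, cfg, bg_hist=bg)
        evolved.append(pix)
        if len(pix):
            union[pix[:, 0], pix[:, 1]] = True

    if not union.any():
        return []

    evolved_masks = [pixels_to_mask(p, shape) for p in evolved]
    adjacency = [
        ndimage.binary_dilation(obj.footprint(shape), _STRUCT_8) for obj in objects
    ]

    results = []
    for comp in connected_components(union, cfg.connectivity_2d):
        if len(comp) < cfg.min_area:
            continue
        comp_mask = pixels_to_mask(comp, shape)
        observed = AppearanceModel.from_pixels(img, comp, cfg.bins, lo, hi)
        best, best_sim = None, -1.0
        for obj, emask, amask in zip(objects, evolved_masks, adjacency):
            if not (comp_mask & emask).any():
                continue
            if not (comp_mask & amask).any():
                continue
            s = similarity(obj.model, observed)
            if s > best_sim or (s == best_sim and best is not None and obj.id < best.id):
                best, best_sim = obj, s
        if best is None:
            continue
        results.append((comp, best, observed))
    return results


def advance(
    objects: list[RootObject],
    stack: ImageStack,
    cfg: TrackerConfig,
    direction: str,
    seg: Optional[Segmentation] = None,
    target_index: Optional[int] = None,
    id_counter: Optional[list] = None,
) -> list[RootObject]:
    """Track all current objects one slice in ``direction``.

    Returns the child objects on the target slice; an object whose evolved
    region collapses or shrinks below min_area has no children (target
    loss).  Children inherit the parent model, conditionally replaced by the
    observed histogram via :func:`update_model`.
    """
    if not objects:
        return []
    n = objects[0].slice_index
    if target_index is None:
        target_index = n + _step(direction)
    if not (0 <= target_index < stack.n_slices):
        raise ValueError(f"target slice {target_index} outside stack")
    if seg is None:
        seg = Segmentation(
            mask=np.zeros(stack.shape, dtype=bool),
            direction_label=np.zeros(stack.shape, dtype=np.uint8),
        )
    children = []
    for comp, parent, observed in _evolve_onto_slice(objects, target_index, stack, seg, cfg):
        model = update_model(parent.model, observed, cfg.beta)
        oid = 0
        if id_counter is not None:
            id_counter[0] += 1
            oid = id_counter[0]
        children.append(
            RootObject(
                slice_index=target_index,
                pixels=comp,
                model=model,
                parent_id=parent.id,
                direction=direction,
                id=oid,
            )
        )
    return children


def look_back(
    objects: list[RootObject],
    stack: ImageStack,
    seg: Segmentation,
    cfg: TrackerConfig,
    pass_direction: str = "down",
    pass_id: int = 0,
) -> list[Marker]:
    """Re-examine the slice behind the current one for unseen roots.

    The previous slice is re-segmented starting from the current objects.
    Components that overlap voxels already labelled there were seen on the
    first visit and are ignored; the rest become markers for a pass in the
    opposite direction, inheriting the most-similar adjacent object's model.
    """
    if not objects:
        return []
    n = objects[0].slice_index
    back_index = n - _step(pass_direction)
    if not (0 <= back_index < stack.n_slices):
        raise ValueError(f"look-back slice {back_index} outside stack")
    marker_direction = "up" if pass_direction == "down" else "down"
    labelled = seg.mask[back_index]
    markers = []
    for comp, parent, _observed in _evolve_onto_slice(objects, back_index, stack, seg, cfg):
        # material visible from below but not labelled from above; a
        # component may be partly labelled (an upward branch still merged
        # with its parent on the junction slice), so the unlabelled residue
        # is decomposed and marked rather than the whole component
        taken = labelled[comp[:, 0], comp[:, 1]]
        if int(taken.sum()) > len(comp) - cfg.min_area:
            continue
        residue = comp[~taken]
        for piece in connected_components(
            pixels_to_mask(residue, stack.shape[1:]), cfg.connectivity_2d
        ):
            if len(piece) < cfg.min_area:
                continue
            markers.append(
                Marker(
                    slice_index=back_index,
                    pixels=piece,
                    direction=marker_direction,
                    source_pass=pass_id,
                    model=parent.model,
                )
            )
    return markers


def _label_pixels(
    seg: Segmentation, slice_index: int, pixels: np.ndarray, direction: str
) -> np.ndarray:
    """Label not-yet-claimed pixels into the segmentation; return the new ones."""
    value = 1 if direction == "down" else 2
    taken = seg.mask[slice_index, pixels[:, 0], pixels[:, 1]]
    fresh = pixels[~taken]
    if len(fresh):
        seg.mask[slice_index, fresh[:, 0], fresh[:, 1]] = True
        seg.direction_label[slice_index, fresh[:, 0], fresh[:, 1]] = value
    return fresh


def _trim_to_fresh(
    obj: RootObject, fresh: np.ndarray, shape: tuple[int, int], cfg: TrackerConfig
) -> list[RootObject]:
    """Restrict an object to its newly labelled pixels.

    If trimming (a merge with already-known material) disconnects the object,
    each remaining component >= min_area continues as a separate object.
    """
    if len(fresh) == len(obj.pixels):
        return [obj]
    if len(fresh) < cfg.min_area:
        return []
    comps = connected_components(pixels_to_mask(fresh, shape), cfg.connectivity_2d)
    out = []
    for comp in comps:
        if len(comp) >= cfg.min_area:
            out.append(
                RootObject(
                    slice_index=obj.slice_index,
                    pixels=comp,
                    model=obj.model,
                    parent_id=obj.parent_id,
                    direction=obj.direction,
                    id=obj.id,
                )
            )
    return out


def run_pass(
    start_objects: list[RootObject],
    start_slice: int,
    direction: str,
    stack: ImageStack,
    seg: Segmentation,
    cfg: TrackerConfig,
    pass_id: int = 0,
    id_counter: Optional[list] = None,
) -> PassResult:
    """Traverse the stack in one direction from already-labelled start objects.

    After each step the pass looks back in the opposite sense (unless
    ``forward_only``), collecting markers.  The pass ends on target loss or
    at the stack boundary.
    """
    if not start_objects:
        raise ValueError("start_objects must be non-empty")
    if id_counter is None:
        id_counter = [max((o.id for o in start_objects), default=0)]
    result = PassResult()
    step = _step(direction)
    current = list(start_objects)
    result.objects_by_slice[start_slice] = list(current)
    n = start_slice
    while current:
        back = n - step
        if not cfg.forward_only and 0 <= back < stack.n_slices:
            result.slices_visited += 1
            for m in look_back(current, stack, seg, cfg, direction, pass_id):
                result.new_markers.append(m)
        target = n + step
        if not (0 <= target < stack.n_slices):
            break
        result.slices_visited += 1
        children = advance(
            current, stack, cfg, direction, seg=seg, target_index=target,
            id_counter=id_counter,
        )
        survivors = []
        for child in children:
            fresh = _label_pixels(seg, target, child.pixels, direction)
            survivors.extend(_trim_to_fresh(child, fresh, stack.shape[1:], cfg))
        current = survivors
        if current:
            result.objects_by_slice[target] = list(current)
        n = target
    return result


def _marker_overlaps_pending(marker: Marker, pending: list[Marker]) -> bool:
    for other in pending:
        if other.slice_index != marker.slice_index or other.status != "pending":
            continue
        a = set(map(tuple, marker.pixels))
        if a.intersection(map(tuple, other.pixels)):
            return True
    return False


def extract_root_system(
    stack: ImageStack, seed: tuple[int, int], cfg: TrackerConfig
) -> Segmentation:
    """Segment a full root system from a single seed point on slice 0.

    Runs the initial downward pass, then consumes pending markers in fixed
    order (lowest slice first, then creation order), alternating pass
    directions until no markers remain.  With ``cfg.forward_only`` the
    look-back machinery is disabled and the result is the plain top-to-bottom
    tracker's output.
    """
    seg = Segmentation(
        mask=np.zeros(stack.shape, dtype=bool),
        direction_label=np.zeros(stack.shape, dtype=np.uint8),
    )
    first = init_from_click(stack, seed, cfg)
    _label_pixels(seg, 0, first.pixels, "down")
    seg.slice_visits = 1  # the seed segmentation itself
    id_counter = [first.id]

    creation_counter = 0
    all_markers: list[Marker] = []

    def _absorb(new_markers: list[Marker]) -> None:
        nonlocal creation_counter
        for m in new_markers:
            if _marker_overlaps_pending(m, all_markers):
                continue
            m.created_order = creation_counter
            creation_counter += 1
            all_markers.append(m)

    result = run_pass([first], 0, "down", stack, seg, cfg, pass_id=0, id_counter=id_counter)
    seg.slice_visits += result.slices_visited
    seg.pass_count = 1
    _absorb(result.new_markers)

    while True:
        pending = [m for m in all_markers if m.status == "pending"]
        if not pending:
            break
        pending.sort(key=lambda m: (m.slice_index, m.created_order))
        marker = pending[0]
        taken = seg.mask[marker.slice_index, marker.pixels[:, 0], marker.pixels[:, 1]]
        fresh = marker.pixels[~taken]
        if len(fresh) < cfg.min_area:
            marker.status = "discarded"
            continue
        marker.status = "consumed"
        img = stack.voxels[marker.slice_index]
        lo, hi = stack.intensity_range()
        observed = AppearanceModel.from_pixels(img, fresh, cfg.bins, lo, hi)
        model = (
            update_model(marker.model, observed, cfg.beta)
            if marker.model is not None
            else observed
        )
        labelled = _label_pixels(seg, marker.slice_index, fresh, marker.direction)
        id_counter[0] += 1
        start = RootObject(
            slice_index=marker.slice_index,
            pixels=labelled,
            model=model,
            direction=marker.direction,
            id=id_counter[0],
        )
        result = run_pass(
            [start], marker.slice_index, marker.direction, stack, seg, cfg,
            pass_id=seg.pass_count, id_counter=id_counter,
        )
        seg.pass_count += 1
        seg.slice_visits += result.slices_visited
        _absorb(result.new_markers)

    seg.marker_log = all_markers
    return seg
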
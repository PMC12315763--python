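"""Morphological repair of the skull class.

Bright marrow in the diploe is a classic failure mode of intensity-driven
tissue segmentation: it ends up in the soft-head class, splitting the
skull and thinning it.  ``correct_skull_segment`` reclaims such voxels
(head-labelled, enclosed by the morphological closing of the skull, not
part of the outer scalp component, and brighter than the cortical-bone
intensity estimate), fills cavities fully enclosed by skull, and prunes
small disconnected skull islands.  Brain classes are never modified and
every voxel keeps exactly one label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import BACKGROUND, HEAD, SKULL, TissueSegmentation, VolumeGrid

__all__ = ["CorrectionReport", "CorrectionError", "correct_skull_segment"]

DEFAULT_CLOSE_RADIUS_MM = 3.0
#: island threshold expressed as a volume: 100 voxels at 1 mm^3
DEFAULT_MIN_ISLAND_MM3 = 100.0
#: percentile of skull intensities taken as the cortical-bone floor
CORTICAL_PERCENTILE = 5.0


class CorrectionError(RuntimeError):
    pass


@dataclass
class CorrectionReport:
    """Bookkeeping of what the correction changed."""

    n_reclaimed: int
    n_filled: int
    n_removed: int
    changed_mask: np.ndarray

    def __post_init__(self) -> None:
        n_changed = int(self.changed_mask.sum())
        # every changed voxel is accounted for by exactly one of the steps
        assert self.n_reclaimed + self.n_filled + self.n_removed >= n_changed


def _mm_distance_to(mask: np.ndarray, spacing: np.ndarray) -> np.ndarray:
    """Distance (mm) from each voxel center to the nearest True voxel center."""
    return ndimage.distance_transform_edt(~mask, sampling=spacing)


def _close_mm(mask: np.ndarray, radius_mm: float, spacing: np.ndarray) -> np.ndarray:
    """Morphological closing with a Euclidean ball of ``radius_mm``.

    Implemented with two distance transforms, which keeps the structuring
    element spherical in mm regardless of voxel anisotropy and is fast for
    large radii.
    """
    if radius_mm <= 0:
        return mask.copy()
    r = radius_mm + 1e-9
    dilated = _mm_distance_to(mask, spacing) <= r
    # erosion of the dilated set by the same ball
    return ndimage.distance_transform_edt(dilated, sampling=spacing) > r


_STRUCT_6 = ndimage.generate_binary_structure(3, 1)
_STRUCT_26 = ndimage.generate_binary_structure(3, 3)


def _outer_head_component_ids(
    labels: np.ndarray, closed_skull: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Label head-class components (6-connectivity) and identify the outer ones.

    A head component is "outer" (true scalp) if it touches the background
    class or the volume border AND the majority of its voxels lie outside
    the closed skull.  The majority condition keeps misassigned marrow
    that merely grazes the background (e.g. at a defaced/cut inferior rim)
    from masquerading as scalp.
    """
    head = labels == HEAD
    comp, n_comp = ndimage.label(head, structure=_STRUCT_6)
    if n_comp == 0:
        return comp, np.empty(0, dtype=int)
    bg_adjacent = ndimage.binary_dilation(labels == BACKGROUND, structure=_STRUCT_6)
    border = np.zeros(labels.shape, dtype=bool)
    border[0, :, :] = border[-1, :, :] = True
    border[:, 0, :] = border[:, -1, :] = True
    border[:, :, 0] = border[:, :, -1] = True
    touching = np.unique(comp[head & (bg_adjacent | border)])
    touching = touching[touching > 0]
    idx = np.arange(1, n_comp + 1)
    sizes = ndimage.sum_labels(head, comp, index=idx)
    outside = ndimage.sum_labels(head & ~closed_skull, comp, index=idx)
    majority_outside = idx[outside > 0.5 * sizes]
    outer_ids = np.intersect1d(touching, majority_outside)
    return comp, outer_ids


def correct_skull_segment(
    seg: TissueSegmentation,
    t1: VolumeGrid,
    close_radius_mm: float = DEFAULT_CLOSE_RADIUS_MM,
    min_island_mm3: float = DEFAULT_MIN_ISLAND_MM3,
    intensity_guard: bool = True,
) -> tuple[TissueSegmentation, CorrectionReport]:
    """Repair the skull class of a six-class segmentation.

    Steps, in order: (a) reclaim head-labelled voxels that lie inside the
    closing of the skull mask and do not belong to the outer scalp
    component (optionally gated on T1 intensity above the cortical-bone
    estimate); (b) fill cavities fully enclosed by skull; (c) delete skull
    islands smaller than ``min_island_mm3`` and relabel them to the
    majority 6-neighbour class.  GM/WM/CSF voxels are never touched.

    Returns a hard-label segmentation and a :class:`CorrectionReport`.
    """
    if not seg.grid.same_grid(t1):
        raise CorrectionError("t1 and segmentation are not on the same grid")
    labels = seg.labels().copy()
    labels_before = labels.copy()
    spacing = seg.spacing
    skull = labels == SKULL
    if not skull.any():
        raise CorrectionError("segmentation has an empty skull class; nothing to correct")

    # (a) reclaim marrow misassigned to the head class
    closed = _close_mm(skull, close_radius_mm, spacing)
    comp, outer_ids = _outer_head_component_ids(labels, closed)
    candidates = (labels == HEAD) & closed & ~np.isin(comp, outer_ids)
    if intensity_guard:
        cortical_floor = np.percentile(t1.data[skull], CORTICAL_PERCENTILE)
        candidates &= t1.data > cortical_floor
    labels[candidates] = SKULL
    n_reclaimed = int(candidates.sum())

    # (b) fill cavities fully enclosed by skull (head/background only; the
    # brain is also enclosed but its classes are protected)
    skull = labels == SKULL
    enclosed = ndimage.binary_fill_holes(skull, structure=_STRUCT_6) & ~skull
    fillable = enclosed & np.isin(labels, (HEAD, BACKGROUND))
    labels[fillable] = SKULL
    n_filled = int(fillable.sum())

    # (c) prune small skull islands (26-connectivity components)
    skull = labels == SKULL
    voxel_volume = float(np.prod(spacing))
    min_island_voxels = max(1, int(round(min_island_mm3 / voxel_volume)))
    comp26, n_comp = ndimage.label(skull, structure=_STRUCT_26)
    n_removed = 0
    if n_comp > 1:
        sizes = ndimage.sum_labels(skull, comp26, index=np.arange(1, n_comp + 1))
        for cid in np.nonzero(sizes < min_island_voxels)[0] + 1:
            island = comp26 == cid
            labels[island] = _majority_neighbor_class(labels, island)
            n_removed += int(island.sum())

    seg_corrected = TissueSegmentation.from_labels(labels, seg.affine)
    report = CorrectionReport(
        n_reclaimed=n_reclaimed,
        n_filled=n_filled,
        n_removed=n_removed,
        changed_mask=labels != labels_before,
    )
    return seg_corrected, report


def _majority_neighbor_class(labels: np.ndarray, island: np.ndarray) -> int:
    """Majority non-skull class among the 6-neighbours of an island."""
    ring = ndimage.binary_dilation(island, structure=_STRUCT_6) & ~island
    neighbor_labels = labels[ring]
    neighbor_labels = neighbor_labels[neighbor_labels != SKULL]
    if neighbor_labels.size == 0:
        return HEAD
    counts = np.bincount(neighbor_labels, minlength=6)
    return int(np.argmax(counts))
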
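"""Voxelwise thickness maps from dual Euclidean distance transforms.

For a layer bounded by two classes, the thickness at each layer voxel is
the distance to the inner bound plus the distance to the outer bound,
minus one mean voxel spacing.  The subtraction removes the discretization
bias of center-to-center distances: for an axis-aligned slab of n voxels
at spacing h the two distances sum to (n + 1) * h, so the corrected value
is exactly n * h at every slab voxel.

Bone thickness runs from CSF to the soft head class; head-tissue thickness
runs from skull to background, with voxels more than 30 mm from the skull
and voxels below the inferior rim of the skull excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import BACKGROUND, CSF, HEAD, SKULL, TissueSegmentation, VolumeGrid

__all__ = [
    "DistanceError",
    "DistancePair",
    "ThicknessMap",
    "edt_to_class",
    "distance_pair",
    "bone_thickness_map",
    "head_thickness_map",
    "HEAD_MAX_SKULL_DISTANCE_MM",
]

#: head voxels farther than this from the skull are excluded from TAP
HEAD_MAX_SKULL_DISTANCE_MM = 30.0
#: QC flag threshold on voxel anisotropy (max/min spacing - 1)
ANISOTROPY_QC_THRESHOLD = 0.20


class DistanceError(ValueError):
    pass


@dataclass
class DistancePair:
    """Distances (mm) from each domain voxel to an inner and an outer class."""

    d_inner: np.ndarray
    d_outer: np.ndarray
    domain_mask: np.ndarray


@dataclass
class ThicknessMap:
    """Per-voxel thickness in mm; NaN outside the domain and on exclusions."""

    values: np.ndarray
    domain_mask: np.ndarray
    excluded_mask: np.ndarray
    qc_flags: list[str] = field(default_factory=list)

    @property
    def included_mask(self) -> np.ndarray:
        return self.domain_mask & ~self.excluded_mask

    def mean(self) -> float:
        inc = self.included_mask
        if not inc.any():
            return float("nan")
        return float(np.nanmean(self.values[inc]))


def edt_to_class(
    mask_domain: np.ndarray, mask_target: np.ndarray, spacing
) -> np.ndarray:
    """Distance (mm) from each domain-voxel center to the nearest target-voxel center.

    Anisotropy-aware (exact Euclidean metric with per-axis spacing).
    Returns a full volume with NaN outside the domain.
    """
    mask_target = np.asarray(mask_target, dtype=bool)
    if not mask_target.any():
        raise DistanceError("target class is empty")
    d = ndimage.distance_transform_edt(~mask_target, sampling=np.asarray(spacing, float))
    out = np.where(np.asarray(mask_domain, dtype=bool), d, np.nan)
    return out


def distance_pair(
    labels: np.ndarray,
    domain_class: int,
    inner_class: int,
    outer_class: int,
    spacing,
) -> DistancePair:
    domain = labels == domain_class
    return DistancePair(
        d_inner=edt_to_class(domain, labels == inner_class, spacing),
        d_outer=edt_to_class(domain, labels == outer_class, spacing),
        domain_mask=domain,
    )


def _mean_spacing(spacing: np.ndarray, flags: list[str]) -> float:
    spacing = np.asarray(spacing, float)
    if spacing.max() / spacing.min() - 1.0 > ANISOTROPY_QC_THRESHOLD:
        flags.append("anisotropic_voxels")
    return float(spacing.mean())


def bone_thickness_map(seg_corrected: TissueSegmentation) -> ThicknessMap:
    """Bone thickness: d(CSF) + d(head) - mean spacing, per skull voxel."""
    labels = seg_corrected.labels()
    flags: list[str] = []
    hbar = _mean_spacing(seg_corrected.spacing, flags)
    pair = distance_pair(labels, SKULL, CSF, HEAD, seg_corrected.spacing)
    values = np.where(
        pair.domain_mask, np.maximum(pair.d_inner + pair.d_outer - hbar, 0.0), np.nan
    )
    return ThicknessMap(
        values=values,
        domain_mask=pair.domain_mask,
        excluded_mask=np.zeros(labels.shape, dtype=bool),
        qc_flags=flags,
    )


def head_thickness_map(
    seg_corrected: TissueSegmentation,
    max_skull_distance_mm: float = HEAD_MAX_SKULL_DISTANCE_MM,
    inferior_cut_world_z: float | None = None,
) -> ThicknessMap:
    """Soft-head-tissue thickness: d(skull) + d(background) - mean spacing.

    Exclusions: voxels with d(skull) above ``max_skull_distance_mm`` and
    voxels inferior (world z) to the lowest skull voxel, or to
    ``inferior_cut_world_z`` when given (e.g. the bottom of an atlas bone
    mask mapped to individual space).
    """
    labels = seg_corrected.labels()
    flags: list[str] = []
    hbar = _mean_spacing(seg_corrected.spacing, flags)
    pair = distance_pair(labels, HEAD, SKULL, BACKGROUND, seg_corrected.spacing)

    excluded = pair.domain_mask & (pair.d_inner > max_skull_distance_mm)
    world_z = _world_z(seg_corrected.grid)
    if inferior_cut_world_z is None:
        skull = labels == SKULL
        if skull.any():
            inferior_cut_world_z = float(world_z[skull].min())
    if inferior_cut_world_z is not None:
        excluded |= pair.domain_mask & (world_z < inferior_cut_world_z - 1e-9)

    values = np.where(
        pair.domain_mask & ~excluded,
        np.maximum(pair.d_inner + pair.d_outer - hbar, 0.0),
        np.nan,
    )
    return ThicknessMap(
        values=values, domain_mask=pair.domain_mask, excluded_mask=excluded, qc_flags=flags
    )


def _world_z(grid: VolumeGrid) -> np.ndarray:
    """World z coordinate of every voxel center."""
    ii, jj, kk = np.meshgrid(
        np.arange(grid.shape[0]),
        np.arange(grid.shape[1]),
        np.arange(grid.shape[2]),
        indexing="ij",
    )
    a = grid.affine
    return a[2, 0] * ii + a[2, 1] * jj + a[2, 2] * kk + a[2, 3]
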
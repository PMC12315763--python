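"""Procedural calvarial sector atlas and regional aggregation.

The atlas partitions directions around the head center into seven named
sectors (frontal, parietal L/R, occipital, temporal L/R, sphenoid) using
fixed angular bounds on the unit direction (x right, y anterior,
z superior):

    occipital:  n_y < -0.30                      (posterior)
    frontal:    n_y >  0.30 and n_z >= 0.15      (anterior-superior)
    sphenoid:   n_y >  0.30 and n_z <  0.15      (anterior-inferior)
    parietal:   |n_y| <= 0.30 and n_z >= 0.15    (lateral-superior, L/R by n_x)
    temporal:   |n_y| <= 0.30 and n_z <  0.15    (lateral-inferior, L/R by n_x)

These bounds are documented stand-ins for a manually drawn anatomical
atlas; an external label volume can replace them via the CLI.  The bone
mask keeps only frontal/parietal/occipital (labels 1-4) — regions that are
thin or commonly clipped by defacing (temporal, sphenoid) are excluded.
Labels are assigned densely over the grid so that nearest-neighbour
mapping covers every skull voxel of an individual scan.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import VolumeGrid
from .phantom import PhantomSpec, _layer_labels, T_INNER_TABLE, T_DIPLOE, T_OUTER_TABLE

__all__ = [
    "REGION_NAMES",
    "BONE_MASK_LABELS",
    "OCCIPITAL",
    "CalvarialAtlas",
    "TransformError",
    "sector_labels",
    "build_template_atlas",
    "build_atlas_for_grid",
    "map_atlas_to_individual",
    "regional_aggregate",
]

REGION_NAMES: dict[int, str] = {
    0: "none",
    1: "frontal",
    2: "parietal-left",
    3: "parietal-right",
    4: "occipital",
    5: "temporal-left",
    6: "temporal-right",
    7: "sphenoid",
}
FRONTAL, PARIETAL_L, PARIETAL_R, OCCIPITAL, TEMPORAL_L, TEMPORAL_R, SPHENOID = range(1, 8)
BONE_MASK_LABELS = frozenset({FRONTAL, PARIETAL_L, PARIETAL_R, OCCIPITAL})

# angular bounds of the sector partition (unit-direction components)
_NY_SPLIT = 0.30
_NZ_SPLIT = 0.15
# directions are undefined within this radius of the center
_CORE_RADIUS_MM = 5.0


class TransformError(ValueError):
    pass


@dataclass
class CalvarialAtlas:
    """Integer sector labels, a name table, and the defacing-safe bone mask."""

    labels: VolumeGrid
    names: dict[int, str]
    bone_mask: VolumeGrid

    def __post_init__(self) -> None:
        lab = self.labels.data
        mask = self.bone_mask.data.astype(bool)
        forbidden = np.isin(lab, (TEMPORAL_L, TEMPORAL_R, SPHENOID))
        if np.any(mask & forbidden):
            raise ValueError("bone mask must exclude temporal and sphenoid sectors")

    def save(self, labels_path: str | Path, names_path: str | Path | None = None) -> None:
        from .io import save_volume

        save_volume(self.labels, labels_path, dtype=np.int16)
        if names_path is not None:
            Path(names_path).write_text(
                json.dumps({str(k): v for k, v in self.names.items()}, indent=2) + "\n"
            )


def sector_labels(coords_world: np.ndarray, center: np.ndarray) -> np.ndarray:
    """Sector label for each world-coordinate row (N, 3) relative to ``center``."""
    d = np.asarray(coords_world, float) - np.asarray(center, float)
    r = np.linalg.norm(d, axis=-1)
    labels = np.zeros(r.shape, dtype=np.int16)
    ok = r > _CORE_RADIUS_MM
    with np.errstate(invalid="ignore", divide="ignore"):
        n = d / np.where(r > 0, r, 1.0)[..., None]
    nx, ny, nz = n[..., 0], n[..., 1], n[..., 2]

    occ = ny < -_NY_SPLIT
    ant = ny > _NY_SPLIT
    mid = ~occ & ~ant
    sup = nz >= _NZ_SPLIT

    labels[ok & occ] = OCCIPITAL
    labels[ok & ant & sup] = FRONTAL
    labels[ok & ant & ~sup] = SPHENOID
    labels[ok & mid & sup & (nx < 0)] = PARIETAL_L
    labels[ok & mid & sup & (nx >= 0)] = PARIETAL_R
    labels[ok & mid & ~sup & (nx < 0)] = TEMPORAL_L
    labels[ok & mid & ~sup & (nx >= 0)] = TEMPORAL_R
    return labels


def _grid_world_coords(grid_shape, affine: np.ndarray) -> np.ndarray:
    ii, jj, kk = np.meshgrid(
        np.arange(grid_shape[0]),
        np.arange(grid_shape[1]),
        np.arange(grid_shape[2]),
        indexing="ij",
    )
    ijk = np.stack([ii, jj, kk], axis=-1).astype(float)
    return ijk @ affine[:3, :3].T + affine[:3, 3]


def build_template_atlas(template_spec: PhantomSpec) -> CalvarialAtlas:
    """Sector atlas on the template grid defined by a phantom-like geometry.

    Labels are assigned densely by direction from the template center, so
    the template skull shell is fully covered; the bone mask keeps
    frontal/parietal/occipital labels only.
    """
    affine = template_spec.affine()
    coords = _grid_world_coords(template_spec.shape, affine)
    # template center = world origin (phantom affines are centered)
    labels = sector_labels(coords, np.zeros(3))
    # sanity: every voxel of the template skull shell is labelled
    fine = _layer_labels(template_spec)
    shell = np.isin(fine, (T_INNER_TABLE, T_DIPLOE, T_OUTER_TABLE))
    if np.any(labels[shell] == 0):
        raise RuntimeError("template shell voxel fell inside the unlabeled core")
    mask = np.isin(labels, tuple(BONE_MASK_LABELS))
    return CalvarialAtlas(
        labels=VolumeGrid(data=labels, affine=affine),
        names=dict(REGION_NAMES),
        bone_mask=VolumeGrid(data=mask.astype(np.uint8), affine=affine),
    )


def build_atlas_for_grid(grid: VolumeGrid, skull_mask: np.ndarray) -> CalvarialAtlas:
    """Sector atlas directly on an individual grid, centered on the skull centroid."""
    if not skull_mask.any():
        raise ValueError("skull mask is empty")
    coords = _grid_world_coords(grid.shape, grid.affine)
    centroid_vox = np.mean(np.argwhere(skull_mask), axis=0)
    center = grid.voxel_to_world(centroid_vox)[0]
    labels = sector_labels(coords, center)
    mask = np.isin(labels, tuple(BONE_MASK_LABELS))
    return CalvarialAtlas(
        labels=VolumeGrid(data=labels, affine=grid.affine),
        names=dict(REGION_NAMES),
        bone_mask=VolumeGrid(data=mask.astype(np.uint8), affine=grid.affine),
    )


def map_atlas_to_individual(
    atlas: CalvarialAtlas,
    affine_template_to_individual: np.ndarray,
    target_grid: VolumeGrid,
) -> CalvarialAtlas:
    """Nearest-neighbour resampling of labels and mask onto an individual grid.

    ``affine_template_to_individual`` maps template world mm to individual
    world mm (the linear transform from the segmentation step).
    """
    T = np.asarray(affine_template_to_individual, float)
    if T.shape != (4, 4) or abs(np.linalg.det(T)) < 1e-12:
        raise TransformError("template-to-individual affine must be an invertible 4x4")
    # individual voxel -> individual world -> template world -> template voxel
    chain = np.linalg.inv(atlas.labels.affine) @ np.linalg.inv(T) @ target_grid.affine
    ii, jj, kk = np.meshgrid(
        np.arange(target_grid.shape[0]),
        np.arange(target_grid.shape[1]),
        np.arange(target_grid.shape[2]),
        indexing="ij",
    )
    ijk = np.stack([ii, jj, kk], axis=-1).astype(float)
    tmpl_vox = ijk @ chain[:3, :3].T + chain[:3, 3]
    coords = np.moveaxis(tmpl_vox, -1, 0)
    labels = ndimage.map_coordinates(
        atlas.labels.data.astype(np.int16), coords, order=0, mode="constant", cval=0
    )
    mask = ndimage.map_coordinates(
        atlas.bone_mask.data.astype(np.uint8), coords, order=0, mode="constant", cval=0
    )
    return CalvarialAtlas(
        labels=VolumeGrid(data=labels, affine=target_grid.affine),
        names=dict(atlas.names),
        bone_mask=VolumeGrid(data=mask, affine=target_grid.affine),
    )


def regional_aggregate(
    measure: np.ndarray,
    labels: np.ndarray,
    bone_mask: np.ndarray,
    skull_mask: np.ndarray,
    names: dict[int, str] | None = None,
    value_name: str = "mean_value",
) -> pd.DataFrame:
    """Per-region (and global) mean of ``measure`` over skull voxels.

    Region rows average over ``skull & (labels == r) & bone_mask``; the
    global row averages over ``skull & bone_mask``.  NaN measure values are
    ignored; empty regions get n_voxels = 0 and a flag.
    """
    names = dict(REGION_NAMES if names is None else names)
    measure = np.asarray(measure, float)
    labels = np.asarray(labels)
    bone_mask = np.asarray(bone_mask, bool)
    skull_mask = np.asarray(skull_mask, bool)
    rows = []
    region_ids = sorted(k for k in names if k != 0)
    for rid in region_ids:
        sel = skull_mask & bone_mask & (labels == rid)
        vals = measure[sel]
        vals = vals[np.isfinite(vals)]
        rows.append(
            {
                "region_id": rid,
                "region_name": names[rid],
                value_name: float(vals.mean()) if vals.size else float("nan"),
                "n_voxels": int(vals.size),
                "flagged": vals.size == 0,
            }
        )
    sel = skull_mask & bone_mask
    vals = measure[sel]
    vals = vals[np.isfinite(vals)]
    rows.append(
        {
            "region_id": 0,
            "region_name": "global",
            value_name: float(vals.mean()) if vals.size else float("nan"),
            "n_voxels": int(vals.size),
            "flagged": vals.size == 0,
        }
    )
    return pd.DataFrame(rows)
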
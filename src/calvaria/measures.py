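"""The four headline head measures.

proxy BMD    — negated WM-normalized mean skull intensity of the occipital
               sector (bright marrow means low density, so the sign flip
               makes the proxy increase with density).
bone thickness — occipital mean of the voxelwise bone thickness map.
IAP          — intensity-based adiposity proxy: mixture-weighted average of
               the Gaussian peaks fitted to the soft-head-class intensity
               histogram, WM-normalized.
TAP          — thickness-based adiposity proxy: mean soft-tissue thickness
               over voxels whose nearest skull voxel is occipital, after
               the 30 mm and lower-head exclusions.

All intensity measures are normalized by a white-matter reference (median
T1 over high-probability WM voxels), which makes them invariant to global
intensity scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.mixture import GaussianMixture

from . import atlas as atlas_mod
from .atlas import OCCIPITAL, REGION_NAMES, CalvarialAtlas, regional_aggregate
from .correction import correct_skull_segment
from .io import HEAD, SKULL, WM, HeadMeasures, TissueSegmentation, VolumeGrid
from .surface import (
    extract_midline_surface,
    percentage_position_map,
    sample_normal_profiles,
    split_profiles,
)
from .thickness import ThicknessMap, bone_thickness_map, head_thickness_map

__all__ = [
    "WmReference",
    "GaussianMixtureFit",
    "MeasureConfig",
    "ReferenceError",
    "wm_reference",
    "bone_intensity",
    "proxy_bmd",
    "fit_head_gmm",
    "iap",
    "tap",
    "compute_all",
]

WM_PROBABILITY_THRESHOLD = 0.9
MIN_WM_VOXELS = 100
MIN_HEAD_VOXELS = 1000
#: an IAP below this triggers a fat-suppression QC warning
IAP_FAT_SUPPRESSION_FLOOR = 0.3


class ReferenceError(RuntimeError):
    pass


@dataclass
class WmReference:
    """White-matter intensity reference used for normalization."""

    wm_intensity: float

    def __post_init__(self) -> None:
        if not self.wm_intensity > 0:
            raise ReferenceError("WM reference intensity must be > 0")


@dataclass
class GaussianMixtureFit:
    """1-D Gaussian mixture parameters, components sorted by mean."""

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    qc_flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, float)
        self.sds = np.asarray(self.sds, float)
        self.weights = np.asarray(self.weights, float)
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must be nonnegative and sum to 1")
        if np.any(self.sds <= 0):
            raise ValueError("mixture sds must be > 0")

    @property
    def K(self) -> int:
        return len(self.means)


@dataclass
class MeasureConfig:
    """Knobs of the full pipeline, mirrored by the CLI."""

    seed: int = 0
    gmm_k: int = 4
    close_radius_mm: float = 3.0
    min_island_mm3: float = 100.0
    intensity_guard: bool = True
    n_profile_samples: int = 7
    head_max_skull_distance_mm: float = 30.0
    gmm_max_voxels: int = 60_000
    do_surface: bool = True
    template_to_individual: np.ndarray | None = None


def wm_reference(t1: VolumeGrid, seg: TissueSegmentation) -> WmReference:
    """Median T1 intensity over confident WM voxels."""
    if seg.kind == "probability":
        wm_mask = seg.maps[WM].data > WM_PROBABILITY_THRESHOLD
    else:
        wm_mask = seg.maps[WM].data.astype(bool)
    n = int(wm_mask.sum())
    if n < MIN_WM_VOXELS:
        raise ReferenceError(f"only {n} qualifying WM voxels (need {MIN_WM_VOXELS})")
    return WmReference(wm_intensity=float(np.median(t1.data[wm_mask])))


def bone_intensity(
    t1: VolumeGrid,
    seg_corrected: TissueSegmentation,
    atlas_individual: CalvarialAtlas,
    wm: WmReference,
) -> pd.DataFrame:
    """WM-normalized mean skull intensity, per atlas region and globally."""
    skull = seg_corrected.mask(SKULL)
    if not skull.any():
        raise ReferenceError("corrected segmentation has an empty skull class")
    normalized = t1.data / wm.wm_intensity
    return regional_aggregate(
        normalized,
        atlas_individual.labels.data,
        atlas_individual.bone_mask.data.astype(bool),
        skull,
        names=atlas_individual.names,
        value_name="mean_intensity",
    )


def proxy_bmd(occipital_bone_intensity: float) -> float:
    """Proxy BMD: the negated normalized occipital intensity.

    Any strictly decreasing transform of marrow brightness is a consistent
    density proxy; negation is the declared convention here.
    """
    return -float(occipital_bone_intensity)


def fit_head_gmm(
    t1: VolumeGrid,
    seg: TissueSegmentation,
    K: int = 4,
    seed: int = 0,
    max_voxels: int = 60_000,
) -> GaussianMixtureFit:
    """K-component 1-D Gaussian mixture of soft-head-class intensities.

    Deterministic given ``seed`` (seeded EM and seeded subsampling).  A
    degenerate component (weight < 1e-4) triggers a refit with K - 1 and a
    QC flag.
    """
    head_mask = seg.mask(HEAD)
    values = t1.data[head_mask].astype(np.float64)
    if values.size < MIN_HEAD_VOXELS:
        raise ReferenceError(
            f"head class has {values.size} voxels (need {MIN_HEAD_VOXELS})"
        )
    rng = np.random.default_rng(seed)
    if values.size > max_voxels:
        values = values[rng.choice(values.size, size=max_voxels, replace=False)]
    flags: list[str] = []
    while True:
        gm = GaussianMixture(
            n_components=K,
            covariance_type="full",
            random_state=seed,
            n_init=1,
            max_iter=500,
        ).fit(values[:, None])
        weights = gm.weights_
        if np.min(weights) >= 1e-4 or K == 1:
            break
        flags.append(f"gmm_degenerate_refit_k{K - 1}")
        K -= 1
    order = np.argsort(gm.means_.ravel())
    return GaussianMixtureFit(
        means=gm.means_.ravel()[order],
        sds=np.sqrt(gm.covariances_.reshape(-1)[order]),
        weights=gm.weights_[order] / gm.weights_[order].sum(),
        qc_flags=flags,
    )


def iap(fit: GaussianMixtureFit, wm: WmReference) -> float:
    """Intensity-based adiposity proxy: weighted peak average over WM."""
    return float(np.sum(fit.weights * fit.means) / wm.wm_intensity)


def tap(
    head_thickness: ThicknessMap,
    labels_individual: np.ndarray,
    bone_mask: np.ndarray,
    skull_mask: np.ndarray,
    region: int = OCCIPITAL,
) -> tuple[float, list[str]]:
    """Mean included head thickness over the soft tissue of one skull sector.

    Each included soft-tissue voxel is assigned the atlas label of its
    nearest skull voxel; only voxels whose nearest skull voxel lies in the
    bone mask and in ``region`` contribute.
    """
    flags: list[str] = []
    included = head_thickness.included_mask
    if not included.any():
        return float("nan"), ["tap_no_included_voxels"]
    _, nearest = ndimage.distance_transform_edt(~skull_mask, return_indices=True)
    ni, nj, nk = (nearest[d][included] for d in range(3))
    near_labels = labels_individual[ni, nj, nk]
    near_in_mask = np.asarray(bone_mask, bool)[ni, nj, nk]
    sel_vals = head_thickness.values[included][(near_labels == region) & near_in_mask]
    sel_vals = sel_vals[np.isfinite(sel_vals)]
    if sel_vals.size == 0:
        return float("nan"), ["tap_region_empty"]
    return float(sel_vals.mean()), flags


def compute_all(
    t1: VolumeGrid,
    seg: TissueSegmentation,
    atlas: CalvarialAtlas | None = None,
    config: MeasureConfig | None = None,
) -> HeadMeasures:
    """Run the full pipeline: correction -> thickness -> surface -> atlas -> measures.

    Deterministic given ``config.seed``.  When no atlas is supplied, a
    procedural sector atlas centered on the subject's skull is used.
    """
    config = config or MeasureConfig()
    flags: list[str] = list(seg.qc_flags)
    seg.validate()

    seg_c, report = correct_skull_segment(
        seg,
        t1,
        close_radius_mm=config.close_radius_mm,
        min_island_mm3=config.min_island_mm3,
        intensity_guard=config.intensity_guard,
    )
    if report.n_reclaimed or report.n_filled or report.n_removed:
        flags.append(
            f"correction_changed_{report.n_reclaimed}_{report.n_filled}_{report.n_removed}"
        )

    skull_mask = seg_c.mask(SKULL)
    if atlas is None:
        atlas_ind = atlas_mod.build_atlas_for_grid(seg_c.grid, skull_mask)
    elif (
        atlas.labels.same_grid(seg_c.grid)
        and config.template_to_individual is None
    ):
        atlas_ind = atlas
    else:
        T = (
            np.eye(4)
            if config.template_to_individual is None
            else config.template_to_individual
        )
        atlas_ind = atlas_mod.map_atlas_to_individual(atlas, T, seg_c.grid)

    wm = wm_reference(t1, seg)

    bone_thick = bone_thickness_map(seg_c)
    flags += [f for f in bone_thick.qc_flags if f not in flags]
    head_thick = head_thickness_map(
        seg_c, max_skull_distance_mm=config.head_max_skull_distance_mm
    )

    intensity_table = bone_intensity(t1, seg_c, atlas_ind, wm)
    thickness_table = regional_aggregate(
        bone_thick.values,
        atlas_ind.labels.data,
        atlas_ind.bone_mask.data.astype(bool),
        skull_mask,
        names=atlas_ind.names,
        value_name="mean_thickness_mm",
    )
    region_table = intensity_table.merge(
        thickness_table[["region_id", "mean_thickness_mm"]], on="region_id"
    )
    region_table["n_vertices"] = 0

    extras: dict = {}
    if config.do_surface:
        try:
            pos = percentage_position_map(seg_c)
            flags += [f for f in pos.qc_flags if f not in flags]
            surf = extract_midline_surface(pos, seg_c.spacing, seg_c.affine)
            profiles, offsets, valid = sample_normal_profiles(
                surf, t1, bone_thick, n_samples=config.n_profile_samples
            )
            if not valid.all():
                flags.append("surface_profiles_partially_invalid")
            cortical, marrow = split_profiles(profiles, offsets, valid)
            vert_labels = atlas_mod.sector_labels(
                surf.vertices, _skull_center(seg_c, skull_mask)
            )
            surf.region_label = vert_labels
            surf.cortical_intensity = cortical
            surf.marrow_intensity = marrow
            counts = {
                rid: int(np.sum((vert_labels == rid) & valid))
                for rid in REGION_NAMES
                if rid != 0
            }
            region_table["n_vertices"] = [
                counts.get(rid, 0) if rid != 0 else int(valid.sum())
                for rid in region_table["region_id"]
            ]
            occ_valid = (vert_labels == OCCIPITAL) & valid
            if occ_valid.any():
                extras["occipital_cortical_intensity"] = float(
                    np.nanmean(cortical[occ_valid]) / wm.wm_intensity
                )
                extras["occipital_marrow_intensity"] = float(
                    np.nanmean(marrow[occ_valid]) / wm.wm_intensity
                )
            extras["surface_mean_thickness_mm"] = float(
                np.nanmean(surf.thickness_mm[valid])
            )
        except Exception as exc:  # surface stage is non-fatal
            flags.append(f"surface_stage_failed:{type(exc).__name__}")

    fit = fit_head_gmm(
        t1, seg_c, K=config.gmm_k, seed=config.seed, max_voxels=config.gmm_max_voxels
    )
    flags += [f for f in fit.qc_flags if f not in flags]
    iap_value = iap(fit, wm)
    if iap_value < IAP_FAT_SUPPRESSION_FLOOR:
        flags.append("possible_fat_suppression")

    occ_row = region_table[region_table["region_id"] == OCCIPITAL].iloc[0]
    if occ_row["n_voxels"] == 0:
        flags.append("occipital_region_empty")
        bmd_value = float("nan")
        bone_thickness_value = float("nan")
    else:
        bmd_value = proxy_bmd(occ_row["mean_intensity"])
        bone_thickness_value = float(occ_row["mean_thickness_mm"])

    tap_value, tap_flags = tap(
        head_thick,
        atlas_ind.labels.data,
        atlas_ind.bone_mask.data.astype(bool),
        skull_mask,
    )
    flags += tap_flags

    extras["wm_intensity"] = wm.wm_intensity
    extras["gmm_means"] = fit.means.tolist()
    extras["gmm_weights"] = fit.weights.tolist()
    extras["global_bone_intensity"] = float(
        region_table.loc[region_table["region_id"] == 0, "mean_intensity"].iloc[0]
    )
    extras["global_bone_thickness_mm"] = float(
        region_table.loc[region_table["region_id"] == 0, "mean_thickness_mm"].iloc[0]
    )

    ordered = region_table[
        [
            "region_id",
            "region_name",
            "mean_intensity",
            "mean_thickness_mm",
            "n_voxels",
            "n_vertices",
        ]
    ].copy()
    return HeadMeasures(
        proxy_bmd=bmd_value,
        bone_thickness_mm=bone_thickness_value,
        iap=iap_value,
        tap_mm=tap_value,
        region_table=ordered,
        qc_flags=flags,
        extras=extras,
    )


def _skull_center(seg: TissueSegmentation, skull_mask: np.ndarray) -> np.ndarray:
    centroid_vox = np.mean(np.argwhere(skull_mask), axis=0)
    return seg.grid.voxel_to_world(centroid_vox)[0]
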
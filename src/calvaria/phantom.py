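"""Synthetic layered head phantoms with known ground truth.

A phantom is a set of concentric (optionally rotated) ellipsoidal shells:

    brain (WM core + GM cortex) -> CSF -> inner table -> diploe
        -> outer table -> scalp -> background

Layer membership is decided by the distance of each voxel center from the
brain surface (Euclidean distance transform of the brain mask), so layer
thicknesses are uniform in mm for arbitrary ellipsoids and rotations.
Scalp voxels draw their intensity from a two-component (muscle/fat)
mixture with mixing weight ``fat_fraction``; the diploe is bright with a
configurable mean, standing in for marrow whose T1 intensity tracks low
bone density.  Noise (Gaussian or Rician) and an optional smooth
multiplicative bias field are applied after layering.  The returned
segmentation encodes the noise-free ground-truth classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage

from .io import (
    BACKGROUND,
    CSF,
    GM,
    HEAD,
    SKULL,
    WM,
    TissueSegmentation,
    VolumeGrid,
)

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "GeometryError",
    "generate_phantom",
    "plant_marrow_misclassification",
    "make_retest_pair",
    "PRESETS",
    "preset_spec",
]

# Fine-grained truth labels (more detailed than the six-class segmentation).
T_BACKGROUND, T_WM, T_GM, T_CSF, T_INNER_TABLE, T_DIPLOE, T_OUTER_TABLE, T_SCALP = range(8)

#: fine label -> six-class segmentation label
FINE_TO_CLASS = {
    T_BACKGROUND: BACKGROUND,
    T_WM: WM,
    T_GM: GM,
    T_CSF: CSF,
    T_INNER_TABLE: SKULL,
    T_DIPLOE: SKULL,
    T_OUTER_TABLE: SKULL,
    T_SCALP: HEAD,
}


class GeometryError(ValueError):
    """Raised when the requested layers do not fit inside the grid."""


def _default_tissue_means() -> dict[str, float]:
    # T1-like ordering: fat > WM > GM ~ muscle > cortical bone > CSF > air.
    return {
        "gm": 280.0,
        "wm": 400.0,
        "csf": 120.0,
        "cortical_bone": 150.0,
        "muscle": 250.0,
        "fat": 500.0,
        "background": 30.0,
    }


@dataclass
class PhantomSpec:
    """Parameters of a layered head phantom.

    All linear dimensions are mm.  ``fat_fraction`` controls the scalp's
    muscle/fat mixture; ``diploe_intensity`` is the marrow mean intensity
    (the BMD-linked knob: brighter marrow stands for lower density).
    """

    shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    brain_radii: tuple[float, float, float] = (28.0, 26.0, 24.0)
    csf_gap_mm: float = 2.0
    inner_table_mm: float = 1.5
    diploe_mm: float = 2.5
    outer_table_mm: float = 1.5
    scalp_mm: float = 5.0
    cortex_mm: float = 3.0
    diploe_intensity: float = 450.0
    fat_fraction: float = 0.3
    tissue_means: dict[str, float] = field(default_factory=_default_tissue_means)
    noise_sd: float = 10.0
    noise_model: Literal["gaussian", "rician"] = "gaussian"
    bias_amplitude: float = 0.0
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    open_inferior: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("csf_gap_mm", "inner_table_mm", "diploe_mm", "outer_table_mm", "scalp_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.fat_fraction <= 1.0:
            raise ValueError("fat_fraction must be in [0, 1]")
        tm = self.tissue_means
        if tm["cortical_bone"] >= self.diploe_intensity:
            raise ValueError("cortical bone must be darker than the diploe")
        if tm["cortical_bone"] >= tm["wm"]:
            raise ValueError("cortical bone must be darker than WM")

    @property
    def skull_thickness_mm(self) -> float:
        return self.inner_table_mm + self.diploe_mm + self.outer_table_mm

    @property
    def total_offset_mm(self) -> float:
        return self.csf_gap_mm + self.skull_thickness_mm + self.scalp_mm

    def affine(self) -> np.ndarray:
        """Diagonal RAS affine with the world origin at the grid center."""
        aff = np.eye(4)
        sp = np.asarray(self.spacing, dtype=float)
        shp = np.asarray(self.shape, dtype=float)
        aff[:3, :3] = np.diag(sp)
        aff[:3, 3] = -sp * (shp - 1) / 2.0
        return aff


@dataclass
class PhantomTruth:
    """Ground truth accompanying a generated phantom."""

    labels: np.ndarray  # fine labels (T_* constants)
    skull_thickness_mm: float
    scalp_thickness_mm: float
    diploe_intensity: float
    fat_fraction: float
    skull_thickness_map: np.ndarray  # mm on skull voxels, NaN elsewhere
    scalp_thickness_map: np.ndarray  # mm on scalp voxels, NaN elsewhere
    scalp_fat_mask: np.ndarray  # scalp voxels drawn from the fat component
    spec: PhantomSpec

    @property
    def diploe_mask(self) -> np.ndarray:
        return self.labels == T_DIPLOE

    @property
    def skull_mask(self) -> np.ndarray:
        return np.isin(self.labels, (T_INNER_TABLE, T_DIPLOE, T_OUTER_TABLE))

    @property
    def scalp_mask(self) -> np.ndarray:
        return self.labels == T_SCALP


def _rotation_matrix(rotation_deg: tuple[float, float, float]) -> np.ndarray:
    """Intrinsic x-y-z rotation matrix from Euler angles in degrees."""
    rx, ry, rz = np.deg2rad(rotation_deg)
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def _world_coordinates(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    # the phantom affine is diagonal by construction; build axis coordinates directly
    sp = np.asarray(spec.spacing, float)
    shp = np.asarray(spec.shape, float)
    origin = -sp * (shp - 1) / 2.0
    xs = origin[0] + sp[0] * np.arange(spec.shape[0])
    ys = origin[1] + sp[1] * np.arange(spec.shape[1])
    zs = origin[2] + sp[2] * np.arange(spec.shape[2])
    return np.meshgrid(xs, ys, zs, indexing="ij")


def _layer_labels(spec: PhantomSpec) -> np.ndarray:
    """Rasterize the fine ground-truth labels for ``spec``."""
    sp = np.asarray(spec.spacing, float)
    half_extent = sp * (np.asarray(spec.shape, float) - 1) / 2.0
    if np.max(spec.brain_radii) + spec.total_offset_mm >= np.min(half_extent):
        raise GeometryError(
            f"layers (radius {np.max(spec.brain_radii):.1f} + offsets "
            f"{spec.total_offset_mm:.1f} mm) exceed the grid half-extent "
            f"{np.min(half_extent):.1f} mm"
        )

    X, Y, Z = _world_coordinates(spec)
    R = _rotation_matrix(spec.rotation_deg)
    # rotate the anatomy: evaluate the ellipsoid at inverse-rotated coordinates
    Rt = R.T
    xr = Rt[0, 0] * X + Rt[0, 1] * Y + Rt[0, 2] * Z
    yr = Rt[1, 0] * X + Rt[1, 1] * Y + Rt[1, 2] * Z
    zr = Rt[2, 0] * X + Rt[2, 1] * Y + Rt[2, 2] * Z
    a, b, c = spec.brain_radii
    brain = (xr / a) ** 2 + (yr / b) ** 2 + (zr / c) ** 2 <= 1.0

    # distance (mm) from each voxel center to the nearest brain voxel center
    dist_out = ndimage.distance_transform_edt(~brain, sampling=sp)
    # depth inside the brain, for the GM cortex / WM core split
    depth_in = ndimage.distance_transform_edt(brain, sampling=sp)

    labels = np.full(spec.shape, T_BACKGROUND, dtype=np.uint8)
    labels[brain & (depth_in > spec.cortex_mm)] = T_WM
    labels[brain & (depth_in <= spec.cortex_mm)] = T_GM

    edges = np.cumsum(
        [
            spec.csf_gap_mm,
            spec.inner_table_mm,
            spec.diploe_mm,
            spec.outer_table_mm,
            spec.scalp_mm,
        ]
    )
    shells = (T_CSF, T_INNER_TABLE, T_DIPLOE, T_OUTER_TABLE, T_SCALP)
    lo = 0.0
    for lab, hi in zip(shells, edges):
        band = ~brain & (dist_out > lo + 1e-9) & (dist_out <= hi + 1e-9)
        labels[band] = lab
        lo = hi

    if spec.open_inferior:
        # leave the inferior quarter open: no skull or scalp below z = -c/2
        z_cut = -c / 2.0
        inferior = Z < z_cut
        open_mask = inferior & np.isin(
            labels, (T_INNER_TABLE, T_DIPLOE, T_OUTER_TABLE, T_SCALP)
        )
        labels[open_mask] = T_BACKGROUND
    return labels


def _bias_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative field 1 + amplitude * poly, poly zero-mean, |poly|<=1."""
    if spec.bias_amplitude == 0:
        return np.ones(spec.shape)
    X, Y, Z = _world_coordinates(spec)
    half = np.asarray(spec.spacing, float) * (np.asarray(spec.shape, float) - 1) / 2.0
    x, y, z = X / half[0], Y / half[1], Z / half[2]
    coeff = rng.uniform(-1.0, 1.0, size=9)
    poly = (
        coeff[0] * x
        + coeff[1] * y
        + coeff[2] * z
        + coeff[3] * x * y
        + coeff[4] * x * z
        + coeff[5] * y * z
        + coeff[6] * x * x
        + coeff[7] * y * y
        + coeff[8] * z * z
    )
    poly -= poly.mean()
    peak = np.max(np.abs(poly))
    if peak > 0:
        poly /= peak
    return 1.0 + spec.bias_amplitude * poly


def _segmentation_from_fine(
    labels: np.ndarray, affine: np.ndarray, kind: str, spacing: np.ndarray
) -> TissueSegmentation:
    class_labels = np.zeros(labels.shape, dtype=np.uint8)
    for fine, cls in FINE_TO_CLASS.items():
        class_labels[labels == fine] = cls
    if kind == "label":
        return TissueSegmentation.from_labels(class_labels, affine)
    # probability maps: 1 mm Gaussian smoothing of the binary maps, renormalized
    sigma_vox = 1.0 / np.asarray(spacing, float)
    maps = []
    for cls in range(6):
        soft = ndimage.gaussian_filter((class_labels == cls).astype(np.float64), sigma=sigma_vox)
        maps.append(soft)
    total = np.sum(maps, axis=0)
    total[total == 0] = 1.0
    grids = tuple(VolumeGrid(data=m / total, affine=affine) for m in maps)
    return TissueSegmentation(maps=grids, kind="probability")


def generate_phantom(
    spec: PhantomSpec,
    seg_kind: str = "label",
    noise_seed: int | None = None,
) -> tuple[VolumeGrid, TissueSegmentation, PhantomTruth]:
    """Generate a phantom T1 volume, its segmentation, and the ground truth.

    ``spec.seed`` drives the anatomy (scalp muscle/fat composition);
    ``noise_seed`` (default: derived from ``spec.seed``) drives the noise
    and bias realization, so retest pairs can share anatomy while drawing
    independent noise.  Deterministic given both seeds.
    """
    labels = _layer_labels(spec)
    affine = spec.affine()
    sp = np.asarray(spec.spacing, float)

    tm = spec.tissue_means
    intensity_by_fine = {
        T_BACKGROUND: tm["background"],
        T_WM: tm["wm"],
        T_GM: tm["gm"],
        T_CSF: tm["csf"],
        T_INNER_TABLE: tm["cortical_bone"],
        T_DIPLOE: spec.diploe_intensity,
        T_OUTER_TABLE: tm["cortical_bone"],
    }
    t1 = np.empty(spec.shape, dtype=np.float64)
    for fine, mean in intensity_by_fine.items():
        t1[labels == fine] = mean

    anatomy_rng = np.random.default_rng(spec.seed)
    scalp = labels == T_SCALP
    fat_draw = anatomy_rng.random(spec.shape) < spec.fat_fraction
    scalp_fat = scalp & fat_draw
    t1[scalp & ~scalp_fat] = tm["muscle"]
    t1[scalp_fat] = tm["fat"]

    if noise_seed is None:
        noise_seed = spec.seed + 0x5EED
    noise_rng = np.random.default_rng(noise_seed)
    t1 *= _bias_field(spec, noise_rng)
    if spec.noise_sd > 0:
        if spec.noise_model == "gaussian":
            t1 = t1 + noise_rng.normal(0.0, spec.noise_sd, size=spec.shape)
        elif spec.noise_model == "rician":
            n1 = noise_rng.normal(0.0, spec.noise_sd, size=spec.shape)
            n2 = noise_rng.normal(0.0, spec.noise_sd, size=spec.shape)
            t1 = np.sqrt((t1 + n1) ** 2 + n2**2)
        else:
            raise ValueError(f"unknown noise model {spec.noise_model!r}")

    skull_mask = np.isin(labels, (T_INNER_TABLE, T_DIPLOE, T_OUTER_TABLE))
    skull_map = np.where(skull_mask, spec.skull_thickness_mm, np.nan)
    scalp_map = np.where(scalp, spec.scalp_mm, np.nan)

    truth = PhantomTruth(
        labels=labels,
        skull_thickness_mm=spec.skull_thickness_mm,
        scalp_thickness_mm=spec.scalp_mm,
        diploe_intensity=spec.diploe_intensity,
        fat_fraction=spec.fat_fraction,
        skull_thickness_map=skull_map,
        scalp_thickness_map=scalp_map,
        scalp_fat_mask=scalp_fat,
        spec=spec,
    )
    t1_grid = VolumeGrid(data=t1, affine=affine)
    seg = _segmentation_from_fine(labels, affine, seg_kind, sp)
    return t1_grid, seg, truth


def plant_marrow_misclassification(
    seg: TissueSegmentation,
    truth: PhantomTruth,
    fraction: float,
    seed: int,
) -> tuple[TissueSegmentation, np.ndarray]:
    """Relabel a connected random subset of diploe voxels from skull to head.

    Emulates the segmentation failure mode in which bright marrow is
    assigned to the soft-head class.  ``fraction`` of the diploe voxel
    count is corrupted; the planted mask records exactly those voxels.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    diploe = truth.diploe_mask
    n_diploe = int(diploe.sum())
    if n_diploe == 0:
        raise ValueError("phantom has no diploe layer")
    planted = np.zeros(seg.shape, dtype=bool)
    n_target = int(round(fraction * n_diploe))
    if n_target > 0:
        planted = _grow_connected_subset(diploe, n_target, np.random.default_rng(seed))

    if not planted.any():
        return seg, planted

    maps = [m.with_data(m.data.copy()) for m in seg.maps]
    skull_vals = maps[SKULL].data[planted].copy()
    maps[HEAD].data[planted] += skull_vals
    maps[SKULL].data[planted] = 0
    corrupted = TissueSegmentation(maps=tuple(maps), kind=seg.kind, qc_flags=list(seg.qc_flags))
    return corrupted, planted


def _grow_connected_subset(
    mask: np.ndarray, n_target: int, rng: np.random.Generator
) -> np.ndarray:
    """Randomized region growing of a 26-connected subset of ``mask``."""
    coords = np.argwhere(mask)
    n_target = min(n_target, len(coords))
    start = tuple(coords[rng.integers(len(coords))])
    shape = mask.shape
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    selected = np.zeros(shape, dtype=bool)
    in_frontier = np.zeros(shape, dtype=bool)
    frontier = [start]
    in_frontier[start] = True
    n_selected = 0
    while frontier and n_selected < n_target:
        i = int(rng.integers(len(frontier)))
        frontier[i], frontier[-1] = frontier[-1], frontier[i]
        vox = frontier.pop()
        selected[vox] = True
        n_selected += 1
        x, y, z = vox
        for dx, dy, dz in offsets:
            nx, ny, nz = x + dx, y + dy, z + dz
            if 0 <= nx < shape[0] and 0 <= ny < shape[1] and 0 <= nz < shape[2]:
                nb = (nx, ny, nz)
                if mask[nb] and not selected[nb] and not in_frontier[nb]:
                    in_frontier[nb] = True
                    frontier.append(nb)
    return selected


def make_retest_pair(
    spec: PhantomSpec,
    seeds: tuple[int, int],
    seg_kind: str = "label",
) -> tuple[
    tuple[VolumeGrid, TissueSegmentation, PhantomTruth],
    tuple[VolumeGrid, TissueSegmentation, PhantomTruth],
]:
    """Two acquisitions of the same anatomy with independent noise/bias draws."""
    if seeds[0] == seeds[1]:
        raise ValueError("retest seeds must differ")
    first = generate_phantom(spec, seg_kind=seg_kind, noise_seed=seeds[0])
    second = generate_phantom(spec, seg_kind=seg_kind, noise_seed=seeds[1])
    return first, second


PRESETS: dict[str, dict] = {
    "default": dict(open_inferior=True),
    "thin-skull": dict(
        inner_table_mm=1.0, diploe_mm=1.2, outer_table_mm=1.0, open_inferior=True
    ),
    "obese": dict(scalp_mm=9.0, fat_fraction=0.6, open_inferior=True),
    "osteoporotic": dict(diploe_intensity=550.0, diploe_mm=3.5, open_inferior=True),
}


def preset_spec(name: str, seed: int = 0, **overrides) -> PhantomSpec:
    """Named phantom presets for the CLI and for tests."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    params = dict(PRESETS[name])
    params.update(overrides)
    return PhantomSpec(seed=seed, **params)
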
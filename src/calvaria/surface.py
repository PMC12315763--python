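"""Mid-skull surface extraction and normal-profile sampling.

The percentage position map assigns each skull voxel its fractional
position between the inner (CSF) and outer (soft head) bone boundary,
p = d_CSF / (d_CSF + d_head); brain-side voxels carry 0 and outside
voxels carry 1, so marching cubes on the p = 0.5 level set yields a
single closed surface through the middle of the skull.  T1 intensity is
sampled trilinearly along the per-vertex normal across the local bone
thickness; the profile minimum estimates the cortical-plate intensity and
a distance-weighted (triangular-kernel) average estimates the marrow
intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import measure as skmeasure

from .io import BACKGROUND, CSF, HEAD, SKULL, TissueSegmentation, VolumeGrid
from .thickness import ThicknessMap, distance_pair

__all__ = [
    "PositionMap",
    "MidlineSurface",
    "SurfaceError",
    "percentage_position_map",
    "extract_midline_surface",
    "sample_normal_profiles",
    "cortical_marrow_split",
    "split_profiles",
]


class SurfaceError(RuntimeError):
    pass


@dataclass
class PositionMap:
    """Fractional inner-to-outer position of each voxel; skull values in (0, 1)."""

    values: np.ndarray
    skull_mask: np.ndarray
    qc_flags: list[str] = field(default_factory=list)


@dataclass
class MidlineSurface:
    """Triangle mesh on the 50 % position level set, with per-vertex scalars."""

    vertices: np.ndarray  # (V, 3) world mm
    faces: np.ndarray  # (F, 3) vertex indices
    normals: np.ndarray  # (V, 3) unit, oriented toward increasing p
    thickness_mm: np.ndarray | None = None
    cortical_intensity: np.ndarray | None = None
    marrow_intensity: np.ndarray | None = None
    region_label: np.ndarray | None = None
    valid: np.ndarray | None = None

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def edges(self) -> np.ndarray:
        e = np.vstack(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        return np.unique(np.sort(e, axis=1), axis=0)

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges()) + len(self.faces)

    def export_ply(self, path: str | Path) -> None:
        """ASCII PLY with per-vertex scalars where available."""
        props = []
        extra_cols = []
        for name, arr in (
            ("thickness_mm", self.thickness_mm),
            ("cortical_intensity", self.cortical_intensity),
            ("marrow_intensity", self.marrow_intensity),
        ):
            if arr is not None:
                props.append(f"property float {name}")
                extra_cols.append(np.asarray(arr, float))
        lines = [
            "ply",
            "format ascii 1.0",
            f"element vertex {self.n_vertices}",
            "property float x",
            "property float y",
            "property float z",
            *props,
            f"element face {len(self.faces)}",
            "property list uchar int vertex_indices",
            "end_header",
        ]
        cols = [self.vertices] + [c[:, None] for c in extra_cols]
        vert_block = np.hstack(cols)
        for row in vert_block:
            lines.append(" ".join(f"{v:.6f}" for v in row))
        for f in self.faces:
            lines.append("3 " + " ".join(str(int(i)) for i in f))
        Path(path).write_text("\n".join(lines) + "\n")


def percentage_position_map(seg_corrected: TissueSegmentation) -> PositionMap:
    """p = d_CSF / (d_CSF + d_head) on skull voxels; 0 inside, 1 outside."""
    labels = seg_corrected.labels()
    skull = labels == SKULL
    if not skull.any():
        raise SurfaceError("empty skull class")
    pair = distance_pair(labels, SKULL, CSF, HEAD, seg_corrected.spacing)
    values = np.zeros(labels.shape, dtype=np.float64)
    values[np.isin(labels, (HEAD, BACKGROUND))] = 1.0
    flags: list[str] = []
    denom = pair.d_inner + pair.d_outer
    degenerate = skull & (denom == 0)
    if degenerate.any():
        flags.append("degenerate_position_voxels")
    with np.errstate(invalid="ignore", divide="ignore"):
        p_skull = pair.d_inner / denom
    values[skull] = p_skull[skull]
    values[degenerate] = 0.5
    return PositionMap(values=values, skull_mask=skull, qc_flags=flags)


def extract_midline_surface(
    position: PositionMap, spacing, affine
) -> MidlineSurface:
    """Marching cubes on the p = 0.5 level set; largest component kept.

    Vertices are mapped through ``affine`` to world mm; normals are the
    (normalized) world-space gradient of p at the vertex, pointing toward
    increasing p (outward).
    """
    p = position.values
    if p.min() >= 0.5 or p.max() <= 0.5:
        raise SurfaceError("position map has no 0.5 crossing")
    verts_vox, faces, _, _ = skmeasure.marching_cubes(p, level=0.5, step_size=1)
    verts_vox, faces = _largest_component(verts_vox, faces)

    affine = np.asarray(affine, float)
    verts_world = verts_vox @ affine[:3, :3].T + affine[:3, 3]

    # world gradient of p: index gradient pushed through the inverse-transpose
    grads_idx = np.stack(np.gradient(p), axis=-1)
    gi = np.stack(
        [
            ndimage.map_coordinates(grads_idx[..., d], verts_vox.T, order=1)
            for d in range(3)
        ],
        axis=-1,
    )
    A = affine[:3, :3]
    gw = gi @ np.linalg.inv(A)  # rows: g_world = A^{-T} g_idx
    norms = np.linalg.norm(gw, axis=1)
    norms[norms == 0] = 1.0
    normals = gw / norms[:, None]
    return MidlineSurface(vertices=verts_world, faces=faces, normals=normals)


def _largest_component(verts: np.ndarray, faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Keep the largest vertex-connected component of a triangle mesh."""
    n = len(verts)
    parent = np.arange(n)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b, c in faces:
        ra, rb, rc = find(a), find(b), find(c)
        parent[rb] = ra
        parent[rc] = ra
    roots = np.array([find(i) for i in range(n)])
    largest = np.bincount(roots).argmax()
    keep = roots == largest
    remap = -np.ones(n, dtype=np.int64)
    remap[keep] = np.arange(int(keep.sum()))
    faces_kept = faces[keep[faces].all(axis=1)]
    return verts[keep], remap[faces_kept]


def sample_normal_profiles(
    surface: MidlineSurface,
    t1: VolumeGrid,
    thickness: ThicknessMap,
    n_samples: int = 7,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Trilinear T1 profiles along each vertex normal across the local thickness.

    Returns ``(profiles, offsets, valid)`` with shapes (V, n), (V, n), (V,).
    Offsets span [-t/2, +t/2] where t is the thickness of the skull voxel
    nearest to the vertex.  Vertices whose samples fall outside the volume
    are marked invalid.  Also stores per-vertex thickness on the surface.
    """
    if n_samples < 3 or n_samples % 2 == 0:
        raise ValueError("n_samples must be odd and >= 3")
    domain = thickness.domain_mask
    if not domain.any():
        raise SurfaceError("thickness map has an empty domain")

    # nearest-domain-voxel lookup for robust per-vertex thickness
    _, nearest = ndimage.distance_transform_edt(~domain, return_indices=True)
    verts_vox = t1.world_to_voxel(surface.vertices)
    idx = np.clip(
        np.round(verts_vox).astype(int),
        0,
        np.asarray(t1.shape) - 1,
    )
    ni = nearest[0][idx[:, 0], idx[:, 1], idx[:, 2]]
    nj = nearest[1][idx[:, 0], idx[:, 1], idx[:, 2]]
    nk = nearest[2][idx[:, 0], idx[:, 1], idx[:, 2]]
    t_local = thickness.values[ni, nj, nk]
    t_local = np.where(np.isfinite(t_local), t_local, 0.0)
    surface.thickness_mm = t_local

    frac = np.linspace(-0.5, 0.5, n_samples)
    offsets = t_local[:, None] * frac[None, :]
    points = surface.vertices[:, None, :] + offsets[..., None] * surface.normals[:, None, :]
    pts_vox = t1.world_to_voxel(points.reshape(-1, 3))
    profiles = ndimage.map_coordinates(
        t1.data.astype(np.float64),
        pts_vox.T,
        order=1,
        mode="constant",
        cval=np.nan,
    ).reshape(len(surface.vertices), n_samples)
    valid = np.isfinite(profiles).all(axis=1)
    surface.valid = valid
    return profiles, offsets, valid


def cortical_marrow_split(
    profile: np.ndarray, offsets: np.ndarray
) -> tuple[float, float]:
    """Separate a bone profile into cortical and marrow intensity.

    Cortical = the profile minimum.  Marrow = the distance-weighted
    average with triangular weights w(o) = max(0, 1 - |o| / (t/2)) that
    peak on the midline and vanish at the bone edges.
    """
    profile = np.asarray(profile, float)
    offsets = np.asarray(offsets, float)
    ok = np.isfinite(profile)
    if ok.sum() < 3:
        raise ValueError("need at least 3 valid samples")
    profile, offsets = profile[ok], offsets[ok]
    cortical = float(profile.min())
    half = float(np.max(np.abs(offsets)))
    if half == 0:
        return cortical, float(profile.mean())
    w = np.maximum(0.0, 1.0 - np.abs(offsets) / half)
    if w.sum() == 0:
        return cortical, float(profile.mean())
    marrow = float(np.sum(w * profile) / np.sum(w))
    return cortical, marrow


def split_profiles(
    profiles: np.ndarray, offsets: np.ndarray, valid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`cortical_marrow_split` over all valid vertices."""
    V, _ = profiles.shape
    cortical = np.full(V, np.nan)
    marrow = np.full(V, np.nan)
    if not valid.any():
        return cortical, marrow
    p = profiles[valid]
    o = offsets[valid]
    cortical[valid] = np.min(p, axis=1)
    half = np.max(np.abs(o), axis=1)
    w = np.maximum(0.0, 1.0 - np.abs(o) / np.where(half > 0, half, 1.0)[:, None])
    wsum = w.sum(axis=1)
    flat = wsum == 0
    w[flat] = 1.0
    wsum = w.sum(axis=1)
    marrow[valid] = np.sum(w * p, axis=1) / wsum
    return cortical, marrow
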
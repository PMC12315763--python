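"""Volume and segmentation I/O.

NIfTI-1/2 reading and writing via nibabel, grid-compatibility checks for
six-class tissue segmentations, and (de)serialization of measure records
as CSV/JSON.

Conventions: voxel indices are 0-based, world coordinates are mm (RAS),
and all thickness values are reported in mm.  Intensities are kept in
native units; any normalization happens downstream in ``measures``.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "VolumeGrid",
    "TissueSegmentation",
    "HeadMeasures",
    "CLASS_NAMES",
    "GM",
    "WM",
    "CSF",
    "SKULL",
    "HEAD",
    "BACKGROUND",
    "GridError",
    "RegistrationError",
    "ConsistencyError",
    "load_volume",
    "save_volume",
    "load_segmentation",
    "write_measures",
    "read_measures",
]

#: Fixed tissue-class order (SPM c1..c6).
CLASS_NAMES = ("gm", "wm", "csf", "skull", "head", "background")
GM, WM, CSF, SKULL, HEAD, BACKGROUND = range(6)

#: Voxelwise probability sums may deviate from 1 by at most this much.
PROB_SUM_TOL = 0.05
#: Fraction of voxels allowed to violate the probability-sum tolerance.
PROB_SUM_BAD_FRACTION = 0.01


class GridError(ValueError):
    """Raised for invalid volume geometry (dimensionality, affine)."""


class RegistrationError(ValueError):
    """Raised when volumes expected to share a grid do not."""


class ConsistencyError(ValueError):
    """Raised when segmentation maps violate their class contract."""


@dataclass
class VolumeGrid:
    """A 3-D scalar field with its voxel-to-world affine.

    Parameters
    ----------
    data:
        3-D array of scalar values (arbitrary intensity units).
    affine:
        4x4 voxel-to-world transform, world in mm (RAS).
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise GridError(f"expected a 3-D volume, got {self.data.ndim}-D")
        if self.affine.shape != (4, 4):
            raise GridError(f"affine must be 4x4, got {self.affine.shape}")
        if not math.isfinite(np.linalg.det(self.affine)) or abs(np.linalg.det(self.affine)) < 1e-12:
            raise GridError("affine is not invertible")
        if np.any(self.spacing <= 0):
            raise GridError("voxel spacing must be strictly positive")

    @property
    def spacing(self) -> np.ndarray:
        """mm per voxel along each axis (column norms of the affine 3x3 block)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def same_grid(self, other: "VolumeGrid", atol: float = 1e-5) -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine, atol=atol)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (N, 3) voxel indices to (N, 3) world mm coordinates."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Map (N, 3) world mm coordinates to (N, 3) fractional voxel indices."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def with_data(self, data: np.ndarray) -> "VolumeGrid":
        return VolumeGrid(data=data, affine=self.affine.copy())


@dataclass
class TissueSegmentation:
    """Six co-registered tissue maps (GM, WM, CSF, skull, head, background).

    ``kind`` is ``"probability"`` (values in [0, 1], voxelwise sum ~ 1) or
    ``"label"`` (disjoint binary masks covering the grid).
    """

    maps: tuple[VolumeGrid, ...]
    kind: str
    qc_flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.maps = tuple(self.maps)
        if len(self.maps) != 6:
            raise ConsistencyError(f"expected 6 tissue maps, got {len(self.maps)}")
        if self.kind not in ("probability", "label"):
            raise ValueError(f"kind must be 'probability' or 'label', got {self.kind!r}")
        ref = self.maps[0]
        for i, m in enumerate(self.maps[1:], start=1):
            if m.shape != ref.shape or not np.array_equal(m.affine, ref.affine):
                raise RegistrationError(
                    f"map {CLASS_NAMES[i]} is not on the same grid as {CLASS_NAMES[0]}"
                )

    @property
    def grid(self) -> VolumeGrid:
        return self.maps[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.maps[0].shape

    @property
    def affine(self) -> np.ndarray:
        return self.maps[0].affine

    @property
    def spacing(self) -> np.ndarray:
        return self.maps[0].spacing

    def validate(self) -> None:
        """Check the class contract for the declared ``kind``."""
        stack = np.stack([m.data for m in self.maps])
        if self.kind == "probability":
            if stack.min() < -1e-9 or stack.max() > 1 + 1e-9:
                raise ConsistencyError("probability maps must lie in [0, 1]")
            total = stack.sum(axis=0)
            bad = np.abs(total - 1.0) > PROB_SUM_TOL
            if bad.mean() > PROB_SUM_BAD_FRACTION:
                raise ConsistencyError(
                    f"voxelwise probability sum outside 1±{PROB_SUM_TOL} "
                    f"on {bad.mean():.1%} of voxels"
                )
        else:
            vals = np.unique(stack)
            if not np.all(np.isin(vals, (0, 1))):
                raise ConsistencyError("label maps must be binary")
            total = stack.sum(axis=0)
            if np.any(total != 1):
                raise ConsistencyError(
                    "label maps must be disjoint and cover the grid "
                    f"(found voxels with class multiplicity != 1: {int(np.sum(total != 1))})"
                )

    def labels(self) -> np.ndarray:
        """Hard class labels by voxelwise argmax.

        Ties resolve to the first class in the fixed order
        GM > WM > CSF > skull > head > background (argmax semantics).
        """
        stack = np.stack([m.data for m in self.maps])
        return np.argmax(stack, axis=0).astype(np.uint8)

    def mask(self, class_index: int) -> np.ndarray:
        """Boolean mask of a class under hard labelling."""
        return self.labels() == class_index

    @classmethod
    def from_labels(cls, labels: np.ndarray, affine: np.ndarray) -> "TissueSegmentation":
        """Build a label-kind segmentation from an integer class volume."""
        labels = np.asarray(labels)
        maps = tuple(
            VolumeGrid(data=(labels == i).astype(np.uint8), affine=np.asarray(affine, float))
            for i in range(6)
        )
        return cls(maps=maps, kind="label")

    def to_labels_segmentation(self) -> "TissueSegmentation":
        """Argmax-harden into a valid label segmentation."""
        if self.kind == "label":
            return self
        return TissueSegmentation.from_labels(self.labels(), self.affine)


# Columns of a HeadMeasures region table.
REGION_TABLE_COLUMNS = (
    "region_id",
    "region_name",
    "mean_intensity",
    "mean_thickness_mm",
    "n_voxels",
    "n_vertices",
)


@dataclass
class HeadMeasures:
    """Per-subject record of the four headline measures plus regional detail.

    ``proxy_bmd`` and ``iap`` are dimensionless (WM-normalized intensities);
    ``bone_thickness_mm`` and ``tap_mm`` are in mm.
    """

    proxy_bmd: float
    bone_thickness_mm: float
    iap: float
    tap_mm: float
    region_table: pd.DataFrame
    qc_flags: list[str] = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.region_table is None:
            self.region_table = pd.DataFrame(columns=list(REGION_TABLE_COLUMNS))
        self.validate()

    def validate(self) -> None:
        if np.isfinite(self.bone_thickness_mm) and self.bone_thickness_mm < 0:
            raise ValueError("bone_thickness_mm must be >= 0")
        if np.isfinite(self.tap_mm) and self.tap_mm < 0:
            raise ValueError("tap_mm must be >= 0")
        for col in ("n_voxels", "n_vertices"):
            if col in self.region_table.columns and len(self.region_table):
                vals = self.region_table[col].to_numpy()
                if np.any(vals < 0):
                    raise ValueError(f"region_table.{col} must be nonnegative")

    def scalar_dict(self) -> dict[str, float]:
        return {
            "proxy_bmd": float(self.proxy_bmd),
            "bone_thickness_mm": float(self.bone_thickness_mm),
            "iap": float(self.iap),
            "tap_mm": float(self.tap_mm),
        }


def load_volume(path: str | Path) -> VolumeGrid:
    """Read a NIfTI-1/2 volume.

    Raises ``FileNotFoundError`` for a missing file and :class:`GridError`
    for a non-3-D image.  Intensity values are not modified.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise GridError(f"{path}: expected a 3-D image, got shape {data.shape}")
    return VolumeGrid(data=np.asarray(data, dtype=np.float64), affine=np.asarray(img.affine))


def save_volume(volume: VolumeGrid, path: str | Path, dtype=np.float32) -> None:
    """Write a :class:`VolumeGrid` as NIfTI (.nii or .nii.gz by extension)."""
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=dtype), volume.affine)
    nib.save(img, str(path))


def load_segmentation(paths: Sequence[str | Path], kind: str) -> TissueSegmentation:
    """Load six tissue maps (c1..c6 order) and validate them as one segmentation.

    Probability maps are clipped to [0, 1]; clipping adds a QC flag.
    """
    if len(paths) != 6:
        raise ValueError(f"expected 6 paths (c1..c6), got {len(paths)}")
    maps = [load_volume(p) for p in paths]
    flags: list[str] = []
    if kind == "probability":
        clipped = False
        for m in maps:
            if m.data.min() < 0 or m.data.max() > 1:
                np.clip(m.data, 0.0, 1.0, out=m.data)
                clipped = True
        if clipped:
            flags.append("probability_maps_clipped")
    seg = TissueSegmentation(maps=tuple(maps), kind=kind, qc_flags=flags)
    seg.validate()
    return seg


def write_measures(measures: HeadMeasures, path: str | Path, format: str = "json") -> None:
    """Serialize a :class:`HeadMeasures` record to JSON or CSV.

    Reading the file back with :func:`read_measures` reproduces all numeric
    fields to 1e-9 or better.
    """
    measures.validate()
    path = Path(path)
    if format == "json":
        payload = {
            **measures.scalar_dict(),
            "qc_flags": list(measures.qc_flags),
            "extras": {k: _jsonable(v) for k, v in measures.extras.items()},
            "region_table": measures.region_table.to_dict(orient="records"),
        }
        path.write_text(json.dumps(payload, indent=2, default=_jsonable) + "\n")
    elif format == "csv":
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["section", "key", "field", "value"])
            for key, value in measures.scalar_dict().items():
                writer.writerow(["scalar", key, "", repr(value)])
            for flag in measures.qc_flags:
                writer.writerow(["qc_flag", flag, "", ""])
            for key, value in measures.extras.items():
                writer.writerow(["extra", key, "", repr(_jsonable(value))])
            for i, row in measures.region_table.iterrows():
                for col in measures.region_table.columns:
                    writer.writerow(["region", str(i), col, repr(_jsonable(row[col]))])
    else:
        raise ValueError(f"unknown format {format!r}")


def read_measures(path: str | Path, format: str | None = None) -> HeadMeasures:
    """Inverse of :func:`write_measures`."""
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "json"
    if format == "json":
        payload = json.loads(path.read_text())
        table = pd.DataFrame(payload.get("region_table", []))
        if table.empty:
            table = pd.DataFrame(columns=list(REGION_TABLE_COLUMNS))
        return HeadMeasures(
            proxy_bmd=payload["proxy_bmd"],
            bone_thickness_mm=payload["bone_thickness_mm"],
            iap=payload["iap"],
            tap_mm=payload["tap_mm"],
            region_table=table,
            qc_flags=list(payload.get("qc_flags", [])),
            extras=dict(payload.get("extras", {})),
        )
    scalars: dict[str, float] = {}
    flags: list[str] = []
    extras: dict = {}
    region_rows: dict[str, dict] = {}
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        assert header[0] == "section"
        for section, key, fieldname, value in reader:
            if section == "scalar":
                scalars[key] = _unrepr(value)
            elif section == "qc_flag":
                flags.append(key)
            elif section == "extra":
                extras[key] = _unrepr(value)
            elif section == "region":
                region_rows.setdefault(key, {})[fieldname] = _unrepr(value)
    table = pd.DataFrame(list(region_rows.values()))
    if table.empty:
        table = pd.DataFrame(columns=list(REGION_TABLE_COLUMNS))
    return HeadMeasures(region_table=table, qc_flags=flags, extras=extras, **scalars)


def _jsonable(value):
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, float) and not math.isfinite(value):
        return None
    return value


def _unrepr(text: str):
    if text == "":
        return ""
    try:
        import ast

        return ast.literal_eval(text)
    except (ValueError, SyntaxError):
        return text
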
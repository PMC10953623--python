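"""Core data types, NIfTI and tabular I/O, and coordinate conventions.

World coordinates are RAS millimetres throughout: +x right, +y anterior,
+z superior.  Volumes read from disk are reoriented to a canonical RAS
axis order so that downstream stages can reason about world geometry
without per-image orientation handling.  Voxel indices are 0-based and a
voxel's world position is the position of its centre.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd


class SchemaError(ValueError):
    """A table or file is missing a required column/field."""


class GeometryError(ValueError):
    """Two volumes that must share a grid do not."""


class DimensionalityError(ValueError):
    """An image is not a 3D scalar volume."""


@dataclass
class VolumeImage:
    """A 3D scalar grid with a voxel-index -> world-mm affine map."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"expected a 3D volume, got {self.data.ndim}D"
            )
        if min(self.data.shape) < 8:
            raise ValueError(
                f"grid dimensions must be >= 8 per axis, got {self.data.shape}"
            )
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")

    @property
    def spacing(self) -> tuple[float, float, float]:
        """Voxel spacing in mm, derived from the affine column norms."""
        return tuple(np.linalg.norm(self.affine[:3, :3], axis=0))

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3 (|det| of the linear part)."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (..., 3) voxel indices to world mm coordinates."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def same_grid(self, other: "VolumeImage | LabelVolume") -> bool:
        return self.data.shape == other.data.shape and np.allclose(
            self.affine, other.affine, atol=1e-5
        )


@dataclass
class LabelVolume:
    """A 3D non-negative integer grid sharing geometry with its image."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise DimensionalityError(
                f"expected a 3D label volume, got {data.ndim}D"
            )
        if np.any(data < 0):
            raise ValueError("label values must be non-negative integers")
        self.data = data.astype(np.int32)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def spacing(self) -> tuple[float, float, float]:
        return tuple(np.linalg.norm(self.affine[:3, :3], axis=0))

    @property
    def voxel_volume(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def is_binary(self) -> bool:
        return bool(np.isin(self.data, (0, 1)).all())

    def same_grid(self, other: "VolumeImage | LabelVolume") -> bool:
        return self.data.shape == other.data.shape and np.allclose(
            self.affine, other.affine, atol=1e-5
        )

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]


@dataclass
class AffineTransform:
    """A world-mm -> world-mm affine map (native -> stereotaxic template).

    ``matrix`` is 4x4 acting on homogeneous RAS coordinates.  ``scale_det``
    is |det| of the 3x3 linear part: the local volume expansion factor from
    native to template space, used for intracranial-volume estimation.
    """

    matrix: np.ndarray
    low_confidence: bool = False

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape != (4, 4):
            raise ValueError("transform matrix must be 4x4")
        if abs(np.linalg.det(self.matrix[:3, :3])) < 1e-12:
            raise ValueError("transform is singular")

    @property
    def scale_det(self) -> float:
        return float(abs(np.linalg.det(self.matrix[:3, :3])))

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix),
                               low_confidence=self.low_confidence)

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        return xyz @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# ventra affine transform v1\n")
            fh.write("direction: native_to_template\n")
            fh.write(f"low_confidence: {int(self.low_confidence)}\n")
            for row in self.matrix:
                fh.write(" ".join(f"{v:.12g}" for v in row) + "\n")

    @classmethod
    def load(cls, path) -> "AffineTransform":
        with open(path) as fh:
            lines = [ln.strip() for ln in fh if ln.strip()]
        if not lines or "affine transform" not in lines[0]:
            raise IOError(f"not a ventra transform file: {path}")
        low_conf = False
        rows = []
        for ln in lines[1:]:
            if ln.startswith("direction:"):
                continue
            if ln.startswith("low_confidence:"):
                low_conf = bool(int(ln.split(":")[1]))
                continue
            rows.append([float(v) for v in ln.split()])
        return cls(np.array(rows), low_confidence=low_conf)


_SEX_CODES = {
    "m": 1, "male": 1, "1": 1,
    "f": 0, "female": 0, "0": 0,
}


@dataclass
class SubjectRecord:
    """One row of the input subject table."""

    id: str
    image_path: str
    age: float
    sex: str  # "male" | "female"
    true_label: Optional[str] = None  # "bvFTD" | "other"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 < self.age < 120):
            raise ValueError(
                f"subject {self.id}: age must be in (0, 120), got {self.age}"
            )
        if self.sex not in ("male", "female"):
            raise ValueError(f"subject {self.id}: unparseable sex {self.sex!r}")

    @property
    def sex_code(self) -> int:
        """Numeric encoding used by the classifier: male=1, female=0."""
        return 1 if self.sex == "male" else 0


def parse_sex(value) -> str:
    key = str(value).strip().lower()
    if key not in _SEX_CODES:
        raise ValueError(f"unparseable sex value {value!r}")
    return "male" if _SEX_CODES[key] == 1 else "female"


REQUIRED_SUBJECT_COLUMNS = ("id", "image_path", "age", "sex")


def read_subject_table(path) -> list[SubjectRecord]:
    """Read the comma-separated subject table.

    Required columns: id, image_path, age, sex.  An optional ``true_label``
    column and any extra columns are preserved (extras under ``metadata``).
    """
    df = pd.read_csv(path, dtype=str)
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in REQUIRED_SUBJECT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"subject table {path} is missing required column(s): "
            + ", ".join(missing)
        )
    extra_cols = [
        c for c in df.columns
        if c not in REQUIRED_SUBJECT_COLUMNS + ("true_label",)
    ]
    records = []
    seen: set[str] = set()
    for idx, row in df.iterrows():
        try:
            age = float(row["age"])
        except (TypeError, ValueError):
            raise ValueError(
                f"row {idx}: non-numeric age {row['age']!r}"
            ) from None
        try:
            rec = SubjectRecord(
                id=str(row["id"]).strip(),
                image_path=str(row["image_path"]).strip(),
                age=age,
                sex=parse_sex(row["sex"]),
                true_label=(
                    str(row["true_label"]).strip()
                    if "true_label" in df.columns
                    and pd.notna(row["true_label"])
                    else None
                ),
                metadata={c: row[c] for c in extra_cols},
            )
        except ValueError as exc:
            raise ValueError(f"row {idx}: {exc}") from None
        if rec.id in seen:
            raise ValueError(f"row {idx}: duplicate subject id {rec.id!r}")
        seen.add(rec.id)
        records.append(rec)
    return records


def read_volume(path) -> VolumeImage:
    """Read a NIfTI volume, reoriented internally to canonical RAS order.

    Reorientation permutes/flips the data grid and updates the affine so
    that world-space content is unchanged: ``affine @ index`` of any
    landmark is identical before and after.
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types
        raise IOError(f"cannot read NIfTI file {path}: {exc}") from exc
    if img.ndim != 3:
        raise DimensionalityError(
            f"{path}: expected a 3D volume, got {img.ndim}D"
        )
    img = nib.as_closest_canonical(img)
    data = np.asarray(img.dataobj, dtype=np.float32)
    return VolumeImage(data=data, affine=np.asarray(img.affine))


def read_label_volume(path) -> LabelVolume:
    vol = read_volume(path)
    data = np.rint(vol.data).astype(np.int32)
    return LabelVolume(data=data, affine=vol.affine)


def write_volume(vol: "VolumeImage | LabelVolume", path) -> None:
    data = vol.data
    if isinstance(vol, LabelVolume):
        data = data.astype(np.int16)
    nib.save(nib.Nifti1Image(data, vol.affine), str(path))


# Column order of the output feature table; ventricle feature fields are
# appended by write_feature_table from the VentricleFeatures schema.
_LEAD_COLUMNS = ("id", "age", "sex", "diagnosis")


def write_feature_table(rows, path) -> None:
    """Write the per-subject feature/diagnosis CSV.

    ``rows`` is a list of (SubjectRecord, VentricleFeatures-or-None,
    diagnosis string) triples.  QC-failed subjects have no features; their
    feature fields are written empty and diagnosis is "QC_FAIL".
    """
    out = []
    feature_fields: list[str] = []
    for rec, feats, diagnosis in rows:
        d = {
            "id": rec.id,
            "age": rec.age,
            "sex": rec.sex,
            "diagnosis": diagnosis,
        }
        if rec.true_label is not None:
            d["true_label"] = rec.true_label
        if feats is not None:
            fdict = feats.as_dict()
            if not feature_fields:
                feature_fields = list(fdict)
            d.update(fdict)
        out.append(d)
    if not feature_fields:
        from .features import VentricleFeatures
        feature_fields = VentricleFeatures.field_names()
    cols = list(_LEAD_COLUMNS)
    if any("true_label" in d for d in out):
        cols.append("true_label")
    cols += [c for c in feature_fields if c not in cols]
    df = pd.DataFrame(out, columns=cols)
    df.to_csv(path, index=False, float_format="%.6f")


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "id" not in df.columns:
        raise SchemaError(f"feature table {path} has no 'id' column")
    return df
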
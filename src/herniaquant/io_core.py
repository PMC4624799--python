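"""Shared data containers, label registry, and NIfTI / CSV round-tripping.

Coordinate conventions used throughout the package:

* patient axes: x = left-to-right (L-R), y = posterior-to-anterior (A-P),
  z = inferior-to-superior (C-C);
* voxel indices are 0-based and a voxel's coordinate is its *center*;
* the affine maps homogeneous voxel indices to patient millimetres.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "LABEL_REGISTRY",
    "LANDMARK_LABELS",
    "METRIC_INDICES",
    "METRIC_NAMES",
    "LabeledVolume",
    "LandmarkSet",
    "CohortTable",
    "FormatError",
    "ValidationError",
    "read_labeled_volume",
    "write_labeled_volume",
    "write_metrics_table",
    "read_metrics_table",
]


class FormatError(ValueError):
    """Malformed or inconsistent external file."""


class ValidationError(ValueError):
    """Contract violation in otherwise well-formed data."""


#: integer label code -> structure name
LABEL_REGISTRY: Mapping[int, str] = {
    0: "background",
    1: "outer_anterior_wall_axial",
    2: "inner_anterior_wall_axial",
    3: "posterior_wall",
    4: "outer_anterior_wall_sagittal",
    5: "inner_anterior_wall_sagittal",
    6: "linea_alba",
    7: "linea_semilunaris",
    8: "hernia",
    10: "xiphoid",
    11: "umbilicus",
    12: "left_asis",
    13: "right_asis",
    14: "pubic_symphysis",
}

#: landmark name -> label code (point landmarks only)
LANDMARK_LABELS: Mapping[str, int] = {
    "xiphoid": 10,
    "umbilicus": 11,
    "left_asis": 12,
    "right_asis": 13,
    "pubic_symphysis": 14,
}

AXIAL_WALL_LABELS = (1, 2, 3)
WALL_LABELS = (1, 2, 3, 4, 5)

METRIC_INDICES = tuple("ABCDEFGHIJKLMNOPQRST")

METRIC_NAMES: Mapping[str, str] = {
    "A": "Hernia volume (cm3)",
    "B": "Hernia L-R diameter (cm)",
    "C": "Hernia A-P diameter (cm)",
    "D": "Hernia C-C diameter (cm)",
    "E": "Hernia anterior surface area (cm2)",
    "F": "Hernia posterior surface area (cm2)",
    "G": "Average A-P hernia thickness (cm)",
    "H": "Normalized horizontal hernia location",
    "I": "Normalized vertical hernia location",
    "J": "Distance from hernia to left ASIS (cm)",
    "K": "Distance from hernia to right ASIS (cm)",
    "L": "Distance from hernia to XP (cm)",
    "M": "Body volume over abdomen (cm3)",
    "N": "Abdominal cavity volume (cm3)",
    "O": "Ratio of hernia to abdominal cavity volume",
    "P": "Mean abdominal wall thickness (cm)",
    "Q": "Std of abdominal wall thickness (cm)",
    "R": "Visceral fat volume (cm3)",
    "S": "Subcutaneous fat volume (cm3)",
    "T": "Evaluated height of abdominal region (cm)",
}

SHAPE_METRICS = tuple("ABCDEFG")
LOCATION_METRICS = tuple("HIJKL")
BODY_METRICS = tuple("MNOPQRST")


@dataclass
class LabeledVolume:
    """An intensity grid plus an integer label grid on a shared geometry.

    ``intensity`` holds Hounsfield-like units; ``labels`` holds codes from
    :data:`LABEL_REGISTRY`; ``affine`` is the 4x4 voxel-index -> patient-mm map.
    """

    intensity: np.ndarray
    labels: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity)
        self.labels = np.asarray(self.labels)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.intensity.shape != self.labels.shape:
            raise FormatError(
                f"intensity shape {self.intensity.shape} != label shape {self.labels.shape}"
            )
        if self.affine.shape != (4, 4):
            raise FormatError("affine must be 4x4")
        if not np.issubdtype(self.labels.dtype, np.integer):
            cast = self.labels.astype(np.int16)
            if not np.array_equal(cast, self.labels):
                raise FormatError("labels are not integral")
            self.labels = cast
        if np.any(self.spacing <= 0):
            raise ValidationError(f"non-positive voxel spacing {self.spacing}")
        unknown = set(np.unique(self.labels)) - set(LABEL_REGISTRY)
        if unknown:
            raise ValidationError(f"unknown label codes: {sorted(unknown)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensity.shape

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel size in mm."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def extent_mm(self) -> np.ndarray:
        """Physical side lengths of the full grid."""
        return np.asarray(self.shape) * self.spacing

    def voxel_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        """Map (n,3) voxel indices to (n,3) patient-mm coordinates."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def mm_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def label_mask(self, code: int) -> np.ndarray:
        return self.labels == code

    def label_points_mm(self, code: int) -> np.ndarray:
        """Patient-mm centers of all voxels carrying ``code`` (n,3)."""
        idx = np.argwhere(self.labels == code)
        if idx.size == 0:
            return np.empty((0, 3))
        return self.voxel_to_mm(idx)


@dataclass
class LandmarkSet:
    """Named anatomical points in patient millimetres.

    ``linea_alba`` / ``linea_semilunaris`` are per-slice point lists; the five
    point landmarks are single coordinates.
    """

    xiphoid: np.ndarray | None = None
    umbilicus: np.ndarray | None = None
    left_asis: np.ndarray | None = None
    right_asis: np.ndarray | None = None
    pubic_symphysis: np.ndarray | None = None
    linea_alba: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    linea_semilunaris: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))

    def require(self, name: str) -> np.ndarray:
        value = getattr(self, name, None)
        if value is None or (isinstance(value, np.ndarray) and value.size == 0):
            raise ValidationError(f"missing required landmark: {name}")
        return np.asarray(value, dtype=float)

    def validate_span(self) -> None:
        left, right = self.require("left_asis"), self.require("right_asis")
        if np.isclose(left[0], right[0]):
            raise ValidationError("left and right ASIS share an x-coordinate")


@dataclass
class CohortTable:
    """Subjects x features with a binary bridge-closure outcome (1 = bridge)."""

    frame: pd.DataFrame
    outcome_column: str = "bridge"

    def __post_init__(self) -> None:
        if self.outcome_column not in self.frame.columns:
            raise ValidationError(f"outcome column {self.outcome_column!r} missing")
        outcome = self.frame[self.outcome_column]
        if outcome.isna().any():
            raise ValidationError("missing outcome values")
        if not set(np.unique(outcome)).issubset({0, 1}):
            raise ValidationError("outcome must be binary 0/1")
        if len(self.feature_names) < 1:
            raise ValidationError("cohort has no feature columns")

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.frame.columns if c not in (self.outcome_column, "subject_id")]

    @property
    def X(self) -> np.ndarray:
        return self.frame[self.feature_names].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.frame[self.outcome_column].to_numpy(dtype=int)

    def require_both_classes(self) -> None:
        if len(np.unique(self.y)) < 2:
            raise ValidationError("outcome takes a single value; model fitting needs both")

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, outcome_column: str = "bridge") -> "CohortTable":
        return cls(pd.read_csv(path), outcome_column=outcome_column)


def read_labeled_volume(image_path: str | Path, label_path: str | Path) -> LabeledVolume:
    """Load a paired intensity + label NIfTI into a :class:`LabeledVolume`.

    The affine is taken from the *image* header; label values are cast to
    integers without change and validated against :data:`LABEL_REGISTRY`.
    """
    img = nib.load(str(image_path))
    lab = nib.load(str(label_path))
    intensity = np.asarray(img.dataobj, dtype=np.float32)
    labels = np.asarray(lab.dataobj)
    if intensity.shape != labels.shape:
        raise FormatError(
            f"grid shape mismatch: image {intensity.shape} vs labels {labels.shape}"
        )
    labels = np.rint(labels).astype(np.int16)
    return LabeledVolume(intensity=intensity, labels=labels, affine=np.asarray(img.affine))


def write_labeled_volume(
    vol: LabeledVolume, image_path: str | Path, label_path: str | Path
) -> None:
    nib.save(nib.Nifti1Image(vol.intensity.astype(np.float32), vol.affine), str(image_path))
    nib.save(nib.Nifti1Image(vol.labels.astype(np.int16), vol.affine), str(label_path))


def _metric_cell(value: float | None) -> str:
    # absent metrics (hernia-free subjects) are written as empty cells, not zeros
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return ""
    return f"{value:.6g}"


def write_metrics_table(rows: Sequence, path: str | Path, ids: Sequence[str] | None = None) -> None:
    """Write metric vectors to CSV: one header row (id + indices A..T), one row
    per subject, deterministic column order; absent metrics as empty cells."""
    from .metrics import MetricVector  # local import avoids a cycle

    rows = list(rows)
    if not rows:
        raise ValidationError("no metric rows to write")
    if ids is None:
        ids = [getattr(r, "subject_id", None) or f"subject_{i:03d}" for i, r in enumerate(rows)]
    if len(ids) != len(rows):
        raise ValidationError("ids and rows length mismatch")
    buf = io.StringIO()
    header = ["id"] + [f"{idx}:{METRIC_NAMES[idx]}" for idx in METRIC_INDICES]
    buf.write(",".join(f'"{h}"' if "," in h else h for h in header) + "\n")
    for sid, row in zip(ids, rows):
        if not isinstance(row, MetricVector):
            raise ValidationError("rows must be MetricVector instances")
        values = row.as_dict()
        buf.write(",".join([str(sid)] + [_metric_cell(values[idx]) for idx in METRIC_INDICES]) + "\n")
    Path(path).write_text(buf.getvalue())


def read_metrics_table(path: str | Path) -> pd.DataFrame:
    """Read a metrics CSV back; columns renamed to bare indices A..T."""
    df = pd.read_csv(path)
    rename = {c: c.split(":", 1)[0] for c in df.columns if ":" in c}
    return df.rename(columns=rename)
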
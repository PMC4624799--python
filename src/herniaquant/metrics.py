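"""Derivation of the 20 named morphometrics (indices A-T) for one subject.

Shape metrics (A-G) come from the dense hernia label, location metrics (H-L)
from the hernia centroid and the bony landmarks, body metrics (M-T) from the
interpolated wall surfaces and the fat compartments, all restricted to the
vertical range with labeled walls.  Shape and location metrics are *absent*
(None), not zero, when no hernia is labeled; the volume ratio O is 0 then.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Optional

import numpy as np

from .io_core import (
    LabeledVolume,
    LandmarkSet,
    METRIC_INDICES,
    ValidationError,
)
from .segmentation import CompartmentMasks, extract_compartments
from .surfaces import WallSurfaces, contours_from_labels, interpolate_walls, wall_thickness_stats

__all__ = [
    "MetricVector",
    "hernia_shape_metrics",
    "hernia_location_metrics",
    "body_metrics",
    "derive_all",
]


@dataclass
class MetricVector:
    A: Optional[float] = None  # hernia volume (cm3)
    B: Optional[float] = None  # hernia L-R diameter (cm)
    C: Optional[float] = None  # hernia A-P diameter (cm)
    D: Optional[float] = None  # hernia C-C diameter (cm)
    E: Optional[float] = None  # hernia anterior surface area (cm2)
    F: Optional[float] = None  # hernia posterior surface area (cm2)
    G: Optional[float] = None  # average A-P hernia thickness (cm)
    H: Optional[float] = None  # normalized horizontal location
    I: Optional[float] = None  # normalized vertical location
    J: Optional[float] = None  # distance hernia -> left ASIS (cm)
    K: Optional[float] = None  # distance hernia -> right ASIS (cm)
    L: Optional[float] = None  # distance hernia -> xiphoid (cm)
    M: Optional[float] = None  # body volume over abdomen (cm3)
    N: Optional[float] = None  # abdominal cavity volume (cm3)
    O: Optional[float] = None  # hernia/cavity volume ratio
    P: Optional[float] = None  # mean wall thickness (cm)
    Q: Optional[float] = None  # SD wall thickness (cm)
    R: Optional[float] = None  # visceral fat volume (cm3)
    S: Optional[float] = None  # subcutaneous fat volume (cm3)
    T: Optional[float] = None  # evaluated height of abdominal region (cm)
    subject_id: Optional[str] = None

    def as_dict(self) -> dict:
        return {idx: getattr(self, idx) for idx in METRIC_INDICES}

    def update(self, values: dict) -> None:
        for key, val in values.items():
            if key not in METRIC_INDICES:
                raise ValidationError(f"unknown metric index {key!r}")
            setattr(self, key, val)


def hernia_shape_metrics(hernia: np.ndarray, spacing: np.ndarray) -> dict | None:
    """Metrics A-G from the dense hernia mask; None if the mask is empty."""
    hernia = np.asarray(hernia, dtype=bool)
    if not hernia.any():
        return None
    sx, sy, sz = (float(s) for s in np.asarray(spacing))
    voxvol = sx * sy * sz

    idx = np.argwhere(hernia)
    extent = (idx.max(axis=0) - idx.min(axis=0) + 1) * np.array([sx, sy, sz])

    # boundary faces by axis via shifts; +y faces count to E, -y faces to F
    pad = np.pad(hernia, 1)
    pos_y = pad[1:-1, 1:-1, 1:-1] & ~pad[1:-1, 2:, 1:-1]
    neg_y = pad[1:-1, 1:-1, 1:-1] & ~pad[1:-1, :-2, 1:-1]
    face_area = sx * sz  # a +-y face spans dx * dz
    E = float(pos_y.sum()) * face_area / 100.0
    F = float(neg_y.sum()) * face_area / 100.0

    # mean A-P chord over occupied (x, z) columns
    col_counts = hernia.sum(axis=1)
    occupied = col_counts > 0
    G = float(col_counts[occupied].mean()) * sy / 10.0

    return {
        "A": float(hernia.sum()) * voxvol / 1e3,
        "B": float(extent[0]) / 10.0,
        "C": float(extent[1]) / 10.0,
        "D": float(extent[2]) / 10.0,
        "E": E,
        "F": F,
        "G": G,
    }


def hernia_centroid_mm(vol: LabeledVolume) -> np.ndarray | None:
    idx = np.argwhere(vol.labels == 8)
    if idx.size == 0:
        return None
    return vol.voxel_to_mm(idx).mean(axis=0)


def hernia_location_metrics(
    centroid_mm: np.ndarray, landmarks: LandmarkSet
) -> dict:
    """Metrics H-L from the hernia centroid and the landmark set.

    H is the projection fraction of the centroid along the left-ASIS ->
    right-ASIS segment (0 at left, 1 at right, may leave [0, 1]); I is the
    normalized height above the ASIS level toward the xiphoid (may be
    negative); J/K/L are Euclidean centroid-to-landmark distances in cm.
    """
    c = np.asarray(centroid_mm, dtype=float)
    left = landmarks.require("left_asis")
    right = landmarks.require("right_asis")
    xiph = landmarks.require("xiphoid")
    landmarks.validate_span()

    seg = right - left
    H = float(np.dot(c - left, seg) / np.dot(seg, seg))
    asis_z = 0.5 * (left[2] + right[2])
    denom = xiph[2] - asis_z
    if denom == 0:
        raise ValidationError("xiphoid and ASIS share a z level; I undefined")
    I = float((c[2] - asis_z) / denom)
    return {
        "H": H,
        "I": I,
        "J": float(np.linalg.norm(c - left)) / 10.0,
        "K": float(np.linalg.norm(c - right)) / 10.0,
        "L": float(np.linalg.norm(c - xiph)) / 10.0,
    }


def body_metrics(
    vol: LabeledVolume,
    body: np.ndarray,
    surfaces: WallSurfaces,
    compartments: CompartmentMasks,
    hernia_volume_cm3: float | None,
) -> dict:
    """Metrics M-T over the labeled vertical range."""
    z0, z1 = surfaces.z_range
    T = (z1 - z0) / 10.0

    idx = np.argwhere(body)
    if idx.size:
        z_mm = vol.voxel_to_mm(idx)[:, 2]
        n_in = int(np.count_nonzero((z_mm >= z0) & (z_mm <= z1)))
    else:
        n_in = 0
    M = n_in * vol.voxel_volume_mm3 / 1e3

    N = surfaces.cavity_volume_cm3()
    O = (hernia_volume_cm3 / N) if hernia_volume_cm3 else 0.0
    P, Q = wall_thickness_stats(surfaces)
    return {
        "M": M,
        "N": N,
        "O": O,
        "P": P,
        "Q": Q,
        "R": compartments.visceral_cm3,
        "S": compartments.subcutaneous_cm3,
        "T": T,
    }


def derive_all(vol: LabeledVolume, subject_id: str | None = None) -> MetricVector:
    """Orchestrate surfaces -> segmentation -> metric stages for one volume."""
    from .reliability import landmarks_from_volume  # shared representative-point rules

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"metric derivation failed in stage {name!r}: {exc}") from exc

    contours = stage("contours", contours_from_labels, vol)
    surfaces = stage("surfaces", interpolate_walls, contours)
    body = stage("body", extract_body_cached, vol)
    compartments = stage("compartments", extract_compartments_with_body, vol, surfaces, body)

    vec = MetricVector(subject_id=subject_id)
    shape = stage("shape", hernia_shape_metrics, vol.labels == 8, vol.spacing)
    hernia_volume = None
    if shape is not None:
        vec.update(shape)
        hernia_volume = shape["A"]
        centroid = hernia_centroid_mm(vol)
        landmarks = stage("landmarks", landmarks_from_volume, vol)
        vec.update(stage("location", hernia_location_metrics, centroid, landmarks))
    vec.update(stage("body_metrics", body_metrics, vol, body, surfaces, compartments, hernia_volume))
    return vec


# thin wrappers so derive_all runs extract_body once
def extract_body_cached(vol: LabeledVolume) -> np.ndarray:
    from .segmentation import extract_body

    return extract_body(vol)


def extract_compartments_with_body(
    vol: LabeledVolume, surfaces: WallSurfaces, body: np.ndarray
) -> CompartmentMasks:
    from .segmentation import BONE_HU, AIR_HU, FatSplit, segment_fat, split_fat

    fat, muscle = segment_fat(vol, body)
    split = split_fat(vol, fat, body, surfaces)
    return CompartmentMasks(
        body=body,
        bone=body & (vol.intensity > BONE_HU),
        air=body & (vol.intensity < AIR_HU),
        fat=fat,
        muscle=muscle,
        visceral_fat=split.visceral_mask,
        subcutaneous_fat=split.subcutaneous_mask,
        visceral_cm3=split.visceral_cm3,
        subcutaneous_cm3=split.subcutaneous_cm3,
    )
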
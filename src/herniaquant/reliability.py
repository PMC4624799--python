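"""Intra-/inter-rater reproducibility statistics between two label sets of the
same scan: mean surface distance and Hausdorff distance for the five wall
structures, Euclidean distance of representative points for the seven
landmarks, and Cohen's kappa for the hernia label."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .io_core import LabeledVolume, LandmarkSet, ValidationError

__all__ = [
    "mean_surface_distance",
    "hausdorff_distance",
    "landmark_representative_point",
    "landmarks_from_volume",
    "cohen_kappa_masks",
    "ReliabilityReport",
    "reliability_report",
    "aggregate_reports",
]

#: structure name -> label code for the five wall structures
STRUCTURES = {
    "axial_outer": 1,
    "axial_inner": 2,
    "sagittal_outer": 4,
    "sagittal_inner": 5,
    "posterior_wall": 3,
}

#: the seven landmark entries, in report order
LANDMARKS = (
    "xiphoid",
    "left_asis",
    "right_asis",
    "umbilicus",
    "linea_alba",
    "linea_semilunaris",
    "pubic_symphysis",
)

_LANDMARK_CODE = {
    "xiphoid": 10,
    "umbilicus": 11,
    "left_asis": 12,
    "right_asis": 13,
    "pubic_symphysis": 14,
    "linea_alba": 6,
    "linea_semilunaris": 7,
}


def _check_points(pts: np.ndarray, name: str) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    if pts.size == 0:
        raise ValidationError(f"empty point set: {name}")
    return pts


def mean_surface_distance(surf_a: np.ndarray, surf_b: np.ndarray) -> float:
    """Symmetric MSD in mm: average of the two directed mean nearest-neighbor
    distances."""
    a = _check_points(surf_a, "surfA")
    b = _check_points(surf_b, "surfB")
    d_ab = cKDTree(b).query(a)[0]
    d_ba = cKDTree(a).query(b)[0]
    return float(0.5 * (d_ab.mean() + d_ba.mean()))


def hausdorff_distance(surf_a: np.ndarray, surf_b: np.ndarray) -> float:
    """Symmetric HD in mm: max of the two directed maxima."""
    a = _check_points(surf_a, "surfA")
    b = _check_points(surf_b, "surfB")
    d_ab = cKDTree(b).query(a)[0]
    d_ba = cKDTree(a).query(b)[0]
    return float(max(d_ab.max(), d_ba.max()))


def _tie_break(pts: np.ndarray, primary: np.ndarray) -> np.ndarray:
    """Deterministic argmax of ``primary`` with superior-then-right-then-
    anterior tie-breaking on the point coordinates."""
    # ascending lexsort on (primary, z, x, y) — last key dominates; take the max
    order = np.lexsort((pts[:, 1], pts[:, 0], pts[:, 2], primary))
    return pts[order[-1]]


def landmark_representative_point(vol: LabeledVolume, landmark: str) -> np.ndarray:
    """One representative mm point per landmark: label-set centroid for the
    xiphoid process / linea alba / linea semilunaris; the labeled point nearest
    the centroid ("centermost") for the umbilicus; the most superior point for
    the pubic symphysis; the most anterior point for the iliac spines.  Ties
    are broken deterministically (superior, then right)."""
    code = _LANDMARK_CODE.get(landmark)
    if code is None:
        raise ValidationError(f"unknown landmark name {landmark!r}")
    pts = vol.label_points_mm(code)
    if len(pts) == 0:
        raise ValidationError(f"landmark {landmark!r} not labeled")
    if landmark in ("xiphoid", "linea_alba", "linea_semilunaris"):
        return pts.mean(axis=0)
    if landmark == "umbilicus":
        c = pts.mean(axis=0)
        d = np.linalg.norm(pts - c, axis=1)
        return _tie_break(pts, -d)
    if landmark == "pubic_symphysis":
        return _tie_break(pts, pts[:, 2])
    # left/right ASIS: most anterior
    return _tie_break(pts, pts[:, 1])


def landmarks_from_volume(vol: LabeledVolume) -> LandmarkSet:
    """Apply the representative-point rules to all labeled landmarks."""
    kwargs = {}
    for name in ("xiphoid", "umbilicus", "left_asis", "right_asis", "pubic_symphysis"):
        try:
            kwargs[name] = landmark_representative_point(vol, name)
        except ValidationError:
            pass
    lm = LandmarkSet(**kwargs)
    lm.linea_alba = vol.label_points_mm(6)
    lm.linea_semilunaris = vol.label_points_mm(7)
    return lm


def cohen_kappa_masks(
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    region: np.ndarray | None = None,
    region_margin: int = 10,
) -> float | None:
    """Voxelwise Cohen's kappa over ``region``.

    The negative-class region matters: by default it is the bounding box of
    maskA | maskB dilated by ``region_margin`` voxels, avoiding kappa
    inflation from vast empty background.  Returns None when the chance
    agreement is 1 (degenerate marginals).
    """
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValidationError("mask shapes differ")
    if region is None:
        union = a | b
        if not union.any():
            raise ValidationError("both masks empty and no region given")
        region = np.zeros_like(a)
        slices = tuple(
            slice(max(0, s.start - region_margin), min(dim, s.stop + region_margin))
            for s, dim in zip(ndimage.find_objects(union.astype(np.int8))[0], a.shape)
        )
        region[slices] = True
    else:
        region = np.asarray(region, dtype=bool)
        if not region.any():
            raise ValidationError("empty kappa region")
        if np.any((a | b) & ~region):
            raise ValidationError("region must contain both masks")
    av, bv = a[region], b[region]
    n = av.size
    p_o = float(np.count_nonzero(av == bv)) / n
    pa1, pb1 = float(av.sum()) / n, float(bv.sum()) / n
    p_e = pa1 * pb1 + (1 - pa1) * (1 - pb1)
    if 1.0 - p_e == 0.0:
        return None
    return float((p_o - p_e) / (1.0 - p_e))


@dataclass
class ReliabilityReport:
    msd_mm: dict = field(default_factory=dict)        # structure -> mm or None
    hd_mm: dict = field(default_factory=dict)
    landmark_ed_mm: dict = field(default_factory=dict)
    hernia_kappa: float | None = None

    def validate(self) -> None:
        for key, msd in self.msd_mm.items():
            hd = self.hd_mm.get(key)
            if msd is not None and hd is not None and msd > hd + 1e-9:
                raise ValidationError(f"MSD > HD for {key}")

    def to_dict(self) -> dict:
        return {
            "msd_mm": self.msd_mm,
            "hd_mm": self.hd_mm,
            "landmark_ed_mm": self.landmark_ed_mm,
            "hernia_kappa": self.hernia_kappa,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def reliability_report(vol_a: LabeledVolume, vol_b: LabeledVolume) -> ReliabilityReport:
    """All per-structure and per-landmark statistics for one scan pair.

    A structure or landmark missing in either volume yields a None entry; the
    rest are computed."""
    if vol_a.shape != vol_b.shape or not np.allclose(vol_a.affine, vol_b.affine):
        raise ValidationError("volumes must share grid geometry")
    report = ReliabilityReport()
    for name, code in STRUCTURES.items():
        pa, pb = vol_a.label_points_mm(code), vol_b.label_points_mm(code)
        if len(pa) == 0 or len(pb) == 0:
            report.msd_mm[name] = None
            report.hd_mm[name] = None
            continue
        report.msd_mm[name] = mean_surface_distance(pa, pb)
        report.hd_mm[name] = hausdorff_distance(pa, pb)
    for name in LANDMARKS:
        try:
            ra = landmark_representative_point(vol_a, name)
            rb = landmark_representative_point(vol_b, name)
            report.landmark_ed_mm[name] = float(np.linalg.norm(ra - rb))
        except ValidationError:
            report.landmark_ed_mm[name] = None
    ha, hb = vol_a.labels == 8, vol_b.labels == 8
    if ha.any() or hb.any():
        report.hernia_kappa = cohen_kappa_masks(ha, hb)
    report.validate()
    return report


def aggregate_reports(reports: list[ReliabilityReport]) -> dict:
    """mean +/- SD across a batch of scan pairs, formatted per entry."""
    if not reports:
        raise ValidationError("no reports to aggregate")

    def agg(values):
        vals = [v for v in values if v is not None]
        if not vals:
            return None
        return {"mean": float(np.mean(vals)), "sd": float(np.std(vals)), "n": len(vals)}

    out = {"msd_mm": {}, "hd_mm": {}, "landmark_ed_mm": {}, "hernia_kappa": None}
    for name in STRUCTURES:
        out["msd_mm"][name] = agg([r.msd_mm.get(name) for r in reports])
        out["hd_mm"][name] = agg([r.hd_mm.get(name) for r in reports])
    for name in LANDMARKS:
        out["landmark_ed_mm"][name] = agg([r.landmark_ed_mm.get(name) for r in reports])
    out["hernia_kappa"] = agg([r.hernia_kappa for r in reports])
    return out
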
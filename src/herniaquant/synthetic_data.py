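"""Labeled CT phantoms with analytic ground truth, rater-noise simulation,
and synthetic patient cohorts with known generating coefficients.

The phantom torso is an elliptic cylinder: a skin ellipse, a subcutaneous fat
ring, a muscular wall whose inner border is the *inward normal offset* of the
outer border by a z-varying thickness t(z), a visceral-fat ellipse and a bony
rod inside the cavity, and (optionally) an outward half-ellipsoid hernia cap
that pierces the anterior wall.  Every ground-truth quantity is computed from
this continuous geometry — closed forms where they exist, fine deterministic
quadrature otherwise — never from the voxelization.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.special import ellipe

from .io_core import (
    LANDMARK_LABELS,
    LabeledVolume,
    ValidationError,
    CohortTable,
)

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "make_phantom",
    "perturb_labels",
    "make_cohort",
    "half_ellipsoid_mask",
    "BRIDGE_COHORT_PROFILE",
]


class SpecError(ValueError):
    """Inconsistent phantom or cohort specification."""


# ---------------------------------------------------------------------------
# phantom specification
# ---------------------------------------------------------------------------

#: default intensity model, Hounsfield-like means/SDs per tissue class
DEFAULT_INTENSITIES = {
    "air": (-1000.0, 15.0),
    "fat": (-90.0, 15.0),
    "muscle": (40.0, 15.0),
    "bone": (700.0, 15.0),
    "table": (300.0, 15.0),
}


@dataclass
class PhantomSpec:
    """All knobs of the synthetic torso; ``seed`` fixes every random draw."""

    shape: tuple[int, int, int] = (180, 160, 80)
    spacing: tuple[float, float, float] = (2.0, 2.0, 5.0)

    skin_semi_axes: tuple[float, float] = (160.0, 115.0)
    fat_ring_mm: float = 25.0
    wall_thickness_mean: float = 13.0
    wall_thickness_amp: float = 5.5
    wall_thickness_period: float = 200.0

    hernia: bool = True
    hernia_center_xz: tuple[float, float] = (0.0, 0.0)
    hernia_base_y: float = 70.0
    hernia_semi_axes: tuple[float, float, float] = (50.0, 50.0, 70.0)

    visceral_semi_axes: tuple[float, float] = (60.0, 35.0)
    visceral_center_y: float = 10.0
    spine_center_y: float = -50.0
    spine_radius: float = 12.0

    labeled_z_range: tuple[float, float] = (-175.0, 175.0)
    axial_slice_spacing: float = 50.0
    # offset from the midline so sagittal contours never overwrite linea-alba voxels
    sagittal_x_positions: tuple[float, ...] = (-45.0, 10.0, 45.0)

    landmarks_mm: dict = field(
        default_factory=lambda: {
            "xiphoid": (0.0, 60.0, 185.0),
            "umbilicus": (0.0, 110.0, -20.0),
            "left_asis": (-120.0, -20.0, -160.0),
            "right_asis": (120.0, -20.0, -160.0),
            "pubic_symphysis": (0.0, 40.0, -185.0),
        }
    )
    table_y_range: tuple[float, float] = (-155.0, -140.0)
    intensities: dict = field(default_factory=lambda: dict(DEFAULT_INTENSITIES))
    noise_sd: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.axial_slice_spacing < self.spacing[2]:
            raise SpecError("axial label-slice spacing must be >= slice thickness")
        if min(self.spacing) <= 0:
            raise SpecError("voxel spacing must be positive")
        if self.wall_thickness_mean - self.wall_thickness_amp <= 0:
            raise SpecError("wall thickness must stay positive")
        if self.hernia:
            aw, bw = self.wall_semi_axes
            hx, _ = self.hernia_center_xz
            if abs(hx) >= aw:
                raise SpecError("hernia center outside the anterior wall footprint")
            y_out = bw * np.sqrt(1.0 - (hx / aw) ** 2)
            y_in = y_out - (self.wall_thickness_mean + self.wall_thickness_amp)
            tip = self.hernia_base_y + self.hernia_semi_axes[1]
            if tip <= y_in:
                raise SpecError("hernia cap fully interior to cavity (no wall crossing)")
            if self.hernia_base_y >= y_out:
                raise SpecError("hernia cap does not intersect the anterior wall")

    @property
    def wall_semi_axes(self) -> tuple[float, float]:
        a, b = self.skin_semi_axes
        return a - self.fat_ring_mm, b - self.fat_ring_mm

    def wall_thickness(self, z):
        """t(z) in mm."""
        return self.wall_thickness_mean + self.wall_thickness_amp * np.sin(
            2.0 * np.pi * np.asarray(z) / self.wall_thickness_period
        )

    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        for k in range(3):
            aff[k, k] = self.spacing[k]
            aff[k, 3] = -(self.shape[k] - 1) / 2.0 * self.spacing[k]
        return aff

    def axial_label_z(self) -> np.ndarray:
        z0, z1 = self.labeled_z_range
        return np.arange(z0, z1 + 1e-9, self.axial_slice_spacing)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PhantomSpec":
        raw = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SpecError(f"unknown phantom spec keys: {sorted(unknown)}")
        for key in ("shape", "spacing", "skin_semi_axes", "hernia_center_xz",
                    "hernia_semi_axes", "visceral_semi_axes", "labeled_z_range",
                    "sagittal_x_positions", "table_y_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "landmarks_mm" in raw:
            raw["landmarks_mm"] = {k: tuple(v) for k, v in raw["landmarks_mm"].items()}
        if "intensities" in raw:
            raw["intensities"] = {k: tuple(v) for k, v in raw["intensities"].items()}
        return cls(**raw)


@dataclass
class GroundTruth:
    """Analytic quantities implied by a :class:`PhantomSpec` (volumes in cm3,
    lengths in cm, landmark coordinates in mm)."""

    hernia_volume_cm3: float | None
    hernia_extent_lr_cm: float | None
    hernia_extent_ap_cm: float | None
    hernia_extent_cc_cm: float | None
    hernia_centroid_mm: tuple[float, float, float] | None
    landmarks_mm: dict
    cavity_volume_cm3: float
    body_volume_cm3: float
    visceral_fat_cm3: float
    subcutaneous_fat_cm3: float
    wall_thickness_mean_cm: float
    wall_thickness_sd_cm: float
    evaluated_height_cm: float


# ---------------------------------------------------------------------------
# continuous-geometry helpers
# ---------------------------------------------------------------------------

def _ellipse_perimeter(a: float, b: float) -> float:
    a, b = max(a, b), min(a, b)
    return float(4.0 * a * ellipe(1.0 - (b / a) ** 2))


def _inner_offset_polar(spec: PhantomSpec, t: float, n: int = 4096):
    """Radial table (phi, r) of the inward normal offset of the wall ellipse.

    The offset of a convex curve by t < min curvature radius is convex, so the
    region is star-shaped about the origin and a polar table is exact up to
    the angular sampling.
    """
    aw, bw = spec.wall_semi_axes
    theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    px, py = aw * np.cos(theta), bw * np.sin(theta)
    nx, ny = bw * np.cos(theta), aw * np.sin(theta)
    norm = np.hypot(nx, ny)
    qx, qy = px - t * nx / norm, py - t * ny / norm
    phi = np.arctan2(qy, qx)
    order = np.argsort(phi)
    phi, r = phi[order], np.hypot(qx, qy)[order]
    # wrap for periodic interpolation
    phi = np.concatenate([[phi[-1] - 2 * np.pi], phi, [phi[0] + 2 * np.pi]])
    r = np.concatenate([[r[-1]], r, [r[0]]])
    return phi, r


def _inside_inner(spec: PhantomSpec, t: float, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    phi_t, r_t = _inner_offset_polar(spec, t)
    phi = np.arctan2(y, x)
    return np.hypot(x, y) <= np.interp(phi, phi_t, r_t)


def _inner_offset_points(spec: PhantomSpec, t: float, n: int = 4096):
    aw, bw = spec.wall_semi_axes
    theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    px, py = aw * np.cos(theta), bw * np.sin(theta)
    nx, ny = bw * np.cos(theta), aw * np.sin(theta)
    norm = np.hypot(nx, ny)
    return px - t * nx / norm, py - t * ny / norm


def half_ellipsoid_mask(
    center: tuple[float, float, float],
    semi_axes: tuple[float, float, float],
    xs: np.ndarray,
    ys: np.ndarray,
    zs: np.ndarray,
) -> np.ndarray:
    """Voxel indicator (len(xs), len(ys), len(zs)) of the outward (+y) half of
    an ellipsoid cut by the plane y = center_y, on voxel *centers*."""
    cx, cy, cz = center
    ra, rb, rc = semi_axes
    X = ((xs[:, None, None] - cx) / ra) ** 2
    Y = ((ys[None, :, None] - cy) / rb) ** 2
    Z = ((zs[None, None, :] - cz) / rc) ** 2
    return (X + Y + Z <= 1.0) & (ys[None, :, None] >= cy)


def _hernia_slice(spec: PhantomSpec, z: float, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """2-D indicator of the hernia cap at height z (broadcastable x, y in mm)."""
    if not spec.hernia:
        return np.zeros(np.broadcast(x, y).shape, dtype=bool)
    hx, hz = spec.hernia_center_xz
    ra, rb, rc = spec.hernia_semi_axes
    zz = ((z - hz) / rc) ** 2
    if zz >= 1.0:
        return np.zeros(np.broadcast(x, y).shape, dtype=bool)
    return (((x - hx) / ra) ** 2 + ((y - spec.hernia_base_y) / rb) ** 2 + zz <= 1.0) & (
        y >= spec.hernia_base_y
    )


def _quadrature_extras(spec: PhantomSpec, step_xy: float = 0.5, step_z: float = 1.0):
    """Deterministic fine-grid quadrature of the two quantities without closed
    form: hernia∩fat-ring overlap volume and hernia-outside-skin body gain,
    both restricted to the labeled z range.  Returns (overlap_mm3, extra_mm3).
    """
    if not spec.hernia:
        return 0.0, 0.0
    hx, hz = spec.hernia_center_xz
    ra, rb, rc = spec.hernia_semi_axes
    a_s, b_s = spec.skin_semi_axes
    aw, bw = spec.wall_semi_axes
    z0 = max(hz - rc, spec.labeled_z_range[0])
    z1 = min(hz + rc, spec.labeled_z_range[1])
    if z1 <= z0:
        return 0.0, 0.0
    xs = np.arange(hx - ra, hx + ra + step_xy, step_xy)
    ys = np.arange(spec.hernia_base_y, spec.hernia_base_y + rb + step_xy, step_xy)
    X, Y = xs[:, None], ys[None, :]
    in_skin = (X / a_s) ** 2 + (Y / b_s) ** 2 <= 1.0
    out_wall = (X / aw) ** 2 + (Y / bw) ** 2 > 1.0
    ring = in_skin & out_wall
    cell = step_xy * step_xy
    overlap = 0.0
    extra = 0.0
    for z in np.arange(z0 + step_z / 2, z1, step_z):
        h = _hernia_slice(spec, z, X, Y)
        overlap += float(np.count_nonzero(h & ring)) * cell * step_z
        extra += float(np.count_nonzero(h & ~in_skin)) * cell * step_z
    return overlap, extra


def _ground_truth(spec: PhantomSpec, landmark_snapped: dict) -> GroundTruth:
    aw, bw = spec.wall_semi_axes
    a_s, b_s = spec.skin_semi_axes
    z0, z1 = spec.labeled_z_range
    height = z1 - z0

    # cavity cross-section by the Steiner formula for inward offsets
    area_out = np.pi * aw * bw
    perim = _ellipse_perimeter(aw, bw)
    zf = np.linspace(z0, z1, 20001)
    t = spec.wall_thickness(zf)
    area_in = area_out - perim * t + np.pi * t**2
    cavity = float(np.trapezoid(area_in, zf))

    overlap, extra = _quadrature_extras(spec)
    body = np.pi * a_s * b_s * height + extra
    ring_area = np.pi * (a_s * b_s - aw * bw)
    subcut = ring_area * height - overlap
    va, vb = spec.visceral_semi_axes
    visceral = np.pi * va * vb * height

    if spec.hernia:
        ra, rb, rc = spec.hernia_semi_axes
        hx, hz = spec.hernia_center_xz
        h_vol = 2.0 / 3.0 * np.pi * ra * rb * rc
        centroid = (hx, spec.hernia_base_y + 3.0 * rb / 8.0, hz)
        h_fields = dict(
            hernia_volume_cm3=h_vol / 1e3,
            hernia_extent_lr_cm=2 * ra / 10.0,
            hernia_extent_ap_cm=rb / 10.0,
            hernia_extent_cc_cm=2 * rc / 10.0,
            hernia_centroid_mm=centroid,
        )
    else:
        h_fields = dict(
            hernia_volume_cm3=None,
            hernia_extent_lr_cm=None,
            hernia_extent_ap_cm=None,
            hernia_extent_cc_cm=None,
            hernia_centroid_mm=None,
        )

    return GroundTruth(
        **h_fields,
        landmarks_mm=landmark_snapped,
        cavity_volume_cm3=cavity / 1e3,
        body_volume_cm3=body / 1e3,
        visceral_fat_cm3=visceral / 1e3,
        subcutaneous_fat_cm3=subcut / 1e3,
        wall_thickness_mean_cm=float(np.trapezoid(t, zf) / height) / 10.0,
        wall_thickness_sd_cm=float(
            np.sqrt(np.trapezoid((t - np.trapezoid(t, zf) / height) ** 2, zf) / height)
        )
        / 10.0,
        evaluated_height_cm=height / 10.0,
    )


# ---------------------------------------------------------------------------
# phantom voxelization
# ---------------------------------------------------------------------------

def _grid_axes(spec: PhantomSpec):
    aff = spec.affine()
    axes = [aff[k, 3] + np.arange(spec.shape[k]) * aff[k, k] for k in range(3)]
    return axes[0], axes[1], axes[2]


def _snap_mm(spec: PhantomSpec, point: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Nearest voxel index and its center coordinate."""
    aff = spec.affine()
    idx = np.rint((np.asarray(point, dtype=float) - aff[:3, 3]) / np.diag(aff)[:3]).astype(int)
    idx = np.clip(idx, 0, np.asarray(spec.shape) - 1)
    return idx, aff[:3, 3] + idx * np.diag(aff)[:3]


def _paint_points(labels: np.ndarray, spec: PhantomSpec, pts_mm: np.ndarray, code: int) -> None:
    if len(pts_mm) == 0:
        return
    aff = spec.affine()
    idx = np.rint((pts_mm - aff[:3, 3]) / np.diag(aff)[:3]).astype(int)
    ok = np.all((idx >= 0) & (idx < np.asarray(spec.shape)), axis=1)
    idx = idx[ok]
    labels[idx[:, 0], idx[:, 1], idx[:, 2]] = code


def make_phantom(spec: PhantomSpec) -> tuple[LabeledVolume, GroundTruth]:
    """Voxelize the phantom: CT-like intensities everywhere, wall contours only
    on the sparse label slices, the hernia dense on every slice it crosses,
    single-voxel landmarks; plus the analytic :class:`GroundTruth`."""
    xs, ys, zs = _grid_axes(spec)
    nx, ny, nz = spec.shape
    a_s, b_s = spec.skin_semi_axes
    aw, bw = spec.wall_semi_axes
    X2, Y2 = xs[:, None], ys[None, :]
    in_skin = (X2 / a_s) ** 2 + (Y2 / b_s) ** 2 <= 1.0
    in_wall_outer = (X2 / aw) ** 2 + (Y2 / bw) ** 2 <= 1.0
    va, vb = spec.visceral_semi_axes
    in_visceral = (X2 / va) ** 2 + ((Y2 - spec.visceral_center_y) / vb) ** 2 <= 1.0
    in_spine = X2**2 + (Y2 - spec.spine_center_y) ** 2 <= spec.spine_radius**2
    ty0, ty1 = spec.table_y_range
    in_table = (Y2 >= ty0) & (Y2 <= ty1)

    # tissue class codes per voxel: 0 air, 1 fat, 2 muscle/soft, 3 bone, 4 table
    classes = np.zeros(spec.shape, dtype=np.int8)
    for k, z in enumerate(zs):
        t = float(spec.wall_thickness(z))
        inner = _inside_inner(spec, t, X2, Y2)
        hern = _hernia_slice(spec, z, X2, Y2)
        sl = np.zeros((nx, ny), dtype=np.int8)
        sl[in_table & ~in_skin] = 4
        body = in_skin | hern
        sl[body] = 2
        sl[in_skin & ~in_wall_outer] = 1          # subcutaneous ring
        sl[inner & in_visceral] = 1               # visceral fat
        sl[inner & in_spine] = 3                  # spine
        sl[hern] = 2                              # hernia sac content
        classes[:, :, k] = sl

    rng = np.random.default_rng(spec.seed)
    means = np.array(
        [spec.intensities[c][0] for c in ("air", "fat", "muscle", "bone", "table")],
        dtype=np.float32,
    )
    intensity = means[classes] + rng.normal(0.0, spec.noise_sd, spec.shape).astype(np.float32)

    labels = np.zeros(spec.shape, dtype=np.int16)

    # dense hernia label
    if spec.hernia:
        hmask = half_ellipsoid_mask(
            (spec.hernia_center_xz[0], spec.hernia_base_y, spec.hernia_center_xz[1]),
            spec.hernia_semi_axes,
            xs, ys, zs,
        )
        labels[hmask] = 8
    else:
        hmask = np.zeros(spec.shape, dtype=bool)

    def drop_in_hernia(px, py, z):
        keep = ~_hernia_slice(spec, z, px, py)
        return keep

    theta = np.linspace(0.0, 2.0 * np.pi, 4096, endpoint=False)
    for z_lab in spec.axial_label_z():
        k = int(np.argmin(np.abs(zs - z_lab)))
        z = zs[k]
        t = float(spec.wall_thickness(z))
        # posterior wall: posterior half of the inner offset curve
        qx, qy = _inner_offset_points(spec, t)
        post = qy < 0
        pts = np.column_stack([qx[post], qy[post], np.full(post.sum(), z)])
        _paint_points(labels, spec, pts, 3)
        # inner anterior wall
        ant = qy >= 0
        keep = drop_in_hernia(qx[ant], qy[ant], z)
        pts = np.column_stack([qx[ant][keep], qy[ant][keep], np.full(int(keep.sum()), z)])
        _paint_points(labels, spec, pts, 2)
        # outer anterior wall
        ox, oy = aw * np.cos(theta), bw * np.sin(theta)
        ant = oy >= 0
        keep = drop_in_hernia(ox[ant], oy[ant], z)
        pts = np.column_stack([ox[ant][keep], oy[ant][keep], np.full(int(keep.sum()), z)])
        _paint_points(labels, spec, pts, 1)
        # linea alba at the anterior midline, linea semilunaris at +-0.44 a
        _paint_points(labels, spec, np.array([[0.0, bw, z]]), 6)
        for sx in (-0.44 * aw, 0.44 * aw):
            sy = bw * np.sqrt(1.0 - (sx / aw) ** 2)
            if not _hernia_slice(spec, z, np.array(sx), np.array(sy)):
                _paint_points(labels, spec, np.array([[sx, sy, z]]), 7)

    # sagittal anterior-wall contours: one point per slice along z
    z0, z1 = spec.labeled_z_range
    kz = np.where((zs >= z0 - 1e-9) & (zs <= z1 + 1e-9))[0]
    for x_lab in spec.sagittal_x_positions:
        if abs(x_lab) >= aw:
            continue
        y_out = bw * np.sqrt(1.0 - (x_lab / aw) ** 2)
        for k in kz:
            z = zs[k]
            t = float(spec.wall_thickness(z))
            if not _hernia_slice(spec, z, np.array(x_lab), np.array(y_out)):
                _paint_points(labels, spec, np.array([[x_lab, y_out, z]]), 4)
            # inner anterior point at this x: interpolate the offset curve
            qx, qy = _inner_offset_points(spec, t)
            ant = qy >= 0
            order = np.argsort(qx[ant])
            y_in = float(np.interp(x_lab, qx[ant][order], qy[ant][order]))
            if not _hernia_slice(spec, z, np.array(x_lab), np.array(y_in)):
                _paint_points(labels, spec, np.array([[x_lab, y_in, z]]), 5)

    snapped = {}
    for name, code in LANDMARK_LABELS.items():
        point = spec.landmarks_mm.get(name)
        if point is None:
            continue
        idx, center = _snap_mm(spec, np.asarray(point))
        labels[idx[0], idx[1], idx[2]] = code
        snapped[name] = tuple(float(v) for v in center)

    vol = LabeledVolume(intensity=intensity, labels=labels, affine=spec.affine())
    return vol, _ground_truth(spec, snapped)


# ---------------------------------------------------------------------------
# rater-noise simulation
# ---------------------------------------------------------------------------

def perturb_labels(
    vol: LabeledVolume,
    surface_noise_mm: float,
    landmark_noise_mm: float,
    seed: int,
    hernia_noise_mm: float | None = None,
) -> LabeledVolume:
    """Simulate a second rater: wall contour points move along the local
    in-slice normal by N(0, surface_noise); landmarks move isotropically;
    the hernia boundary is perturbed by a smooth random level-set offset with
    pointwise SD ``hernia_noise_mm`` (defaults to ``surface_noise_mm``)."""
    if surface_noise_mm < 0 or landmark_noise_mm < 0:
        raise ValidationError("noise magnitudes must be >= 0")
    if hernia_noise_mm is None:
        hernia_noise_mm = surface_noise_mm
    if surface_noise_mm == 0 and landmark_noise_mm == 0 and hernia_noise_mm == 0:
        return LabeledVolume(vol.intensity.copy(), vol.labels.copy(), vol.affine.copy())

    rng = np.random.default_rng(seed)
    spacing = vol.spacing
    out = np.zeros_like(vol.labels)

    # hernia first so contours/landmarks can overwrite
    hmask = vol.labels == 8
    if hmask.any():
        if hernia_noise_mm > 0:
            d_in = ndimage.distance_transform_edt(hmask, sampling=spacing)
            d_out = ndimage.distance_transform_edt(~hmask, sampling=spacing)
            signed = d_in - d_out
            noise = rng.standard_normal(vol.shape)
            noise = ndimage.gaussian_filter(noise, sigma=10.0 / spacing)
            sd = noise.std()
            if sd > 0:
                noise *= hernia_noise_mm / sd
            out[(signed + noise) > 0] = 8
        else:
            out[hmask] = 8

    def paint(pts_mm: np.ndarray, code: int) -> None:
        if len(pts_mm) == 0:
            return
        inv = np.linalg.inv(vol.affine)
        idx = np.rint(pts_mm @ inv[:3, :3].T + inv[:3, 3]).astype(int)
        ok = np.all((idx >= 0) & (idx < np.asarray(vol.shape)), axis=1)
        idx = idx[ok]
        out[idx[:, 0], idx[:, 1], idx[:, 2]] = code

    def smooth_field(coords: np.ndarray, sd: float, n_modes: int = 50) -> np.ndarray:
        """Stationary random field with pointwise SD exactly ``sd`` and smooth
        variation along ``coords`` (random-phase cosine superposition): a
        rater's deviation moves neighboring contour points together."""
        freqs = rng.uniform(1.0, 12.0, n_modes)       # cycles per 2*pi of coords
        phases = rng.uniform(0.0, 2.0 * np.pi, n_modes)
        field = np.cos(np.outer(coords, freqs) + phases).sum(axis=1)
        return sd * np.sqrt(2.0 / n_modes) * field

    # axial contours: radial in-slice normals about the per-slice wall centroid
    wall_idx = np.argwhere(np.isin(vol.labels, (1, 2, 3)))
    slices = np.unique(wall_idx[:, 2]) if wall_idx.size else []
    for code in (3, 2, 1, 7, 6):
        mask = vol.labels == code
        if not mask.any():
            continue
        for k in slices:
            idx = np.argwhere(mask[:, :, k])
            if idx.size == 0:
                continue
            pts = vol.voxel_to_mm(np.column_stack([idx, np.full(len(idx), k)]))
            ref = vol.voxel_to_mm(
                np.column_stack([wall_idx[wall_idx[:, 2] == k][:, :2],
                                 np.full((wall_idx[:, 2] == k).sum(), k)])
            ).mean(axis=0)
            radial = pts[:, :2] - ref[:2]
            norm = np.linalg.norm(radial, axis=1)
            norm[norm == 0] = 1.0
            radial /= norm[:, None]
            if surface_noise_mm > 0:
                angle = np.arctan2(pts[:, 1] - ref[1], pts[:, 0] - ref[0])
                order = np.argsort(angle)
                # local contour normal from the angle-ordered tangent,
                # oriented outward (radial displacement would bias MSD by
                # cos(angle between radial and normal) on an ellipse)
                sorted_pts = pts[order, :2]
                if len(sorted_pts) >= 5:
                    tang = np.roll(sorted_pts, -1, axis=0) - np.roll(sorted_pts, 1, axis=0)
                    normal = np.column_stack([tang[:, 1], -tang[:, 0]])
                    nn = np.linalg.norm(normal, axis=1)
                    nn[nn == 0] = 1.0
                    normal /= nn[:, None]
                    flip = (normal * radial[order]).sum(axis=1) < 0
                    normal[flip] *= -1
                else:
                    normal = radial[order]
                disp = smooth_field(angle[order], surface_noise_mm)
                pts2 = pts.copy()
                pts2[order, :2] = sorted_pts + normal * disp[:, None]
                pts = pts2
            paint(pts, code)

    # sagittal contours: displace along the A-P axis, smooth along z
    z_extent = vol.extent_mm()[2]
    for code in (5, 4):
        mask = vol.labels == code
        if not mask.any():
            continue
        for i in np.unique(np.argwhere(mask)[:, 0]):
            idx = np.argwhere(mask[i])
            pts = vol.voxel_to_mm(
                np.column_stack([np.full(len(idx), i), idx])
            )
            if surface_noise_mm > 0:
                pts[:, 1] += smooth_field(2.0 * np.pi * pts[:, 2] / z_extent, surface_noise_mm)
            paint(pts, code)

    # landmarks: one isotropic shift per landmark blob
    for code in (10, 11, 12, 13, 14):
        pts = vol.label_points_mm(code)
        if len(pts) == 0:
            continue
        if landmark_noise_mm > 0:
            pts += rng.normal(0.0, landmark_noise_mm, 3)
        paint(pts, code)

    return LabeledVolume(vol.intensity.copy(), out, vol.affine.copy())


# ---------------------------------------------------------------------------
# synthetic cohorts
# ---------------------------------------------------------------------------

#: per-metric (bridge mean, bridge min, bridge max, no-bridge mean, no-bridge
#: min, no-bridge max, family) used to calibrate cohort marginals
BRIDGE_COHORT_PROFILE = {
    "A": (823.56, 57.8, 2300.04, 107.65, 3.99, 367.81, "lognormal"),
    "B": (15.74, 8.51, 24.15, 7.20, 2.80, 12.80, "lognormal"),
    "C": (6.27, 3.05, 10.46, 3.60, 0.70, 7.24, "lognormal"),
    "D": (16.99, 4.50, 26.70, 8.14, 2.40, 22.20, "lognormal"),
    "E": (512.22, 78.93, 1036.63, 123.24, 16.30, 283.31, "lognormal"),
    "F": (448.13, 64.13, 1022.69, 105.59, 14.98, 271.81, "lognormal"),
    "G": (1.40, 0.73, 2.22, 0.72, 0.19, 1.61, "lognormal"),
    "H": (0.63, 0.33, 1.01, 0.68, 0.25, 1.34, "normal"),
    "I": (0.10, 0.0, 0.19, 0.09, -0.02, 0.24, "normal"),
    "J": (16.46, 2.24, 22.84, 15.83, 8.03, 24.87, "normal"),
    "K": (18.54, 11.37, 25.12, 16.91, 5.16, 23.72, "normal"),
    "L": (19.66, 13.00, 30.48, 19.55, 8.89, 30.96, "normal"),
    "M": (32384.43, 22725.75, 42339.98, 29078.13, 19727.07, 46436.02, "lognormal"),
    "N": (9233.44, 6007.36, 15065.04, 9074.89, 4683.12, 15141.70, "lognormal"),
    "O": (0.09, 0.01, 0.31, 0.01, 0.0, 0.04, "lognormal"),
    "P": (1.55, 0.83, 2.44, 1.31, 0.76, 1.62, "normal"),
    "Q": (0.98, 0.39, 1.89, 0.65, 0.33, 1.07, "lognormal"),
    "R": (32.48, 7.12, 65.90, 23.11, 5.94, 48.88, "lognormal"),
    "S": (22960.45, 12114.26, 33288.25, 20346.47, 8218.99, 31283.60, "normal"),
    "T": (35.68, 33.00, 38.00, 35.39, 30.30, 39.90, "normal"),
}


def _draw_metric(rng, mean, lo, hi, family, n):
    sd = (hi - lo) / 4.0
    if sd <= 0:
        raise SpecError(f"non-positive SD implied by range [{lo}, {hi}]")
    if family == "lognormal":
        mean = max(mean, 1e-9)
        s2 = np.log1p((sd / mean) ** 2)
        mu = np.log(mean) - s2 / 2.0
        return rng.lognormal(mu, np.sqrt(s2), n)
    return rng.normal(mean, sd, n)


def make_cohort(
    n_bridge: int,
    n_nobridge: int,
    effect_profile: dict | None = None,
    beta_true: np.ndarray | None = None,
    seed: int = 0,
    outcome: str = "group",
) -> CohortTable:
    """Draw a subjects x metrics table with a binary bridge outcome.

    ``outcome='group'`` labels subjects by their generating group (default
    profile calibrated to the reported two-group means/ranges);
    ``outcome='logistic'`` redraws the outcome from a logistic model with
    ``beta_true`` applied to standardized features, enabling
    parameter-recovery tests.
    """
    import pandas as pd

    if n_bridge < 2 or n_nobridge < 2:
        raise SpecError("each group needs >= 2 subjects for fitting uses")
    profile = effect_profile if effect_profile is not None else BRIDGE_COHORT_PROFILE
    rng = np.random.default_rng(seed)
    cols = {}
    for name, (mb, lob, hib, mn, lon, hin, family) in profile.items():
        vb = _draw_metric(rng, mb, lob, hib, family, n_bridge)
        vn = _draw_metric(rng, mn, lon, hin, family, n_nobridge)
        cols[name] = np.concatenate([vb, vn])
    frame = pd.DataFrame(cols)
    frame.insert(0, "subject_id", [f"s{i:03d}" for i in range(n_bridge + n_nobridge)])

    if outcome == "group":
        y = np.concatenate([np.ones(n_bridge, dtype=int), np.zeros(n_nobridge, dtype=int)])
    elif outcome == "logistic":
        if beta_true is None:
            raise SpecError("outcome='logistic' requires beta_true")
        beta_true = np.asarray(beta_true, dtype=float)
        X = frame[list(profile)].to_numpy(dtype=float)
        if beta_true.shape != (X.shape[1],):
            raise SpecError("beta_true length must match the number of metrics")
        Xs = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
        p = 1.0 / (1.0 + np.exp(-(Xs @ beta_true)))
        y = (rng.random(len(p)) < p).astype(int)
    else:
        raise SpecError(f"unknown outcome mode {outcome!r}")
    frame["bridge"] = y
    return CohortTable(frame)
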
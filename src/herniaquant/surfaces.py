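"""Thin-plate-spline reconstruction of abdominal-wall surfaces from sparse
labeled contours, cavity closure, and wall-thickness statistics.

Anterior wall surfaces are height fields ``y = f(x, z)`` fit by a 2-D TPS
(kernel r^2 log r) with axial and sagittal contour points pooled as controls;
the posterior wall is a second height field; the closed cavity is obtained by
stitching the two per axial level with linear endpoint blending and flat caps.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_core import LabeledVolume, ValidationError

__all__ = [
    "ThinPlateSpline",
    "fit_tps",
    "ContourSet",
    "contours_from_labels",
    "WallSurfaces",
    "interpolate_walls",
    "wall_thickness_stats",
]

log = logging.getLogger(__name__)


class TPSNumericalError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# thin-plate spline
# ---------------------------------------------------------------------------

def _tps_kernel(r2: np.ndarray) -> np.ndarray:
    # U(r) = r^2 log r, U(0) = 0; computed as 0.5 * r^2 log r^2
    out = np.zeros_like(r2)
    pos = r2 > 0
    out[pos] = 0.5 * r2[pos] * np.log(r2[pos])
    return out


@dataclass
class ThinPlateSpline:
    """2-D TPS f(u, v) = a0 + a1 u + a2 v + sum_i w_i U(|p - p_i|)."""

    control_points: np.ndarray   # (n, 2)
    weights: np.ndarray          # (n,)
    affine_coeffs: np.ndarray    # (3,) -> a0, a1, a2
    regularization: float = 0.0

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        out = np.empty(len(pts))
        chunk = 65536
        for s in range(0, len(pts), chunk):
            p = pts[s : s + chunk]
            d2 = ((p[:, None, :] - self.control_points[None, :, :]) ** 2).sum(-1)
            out[s : s + chunk] = (
                _tps_kernel(d2) @ self.weights
                + self.affine_coeffs[0]
                + p @ self.affine_coeffs[1:]
            )
        return out

    def bending_energy(self) -> float:
        d2 = ((self.control_points[:, None, :] - self.control_points[None, :, :]) ** 2).sum(-1)
        return float(self.weights @ _tps_kernel(d2) @ self.weights)


def fit_tps(
    control_points: np.ndarray,
    values: np.ndarray,
    regularization: float = 0.0,
) -> ThinPlateSpline:
    """Solve the TPS system; with ``regularization`` (lambda) 0 the spline
    interpolates every control value exactly and the warp weights satisfy the
    side conditions (orthogonality to the affine space)."""
    pts = np.asarray(control_points, dtype=float)
    vals = np.asarray(values, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValidationError("control points must be (n, 2)")
    if len(pts) != len(vals):
        raise ValidationError("control points and values length mismatch")
    if len(pts) < 4:
        raise ValidationError("2-D TPS needs at least 4 control points")
    if regularization < 0:
        raise ValidationError("regularization must be >= 0")
    # duplicates make the interpolation system singular
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    if d2.min() == 0.0:
        raise TPSNumericalError("duplicate control points make the TPS system singular")
    np.fill_diagonal(d2, 0.0)

    n = len(pts)
    P = np.column_stack([np.ones(n), pts])
    if np.linalg.matrix_rank(P) < 3:
        raise ValidationError("degenerate (collinear) control points: affine part unsolvable")
    K = _tps_kernel(d2) + regularization * np.eye(n)
    A = np.zeros((n + 3, n + 3))
    A[:n, :n] = K
    A[:n, n:] = P
    A[n:, :n] = P.T
    rhs = np.concatenate([vals, np.zeros(3)])
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
        raise TPSNumericalError(f"singular TPS system: {exc}") from exc
    return ThinPlateSpline(
        control_points=pts,
        weights=sol[:n],
        affine_coeffs=sol[n:],
        regularization=regularization,
    )


# ---------------------------------------------------------------------------
# contours
# ---------------------------------------------------------------------------

CONTOUR_KINDS = ("outer_axial", "inner_axial", "posterior", "outer_sagittal", "inner_sagittal")
_KIND_LABEL = {"outer_axial": 1, "inner_axial": 2, "posterior": 3,
               "outer_sagittal": 4, "inner_sagittal": 5}


@dataclass
class Contour:
    kind: str
    axis: str          # 'z' for axial, 'x' for sagittal
    position: float    # slice coordinate along the axis, mm
    points: np.ndarray  # (n, 3) mm


@dataclass
class ContourSet:
    contours: list[Contour] = field(default_factory=list)

    def of_kind(self, *kinds: str) -> list[Contour]:
        return [c for c in self.contours if c.kind in kinds]

    def points(self, *kinds: str) -> np.ndarray:
        parts = [c.points for c in self.of_kind(*kinds)]
        return np.concatenate(parts) if parts else np.empty((0, 3))

    def axial_positions(self, *kinds: str) -> np.ndarray:
        return np.unique([c.position for c in self.of_kind(*kinds) if c.axis == "z"])


def contours_from_labels(vol: LabeledVolume) -> ContourSet:
    """Group wall-label voxels into per-slice contours in patient mm."""
    cs = ContourSet()
    for kind, code in _KIND_LABEL.items():
        idx = np.argwhere(vol.labels == code)
        if idx.size == 0:
            continue
        axis_col = 2 if kind in ("outer_axial", "inner_axial", "posterior") else 0
        for slice_idx in np.unique(idx[:, axis_col]):
            sel = idx[idx[:, axis_col] == slice_idx]
            pts = vol.voxel_to_mm(sel)
            cs.contours.append(
                Contour(
                    kind=kind,
                    axis="z" if axis_col == 2 else "x",
                    position=float(pts[0, axis_col]),
                    points=pts,
                )
            )
    return cs


def _subsample(pts: np.ndarray, max_points: int) -> np.ndarray:
    if len(pts) <= max_points:
        return pts
    step = int(np.ceil(len(pts) / max_points))
    return pts[::step]


# ---------------------------------------------------------------------------
# wall surfaces
# ---------------------------------------------------------------------------

@dataclass
class WallSurfaces:
    """Outer/inner anterior height fields + posterior height field, with the
    per-level lateral span needed to close the cavity."""

    outer: ThinPlateSpline
    inner: ThinPlateSpline
    posterior: ThinPlateSpline
    z_range: tuple[float, float]
    span_z: np.ndarray        # labeled axial slice positions
    span_lo: np.ndarray       # cavity x-min per labeled slice
    span_hi: np.ndarray
    outer_span_lo: np.ndarray  # outer-wall footprint per labeled slice
    outer_span_hi: np.ndarray
    blend_frac: float = 0.02
    _grid: dict = field(default_factory=dict, repr=False)

    # -- lateral spans ------------------------------------------------------
    def cavity_span(self, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        z = np.asarray(z, dtype=float)
        return (
            np.interp(z, self.span_z, self.span_lo),
            np.interp(z, self.span_z, self.span_hi),
        )

    def outer_span(self, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        z = np.asarray(z, dtype=float)
        return (
            np.interp(z, self.span_z, self.outer_span_lo),
            np.interp(z, self.span_z, self.outer_span_hi),
        )

    # -- closed cavity cross-sections ---------------------------------------
    def cross_section(self, z: float, n_x: int = 192):
        """Blended anterior roof / posterior floor heights at level z."""
        lo, hi = self.cavity_span(np.array([z]))
        lo, hi = float(lo[0]), float(hi[0])
        xs = np.linspace(lo, hi, n_x)
        pts = np.column_stack([xs, np.full(n_x, z)])
        roof = self.inner(pts)
        floor = self.posterior(pts)
        width = float(hi - lo)
        w = np.clip(np.minimum(xs - lo, hi - xs) / (self.blend_frac * width), 0.0, 1.0)
        mid = 0.5 * (roof + floor)
        roof_b = mid + (roof - mid) * w
        floor_b = mid - (mid - floor) * w
        return xs, roof_b, floor_b

    def _cavity_grid(self, n_x: int = 192, n_z: int = 160):
        key = (n_x, n_z)
        if key not in self._grid:
            zlevels = np.linspace(self.z_range[0], self.z_range[1], n_z)
            roofs = np.empty((n_z, n_x))
            floors = np.empty((n_z, n_x))
            xs_all = np.empty((n_z, n_x))
            for i, z in enumerate(zlevels):
                xs, roof, floor = self.cross_section(float(z), n_x)
                xs_all[i], roofs[i], floors[i] = xs, roof, floor
            self._grid[key] = (zlevels, xs_all, roofs, floors)
        return self._grid[key]

    def cavity_volume_cm3(self, n_x: int = 192, n_z: int = 160) -> float:
        zlevels, xs_all, roofs, floors = self._cavity_grid(n_x, n_z)
        heights = np.clip(roofs - floors, 0.0, None)
        areas = np.trapezoid(heights, xs_all, axis=1)
        return float(np.trapezoid(areas, zlevels)) / 1e3

    def contains(self, pts_mm: np.ndarray, n_x: int = 192, n_z: int = 160) -> np.ndarray:
        """Vectorized inside-test against the closed cavity surface."""
        pts = np.atleast_2d(np.asarray(pts_mm, dtype=float))
        zlevels, xs_all, roofs, floors = self._cavity_grid(n_x, n_z)
        inside = np.zeros(len(pts), dtype=bool)
        z0, z1 = self.z_range
        okz = (pts[:, 2] >= z0) & (pts[:, 2] <= z1)
        if not okz.any():
            return inside
        p = pts[okz]
        iz = np.clip(np.searchsorted(zlevels, p[:, 2]) - 1, 0, len(zlevels) - 2)
        tz = (p[:, 2] - zlevels[iz]) / (zlevels[iz + 1] - zlevels[iz])

        def interp_level(arr_x, arr_y, rows, x):
            n = arr_x.shape[1]
            lo = arr_x[rows, 0]
            hi = arr_x[rows, -1]
            frac = np.clip((x - lo) / np.where(hi > lo, hi - lo, 1.0), 0.0, 1.0)
            fi = frac * (n - 1)
            i0 = np.clip(fi.astype(int), 0, n - 2)
            ti = fi - i0
            return arr_y[rows, i0] * (1 - ti) + arr_y[rows, i0 + 1] * ti, (x >= lo) & (x <= hi)

        roof0, in0 = interp_level(xs_all, roofs, iz, p[:, 0])
        roof1, in1 = interp_level(xs_all, roofs, iz + 1, p[:, 0])
        floor0, _ = interp_level(xs_all, floors, iz, p[:, 0])
        floor1, _ = interp_level(xs_all, floors, iz + 1, p[:, 0])
        roof = roof0 * (1 - tz) + roof1 * tz
        floor = floor0 * (1 - tz) + floor1 * tz
        inside[okz] = in0 & in1 & (p[:, 1] >= floor) & (p[:, 1] <= roof)
        return inside

    # -- watertight mesh ----------------------------------------------------
    def cavity_mesh(self, n_x: int = 64, n_z: int = 48):
        """Triangulated closed cavity surface (vertices mm, faces)."""
        zlevels, xs_all, roofs, floors = self._cavity_grid(n_x, n_z)
        loops = []
        for i in range(n_z):
            xs = xs_all[i]
            ant = np.column_stack([xs, roofs[i], np.full(n_x, zlevels[i])])
            post = np.column_stack([xs[::-1][1:-1], floors[i][::-1][1:-1],
                                    np.full(n_x - 2, zlevels[i])])
            loops.append(np.concatenate([ant, post]))
        m = loops[0].shape[0]
        verts = np.concatenate(loops)
        faces = []
        for i in range(n_z - 1):
            base0, base1 = i * m, (i + 1) * m
            for j in range(m):
                jn = (j + 1) % m
                faces.append((base0 + j, base0 + jn, base1 + j))
                faces.append((base0 + jn, base1 + jn, base1 + j))
        # flat caps: fan about the loop centroid
        for i, flip in ((0, True), (n_z - 1, False)):
            base = i * m
            cidx = len(verts)
            verts = np.concatenate([verts, loops[i].mean(axis=0, keepdims=True)])
            for j in range(m):
                jn = (j + 1) % m
                tri = (base + j, base + jn, cidx)
                faces.append(tri[::-1] if flip else tri)
        return verts, np.asarray(faces, dtype=int)

    def is_watertight(self) -> bool:
        _, faces = self.cavity_mesh()
        edges = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
        edges = np.sort(edges, axis=1)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return bool(np.all(counts == 2))

    def export_ply(self, path: str | Path) -> None:
        verts, faces = self.cavity_mesh()
        with open(path, "w") as fh:
            fh.write("ply\nformat ascii 1.0\n")
            fh.write(f"element vertex {len(verts)}\n")
            fh.write("property float x\nproperty float y\nproperty float z\n")
            fh.write(f"element face {len(faces)}\nproperty list uchar int vertex_indices\nend_header\n")
            for v in verts:
                fh.write(f"{v[0]:.4f} {v[1]:.4f} {v[2]:.4f}\n")
            for f in faces:
                fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def interpolate_walls(
    contours: ContourSet,
    regularization: float = 0.0,
    max_control: int = 900,
) -> WallSurfaces:
    """Fit the three height-field TPS surfaces and assemble the closed cavity."""
    for kinds in (("outer_axial",), ("inner_axial",)):
        if len(contours.axial_positions(*kinds)) < 2:
            raise ValidationError(
                f"need axial contours on >= 2 slices for {kinds[0]} (wall interpolation)"
            )

    def fit_surface(envelope, *kinds):
        pts = contours.points(*kinds)
        pts = _subsample(pts, max_control)
        uv = pts[:, [0, 2]]
        # collapse duplicate (x, z) columns to the surface envelope: the
        # anterior wall is the upper (+y) envelope, the posterior the lower —
        # a plain mean would bias steep lateral edges inward
        uniq, inv = np.unique(np.round(uv, 6), axis=0, return_inverse=True)
        fill = -np.inf if envelope == "upper" else np.inf
        vals = np.full(len(uniq), fill)
        reducer = np.maximum if envelope == "upper" else np.minimum
        reducer.at(vals, inv, pts[:, 1])
        return fit_tps(uniq, vals, regularization)

    outer = fit_surface("upper", "outer_axial", "outer_sagittal")
    inner = fit_surface("upper", "inner_axial", "inner_sagittal")
    posterior = fit_surface("lower", "posterior")

    zpos = np.unique(
        np.concatenate(
            [
                contours.axial_positions("outer_axial"),
                contours.axial_positions("inner_axial"),
                contours.axial_positions("posterior"),
            ]
        )
    )
    span_lo, span_hi, out_lo, out_hi = [], [], [], []
    for z in zpos:
        cav_pts = [
            c.points for c in contours.of_kind("inner_axial", "posterior")
            if c.axis == "z" and np.isclose(c.position, z)
        ]
        cav = np.concatenate(cav_pts) if cav_pts else np.empty((0, 3))
        outp = [
            c.points for c in contours.of_kind("outer_axial")
            if c.axis == "z" and np.isclose(c.position, z)
        ]
        op = np.concatenate(outp) if outp else cav
        span_lo.append(cav[:, 0].min() if len(cav) else np.nan)
        span_hi.append(cav[:, 0].max() if len(cav) else np.nan)
        out_lo.append(op[:, 0].min() if len(op) else np.nan)
        out_hi.append(op[:, 0].max() if len(op) else np.nan)

    ok = ~np.isnan(span_lo)
    return WallSurfaces(
        outer=outer,
        inner=inner,
        posterior=posterior,
        z_range=(float(zpos.min()), float(zpos.max())),
        span_z=zpos[ok],
        span_lo=np.asarray(span_lo)[ok],
        span_hi=np.asarray(span_hi)[ok],
        outer_span_lo=np.asarray(out_lo)[ok],
        outer_span_hi=np.asarray(out_hi)[ok],
    )


def wall_thickness_stats(
    surfaces: WallSurfaces,
    n_x: int = 48,
    n_z: int = 48,
    edge_margin: float = 0.12,
) -> tuple[float, float]:
    """(mean, SD) wall thickness in cm, sampled uniformly over the common
    anterior footprint along outer-surface normals."""
    z0, z1 = surfaces.z_range
    zs = np.linspace(z0, z1, n_z)
    lo, hi = surfaces.outer_span(zs)
    width = hi - lo
    samples = []
    fracs = np.linspace(edge_margin, 1.0 - edge_margin, n_x)
    X = lo[None, :] + fracs[:, None] * width[None, :]
    Z = np.broadcast_to(zs[None, :], X.shape)
    pts = np.column_stack([X.ravel(), Z.ravel()])
    f_out = surfaces.outer(pts)
    # outer-surface gradient by central differences
    eps = 0.5
    fx = (surfaces.outer(pts + [eps, 0]) - surfaces.outer(pts - [eps, 0])) / (2 * eps)
    fz = (surfaces.outer(pts + [0, eps]) - surfaces.outer(pts - [0, eps])) / (2 * eps)
    norm = np.sqrt(1.0 + fx**2 + fz**2)
    nx_, ny_, nz_ = -fx / norm, 1.0 / norm, -fz / norm
    s = f_out - surfaces.inner(pts)  # zeroth-order guess
    for _ in range(6):
        shifted = np.column_stack([pts[:, 0] - s * nx_, pts[:, 1] - s * nz_])
        s = (f_out - surfaces.inner(shifted)) / ny_
    valid = s > 0
    if not valid.all():
        warnings.warn(
            f"excluded {np.count_nonzero(~valid)} negative-thickness samples "
            "(surfaces intersect locally)",
            RuntimeWarning,
        )
    if not valid.any():
        raise ValidationError("no valid wall-thickness samples")
    samples = s[valid] / 10.0
    return float(samples.mean()), float(samples.std())
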
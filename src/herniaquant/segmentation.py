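"""Intensity-driven body and fat-compartment extraction.

Fuzzy C-means (m = 2, deterministic quantile initialization) separates body
from background/table and fat from muscle; the interpolated cavity surface
splits fat into visceral and subcutaneous compartments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_core import LabeledVolume, ValidationError
from .surfaces import WallSurfaces

__all__ = [
    "FCMResult",
    "fuzzy_cmeans_1d",
    "extract_body",
    "segment_fat",
    "split_fat",
    "FatSplit",
    "CompartmentMasks",
    "extract_compartments",
]

BONE_HU = 200.0
AIR_HU = -500.0


@dataclass
class FCMResult:
    centers: np.ndarray           # sorted ascending
    objective_trace: np.ndarray   # FCM objective per iteration (non-increasing)
    n_iter: int

    def membership(self, values: np.ndarray) -> np.ndarray:
        """(n_values, n_clusters) fuzzy memberships for m = 2."""
        d2 = (np.asarray(values, dtype=float)[:, None] - self.centers[None, :]) ** 2
        d2 = np.maximum(d2, 1e-12)
        inv = 1.0 / d2
        return inv / inv.sum(axis=1, keepdims=True)


def fuzzy_cmeans_1d(
    values: np.ndarray,
    n_clusters: int = 2,
    m: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 300,
    n_bins: int = 1024,
) -> FCMResult:
    """Histogram-weighted 1-D fuzzy C-means with quantile initialization.

    Binning only affects center estimation (memberships are a closed-form
    function of value and centers), keeps the run deterministic, and makes the
    cost independent of voxel count.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValidationError("empty input to fuzzy C-means")
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        hi = lo + 1.0
    counts, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    mids = 0.5 * (edges[:-1] + edges[1:])
    keep = counts > 0
    mids, w = mids[keep], counts[keep].astype(float)

    q = np.linspace(0, 1, n_clusters + 2)[1:-1]
    centers = np.quantile(values, q)
    centers = np.unique(centers)
    while len(centers) < n_clusters:  # degenerate quantiles: nudge apart
        centers = np.sort(np.concatenate([centers, [centers[-1] + 1.0]]))

    trace = []
    for it in range(max_iter):
        d2 = (mids[:, None] - centers[None, :]) ** 2
        d2 = np.maximum(d2, 1e-12)
        ratio = d2 ** (1.0 / (m - 1.0))
        u = 1.0 / (ratio * (1.0 / ratio).sum(axis=1, keepdims=True))
        um = u**m
        trace.append(float((w[:, None] * um * d2).sum()))
        new_centers = (w[:, None] * um * mids[:, None]).sum(axis=0) / (w[:, None] * um).sum(axis=0)
        shift = np.abs(new_centers - centers).max()
        centers = new_centers
        if shift < tol:
            break
    return FCMResult(
        centers=np.sort(centers),
        objective_trace=np.asarray(trace),
        n_iter=len(trace),
    )


def extract_body(vol: LabeledVolume) -> np.ndarray:
    """Body mask: FCM(2) on intensity, higher-mean cluster at membership > 0.5,
    largest 26-connected component, per-slice hole filling.  The scan table is
    removed by the connected-component step."""
    fcm = fuzzy_cmeans_1d(vol.intensity)
    # membership > 0.5 for the higher-mean of two clusters == nearer to it
    threshold = fcm.centers.mean()
    fg = vol.intensity > threshold
    if not fg.any():
        raise ValidationError("empty foreground after intensity clustering")
    lab, n = ndimage.label(fg, structure=np.ones((3, 3, 3), dtype=bool))
    if n == 0:
        raise ValidationError("empty foreground after intensity clustering")
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    body = lab == (1 + int(np.argmax(sizes)))
    for k in range(body.shape[2]):
        body[:, :, k] = ndimage.binary_fill_holes(body[:, :, k])
    return body


def segment_fat(vol: LabeledVolume, body: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(fat, muscle/soft-tissue) masks inside the body after excluding bone
    (> +200 HU) and air (< -500 HU)."""
    if not body.any():
        raise ValidationError("body mask is empty")
    soft = body & (vol.intensity <= BONE_HU) & (vol.intensity >= AIR_HU)
    values = vol.intensity[soft]
    fcm = fuzzy_cmeans_1d(values)
    if fcm.centers[1] - fcm.centers[0] < 30.0:
        # one intensity mode only: splitting it would halve the tissue into
        # spurious "fat"; fall back to a fixed fat/soft-tissue HU boundary
        warnings.warn(
            "fat/muscle intensity modes barely distinguishable "
            f"(centers {fcm.centers}); using fixed -30 HU boundary",
            RuntimeWarning,
        )
        threshold = -30.0
    else:
        threshold = fcm.centers.mean()
    fat = soft & (vol.intensity < threshold)
    muscle = soft & ~fat
    return fat, muscle


@dataclass
class FatSplit:
    visceral_mask: np.ndarray
    subcutaneous_mask: np.ndarray
    visceral_cm3: float
    subcutaneous_cm3: float


def split_fat(
    vol: LabeledVolume,
    fat: np.ndarray,
    body: np.ndarray,
    surfaces: WallSurfaces,
    vertical_range: tuple[float, float] | None = None,
) -> FatSplit:
    """Partition fat by the closed cavity surface within ``vertical_range``
    (defaults to the labeled wall range): inside -> visceral, outside (but in
    body) -> subcutaneous.  visceral + subcutaneous == in-range fat, exactly."""
    if np.any(fat & ~body):
        raise ValidationError("fat voxels outside the body mask")
    if vertical_range is None:
        vertical_range = surfaces.z_range
    idx = np.argwhere(fat)
    vis = np.zeros_like(fat)
    sub = np.zeros_like(fat)
    if idx.size:
        pts = vol.voxel_to_mm(idx)
        z0, z1 = vertical_range
        in_range = (pts[:, 2] >= z0) & (pts[:, 2] <= z1)
        inside = np.zeros(len(pts), dtype=bool)
        inside[in_range] = surfaces.contains(pts[in_range])
        vis[tuple(idx[inside & in_range].T)] = True
        sub[tuple(idx[~inside & in_range].T)] = True
    voxvol = vol.voxel_volume_mm3 / 1e3
    return FatSplit(
        visceral_mask=vis,
        subcutaneous_mask=sub,
        visceral_cm3=float(vis.sum()) * voxvol,
        subcutaneous_cm3=float(sub.sum()) * voxvol,
    )


@dataclass
class CompartmentMasks:
    body: np.ndarray
    bone: np.ndarray
    air: np.ndarray
    fat: np.ndarray
    muscle: np.ndarray
    visceral_fat: np.ndarray
    subcutaneous_fat: np.ndarray
    visceral_cm3: float
    subcutaneous_cm3: float


def extract_compartments(
    vol: LabeledVolume,
    surfaces: WallSurfaces,
    vertical_range: tuple[float, float] | None = None,
) -> CompartmentMasks:
    """Run the full body -> fat -> visceral/subcutaneous chain."""
    body = extract_body(vol)
    fat, muscle = segment_fat(vol, body)
    split = split_fat(vol, fat, body, surfaces, vertical_range)
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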
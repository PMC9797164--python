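"""Automatic landmark and ROI extraction: 3D Harris corners, patch-based
point matching, and gray-level threshold segmentation."""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .geometry import LabelMask, Volume, world_to_voxel
from .pointsets import PairedPointSet

__all__ = ["harris_corners_3d", "match_points", "threshold_segment"]


def harris_response_3d(
    volume: Volume, sigma_grad: float = 1.0, sigma_window: float = 1.6, k: float = 0.001
) -> np.ndarray:
    """Corner response ``R = det(M) - k * trace(M)**3`` of the 3D structure
    tensor ``M`` (Gaussian-windowed outer products of intensity gradients).

    Gradients are taken per mm (spacing-aware) so anisotropic slices do not
    distort the response; the window sigma is in voxels.
    """
    data = ndimage.gaussian_filter(volume.data, sigma_grad, mode="nearest")
    grads = np.gradient(data, *volume.spacing)
    m = np.empty(volume.shape + (3, 3))
    for i in range(3):
        for j in range(i, 3):
            prod = ndimage.gaussian_filter(grads[i] * grads[j], sigma_window, mode="nearest")
            m[..., i, j] = prod
            m[..., j, i] = prod
    det = np.linalg.det(m)
    trace = m[..., 0, 0] + m[..., 1, 1] + m[..., 2, 2]
    return det - k * trace**3


def harris_corners_3d(
    volume: Volume,
    mask: LabelMask | None = None,
    sigma_grad: float = 1.0,
    sigma_window: float = 1.6,
    k: float = 0.001,
    n_points: int = 30,
) -> np.ndarray:
    """Strongest Harris corners as world points (mm), descending response.

    Local maxima use 26-neighborhood non-max suppression; only strictly
    positive responses qualify, so a constant volume returns no corners.
    May return fewer than ``n_points``.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    r = harris_response_3d(volume, sigma_grad, sigma_window, k)
    local_max = r == ndimage.maximum_filter(r, size=3, mode="nearest")
    cand = local_max & (r > 0)
    if mask is not None:
        mask.check_matches(volume)
        cand &= mask.data
    idx = np.argwhere(cand)
    if idx.shape[0] == 0:
        return np.empty((0, 3))
    order = np.argsort(r[tuple(idx.T)])[::-1][:n_points]
    sel = idx[order].astype(np.float64)
    return sel * np.asarray(volume.spacing) + np.asarray(volume.origin)


def _extract_patch(data: np.ndarray, center: np.ndarray, half: np.ndarray):
    lo = center - half
    hi = center + half + 1
    if np.any(lo < 0) or np.any(hi > np.asarray(data.shape)):
        return None
    return data[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def match_points(
    fixed: Volume,
    moving: Volume,
    fixed_pts: np.ndarray,
    search_radius_mm: float = 10.0,
    patch_radius_mm: float = 5.0,
    min_corr: float = 0.5,
    initial_transform=None,
) -> PairedPointSet:
    """Pair fixed landmarks with their best NCC match in the moving image.

    For each fixed point the moving location maximizing normalized
    cross-correlation of an intensity patch is searched (voxel steps) within
    ``search_radius_mm`` of the initial guess (``initial_transform`` applied
    when given). Pairs below ``min_corr`` are dropped; no survivors is an
    error.
    """
    fixed_pts = np.atleast_2d(np.asarray(fixed_pts, dtype=np.float64))
    sp_f = np.asarray(fixed.spacing)
    sp_m = np.asarray(moving.spacing)
    half_f = np.maximum(np.round(patch_radius_mm / sp_f).astype(int), 1)
    half_m = np.maximum(np.round(patch_radius_mm / sp_m).astype(int), 1)
    search = np.maximum(np.round(search_radius_mm / sp_m).astype(int), 0)

    kept_f, kept_m = [], []
    for p in fixed_pts:
        ci = np.round(world_to_voxel(fixed, p)).astype(int)
        patch = _extract_patch(fixed.data, ci, half_f)
        if patch is None:
            continue
        guess = initial_transform.apply(p) if initial_transform is not None else p
        gi = np.round(world_to_voxel(moving, guess)).astype(int)
        best, best_off = -np.inf, None
        for dx in range(-search[0], search[0] + 1):
            for dy in range(-search[1], search[1] + 1):
                for dz in range(-search[2], search[2] + 1):
                    cand = gi + np.array([dx, dy, dz])
                    mp = _extract_patch(moving.data, cand, half_m)
                    if mp is None or mp.shape != patch.shape:
                        continue
                    c = _ncc(patch, mp)
                    if c > best:
                        best, best_off = c, cand
        if best_off is None or best < min_corr:
            continue
        kept_f.append(p)
        kept_m.append(best_off.astype(np.float64) * sp_m + np.asarray(moving.origin))
    if not kept_f:
        raise ValueError("no reliable pairs")
    return PairedPointSet(np.asarray(kept_f), np.asarray(kept_m))


def threshold_segment(
    volume: Volume,
    mask: LabelMask | None = None,
    closing_radius_mm: float = 0.0,
    min_volume_mm3: float = 0.0,
) -> LabelMask:
    """Otsu threshold, keep the largest 26-connected component, then close.

    The threshold is computed on the (optionally masked) histogram; the
    foreground is the above-threshold region. ``min_volume_mm3`` is a
    quality gate standing in for manual confirmation of the contour.
    """
    if mask is not None:
        mask.check_matches(volume)
        vals = volume.data[mask.data]
    else:
        vals = volume.data.ravel()
    if vals.size == 0 or np.ptp(vals) == 0:
        raise ValueError("degenerate histogram")
    thr = threshold_otsu(vals)
    fg = volume.data > thr
    if mask is not None:
        fg &= mask.data
    labels, n = ndimage.label(fg, structure=np.ones((3, 3, 3), bool))
    if n == 0:
        raise ValueError("degenerate histogram")
    counts = np.bincount(labels.ravel())[1:]
    fg = labels == (1 + int(np.argmax(counts)))
    if closing_radius_mm > 0:
        struct = _ball_structure(closing_radius_mm, volume.spacing)
        fg = ndimage.binary_closing(fg, structure=struct)
    voxel_mm3 = float(np.prod(volume.spacing))
    if fg.sum() * voxel_mm3 < min_volume_mm3:
        raise ValueError("segmented component below minimum volume")
    return LabelMask.from_volume(volume, fg)


def _ball_structure(radius_mm: float, spacing) -> np.ndarray:
    half = np.maximum(np.floor(radius_mm / np.asarray(spacing)).astype(int), 0)
    grids = np.meshgrid(
        *[np.arange(-h, h + 1) * s for h, s in zip(half, spacing)], indexing="ij"
    )
    dist2 = sum(g**2 for g in grids)
    return dist2 <= radius_mm**2 + 1e-9
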
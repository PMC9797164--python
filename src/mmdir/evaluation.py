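"""Registration assessment: grouped target registration error, Dice,
Hausdorff distance, checkerboard and orange/cyan overlay renderings."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .geometry import LabelMask, Volume
from .pointsets import PairedPointSet

__all__ = [
    "TREReport",
    "target_registration_error",
    "dice",
    "hausdorff",
    "checkerboard",
    "overlay",
]


@dataclass(frozen=True)
class TREReport:
    """Per-point distances (mm) with group labels and per-group summaries."""

    distances: np.ndarray
    groups: tuple[str, ...]

    @property
    def mean(self) -> float:
        return float(self.distances.mean())

    @property
    def median(self) -> float:
        return float(np.median(self.distances))

    def group_stats(self) -> dict[str, tuple[float, float]]:
        """``{group: (mean, sd)}`` over the per-point distances."""
        out = {}
        for g in dict.fromkeys(self.groups):
            d = self.distances[[i for i, x in enumerate(self.groups) if x == g]]
            out[g] = (float(d.mean()), float(d.std(ddof=1)) if d.size > 1 else 0.0)
        return out


def target_registration_error(pairs: PairedPointSet, t) -> TREReport:
    """Euclidean distance per landmark pair under the backward-mapping
    convention: ``‖x_M - T(x_F)‖``, on held-out pairs."""
    if pairs is None or len(pairs) == 0:
        raise ValueError("empty point set")
    mapped = t.apply(pairs.fixed_points)
    d = np.linalg.norm(pairs.moving_points - mapped, axis=1)
    return TREReport(d, tuple(pairs.groups))


def _check_pair(a: LabelMask, b: LabelMask) -> None:
    if not a.same_geometry(b):
        raise ValueError("masks must share grid geometry")


def dice(a: LabelMask, b: LabelMask) -> float:
    """``2|A ∩ B| / (|A| + |B|)``; undefined when both masks are empty."""
    _check_pair(a, b)
    na, nb = a.n_foreground, b.n_foreground
    if na + nb == 0:
        raise ValueError("undefined DSC: both masks empty")
    inter = int(np.count_nonzero(a.data & b.data))
    return 2.0 * inter / (na + nb)


def _boundary_world(mask: LabelMask) -> np.ndarray:
    """Boundary voxels (6-connectivity erosion difference) in world mm."""
    struct = ndimage.generate_binary_structure(3, 1)
    eroded = ndimage.binary_erosion(mask.data, structure=struct, border_value=0)
    boundary = mask.data & ~eroded
    idx = np.argwhere(boundary).astype(np.float64)
    return idx * np.asarray(mask.spacing) + np.asarray(mask.origin)


def hausdorff(a: LabelMask, b: LabelMask) -> float:
    """Symmetric Hausdorff distance (mm) between mask boundaries.

    ``max(h(A,B), h(B,A))`` with ``h`` the directed max-min Euclidean
    distance over boundary voxel centers (exact nearest neighbours).
    """
    _check_pair(a, b)
    if a.n_foreground == 0 or b.n_foreground == 0:
        raise ValueError("empty mask")
    pa, pb = _boundary_world(a), _boundary_world(b)
    d_ab = cKDTree(pb).query(pa)[0].max()
    d_ba = cKDTree(pa).query(pb)[0].max()
    return float(max(d_ab, d_ba))


def checkerboard(fixed: Volume, moved: Volume, tile: int = 8) -> Volume:
    """Alternate tiles of the two images by parity of ``floor(index/tile)``."""
    if not fixed.same_geometry(moved):
        raise ValueError("checkerboard requires identical geometry")
    if tile < 1:
        raise ValueError("tile must be >= 1")
    ix, iy, iz = np.indices(fixed.shape) // tile
    parity = (ix + iy + iz) % 2
    data = np.where(parity == 0, fixed.data, moved.data)
    return fixed.with_data(data)


def overlay(fixed: Volume, moved: Volume, window: tuple[float, float] | None = None) -> np.ndarray:
    """Orange/cyan RGB blend, shape ``(nx, ny, nz, 3)`` in [0, 1].

    The fixed image fills the orange channel weights (R, G/2), the moved
    image the cyan ones (G/2, B); equal windowed intensities come out gray
    (R == G == B).
    """
    if not fixed.same_geometry(moved):
        raise ValueError("overlay requires identical geometry")
    if window is None:
        lo = min(fixed.data.min(), moved.data.min())
        hi = max(fixed.data.max(), moved.data.max())
        window = (float(lo), float(hi) if hi > lo else float(lo) + 1.0)
    lo, hi = window
    f = np.clip((fixed.data - lo) / (hi - lo), 0.0, 1.0)
    m = np.clip((moved.data - lo) / (hi - lo), 0.0, 1.0)
    rgb = np.stack([f, 0.5 * f + 0.5 * m, m], axis=-1)
    return rgb
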
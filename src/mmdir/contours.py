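"""Contour propagation and margin operations.

Margins are physical (mm) via Euclidean distance transforms so anisotropic
voxels (thick slices) expand correctly in every direction.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .geometry import LabelMask, Volume
from .interp import sample_trilinear

__all__ = ["propagate_mask", "expand_margin", "skin_limit_mask"]


def propagate_mask(mask: LabelMask, t, fixed_geometry: Volume | LabelMask) -> LabelMask:
    """Deform a moving-grid mask onto the fixed grid through ``t``.

    ``t`` maps fixed world to moving world; each fixed voxel is foreground
    iff the trilinear sample of the mask at ``T(x)`` is >= 0.5 (unbiased for
    symmetric interpolation). Identity transform on identical grids is the
    identity map.
    """
    idx = np.indices(fixed_geometry.shape, dtype=np.float64).reshape(3, -1).T
    pts = idx * np.asarray(fixed_geometry.spacing) + np.asarray(fixed_geometry.origin)
    vals = sample_trilinear(mask, t.apply(pts))
    out = (vals >= 0.5).reshape(fixed_geometry.shape)
    return LabelMask(out, fixed_geometry.spacing, fixed_geometry.origin)


def expand_margin(
    mask: LabelMask, margin_mm: float, limit: LabelMask | None = None
) -> LabelMask:
    """Dilate by a physical margin: ``{x : dist_mm(x, mask) <= margin}``,
    clipped to ``limit`` when given. Margin 0 with a full limit returns the
    input mask."""
    if mask.n_foreground == 0:
        raise ValueError("cannot expand an empty mask")
    if margin_mm < 0:
        raise ValueError("margin must be non-negative")
    dist = ndimage.distance_transform_edt(~mask.data, sampling=mask.spacing)
    out = dist <= margin_mm
    if limit is not None:
        limit.check_matches(mask)
        out &= limit.data
    return LabelMask(out, mask.spacing, mask.origin)


def skin_limit_mask(body: LabelMask, depth_mm: float) -> LabelMask:
    """The part of ``body`` deeper than ``depth_mm`` from its surface
    (distance-transform erosion). Depth 0 returns the body unchanged."""
    if body.n_foreground == 0:
        raise ValueError("empty body mask")
    if depth_mm < 0:
        raise ValueError("depth must be non-negative")
    dist = ndimage.distance_transform_edt(body.data, sampling=body.spacing)
    out = dist > depth_mm
    if not out.any():
        raise ValueError("body thinner than depth")
    return LabelMask(out, body.spacing, body.origin)
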
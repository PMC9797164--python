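"""Registration cost terms and their weighted combination.

Three terms enter a single objective:

* ``fiducial_cost`` — mean Euclidean distance (mm) between moving landmarks
  and transformed fixed landmarks;
* ``kappa_cost`` — ``1 - KS`` where ``KS = 2|A & B| / (|A| + |B|)`` is the
  Kappa-statistic overlap of a fixed ROI and the transformed moving ROI;
* ``mutual_information`` — negated mutual information (bits) of paired
  intensity samples.

Everything is minimized; similarity measures enter negated. Each term
returns ``(value, gradient)`` where the gradient is taken w.r.t. the
B-spline coefficients of the transform (``None`` if the transform has no
B-spline part).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import LabelMask, Volume
from .interp import sample_trilinear
from .pointsets import PairedPointSet
from .transforms import BSplineTransform, _bspline_weights, _bspline_weights_d

__all__ = [
    "MIConfig",
    "MetricWeights",
    "fiducial_cost",
    "kappa_cost",
    "mutual_information",
    "mi_estimate",
    "combined_cost",
    "intensity_range",
]


@dataclass(frozen=True)
class MIConfig:
    """Mutual-information estimator settings.

    ``n_bins`` regularly spaced bins per image; Parzen windowing uses a
    zero-order kernel on the fixed axis and a cubic kernel on the moving
    axis. ``fixed_range``/``moving_range`` pin the binned intensity range
    (computed once per resolution level during registration); when absent
    they fall back to robust percentiles of the supplied volumes.
    """

    n_bins: int = 32
    n_samples: int = 2048
    fixed_range: tuple[float, float] | None = None
    moving_range: tuple[float, float] | None = None
    range_percentiles: tuple[float, float] = (0.5, 99.5)

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


@dataclass(frozen=True)
class MetricWeights:
    """Non-negative weights of the fiducial, region and intensity terms."""

    fiducial: float = 1.0
    region: float = 1.0
    intensity: float = 100.0

    def __post_init__(self) -> None:
        w = (self.fiducial, self.region, self.intensity)
        if any(x < 0 for x in w):
            raise ValueError("metric weights must be non-negative")
        if sum(w) <= 0:
            raise ValueError("at least one metric weight must be positive")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.fiducial, self.region, self.intensity)


def intensity_range(volume: Volume, percentiles=(0.5, 99.5)) -> tuple[float, float]:
    """Robust intensity range so outliers (clips) do not crush the bins."""
    lo, hi = np.percentile(volume.data, percentiles)
    if hi <= lo:
        lo, hi = float(volume.data.min()), float(volume.data.max())
        if hi <= lo:
            hi = lo + 1.0
    return float(lo), float(hi)


def _grad_via_weights(
    bsp: BSplineTransform | None, pts: np.ndarray, dcost_dT: np.ndarray
) -> np.ndarray | None:
    """Chain per-point cost derivatives through the B-spline weights."""
    if bsp is None:
        return None
    W = bsp.weight_matrix(pts)
    flat = np.column_stack([W.T @ dcost_dT[:, c] for c in range(3)])
    return flat.reshape(bsp.coefficients.shape)


def fiducial_cost(t, pairs: PairedPointSet):
    """Mean Euclidean distance (mm) between pairs under ``t``.

    Returns ``(value, grad)``; zero iff every transformed fixed point
    coincides with its moving partner.
    """
    if pairs is None or len(pairs) == 0:
        raise ValueError("no fiducial pairs")
    xf = pairs.fixed_points
    xm = pairs.moving_points
    mapped = t.apply(xf)
    diff = xm - mapped
    d = np.linalg.norm(diff, axis=1)
    value = float(d.mean())
    # d‖xm - T(xf)‖/dT = -(xm - T(xf)) / ‖·‖
    safe = np.where(d > 0, d, 1.0)
    dcost_dT = -(diff / safe[:, None]) / len(pairs)
    dcost_dT[d == 0] = 0.0
    return value, _grad_via_weights(getattr(t, "bspline", None), xf, dcost_dT)


def kappa_cost(
    t,
    roi_fixed: LabelMask,
    roi_moving: LabelMask,
    candidate: np.ndarray | None = None,
):
    """``1 - KS`` with the moving mask sampled at ``T(x)`` (soft overlap).

    ``candidate`` optionally restricts the fixed-grid sample voxels (a bool
    array on the fixed grid). A uniform subsample of a region covering both
    masks yields an unbiased KS estimate because the sampling fraction
    cancels in the ratio. The soft moving value is the trilinear
    interpolation of the binary mask, making the term differentiable; a
    hard 0.5 threshold is only used for reporting.
    """
    if roi_fixed.n_foreground == 0 or roi_moving.n_foreground == 0:
        raise ValueError("empty ROI")
    if candidate is None:
        cand = np.ones(roi_fixed.shape, dtype=bool)
    else:
        cand = np.asarray(candidate, dtype=bool)
        if cand.shape != roi_fixed.shape:
            raise ValueError("candidate shape must match the fixed grid")
    idx = np.argwhere(cand).astype(np.float64)
    pts = idx * np.asarray(roi_fixed.spacing) + np.asarray(roi_fixed.origin)
    a = roi_fixed.data[cand].astype(np.float64)
    mapped = t.apply(pts)
    b, gb, _ = sample_trilinear(roi_moving, mapped, with_gradient=True)
    na = a.sum()
    nb = b.sum()
    nab = float(a @ b)
    denom = na + nb
    ks = 2.0 * nab / denom
    value = 1.0 - ks
    bsp = getattr(t, "bspline", None)
    if bsp is None:
        return value, None
    # d(1-KS)/db_x = -(2 a_x (na+nb) - 2 nab) / (na+nb)^2 ; chain through the
    # interpolant gradient, nonzero only near the moving-mask boundary.
    dcost_db = -(2.0 * a * denom - 2.0 * nab) / denom**2
    rows = np.any(gb != 0.0, axis=1)
    if not np.any(rows):
        return value, np.zeros_like(bsp.coefficients)
    dcost_dT = dcost_db[rows, None] * gb[rows]
    return value, _grad_via_weights(bsp, pts[rows], dcost_dT)


def _hard_bins(vals: np.ndarray, rng: tuple[float, float], n_bins: int) -> np.ndarray:
    lo, hi = rng
    u = (vals - lo) / max(hi - lo, 1e-300)
    return np.clip(np.floor(u * n_bins).astype(np.int64), 0, n_bins - 1)


def mutual_information(
    t,
    fixed: Volume,
    moving: Volume,
    cfg: MIConfig = MIConfig(),
    sample_points: np.ndarray | None = None,
    rng: np.random.Generator | int | None = None,
    sample_mask: np.ndarray | None = None,
    mode: str = "parzen",
):
    """Negated mutual information (bits) of fixed/moving intensity samples.

    Returns ``(cost, grad)`` with ``cost = -MI``. Samples are fixed voxel
    centers: either ``sample_points`` (world mm), or ``cfg.n_samples``
    drawn with ``rng`` (restricted to ``sample_mask`` when given), or —
    with neither — every voxel (dense, deterministic).

    ``mode="histogram"`` hard-bins both axes (exact dense estimator used by
    tests and final reporting; no gradient). ``mode="parzen"`` applies a
    cubic Parzen kernel along the moving axis and supplies the analytic
    gradient.
    """
    if mode not in ("parzen", "histogram"):
        raise ValueError(f"unknown MI mode {mode!r}")
    if sample_points is None:
        if sample_mask is not None:
            idx = np.argwhere(np.asarray(sample_mask, dtype=bool)).astype(np.float64)
        else:
            idx = np.indices(fixed.shape, dtype=np.float64).reshape(3, -1).T
        pool = idx * np.asarray(fixed.spacing) + np.asarray(fixed.origin)
        fvals_pool = fixed.data[
            tuple(idx.astype(np.int64).T)
        ]
        if rng is not None and cfg.n_samples < pool.shape[0]:
            gen = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
            pick = gen.choice(pool.shape[0], size=cfg.n_samples, replace=False)
            pts, fvals = pool[pick], fvals_pool[pick]
        else:
            pts, fvals = pool, fvals_pool
    else:
        pts = np.atleast_2d(np.asarray(sample_points, dtype=np.float64))
        fvals = sample_trilinear(fixed, pts)

    cost, dcost_dT, used = mi_estimate(t, fixed, moving, cfg, pts, fvals, mode)
    bsp = getattr(t, "bspline", None)
    if dcost_dT is None or bsp is None:
        return cost, None
    return cost, _grad_via_weights(bsp, used, dcost_dT)


def mi_estimate(
    t,
    fixed: Volume,
    moving: Volume,
    cfg: MIConfig,
    pts: np.ndarray,
    fvals: np.ndarray | None = None,
    mode: str = "parzen",
):
    """MI estimator core at explicit fixed-domain sample points.

    Returns ``(cost, dcost_dT, used_pts)`` where ``dcost_dT`` (n, 3) is the
    derivative of ``-MI`` w.r.t. the mapped moving-space position of each
    surviving sample (``None`` in histogram mode); callers chain it through
    whatever parameterization they optimize.
    """
    pts = np.atleast_2d(np.asarray(pts, dtype=np.float64))
    if fvals is None:
        fvals = sample_trilinear(fixed, pts)
    mapped = t.apply(pts)
    mvals, mgrad, inside = sample_trilinear(moving, mapped, with_gradient=True)
    if int(inside.sum()) < cfg.n_bins:
        raise ValueError("insufficient overlap")
    pts, fvals, mvals, mgrad = pts[inside], fvals[inside], mvals[inside], mgrad[inside]

    nb = cfg.n_bins
    f_range = cfg.fixed_range or intensity_range(fixed, cfg.range_percentiles)
    m_range = cfg.moving_range or intensity_range(moving, cfg.range_percentiles)
    bf = _hard_bins(fvals, f_range, nb)
    n = fvals.shape[0]

    if mode == "histogram":
        bm = _hard_bins(mvals, m_range, nb)
        joint = np.zeros((nb, nb))
        np.add.at(joint, (bf, bm), 1.0)
        p = joint / n
        pf = p.sum(axis=1, keepdims=True)
        pm = p.sum(axis=0, keepdims=True)
        nz = p > 0
        mi = float(np.sum(p[nz] * np.log2(p[nz] / (pf @ pm)[nz])))
        return -mi, None, pts

    # Parzen: cubic kernel on the moving axis spanning 4 bins; the moving
    # coordinate is placed in [1, nb-2] so the kernel never leaves the range.
    lo, hi = m_range
    su = (nb - 3) / max(hi - lo, 1e-300)
    um = np.clip((mvals - lo) * su + 1.0, 1.0, (nb - 2) - 1e-9)
    clipped = (um <= 1.0) | (um >= (nb - 2) - 1e-9)
    j0 = np.floor(um).astype(np.int64)
    frac = um - j0
    w = _bspline_weights(frac)  # (n, 4) for bins j0-1 .. j0+2
    cols = j0[:, None] + np.arange(-1, 3)[None, :]

    p = np.zeros((nb, nb))
    np.add.at(p, (np.repeat(bf, 4), cols.ravel()), w.ravel())
    p /= n
    pf = p.sum(axis=1, keepdims=True)
    pm = p.sum(axis=0, keepdims=True)
    nz = p > 1e-300
    logterm = np.zeros_like(p)
    logterm[nz] = np.log2(p[nz] / (pf @ pm)[nz])
    mi = float(np.sum(p[nz] * logterm[nz]))

    dw = _bspline_weights_d(frac)
    L = logterm[np.repeat(bf, 4), cols.ravel()].reshape(-1, 4)
    dmi_dm = (dw * L).sum(axis=1) * su / n
    dmi_dm[clipped] = 0.0
    dcost_dT = (-dmi_dm)[:, None] * mgrad
    return -mi, dcost_dT, pts


def combined_cost(
    t,
    weights: MetricWeights,
    pairs: PairedPointSet | None = None,
    roi_fixed: LabelMask | None = None,
    roi_moving: LabelMask | None = None,
    fixed: Volume | None = None,
    moving: Volume | None = None,
    mi_config: MIConfig = MIConfig(),
    kappa_candidate: np.ndarray | None = None,
    mi_sample_points: np.ndarray | None = None,
    mi_rng=None,
    mi_sample_mask: np.ndarray | None = None,
    mi_mode: str = "parzen",
):
    """Weighted mean of the three terms: ``(1/Σω) Σ ω_i C_i``.

    With exactly one nonzero weight this equals that component exactly; a
    nonzero-weight metric whose inputs are missing raises an error naming it.
    """
    wf, wr, wi = weights.as_tuple()
    total_w = wf + wr + wi
    value = 0.0
    grad = None

    def _acc(w: float, v: float, g):
        nonlocal value, grad
        value += w * v / total_w
        if g is not None:
            if grad is None:
                grad = np.zeros_like(g)
            grad = grad + (w / total_w) * g

    if wf > 0:
        if pairs is None:
            raise ValueError("fiducial metric has nonzero weight but no point pairs")
        _acc(wf, *fiducial_cost(t, pairs))
    if wr > 0:
        if roi_fixed is None or roi_moving is None:
            raise ValueError("region metric has nonzero weight but ROI masks missing")
        _acc(wr, *kappa_cost(t, roi_fixed, roi_moving, candidate=kappa_candidate))
    if wi > 0:
        if fixed is None or moving is None:
            raise ValueError("intensity metric has nonzero weight but volumes missing")
        _acc(
            wi,
            *mutual_information(
                t,
                fixed,
                moving,
                mi_config,
                sample_points=mi_sample_points,
                rng=mi_rng,
                sample_mask=mi_sample_mask,
                mode=mi_mode,
            ),
        )
    return value, grad
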
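"""Registration pipeline: affine initialization, Gaussian pyramid,
multi-resolution B-spline refinement, stochastic gradient descent on the
weighted multi-metric objective.

The affine stage optimizes mutual information only; fiducial and region
terms join in the deformable stage. Between pyramid levels the control grid
is refined by exact cubic B-spline subdivision, so the represented field is
carried over unchanged.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation, gaussian_filter
from scipy.optimize import minimize

from .geometry import LabelMask, Volume
from .interp import sample_trilinear
from .metrics import (
    MIConfig,
    MetricWeights,
    fiducial_cost,
    intensity_range,
    kappa_cost,
    mi_estimate,
)
from .pointsets import PairedPointSet
from .transforms import (
    AffineTransform,
    BSplineTransform,
    CompositeTransform,
    bspline_grid_for_domain,
    refine_bspline,
)

__all__ = [
    "RegistrationConfig",
    "RegistrationResult",
    "gaussian_pyramid",
    "sgd_minimize",
    "register_affine",
    "register_multimetric",
    "resample_volume",
]


@dataclass(frozen=True)
class RegistrationConfig:
    """Settings for the full pipeline.

    ``grid_spacing_mm`` is the control spacing at the finest level; coarser
    levels use double the spacing of the next finer one (strictly decreasing
    schedule). ``sigmas`` are smoothing widths in voxels per pyramid level,
    coarse to fine; ``None`` derives them from the factors.
    """

    levels: int = 3
    factors: tuple[int, ...] = (4, 2, 1)
    sigmas: tuple[float, ...] | None = None
    grid_spacing_mm: float = 12.0
    max_iterations: int = 500
    affine_iterations: int = 150
    sgd_a: float | None = None
    sgd_A: float = 50.0
    sgd_alpha: float = 0.602
    initial_step_mm: float = 1.0
    tolerance: float = 1e-6
    weights: MetricWeights = field(default_factory=MetricWeights)
    n_bins: int = 32
    n_samples: int = 2048
    kappa_samples: int = 4000
    kappa_margin_mm: float = 20.0
    do_affine: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.max_iterations < 1 or self.affine_iterations < 1:
            raise ValueError("iteration counts must be >= 1")
        if len(self.factors) != self.levels:
            raise ValueError("one downsample factor per level required")
        if self.factors[-1] != 1:
            raise ValueError("the finest level must have factor 1")
        if self.grid_spacing_mm <= 0:
            raise ValueError("grid spacing must be positive")

    def level_sigmas(self) -> tuple[float, ...]:
        if self.sigmas is not None:
            return self.sigmas
        return tuple(max((f - 1) / 2.0, 0.0) for f in self.factors)


@dataclass
class RegistrationResult:
    transform: CompositeTransform
    affine: AffineTransform
    level_traces: list[list[float]]
    iterations: list[int]
    initial_metrics: dict[str, float]
    final_metrics: dict[str, float]
    config: RegistrationConfig
    seed: int
    elapsed_s: float = 0.0
    level_metric_traces: list[list[dict]] = field(default_factory=list)


def gaussian_pyramid(
    volume: Volume,
    levels: int = 3,
    sigmas: tuple[float, ...] | None = None,
    factors: tuple[int, ...] = (4, 2, 1),
) -> list[Volume]:
    """Smooth-then-subsample pyramid, coarsest first.

    Level ``k`` is the input smoothed with ``sigmas[k]`` (voxels) and
    strided by ``factors[k]``; the origin (voxel-0 center) is preserved so
    world geometry stays aligned across levels.
    """
    if sigmas is None:
        sigmas = tuple(max((f - 1) / 2.0, 0.0) for f in factors)
    out = []
    for sigma, f in zip(sigmas, factors):
        data = gaussian_filter(volume.data, sigma, mode="nearest") if sigma > 0 else volume.data
        data = data[::f, ::f, ::f]
        out.append(Volume(data, tuple(s * f for s in volume.spacing), volume.origin))
    return out


def _stride_mask(mask: LabelMask, factor: int) -> LabelMask:
    return LabelMask(
        mask.data[::factor, ::factor, ::factor],
        tuple(s * factor for s in mask.spacing),
        mask.origin,
    )


def sgd_minimize(
    cost_fn,
    init_params: np.ndarray,
    max_iterations: int = 500,
    a: float | None = None,
    A: float = 50.0,
    alpha: float = 0.602,
    initial_step: float = 1.0,
    tolerance: float = 1e-6,
):
    """Gradient descent with decaying gain ``gamma_t = a / (t + A)**alpha``.

    ``cost_fn(params, t)`` returns ``(value, gradient)``; the iteration
    index lets stochastic costs resample deterministically. When ``a`` is
    None it is scaled so the first update moves the largest parameter by
    ``initial_step``. Returns ``(params, trace, n_iterations)``.
    """
    x = np.asarray(init_params, dtype=np.float64).copy()
    trace: list[float] = []
    value, grad = cost_fn(x, 0)
    if not np.isfinite(value) or not np.all(np.isfinite(grad)):
        raise RuntimeError("non-finite cost or gradient at iteration 0")
    if a is None:
        gmax = float(np.max(np.abs(grad)))
        a = 0.0 if gmax == 0.0 else initial_step * (A + 1.0) ** alpha / gmax
    n_done = 0
    for t in range(max_iterations):
        trace.append(float(value))
        gnorm = float(np.linalg.norm(grad))
        if gnorm < tolerance:
            break
        gain = a / (t + A) ** alpha
        x = x - gain * grad
        n_done = t + 1
        if t + 1 < max_iterations:
            value, grad = cost_fn(x, t + 1)
            if not np.isfinite(value) or not np.all(np.isfinite(grad)):
                raise RuntimeError(f"non-finite cost or gradient at iteration {t + 1}")
    return x, trace, n_done


def _sample_pool(fixed: Volume, sample_mask: np.ndarray | None):
    """Fixed-grid sample candidates: world points and their intensities."""
    if sample_mask is not None:
        idx = np.argwhere(np.asarray(sample_mask, dtype=bool)).astype(np.float64)
    else:
        idx = np.indices(fixed.shape, dtype=np.float64).reshape(3, -1).T
    pts = idx * np.asarray(fixed.spacing) + np.asarray(fixed.origin)
    fvals = fixed.data[tuple(idx.astype(np.int64).T)]
    return pts, fvals


def _dense_pool(pts: np.ndarray, fvals: np.ndarray, cap: int = 80_000):
    """Deterministic subset for dense-mode (reporting) evaluations."""
    if pts.shape[0] <= cap:
        return pts, fvals
    stride = int(np.ceil(pts.shape[0] / cap))
    return pts[::stride], fvals[::stride]


def register_affine(
    fixed: Volume,
    moving: Volume,
    cfg: RegistrationConfig = RegistrationConfig(),
    sample_mask: np.ndarray | None = None,
) -> AffineTransform:
    """MI-driven affine alignment on the coarsest pyramid level.

    Minimizes Parzen-window negative MI over a deterministic sample set with
    L-BFGS and analytic gradients (12 parameters, centered and scaled so
    matrix and translation entries are commensurate). The result is
    guaranteed no worse than the identity under the dense histogram-mode MI
    (the identity is returned otherwise).
    """
    sig = cfg.level_sigmas()
    fixed_c = gaussian_pyramid(fixed, cfg.levels, sig, cfg.factors)[0]
    moving_c = gaussian_pyramid(moving, cfg.levels, sig, cfg.factors)[0]
    mask_c = None
    if sample_mask is not None:
        f = cfg.factors[0]
        mask_c = np.asarray(sample_mask, dtype=bool)[::f, ::f, ::f]

    mi_cfg = MIConfig(
        n_bins=cfg.n_bins,
        n_samples=cfg.n_samples,
        fixed_range=intensity_range(fixed_c),
        moving_range=intensity_range(moving_c),
    )
    pool_pts, pool_f = _sample_pool(fixed_c, mask_c)
    gen = np.random.default_rng([cfg.seed, 7919])
    n = min(4 * cfg.n_samples, pool_pts.shape[0])
    pick = gen.choice(pool_pts.shape[0], size=n, replace=False)
    pts, fvals = pool_pts[pick], pool_f[pick]
    ext = fixed.extent_mm
    center = ext.mean(axis=0)
    radius = float(np.linalg.norm((ext[1] - ext[0]) / 2.0)) or 1.0

    def build(q: np.ndarray) -> AffineTransform:
        m = np.eye(3) + q[:9].reshape(3, 3) / radius
        t = center - m @ center + q[9:]
        return AffineTransform(m, t)

    def cost(q: np.ndarray):
        value, dcost_dT, used = mi_estimate(
            build(q), fixed_c, moving_c, mi_cfg, pts, fvals, mode="parzen"
        )
        xc = (used - center) / radius
        g = np.empty(12)
        g[:9] = (dcost_dT[:, :, None] * xc[:, None, :]).sum(axis=0).ravel()
        g[9:] = dcost_dT.sum(axis=0)
        return value, g

    try:
        opt = minimize(
            cost,
            np.zeros(12),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": cfg.affine_iterations},
        )
        q = opt.x
    except ValueError as exc:  # insufficient overlap
        raise ValueError(f"affine initialization failed: {exc}") from exc

    dense_pts, dense_f = _dense_pool(pool_pts, pool_f)
    result = build(q)

    def dense_mi(aff):
        v, _, _ = mi_estimate(aff, fixed_c, moving_c, mi_cfg, dense_pts, dense_f, mode="histogram")
        return v

    if dense_mi(result) > dense_mi(AffineTransform.identity()):
        return AffineTransform.identity()
    return result


class _LevelObjective:
    """Per-level combined cost with cached B-spline weight matrices.

    Equivalent to :func:`mmdir.metrics.combined_cost`, but the fixed-point
    weight matrices of the kappa term are built once per level instead of
    per iteration (the candidate voxels do not move).
    """

    def __init__(
        self,
        level: int,
        cfg: RegistrationConfig,
        affine: AffineTransform,
        template: BSplineTransform,
        fixed: Volume,
        moving: Volume,
        pairs: PairedPointSet | None,
        roi_fixed: LabelMask | None,
        roi_moving: LabelMask | None,
        sample_mask: np.ndarray | None,
        rng_key: int,
    ):
        self.level = level
        self.cfg = cfg
        self.affine = affine
        self.template = template
        self.fixed = fixed
        self.moving = moving
        self.pairs = pairs
        self.roi_fixed = roi_fixed
        self.roi_moving = roi_moving
        self.rng_key = rng_key
        self.history: list[dict] = []
        w = cfg.weights
        self.mi_cfg = MIConfig(
            n_bins=cfg.n_bins,
            n_samples=cfg.n_samples,
            fixed_range=intensity_range(fixed),
            moving_range=intensity_range(moving),
        )
        self.pool_pts, self.pool_f = _sample_pool(fixed, sample_mask)
        self.dense_pts, self.dense_f = _dense_pool(self.pool_pts, self.pool_f)

        self.W_fid = None
        if w.fiducial > 0 and pairs is not None:
            self.W_fid = template.weight_matrix(pairs.fixed_points)

        self.kappa_pts = None
        if w.region > 0 and roi_fixed is not None and roi_moving is not None:
            margin = np.maximum(
                np.ceil(cfg.kappa_margin_mm / np.asarray(roi_fixed.spacing)).astype(int), 1
            )
            cand = _box_dilate(roi_fixed.data, margin)
            idx = np.argwhere(cand)
            gen = np.random.default_rng([cfg.seed, 104729, rng_key, level])
            if idx.shape[0] > cfg.kappa_samples:
                pick = gen.choice(idx.shape[0], size=cfg.kappa_samples, replace=False)
                idx = idx[pick]
            self.kappa_a = roi_fixed.data[tuple(idx.T)].astype(np.float64)
            self.kappa_pts = idx.astype(np.float64) * np.asarray(
                roi_fixed.spacing
            ) + np.asarray(roi_fixed.origin)
            self.W_kappa = template.weight_matrix(self.kappa_pts)
            self.kappa_aff = affine.apply(self.kappa_pts)
            # deterministic subset of the candidate region for dense
            # (reporting/guard) evaluations — unbiased for the KS ratio
            dense_idx = np.argwhere(cand)
            if dense_idx.shape[0] > 20_000:
                dense_idx = dense_idx[:: int(np.ceil(dense_idx.shape[0] / 20_000))]
            self.kappa_dense = np.zeros_like(cand)
            self.kappa_dense[tuple(dense_idx.T)] = True

    # -- term evaluations ---------------------------------------------------

    def _fiducial(self, t, flat_coeffs):
        value, grad = None, None
        xf = self.pairs.fixed_points
        mapped = self.affine.apply(xf) + (self.W_fid @ flat_coeffs)
        diff = self.pairs.moving_points - mapped
        d = np.linalg.norm(diff, axis=1)
        value = float(d.mean())
        safe = np.where(d > 0, d, 1.0)
        dT = -(diff / safe[:, None]) / len(self.pairs)
        dT[d == 0] = 0.0
        grad = np.column_stack([self.W_fid.T @ dT[:, c] for c in range(3)])
        return value, grad

    def _kappa(self, flat_coeffs):
        mapped = self.kappa_aff + self.W_kappa @ flat_coeffs
        b, gb, _ = sample_trilinear(self.roi_moving, mapped, with_gradient=True)
        a = self.kappa_a
        na, nb_, nab = a.sum(), b.sum(), float(a @ b)
        denom = na + nb_
        value = 1.0 - 2.0 * nab / denom
        dcost_db = -(2.0 * a * denom - 2.0 * nab) / denom**2
        dT = dcost_db[:, None] * gb
        grad = np.column_stack([self.W_kappa.T @ dT[:, c] for c in range(3)])
        return value, grad

    def _mi(self, t, it: int):
        gen = np.random.default_rng([self.cfg.seed, 15485863, self.rng_key, self.level, it])
        n = min(self.cfg.n_samples, self.pool_pts.shape[0])
        pick = gen.choice(self.pool_pts.shape[0], size=n, replace=False)
        value, dcost_dT, used = mi_estimate(
            t, self.fixed, self.moving, self.mi_cfg, self.pool_pts[pick],
            self.pool_f[pick], mode="parzen",
        )
        bsp = t.bspline
        W = bsp.weight_matrix(used)
        grad = np.column_stack([W.T @ dcost_dT[:, c] for c in range(3)])
        return value, grad

    def __call__(self, params: np.ndarray, it: int):
        flat = params.reshape(-1, 3)
        bsp = self.template.with_coefficients(params)
        t = CompositeTransform((self.affine, bsp))
        w = self.cfg.weights
        total = w.fiducial + w.region + w.intensity
        value = 0.0
        grad = np.zeros_like(flat)
        parts = {"fiducial": np.nan, "region": np.nan, "intensity": np.nan}
        if w.fiducial > 0:
            v, g = self._fiducial(t, flat)
            parts["fiducial"] = v
            value += w.fiducial * v / total
            grad += (w.fiducial / total) * g
        if w.region > 0:
            v, g = self._kappa(flat)
            parts["region"] = v
            value += w.region * v / total
            grad += (w.region / total) * g
        if w.intensity > 0:
            v, g = self._mi(t, it)
            parts["intensity"] = v
            value += w.intensity * v / total
            grad += (w.intensity / total) * g
        self.history.append({"iteration": it, "total": value, **parts})
        return value, grad.ravel()

    def dense_value(self, params: np.ndarray) -> float:
        """Deterministic (histogram-mode MI, full candidate) combined cost."""
        bsp = self.template.with_coefficients(params)
        t = CompositeTransform((self.affine, bsp))
        w = self.cfg.weights
        total = w.fiducial + w.region + w.intensity
        value = 0.0
        if w.fiducial > 0:
            v, _ = fiducial_cost(t, self.pairs)
            value += w.fiducial * v / total
        if w.region > 0:
            v, _ = kappa_cost(t, self.roi_fixed, self.roi_moving, candidate=self.kappa_dense)
            value += w.region * v / total
        if w.intensity > 0:
            v, _, _ = mi_estimate(
                t, self.fixed, self.moving, self.mi_cfg, self.dense_pts, self.dense_f,
                mode="histogram",
            )
            value += w.intensity * v / total
        return value


def _box_dilate(mask: np.ndarray, margin: np.ndarray) -> np.ndarray:
    out = mask.copy()
    for ax, m in enumerate(margin):
        if m <= 0:
            continue
        kernel_shape = [1, 1, 1]
        kernel_shape[ax] = 2 * int(m) + 1
        out = binary_dilation(out, structure=np.ones(kernel_shape, bool))
    return out


def register_multimetric(
    fixed: Volume,
    moving: Volume,
    cfg: RegistrationConfig = RegistrationConfig(),
    pairs: PairedPointSet | None = None,
    roi_fixed: LabelMask | None = None,
    roi_moving: LabelMask | None = None,
    fixed_body: LabelMask | None = None,
) -> RegistrationResult:
    """Full pipeline: affine stage, then per-level B-spline optimization.

    Metrics with nonzero weight must have their inputs; ``fixed_body``
    optionally restricts intensity sampling to the patient body. The dense
    combined cost at the solution never exceeds its value at the affine-only
    initialization (the initialization is returned otherwise).
    """
    w = cfg.weights
    if w.fiducial > 0 and pairs is None:
        raise ValueError("fiducial metric has nonzero weight but no point pairs")
    if w.region > 0 and (roi_fixed is None or roi_moving is None):
        raise ValueError("region metric has nonzero weight but ROI masks missing")
    if roi_fixed is not None:
        roi_fixed.check_matches(fixed)
    if fixed_body is not None:
        fixed_body.check_matches(fixed)
    if roi_moving is not None:
        roi_moving.check_matches(moving)

    t0 = time.perf_counter()
    body = fixed_body.data if fixed_body is not None else None
    affine = (
        register_affine(fixed, moving, cfg, sample_mask=body)
        if cfg.do_affine
        else AffineTransform.identity()
    )

    sig = cfg.level_sigmas()
    fixed_pyr = gaussian_pyramid(fixed, cfg.levels, sig, cfg.factors)
    moving_pyr = gaussian_pyramid(moving, cfg.levels, sig, cfg.factors)

    ext = fixed.extent_mm
    coarse_spacing = cfg.grid_spacing_mm * 2 ** (cfg.levels - 1)
    bsp = bspline_grid_for_domain(ext[0], ext[1], coarse_spacing)

    traces: list[list[float]] = []
    iters: list[int] = []
    objectives: list[_LevelObjective] = []
    for level in range(cfg.levels):
        f = cfg.factors[level]
        roi_fixed_l = _stride_mask(roi_fixed, f) if roi_fixed is not None else None
        body_l = body[::f, ::f, ::f] if body is not None else None
        obj = _LevelObjective(
            level,
            cfg,
            affine,
            bsp,
            fixed_pyr[level],
            moving_pyr[level],
            pairs,
            roi_fixed_l,
            roi_moving,
            body_l,
            rng_key=31,
        )
        objectives.append(obj)
        params0 = bsp.coefficients.ravel().copy()
        start_dense = obj.dense_value(params0)
        params, trace, n_it = sgd_minimize(
            obj,
            params0,
            max_iterations=cfg.max_iterations,
            a=cfg.sgd_a,
            A=cfg.sgd_A,
            alpha=cfg.sgd_alpha,
            initial_step=cfg.initial_step_mm,
            tolerance=cfg.tolerance,
        )
        if obj.dense_value(params) > start_dense:  # keep the level monotone
            params = params0
        traces.append(trace)
        iters.append(n_it)
        bsp = bsp.with_coefficients(params)
        if level + 1 < cfg.levels:
            bsp = refine_bspline(bsp)

    final = CompositeTransform((affine, bsp))
    finest = objectives[-1]
    zero = np.zeros(bsp.coefficients.size)
    init_dense = finest.dense_value(zero)
    final_dense = finest.dense_value(bsp.coefficients.ravel())
    if final_dense > init_dense + 1e-9:
        bsp = bsp.with_coefficients(zero)
        final = CompositeTransform((affine, bsp))
        final_dense = init_dense

    def _report(t) -> dict[str, float]:
        out: dict[str, float] = {}
        if pairs is not None:
            out["fiducial_mm"], _ = fiducial_cost(t, pairs)
        if roi_fixed is not None and roi_moving is not None:
            margin = np.maximum(
                np.ceil(cfg.kappa_margin_mm / np.asarray(roi_fixed.spacing)).astype(int), 1
            )
            cand = _box_dilate(roi_fixed.data, margin)
            v, _ = kappa_cost(t, roi_fixed, roi_moving, candidate=cand)
            out["kappa"] = 1.0 - v
        v, _, _ = mi_estimate(
            t, finest.fixed, finest.moving, finest.mi_cfg, finest.dense_pts,
            finest.dense_f, mode="histogram",
        )
        out["mi_bits"] = -v
        out["combined"] = finest.dense_value(
            t.bspline.coefficients.ravel()
            if t.bspline is not None
            else np.zeros(bsp.coefficients.size)
        )
        return out

    init_metrics = _report(CompositeTransform((affine, bsp.with_coefficients(zero))))
    final_metrics = _report(final)
    return RegistrationResult(
        transform=final,
        affine=affine,
        level_traces=traces,
        iterations=iters,
        initial_metrics=init_metrics,
        final_metrics=final_metrics,
        config=cfg,
        seed=cfg.seed,
        elapsed_s=time.perf_counter() - t0,
        level_metric_traces=[obj.history for obj in objectives],
    )


def resample_volume(moving: Volume, t, like: Volume, fill: float = 0.0) -> Volume:
    """Moving image resampled on the grid of ``like`` through ``t``."""
    pts = like.voxel_centers()
    vals = sample_trilinear(moving, t.apply(pts), fill=fill)
    return Volume(vals.reshape(like.shape), like.spacing, like.origin)
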
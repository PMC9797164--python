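"""Synthetic resection phantom.

Generates a paired "pre-operative" (moving) and "post-operative" (fixed)
CT-like volume with a known smooth ground-truth deformation and, optionally,
surgical non-correspondence: the tumor region of the warped volume is
replaced by a seroma-like cavity with bright marker clips on its rim.

The anatomy is deliberately primitive-based: a chest-wall slab with
rib-like rods (rigid landmark group), a hemispherical breast of fat with a
textured gland blob (intensity/region/soft-tissue signal) and a nipple bump
on the skin (boundary landmark group).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .contours import expand_margin, skin_limit_mask
from .geometry import LabelMask, Volume
from .interp import sample_trilinear
from .pointsets import PairedPointSet
from .transforms import BSplineTransform, bspline_grid_for_domain, refine_bspline

__all__ = [
    "PhantomConfig",
    "PhantomCase",
    "generate_phantom",
    "random_smooth_deformation",
    "simulate_resection",
]


@dataclass(frozen=True)
class PhantomConfig:
    shape: tuple[int, int, int] = (96, 96, 48)
    spacing: tuple[float, float, float] = (1.5, 1.5, 3.0)
    background: float = 0.0
    fat: float = 100.0
    muscle: float = 120.0
    gland: float = 104.0
    tumor_intensity: float = 110.0
    rib: float = 400.0
    clip: float = 1000.0
    seroma: float = 55.0
    texture_amplitude: float = 5.0
    texture_sigma_vox: float = 2.0
    tumor_center_mm: tuple[float, float, float] | None = None
    tumor_radius_mm: float = 8.0
    deformation_amplitude_mm: float = 25.0
    deformation_spacing_mm: float = 48.0
    deformation_fine_amplitude_mm: float = 0.0
    n_soft: int = 20
    n_rigid: int = 5
    n_boundary: int = 5
    n_fiducials: int = 30
    n_clips: int = 6
    fiducial_jitter_mm: float = 0.5
    cavity_margin_mm: float = 10.0
    cavity_offset_mm: float = 18.0
    noise_sd: float = 4.0
    resection: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clips < 5:
            raise ValueError("at least five clips are required")
        if self.n_soft + self.n_rigid + self.n_boundary < 1:
            raise ValueError("at least one evaluation landmark required")
        if self.n_fiducials < 1:
            raise ValueError("at least one fiducial pair required")
        if self.tumor_radius_mm <= 0:
            raise ValueError("tumor radius must be positive")
        if self.deformation_amplitude_mm < 0:
            raise ValueError("deformation amplitude must be non-negative")


@dataclass
class PhantomCase:
    moving: Volume
    fixed: Volume
    gt_transform: BSplineTransform
    landmarks: PairedPointSet
    fiducials: PairedPointSet
    gland_moving: LabelMask
    gland_fixed: LabelMask
    body_moving: LabelMask
    body_fixed: LabelMask
    tumor_moving: LabelMask
    tumor_bed: LabelMask
    boost_ctv: LabelMask
    config: PhantomConfig


class _Anatomy:
    """Analytic shape predicates in moving-image world coordinates (mm)."""

    def __init__(self, cfg: PhantomConfig):
        ext = (np.asarray(cfg.shape) - 1) * np.asarray(cfg.spacing)
        self.ext = ext
        cx, cz = ext[0] / 2.0, ext[2] / 2.0
        self.wall_y = 0.25 * ext[1]
        self.breast_center = np.array([cx, self.wall_y, cz])
        self.breast_semi = np.array([0.40 * ext[0], 0.52 * ext[1], 0.40 * ext[2]])
        self.gland_center = np.array([cx, self.wall_y + 0.18 * ext[1], cz])
        self.gland_semi = np.array([38.0, 30.0, 38.0])
        apex_y = self.wall_y + self.breast_semi[1]
        self.nipple_center = np.array([cx, apex_y - 2.0, cz])
        self.nipple_radius = 7.0
        self.rib_y = 0.14 * ext[1]
        self.rib_z = np.array([0.25, 0.5, 0.75]) * ext[2]
        self.rib_radius = 4.0
        if cfg.tumor_center_mm is not None:
            self.tumor_center = np.asarray(cfg.tumor_center_mm, dtype=np.float64)
        else:
            self.tumor_center = self.gland_center + np.array([4.0, 2.0, -4.0])
        self.tumor_radius = cfg.tumor_radius_mm

    def slab(self, p):
        return p[:, 1] <= self.wall_y

    def breast(self, p):
        u = (p - self.breast_center) / self.breast_semi
        return (np.sum(u**2, axis=1) <= 1.0) & (p[:, 1] >= self.wall_y)

    def nipple(self, p):
        return np.linalg.norm(p - self.nipple_center, axis=1) <= self.nipple_radius

    def body(self, p):
        return self.slab(p) | self.breast(p) | self.nipple(p)

    def gland(self, p):
        u = (p - self.gland_center) / self.gland_semi
        return np.sum(u**2, axis=1) <= 1.0

    def tumor(self, p):
        return np.linalg.norm(p - self.tumor_center, axis=1) <= self.tumor_radius

    def ribs(self, p):
        hit = np.zeros(p.shape[0], dtype=bool)
        for zc in self.rib_z:
            hit |= (p[:, 1] - self.rib_y) ** 2 + (p[:, 2] - zc) ** 2 <= self.rib_radius**2
        return hit & self.slab(p)


def random_smooth_deformation(
    domain_lo,
    domain_hi,
    control_spacing_mm: float = 48.0,
    amplitude_mm: float = 12.0,
    seed: int = 0,
) -> BSplineTransform:
    """Random B-spline field, coefficients i.i.d. uniform in ±amplitude,
    tapered to zero over the outer three knot rows of the domain edge.

    By the partition of unity the displacement magnitude never exceeds
    ``amplitude_mm * sqrt(3)`` per component bound ``amplitude_mm``;
    amplitude 0 is the identity.
    """
    template = bspline_grid_for_domain(domain_lo, domain_hi, control_spacing_mm)
    shape = template.coefficients.shape
    rng = np.random.default_rng(seed)
    coeffs = rng.uniform(-amplitude_mm, amplitude_mm, size=shape)
    for ax in range(3):
        n = shape[ax]
        i = np.arange(n, dtype=np.float64)
        ramp = np.clip(np.minimum(i, n - 1 - i) / 3.0, 0.0, 1.0)
        view = [None, None, None, None]
        view[ax] = slice(None)
        coeffs *= ramp[tuple(view)]
    return template.with_coefficients(coeffs)


def simulate_resection(
    volume: Volume,
    tumor: LabelMask,
    cfg: PhantomConfig,
    rng: np.random.Generator | None = None,
) -> tuple[Volume, LabelMask]:
    """Replace the (dilated) tumor region with seroma and insert rim clips.

    The cavity center is displaced from the tumor by ``cavity_offset_mm``
    in a random direction (asymmetric excision: the resection cavity is not
    a uniform expansion of the tumor). Returns the post-operative volume
    and the cavity mask. Voxels outside the cavity are bit-exact copies of
    the input.
    """
    if tumor.n_foreground == 0:
        raise ValueError("tumor mask is empty")
    tumor.check_matches(volume)
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    seed_mask = tumor
    if cfg.cavity_offset_mm > 0:
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        shift = np.round(cfg.cavity_offset_mm * direction / np.asarray(volume.spacing))
        shifted = np.zeros_like(tumor.data)
        src = np.argwhere(tumor.data) + shift.astype(int)
        ok = np.all((src >= 0) & (src < np.asarray(tumor.shape)), axis=1)
        shifted[tuple(src[ok].T)] = True
        if shifted.any():
            seed_mask = LabelMask(shifted, tumor.spacing, tumor.origin)
    cavity = expand_margin(seed_mask, cfg.cavity_margin_mm)
    data = volume.data.copy()
    n_cavity = cavity.n_foreground
    data[cavity.data] = cfg.seroma + rng.normal(0.0, cfg.noise_sd, size=n_cavity)

    struct = ndimage.generate_binary_structure(3, 1)
    rim = cavity.data & ~ndimage.binary_erosion(cavity.data, struct, border_value=0)
    rim_idx = np.argwhere(rim)
    if rim_idx.shape[0] < cfg.n_clips:
        raise ValueError("cavity rim too small for requested clip count")
    pick = _farthest_points(rim_idx.astype(np.float64) * np.asarray(volume.spacing),
                            cfg.n_clips, rng)
    for i in pick:
        data[tuple(rim_idx[i])] = cfg.clip
    return Volume(data, volume.spacing, volume.origin), cavity


def _farthest_points(pts: np.ndarray, n: int, rng: np.random.Generator) -> list[int]:
    """Greedy farthest-point subset indices (spreads selections out)."""
    chosen = [int(rng.integers(pts.shape[0]))]
    d = np.linalg.norm(pts - pts[chosen[0]], axis=1)
    while len(chosen) < n:
        nxt = int(np.argmax(d))
        chosen.append(nxt)
        d = np.minimum(d, np.linalg.norm(pts - pts[nxt], axis=1))
    return chosen


def _invert_points(bsp: BSplineTransform, targets: np.ndarray, iters: int = 200) -> np.ndarray:
    """Solve T(x) = target by fixed-point iteration (contractive field)."""
    x = targets.copy()
    for _ in range(iters):
        x = targets - bsp.displacement(x)
    return x


def generate_phantom(cfg: PhantomConfig = PhantomConfig()) -> PhantomCase:
    """Build a deterministic phantom case from the configuration."""
    anat = _Anatomy(cfg)
    rng_tex = np.random.default_rng([cfg.seed, 1])
    rng_def = np.random.default_rng([cfg.seed, 2])
    rng_noise = np.random.default_rng([cfg.seed, 3])
    rng_marks = np.random.default_rng([cfg.seed, 4])
    rng_resect = np.random.default_rng([cfg.seed, 5])

    shape = cfg.shape
    spacing = np.asarray(cfg.spacing)
    idx = np.indices(shape, dtype=np.float64).reshape(3, -1).T
    pts = idx * spacing  # origin (0,0,0)

    # --- moving (pre-operative) volume, noise-free ------------------------
    data = np.full(pts.shape[0], cfg.background)
    data[anat.slab(pts)] = cfg.muscle
    data[anat.breast(pts) | anat.nipple(pts)] = cfg.fat
    gland_m = anat.gland(pts)
    texture = ndimage.gaussian_filter(
        rng_tex.standard_normal(shape), cfg.texture_sigma_vox, mode="nearest"
    )
    texture *= cfg.texture_amplitude / max(texture.std(), 1e-12)
    data[gland_m] = cfg.gland + texture.ravel()[gland_m]
    tumor_m = anat.tumor(pts)
    data[tumor_m] = cfg.tumor_intensity
    data[anat.ribs(pts)] = cfg.rib
    moving_clean = Volume(data.reshape(shape), cfg.spacing, (0.0, 0.0, 0.0))

    gland_moving = LabelMask(gland_m.reshape(shape), cfg.spacing)
    body_moving = LabelMask(anat.body(pts).reshape(shape), cfg.spacing)
    tumor_moving = LabelMask(tumor_m.reshape(shape), cfg.spacing)
    if np.any(tumor_moving.data & ~gland_moving.data):
        raise ValueError("tumor is not strictly inside the gland region")

    # --- ground-truth deformation and fixed (post-operative) volume -------
    lo, hi = moving_clean.extent_mm
    gt = random_smooth_deformation(
        lo, hi, cfg.deformation_spacing_mm, cfg.deformation_amplitude_mm,
        seed=rng_def.integers(2**31),
    )
    if cfg.deformation_fine_amplitude_mm > 0 and cfg.deformation_amplitude_mm > 0:
        # second, half-spacing component: complex local deformation that a
        # smooth interpolation from skin/rib anchors cannot reproduce
        gt = refine_bspline(gt)
        fine = random_smooth_deformation(
            lo, hi, cfg.deformation_spacing_mm / 2.0,
            cfg.deformation_fine_amplitude_mm, seed=rng_def.integers(2**31),
        )
        coeffs = gt.coefficients.copy()
        off = np.round(
            (fine.grid_origin - gt.grid_origin) / gt.grid_spacing
        ).astype(int)
        fshape = np.asarray(fine.grid_shape)
        gshape = np.asarray(gt.grid_shape)
        g_lo = np.maximum(off, 0)
        g_hi = np.minimum(off + fshape, gshape)
        f_lo = g_lo - off
        f_hi = g_hi - off
        coeffs[
            g_lo[0] : g_hi[0], g_lo[1] : g_hi[1], g_lo[2] : g_hi[2]
        ] += fine.coefficients[
            f_lo[0] : f_hi[0], f_lo[1] : f_hi[1], f_lo[2] : f_hi[2]
        ]
        gt = gt.with_coefficients(coeffs)
    mapped = gt.apply(pts)
    fixed_data = sample_trilinear(moving_clean, mapped, fill=cfg.background)
    fixed_clean = Volume(fixed_data.reshape(shape), cfg.spacing, (0.0, 0.0, 0.0))

    gland_fixed = LabelMask(anat.gland(mapped).reshape(shape), cfg.spacing)
    body_fixed = LabelMask(anat.body(mapped).reshape(shape), cfg.spacing)
    tumor_fixed = LabelMask(anat.tumor(mapped).reshape(shape), cfg.spacing)

    moving = moving_clean.with_data(
        moving_clean.data + rng_noise.normal(0.0, cfg.noise_sd, shape)
    )
    fixed = fixed_clean.with_data(
        fixed_clean.data + rng_noise.normal(0.0, cfg.noise_sd, shape)
    )

    if cfg.resection:
        fixed, tumor_bed = simulate_resection(fixed, tumor_fixed, cfg, rng_resect)
    else:
        tumor_bed = expand_margin(tumor_fixed, cfg.cavity_margin_mm)

    boost_ctv = expand_margin(
        tumor_bed, 10.0, limit=skin_limit_mask(body_fixed, 5.0)
    )

    # --- landmarks --------------------------------------------------------
    # exclude the moving-space image of the resection cavity (plus a small
    # buffer): points there have no post-operative correspondence
    from scipy.spatial import cKDTree

    cavity_moving = gt.apply(tumor_bed.foreground_world())
    near_cavity = (
        cKDTree(cavity_moving).query(pts, distance_upper_bound=4.0)[0] < np.inf
    )
    tumor_dist = np.linalg.norm(pts - anat.tumor_center, axis=1)
    soft_cand = (
        gland_m
        & ~near_cavity
        & (tumor_dist > cfg.tumor_radius_mm + 3.0)
        & (tumor_dist < 50.0)
    )
    # objective fiducials live in the gland interior so that gland-surface
    # information enters only through the region term
    u = (pts - anat.gland_center) / anat.gland_semi
    interior = np.sum(u**2, axis=1) <= 0.85**2
    fid_cand = soft_cand & interior
    rigid_cand = anat.ribs(pts)
    nipple_d = np.linalg.norm(pts - anat.nipple_center, axis=1)
    bnd_cand = body_moving.data.ravel() & (nipple_d <= anat.nipple_radius + 6.0)

    def _pick_group(cand: np.ndarray, n: int, label: str):
        cand_pts = pts[cand]
        if cand_pts.shape[0] < n:
            raise ValueError(f"not enough candidate voxels for {label} landmarks")
        sel = _farthest_points(cand_pts, min(3 * n, cand_pts.shape[0]), rng_marks)
        chosen = cand_pts[sel[:n]] if len(sel) >= n else cand_pts[sel]
        return chosen

    fid_m = _pick_group(fid_cand, cfg.n_fiducials, "fiducial")
    soft_m = _pick_group(soft_cand, cfg.n_soft + 5, "soft-tissue")
    # held-out evaluation points must not reuse objective fiducials
    too_close = (
        np.linalg.norm(soft_m[:, None, :] - fid_m[None, :, :], axis=2).min(axis=1) < 1e-6
    )
    soft_m = soft_m[~too_close][: cfg.n_soft]
    rigid_m = _pick_group(rigid_cand, cfg.n_rigid, "rigid")
    bnd_m = _pick_group(bnd_cand, cfg.n_boundary, "boundary")

    def _pair(moving_pts: np.ndarray, groups):
        fixed_pts = _invert_points(gt, moving_pts)
        inside = np.all((fixed_pts >= lo) & (fixed_pts <= hi), axis=1)
        return PairedPointSet(fixed_pts[inside], moving_pts[inside],
                              tuple(g for g, ok in zip(groups, inside) if ok))

    marks_m = np.vstack([soft_m, rigid_m, bnd_m])
    groups = (
        ("soft_tissue",) * soft_m.shape[0]
        + ("rigid",) * rigid_m.shape[0]
        + ("boundary",) * bnd_m.shape[0]
    )
    landmarks = _pair(marks_m, groups)
    fiducials = _pair(fid_m, ("unassigned",) * fid_m.shape[0])
    if cfg.fiducial_jitter_mm > 0:
        # objective fiducials carry a localization error (confirmation on
        # thick slices is imperfect); held-out evaluation landmarks do not
        jitter = rng_marks.normal(0.0, cfg.fiducial_jitter_mm,
                                  fiducials.moving_points.shape)
        fiducials = PairedPointSet(
            fiducials.fixed_points, fiducials.moving_points + jitter,
            fiducials.groups,
        )

    return PhantomCase(
        moving=moving,
        fixed=fixed,
        gt_transform=gt,
        landmarks=landmarks,
        fiducials=fiducials,
        gland_moving=gland_moving,
        gland_fixed=gland_fixed,
        body_moving=body_moving,
        body_fixed=body_fixed,
        tumor_moving=tumor_moving,
        tumor_bed=tumor_bed,
        boost_ctv=boost_ctv,
        config=cfg,
    )
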
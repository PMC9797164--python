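import numpy as np
import pytest
from scipy import ndimage

from mmdir.evaluation import target_registration_error
from mmdir.geometry import Volume
from mmdir.interp import sample_trilinear
from mmdir.phantom import PhantomConfig, generate_phantom
from mmdir.pointsets import PairedPointSet
from mmdir.registration import (
    RegistrationConfig,
    gaussian_pyramid,
    register_affine,
    register_multimetric,
    sgd_minimize,
)

FAST = RegistrationConfig(max_iterations=40, affine_iterations=60, seed=3)
# high-contrast variant: the tiny grid needs visible structure for MI
SMALL_PHANTOM = PhantomConfig(
    shape=(48, 48, 24), spacing=(3.0, 3.0, 6.0),
    deformation_amplitude_mm=16.0, resection=False, seed=21,
    fiducial_jitter_mm=0.0, gland=140.0, texture_amplitude=25.0,
)


class TestGaussianPyramid:
    def test_constant_invariance(self):
        v = Volume(np.full((32, 32, 32), 7.5))
        for level in gaussian_pyramid(v):
            assert np.allclose(level.data, 7.5)

    def test_shapes(self, rng):
        v = Volume(rng.uniform(0, 1, (64, 64, 64)))
        shapes = [lv.shape for lv in gaussian_pyramid(v, factors=(4, 2, 1))]
        assert shapes == [(16, 16, 16), (32, 32, 32), (64, 64, 64)]

    def test_world_extents_preserved(self, aniso_volume):
        for level, f in zip(gaussian_pyramid(aniso_volume), (4, 2, 1)):
            assert level.origin == aniso_volume.origin
            assert np.allclose(level.spacing, np.asarray(aniso_volume.spacing) * f)

    def test_impulse_matches_convolution_oracle(self):
        data = np.zeros((32, 32, 32))
        data[16, 16, 16] = 1.0
        v = Volume(data)
        sigma, factor = 1.5, 2
        level = gaussian_pyramid(v, levels=1, sigmas=(sigma,), factors=(factor,))[0]
        # independent oracle: explicit separable kernel, then stride
        r = int(4.0 * sigma + 0.5)
        x = np.arange(-r, r + 1)
        k = np.exp(-0.5 * x**2 / sigma**2)
        k /= k.sum()
        smoothed = data
        for ax in range(3):
            smoothed = ndimage.correlate1d(smoothed, k, axis=ax, mode="nearest")
        assert np.abs(level.data - smoothed[::factor, ::factor, ::factor]).max() < 1e-6


class TestSGD:
    @staticmethod
    def quadratic(center):
        def cost(x, _):
            return float(np.sum((x - center) ** 2)), 2.0 * (x - center)

        return cost

    def test_quadratic_bowl(self):
        c = np.array([3.0, -2.0, 1.0])
        x, trace, n = sgd_minimize(self.quadratic(c), np.zeros(3), max_iterations=500)
        assert np.abs(x - c).max() < 1e-3
        assert n <= 500

    def test_stationary_start_early_stop(self):
        c = np.array([1.0, 2.0, 3.0])
        x, trace, n = sgd_minimize(self.quadratic(c), c.copy(), max_iterations=500)
        assert np.array_equal(x, c)
        assert n == 0

    def test_seed_determinism(self):
        def noisy(x, t):
            gen = np.random.default_rng([9, t])
            g = 2.0 * x + gen.normal(0, 0.1, x.shape)
            return float(np.sum(x**2)), g

        x1, tr1, _ = sgd_minimize(noisy, np.ones(4), max_iterations=50)
        x2, tr2, _ = sgd_minimize(noisy, np.ones(4), max_iterations=50)
        assert np.array_equal(x1, x2)
        assert tr1 == tr2

    def test_nonfinite_raises_with_iteration(self):
        def bad(x, t):
            return (np.inf, np.zeros_like(x)) if t >= 3 else (1.0, np.ones_like(x))

        with pytest.raises(RuntimeError, match="iteration 3"):
            sgd_minimize(bad, np.zeros(2), max_iterations=10)


def smooth_volume(rng, shape=(40, 40, 40), spacing=(2.0, 2.0, 2.0)):
    data = ndimage.gaussian_filter(rng.uniform(0, 100, shape), 2.0)
    return Volume(data, spacing)


class TestRegisterAffine:
    def test_self_registration_near_identity(self, rng):
        v = smooth_volume(rng)
        cfg = RegistrationConfig(levels=2, factors=(2, 1), affine_iterations=80, seed=1)
        aff = register_affine(v, v, cfg)
        assert np.linalg.norm(aff.translation + (aff.matrix - np.eye(3)) @ [40, 40, 40]) < 1.0

    def test_translation_recovered(self, rng):
        v = smooth_volume(rng, shape=(48, 48, 48))
        moving = Volume(v.data, v.spacing, origin=(6.0, -4.0, 5.0))
        cfg = RegistrationConfig(levels=2, factors=(2, 1), affine_iterations=300, seed=1)
        aff = register_affine(v, moving, cfg)
        center = np.asarray(v.extent_mm).mean(axis=0)
        mapped = aff.apply(center)
        assert np.abs(mapped - (center + [6.0, -4.0, 5.0])).max() < 1.0

    def test_scale_recovered(self, rng):
        base = smooth_volume(rng, shape=(48, 48, 48))
        center = np.asarray(base.extent_mm).mean(axis=0)
        pts = base.voxel_centers()
        fixed = Volume(
            sample_trilinear(base, center + 1.05 * (pts - center)).reshape(base.shape),
            base.spacing,
        )
        cfg = RegistrationConfig(levels=2, factors=(2, 1), affine_iterations=300, seed=1)
        aff = register_affine(fixed, base, cfg)
        scales = np.diag(aff.matrix)
        assert np.abs(scales - 1.05).max() < 0.05 * 1.05


@pytest.fixture(scope="module")
def phantom_case():
    return generate_phantom(SMALL_PHANTOM)


class TestRegisterMultimetric:
    def test_missing_inputs_error(self, phantom_case):
        with pytest.raises(ValueError, match="fiducial"):
            register_multimetric(phantom_case.fixed, phantom_case.moving, FAST)

    def test_self_registration(self, rng, phantom_case):
        v = phantom_case.moving
        self_pairs = PairedPointSet(
            phantom_case.fiducials.moving_points, phantom_case.fiducials.moving_points
        )
        res = register_multimetric(
            v, v, FAST,
            pairs=self_pairs,
            roi_fixed=phantom_case.gland_moving,
            roi_moving=phantom_case.gland_moving,
        )
        pts = rng.uniform(20, 100, (20, 3))
        rep = target_registration_error(PairedPointSet(pts, pts), res.transform)
        assert rep.distances.max() < 0.5 * min(v.spacing)

    def test_combined_cost_not_worse_than_init(self, phantom_case):
        res = register_multimetric(
            phantom_case.fixed, phantom_case.moving, FAST,
            pairs=phantom_case.fiducials,
            roi_fixed=phantom_case.gland_fixed,
            roi_moving=phantom_case.gland_moving,
            fixed_body=phantom_case.body_fixed,
        )
        assert res.final_metrics["combined"] <= res.initial_metrics["combined"] + 1e-9

    def test_phantom_recovery(self, phantom_case):
        cfg = RegistrationConfig(max_iterations=100, affine_iterations=60, seed=3)
        res = register_multimetric(
            phantom_case.fixed, phantom_case.moving, cfg,
            pairs=phantom_case.fiducials,
            roi_fixed=phantom_case.gland_fixed,
            roi_moving=phantom_case.gland_moving,
            fixed_body=phantom_case.body_fixed,
        )
        before = target_registration_error(phantom_case.landmarks, _identity()).median
        after = target_registration_error(phantom_case.landmarks, res.transform).median
        assert after <= 0.2 * before

    def test_intensity_only_ignores_unsupplied_inputs(self, phantom_case):
        from dataclasses import replace

        from mmdir.metrics import MetricWeights

        cfg = replace(FAST, weights=MetricWeights(0.0, 0.0, 1.0), max_iterations=15)
        r1 = register_multimetric(phantom_case.fixed, phantom_case.moving, cfg)
        r2 = register_multimetric(
            phantom_case.fixed, phantom_case.moving, cfg,
            pairs=phantom_case.fiducials,
            roi_fixed=phantom_case.gland_fixed,
            roi_moving=phantom_case.gland_moving,
        )
        assert np.array_equal(
            r1.transform.bspline.coefficients, r2.transform.bspline.coefficients
        )

    def test_seed_determinism(self, phantom_case):
        from dataclasses import replace

        cfg = replace(FAST, max_iterations=15)
        r1 = register_multimetric(
            phantom_case.fixed, phantom_case.moving, cfg,
            pairs=phantom_case.fiducials,
            roi_fixed=phantom_case.gland_fixed,
            roi_moving=phantom_case.gland_moving,
        )
        r2 = register_multimetric(
            phantom_case.fixed, phantom_case.moving, cfg,
            pairs=phantom_case.fiducials,
            roi_fixed=phantom_case.gland_fixed,
            roi_moving=phantom_case.gland_moving,
        )
        assert np.array_equal(
            r1.transform.bspline.coefficients, r2.transform.bspline.coefficients
        )
        assert r1.level_traces == r2.level_traces


def _identity():
    class _I:
        bspline = None

        def apply(self, pts):
            return np.asarray(pts, dtype=float)

    return _I()
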
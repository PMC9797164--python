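import numpy as np
import pytest

from mmdir.evaluation import (
    checkerboard,
    dice,
    hausdorff,
    overlay,
    target_registration_error,
)
from mmdir.geometry import LabelMask, Volume
from mmdir.metrics import kappa_cost
from mmdir.pointsets import PairedPointSet
from mmdir.transforms import AffineTransform


def mask_from_slices(shape, sl, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
    data = np.zeros(shape, bool)
    data[sl] = True
    return LabelMask(data, spacing, origin)


class TestTRE:
    def test_coincident_zero(self, identity, rng):
        pts = rng.uniform(0, 10, (7, 3))
        rep = target_registration_error(PairedPointSet(pts, pts), identity)
        assert np.all(rep.distances == 0)

    def test_arithmetic(self, identity):
        f = np.zeros((2, 3))
        m = np.array([[3.0, 4.0, 0.0], [0.0, 0.0, 5.0]])
        rep = target_registration_error(PairedPointSet(f, m), identity)
        assert np.allclose(rep.distances, [5.0, 5.0])
        assert rep.mean == 5.0

    def test_brute_force_oracle(self, rng):
        pts_f = rng.uniform(0, 10, (15, 3))
        pts_m = rng.uniform(0, 10, (15, 3))
        t = AffineTransform(np.eye(3) + rng.normal(0, 0.05, (3, 3)), rng.normal(0, 1, 3))
        rep = target_registration_error(PairedPointSet(pts_f, pts_m), t)
        for i in range(15):
            expected = np.sqrt(np.sum((pts_m[i] - t.apply(pts_f[i])) ** 2))
            assert rep.distances[i] == pytest.approx(expected, abs=1e-12)

    def test_group_stats_recomputable(self, identity, rng):
        pts = rng.uniform(0, 10, (6, 3))
        offs = rng.normal(0, 2, (6, 3))
        groups = ("rigid", "rigid", "soft_tissue", "soft_tissue", "boundary", "boundary")
        rep = target_registration_error(PairedPointSet(pts, pts + offs, groups), identity)
        stats = rep.group_stats()
        d = np.linalg.norm(offs, axis=1)
        assert stats["rigid"][0] == pytest.approx(d[:2].mean(), abs=1e-12)

    def test_empty_rejected(self, identity):
        with pytest.raises(ValueError, match="empty"):
            target_registration_error(None, identity)


class TestDice:
    def test_self_is_one(self, cube_mask):
        assert dice(cube_mask, cube_mask) == 1.0

    def test_disjoint_zero(self):
        a = mask_from_slices((10, 10, 10), np.s_[0:2, 0:2, 0:2])
        b = mask_from_slices((10, 10, 10), np.s_[6:8, 6:8, 6:8])
        assert dice(a, b) == 0.0

    def test_arithmetic(self):
        a = mask_from_slices((10, 10, 10), np.s_[0, 0, 0:6])
        b = mask_from_slices((10, 10, 10), np.s_[0, 0, 4:6])
        assert dice(a, b) == pytest.approx(0.5, abs=1e-12)

    def test_symmetric(self, rng):
        a = LabelMask(rng.random((8, 8, 8)) > 0.5)
        b = LabelMask(rng.random((8, 8, 8)) > 0.5)
        assert dice(a, b) == dice(b, a)

    def test_both_empty_rejected(self):
        e = LabelMask(np.zeros((4, 4, 4), bool))
        with pytest.raises(ValueError, match="undefined DSC"):
            dice(e, e)

    def test_matches_hard_kappa(self, identity, rng):
        # same formula as the overlap cost term on identical inputs
        a = LabelMask(rng.random((8, 8, 8)) > 0.6)
        b = LabelMask(rng.random((8, 8, 8)) > 0.6)
        cost, _ = kappa_cost(identity, a, b)
        assert dice(b, a) == pytest.approx(1.0 - cost, abs=1e-12)


class TestHausdorff:
    def test_self_zero(self, cube_mask):
        assert hausdorff(cube_mask, cube_mask) == 0.0

    def test_single_voxel_distance(self):
        a = mask_from_slices((10, 10, 10), np.s_[1, 1, 1])
        b = mask_from_slices((10, 10, 10), np.s_[4, 5, 1])
        assert hausdorff(a, b) == pytest.approx(5.0, abs=1e-12)

    def test_brute_force_oracle(self, rng):
        # O(n^2) max-min over boundary points
        from scipy import ndimage

        for _ in range(30):
            a = rng.random((7, 7, 7)) > 0.6
            b = rng.random((7, 7, 7)) > 0.6
            if not a.any() or not b.any():
                continue
            spacing = (1.5, 1.0, 2.0)
            ma, mb = LabelMask(a, spacing), LabelMask(b, spacing)
            got = hausdorff(ma, mb)
            struct = ndimage.generate_binary_structure(3, 1)

            def boundary(m):
                return np.argwhere(
                    m & ~ndimage.binary_erosion(m, struct, border_value=0)
                ) * np.asarray(spacing)

            pa, pb = boundary(a), boundary(b)
            dmat = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
            expected = max(dmat.min(axis=1).max(), dmat.min(axis=0).max())
            assert got == pytest.approx(expected, abs=1e-9)

    def test_symmetric(self, rng):
        a = LabelMask(rng.random((8, 8, 8)) > 0.6)
        b = LabelMask(rng.random((8, 8, 8)) > 0.6)
        assert hausdorff(a, b) == hausdorff(b, a)

    def test_empty_rejected(self, cube_mask):
        with pytest.raises(ValueError, match="empty"):
            hausdorff(cube_mask, LabelMask(np.zeros((16, 16, 16), bool)))

    def test_axis_permutation_invariant(self, rng):
        a = rng.random((8, 8, 8)) > 0.6
        b = rng.random((8, 8, 8)) > 0.6
        v1 = hausdorff(LabelMask(a), LabelMask(b))
        perm = (1, 2, 0)
        v2 = hausdorff(LabelMask(np.transpose(a, perm)), LabelMask(np.transpose(b, perm)))
        assert v1 == pytest.approx(v2, abs=1e-12)


class TestCheckerboard:
    def test_identical_inputs(self, small_volume):
        out = checkerboard(small_volume, small_volume, tile=4)
        assert np.array_equal(out.data, small_volume.data)

    def test_full_extent_tile(self, small_volume, rng):
        other = Volume(rng.uniform(0, 1, (16, 16, 16)))
        out = checkerboard(small_volume, other, tile=16)
        assert np.array_equal(out.data, small_volume.data)

    def test_parity_pattern(self):
        zero = Volume(np.zeros((4, 4, 4)))
        one = Volume(np.ones((4, 4, 4)))
        out = checkerboard(zero, one, tile=2)
        ix, iy, iz = np.indices((4, 4, 4)) // 2
        assert np.array_equal(out.data, ((ix + iy + iz) % 2).astype(float))

    def test_geometry_mismatch(self, small_volume):
        other = Volume(np.zeros((16, 16, 16)), spacing=(2, 2, 2))
        with pytest.raises(ValueError, match="geometry"):
            checkerboard(small_volume, other)


class TestOverlay:
    def test_identical_is_gray(self, small_volume):
        rgb = overlay(small_volume, small_volume)
        assert np.allclose(rgb[..., 0], rgb[..., 1])
        assert np.allclose(rgb[..., 1], rgb[..., 2])

    def test_pure_orange_where_moved_zero(self):
        f = Volume(np.full((4, 4, 4), 10.0))
        m = Volume(np.zeros((4, 4, 4)))
        rgb = overlay(f, m, window=(0.0, 10.0))
        assert np.allclose(rgb[..., 0], 1.0)
        assert np.allclose(rgb[..., 1], 0.5)
        assert np.allclose(rgb[..., 2], 0.0)

    def test_channel_formula_oracle(self, rng):
        f = Volume(rng.uniform(0, 10, (5, 5, 5)))
        m = Volume(rng.uniform(0, 10, (5, 5, 5)))
        rgb = overlay(f, m, window=(0.0, 10.0))
        fn, mn = f.data / 10.0, m.data / 10.0
        for idx in np.ndindex((5, 5, 5)):
            assert rgb[idx][0] == pytest.approx(fn[idx], abs=1e-12)
            assert rgb[idx][1] == pytest.approx(0.5 * fn[idx] + 0.5 * mn[idx], abs=1e-12)
            assert rgb[idx][2] == pytest.approx(mn[idx], abs=1e-12)
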
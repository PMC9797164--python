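import numpy as np
import pytest

from mmdir.geometry import LabelMask, Volume
from mmdir.metrics import (
    MIConfig,
    MetricWeights,
    combined_cost,
    fiducial_cost,
    kappa_cost,
    mutual_information,
)
from mmdir.pointsets import PairedPointSet
from mmdir.transforms import AffineTransform, CompositeTransform, bspline_grid_for_domain


def random_affine(rng):
    return AffineTransform(np.eye(3) + rng.normal(0, 0.05, (3, 3)), rng.normal(0, 2, 3))


class TestFiducialCost:
    def test_coincident_pairs_zero(self, identity, rng):
        pts = rng.uniform(0, 10, (8, 3))
        value, _ = fiducial_cost(identity, PairedPointSet(pts, pts))
        assert value == 0.0

    def test_three_four_five(self, identity, rng):
        pts = rng.uniform(0, 10, (6, 3))
        value, _ = fiducial_cost(identity, PairedPointSet(pts, pts + [3.0, 4.0, 0.0]))
        assert value == pytest.approx(5.0, abs=1e-12)

    def test_brute_force_oracle(self, rng):
        # independent per-pair loop over 100 random instances
        for _ in range(100):
            pts_f = rng.uniform(-10, 10, (10, 3))
            pts_m = rng.uniform(-10, 10, (10, 3))
            t = random_affine(rng)
            value, _ = fiducial_cost(t, PairedPointSet(pts_f, pts_m))
            expected = np.mean(
                [np.sqrt(np.sum((pts_m[i] - t.apply(pts_f[i])) ** 2)) for i in range(10)]
            )
            assert value == pytest.approx(expected, abs=1e-12)

    def test_pair_order_invariance(self, rng):
        pts_f = rng.uniform(0, 10, (12, 3))
        pts_m = rng.uniform(0, 10, (12, 3))
        t = random_affine(rng)
        v1, _ = fiducial_cost(t, PairedPointSet(pts_f, pts_m))
        perm = rng.permutation(12)
        v2, _ = fiducial_cost(t, PairedPointSet(pts_f[perm], pts_m[perm]))
        assert v1 == pytest.approx(v2, abs=1e-12)

    def test_empty_rejected(self, identity):
        with pytest.raises(ValueError, match="no fiducial pairs"):
            fiducial_cost(identity, None)


class TestKappaCost:
    def test_self_overlap_zero(self, identity, cube_mask):
        value, _ = kappa_cost(identity, cube_mask, cube_mask)
        assert value == 0.0

    def test_disjoint_masks(self, identity):
        a = np.zeros((16, 16, 16), bool)
        b = np.zeros((16, 16, 16), bool)
        a[1:3, 1:3, 1:3] = True
        b[10:14, 10:14, 10:14] = True
        value, _ = kappa_cost(identity, LabelMask(a), LabelMask(b))
        assert value == 1.0

    def test_arithmetic_example(self, identity):
        # |A| = |B| = 4, overlap 2 -> KS = 0.5
        a = np.zeros((8, 8, 8), bool)
        b = np.zeros((8, 8, 8), bool)
        a[2, 2, 2:6] = True
        b[2, 2, 4:8] = True
        value, _ = kappa_cost(identity, LabelMask(a), LabelMask(b))
        assert value == pytest.approx(0.5, abs=1e-12)

    def test_symmetric_under_identity(self, identity, rng):
        for _ in range(20):
            a = LabelMask(rng.random((10, 10, 10)) > 0.7)
            b = LabelMask(rng.random((10, 10, 10)) > 0.7)
            va, _ = kappa_cost(identity, a, b)
            vb, _ = kappa_cost(identity, b, a)
            assert va == pytest.approx(vb, abs=1e-12)

    def test_hard_ks_brute_force_oracle(self, identity, rng):
        # voxel-counting oracle under the identity transform
        for _ in range(100):
            a = rng.random((8, 8, 8)) > 0.6
            b = rng.random((8, 8, 8)) > 0.6
            if not a.any() or not b.any():
                continue
            value, _ = kappa_cost(identity, LabelMask(a), LabelMask(b))
            ks = 2.0 * np.sum(a & b) / (np.sum(a) + np.sum(b))
            assert value == pytest.approx(1.0 - ks, abs=1e-12)

    def test_empty_rejected(self, identity, cube_mask):
        with pytest.raises(ValueError, match="empty ROI"):
            kappa_cost(identity, LabelMask(np.zeros((16, 16, 16), bool)), cube_mask)


class TestMutualInformation:
    def test_fair_binary_source_one_bit(self, identity):
        data = np.zeros((8, 8, 8))
        data[::2] = 100.0  # half the voxels at each level
        v = Volume(data)
        cfg = MIConfig(n_bins=2, fixed_range=(0.0, 100.1), moving_range=(0.0, 100.1))
        cost, _ = mutual_information(identity, v, v, cfg, mode="histogram")
        assert -cost == pytest.approx(1.0, abs=1e-12)

    def test_constant_moving_zero(self, identity, small_volume):
        const = Volume(np.full((16, 16, 16), 7.0))
        cfg = MIConfig(n_bins=8, moving_range=(0.0, 14.0))
        cost, _ = mutual_information(identity, small_volume, const, cfg, mode="histogram")
        assert -cost == pytest.approx(0.0, abs=1e-12)

    def test_histogram_mode_double_sum_oracle(self, identity, rng):
        # explicit joint-histogram double loop on 8x8x8 pairs
        for _ in range(100):
            f = rng.uniform(0, 50, (8, 8, 8))
            m = rng.uniform(0, 50, (8, 8, 8))
            nb = 6
            cfg = MIConfig(n_bins=nb, fixed_range=(0.0, 50.0), moving_range=(0.0, 50.0))
            cost, _ = mutual_information(
                identity, Volume(f), Volume(m), cfg, mode="histogram"
            )
            bf = np.clip((f.ravel() / 50.0 * nb).astype(int), 0, nb - 1)
            bm = np.clip((m.ravel() / 50.0 * nb).astype(int), 0, nb - 1)
            joint = np.zeros((nb, nb))
            for x, y in zip(bf, bm):
                joint[x, y] += 1
            p = joint / joint.sum()
            pf, pm = p.sum(1), p.sum(0)
            mi = 0.0
            for i in range(nb):
                for j in range(nb):
                    if p[i, j] > 0:
                        mi += p[i, j] * np.log2(p[i, j] / (pf[i] * pm[j]))
            assert -cost == pytest.approx(mi, abs=1e-12)

    def test_self_mi_equals_entropy(self, identity, small_volume):
        nb = 16
        cfg = MIConfig(n_bins=nb, fixed_range=(0.0, 100.0), moving_range=(0.0, 100.0))
        cost, _ = mutual_information(identity, small_volume, small_volume, cfg, mode="histogram")
        bins = np.clip((small_volume.data.ravel() / 100.0 * nb).astype(int), 0, nb - 1)
        p = np.bincount(bins, minlength=nb) / bins.size
        entropy = -np.sum(p[p > 0] * np.log2(p[p > 0]))
        assert -cost == pytest.approx(entropy, abs=1e-9)

    def test_independent_volumes_low_mi(self, identity, rng):
        f = Volume(rng.uniform(0, 1, (24, 24, 24)))
        m = Volume(rng.uniform(0, 1, (24, 24, 24)))
        cfg = MIConfig(n_bins=16, fixed_range=(0, 1), moving_range=(0, 1))
        cost, _ = mutual_information(identity, f, m, cfg, mode="histogram")
        assert -cost < 0.05

    def test_insufficient_overlap_error(self, small_volume):
        t = AffineTransform.translate((1000.0, 0.0, 0.0))
        with pytest.raises(ValueError, match="insufficient overlap"):
            mutual_information(t, small_volume, small_volume, MIConfig())

    def test_parzen_seeded_deterministic(self, small_volume, rng):
        bsp = bspline_grid_for_domain((0, 0, 0), (15, 15, 15), 5.0)
        bsp = bsp.with_coefficients(rng.normal(0, 0.5, bsp.coefficients.shape))
        t = CompositeTransform((AffineTransform.identity(), bsp))
        cfg = MIConfig(n_bins=8, n_samples=512)
        m = Volume(small_volume.data + 1.0)
        v1, g1 = mutual_information(t, small_volume, m, cfg, rng=42)
        v2, g2 = mutual_information(t, small_volume, m, cfg, rng=42)
        assert v1 == v2
        assert np.array_equal(g1, g2)


class TestMetricWeights:
    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            MetricWeights(-1.0, 0.0, 1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            MetricWeights(0.0, 0.0, 0.0)


class TestCombinedCost:
    def _inputs(self, rng):
        f = Volume(rng.uniform(0, 100, (12, 12, 12)))
        m = Volume(np.clip(f.data + rng.normal(0, 5, f.shape), 0, None))
        a = np.zeros((12, 12, 12), bool)
        a[3:8, 3:8, 3:8] = True
        b = np.zeros((12, 12, 12), bool)
        b[4:9, 3:8, 3:8] = True
        pts = rng.uniform(2, 10, (6, 3))
        return dict(
            pairs=PairedPointSet(pts, pts + rng.normal(0, 1, (6, 3))),
            roi_fixed=LabelMask(a),
            roi_moving=LabelMask(b),
            fixed=f,
            moving=m,
            mi_config=MIConfig(n_bins=8),
            mi_mode="histogram",
        )

    def test_matches_weighted_mean_of_components(self, identity, rng):
        inputs = self._inputs(rng)
        c1, _ = fiducial_cost(identity, inputs["pairs"])
        c2, _ = kappa_cost(identity, inputs["roi_fixed"], inputs["roi_moving"])
        c3, _ = mutual_information(
            identity, inputs["fixed"], inputs["moving"], inputs["mi_config"], mode="histogram"
        )
        w = MetricWeights(1.0, 1.0, 100.0)
        value, _ = combined_cost(identity, w, **inputs)
        expected = (1.0 * c1 + 1.0 * c2 + 100.0 * c3) / 102.0
        assert value == pytest.approx(expected, abs=1e-12)

    def test_random_weights_loop_oracle(self, identity, rng):
        inputs = self._inputs(rng)
        c1, _ = fiducial_cost(identity, inputs["pairs"])
        c2, _ = kappa_cost(identity, inputs["roi_fixed"], inputs["roi_moving"])
        c3, _ = mutual_information(
            identity, inputs["fixed"], inputs["moving"], inputs["mi_config"], mode="histogram"
        )
        for _ in range(100):
            wf, wr, wi = rng.uniform(0.1, 10, 3)
            value, _ = combined_cost(identity, MetricWeights(wf, wr, wi), **inputs)
            expected = (wf * c1 + wr * c2 + wi * c3) / (wf + wr + wi)
            assert value == pytest.approx(expected, abs=1e-12)

    def test_single_weight_equals_component(self, identity, rng):
        inputs = self._inputs(rng)
        value, _ = combined_cost(identity, MetricWeights(1.0, 0.0, 0.0), **inputs)
        expected, _ = fiducial_cost(identity, inputs["pairs"])
        assert value == expected

    def test_missing_input_names_metric(self, identity, rng):
        inputs = self._inputs(rng)
        inputs.pop("pairs")
        with pytest.raises(ValueError, match="fiducial"):
            combined_cost(identity, MetricWeights(1.0, 0.0, 1.0), **inputs)
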
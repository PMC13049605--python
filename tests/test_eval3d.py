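"""DVH statistics and voxel-wise aggregation against brute-force oracles."""

import numpy as np
import pytest

from protonrem.eval3d import (
    coverage_verdict,
    dose_at_volume,
    dvh,
    ooi_metrics,
    volume_at_dose,
    voxelwise_mean,
    voxelwise_min,
)

from .conftest import grid_of


def rand_grids(rng, n, shape=(8, 7, 6)):
    return [grid_of(rng.uniform(0.0, 40.0, shape)) for _ in range(n)]


class TestVoxelwiseAggregation:
    def test_single_grid_identity(self):
        g = grid_of(np.arange(27.0).reshape(3, 3, 3))
        np.testing.assert_array_equal(voxelwise_min([g]).values, g.values)
        np.testing.assert_array_equal(voxelwise_mean([g]).values, g.values)

    def test_offset_pair(self):
        rng = np.random.default_rng(0)
        a = grid_of(rng.uniform(0, 30, (5, 5, 5)))
        b = a.copy_with(a.values + 1.0)
        np.testing.assert_array_equal(voxelwise_min([a, b]).values, a.values)
        np.testing.assert_allclose(voxelwise_mean([a, b]).values, a.values + 0.5)

    def test_matches_naive_loops_on_random_ensembles(self):
        rng = np.random.default_rng(42)
        for trial in range(25):
            grids = rand_grids(rng, rng.integers(2, 8), shape=(6, 5, 4))
            vmin = voxelwise_min(grids).values
            vmean = voxelwise_mean(grids).values
            for idx in np.ndindex(*vmin.shape):
                samples = [g.values[idx] for g in grids]
                assert vmin[idx] == min(samples)
                assert vmean[idx] == pytest.approx(np.mean(samples))

    def test_min_dominates_every_member(self):
        rng = np.random.default_rng(3)
        grids = rand_grids(rng, 28)
        vmin = voxelwise_min(grids).values
        for g in grids:
            assert np.all(vmin <= g.values + 1e-15)

    def test_geometry_mismatch_rejected(self):
        a = grid_of(np.zeros((4, 4, 4)))
        b = grid_of(np.zeros((4, 4, 5)))
        with pytest.raises(ValueError):
            voxelwise_min([a, b])
        with pytest.raises(ValueError):
            voxelwise_mean([])


class TestDVH:
    def test_uniform_dose(self):
        g = grid_of(np.full((5, 5, 5), 30.0))
        mask = np.ones((5, 5, 5), bool)
        h = dvh(g, mask)
        for v in (1.0, 50.0, 98.0, 100.0):
            assert dose_at_volume(h, v) == 30.0
        pct, cm3 = volume_at_dose(h, 29.0)
        assert pct == 100.0
        assert cm3 == pytest.approx(125 * g.voxel_volume_cm3)

    def test_d98_floor_convention_on_1_to_100(self):
        vals = np.arange(1.0, 101.0).reshape(4, 5, 5)
        h = dvh(grid_of(vals), np.ones((4, 5, 5), bool))
        # hottest 98 voxels are 3..100, their minimum is 3
        assert dose_at_volume(h, 98.0) == 3.0
        assert dose_at_volume(h, 100.0) == 1.0
        assert dose_at_volume(h, 1.0) == 100.0

    def test_quantile_monotonicity(self):
        rng = np.random.default_rng(11)
        h = dvh(grid_of(rng.uniform(0, 60, (6, 6, 6))), np.ones((6, 6, 6), bool))
        assert dose_at_volume(h, 98.0) <= dose_at_volume(h, 50.0) <= dose_at_volume(h, 2.0)

    def test_dose_at_volume_matches_sort_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(40):
            vals = rng.uniform(0, 50, (5, 4, 5))
            mask = rng.random((5, 4, 5)) > 0.3
            if not mask.any():
                continue
            h = dvh(grid_of(vals), mask)
            samples = np.sort(vals[mask])[::-1]
            for v in rng.uniform(1.0, 100.0, 5):
                k = max(int(np.floor(v / 100.0 * len(samples))), 1)
                assert dose_at_volume(h, v) == samples[k - 1]

    def test_volume_at_dose_matches_counting_oracle(self):
        rng = np.random.default_rng(22)
        for _ in range(40):
            vals = rng.uniform(0, 50, (5, 5, 4))
            mask = rng.random((5, 5, 4)) > 0.3
            if not mask.any():
                continue
            h = dvh(grid_of(vals), mask)
            thr = rng.uniform(0, 55)
            expected = 100.0 * np.sum(vals[mask] >= thr) / mask.sum()
            pct, _ = volume_at_dose(h, thr)
            assert pct == pytest.approx(expected)

    def test_inverse_consistency(self):
        # under the floor convention the round-trip is exact up to the
        # one-voxel volume granularity 100/n
        rng = np.random.default_rng(23)
        h = dvh(grid_of(rng.uniform(0, 50, (6, 6, 6))), np.ones((6, 6, 6), bool))
        granularity = 100.0 / h.n_voxels
        for v in (10.0, 50.0, 95.0, 98.0):
            d = dose_at_volume(h, v)
            pct, _ = volume_at_dose(h, d)
            assert pct >= v - granularity - 1e-12

    def test_empty_mask_rejected(self):
        g = grid_of(np.zeros((3, 3, 3)))
        with pytest.raises(ValueError):
            dvh(g, np.zeros((3, 3, 3), bool))
        h = dvh(g, np.ones((3, 3, 3), bool))
        with pytest.raises(ValueError):
            dose_at_volume(h, 0.0)
        with pytest.raises(ValueError):
            dose_at_volume(h, 101.0)


class TestCoverageGate:
    def test_strict_thresholds(self):
        # D98 = 95.0 % exactly and V95 = 98.0 % exactly must both FAIL (strict >)
        n = 100
        vals = np.full(n, 30.0)
        vals[:2] = 0.0  # 98 voxels at prescription
        g = grid_of(vals.reshape(4, 5, 5))
        v = coverage_verdict(g, np.ones((4, 5, 5), bool), prescription=30.0)
        assert v.v95_pct == 98.0 and not v.passed
        vals = np.full(n, 0.95 * 30.0)
        g = grid_of(vals.reshape(4, 5, 5))
        v = coverage_verdict(g, np.ones((4, 5, 5), bool), prescription=30.0)
        assert v.d98_pct_of_rx == pytest.approx(95.0) and not v.passed

    def test_passing_plan(self):
        g = grid_of(np.full((4, 5, 5), 30.0))
        v = coverage_verdict(g, np.ones((4, 5, 5), bool), prescription=30.0)
        assert v.passed and v.v95_pct == 100.0


class TestOOIMetrics:
    def test_means_and_volume_metrics(self):
        shape = (6, 6, 6)
        vals = np.zeros(shape)
        masks = {
            "heart": np.zeros(shape, bool),
            "lungs": np.zeros(shape, bool),
            "breast_l": np.zeros(shape, bool),
        }
        masks["heart"][:2] = True
        masks["lungs"][3:] = True
        masks["breast_l"][2] = True
        vals[:2] = 4.0
        vals[3:5] = 2.0
        m = ooi_metrics(grid_of(vals), masks, prescription=30.0)
        assert m.mean_dose["heart"] == pytest.approx(4.0)
        # lungs: 108 voxels, 72 of them at 2 Gy >= 5 % of 30 Gy = 1.5 Gy
        assert m.vx_pct["lungs"] == pytest.approx(100.0 * 72 / 108)
        assert m.mean_dose["breast_l"] == 0.0
        assert m.vx_pct["breast_l"] == 0.0

    def test_linearity_in_dose(self, small_avg):
        rng = np.random.default_rng(8)
        vals = rng.uniform(0, 30, small_avg.shape)
        g = grid_of(vals)
        m1 = ooi_metrics(g, small_avg.masks, 30.0)
        m2 = ooi_metrics(g.copy_with(2.0 * vals), small_avg.masks, 30.0)
        for k in m1.mean_dose:
            assert m2.mean_dose[k] == pytest.approx(2.0 * m1.mean_dose[k])
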
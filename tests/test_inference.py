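"""Group inference: voxelwise t, smoothness estimation, clusters, RFT p."""
import numpy as np
import pytest
from scipy import ndimage, stats

from rehoflow import inference


def _zscore(x):
    return (x - x.mean()) / x.std(ddof=1)


class TestVoxelwiseTtest:
    def test_identical_groups_give_zero(self, rng):
        maps = rng.standard_normal((4, 5, 5, 5))
        t = inference.voxelwise_ttest(maps, maps.copy(), np.ones((5, 5, 5), bool))
        assert np.allclose(t.values, 0)
        assert t.df == 6

    def test_antisymmetric_under_group_swap(self, rng):
        A = rng.standard_normal((5, 4, 4, 4))
        B = rng.standard_normal((6, 4, 4, 4))
        mask = np.ones((4, 4, 4), bool)
        t1 = inference.voxelwise_ttest(A, B, mask)
        t2 = inference.voxelwise_ttest(B, A, mask)
        assert np.allclose(t1.values, -t2.values)

    def test_closed_form_pooled_t(self, rng):
        # exact construction: sample means 1 vs 0, pooled SD 1, n=20/20 -> t = sqrt(10)
        a = _zscore(rng.standard_normal(20)) + 1.0
        b = _zscore(rng.standard_normal(20))
        A = a.reshape(-1, 1, 1, 1)
        B = b.reshape(-1, 1, 1, 1)
        t = inference.voxelwise_ttest(A, B, np.ones((1, 1, 1), bool))
        assert t.values[0, 0, 0] == pytest.approx(np.sqrt(10), rel=1e-12)
        assert t.df == 38

    def test_matches_scipy_per_voxel(self, rng):
        A = rng.standard_normal((8, 3, 3, 3))
        B = rng.standard_normal((9, 3, 3, 3))
        t = inference.voxelwise_ttest(A, B, np.ones((3, 3, 3), bool))
        ref = stats.ttest_ind(A, B, axis=0).statistic
        assert np.allclose(t.values, ref, atol=1e-10)

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValueError):
            inference.voxelwise_ttest(rng.standard_normal((1, 2, 2, 2)),
                                      rng.standard_normal((5, 2, 2, 2)),
                                      np.ones((2, 2, 2), bool))


class TestSmoothnessEstimation:
    def test_known_kernel_recovered(self, rng):
        maps = ndimage.gaussian_filter(rng.standard_normal((20, 30, 30, 30)),
                                       sigma=(0, 0.8493, 0.8493, 0.8493))  # 6 mm at 3 mm vox
        resid = maps - maps.mean(axis=0)
        sm = inference.estimate_smoothness(resid, np.ones((30, 30, 30), bool), 3.0)
        assert np.all(np.abs(sm.fwhm_mm - 6.0) < 1.0)

    def test_white_noise_floors_at_voxel_size(self, rng):
        maps = rng.standard_normal((20, 12, 12, 12))
        sm = inference.estimate_smoothness(maps - maps.mean(axis=0),
                                           np.ones((12, 12, 12), bool), 3.0)
        assert np.all(sm.fwhm_mm == pytest.approx(3.0, abs=0.5))

    def test_resels_scale_with_voxel_size(self, rng):
        maps = rng.standard_normal((10, 10, 10, 10))
        resid = maps - maps.mean(axis=0)
        mask = np.ones((10, 10, 10), bool)
        sm1 = inference.estimate_smoothness(resid, mask, 3.0)
        sm2 = inference.estimate_smoothness(resid, mask, 6.0)
        # same lattice smoothness; resel counts are voxel-unit and identical
        assert sm2.resels[3] == pytest.approx(sm1.resels[3])
        assert sm2.fwhm_mm[0] == pytest.approx(2 * sm1.fwhm_mm[0])

    def test_too_few_maps_rejected(self, rng):
        with pytest.raises(ValueError):
            inference.estimate_smoothness(rng.standard_normal((2, 5, 5, 5)),
                                          np.ones((5, 5, 5), bool), 3.0)


class TestReselCounts:
    def test_full_box(self):
        R = inference.resel_counts(np.ones((11, 11, 11), bool), [2.0, 2.0, 2.0])
        # box of side 10 voxels = 5 resels: R3 = 125, R2 = 3*25, R1 = 3*5, R0 = 1
        assert R[0] == 1
        assert R[1] == pytest.approx(15)
        assert R[2] == pytest.approx(75)
        assert R[3] == pytest.approx(125)


class TestExtractClusters:
    def _two_cubes(self):
        m = np.zeros((12, 12, 12), bool)
        m[1:3, 1:3, 1:3] = True
        m[8:10, 8:10, 8:10] = True
        return m

    def test_two_disjoint_cubes(self):
        mask = self._two_cubes()
        stat = np.where(mask, 5.0, 0.0)
        cl = inference.extract_clusters(stat, mask)
        assert len(cl) == 2 and sorted(c.extent for c in cl) == [8, 8]

    def test_single_voxel_cluster(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = True
        cl = inference.extract_clusters(np.where(mask, 3.0, 0.0), mask,
                                        affine=np.diag([3.0, 3, 3, 1]))
        assert len(cl) == 1 and cl[0].extent == 1
        assert cl[0].peak_mm == (6.0, 6.0, 6.0)

    def test_diagonal_touch_depends_on_connectivity(self):
        mask = np.zeros((4, 4, 4), bool)
        mask[1, 1, 1] = True
        mask[2, 2, 2] = True  # touch only at a corner
        stat = np.where(mask, 1.0, 0.0)
        assert len(inference.extract_clusters(stat, mask, connectivity=26)) == 1
        assert len(inference.extract_clusters(stat, mask, connectivity=6)) == 2
        ref, n = ndimage.label(mask, structure=np.ones((3, 3, 3)))
        assert n == 1

    def test_peak_is_max_abs(self):
        mask = np.zeros((4, 4, 4), bool)
        mask[1:3, 1, 1] = True
        stat = np.zeros((4, 4, 4))
        stat[1, 1, 1], stat[2, 1, 1] = -4.0, 2.0
        cl = inference.extract_clusters(stat, mask)
        assert cl[0].peak_stat == -4.0 and cl[0].peak_ijk == (1, 1, 1)

    def test_bad_connectivity_rejected(self):
        with pytest.raises(ValueError):
            inference.extract_clusters(np.zeros((3, 3, 3)), np.zeros((3, 3, 3), bool),
                                       connectivity=10)


def _smooth_null_cohort(rng, n=10, shape=(20, 20, 20), fwhm=2.4):
    sigma = fwhm / 2.3548
    maps = ndimage.gaussian_filter(rng.standard_normal((2 * n,) + shape),
                                   sigma=(0, sigma, sigma, sigma))
    return maps[:n], maps[n:]


class TestGrfThreshold:
    def test_extreme_voxel_p_empties_list(self, rng):
        A, B = _smooth_null_cohort(rng)
        mask = np.ones((20, 20, 20), bool)
        t = inference.voxelwise_ttest(A, B, mask)
        sm = inference.estimate_smoothness(inference.group_residuals(A, B), mask, 1.0)
        assert inference.grf_cluster_threshold(t, sm, voxel_p=1e-9) == []

    def test_lower_voxel_p_never_grows_suprathreshold_set(self, rng):
        A, B = _smooth_null_cohort(rng)
        mask = np.ones((20, 20, 20), bool)
        t = inference.voxelwise_ttest(A, B, mask)
        sm = inference.estimate_smoothness(inference.group_residuals(A, B), mask, 1.0)
        counts = []
        for vp in (0.05, 0.01, 0.005, 0.001):
            cl = inference.grf_cluster_threshold(t, sm, voxel_p=vp, return_all=True)
            counts.append(sum(c.extent for c in cl))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_cluster_p_decreases_with_extent(self, rng):
        A, B = _smooth_null_cohort(rng)
        mask = np.ones((20, 20, 20), bool)
        t = inference.voxelwise_ttest(A, B, mask)
        sm = inference.estimate_smoothness(inference.group_residuals(A, B), mask, 1.0)
        cl = inference.grf_cluster_threshold(t, sm, voxel_p=0.05, return_all=True)
        ordered = sorted(cl, key=lambda c: c.extent)
        ps = [c.p_cluster for c in ordered]
        assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))

    def test_strong_planted_effect_survives(self, rng):
        A, B = _smooth_null_cohort(rng, n=12)
        bump = np.zeros((20, 20, 20))
        bump[8:13, 8:13, 8:13] = 2.0
        A = A + bump
        mask = np.ones((20, 20, 20), bool)
        t = inference.voxelwise_ttest(A, B, mask)
        sm = inference.estimate_smoothness(inference.group_residuals(A, B), mask, 1.0)
        cl = inference.grf_cluster_threshold(t, sm)
        assert cl and cl[0].sign == 1
        roi = inference.define_roi_from_cluster(cl[0], (20, 20, 20))
        assert roi[10, 10, 10]

    def test_one_tailed_option(self, rng):
        A, B = _smooth_null_cohort(rng, n=12)
        bump = np.zeros((20, 20, 20))
        bump[8:13, 8:13, 8:13] = 2.0
        t = inference.voxelwise_ttest(A + bump, B, np.ones((20, 20, 20), bool))
        sm = inference.estimate_smoothness(inference.group_residuals(A + bump, B),
                                           np.ones((20, 20, 20), bool), 1.0)
        pos = inference.grf_cluster_threshold(t, sm, tails="pos")
        neg = inference.grf_cluster_threshold(t, sm, tails="neg")
        assert pos and all(c.sign == 1 for c in pos)
        assert all(c.sign == -1 for c in neg)


class TestPermutationFallback:
    def test_planted_effect_survives_and_null_calibrated(self, rng):
        A, B = _smooth_null_cohort(rng, n=12, shape=(16, 16, 16))
        bump = np.zeros((16, 16, 16))
        bump[6:11, 6:11, 6:11] = 2.0
        mask = np.ones((16, 16, 16), bool)
        cl = inference.permutation_cluster_threshold(A + bump, B, mask,
                                                     n_perm=99, seed=4)
        assert cl and cl[0].sign == 1
        assert 0 < cl[0].p_cluster <= 1
        # null data: surviving clusters are rare
        An, Bn = _smooth_null_cohort(rng, n=12, shape=(16, 16, 16))
        null_cl = inference.permutation_cluster_threshold(An, Bn, mask,
                                                          n_perm=99, seed=5)
        assert len(null_cl) <= 1

    def test_agrees_with_grf_on_strong_effect(self, rng):
        A, B = _smooth_null_cohort(rng, n=12, shape=(16, 16, 16))
        bump = np.zeros((16, 16, 16))
        bump[6:11, 6:11, 6:11] = 2.0
        mask = np.ones((16, 16, 16), bool)
        t = inference.voxelwise_ttest(A + bump, B, mask)
        sm = inference.estimate_smoothness(inference.group_residuals(A + bump, B), mask, 1.0)
        grf = inference.grf_cluster_threshold(t, sm)
        perm = inference.permutation_cluster_threshold(A + bump, B, mask, n_perm=99, seed=6)
        assert grf and perm
        assert grf[0].extent == perm[0].extent  # same cluster-forming threshold


class TestRoiFromCluster:
    def test_roundtrip_mean(self, rng):
        from rehoflow import connectivity
        from conftest import make_volume
        mask = np.zeros((6, 6, 6), bool)
        mask[1:3, 1:3, 1] = True
        stat = np.where(mask, 4.0, 0.0)
        cl = inference.extract_clusters(stat, mask)[0]
        roi = inference.define_roi_from_cluster(cl, (6, 6, 6))
        assert roi.sum() == cl.extent == 4
        vol = make_volume(rng.standard_normal((6, 6, 6, 10)))
        series = connectivity.extract_roi_timeseries(vol, roi)
        assert np.allclose(series, vol.data[roi].mean(axis=0))
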
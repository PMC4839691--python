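"""Running t-tests, clusters, permutation null, ROIs, deviance analysis."""

import itertools

import numpy as np
import pytest
from scipy import stats

from acimage.groupstats import (cluster_permutation_test, define_rois,
                                find_clusters, individual_deviance_analysis,
                                roi_compare, running_ttest)


def _noise_maps(n, shape=(12, 15), seed=0, loc=0.0):
    rng = np.random.default_rng(seed)
    return [loc + rng.standard_normal(shape) for _ in range(n)]


class TestRunningTTest:
    def test_identical_groups_give_zero_t(self):
        maps = _noise_maps(5)
        t, p = running_ttest(maps, maps)
        assert np.allclose(t, 0.0)
        assert np.allclose(p, 1.0)

    def test_matches_textbook_pooled_t(self):
        a = [np.array([[1.0]]), np.array([[2.0]]), np.array([[4.0]])]
        b = [np.array([[5.0]]), np.array([[6.0]]), np.array([[10.0]])]
        t, p = running_ttest(a, b)
        expected = stats.ttest_ind([1, 2, 4], [5, 6, 10], equal_var=True)
        assert t[0, 0] == pytest.approx(expected.statistic, abs=1e-10)
        assert p[0, 0] == pytest.approx(expected.pvalue, abs=1e-10)

    def test_zero_variance_bins_warn(self):
        a = [np.ones((2, 2)) for _ in range(4)]
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            t, p = running_ttest(a)
        assert np.allclose(t, 0.0) and np.allclose(p, 1.0)

    def test_one_sample_mode(self):
        maps = _noise_maps(10, loc=1.0, seed=3)
        t, p = running_ttest(maps)
        expected = stats.ttest_1samp(np.stack(maps), 0.0, axis=0)
        assert np.allclose(t, expected.statistic)


class TestFindClusters:
    def test_nothing_significant(self):
        p = np.ones((6, 6))
        assert find_clusters(p, np.zeros((6, 6)), alpha=0.05) == []

    def test_diagonal_touch_is_two_clusters(self):
        p = np.ones((4, 4))
        t = np.zeros((4, 4))
        p[0, 0] = p[1, 1] = 1e-6
        t[0, 0] = t[1, 1] = 3.0
        masks = find_clusters(p, t, alpha=0.05)
        assert len(masks) == 2

    def test_opposite_signs_split(self):
        p = np.full((1, 4), 1e-6)
        t = np.array([[2.0, 2.0, -2.0, -2.0]])
        masks = find_clusters(p, t, alpha=0.05)
        assert len(masks) == 2
        assert sorted(m.sum() for m in masks) == [2, 2]

    def test_planted_block_found_by_floodfill_oracle(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(0.1, 1.0, size=(20, 20))
        t = np.ones((20, 20))
        p[5:8, 9:12] = 1e-12
        masks = find_clusters(p, t, alpha=0.05)
        assert len(masks) == 1
        # independent flood-fill oracle over the thresholded grid
        sig = p < 0.05
        seen = np.zeros_like(sig)
        comps = []
        for seed_pt in zip(*np.nonzero(sig)):
            if seen[seed_pt]:
                continue
            stack, comp = [seed_pt], set()
            while stack:
                i, j = stack.pop()
                if not (0 <= i < 20 and 0 <= j < 20) or seen[i, j] \
                        or not sig[i, j]:
                    continue
                seen[i, j] = True
                comp.add((i, j))
                stack += [(i + 1, j), (i - 1, j), (i, j + 1), (i, j - 1)]
            comps.append(comp)
        assert len(comps) == 1
        assert comps[0] == set(zip(*np.nonzero(masks[0])))

    def test_min_size_filter(self):
        p = np.ones((5, 5))
        t = np.ones((5, 5))
        p[0, :3] = 1e-6
        assert find_clusters(p, t, alpha=0.05, min_size=4) == []
        assert len(find_clusters(p, t, alpha=0.05, min_size=3)) == 1

    def test_visit_order_invariance(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(0, 0.2, size=(10, 10))
        t = rng.standard_normal((10, 10))
        ref = {frozenset(zip(*np.nonzero(m)))
               for m in find_clusters(p, t, alpha=0.05)}
        again = {frozenset(zip(*np.nonzero(m)))
                 for m in find_clusters(p.copy(), t.copy(), alpha=0.05)}
        assert ref == again


class TestClusterPermutation:
    def test_exhaustive_3v3_matches_bruteforce(self):
        rng = np.random.default_rng(1)
        a = [rng.standard_normal((4, 5)) + 1.0 for _ in range(3)]
        b = [rng.standard_normal((4, 5)) for _ in range(3)]
        res = cluster_permutation_test(a, b, n_perm=5000, alpha=0.2, seed=0)
        assert res.n_permutations == 20    # C(6,3) exhaustive
        # brute-force oracle: enumerate all 20 label splits directly
        pooled = np.stack(a + b)

        def max_stat(idx_a):
            idx_a = list(idx_a)
            idx_b = [i for i in range(6) if i not in idx_a]
            r = stats.ttest_ind(pooled[idx_a], pooled[idx_b], axis=0,
                                equal_var=True)
            masks = find_clusters(r.pvalue, r.statistic, alpha=0.2)
            return max((abs(r.statistic[m].sum()) for m in masks),
                       default=0.0)

        null = [max_stat(c) for c in itertools.combinations(range(6), 3)]
        for s_obs, p_obs in zip(res.cluster_stat, res.p_values):
            expected = np.mean([x >= abs(s_obs) for x in null])
            assert p_obs == pytest.approx(expected, abs=1e-12)

    def test_planted_difference_detected(self):
        rng = np.random.default_rng(2)
        shape = (15, 15)
        a = [rng.standard_normal(shape) for _ in range(10)]
        b = [rng.standard_normal(shape) for _ in range(10)]
        for m in b:
            m[4:9, 4:9] += 3.0     # 3-SD block difference
        res = cluster_permutation_test(a, b, n_perm=300, alpha=0.05, seed=3)
        best = np.argmin(res.p_values)
        assert res.p_values[best] < 0.05
        # detected cluster overlaps the planted block
        planted = np.zeros(shape, bool)
        planted[4:9, 4:9] = True
        overlap = (res.clusters[best] & planted).sum()
        assert overlap >= 0.5 * planted.sum()

    def test_p_value_bounds(self):
        a = _noise_maps(4, seed=10)
        b = _noise_maps(4, seed=11)
        res = cluster_permutation_test(a, b, n_perm=100, alpha=0.3, seed=0)
        if len(res.p_values):
            assert np.all(res.p_values >= 1.0 / (res.n_permutations + 1))
            assert np.all(res.p_values <= 1.0)


class TestROIs:
    def test_all_zero_maps_allow_empty_roiset(self):
        maps = [np.zeros((8, 8)) for _ in range(5)]
        with pytest.warns(RuntimeWarning):
            rois = define_rois(maps)
        assert len(rois) == 0

    def test_consistent_region_recovered(self):
        rng = np.random.default_rng(4)
        shape = (12, 12)
        region = np.zeros(shape, bool)
        region[3:5, 2:7] = True       # 10-bin region
        maps = [10.0 * region + rng.standard_normal(shape)
                for _ in range(20)]
        rois = define_rois(maps)
        assert len(rois) == 1
        assert rois.polarity[0] == 1
        mask = rois.masks[0]
        assert (mask & region).sum() == region.sum()

    def test_six_bin_region_rejected_by_min_size(self):
        rng = np.random.default_rng(5)
        shape = (12, 12)
        region = np.zeros(shape, bool)
        region[3:5, 2:5] = True       # exactly 6 bins
        maps = [20.0 * region + 0.01 * rng.standard_normal(shape)
                for _ in range(20)]
        rois = define_rois(maps)
        for m in rois.masks:          # nothing of size < 7 survives
            assert m.sum() >= 7
        assert all((m & region).sum() < region.sum() or m.sum() >= 7
                   for m in rois.masks)
        # the planted 6-bin region itself must not be an ROI
        assert not any((m == region).all() for m in rois.masks)

    def test_centroid_in_axis_units(self):
        rng = np.random.default_rng(6)
        shape = (10, 10)
        region = np.zeros(shape, bool)
        region[4:6, 4:8] = True
        maps = [10.0 * region + 0.1 * rng.standard_normal(shape)
                for _ in range(10)]
        ft = np.linspace(0, 680, shape[1])
        cf = np.linspace(100, 8000, shape[0])
        rois = define_rois(maps, frame_times=ft, center_frequencies=cf)
        (t_c, f_c) = rois.centroids[0]
        assert ft[4] <= t_c <= ft[7]
        assert cf[4] <= f_c <= cf[5]


class TestROICompare:
    def _rois(self, shape=(8, 8)):
        rng = np.random.default_rng(7)
        region = np.zeros(shape, bool)
        region[2:4, 2:6] = True
        maps = [5.0 * region + 0.5 * rng.standard_normal(shape)
                for _ in range(12)]
        return define_rois(maps), maps

    def test_identical_groups_t_zero(self):
        rois, maps = self._rois()
        table = roi_compare(rois, maps, maps)
        assert np.all(np.abs(table["t"]) < 1e-12)

    def test_matches_closed_form_t(self):
        rois, maps = self._rois()
        a, b = maps[:6], maps[6:]
        table = roi_compare(rois, a, b)
        mask = rois.masks[0]
        va = [m[mask].mean() for m in a]
        vb = [m[mask].mean() for m in b]
        expected = stats.ttest_ind(va, vb, equal_var=True)
        assert table["t"].iloc[0] == pytest.approx(expected.statistic,
                                                   abs=1e-10)

    def test_missing_cue_region_flagged(self):
        rng = np.random.default_rng(8)
        shape = (10, 10)
        r1 = np.zeros(shape, bool)
        r1[1:3, 1:6] = True
        r2 = np.zeros(shape, bool)
        r2[7:9, 3:8] = True
        base = 5.0 * r1 + 5.0 * r2
        maps_a = [base + 0.4 * rng.standard_normal(shape)
                  for _ in range(10)]
        # group B under-weights the second cue region
        maps_b = [5.0 * r1 + 3.5 * r2 + 0.4 * rng.standard_normal(shape)
                  for _ in range(10)]
        rois = define_rois(maps_a + maps_b)
        table = roi_compare(rois, maps_a, maps_b)
        hit = [bool((m & r2).sum() > 0.5 * r2.sum()) for m in rois.masks]
        assert any(hit)
        for flag, p in zip(hit, table["p"]):
            if flag:
                assert p < 0.01


class TestIndividualDeviance:
    def test_two_pass_hand_example(self):
        # pass 1: mean 14, sd 8.944 -> 30 is 1.79 SD out, dropped;
        # pass 2: controls all 10 (sd 0) -> case equal to mean not
        # deviant
        flags = individual_deviance_analysis([10, 10, 10, 10, 30], [10])
        assert not flags[0]
        # a case different from the collapsed mean is deviant
        assert individual_deviance_analysis([10, 10, 10, 10, 30], [11])[0]

    def test_case_at_mean_never_deviant(self):
        rng = np.random.default_rng(0)
        c = rng.normal(50, 5, size=30)
        assert not individual_deviance_analysis(c, [c.mean()])[0]

    def test_zero_sd_controls_raise(self):
        with pytest.raises(ValueError, match="zero"):
            individual_deviance_analysis([0.0, 0.0, 0.0], [1.0])

    def test_direction_low(self):
        c = [10.0, 11.0, 9.0, 10.5, 9.5]
        flags_low = individual_deviance_analysis(c, [5.0, 15.0],
                                                 direction="low")
        assert flags_low[0] and not flags_low[1]
        flags_high = individual_deviance_analysis(c, [5.0, 15.0],
                                                  direction="high")
        assert not flags_high[0] and flags_high[1]

    def test_threshold_approximates_fifth_percentile_z(self):
        # 1.65 is the conventional two-decimal normal 95th-percentile
        # quantile (exact value 1.6449)
        assert abs(1.65 - stats.norm.ppf(0.95)) < 0.01
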
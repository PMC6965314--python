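"""Group inference: covariate-adjusted voxel-wise t, permutation FWE control,
cluster extraction, clinical correlation, and summary-statistic tests."""

import numpy as np
import pytest
from scipy import stats

from gfcpipe.core import Bold4D
from gfcpipe.gfcmetric import GrayMask
from gfcpipe.groupstats import (
    bonferroni_threshold,
    build_design,
    chi2_2x2,
    cluster_mean_feature,
    extract_clusters,
    pearson_p_from_r,
    pearson_r_p,
    permutation_fwe,
    roi_fc_group_test,
    ttest_from_summary,
    voxelwise_glm_t,
)


def _full_mask(shape):
    return GrayMask(mask=np.ones(shape, dtype=bool), threshold=0.0)


class TestVoxelwiseGlm:
    def test_reduces_to_pooled_two_sample_t(self, rng):
        maps = rng.normal(size=(14, 30))
        group = np.r_[np.ones(7), np.zeros(7)]
        design = np.column_stack([np.ones(14), group])
        t, df = voxelwise_glm_t(maps, design)
        assert df == 12
        ref = stats.ttest_ind(maps[:7], maps[7:], equal_var=True)
        np.testing.assert_allclose(t, ref.statistic, atol=1e-10)

    def test_null_t_follows_student_distribution(self):
        pooled = []
        for seed in range(20):
            rng = np.random.default_rng(3000 + seed)
            maps = rng.normal(size=(20, 300))
            group = rng.permutation(np.r_[np.ones(10), np.zeros(10)])
            design, _ = build_design(group, rng.normal(size=20), rng.normal(size=20))
            t, df = voxelwise_glm_t(maps, design)
            pooled.append(t)
        pooled = np.concatenate(pooled)
        ks = stats.kstest(pooled, stats.t(df=16).cdf)
        assert ks.pvalue > 0.01

    def test_degenerate_identical_maps_guarded_to_zero(self):
        maps = np.tile(np.arange(5.0), (10, 1))
        design = np.column_stack([np.ones(10), np.r_[np.ones(5), np.zeros(5)]])
        with pytest.warns(UserWarning, match="zero residual variance"):
            t, _ = voxelwise_glm_t(maps, design)
        np.testing.assert_array_equal(t, 0.0)

    def test_tiny_group_rejected(self, rng):
        design = np.column_stack([np.ones(5), [1, 0, 0, 0, 0]])
        with pytest.raises(ValueError, match="at least 2"):
            voxelwise_glm_t(rng.normal(size=(5, 4)), design)


class TestPermutationFwe:
    def test_all_equal_maps_give_p_one(self):
        maps = np.tile(np.arange(6.0), (12, 1))
        design = np.column_stack([np.ones(12), np.r_[np.ones(6), np.zeros(6)]])
        res = permutation_fwe(maps, design, n_perm=100, seed=0, alpha=0.5)
        np.testing.assert_array_equal(res.fwe_p, 1.0)

    def test_fwe_p_monotone_in_abs_t(self, rng):
        maps = rng.normal(size=(16, 50))
        maps[:8] += np.linspace(0, 1.5, 50)
        design = np.column_stack([np.ones(16), np.r_[np.ones(8), np.zeros(8)]])
        res = permutation_fwe(maps, design, n_perm=200, seed=1)
        order = np.argsort(np.abs(res.t))
        diffs = np.diff(res.fwe_p[order])
        assert (diffs <= 1e-12).all()
        assert (res.fwe_p >= res.p_uncorrected - 1e-12).all()

    def test_reproducible_with_fixed_seed(self, rng):
        maps = rng.normal(size=(12, 40))
        design = np.column_stack([np.ones(12), np.r_[np.ones(6), np.zeros(6)]])
        a = permutation_fwe(maps, design, n_perm=150, seed=42)
        b = permutation_fwe(maps, design, n_perm=150, seed=42)
        np.testing.assert_array_equal(a.fwe_p, b.fwe_p)

    def test_small_n_perm_rejected(self, rng):
        maps = rng.normal(size=(8, 10))
        design = np.column_stack([np.ones(8), np.r_[np.ones(4), np.zeros(4)]])
        with pytest.raises(ValueError):
            permutation_fwe(maps, design, n_perm=50)


class TestExtractClusters:
    def _maps_for(self, blob, shape=(8, 8, 8), t_val=-5.0):
        mask = _full_mask(shape)
        t = np.zeros(mask.n_voxels)
        p = np.ones(mask.n_voxels)
        cols = mask.lookup[tuple(np.asarray(blob).T)]
        t[cols] = t_val
        p[cols] = 0.01
        return t, p, mask

    def test_single_blob_reported_with_size(self):
        blob = [(x, y, z) for x in range(2, 5) for y in range(3, 6) for z in (2, 3, 4)]
        blob = blob[:19]
        t, p, mask = self._maps_for(blob)
        clusters = extract_clusters(t, p, mask, alpha=0.05)
        assert len(clusters) == 1
        assert clusters[0].n_voxels == 19
        assert clusters[0].sign == -1

    def test_no_significant_voxels_gives_empty_list(self):
        mask = _full_mask((4, 4, 4))
        assert extract_clusters(np.zeros(64), np.ones(64), mask) == []

    def test_diagonal_neighbors_split_by_connectivity(self):
        t, p, mask = self._maps_for([(1, 1, 1), (2, 2, 2)])
        assert len(extract_clusters(t, p, mask, connectivity=26)) == 1
        assert len(extract_clusters(t, p, mask, connectivity=6)) == 2

    def test_opposite_signs_never_merge(self):
        mask = _full_mask((4, 4, 4))
        t = np.zeros(64)
        p = np.ones(64)
        cols = mask.lookup[1, 1, 1], mask.lookup[1, 1, 2]
        t[cols[0]], t[cols[1]] = -4.0, 4.0
        p[list(cols)] = 0.01
        clusters = extract_clusters(t, p, mask)
        assert len(clusters) == 2
        assert {c.sign for c in clusters} == {-1, 1}


class TestClusterFeature:
    def test_single_voxel_cluster_returns_that_voxel(self, rng):
        mask = _full_mask((3, 3, 3))
        maps = rng.normal(size=(5, 27))
        t = np.zeros(27)
        p = np.ones(27)
        t[mask.lookup[1, 2, 0]] = -6.0
        p[mask.lookup[1, 2, 0]] = 0.001
        (cluster,) = extract_clusters(t, p, mask)
        np.testing.assert_array_equal(
            cluster_mean_feature(maps, mask, cluster), maps[:, mask.lookup[1, 2, 0]]
        )

    def test_constant_map_gives_constant_feature(self):
        mask = _full_mask((3, 3, 3))
        maps = np.full((4, 27), 2.5)
        t = np.full(27, -5.0)
        p = np.full(27, 0.01)
        (cluster,) = extract_clusters(t, p, mask)
        np.testing.assert_allclose(cluster_mean_feature(maps, mask, cluster), 2.5)


class TestScalarStats:
    def test_reported_correlation_p_value(self):
        # r = -0.476 with n = 19 patients -> p = 0.039 two-tailed
        assert round(pearson_p_from_r(-0.476, 19), 3) == 0.039

    def test_perfect_correlation(self):
        x = np.arange(10.0)
        r, p = pearson_r_p(x, 3 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-12

    def test_matches_scipy_pearsonr(self, rng):
        x, y = rng.normal(size=(2, 25))
        r, p = pearson_r_p(x, y)
        ref = stats.pearsonr(x, y)
        assert r == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_r_p(np.ones(10), np.arange(10.0))

    @pytest.mark.parametrize("alpha,m,expected", [(0.05, 2, 0.025), (0.05, 1, 0.05), (0.1, 5, 0.02)])
    def test_bonferroni(self, alpha, m, expected):
        assert bonferroni_threshold(alpha, m) == pytest.approx(expected)

    def test_age_comparison_from_group_summaries(self):
        # 38.74 +/- 10.71 (n=19) vs 39.62 +/- 6.62 (n=21) -> p = 0.75
        t, df, p = ttest_from_summary(38.74, 10.71, 19, 39.62, 6.62, 21)
        assert df == 38
        assert round(p, 2) == 0.75

    def test_equal_means_give_zero_t(self):
        t, _, p = ttest_from_summary(5.0, 1.0, 10, 5.0, 2.0, 12)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_summary_t_matches_raw_data_t(self, rng):
        a = rng.normal(size=15)
        b = rng.normal(size=18) + 0.4
        t_sum, _, p_sum = ttest_from_summary(
            a.mean(), a.std(ddof=1), 15, b.mean(), b.std(ddof=1), 18
        )
        ref = stats.ttest_ind(a, b, equal_var=True)
        assert t_sum == pytest.approx(ref.statistic, abs=1e-10)
        assert p_sum == pytest.approx(ref.pvalue, abs=1e-10)

    def test_sex_ratio_chi_square(self):
        # 9/10 male/female patients vs 6/15 controls -> p = 0.22
        chi2, df, p = chi2_2x2(9, 10, 6, 15)
        assert df == 1
        assert round(p, 2) == 0.22

    def test_proportional_table_gives_zero_chi2(self):
        chi2, _, p = chi2_2x2(10, 10, 10, 10)
        assert chi2 == 0.0 and p == pytest.approx(1.0)

    def test_chi2_matches_expected_count_formula_and_scipy(self):
        a, b, c, d = 7, 12, 9, 5
        chi2, _, p = chi2_2x2(a, b, c, d)
        obs = np.array([[a, b], [c, d]], dtype=float)
        expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        brute = ((obs - expected) ** 2 / expected).sum()
        assert chi2 == pytest.approx(brute, abs=1e-10)
        ref = stats.chi2_contingency(obs, correction=False)
        assert chi2 == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)


class TestRoiFc:
    def _bolds_from_series(self, series_a, series_b):
        """Embed two 1-voxel regions into tiny 4D volumes."""
        bolds = []
        for sa, sb in zip(series_a, series_b):
            data = np.zeros((2, 1, 1, sa.size))
            data[0, 0, 0] = sa
            data[1, 0, 0] = sb
            bolds.append(Bold4D(data=data, voxel_size_mm=3.0, tr_s=2.0))
        mask_a = np.array([[[True]], [[False]]])
        mask_b = np.array([[[False]], [[True]]])
        return bolds, mask_a, mask_b

    def test_identical_series_give_clipped_unit_r(self, rng):
        base = rng.normal(size=(8, 30))
        bolds, ma, mb = self._bolds_from_series(base, base.copy())
        with pytest.warns(UserWarning, match="clip"):
            res = roi_fc_group_test(bolds, ma, mb, np.r_[np.ones(4), np.zeros(4)])
        assert np.isfinite(res.z).all()
        assert res.z.min() > 5.0  # atanh near 1

    def test_planted_lower_coupling_detected(self, rng):
        shared = rng.normal(size=30)
        sa, sb = [], []
        groups = np.r_[np.ones(8), np.zeros(8)]
        for g in groups:
            w = 0.2 if g == 1 else 0.9
            sa.append(shared + rng.normal(0, 0.5, 30))
            sb.append(w * shared + rng.normal(0, 0.5, 30))
        bolds, ma, mb = self._bolds_from_series(np.array(sa), np.array(sb))
        res = roi_fc_group_test(bolds, ma, mb, groups)
        assert res.t < 0 and res.p < 0.05

    def test_null_type_one_error_calibrated(self):
        rejections = 0
        n_rep = 300
        rng = np.random.default_rng(777)
        groups = np.r_[np.ones(8), np.zeros(8)]
        for _ in range(n_rep):
            sa = rng.normal(size=(16, 25))
            sb = rng.normal(size=(16, 25))
            bolds, ma, mb = self._bolds_from_series(sa, sb)
            res = roi_fc_group_test(bolds, ma, mb, groups)
            rejections += res.p < 0.05
        rate = rejections / n_rep
        assert 0.012 < rate < 0.088  # 0.05 +/- 3 binomial SE
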
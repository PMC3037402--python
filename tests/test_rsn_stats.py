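import numpy as np
import pytest
from scipy import stats

from rsnparc import (
    GridSpec,
    clinical_correlation,
    cluster_threshold,
    group_mask,
    two_sample_t_cov,
)
from rsnparc.core import InvalidArgumentError
from rsnparc.rsn_stats import RankDeficiencyError, _one_sample_t


def _glm_oracle(yA, yB, cov):
    """Brute-force normal-equations GLM for one voxel."""
    y = np.concatenate([yA, yB])
    n = len(y)
    X = np.column_stack([np.ones(n), np.r_[np.ones(len(yA)), np.zeros(len(yB))], cov])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    df = n - 3
    sigma2 = resid @ resid / df
    se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
    return beta[1] / se, df


class TestGroupMask:
    def test_identical_groups_mask_equals_thresholded_map(self):
        rng = np.random.default_rng(0)
        maps = rng.standard_normal((13, 8, 8, 6)) + 1.0
        mask = group_mask({"a": maps, "b": maps}, p_thresh=0.001)
        t, df = _one_sample_t(maps)
        expected = t > stats.t.ppf(0.999, df)
        np.testing.assert_array_equal(mask, expected)

    def test_disjoint_activations_empty_mask(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal((10, 6, 6, 4)) * 0.1
        b = a.copy()
        a[:, :3] += 5.0
        b[:, 3:] += 5.0
        with pytest.warns(RuntimeWarning):
            mask = group_mask({"a": a, "b": b})
        assert not mask.any()

    def test_shared_planted_network_covered(self, small_grid):
        # subject maps = network + unit noise, per-voxel effect size 2 at peak
        from rsnparc import make_rsfmri_cohort

        _, truth = make_rsfmri_cohort(small_grid, 1, 1, seed=2, n_timepoints=64)
        net = truth.network_maps[0]
        rng = np.random.default_rng(3)
        a = 2.0 * net + rng.standard_normal((13, *net.shape))
        b = 2.0 * net + rng.standard_normal((13, *net.shape))
        mask = group_mask({"a": a, "b": b}, p_thresh=0.001)
        support = net >= 0.8
        assert mask[support].mean() >= 0.8


class TestTwoSampleTCov:
    def test_identical_groups_zero_covariate_all_zero_t(self):
        rng = np.random.default_rng(4)
        a = rng.standard_normal((5, 4, 4, 3))
        stat = two_sample_t_cov(a, a.copy(), covariate=np.zeros(10))
        np.testing.assert_allclose(stat.t_values, 0.0, atol=1e-10)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        yA = rng.standard_normal(3) + 1.0
        yB = rng.standard_normal(3)
        cov = rng.standard_normal(6)
        stat = two_sample_t_cov(yA[:, None], yB[:, None], covariate=cov)
        t_oracle, df = _glm_oracle(yA, yB, cov)
        assert stat.t_values[0] == pytest.approx(t_oracle, abs=1e-10)
        assert stat.df == df == 3

    def test_matches_oracle_on_many_voxels(self):
        rng = np.random.default_rng(6)
        a = rng.standard_normal((8, 50))
        b = rng.standard_normal((7, 50))
        cov = rng.standard_normal(15)
        stat = two_sample_t_cov(a, b, covariate=cov)
        for v in range(0, 50, 7):
            t_oracle, _ = _glm_oracle(a[:, v], b[:, v], cov)
            assert stat.t_values[v] == pytest.approx(t_oracle, abs=1e-10)

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(7)
        a = rng.standard_normal((13, 1000))
        b = rng.standard_normal((13, 1000))
        cov = rng.standard_normal(26)
        stat = two_sample_t_cov(a, b, covariate=cov)
        crit = stats.t.ppf(1 - 0.001 / 2, stat.df)
        rate = np.mean(np.abs(stat.t_values) > crit)
        # nominal 0.1%; 3 binomial SE at 1000 voxels
        assert rate <= 0.001 + 3 * np.sqrt(0.001 * 0.999 / 1000)

    def test_collinear_covariate_rejected(self):
        rng = np.random.default_rng(8)
        a, b = rng.standard_normal((3, 5)), rng.standard_normal((3, 5))
        group_coded = np.array([2.0, 2.0, 2.0, -1.0, -1.0, -1.0])
        with pytest.raises(RankDeficiencyError):
            two_sample_t_cov(a, b, covariate=group_coded)


class TestClusterThreshold:
    def test_no_suprathreshold_voxels_empty_report(self):
        rng = np.random.default_rng(9)
        a = rng.standard_normal((6, 5, 5, 4)) * 1e-3
        stat = cluster_threshold(a, a.copy(), n_perm=100, seed=0)
        assert stat.clusters.empty
        assert stat.cluster_labels.max() == 0

    def test_planted_cluster_detected_and_covered(self):
        rng = np.random.default_rng(10)
        shape = (10, 10, 8)
        effect = np.zeros(shape)
        effect[3:8, 3:7, 3:4] = 3.0          # 20-voxel planted cluster
        a = effect + rng.standard_normal((10, *shape)) * 0.5
        b = rng.standard_normal((10, *shape)) * 0.5
        stat = cluster_threshold(a, b, n_perm=300, seed=1, k_min=5)
        sig = stat.significant_clusters
        assert len(sig) == 1
        lab = int(sig.iloc[0]["label"])
        covered = (stat.cluster_labels == lab) & (effect > 0)
        assert covered.sum() >= 0.9 * 20

    def test_small_extent_excluded_by_k_min(self):
        rng = np.random.default_rng(11)
        shape = (8, 8, 6)
        effect = np.zeros(shape)
        effect[2:4, 3:5, 2] = 10.0           # extent-4 effect, arbitrarily strong
        a = effect + rng.standard_normal((8, *shape)) * 0.3
        b = rng.standard_normal((8, *shape)) * 0.3
        stat = cluster_threshold(a, b, n_perm=200, seed=2, k_min=5)
        four_vox = stat.clusters[stat.clusters["extent"] <= 4]
        assert not four_vox.empty          # the effect is found...
        assert not four_vox["significant"].any()  # ...but never reported

    def test_null_family_wise_error_controlled(self):
        rng = np.random.default_rng(12)
        fp = 0
        reps = 15
        for r in range(reps):
            a = rng.standard_normal((8, 9, 9, 7))
            b = rng.standard_normal((8, 9, 9, 7))
            stat = cluster_threshold(a, b, n_perm=300, seed=r, k_min=5)
            fp += int((not stat.clusters.empty) and stat.clusters["significant"].any())
        assert fp / reps <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / reps)

    def test_low_permutation_count_warns(self):
        rng = np.random.default_rng(13)
        a = rng.standard_normal((4, 4, 4, 3))
        with pytest.warns(RuntimeWarning):
            cluster_threshold(a, a.copy(), n_perm=50, seed=0)

    def test_peak_world_coordinates_round_trip(self):
        rng = np.random.default_rng(14)
        grid = GridSpec(dims=(8, 8, 6), voxel_size=(3, 3, 4))
        effect = np.zeros(grid.dims)
        effect[2:6, 2:6, 2:4] = 3.0
        a = effect + rng.standard_normal((8, *grid.dims)) * 0.5
        b = rng.standard_normal((8, *grid.dims)) * 0.5
        stat = cluster_threshold(a, b, n_perm=150, seed=3, grid=grid)
        for _, row in stat.clusters.iterrows():
            back = grid.world_to_voxel(np.array(row["peak_world"]))[0]
            np.testing.assert_array_equal(back, np.array(row["peak_ijk"], dtype=float))


class TestClinicalCorrelation:
    def test_planted_amplitude_score_correlates_at_peak(self, small_grid):
        rng = np.random.default_rng(15)
        net = np.zeros(small_grid.dims)
        net[5:9, 6:10, 4:8] = 1.0
        amp = rng.uniform(0.5, 2.0, size=13)
        maps = amp[:, None, None, None] * net + 0.05 * rng.standard_normal((13, *small_grid.dims))
        peak = (6, 7, 5)
        out = clinical_correlation(maps, amp, [peak], small_grid, svc_radius=10.0)
        assert abs(out.iloc[0]["r"]) > 0.9
        assert out.iloc[0]["significant"]

    def test_permuted_score_false_positive_rate(self, small_grid):
        rng = np.random.default_rng(16)
        net = np.zeros(small_grid.dims)
        net[5:9, 6:10, 4:8] = 1.0
        amp = rng.uniform(0.5, 2.0, size=13)
        maps = amp[:, None, None, None] * net + 0.05 * rng.standard_normal((13, *small_grid.dims))
        hits = 0
        reps = 40
        for _ in range(reps):
            shuffled = rng.permutation(amp)
            out = clinical_correlation(maps, shuffled, [(6, 7, 5)], small_grid)
            hits += int(out.iloc[0]["significant"])
        # Bonferroni SVC is conservative; rate must not exceed nominal + MC
        assert hits / reps <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / reps)

    def test_radius_zero_is_single_uncorrected_voxel(self, small_grid):
        rng = np.random.default_rng(17)
        maps = rng.standard_normal((8, *small_grid.dims))
        score = rng.standard_normal(8)
        out = clinical_correlation(maps, score, [(3, 3, 3)], small_grid, svc_radius=0.0)
        assert out.iloc[0]["n_sphere_voxels"] == 1
        r, p = stats.pearsonr(maps[:, 3, 3, 3], score)
        assert out.iloc[0]["r"] == pytest.approx(r)
        assert out.iloc[0]["p_svc"] == pytest.approx(p)

    def test_constant_score_rejected(self, small_grid):
        maps = np.zeros((6, *small_grid.dims))
        with pytest.raises(InvalidArgumentError):
            clinical_correlation(maps, np.ones(6), [(1, 1, 1)], small_grid)
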
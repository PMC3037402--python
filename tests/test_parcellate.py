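import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rsnparc import (
    aggregate_profiles,
    choose_k,
    compare_centroids,
    concat_profiles,
    extract_seeds,
    make_profile_cohort,
    seed_count_stats,
    silhouette_mean,
)
from rsnparc.core import InvalidArgumentError
from rsnparc.parcellate import ConnectivityParcellation, EmptyRoiError


def silhouette_bruteforce(X, labels):
    """Double-loop Rousseeuw silhouette oracle (Euclidean)."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n = len(X)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d[i, j] = np.sqrt(((X[i] - X[j]) ** 2).sum())
    vals = []
    for i in range(n):
        own = labels == labels[i]
        if own.sum() == 1:
            vals.append(0.0)
            continue
        a = d[i, own].sum() / (own.sum() - 1)
        b = min(d[i, labels == c].mean() for c in set(labels) if c != labels[i])
        vals.append((b - a) / max(a, b))
    return float(np.mean(vals))


class TestExtractSeeds:
    def _slab(self, shape=(10, 18, 5), boundary=10):
        gm = np.zeros(shape)
        gm[:, :boundary, :] = 1.0
        return gm, np.zeros(shape), np.ones(shape)

    def test_analytic_slab_boundary_exact(self):
        gm, csf, roi = self._slab()
        seeds = extract_seeds(gm, csf, roi)
        # hand-derived: the GM->WM step at y=9/10 activates the Sobel rows
        # on both sides of the interface, across all x and z
        expected = {
            (x, y, z) for x in range(10) for y in (9, 10) for z in range(5)
        }
        assert set(map(tuple, seeds.coords)) == expected

    def test_roi_restriction(self):
        gm, csf, roi = self._slab()
        roi[:] = 0.0
        roi[3:6, :, :] = 0.6
        seeds = extract_seeds(gm, csf, roi, roi_thresh=0.5)
        assert set(seeds.coords[:, 0]) == {3, 4, 5}

    def test_uniform_gm_has_no_boundary(self):
        shape = (8, 8, 4)
        with pytest.raises(EmptyRoiError):
            extract_seeds(np.ones(shape), np.zeros(shape), np.ones(shape))

    def test_csf_notch_removes_adjacent_seeds(self):
        gm, csf, roi = self._slab()
        base = set(map(tuple, extract_seeds(gm, csf, roi).coords))
        csf_notch = np.zeros_like(csf)
        notch = [(5, 9, 2), (5, 10, 2)]
        for v in notch:
            csf_notch[v] = 1.0
        got = set(map(tuple, extract_seeds(gm, csf_notch, roi).coords))
        # hand-derived removal: the notch voxels and their 6-neighbors
        removed = set()
        for v in notch:
            removed.add(v)
            for ax in range(3):
                for dd in (-1, 1):
                    w = list(v)
                    w[ax] += dd
                    removed.add(tuple(w))
        assert base - got == removed & base


class TestAggregateProfiles:
    def test_single_region_single_column(self):
        counts = np.zeros((2, 4, 4, 4), dtype=int)
        counts[:, 1, 1, 1] = 5
        atlas = np.zeros((4, 4, 4), dtype=int)
        atlas[:2] = 3
        prof = aggregate_profiles(counts, atlas)
        assert list(prof.columns) == ["region_03"]
        assert (prof["region_03"] == 5).all()

    def test_excluded_region_column_absent(self):
        counts = np.ones((1, 4, 4, 4), dtype=int)
        atlas = np.zeros((4, 4, 4), dtype=int)
        atlas[:2] = 1
        atlas[2:] = 2
        prof = aggregate_profiles(counts, atlas, exclude=(1,))
        assert list(prof.columns) == ["region_02"]

    def test_unknown_exclusion_rejected(self):
        counts = np.zeros((1, 2, 2, 2), dtype=int)
        atlas = np.ones((2, 2, 2), dtype=int)
        with pytest.raises(InvalidArgumentError):
            aggregate_profiles(counts, atlas, exclude=(9,))

    def test_majority_downsampled_atlas(self):
        # counts at half resolution; atlas labels resolve by block majority
        counts = np.zeros((1, 2, 2, 2), dtype=int)
        counts[0, 0, 0, 0] = 7
        atlas = np.zeros((4, 4, 4), dtype=int)
        atlas[:2, :2, :2] = 4          # the block holding the visits
        atlas[2:, :, :] = 5
        prof = aggregate_profiles(counts, atlas)
        assert prof.loc[prof.index[0], "region_04"] == 7
        assert prof.loc[prof.index[0], "region_05"] == 0

    def test_tracker_two_target_profiles_cluster(self):
        from rsnparc.synthgen import toy_tracker

        dims = (10, 21, 5)
        field = np.zeros((*dims, 3))
        field[:5, ..., 1] = 1.0
        field[5:, ..., 1] = -1.0
        seeds = [(x, 10, 2) for x in range(10)]
        counts = toy_tracker(field, seeds, n_samples=30, step=1.0, angle_sd=5.0, seed=0)
        atlas = np.zeros(dims, dtype=int)
        atlas[:, 16:, :] = 1
        atlas[:, :5, :] = 2
        prof = aggregate_profiles(counts, atlas)
        from sklearn.cluster import KMeans

        pred = KMeans(n_clusters=2, n_init=5, random_state=0).fit_predict(
            prof.to_numpy() / prof.to_numpy().sum(axis=1, keepdims=True)
        )
        assert len(set(pred[:5])) == 1 and len(set(pred[5:])) == 1
        assert pred[0] != pred[5]


class TestSilhouette:
    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(0)
        for trial in range(5):
            n = int(rng.integers(10, 50))
            k = int(rng.integers(2, 5))
            X = rng.standard_normal((n, 6))
            labels = rng.integers(0, k, size=n)
            if len(np.unique(labels)) < 2 or np.all(np.bincount(labels) <= 1):
                continue
            got = silhouette_mean(X, labels)
            assert got == pytest.approx(silhouette_bruteforce(X, labels), abs=1e-12)

    def test_separated_clouds_high_silhouette(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.standard_normal((20, 3)), rng.standard_normal((20, 3)) + 30])
        labels = np.r_[np.zeros(20), np.ones(20)]
        assert silhouette_mean(X, labels) > 0.9

    def test_random_labels_near_zero(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((60, 4))
        vals = [
            silhouette_mean(X, rng.integers(0, 2, size=60)) for _ in range(10)
        ]
        assert abs(np.mean(vals)) < 0.05

    def test_singleton_only_clustering_undefined(self):
        with pytest.raises(InvalidArgumentError):
            silhouette_mean(np.eye(3), np.array([0, 1, 2]))

    def test_similarity_ratio_variant_orders_like_standard(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.standard_normal((15, 3)), rng.standard_normal((15, 3)) + 10])
        good = np.r_[np.zeros(15), np.ones(15)]
        bad = rng.integers(0, 2, size=30)
        sr = lambda lab: silhouette_mean(X, lab, variant="similarity_ratio")
        assert sr(good) > sr(bad)
        assert -1.0 <= sr(bad) <= sr(good) <= 1.0


class TestChooseK:
    def _group_profiles(self, k, seed, sep=1.0, n_seeds=30, n_sub=4):
        profiles, truth = make_profile_cohort(
            n_seeds, 48, (k, k), sep, seed=seed, n_subjects_per_group=n_sub
        )
        dfs = [df for df in profiles if df.attrs["group"] == "patient"]
        return concat_profiles(dfs), truth

    @pytest.mark.parametrize("k", [2, 4])
    def test_recovers_planted_k(self, k):
        mat, _ = self._group_profiles(k, seed=10 + k)
        res = choose_k(mat, n_restarts=10, seed=0)
        assert res.chosen_k == k
        assert res.labels.min() == 1 and res.labels.max() == k
        assert res.silhouette_curve.idxmax() == k

    def test_group_design_two_vs_four(self):
        profiles, truth = make_profile_cohort(
            30, 48, (4, 2), 1.0, seed=3, n_subjects_per_group=4
        )
        chosen = {}
        for group in ("patient", "control"):
            dfs = [df for df in profiles if df.attrs["group"] == group]
            chosen[group] = choose_k(concat_profiles(dfs), n_restarts=10, seed=0).chosen_k
        assert chosen == {"patient": 4, "control": 2}

    def test_zero_separation_flags_no_structure(self):
        mat, _ = self._group_profiles(2, seed=4, sep=0.0)
        res = choose_k(mat, n_restarts=5, seed=0)
        assert res.no_structure and res.chosen_k is None

    def test_invariant_to_row_permutation_and_scaling(self):
        mat, _ = self._group_profiles(3, seed=5)
        res = choose_k(mat, n_restarts=10, seed=0)
        rng = np.random.default_rng(6)
        perm = rng.permutation(len(mat))
        res_p = choose_k(mat.iloc[perm], n_restarts=10, seed=0)
        res_s = choose_k(mat * 10, n_restarts=10, seed=0)
        assert res_p.chosen_k == res.chosen_k == res_s.chosen_k
        np.testing.assert_allclose(
            res.silhouette_curve.to_numpy(), res_s.silhouette_curve.to_numpy(), atol=1e-9
        )

    def test_per_subject_seed_counts_complete(self):
        mat, _ = self._group_profiles(2, seed=7)
        res = choose_k(mat, n_restarts=5, seed=0)
        assert res.seed_counts.shape == (4, 2)
        assert (res.seed_counts.sum(axis=1) == 30).all()

    def test_too_few_seeds_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ConnectivityParcellation(k_range=(2, 15)).fit(np.random.default_rng(0).random((10, 5)))


class TestCompareCentroids:
    def _result(self, centroids):
        df = pd.DataFrame(
            centroids,
            index=range(1, len(centroids) + 1),
            columns=[f"region_{j:02d}" for j in range(centroids.shape[1])],
        )
        counts = pd.DataFrame(
            np.random.default_rng(0).integers(3, 10, size=(4, len(centroids))),
            index=[f"sub-{i}" for i in range(4)],
            columns=[f"cluster_{c}" for c in range(1, len(centroids) + 1)],
        )
        from rsnparc.parcellate import ParcellationResult

        return ParcellationResult(
            labels=np.ones(10, dtype=int), centroids=df, chosen_k=len(centroids),
            seed_counts=counts,
        )

    def test_identical_results_all_unchanged_or_absent(self):
        rng = np.random.default_rng(1)
        c = rng.random((3, 6)) + 0.1
        comp = compare_centroids(self._result(c), self._result(c.copy()))
        assert set(comp.table["class"]) <= {"unchanged", "absent"}
        assert comp.unmatched_a == comp.unmatched_b == []

    def test_extra_peak_in_b_flagged_group_unique(self):
        rng = np.random.default_rng(2)
        c = rng.random((2, 6)) + 0.2
        c2 = c.copy()
        c[0, 5] = 0.0          # region absent in A...
        c2[0, 5] = 0.5         # ...present in B
        comp = compare_centroids(self._result(c), self._result(c2))
        row = comp.table[(comp.table["cluster_a"] == 1) & (comp.table["region"] == "region_05")]
        assert row["class"].item() == "present-in-B-only"

    def test_doubled_amplitude_flagged_increased(self):
        rng = np.random.default_rng(3)
        c = rng.random((2, 6)) + 0.2
        c2 = c.copy()
        c[1, 2] *= 2.0
        comp = compare_centroids(self._result(c), self._result(c2))
        row = comp.table[(comp.table["cluster_a"] == 2) & (comp.table["region"] == "region_02")]
        assert row["class"].item() == "increased"

    def test_reports_are_mirrored(self):
        rng = np.random.default_rng(4)
        a, b = rng.random((3, 6)) + 0.1, rng.random((3, 6)) + 0.1
        ra, rb = self._result(a), self._result(b)
        ab = compare_centroids(ra, rb)
        ba = compare_centroids(rb, ra)
        flip = {
            "present-in-A-only": "present-in-B-only",
            "present-in-B-only": "present-in-A-only",
            "increased": "decreased",
            "decreased": "increased",
            "unchanged": "unchanged",
            "absent": "absent",
        }
        key = lambda t: t.sort_values(["cluster_a", "cluster_b", "region"], ignore_index=True)
        tab_ab = key(ab.table)
        tab_ba = ba.table.rename(columns={"cluster_a": "cluster_b", "cluster_b": "cluster_a"})
        tab_ba["class"] = tab_ba["class"].map(flip)
        tab_ba = key(tab_ba)
        assert tab_ab["class"].tolist() == tab_ba["class"].tolist()

    def test_unequal_k_reports_group_unique_cluster(self):
        rng = np.random.default_rng(5)
        a = rng.random((2, 6)) + 0.1
        b = np.vstack([a + 0.01 * rng.random((2, 6)), rng.random((1, 6)) + 0.1])
        comp = compare_centroids(self._result(a), self._result(b))
        assert comp.unmatched_a == []
        assert len(comp.unmatched_b) == 1


class TestSeedCountStats:
    def test_identical_groups_zero_t(self):
        rng = np.random.default_rng(6)
        c = rng.random((2, 6)) + 0.1
        maker = TestCompareCentroids()
        ra, rb = maker._result(c), maker._result(c.copy())
        rb.seed_counts = ra.seed_counts.copy()
        out = seed_count_stats(ra, rb)
        np.testing.assert_allclose(out["t_tests"]["t"], 0.0, atol=1e-12)

    def test_shifted_counts_give_signed_t(self):
        rng = np.random.default_rng(7)
        c = rng.random((2, 6)) + 0.1
        maker = TestCompareCentroids()
        ra, rb = maker._result(c), maker._result(c.copy())
        rb.seed_counts = ra.seed_counts + 5
        out = seed_count_stats(ra, rb)
        assert (out["t_tests"]["t"] < 0).all()

    def test_spearman_matches_rank_formula(self):
        maker = TestCompareCentroids()
        c = np.random.default_rng(8).random((1, 6)) + 0.1
        ra, rb = maker._result(c), maker._result(c.copy())
        ra.seed_counts = pd.DataFrame(
            {"cluster_1": [4.0, 7.0, 11.0]}, index=["s1", "s2", "s3"]
        )
        scores = pd.DataFrame({"score": [2.0, 9.0, 5.0]}, index=["s1", "s2", "s3"])
        out = seed_count_stats(ra, rb, scores=scores)
        row = out["correlations"].query("group == 'A' and score == 'score'")
        # rank formula: rho = 1 - 6*sum(d^2)/(n(n^2-1)); ranks (1,2,3) vs (1,3,2)
        rho_oracle = 1 - 6 * 2 / (3 * 8)
        assert row["rho"].item() == pytest.approx(rho_oracle, abs=1e-12)
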
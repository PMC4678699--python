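"""ISODATA core: distances, initialization, discard/split/merge, full loop."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from stisodata.isodata import (
    IsodataParams,
    assign_voxels,
    derive_dispersion_params,
    discard_small_clusters,
    global_covariance,
    initialize_centroids,
    inter_cluster_distances,
    intra_cluster_distances,
    mahalanobis,
    merge_clusters,
    run_isodata,
    split_cluster,
)

from conftest import make_features, two_blob_features


class TestMahalanobis:
    def test_zero_iff_equal(self):
        x = np.array([1.0, 2.0, 3.0])
        assert mahalanobis(x, x, np.ones(3)) == 0.0
        assert mahalanobis(x, x + 1e-3, np.ones(3)) > 0.0

    def test_identity_reduces_to_euclidean(self):
        assert mahalanobis([1.0, 0.0], [0.0, 0.0], np.ones(2)) == pytest.approx(1.0)

    def test_diagonal_quadratic_form_by_hand(self):
        # diff (2, 0), cov diag(4, 1): sqrt(4/4) = 1
        assert mahalanobis([2.0, 0.0], [0.0, 0.0], np.array([4.0, 1.0])) == pytest.approx(1.0)

    def test_full_matrix_matches_diagonal(self):
        d = np.array([0.3, -1.2])
        diag = np.array([2.0, 5.0])
        assert mahalanobis(d, np.zeros(2), diag) == pytest.approx(
            mahalanobis(d, np.zeros(2), np.diag(diag))
        )

    def test_singular_covariance_rejected(self):
        with pytest.raises(np.linalg.LinAlgError):
            mahalanobis([1.0, 0.0], [0.0, 0.0], np.zeros((2, 2)))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mahalanobis([1.0], [0.0, 0.0], np.ones(2))


class TestDeriveDispersionParams:
    def _features_with_rois(self, wm_vals, gm_vals):
        X = np.vstack([wm_vals, gm_vals]).astype(float)
        feats = make_features(X)
        n_wm = len(wm_vals)
        wm = np.zeros(feats.shape, dtype=bool)
        wm[:n_wm, 0, 0] = True
        gm = np.zeros(feats.shape, dtype=bool)
        gm[n_wm:, 0, 0] = True
        return feats, wm, gm

    def test_identical_means_give_zero_phi_c(self):
        feats, wm, gm = self._features_with_rois(
            [[0.0, 1.0], [2.0, 1.0]], [[1.0, 0.0], [1.0, 2.0]]
        )
        phi_c, _ = derive_dispersion_params(feats, wm, gm)
        assert phi_c == pytest.approx(0.0)

    def test_constant_wm_gives_zero_phi_s(self):
        feats, wm, gm = self._features_with_rois(
            [[1.0, 1.0], [1.0, 1.0]], [[2.0, 3.0], [4.0, 5.0]]
        )
        _, phi_s = derive_dispersion_params(feats, wm, gm)
        assert phi_s == 0.0

    def test_phi_s_is_population_sd_of_pooled_wm_values(self):
        # WM values pooled over rows and columns {0, 2}: population sd = 1
        feats, wm, gm = self._features_with_rois(
            [[0.0, 2.0], [2.0, 0.0]], [[1.0, 1.0], [1.0, 1.0]]
        )
        _, phi_s = derive_dispersion_params(feats, wm, gm)
        assert phi_s == pytest.approx(1.0)

    def test_empty_roi_rejected(self):
        feats, wm, gm = self._features_with_rois([[0.0, 1.0]], [[1.0, 0.0]])
        with pytest.raises(ValueError, match=">= 2"):
            derive_dispersion_params(feats, wm, gm)


class TestInitializeCentroids:
    def test_k1_returns_a_data_row(self):
        feats, _ = two_blob_features(n_per=20, seed=1)
        c = initialize_centroids(feats, 1, np.random.default_rng(0))
        assert any(np.allclose(c[0], row) for row in feats.data)

    def test_seed_determinism(self):
        feats, _ = two_blob_features(n_per=50, seed=2)
        a = initialize_centroids(feats, 4, np.random.default_rng(9))
        b = initialize_centroids(feats, 4, np.random.default_rng(9))
        np.testing.assert_array_equal(a, b)

    def test_far_clouds_both_represented(self):
        # With two well-separated clouds and k=2, the distance-proportional
        # rule should pick one centroid per cloud nearly always.
        feats, labels = two_blob_features(n_per=50, separation=50.0, seed=3)
        hits = 0
        for seed in range(100):
            c = initialize_centroids(feats, 2, np.random.default_rng(seed))
            sides = {int(row[0] > 25.0) for row in c}
            hits += sides == {0, 1}
        assert hits >= 95

    def test_k_larger_than_rows_rejected(self):
        feats = make_features(np.zeros((3, 2)))
        with pytest.raises(ValueError):
            initialize_centroids(feats, 4, np.random.default_rng(0))

    def test_duplicate_rows_cannot_support_k(self):
        feats = make_features(np.ones((10, 2)))
        with pytest.raises(ValueError, match="distinct"):
            initialize_centroids(feats, 3, np.random.default_rng(0))


class TestAssignVoxels:
    def test_single_centroid_takes_all(self):
        X = np.random.default_rng(0).normal(size=(20, 3))
        out = assign_voxels(X, X[:1] * 0.0, np.ones(3))
        assert (out == 0).all()

    def test_row_equal_to_centroid_assigned_there(self):
        centroids = np.array([[0.0, 0.0], [5.0, 5.0]])
        out = assign_voxels(np.array([[5.0, 5.0]]), centroids, np.ones(2))
        assert out[0] == 1

    def test_two_centroid_hand_case(self):
        centroids = np.array([[0.0, 0.0], [10.0, 0.0]])
        out = assign_voxels(np.array([[4.0, 0.0]]), centroids, np.ones(2))
        assert out[0] == 0

    def test_tie_broken_by_lowest_id(self):
        centroids = np.array([[0.0, 0.0], [2.0, 0.0]])
        out = assign_voxels(np.array([[1.0, 0.0]]), centroids, np.ones(2))
        assert out[0] == 0


class TestDiscardSmallClusters:
    def test_all_large_enough_unchanged(self):
        X = np.vstack([np.zeros((5, 2)), np.ones((5, 2)) * 10])
        centroids = np.array([[0.0, 0.0], [10.0, 10.0]])
        assignments = np.repeat([0, 1], 5)
        c, a = discard_small_clusters(X, centroids, assignments, np.ones(2), 3)
        np.testing.assert_array_equal(a, assignments)

    def test_small_cluster_absorbed_by_nearest(self):
        X = np.vstack([np.zeros((10, 2)), np.ones((2, 2)) * 2, np.ones((10, 2)) * 10])
        centroids = np.array([[0.0, 0.0], [2.0, 2.0], [10.0, 10.0]])
        assignments = np.repeat([0, 1, 2], [10, 2, 10])
        c, a = discard_small_clusters(X, centroids, assignments, np.ones(2), 5)
        assert len(c) == 2
        sizes = np.bincount(a)
        assert (sizes >= 5).all()
        # the two orphans sit at (2,2): nearest survivor is the origin cluster
        assert (a[10:12] == 0).all()

    def test_all_below_threshold_rejected(self):
        X = np.array([[0.0, 0.0], [10.0, 10.0]])
        with pytest.raises(ValueError, match="phi_n"):
            discard_small_clusters(
                X, X.copy(), np.array([0, 1]), np.ones(2), 5
            )


class TestSplitMerge:
    def test_split_recovers_two_blobs(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 0.1, size=(50, 2))
        b = rng.normal(0, 0.1, size=(50, 2)) + [8.0, 0.0]
        X = np.vstack([a, b])
        centroids = X.mean(axis=0, keepdims=True)
        assignments = np.zeros(len(X), dtype=int)
        c, a2, did = split_cluster(X, centroids, assignments, np.ones(2), 0, 5)
        assert did and len(c) == 2
        labels = np.repeat([0, 1], 50)
        assert adjusted_rand_score(labels, a2) == 1.0

    def test_split_skipped_when_child_below_phi_n(self):
        X = np.vstack([np.zeros((40, 2)), [[8.0, 0.0]] * 2])
        centroids = X.mean(axis=0, keepdims=True)
        c, a2, did = split_cluster(
            X, centroids, np.zeros(len(X), dtype=int), np.ones(2), 0, 10
        )
        assert not did and len(c) == 1

    def test_no_merge_when_all_pairs_separated(self):
        X = np.repeat([[0.0, 0.0], [10.0, 10.0]], 5, axis=0)
        centroids = np.array([[0.0, 0.0], [10.0, 10.0]])
        assignments = np.repeat([0, 1], 5)
        c, a2, did = merge_clusters(
            X, centroids.copy(), assignments, np.ones(2), 1.0, 1, 1
        )
        assert not did and len(c) == 2

    def test_identical_centroids_merge_first(self):
        X = np.repeat([[0.0, 0.0], [0.0, 0.0], [9.0, 9.0]], 4, axis=0)
        centroids = np.array([[0.0, 0.0], [0.0, 0.0], [9.0, 9.0]])
        assignments = np.repeat([0, 1, 2], 4)
        c, a2, did = merge_clusters(
            X, centroids.copy(), assignments, np.ones(2), 1.0, 1, 1
        )
        assert did and len(c) == 2

    def test_at_most_l_merges_per_call(self):
        # three mutually close clusters, L = 1: exactly one merge
        X = np.repeat([[0.0, 0.0], [0.1, 0.0], [0.2, 0.0]], 4, axis=0)
        centroids = np.array([[0.0, 0.0], [0.1, 0.0], [0.2, 0.0]])
        assignments = np.repeat([0, 1, 2], 4)
        c, a2, did = merge_clusters(
            X, centroids.copy(), assignments, np.ones(2), 5.0, 1, 1
        )
        assert did and len(c) == 2

    def test_merge_respects_lower_bound(self):
        X = np.repeat([[0.0, 0.0], [0.1, 0.0]], 4, axis=0)
        centroids = np.array([[0.0, 0.0], [0.1, 0.0]])
        assignments = np.repeat([0, 1], 4)
        c, _, did = merge_clusters(
            X, centroids.copy(), assignments, np.ones(2), 5.0, 3, 2
        )
        assert not did and len(c) == 2


class TestRunIsodata:
    def _blob_params(self, **kw):
        defaults = dict(phi_n=10, phi_c=1.0, phi_s=3.0, k_init=2, k_anchor=1,
                        max_iter=50, eps_r=1e-4, max_merges=1)
        defaults.update(kw)
        return IsodataParams(**defaults)

    def test_two_blobs_recovered_exactly(self):
        feats, labels = two_blob_features(n_per=200, separation=10.0, seed=5)
        model = run_isodata(feats, self._blob_params(), seed=5)
        assert model.n_clusters == 2
        assert adjusted_rand_score(labels, model.assignments) == 1.0

    def test_single_blob_merges_to_lower_bound(self):
        rng = np.random.default_rng(6)
        feats = make_features(rng.normal(size=(300, 2)))
        model = run_isodata(
            feats, self._blob_params(k_init=4, phi_c=50.0, phi_s=50.0), seed=6
        )
        assert model.n_clusters == 1

    def test_seed_determinism_bit_identical(self):
        feats, _ = two_blob_features(n_per=100, seed=7)
        m1 = run_isodata(feats, self._blob_params(), seed=11)
        m2 = run_isodata(feats, self._blob_params(), seed=11)
        np.testing.assert_array_equal(m1.assignments, m2.assignments)
        np.testing.assert_array_equal(m1.centroids, m2.centroids)

    def test_every_row_assigned_every_iteration(self):
        feats, _ = two_blob_features(n_per=100, seed=8)
        model = run_isodata(feats, self._blob_params(), seed=8)
        assert len(model.assignments) == feats.n_voxels
        for rec in model.iteration_log:
            assert sum(rec["sizes"]) == feats.n_voxels

    def test_final_count_in_allowed_range_and_sizes_above_phi_n(self):
        feats, _ = two_blob_features(n_per=200, separation=10.0, seed=9)
        params = self._blob_params(k_anchor=1)
        model = run_isodata(feats, params, seed=9)
        assert params.min_clusters <= model.n_clusters <= params.max_clusters
        assert (model.cluster_sizes() >= params.phi_n).all()

    def test_assignment_never_increases_total_dispersion(self):
        # For fixed centroids, reassignment minimizes each row's distance, so
        # the summed within-cluster dispersion cannot grow. Oracle: recompute
        # both sums directly.
        rng = np.random.default_rng(10)
        X = rng.normal(size=(100, 3))
        feats = make_features(X)
        cov = global_covariance(feats)
        centroids = X[:4].copy()
        before_assign = rng.integers(0, 4, size=100)

        def total(assignments):
            return sum(
                mahalanobis(X[i], centroids[assignments[i]], cov) ** 2
                for i in range(len(X))
            )

        after = assign_voxels(X, centroids, cov)
        assert total(after) <= total(before_assign) + 1e-12

    def test_reduces_to_lloyd_kmeans_fixed_point(self):
        # With discard/split/merge disabled the loop is Lloyd's algorithm
        # under Mahalanobis distance; its fixed point must match a
        # brute-force Lloyd iteration run to convergence from the same init.
        rng = np.random.default_rng(12)
        X = np.vstack([
            rng.normal(0, 1, size=(100, 2)),
            rng.normal(6, 1, size=(100, 2)),
        ])
        feats = make_features(X)
        params = IsodataParams(
            phi_n=1, phi_c=1e-12, phi_s=np.inf, k_init=3, k_anchor=2,
            max_iter=200, eps_r=1e-12, max_merges=1,
        )
        model = run_isodata(feats, params, seed=13)

        cov = global_covariance(feats)
        centroids = initialize_centroids(feats, 3, np.random.default_rng(13))
        for _ in range(500):
            a = assign_voxels(X, centroids, cov)
            new = []
            for j in range(len(centroids)):
                members = X[a == j]
                new.append(members.mean(axis=0) if len(members) else centroids[j])
            new = np.array([c for j, c in enumerate(new) if (a == j).any()])
            if new.shape == centroids.shape and np.allclose(new, centroids):
                break
            centroids = new
        oracle = assign_voxels(X, centroids, cov)
        assert adjusted_rand_score(oracle, model.assignments) == 1.0

    def test_missing_dispersion_params_rejected(self):
        feats, _ = two_blob_features(n_per=20, seed=14)
        with pytest.raises(ValueError, match="phi_c and phi_s"):
            run_isodata(feats, IsodataParams(phi_n=2), seed=0)

    def test_d_intra_d_inter_definitions(self):
        X = np.array([[0.0], [2.0], [10.0], [12.0]])
        centroids = np.array([[1.0], [11.0]])
        assignments = np.array([0, 0, 1, 1])
        cov = np.ones(1)
        di = intra_cluster_distances(X, centroids, assignments, cov)
        np.testing.assert_allclose(di, [1.0, 1.0])
        dd = inter_cluster_distances(centroids, cov)
        assert dd[0, 1] == pytest.approx(10.0)
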
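"""k-means and fuzzy c-means intensity clustering, plus binarization."""

import numpy as np
import pytest

from gwtedge import (
    DegenerateInputError,
    FcmConfig,
    binarize,
    fcm_cluster,
    fcm_membership_update,
    kmeans_cluster,
)
from oracles import best_two_partition_cost, fcm_fixed_point


class TestKMeans:
    def test_separated_pairs_find_exact_centers(self):
        res = kmeans_cluster(np.array([0.0, 0.0, 10.0, 10.0]), n_clusters=2, seed=1)
        assert sorted(res.centers) == [0.0, 10.0]
        assert res.cost_trace[-1] == 0.0
        assert res.converged

    def test_single_cluster_center_is_mean(self, rng):
        vals = rng.random(20) * 7
        res = kmeans_cluster(vals, n_clusters=1, seed=0)
        assert res.centers[0] == pytest.approx(vals.mean())

    def test_cost_trace_non_increasing(self, rng):
        for seed in range(5):
            vals = rng.random(200) * 255
            res = kmeans_cluster(vals, n_clusters=3, seed=seed)
            assert np.all(np.diff(res.cost_trace) <= 1e-9)

    def test_final_cost_bounded_below_by_exhaustive_optimum(self, rng):
        for seed in range(20):
            vals = rng.random(8) * 100
            res = kmeans_cluster(vals, n_clusters=2, seed=seed)
            opt = best_two_partition_cost(vals)
            assert res.cost_trace[-1] >= opt - 1e-9
            # recorded cost is consistent with the returned labels/centers
            recomputed = float(
                ((vals - res.centers[res.labels]) ** 2).sum())
            assert res.cost_trace[-1] == pytest.approx(recomputed, rel=1e-6)

    def test_labels_preserve_input_shape(self, rng):
        vals = rng.random((6, 7)) * 9
        res = kmeans_cluster(vals, n_clusters=2, seed=0)
        assert res.labels.shape == (6, 7)
        assert set(np.unique(res.labels)) <= {0, 1}

    def test_seed_determinism(self, rng):
        vals = rng.random(100)
        a = kmeans_cluster(vals, n_clusters=2, seed=42)
        b = kmeans_cluster(vals, n_clusters=2, seed=42)
        np.testing.assert_array_equal(a.labels, b.labels)
        np.testing.assert_array_equal(a.centers, b.centers)
        np.testing.assert_array_equal(a.cost_trace, b.cost_trace)

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(DegenerateInputError):
            kmeans_cluster(np.array([5.0, 5.0, 5.0]), n_clusters=2)
        with pytest.raises(ValueError):
            kmeans_cluster(np.array([]), n_clusters=1)


class TestFcm:
    def test_equidistant_pixel_gets_half_membership(self):
        mu = fcm_membership_update(np.array([5.0]), np.array([0.0, 10.0]), 2.0)
        np.testing.assert_allclose(mu[0], [0.5, 0.5])

    def test_pixel_on_center_gets_full_membership(self):
        mu = fcm_membership_update(np.array([10.0]), np.array([0.0, 10.0]), 2.0)
        np.testing.assert_allclose(mu[0], [0.0, 1.0])

    def test_memberships_sum_to_one(self, rng):
        vals = rng.random(500) * 255
        res = fcm_cluster(vals, FcmConfig(n_clusters=3, seed=2))
        np.testing.assert_allclose(res.memberships.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(res.memberships >= 0) and np.all(res.memberships <= 1)

    def test_converged_centers_match_independent_fixed_point(self, rng):
        vals = rng.random(20) * 50
        cfg = FcmConfig(n_clusters=2, fuzziness=2.0, tol=1e-10, max_iter=5000, seed=7)
        res = fcm_cluster(vals, cfg)
        # identical random initialization, independently coded iteration
        init_rng = np.random.default_rng(7)
        mu0 = init_rng.random((vals.size, 2))
        mu0 /= mu0.sum(axis=1, keepdims=True)
        oracle_centers = fcm_fixed_point(vals, mu0, fuzziness=2.0, tol=1e-10)
        np.testing.assert_allclose(np.sort(res.centers),
                                   np.sort(oracle_centers), atol=1e-6)

    def test_hard_labels_approach_kmeans_as_fuzziness_shrinks(self):
        vals = np.array([0.0, 0.0, 10.0, 10.0])
        res = fcm_cluster(vals, FcmConfig(fuzziness=1.05, seed=3))
        km = kmeans_cluster(vals, n_clusters=2, seed=3)
        # compare partitions up to label permutation
        fcm_part = res.labels == res.labels[0]
        km_part = km.labels == km.labels[0]
        np.testing.assert_array_equal(fcm_part, km_part)

    def test_seed_determinism(self, rng):
        vals = rng.random(80)
        a = fcm_cluster(vals, FcmConfig(seed=11))
        b = fcm_cluster(vals, FcmConfig(seed=11))
        np.testing.assert_array_equal(a.memberships, b.memberships)
        np.testing.assert_array_equal(a.centers, b.centers)

    def test_invalid_fuzziness_rejected(self):
        with pytest.raises(ValueError):
            FcmConfig(fuzziness=1.0)

    def test_identical_values_rejected(self):
        with pytest.raises(DegenerateInputError):
            fcm_cluster(np.full(10, 3.3), FcmConfig())


class TestBinarize:
    def test_brighter_cluster_becomes_foreground(self):
        res = kmeans_cluster(np.array([3.0, 3.0, 90.0, 90.0, 3.0]),
                             n_clusters=2, seed=0)
        mask = binarize(res)
        np.testing.assert_array_equal(mask, [0, 0, 1, 1, 0])

    def test_toy_grid_matches_hand_assignment(self):
        grid = np.array([[0.0, 0.0, 10.0, 10.0],
                         [0.0, 10.0, 10.0, 0.0],
                         [10.0, 10.0, 0.0, 0.0],
                         [0.0, 0.0, 0.0, 10.0]])
        mask = binarize(kmeans_cluster(grid, n_clusters=2, seed=5))
        np.testing.assert_array_equal(mask, (grid == 10.0).astype(np.uint8))

    def test_invariant_under_label_permutation(self, rng):
        vals = rng.random(50) * 20
        res = kmeans_cluster(vals, n_clusters=2, seed=0)
        swapped = type(res)(
            centers=res.centers[::-1].copy(),
            labels=1 - res.labels,
            memberships=None,
            cost_trace=res.cost_trace,
            iterations=res.iterations,
            converged=res.converged,
        )
        np.testing.assert_array_equal(binarize(res), binarize(swapped))

    def test_requires_exactly_two_clusters(self, rng):
        res = kmeans_cluster(rng.random(30), n_clusters=3, seed=0)
        with pytest.raises(ValueError):
            binarize(res)


def test_kmeans_agrees_with_sklearn_on_well_separated_data(rng):
    """Independent cross-check: same optimum as scikit-learn's k-means."""
    sklearn = pytest.importorskip("sklearn.cluster")
    vals = np.concatenate([rng.normal(10, 1, 50), rng.normal(200, 1, 50)])
    res = kmeans_cluster(vals, n_clusters=2, seed=0)
    km = sklearn.KMeans(n_clusters=2, n_init=5, random_state=0).fit(vals[:, None])
    np.testing.assert_allclose(np.sort(res.centers),
                               np.sort(km.cluster_centers_.ravel()), rtol=1e-6)
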
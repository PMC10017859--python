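"""Spherical k-means behavior and the model-selection diagnostics."""

from itertools import product

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score, calinski_harabasz_score, silhouette_score

from semharm import calinski_harabasz, elbow_scan, silhouette_mean, spherical_kmeans


def antipodal_bundles(n_per=20, seed=0, spread=1e-4):
    rng = np.random.default_rng(seed)
    mu = np.array([1.0, 0, 0])
    a = mu + spread * rng.normal(size=(n_per, 3))
    b = -mu + spread * rng.normal(size=(n_per, 3))
    X = np.vstack([a, b])
    X /= np.linalg.norm(X, axis=1, keepdims=True)
    labels = np.array([0] * n_per + [1] * n_per)
    return X, labels


class TestSphericalKMeans:
    def test_k1_centroid_is_normalized_mean_direction(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0]])
        model = spherical_kmeans(X, k=1, seed=0)
        np.testing.assert_allclose(model.centroids[0], [0.70710678, 0.70710678], atol=1e-8)

    def test_antipodal_bundles_separated_exactly(self):
        X, truth = antipodal_bundles()
        model = spherical_kmeans(X, k=2, restarts=5, seed=0)
        assert adjusted_rand_score(truth, model.labels) == 1.0
        assert model.inertia <= 1e-6  # tight bundles: negligible within-cluster dissimilarity

    def test_planted_mixture_recovery(self, planted6):
        model = spherical_kmeans(planted6.X, k=6, max_iter=10, restarts=10, seed=7)
        assert adjusted_rand_score(planted6.labels, model.labels) >= 0.95

    def test_centroid_rows_unit_norm(self, planted6):
        model = spherical_kmeans(planted6.X, k=6, restarts=3, seed=1)
        np.testing.assert_allclose(np.linalg.norm(model.centroids, axis=1), 1.0, atol=1e-9)

    def test_inertia_monotone_descent_within_run(self, planted6):
        model = spherical_kmeans(planted6.X, k=6, max_iter=10, restarts=1, seed=3)
        hist = model.inertia_history
        assert all(b <= a + 1e-9 for a, b in zip(hist, hist[1:]))

    def test_labels_invariant_under_positive_rescaling(self, planted6, rng):
        scales = rng.uniform(0.1, 10.0, size=planted6.X.shape[0])[:, None]
        a = spherical_kmeans(planted6.X, k=4, restarts=3, seed=5)
        b = spherical_kmeans(planted6.X * scales, k=4, restarts=3, seed=5)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_matches_exhaustive_enumeration_on_tiny_instance(self):
        """With many restarts the fitted objective equals the global optimum
        found by enumerating every 2-coloring of 6 points."""
        rng = np.random.default_rng(4)
        X = rng.normal(size=(6, 3))
        X /= np.linalg.norm(X, axis=1, keepdims=True)
        best = np.inf
        for assign in product(range(2), repeat=6):
            a = np.array(assign)
            if len(set(assign)) < 2:
                continue
            inertia = 0.0
            for j in range(2):
                m = X[a == j].mean(axis=0)
                m /= np.linalg.norm(m)
                inertia += float(np.sum(1.0 - X[a == j] @ m))
            best = min(best, inertia)
        model = spherical_kmeans(X, k=2, max_iter=50, restarts=50, seed=0)
        assert model.inertia == pytest.approx(best, abs=1e-10)

    def test_k_bounds(self):
        with pytest.raises(ValueError):
            spherical_kmeans(np.eye(3), k=4)

    def test_deterministic_given_seed(self, planted6):
        a = spherical_kmeans(planted6.X, k=5, restarts=3, seed=9)
        b = spherical_kmeans(planted6.X, k=5, restarts=3, seed=9)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert a.inertia == b.inertia

    @pytest.mark.parametrize("init", ["random", "cosine_plus_plus", "similar_cut_like"])
    def test_all_init_methods_fit(self, planted6, init):
        model = spherical_kmeans(planted6.X, k=6, init=init, restarts=3, seed=2)
        assert model.inertia >= 0
        assert set(model.labels) == set(range(6))


class TestCalinskiHarabasz:
    def test_hand_computed_value(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        labels = np.array([0, 0, 1, 1])
        # B = 2*(0.5-5.5)^2 + 2*(10.5-5.5)^2 = 100; W = 1; CH = (100/1)/(1/2)
        assert calinski_harabasz(X, labels) == pytest.approx(200.0, abs=1e-12)

    def test_degenerate_clusters_give_infinity(self):
        X = np.array([[0.0, 0], [0, 0], [1, 1], [1, 1]])
        assert calinski_harabasz(X, np.array([0, 0, 1, 1])) == np.inf

    def test_matches_sklearn_oracle(self, rng):
        X = rng.normal(size=(30, 3))
        labels = rng.integers(0, 3, size=30)
        assert calinski_harabasz(X, labels) == pytest.approx(
            calinski_harabasz_score(X, labels), rel=1e-10
        )

    def test_requires_two_clusters(self, rng):
        with pytest.raises(ValueError):
            calinski_harabasz(rng.normal(size=(5, 2)), np.zeros(5, dtype=int))


class TestSilhouette:
    def test_antipodal_bundles_near_one(self):
        X, labels = antipodal_bundles()
        assert silhouette_mean(X, labels, metric="cosine") >= 0.99

    @pytest.mark.parametrize("metric", ["cosine", "euclidean"])
    def test_matches_pairwise_loop_oracle(self, rng, metric):
        from scipy.spatial.distance import cosine as cos_d, euclidean

        X = rng.normal(size=(25, 4))
        labels = rng.integers(0, 3, size=25)
        dist = cos_d if metric == "cosine" else euclidean
        scores = []
        for i in range(25):
            same = [j for j in range(25) if labels[j] == labels[i] and j != i]
            if not same:
                scores.append(0.0)
                continue
            a = np.mean([dist(X[i], X[j]) for j in same])
            b = min(
                np.mean([dist(X[i], X[j]) for j in range(25) if labels[j] == other])
                for other in set(labels)
                if other != labels[i]
            )
            scores.append((b - a) / max(a, b))
        assert silhouette_mean(X, labels, metric=metric) == pytest.approx(np.mean(scores), abs=1e-12)

    def test_matches_sklearn_on_euclidean(self, rng):
        X = rng.normal(size=(30, 3))
        labels = rng.integers(0, 3, size=30)
        assert silhouette_mean(X, labels, metric="euclidean") == pytest.approx(
            silhouette_score(X, labels, metric="euclidean"), abs=1e-10
        )

    def test_random_labels_on_structureless_data_near_zero(self):
        rng = np.random.default_rng(77)
        X = rng.uniform(size=(200, 5))
        labels = rng.integers(0, 4, size=200)
        assert abs(silhouette_mean(X, labels, metric="euclidean")) <= 0.1

    def test_single_cluster_rejected(self, rng):
        with pytest.raises(ValueError):
            silhouette_mean(rng.normal(size=(5, 2)), np.zeros(5, dtype=int))


class TestElbowScan:
    def test_one_row_per_k(self, planted6):
        diag = elbow_scan(planted6.X, list(range(2, 11)), restarts=2, seed=0)
        assert len(diag.table) == 9
        assert list(diag.table["k"]) == list(range(2, 11))

    def test_knee_recovers_planted_component_count(self, planted6):
        diag = elbow_scan(planted6.X, list(range(2, 11)), restarts=10, seed=3)
        assert diag.knee_k() == 6

    def test_inertia_non_increasing_in_k(self, planted6):
        diag = elbow_scan(planted6.X, list(range(2, 11)), restarts=10, seed=1)
        inertia = diag.table["inertia"].to_numpy()
        assert np.all(np.diff(inertia) <= 1e-6)

    def test_silhouette_column_in_range(self, planted6):
        diag = elbow_scan(planted6.X, [2, 4, 6], restarts=2, seed=0)
        assert diag.table["mean_silhouette"].between(-1, 1).all()
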
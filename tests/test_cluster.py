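import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from foxgate.cluster import (cattell_dimension, hddc_fit, kmeans_fit,
                             select_cluster_by_centroid)


def exhaustive_within_ss(points: np.ndarray, k: int) -> float:
    """Brute-force minimum within-cluster sum of squares over all
    k-labelings of the points (independent oracle, feasible for n <= 8)."""
    n = len(points)
    best = np.inf
    for labels in itertools.product(range(k), repeat=n):
        if len(set(labels)) < k:
            continue
        ss = 0.0
        arr = np.asarray(labels)
        for j in range(k):
            grp = points[arr == j]
            ss += ((grp - grp.mean(axis=0)) ** 2).sum()
        best = min(best, ss)
    return best


class TestKMeans:
    def test_three_pairs_in_one_dimension(self):
        pts = np.array([0.0, 1, 10, 11, 20, 21])
        res = kmeans_fit(pts, k=3, seed=0, n_init=20)
        assert sorted(np.round(res.centroids.ravel(), 6)) == [0.5, 10.5, 20.5]
        assert res.within_ss == pytest.approx(1.5)
        # pairs share a cluster
        lab = res.labels
        assert lab[0] == lab[1] and lab[2] == lab[3] and lab[4] == lab[5]

    def test_k_equals_n_gives_zero_ss(self):
        pts = np.arange(5.0)
        assert kmeans_fit(pts, k=5, seed=0).within_ss == pytest.approx(0.0)

    def test_duplicating_points_doubles_ss(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(20, 2))
        single = kmeans_fit(pts, k=3, seed=1, n_init=20)
        double = kmeans_fit(np.vstack([pts, pts]), k=3, seed=1, n_init=20)
        assert double.within_ss == pytest.approx(2 * single.within_ss, rel=1e-6)
        assert (sorted(map(tuple, np.round(single.centroids, 9)))
                == sorted(map(tuple, np.round(double.centroids, 9))))

    def test_fewer_points_than_k_rejected(self):
        with pytest.raises(ValueError):
            kmeans_fit(np.arange(2.0), k=3)

    @pytest.mark.parametrize("case", range(12))
    def test_matches_exhaustive_oracle_on_tiny_instances(self, case):
        rng = np.random.default_rng(100 + case)
        n = int(rng.integers(4, 9))
        p = int(rng.integers(1, 3))
        k = int(rng.integers(2, min(n, 4)))
        pts = rng.normal(size=(n, p)) * rng.uniform(0.5, 3)
        res = kmeans_fit(pts, k=k, seed=case, n_init=20)
        assert res.within_ss == pytest.approx(
            exhaustive_within_ss(pts, k), rel=1e-8, abs=1e-10)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(200, 3))
        a = kmeans_fit(pts, k=3, seed=9)
        b = kmeans_fit(pts, k=3, seed=9)
        assert np.array_equal(a.labels, b.labels)
        np.testing.assert_array_equal(a.centroids, b.centroids)


class TestHddc:
    def _two_clouds(self, seed=0, n=1000):
        rng = np.random.default_rng(seed)
        cov = np.diag([4.0, 0.3, 0.05])
        a = rng.multivariate_normal([0, 0, 0], cov, size=n)
        b = rng.multivariate_normal([10, 10, 10], cov, size=n)
        X = np.vstack([a, b])
        truth = np.repeat([0, 1], n)
        return X, truth

    def test_recovers_separated_elongated_clouds(self):
        X, truth = self._two_clouds()
        model = hddc_fit(X, k=2, seed=4)
        assert adjusted_rand_score(truth, model.labels) >= 0.99

    def test_single_isotropic_gaussian(self):
        rng = np.random.default_rng(2)
        X = rng.normal(5.0, 2.0, size=(4000, 3))
        model = hddc_fit(X, k=1, seed=0)
        se = 2.0 / np.sqrt(len(X))
        assert np.all(np.abs(model.means[0] - 5.0) < 3 * se)
        # isotropic data: signal eigenvalues close to the noise variance
        assert np.all(np.abs(model.signal[0] - model.noise[0])
                      < 0.2 * model.noise[0])

    def test_loglik_trace_non_decreasing(self):
        X, _ = self._two_clouds(seed=7, n=400)
        for seed in range(4):
            model = hddc_fit(X, k=2, seed=seed)
            diffs = np.diff(model.loglik_trace)
            assert np.all(diffs >= -1e-8 * np.abs(model.loglik_trace[:-1]))

    def test_covariance_reconstruction_with_full_subspace(self):
        """With d = p-1 the restricted covariance approaches the sample
        covariance of single-cluster data."""
        rng = np.random.default_rng(5)
        L = rng.normal(size=(3, 3))
        X = rng.normal(size=(5000, 3)) @ L.T
        model = hddc_fit(X, k=1, seed=0, d_select_threshold=0.0)
        assert model.dims[0] == 2
        sample_cov = np.cov(X.T, bias=True)
        np.testing.assert_allclose(model.cluster_covariance(0), sample_cov,
                                   rtol=0.15, atol=0.05)

    def test_univariate_mixture(self):
        rng = np.random.default_rng(8)
        X = np.concatenate([rng.normal(0, 1, 600), rng.normal(8, 0.5, 400)])
        model = hddc_fit(X, k=2, seed=1)
        means = np.sort(model.means.ravel())
        assert abs(means[0] - 0) < 0.2 and abs(means[1] - 8) < 0.2
        assert np.all(model.dims == 0)

    def test_restricted_covariance_structure(self):
        X, _ = self._two_clouds(seed=9, n=500)
        model = hddc_fit(X, k=2, seed=2)
        for j in range(2):
            Q = model.bases[j]
            np.testing.assert_allclose(Q.T @ Q, np.eye(Q.shape[1]), atol=1e-10)
            assert np.all(model.signal[j] >= model.noise[j])
            assert model.noise[j] > 0
        assert model.weights.sum() == pytest.approx(1.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            hddc_fit(np.random.default_rng(0).normal(size=(5, 2)), k=3)

    def test_deterministic_under_seed(self):
        X, _ = self._two_clouds(seed=11, n=300)
        a = hddc_fit(X, k=2, seed=13)
        b = hddc_fit(X, k=2, seed=13)
        assert np.array_equal(a.labels, b.labels)
        np.testing.assert_array_equal(a.means, b.means)


class TestCattell:
    def test_clear_gap(self):
        assert cattell_dimension(np.array([10.0, 9.0, 1.0, 0.9]), 0.2) == 2

    def test_flat_spectrum_gives_one(self):
        assert cattell_dimension(np.array([1.0, 1.0, 1.0]), 0.2) == 1

    def test_univariate_gives_zero(self):
        assert cattell_dimension(np.array([2.0]), 0.2) == 0


class TestCentroidSelection:
    class _Fit:
        def __init__(self, centroids, roles):
            self.centroids = np.asarray(centroids, float)
            self.roles = roles

    def test_max_and_min(self):
        fit = self._Fit([[-0.2], [0.1], [1.7]], ("FOXP3",))
        assert select_cluster_by_centroid(fit, "FOXP3", "max") == 2
        assert select_cluster_by_centroid(fit, "FOXP3", "min") == 0

    def test_single_cluster(self):
        fit = self._Fit([[0.5]], ("FOXP3",))
        assert select_cluster_by_centroid(fit, "FOXP3", "max") == 0

    def test_tie_takes_lowest_index_with_warning(self):
        fit = self._Fit([[1.0], [1.0], [0.0]], ("FOXP3",))
        with pytest.warns(UserWarning, match="tie"):
            assert select_cluster_by_centroid(fit, "FOXP3", "max") == 0

    def test_unknown_role_rejected(self):
        fit = self._Fit([[1.0]], ("FOXP3",))
        with pytest.raises(KeyError):
            select_cluster_by_centroid(fit, "CD8", "max")
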
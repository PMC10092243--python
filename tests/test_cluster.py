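from itertools import combinations

import numpy as np
import pytest
from sklearn.mixture import GaussianMixture

from addpheno import (
    ClusterLabeler,
    KMedians,
    assign_roles,
    fit_gmm,
    fit_kmeans,
    fit_kmedians,
    select_cluster_number,
    silhouette,
)
from addpheno.exceptions import InputError, UndefinedScoreError
from tests.conftest import binary_truth

# --- independent oracles ----------------------------------------------------


def brute_force_bipartition(X, block_cost):
    """Minimum 2-cluster cost over every bipartition (exhaustive)."""
    n = len(X)
    best = np.inf
    idx = set(range(n))
    for r in range(1, n // 2 + 1):
        for comb in combinations(range(n), r):
            a = np.array(comb)
            b = np.array(sorted(idx - set(comb)))
            best = min(best, block_cost(X[a]) + block_cost(X[b]))
    return best


def l1_block_cost(block):
    return float(np.abs(block - np.median(block, axis=0)).sum())


def l2_block_cost(block):
    return float(((block - block.mean(axis=0)) ** 2).sum())


def naive_silhouette(X, labels, p):
    """O(n^2) per-point silhouette from first principles (Minkowski-p)."""
    n = len(X)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            D[i, j] = np.sum(np.abs(X[i] - X[j]) ** p) ** (1 / p)
    scores = []
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not same:
            scores.append(0.0)
            continue
        a = np.mean([D[i, j] for j in same])
        b = min(
            np.mean([D[i, j] for j in range(n) if labels[j] == lab])
            for lab in set(labels) if lab != labels[i]
        )
        scores.append((b - a) / max(a, b))
    return float(np.mean(scores))


# --- k-medians --------------------------------------------------------------


class TestKMedians:
    def test_symmetric_pairs(self):
        X = np.array([[0, 0, 0], [1, 1, 1], [10, 10, 10], [11, 11, 11]], float)
        km = KMedians(n_clusters=2, random_state=0).fit(X)
        assert km.labels_[0] == km.labels_[1] != km.labels_[2] == km.labels_[3]
        centers = sorted(map(tuple, km.cluster_centers_))
        assert centers == [(0.5, 0.5, 0.5), (10.5, 10.5, 10.5)]
        assert km.inertia_ == pytest.approx(6.0)

    def test_k_equals_n_zero_objective(self):
        X = np.arange(12, dtype=float).reshape(4, 3)
        km = KMedians(n_clusters=4, random_state=0).fit(X)
        assert km.inertia_ == pytest.approx(0.0)
        assert sorted(map(tuple, km.cluster_centers_)) == sorted(map(tuple, X))

    def test_n_less_than_k_rejected(self):
        with pytest.raises(InputError):
            KMedians(n_clusters=3).fit(np.ones((2, 3)))

    @pytest.mark.parametrize("seed", range(25))
    def test_objective_is_exhaustive_bipartition_optimum(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.random((8, 3)) * 10
        km = KMedians(n_clusters=2, random_state=seed).fit(X)
        assert km.inertia_ == pytest.approx(
            brute_force_bipartition(X, l1_block_cost), abs=1e-9
        )

    def test_predict_matches_training_labels(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 1, (20, 3)), rng.normal(8, 1, (20, 3))])
        km = KMedians(n_clusters=2, random_state=1).fit(X)
        np.testing.assert_array_equal(km.predict(X), km.labels_)


class TestKMeans:
    def test_symmetric_pairs_match_kmedians(self):
        X = np.array([[0, 0, 0], [1, 1, 1], [10, 10, 10], [11, 11, 11]], float)
        model = fit_kmeans(X, k=2, seed=0, scale=False)
        centers = sorted(map(tuple, model.centers_))
        assert centers == [(0.5, 0.5, 0.5), (10.5, 10.5, 10.5)]

    def test_single_cluster_centroid_is_mean(self):
        rng = np.random.default_rng(0)
        X = rng.random((10, 3))
        model = fit_kmeans(X, k=1, seed=0, scale=False)
        np.testing.assert_allclose(model.centers_[0], X.mean(axis=0), atol=1e-9)

    @pytest.mark.parametrize("seed", range(25))
    def test_objective_is_exhaustive_bipartition_optimum(self, seed):
        rng = np.random.default_rng(1000 + seed)
        X = rng.random((8, 3)) * 10
        model = fit_kmeans(X, k=2, seed=seed, scale=False)
        assert model.objective_ == pytest.approx(
            brute_force_bipartition(X, l2_block_cost), abs=1e-7
        )


class TestGMM:
    def test_separated_blobs_recovered_exactly(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(0, 0.3, (20, 3)), rng.normal(10, 0.3, (20, 3))])
        model = fit_gmm(X, k=2, seed=2, scale=False)
        labels = model.labels_
        assert len(set(labels[:20])) == 1 and len(set(labels[20:])) == 1
        assert labels[0] != labels[-1]

    def test_single_component_closed_form(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(200, 3))
        model = fit_gmm(X, k=1, seed=3, scale=False)
        np.testing.assert_allclose(model.centers_[0], X.mean(axis=0), atol=1e-6)
        np.testing.assert_allclose(
            model.covariances_[0], np.cov(X.T, bias=True), atol=1e-4
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_em_loglikelihood_nondecreasing(self, seed):
        """Stepping EM one iteration at a time must never lower the
        per-sample lower bound (checked with this pipeline's GMM settings)."""
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(40, 3)) + rng.integers(0, 2, 40)[:, None] * 3
        gm = GaussianMixture(
            n_components=2, covariance_type="full", reg_covar=1e-6,
            max_iter=1, warm_start=True, tol=0.0, random_state=seed,
            init_params="random",
        )
        trace = []
        import warnings
        for _ in range(30):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gm.fit(X)
            trace.append(gm.lower_bound_)
        assert all(b >= a - 1e-9 for a, b in zip(trace, trace[1:]))


# --- silhouette -------------------------------------------------------------


class TestSilhouette:
    def test_two_cluster_line_example(self):
        """Hand-computed score for 1-D points {0,1} vs {10,11}:
        s = ((10.5-1)/10.5 + (9.5-1)/9.5)/2 = 0.899749..."""
        X = np.array([[0, 0, 0], [1, 0, 0], [10, 0, 0], [11, 0, 0]], float)
        labels = [0, 0, 1, 1]
        expected = ((10.5 - 1) / 10.5 + (9.5 - 1) / 9.5) / 2
        assert silhouette(X, labels, metric="euclidean") == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("metric,p", [("euclidean", 2), ("manhattan", 1)])
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_pairwise_oracle(self, metric, p, seed):
        rng = np.random.default_rng(seed)
        X = rng.random((30, 3))
        labels = rng.integers(0, 3, 30)
        if len(set(labels)) < 2:
            labels[0] = (labels[0] + 1) % 3
        assert silhouette(X, labels, metric=metric) == pytest.approx(
            naive_silhouette(X, labels, p), abs=1e-12
        )

    def test_superimposed_clusters_not_positive(self):
        rng = np.random.default_rng(4)
        X = rng.random((20, 3))
        X = np.vstack([X, X])
        labels = [0] * 20 + [1] * 20
        assert silhouette(X, labels) <= 0

    def test_tight_far_clusters_near_one(self):
        X = np.vstack([np.zeros((10, 3)) + 1e-9 * np.arange(10)[:, None],
                       np.full((10, 3), 1e6)])
        labels = [0] * 10 + [1] * 10
        assert silhouette(X, labels) > 0.999

    def test_single_cluster_undefined(self):
        with pytest.raises(UndefinedScoreError):
            silhouette(np.random.default_rng(0).random((5, 3)), [0] * 5)


# --- cluster-number voting --------------------------------------------------


def _blob_sets(n_sets, n_blobs, seed):
    rng = np.random.default_rng(seed)
    sets = []
    for _ in range(n_sets):
        blobs = [rng.normal(c * 20, 0.5, (8, 3)) for c in range(n_blobs)]
        sets.append(np.vstack(blobs))
    return sets


class TestSelectClusterNumber:
    def test_two_blob_sets_unanimous(self):
        report = select_cluster_number(_blob_sets(10, 2, 0), method="kmedians", seed=0)
        assert report.modal_k == 2
        assert report.modal_fraction == 1.0

    def test_three_blob_sets_vote_three(self):
        report = select_cluster_number(_blob_sets(10, 3, 1), method="kmeans", seed=1)
        assert report.modal_k == 3

    def test_set_too_small_rejected(self):
        sets = [np.random.default_rng(0).random((5, 3))]
        with pytest.raises(InputError, match="set 0"):
            select_cluster_number(sets, k_range=range(2, 7))


# --- role assignment --------------------------------------------------------


class TestAssignRoles:
    @staticmethod
    def _punished_split_fixture():
        rng = np.random.default_rng(8)
        X = np.column_stack([
            rng.normal(50, 1, 6),            # motivation: pure noise
            rng.normal(10, 1, 6),            # seeking: pure noise
            np.r_[rng.normal(5, 1, 3), rng.normal(90, 2, 3)],
        ])
        return X

    def test_higher_punished_centroid_is_vulnerable(self):
        X = self._punished_split_fixture()
        model = fit_kmedians(X, k=2, seed=0)
        roles = assign_roles(model, X)
        np.testing.assert_array_equal(
            roles, ["resilient"] * 3 + ["vulnerable"] * 3
        )

    def test_invariant_to_cluster_index_permutation(self):
        X = self._punished_split_fixture()
        model = fit_kmedians(X, k=2, seed=0)
        roles = assign_roles(model, X)
        # permute the fitted cluster indices and re-derive roles
        model.centers_ = model.centers_[::-1].copy()
        model.estimator_.cluster_centers_ = model.estimator_.cluster_centers_[::-1].copy()
        roles_permuted = assign_roles(model, X)
        np.testing.assert_array_equal(roles, roles_permuted)

    @pytest.mark.parametrize("method", ["kmedians", "kmeans", "gmm"])
    def test_well_separated_roles_equal_planted_truth(self, well_separated, method):
        cohort, truth = well_separated
        fitter = {"kmedians": fit_kmedians, "kmeans": fit_kmeans, "gmm": fit_gmm}[method]
        model = fitter(cohort.features, k=2, seed=0)
        roles = assign_roles(model, cohort.features)
        np.testing.assert_array_equal(roles, binary_truth(truth))


class TestFitInvariances:
    @pytest.mark.parametrize("method", ["kmedians", "kmeans", "gmm"])
    def test_partition_invariant_to_row_order(self, well_separated, method):
        cohort, _ = well_separated
        X = cohort.features
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(X))
        m1 = ClusterLabeler(method, 2, random_state=0).fit(X)
        m2 = ClusterLabeler(method, 2, random_state=0).fit(X[perm])
        r1 = assign_roles(m1, X)
        r2 = assign_roles(m2, X[perm])
        np.testing.assert_array_equal(r1[perm], r2)
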
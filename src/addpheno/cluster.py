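"""Unsupervised stage: K-medians / K-means / Gaussian-mixture clustering,
silhouette-based cluster-number voting, and mapping clusters to roles.

K-medians is implemented here as Lloyd-style alternation under the L1
(Manhattan) distance with coordinate-wise median centroid updates and Forgy
initialisation (random distinct data points), restarted ``n_init`` times and
keeping the fit with the lowest within-cluster L1 sum. K-means and the
Gaussian mixture are delegated to scikit-learn with matching conventions.

Roles are assigned only for k=2: the cluster whose centroid has the larger
punished-responding coordinate (in original, unstandardised units) is the
vulnerable one — animals that keep responding under punishment are the
compulsive, addiction-prone phenotype.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples
from sklearn.mixture import GaussianMixture
from sklearn.utils import check_random_state
from sklearn.utils.validation import check_is_fitted

from .exceptions import AmbiguityError, InputError, UndefinedScoreError

#: Index of the punished-responding (compulsivity) coordinate in feature space.
PUNISHED_DIM = 2

METHOD_METRIC = {"kmedians": "manhattan", "kmeans": "euclidean", "gmm": "euclidean"}


def _check_features(X, min_rows: int = 1) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise InputError(f"expected a 2-D feature matrix, got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise InputError("feature matrix contains non-finite values")
    if X.shape[0] < min_rows:
        raise InputError(f"need at least {min_rows} rows, got {X.shape[0]}")
    return X


def _block_cost_l1(block: np.ndarray) -> float:
    return float(np.abs(block - np.median(block, axis=0)).sum())


def _block_cost_l2(block: np.ndarray) -> float:
    return float(((block - block.mean(axis=0)) ** 2).sum())


#: Pairwise-swap polishing is quadratic in n; only affordable on small fits.
_PAIR_SWAP_MAX_N = 64
#: Below this size the k=2 problem is solved exactly by enumerating all
#: 2^(n-1)-1 bipartitions (Lloyd restarts can stall in local optima that no
#: small neighbourhood escapes; at these sizes enumeration is cheaper).
_EXACT_BIPARTITION_MAX_N = 12


def _exact_bipartition(X: np.ndarray, block_cost) -> np.ndarray:
    """Globally optimal 2-cluster labels by exhaustive enumeration."""
    n = X.shape[0]
    best_cost, best_mask = np.inf, None
    for code in range(1, 2 ** (n - 1)):
        mask = np.array([(code >> i) & 1 for i in range(n)], dtype=bool)
        c = block_cost(X[mask]) + block_cost(X[~mask])
        if c < best_cost - 1e-15:
            best_cost, best_mask = c, mask
    return best_mask.astype(int)


def _local_search(X: np.ndarray, labels: np.ndarray, k: int, block_cost) -> np.ndarray:
    """Greedy label-improvement polish after Lloyd convergence.

    Lloyd alternation can stall in partition-local optima that single-point
    relocations (Hartigan-style moves) or, on small instances, two-point
    swaps escape. Moves are accepted only when they strictly lower the total
    within-cluster cost, so the objective stays non-increasing.
    """
    labels = labels.copy()
    n = X.shape[0]

    def total(lbls: np.ndarray) -> float:
        return sum(block_cost(X[lbls == j]) for j in range(k) if np.any(lbls == j))

    cur = total(labels)
    improved = True
    while improved:
        improved = False
        for i in range(n):
            src = labels[i]
            if np.sum(labels == src) == 1:
                continue  # never empty a cluster
            for j in range(k):
                if j == src:
                    continue
                trial = labels.copy()
                trial[i] = j
                c = total(trial)
                if c < cur - 1e-12:
                    labels, cur = trial, c
                    improved = True
                    break
        if not improved and k == 2 and n <= _PAIR_SWAP_MAX_N:
            # two-point neighbourhood for the bipartition case: flip both
            # labels of a pair (covers swaps and double relocations)
            for i in range(n):
                for j in range(i + 1, n):
                    trial = labels.copy()
                    trial[i], trial[j] = 1 - trial[i], 1 - trial[j]
                    if not (np.any(trial == 0) and np.any(trial == 1)):
                        continue
                    c = total(trial)
                    if c < cur - 1e-12:
                        labels, cur = trial, c
                        improved = True
                        break
                if improved:
                    break
    return labels


class KMedians(ClusterMixin, BaseEstimator):
    """K-medians clustering (Lloyd alternation under the L1 metric).

    Parameters
    ----------
    n_clusters : int
        Number of clusters k.
    n_init : int
        Number of Forgy restarts; the solution with the lowest within-cluster
        L1 sum is kept.
    max_iter, tol : convergence control on the objective decrease.
    random_state : seed for the restart stream.

    Attributes
    ----------
    cluster_centers_ : (k, d) coordinate-wise medians per cluster.
    labels_ : training assignment; distance ties go to the lowest index.
    inertia_ : within-cluster L1 sum at convergence.
    n_iter_ : iterations used by the best restart.
    """

    def __init__(self, n_clusters=2, n_init=25, max_iter=300, tol=1e-6, random_state=None):
        self.n_clusters = n_clusters
        self.n_init = n_init
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def _single_run(
        self, X: np.ndarray, rng, init_centers: np.ndarray | None = None
    ) -> tuple[np.ndarray, np.ndarray, float, int]:
        n, _ = X.shape
        k = self.n_clusters
        if init_centers is None:
            centers = X[rng.choice(n, size=k, replace=False)].copy()
        else:
            centers = init_centers.copy()
        prev_obj = np.inf
        labels = np.zeros(n, dtype=int)
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            dist = cdist(X, centers, metric="cityblock")
            labels = np.argmin(dist, axis=1)  # argmin breaks ties toward lower index
            for j in range(k):
                if not np.any(labels == j):
                    # re-seed an emptied centroid at the point farthest (L1)
                    # from its currently assigned centroid
                    far = np.argmax(dist[np.arange(n), labels])
                    centers[j] = X[far]
                    labels[far] = j
            for j in range(k):
                centers[j] = np.median(X[labels == j], axis=0)
            obj = float(np.abs(X - centers[labels]).sum())
            if prev_obj - obj <= self.tol:
                prev_obj = min(prev_obj, obj)
                break
            prev_obj = obj
        return centers, labels, prev_obj, n_iter

    def fit(self, X, y=None):
        X = _check_features(X)
        if X.shape[0] < self.n_clusters:
            raise InputError(
                f"n_samples={X.shape[0]} < n_clusters={self.n_clusters}"
            )
        rng = check_random_state(self.random_state)
        if self.n_clusters == 2 and X.shape[0] <= _EXACT_BIPARTITION_MAX_N:
            exact = _exact_bipartition(X, _block_cost_l1)
            init = np.vstack([np.median(X[exact == j], axis=0) for j in range(2)])
            best = self._single_run(X, rng, init_centers=init)
        else:
            best = None
            for _ in range(self.n_init):
                run = self._single_run(X, rng)
                if best is None or run[2] < best[2]:
                    best = run
            centers, labels, obj, n_iter = best
            polished = _local_search(X, labels, self.n_clusters, _block_cost_l1)
            if not np.array_equal(polished, labels):
                # restart Lloyd from the polished partition's medians so the
                # final assignment is nearest-center consistent
                init = np.vstack([np.median(X[polished == j], axis=0)
                                  for j in range(self.n_clusters)])
                best = self._single_run(X, rng, init_centers=init)
        self.cluster_centers_, self.labels_, self.inertia_, self.n_iter_ = best
        return self

    def predict(self, X):
        check_is_fitted(self, "cluster_centers_")
        X = _check_features(X)
        return np.argmin(cdist(X, self.cluster_centers_, metric="cityblock"), axis=1)

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


class ClusterLabeler(ClusterMixin, BaseEstimator):
    """Clustering front-end shared by the whole pipeline.

    Standardises features (z-score per dimension; statistics can be supplied
    so test/new animals reuse training statistics), fits the requested
    clustering method, and — when ``n_clusters == 2`` — orients the clusters
    into vulnerable/resilient roles by the punished-responding centroid rule.

    Attributes
    ----------
    mean_, scale_ : standardisation used (training statistics).
    estimator_ : the fitted underlying clusterer/mixture.
    labels_ : training cluster indices.
    centers_ : cluster centroids / component means in original units.
    objective_ : within-cluster L1/L2 sum, or total log-likelihood for gmm.
    role_map_ : dict cluster index -> role, only when n_clusters == 2.
    """

    def __init__(
        self,
        method="kmedians",
        n_clusters=2,
        scale=True,
        scaling=None,
        n_init=25,
        max_iter=300,
        tol=1e-6,
        random_state=None,
    ):
        self.method = method
        self.n_clusters = n_clusters
        self.scale = scale
        self.scaling = scaling
        self.n_init = n_init
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    # -- scaling -----------------------------------------------------------
    def _fit_scaling(self, X: np.ndarray) -> None:
        if self.scaling is not None:
            self.mean_, self.scale_ = (np.asarray(a, dtype=float) for a in self.scaling)
        elif self.scale:
            self.mean_ = X.mean(axis=0)
            sd = X.std(axis=0)
            sd[sd == 0] = 1.0  # constant dimension: leave centred, unscaled
            self.scale_ = sd
        else:
            self.mean_ = np.zeros(X.shape[1])
            self.scale_ = np.ones(X.shape[1])

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "mean_")
        return (_check_features(X) - self.mean_) / self.scale_

    def _inverse(self, Z: np.ndarray) -> np.ndarray:
        return Z * self.scale_ + self.mean_

    # -- fitting -----------------------------------------------------------
    def fit(self, X, y=None):
        X = _check_features(X)
        if self.method not in METHOD_METRIC:
            raise InputError(f"unknown clustering method {self.method!r}")
        if X.shape[0] < self.n_clusters:
            raise InputError(f"n_samples={X.shape[0]} < n_clusters={self.n_clusters}")
        self._fit_scaling(X)
        Z = (X - self.mean_) / self.scale_
        seed = self.random_state
        if self.method == "kmedians":
            est = KMedians(
                n_clusters=self.n_clusters, n_init=self.n_init,
                max_iter=self.max_iter, tol=self.tol, random_state=seed,
            ).fit(Z)
            centers_z, labels, objective = est.cluster_centers_, est.labels_, est.inertia_
        elif self.method == "kmeans":
            if self.n_clusters == 2 and Z.shape[0] <= _EXACT_BIPARTITION_MAX_N:
                exact = _exact_bipartition(Z, _block_cost_l2)
                init = np.vstack([Z[exact == j].mean(axis=0) for j in range(2)])
                est = KMeans(n_clusters=2, init=init, n_init=1,
                             max_iter=self.max_iter, tol=self.tol,
                             random_state=seed).fit(Z)
            else:
                est = KMeans(
                    n_clusters=self.n_clusters, init="random", n_init=self.n_init,
                    max_iter=self.max_iter, tol=self.tol, random_state=seed,
                ).fit(Z)
                labels = _local_search(Z, est.labels_, self.n_clusters, _block_cost_l2)
                if not np.array_equal(labels, est.labels_):
                    init = np.vstack([Z[labels == j].mean(axis=0)
                                      for j in range(self.n_clusters)])
                    est = KMeans(
                        n_clusters=self.n_clusters, init=init, n_init=1,
                        max_iter=self.max_iter, tol=self.tol, random_state=seed,
                    ).fit(Z)
            labels = est.labels_
            centers_z, objective = est.cluster_centers_, est.inertia_
        else:  # gmm
            est = GaussianMixture(
                n_components=self.n_clusters, covariance_type="full",
                reg_covar=1e-6, n_init=self.n_init, max_iter=self.max_iter,
                tol=self.tol, random_state=seed,
            ).fit(Z)
            labels = est.predict(Z)
            centers_z = est.means_
            objective = float(est.score(Z) * Z.shape[0])
            self.weights_ = est.weights_
            self.covariances_ = est.covariances_
        self.estimator_ = est
        self.labels_ = np.asarray(labels, dtype=int)
        self.centers_ = self._inverse(np.asarray(centers_z, dtype=float))
        self.objective_ = float(objective)
        self.role_map_ = _role_map_from_centers(self.centers_) if self.n_clusters == 2 else None
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "estimator_")
        return np.asarray(self.estimator_.predict(self.transform(X)), dtype=int)

    def predict_roles(self, X) -> np.ndarray:
        """Vulnerable/resilient role per row (requires n_clusters == 2)."""
        check_is_fitted(self, "estimator_")
        if self.role_map_ is None:
            raise InputError("roles are defined only for n_clusters == 2")
        idx = self.predict(X)
        return np.array([self.role_map_[i] for i in idx], dtype=object)

    @property
    def roles_(self) -> np.ndarray:
        """Training-set roles (requires n_clusters == 2)."""
        check_is_fitted(self, "labels_")
        if self.role_map_ is None:
            raise InputError("roles are defined only for n_clusters == 2")
        return np.array([self.role_map_[i] for i in self.labels_], dtype=object)

    @property
    def metric(self) -> str:
        return METHOD_METRIC[self.method]


def _role_map_from_centers(centers: np.ndarray) -> dict[int, str]:
    """Orient two clusters into roles by centroid comparison in original units.

    Larger punished-responding wins "vulnerable"; ties fall back to larger
    motivation, then larger seeking; a full tie is ambiguous.
    """
    c0, c1 = centers[0], centers[1]
    for dim in (PUNISHED_DIM, 0, 1):
        if c0[dim] != c1[dim]:
            vuln = 0 if c0[dim] > c1[dim] else 1
            return {vuln: "vulnerable", 1 - vuln: "resilient"}
    raise AmbiguityError("cluster centroids are identical on every dimension")


def assign_roles(model: ClusterLabeler, X) -> np.ndarray:
    """Per-animal roles from a fitted k=2 clustering (refreshes the role map)."""
    check_is_fitted(model, "centers_")
    if model.n_clusters != 2:
        raise InputError("role assignment requires n_clusters == 2")
    model.role_map_ = _role_map_from_centers(model.centers_)
    return model.predict_roles(X)


# -- convenience constructors matching the three methods ---------------------

def fit_kmedians(features, k=2, seed=None, n_restarts=25, max_iter=300, tol=1e-6,
                 scale=True, scaling=None) -> ClusterLabeler:
    return ClusterLabeler("kmedians", k, scale, scaling, n_restarts, max_iter, tol,
                          seed).fit(features)


def fit_kmeans(features, k=2, seed=None, n_restarts=25, max_iter=300, tol=1e-6,
               scale=True, scaling=None) -> ClusterLabeler:
    return ClusterLabeler("kmeans", k, scale, scaling, n_restarts, max_iter, tol,
                          seed).fit(features)


def fit_gmm(features, k=2, seed=None, n_restarts=25, max_iter=300, tol=1e-6,
            scale=True, scaling=None) -> ClusterLabeler:
    return ClusterLabeler("gmm", k, scale, scaling, n_restarts, max_iter, tol,
                          seed).fit(features)


def silhouette(features, labels, metric: str = "euclidean") -> float:
    """Mean silhouette coefficient.

    Per point, s = (b - a) / max(a, b) with a the mean intra-cluster distance
    (self excluded) and b the smallest mean distance to another cluster;
    singleton clusters score 0. The metric should match the clustering
    geometry (L1 for K-medians, L2 otherwise).
    """
    X = _check_features(features)
    labels = np.asarray(labels)
    if labels.shape[0] != X.shape[0]:
        raise InputError("labels length does not match feature rows")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise UndefinedScoreError("silhouette is undefined for a single cluster")
    return float(np.mean(silhouette_samples(X, labels, metric=metric)))


@dataclass
class ClusterNumberReport:
    """Silhouette vote over many sets for the cluster number."""

    per_set_best_k: list[int]
    modal_k: int
    modal_fraction: float
    k_range: list[int]

    @property
    def n_sets(self) -> int:
        return len(self.per_set_best_k)


def select_cluster_number(
    sets,
    method: str = "kmedians",
    k_range=range(2, 7),
    seed: int | None = None,
    n_restarts: int = 10,
    metric: str | None = None,
) -> ClusterNumberReport:
    """Silhouette majority vote for k across many cohorts.

    Each set (a Cohort or feature matrix) is standardised on its own
    statistics and clustered at every k in ``k_range``; the k with the
    highest mean silhouette wins the set's vote (ties toward smaller k), and
    the modal best-k across sets is reported together with its vote share.
    """
    k_range = list(k_range)
    if not k_range or min(k_range) < 2:
        raise InputError("k_range must contain integers >= 2")
    metric = metric or METHOD_METRIC[method]
    feature_sets = [s.features if hasattr(s, "features") else np.asarray(s, dtype=float)
                    for s in sets]
    for i, F in enumerate(feature_sets):
        if F.shape[0] < max(k_range) + 1:
            raise InputError(
                f"set {i} has {F.shape[0]} animals; need at least {max(k_range) + 1}"
            )
    rng = np.random.default_rng(seed)
    per_set_best_k = []
    for F in feature_sets:
        scores = []
        for k in k_range:
            model = ClusterLabeler(
                method, n_clusters=k, n_init=n_restarts,
                random_state=int(rng.integers(2**31 - 1)),
            ).fit(F)
            try:
                s = silhouette(model.transform(F), model.labels_, metric=metric)
            except UndefinedScoreError:
                s = -np.inf  # collapsed fit cannot win the vote
            scores.append(s)
        best = k_range[int(np.argmax(scores))]  # argmax ties -> first (smaller k)
        per_set_best_k.append(best)
    counts = Counter(per_set_best_k)
    top = max(counts.values())
    modal_k = min(k for k, c in counts.items() if c == top)
    return ClusterNumberReport(
        per_set_best_k=per_set_best_k,
        modal_k=modal_k,
        modal_fraction=top / len(per_set_best_k),
        k_range=k_range,
    )
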
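"""Single-animal diagnosis irrespective of cohort.

The end product of the pipeline: cluster a full reference cohort once (k=2),
orient the clusters into vulnerable/resilient roles, train a predictor on
every reference animal's features and role, then label any future animal by
passing its three raw response counts through the stored standardisation and
the trained predictor — no refitting, no dependence on the cohort the new
animal happens to arrive with.
"""

from __future__ import annotations

import hashlib
import json
import pickle
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .cluster import ClusterLabeler, assign_roles
from .exceptions import DegenerateStructureError, InputError
from .io import BehaviorProfile, Cohort
from .supervised import VULNERABLE, fit_predictor, predict


def _digest(features: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(features).tobytes()).hexdigest()[:16]


class VulnerabilityClassifier(ClassifierMixin, BaseEstimator):
    """Reference-cohort clustering followed by a supervised predictor.

    Parameters mirror the two pipeline stages: ``cluster_method`` in
    {kmedians, kmeans, gmm} and ``algorithm`` in {knn, logreg, svm, ann}.
    ``by_centroid=True`` switches prediction to nearest-centroid assignment
    under the clustering's own metric (a comparison mode; the default path
    uses the trained predictor).

    Fitted attributes: ``cluster_model_``, ``predictor_``, ``roles_`` (the
    reference animals' roles), ``provenance_`` (cohort digest, params, seed).
    """

    def __init__(
        self,
        cluster_method="kmedians",
        algorithm="ann",
        cluster_config=None,
        predictor_config=None,
        by_centroid=False,
        random_state=None,
    ):
        self.cluster_method = cluster_method
        self.algorithm = algorithm
        self.cluster_config = cluster_config
        self.predictor_config = predictor_config
        self.by_centroid = by_centroid
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 10:
            raise InputError(
                f"reference cohort must have at least 10 animals, got {X.shape[0] if X.ndim == 2 else 'non-matrix'}"
            )
        ccfg = dict(self.cluster_config or {})
        rng = np.random.default_rng(self.random_state)
        seed_cluster, seed_fit = (int(rng.integers(2**31 - 1)) for _ in range(2))
        self.cluster_model_ = ClusterLabeler(
            self.cluster_method, n_clusters=2, scale=True,
            n_init=ccfg.get("n_restarts", 25), max_iter=ccfg.get("max_iter", 300),
            tol=ccfg.get("tol", 1e-6), random_state=seed_cluster,
        ).fit(X)
        self.roles_ = assign_roles(self.cluster_model_, X)
        if np.unique(self.roles_).size < 2:
            raise DegenerateStructureError(
                "reference clustering collapsed to a single role"
            )
        self.predictor_ = fit_predictor(
            X, self.roles_, self.algorithm, self.predictor_config,
            scaling=(self.cluster_model_.mean_, self.cluster_model_.scale_),
            seed=seed_fit,
        )
        self.classes_ = np.array(["resilient", "vulnerable"], dtype=object)
        self.provenance_ = {
            "cohort_digest": _digest(X),
            "n_reference": int(X.shape[0]),
            "cluster_method": self.cluster_method,
            "algorithm": self.algorithm,
            "cluster_config": ccfg,
            "predictor_config": dict(self.predictor_config or {}),
            "random_state": self.random_state,
        }
        return self

    def _predict_scores(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if self.by_centroid:
            idx = self.cluster_model_.predict(X)
            roles = np.array([self.cluster_model_.role_map_[i] for i in idx], dtype=object)
            scores = (roles == VULNERABLE).astype(float)
            return roles, scores
        return predict(self.predictor_, X)

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "predictor_")
        return self._predict_scores(np.asarray(X, dtype=float))[0]

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "predictor_")
        _, scores = self._predict_scores(np.asarray(X, dtype=float))
        return np.column_stack([1.0 - scores, scores])

    def save(self, path) -> None:
        check_is_fitted(self, "predictor_")
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path) -> "VulnerabilityClassifier":
        with open(path, "rb") as fh:
            obj = pickle.load(fh)
        if not isinstance(obj, VulnerabilityClassifier):
            raise InputError(f"{path} does not contain a saved classifier")
        return obj


def fit_reference(
    cohort: Cohort,
    cluster_method: str = "kmedians",
    algorithm: str = "ann",
    cluster_config: dict | None = None,
    predictor_config: dict | None = None,
    seed: int | None = None,
) -> VulnerabilityClassifier:
    """Fit the diagnostic classifier on a full reference cohort."""
    return VulnerabilityClassifier(
        cluster_method, algorithm, cluster_config, predictor_config,
        random_state=seed,
    ).fit(cohort.features)


@dataclass
class CorrespondenceTable:
    """Cross-tabulation of assigned roles against original crit groups."""

    table: pd.DataFrame  # index: resilient/vulnerable; columns: crit 0..3
    n_unlabelled: int

    def count(self, role: str, crit: int) -> int:
        return int(self.table.loc[role, crit])

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def cross_validate_full(classifier: VulnerabilityClassifier, cohort: Cohort) -> CorrespondenceTable:
    """Cross-tabulate the reference clustering's roles against crit groups.

    Roles come from the reference cluster model (not the predictor); animals
    without a crit label are excluded and counted.
    """
    check_is_fitted(classifier, "cluster_model_")
    crit = cohort.crit_labels
    has = ~np.isnan(crit)
    if not np.any(has):
        raise InputError("cohort carries no crit labels to cross-validate against")
    roles = classifier.cluster_model_.predict_roles(cohort.features)
    table = pd.DataFrame(0, index=["resilient", "vulnerable"], columns=[0, 1, 2, 3])
    for role, c in zip(roles[has], crit[has].astype(int)):
        table.loc[role, c] += 1
    return CorrespondenceTable(table=table, n_unlabelled=int(np.sum(~has)))


def label_animal(
    classifier: VulnerabilityClassifier, profile: BehaviorProfile | np.ndarray
) -> tuple[str, float]:
    """Label one animal; identical to submitting it within any batch."""
    check_is_fitted(classifier, "predictor_")
    x = profile.features if isinstance(profile, BehaviorProfile) else np.asarray(profile, float)
    x = np.atleast_2d(x)
    if x.shape != (1, 3):
        raise InputError(f"expected one 3-dimensional profile, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise InputError("profile contains non-finite measurements")
    roles, scores = classifier._predict_scores(x)
    return str(roles[0]), float(scores[0])


@dataclass
class IndependentReport:
    """Agreement between predicted roles and 0crit/3crit designations."""

    n_animals: int
    n_crit_labelled: int
    n_3crit: int
    n_0crit: int
    frac_3crit_vulnerable: float | None
    frac_0crit_resilient: float | None
    extreme_group_accuracy: float | None  # over the 0crit+3crit subset

    def to_dict(self) -> dict:
        return json.loads(json.dumps(self.__dict__))


def predict_independent(
    classifier: VulnerabilityClassifier, cohort: Cohort
) -> tuple[np.ndarray, IndependentReport]:
    """Label a completely independent cohort and report crit-group overlap."""
    check_is_fitted(classifier, "predictor_")
    if len(cohort) == 0:
        return np.array([], dtype=object), IndependentReport(0, 0, 0, 0, None, None, None)
    roles, _ = classifier._predict_scores(cohort.features)
    crit = cohort.crit_labels
    has = ~np.isnan(crit)
    is3 = has & (crit == 3)
    is0 = has & (crit == 0)
    frac3 = float(np.mean(roles[is3] == "vulnerable")) if np.any(is3) else None
    frac0 = float(np.mean(roles[is0] == "resilient")) if np.any(is0) else None
    extreme = is0 | is3
    if np.any(extreme):
        expected = np.where(crit[extreme] == 3, "vulnerable", "resilient")
        acc = float(np.mean(roles[extreme] == expected))
    else:
        acc = None
    report = IndependentReport(
        n_animals=len(cohort),
        n_crit_labelled=int(np.sum(has)),
        n_3crit=int(np.sum(is3)),
        n_0crit=int(np.sum(is0)),
        frac_3crit_vulnerable=frac3,
        frac_0crit_resilient=frac0,
        extreme_group_accuracy=acc,
    )
    return roles, report
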
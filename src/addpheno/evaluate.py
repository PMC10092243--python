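"""Label-transfer evaluation over repeated random splits.

The validation loop: a cohort is split many times (default 50) into 67%
training / 33% test sets; both sets are clustered separately at k=2 (the
test set's own cluster roles serve as ground truth); a predictor is trained
on the training set's features and cluster roles and applied to the test
set; agreement between the two label sources is tallied in a 2x2
classification matrix and summarised as accuracy, precision, recall and
ROC-AUC, reported as the median across iterations plus the fraction of
iterations landing in the top decile of the metric's range (>= 0.90).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import trapezoid
from scipy.stats import gaussian_kde
from sklearn.metrics import roc_auc_score

from .cluster import ClusterLabeler, assign_roles
from .exceptions import AmbiguityError, InputError, IntegrityError, UndefinedScoreError
from .io import Cohort, SplitArchive
from .supervised import VULNERABLE, fit_predictor, predict

TOP_DECILE_THRESHOLD = 0.90


@dataclass(frozen=True)
class SplitConfig:
    n_splits: int = 50
    test_fraction: float = 0.33
    seed: int = 0

    def validate(self) -> None:
        if self.n_splits < 1:
            raise InputError("n_splits must be >= 1")
        if not (0 < self.test_fraction < 1):
            raise InputError("test_fraction must be in (0, 1)")


def make_splits(cohort: Cohort, config: SplitConfig | None = None) -> SplitArchive:
    """Repeated uniform random 67/33 splits of one cohort."""
    config = config or SplitConfig()
    config.validate()
    n = len(cohort)
    if n < 6:
        raise InputError(f"cohort of {n} animals is too small to split")
    n_test = int(round(config.test_fraction * n))
    n_test = min(max(n_test, 1), n - 1)
    rng = np.random.default_rng(config.seed)
    pairs = []
    for _ in range(config.n_splits):
        perm = rng.permutation(n)
        test_idx = np.sort(perm[:n_test])
        train_idx = np.sort(perm[n_test:])
        pairs.append((cohort.subset(train_idx), cohort.subset(test_idx)))
    archive = SplitArchive(pairs)
    archive.validate(parent=cohort)
    return archive


@dataclass(frozen=True)
class ClassificationMatrix:
    """2x2 tally: clustering roles (rows: truth) vs predictions (columns)."""

    TV: int  # true vulnerable
    FR: int  # false resilient (clustering vulnerable, predicted resilient)
    FV: int  # false vulnerable
    TR: int  # true resilient

    @property
    def total(self) -> int:
        return self.TV + self.FR + self.FV + self.TR


def confusion(true_roles, predicted_roles) -> ClassificationMatrix:
    t = np.asarray(true_roles, dtype=object)
    p = np.asarray(predicted_roles, dtype=object)
    if t.shape != p.shape:
        raise IntegrityError(f"length mismatch: {t.shape} vs {p.shape}")
    tv = t == VULNERABLE
    pv = p == VULNERABLE
    return ClassificationMatrix(
        TV=int(np.sum(tv & pv)),
        FR=int(np.sum(tv & ~pv)),
        FV=int(np.sum(~tv & pv)),
        TR=int(np.sum(~tv & ~pv)),
    )


@dataclass
class MetricSample:
    """One iteration's agreement metrics; undefined entries are None + flag."""

    accuracy: float
    precision: float | None
    recall: float | None
    roc_auc: float
    precision_defined: bool = True
    recall_defined: bool = True


def metrics(matrix: ClassificationMatrix, true_roles, scores) -> MetricSample:
    """Accuracy, precision, recall and ROC-AUC from one iteration.

    accuracy = (TV+TR)/(TV+TR+FV+FR); precision = TV/(TV+FV);
    recall = TV/(TV+FR); each left undefined (flagged) when its denominator
    is zero. ROC-AUC is the probability that a random vulnerable animal's
    score exceeds a random resilient one's, ties counted 1/2 (Mann-Whitney
    construction), computed from the continuous scores.
    """
    t = np.asarray(true_roles, dtype=object)
    scores = np.asarray(scores, dtype=float)
    if t.shape[0] != scores.shape[0]:
        raise IntegrityError("scores not aligned with true_roles")
    n_vuln = int(np.sum(t == VULNERABLE))
    if matrix.TV + matrix.FR != n_vuln or matrix.total != t.shape[0]:
        raise IntegrityError("classification matrix inconsistent with label vectors")
    if n_vuln == 0 or n_vuln == t.shape[0]:
        raise UndefinedScoreError("ROC-AUC undefined: single-class truth")

    accuracy = (matrix.TV + matrix.TR) / matrix.total
    precision = recall = None
    precision_defined = matrix.TV + matrix.FV > 0
    recall_defined = matrix.TV + matrix.FR > 0
    if precision_defined:
        precision = matrix.TV / (matrix.TV + matrix.FV)
    if recall_defined:
        recall = matrix.TV / (matrix.TV + matrix.FR)
    auc = float(roc_auc_score((t == VULNERABLE).astype(int), scores))
    return MetricSample(accuracy, precision, recall, auc, precision_defined, recall_defined)


METRIC_NAMES = ("accuracy", "precision", "recall", "roc_auc")


@dataclass
class MetricSummary:
    """Median and top-decile fraction per metric across iterations.

    The "top decile" is the [0.90, 1.0] band of the metric's range, matching
    how tables of per-combination scores report the share of iterations at
    or above 0.90. Undefined precision/recall iterations are excluded from
    that metric's median, with counts kept in ``n_undefined``.
    """

    combination: tuple
    n_iterations: int
    n_excluded: int
    medians: dict = field(default_factory=dict)
    top_decile_fractions: dict = field(default_factory=dict)
    n_undefined: dict = field(default_factory=dict)


def summarize(samples: list[MetricSample], combination=(), n_excluded: int = 0) -> MetricSummary:
    summary = MetricSummary(
        combination=tuple(combination),
        n_iterations=len(samples),
        n_excluded=n_excluded,
    )
    for name in METRIC_NAMES:
        vals = np.array([getattr(s, name) for s in samples
                         if getattr(s, name) is not None], dtype=float)
        summary.n_undefined[name] = len(samples) - vals.size
        if vals.size:
            summary.medians[name] = float(np.median(vals))
            summary.top_decile_fractions[name] = float(
                np.mean(vals >= TOP_DECILE_THRESHOLD)
            )
        else:
            summary.medians[name] = float("nan")
            summary.top_decile_fractions[name] = float("nan")
    return summary


def _cluster_pair(Xtr, Xte, method, n_restarts, max_iter, tol, seed_tr, seed_te):
    """Cluster training and test sets separately, test standardised on
    training statistics; returns (train model, test model)."""
    train_model = ClusterLabeler(
        method, n_clusters=2, scale=True, n_init=n_restarts,
        max_iter=max_iter, tol=tol, random_state=seed_tr,
    ).fit(Xtr)
    test_model = ClusterLabeler(
        method, n_clusters=2, scaling=(train_model.mean_, train_model.scale_),
        n_init=n_restarts, max_iter=max_iter, tol=tol, random_state=seed_te,
    ).fit(Xte)
    return train_model, test_model


def run_combination(
    cohort: Cohort,
    cluster_method: str = "kmedians",
    algorithm: str = "knn",
    predictor_config: dict | None = None,
    split_config: SplitConfig | None = None,
    n_restarts: int = 25,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int | None = None,
    splits: SplitArchive | None = None,
) -> tuple[MetricSummary, list[MetricSample]]:
    """Evaluate one clustering x prediction combination over repeated splits.

    Iterations where either set collapses to a single cluster role (or where
    cluster orientation is ambiguous, or the training roles are single-class)
    are flagged and excluded; their count is reported in the summary.
    """
    split_config = split_config or SplitConfig(seed=0 if seed is None else seed)
    archive = splits if splits is not None else make_splits(cohort, split_config)
    base_seed = split_config.seed if seed is None else seed

    samples: list[MetricSample] = []
    n_excluded = 0
    for train, test in archive.pairs:
        # per-pair seeds derive from the pair's membership, not the loop
        # index, so the summary is invariant to processing order
        key = f"{base_seed}:{','.join(sorted(train.animal_ids))}|{','.join(sorted(test.animal_ids))}"
        digest = hashlib.sha256(key.encode()).digest()
        seed_tr, seed_te, seed_fit = (
            int.from_bytes(digest[4 * i: 4 * i + 4], "big") % (2**31) for i in range(3)
        )
        try:
            train_model, test_model = _cluster_pair(
                train.features, test.features, cluster_method,
                n_restarts, max_iter, tol, seed_tr, seed_te,
            )
            train_roles = assign_roles(train_model, train.features)
            test_roles = assign_roles(test_model, test.features)
            if np.unique(test_roles).size < 2 or np.unique(train_roles).size < 2:
                raise UndefinedScoreError("a set collapsed to a single role")
            predictor = fit_predictor(
                train.features, train_roles, algorithm, predictor_config,
                scaling=(train_model.mean_, train_model.scale_), seed=seed_fit,
            )
            pred_roles, scores = predict(predictor, test.features)
            sample = metrics(confusion(test_roles, pred_roles), test_roles, scores)
        except (UndefinedScoreError, AmbiguityError, InputError):
            n_excluded += 1
            continue
        samples.append(sample)

    summary = summarize(
        samples,
        combination=(cluster_method, algorithm, tuple(sorted((predictor_config or {}).items()))),
        n_excluded=n_excluded,
    )
    return summary, samples


@dataclass
class KdeCurve:
    """Gaussian-kernel density of metric values over [0, 1]."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    fallback: bool = False

    @property
    def integral(self) -> float:
        return float(trapezoid(self.density, self.grid))


#: Minimal bandwidth used when the samples are (near-)constant.
MIN_BANDWIDTH = 0.01


def kde_curve(samples, bandwidth: float | None = None, n_grid: int = 1001) -> KdeCurve:
    """Kernel density estimate of metric values, normalised on [0, 1].

    Boundary mass is reflected at 0 and 1 so the curve integrates to one
    over the unit interval. Constant samples (zero variance) fall back to a
    fixed minimal bandwidth and are flagged.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise InputError("need at least 2 samples for a density estimate")
    grid = np.linspace(0.0, 1.0, n_grid)
    fallback = False
    std = x.std()
    if bandwidth is not None:
        if bandwidth <= 0:
            raise InputError("bandwidth must be positive")
        h = float(bandwidth)
    elif std == 0:
        h = MIN_BANDWIDTH
        fallback = True
    else:
        kde = gaussian_kde(x)
        h = float(kde.factor * std)
        h = max(h, MIN_BANDWIDTH / 10)

    def _gauss(u: np.ndarray) -> np.ndarray:
        diff = (u[:, None] - x[None, :]) / h
        return np.exp(-0.5 * diff**2).sum(axis=1) / (x.size * h * np.sqrt(2 * np.pi))

    density = _gauss(grid) + _gauss(-grid) + _gauss(2.0 - grid)
    return KdeCurve(grid=grid, density=density, bandwidth=h, fallback=fallback)
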
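"""Supervised stage: predictors trained on clustering-derived roles.

Four algorithm families are supported — K-nearest neighbours, logistic
regression, an RBF-kernel support vector machine, and a feed-forward neural
network with ELU hidden activations — each exposing a hard vulnerable /
resilient label plus a continuous score in [0, 1] interpreted as the
confidence that the animal is vulnerable. KNN / logistic regression / SVM
are scikit-learn estimators (the SVM's score is a logistic calibration of
its margins); the ELU network is implemented here because its architecture
(ELU activations, plain deep stacking at 5/50/500 hidden layers,
cross-entropy loss minimised by backpropagation with early stopping on a
held-out validation fraction) is part of the pipeline's definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.calibration import CalibratedClassifierCV
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .exceptions import DegenerateLabelsError, InputError
from .io import ROLES

ALGORITHMS = ("knn", "logreg", "svm", "ann")

VULNERABLE = "vulnerable"


def _elu(x: np.ndarray) -> np.ndarray:
    out = np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))
    return out


def _elu_grad(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, 1.0, np.exp(np.minimum(x, 0.0)))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


@dataclass
class ANNConfig:
    """Architecture and training control of the ELU network.

    hidden_layers is the depth (the study scans 5, 50 and 500); the width is
    constant across layers. Early stopping monitors cross-entropy on a
    held-out validation fraction and restores the best weights.
    """

    hidden_layers: int = 5
    neurons_per_layer: int = 8
    learning_rate: float = 0.01
    max_epochs: int = 2000
    patience: int = 20
    validation_fraction: float = 0.2
    tol: float = 1e-4

    def validate(self) -> None:
        if self.hidden_layers < 1:
            raise InputError("hidden_layers must be >= 1")
        if self.neurons_per_layer < 1:
            raise InputError("neurons_per_layer must be >= 1")
        if not (0 < self.validation_fraction < 0.5):
            raise InputError("validation_fraction must be in (0, 0.5)")


class EluNetClassifier(ClassifierMixin, BaseEstimator):
    """Binary feed-forward network with ELU hidden units.

    Full-batch Adam on the binary cross-entropy, with early stopping on a
    randomly held-out validation fraction (patience in epochs, best weights
    restored). ``loss_curve_`` records the training loss per epoch.
    """

    def __init__(
        self,
        hidden_layers=5,
        neurons_per_layer=8,
        learning_rate=0.01,
        max_epochs=2000,
        patience=20,
        validation_fraction=0.2,
        tol=1e-4,
        random_state=None,
    ):
        self.hidden_layers = hidden_layers
        self.neurons_per_layer = neurons_per_layer
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.tol = tol
        self.random_state = random_state

    # -- forward/backward --------------------------------------------------
    def _forward(self, X, weights, biases):
        """Return pre-activations and activations of every layer."""
        pre, act = [], [X]
        h = X
        for W, b in zip(weights[:-1], biases[:-1]):
            z = h @ W + b
            pre.append(z)
            h = _elu(z)
            act.append(h)
        z = h @ weights[-1] + biases[-1]
        pre.append(z)
        return pre, act, z[:, 0]

    @staticmethod
    def _loss(logits: np.ndarray, y: np.ndarray) -> float:
        # stable binary cross-entropy from logits
        return float(np.mean(np.logaddexp(0.0, logits) - y * logits))

    def fit(self, X, y):
        ANNConfig(
            self.hidden_layers, self.neurons_per_layer, self.learning_rate,
            self.max_epochs, self.patience, self.validation_fraction, self.tol,
        ).validate()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if not np.all(np.isfinite(X)):
            raise InputError("non-finite training features")
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise DegenerateLabelsError(
                f"need exactly 2 classes in training labels, got {self.classes_.size}"
            )
        yb = (y == self.classes_[1]).astype(float)
        n, d = X.shape
        rng = np.random.default_rng(self.random_state)

        n_val = max(1, int(round(self.validation_fraction * n)))
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        if np.unique(yb[tr_idx]).size < 2:  # keep both classes in the training part
            tr_idx, val_idx = perm, perm[:n_val]
        Xtr, ytr, Xval, yval = X[tr_idx], yb[tr_idx], X[val_idx], yb[val_idx]

        width = self.neurons_per_layer
        dims = [d] + [width] * self.hidden_layers + [1]
        # variance-preserving init for ELU stacks (He-style gain)
        weights = [rng.normal(0.0, np.sqrt(2.0 / dims[i]), size=(dims[i], dims[i + 1]))
                   for i in range(len(dims) - 1)]
        biases = [np.zeros(dims[i + 1]) for i in range(len(dims) - 1)]

        best_val = np.inf
        best = ([W.copy() for W in weights], [b.copy() for b in biases])
        since_best = 0
        self.loss_curve_ = []
        self.validation_scores_ = []
        lr = self.learning_rate
        lr_cap = self.learning_rate * 100.0

        pre, act, logits = self._forward(Xtr, weights, biases)
        cur_loss = self._loss(logits, ytr)

        for _epoch in range(1, self.max_epochs + 1):
            self.loss_curve_.append(cur_loss)

            delta = (_sigmoid(logits) - ytr)[:, None] / Xtr.shape[0]
            grads_w, grads_b = [None] * len(weights), [None] * len(biases)
            for layer in range(len(weights) - 1, -1, -1):
                grads_w[layer] = act[layer].T @ delta
                grads_b[layer] = delta.sum(axis=0)
                if layer > 0:
                    delta = (delta @ weights[layer].T) * _elu_grad(pre[layer - 1])

            # backtracking line search: full-batch gradient descent accepting
            # only steps that do not increase the training loss
            accepted = False
            for _try in range(25):
                trial_w = [W - lr * g for W, g in zip(weights, grads_w)]
                trial_b = [b - lr * g for b, g in zip(biases, grads_b)]
                pre_t, act_t, logits_t = self._forward(Xtr, trial_w, trial_b)
                new_loss = self._loss(logits_t, ytr)
                if np.isfinite(new_loss) and new_loss <= cur_loss:
                    accepted = True
                    break
                lr *= 0.5
            if not accepted:
                break  # gradient step cannot reduce the loss further
            weights, biases = trial_w, trial_b
            pre, act, logits = pre_t, act_t, logits_t
            cur_loss = new_loss
            lr = min(lr * 1.2, lr_cap)

            _, _, val_logits = self._forward(Xval, weights, biases)
            val_loss = self._loss(val_logits, yval)
            self.validation_scores_.append(val_loss)
            if val_loss < best_val - self.tol:
                best_val = val_loss
                best = ([W.copy() for W in weights], [b.copy() for b in biases])
                since_best = 0
            else:
                since_best += 1
                if since_best >= self.patience:
                    break

        self.weights_, self.biases_ = best
        self.n_epochs_ = len(self.loss_curve_)
        return self

    def decision_function(self, X):
        check_is_fitted(self, "weights_")
        X = np.asarray(X, dtype=float)
        _, _, logits = self._forward(X, self.weights_, self.biases_)
        return logits

    def predict_proba(self, X):
        p1 = _sigmoid(self.decision_function(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return self.classes_[(self.decision_function(X) >= 0).astype(int)]


@dataclass
class PredictorModel:
    """A fitted predictor plus the standardisation it expects.

    ``scaling`` is the (mean, scale) pair inherited from the paired
    clustering so that new animals are transformed identically.
    """

    algorithm: str
    estimator: object
    scaling: tuple[np.ndarray, np.ndarray] | None = None
    seed: int | None = None
    config: dict = field(default_factory=dict)

    def _transform(self, X: np.ndarray) -> np.ndarray:
        if self.scaling is None:
            return X
        mean, scale = self.scaling
        return (X - mean) / scale


def make_estimator(algorithm: str, config: dict | None = None, seed: int | None = None):
    """Construct the underlying estimator with the package defaults.

    Defaults: 5 neighbours for KNN (odd, no vote ties); near-unregularised
    L2 logistic regression; RBF SVM with scale bandwidth and Platt-calibrated
    probabilities; ELU network of depth 5 and width 8.
    """
    config = dict(config or {})
    if algorithm == "knn":
        return KNeighborsClassifier(n_neighbors=config.get("n_neighbors", 5))
    if algorithm == "logreg":
        return LogisticRegression(C=config.get("C", 1e4), max_iter=2000)
    if algorithm == "svm":
        base = SVC(
            kernel=config.get("kernel", "rbf"), gamma=config.get("gamma", "scale"),
            C=config.get("C", 1.0), random_state=seed,
        )
        # logistic (Platt) link fitted on the signed margins -> score in [0, 1]
        return CalibratedClassifierCV(
            base, method="sigmoid", cv=config.get("calibration_cv", 3), ensemble=False
        )
    if algorithm == "ann":
        return EluNetClassifier(
            hidden_layers=config.get("hidden_layers", 5),
            neurons_per_layer=config.get("neurons_per_layer", 8),
            learning_rate=config.get("learning_rate", 0.01),
            max_epochs=config.get("max_epochs", 2000),
            patience=config.get("patience", 20),
            validation_fraction=config.get("validation_fraction", 0.2),
            random_state=seed,
        )
    raise InputError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")


def fit_predictor(
    train_features,
    train_roles,
    algorithm: str = "ann",
    config: dict | None = None,
    scaling=None,
    seed: int | None = None,
) -> PredictorModel:
    """Fit a predictor on (already raw) features and clustering-derived roles."""
    X = np.asarray(train_features, dtype=float)
    if not np.all(np.isfinite(X)):
        raise InputError("non-finite training features")
    roles = np.asarray(train_roles, dtype=object)
    if X.shape[0] < 4:
        raise InputError(f"need at least 4 training animals, got {X.shape[0]}")
    bad = set(roles) - set(ROLES)
    if bad:
        raise InputError(f"roles outside {ROLES}: {sorted(bad)}")
    if np.unique(roles).size < 2:
        raise DegenerateLabelsError("training roles contain a single class")
    model = PredictorModel(
        algorithm=algorithm,
        estimator=make_estimator(algorithm, config, seed),
        scaling=None if scaling is None else tuple(np.asarray(a, float) for a in scaling),
        seed=seed,
        config=dict(config or {}),
    )
    y = (roles == VULNERABLE).astype(int)
    model.estimator.fit(model._transform(X), y)
    return model


def predict(model: PredictorModel, features) -> tuple[np.ndarray, np.ndarray]:
    """Hard roles plus vulnerability scores in [0, 1] for new animals.

    Scores are the model's probability of the vulnerable class (neighbour
    vote fraction for KNN, Platt-calibrated margin for the SVM); the hard
    role is score >= 0.5.
    """
    X = np.asarray(features, dtype=float)
    if not np.all(np.isfinite(X)):
        raise InputError("non-finite query features")
    check_is_fitted(model.estimator)
    Z = model._transform(X)
    proba = model.estimator.predict_proba(Z)
    classes = list(model.estimator.classes_)
    scores = proba[:, classes.index(1)]
    roles = np.where(scores >= 0.5, "vulnerable", "resilient").astype(object)
    return roles, scores
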
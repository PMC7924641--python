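"""The five classical classifiers behind one fit/predict contract.

Linear SVM, cubic SVM, 1-nearest-neighbour, linear discriminant analysis
(LDA) and an ensemble subspace discriminant (ESD): 30 discriminant learners,
each trained on a seeded random feature subset of size min(1024, d), combined
by averaging class posterior scores.

Conventions fixed here because the originals are toolbox presets rather than
published values: SVMs use box constraint C = 1, one-vs-one multiclass and
per-feature standardisation fitted on the training rows; the cubic kernel is
(x.x'/d + 1)^3; LDA uses the least-squares/pseudo-inverse route (singular
covariance is the normal case when d >> n); 1-NN ties on distance resolve to
the lowest training index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .exceptions import ConfigurationError, DataError
from .features import FeatureMatrix

CLASSIFIER_KINDS = ("svm_linear", "svm_cubic", "knn1", "lda", "subspace_discriminant_ensemble")


@dataclass
class ClassifierSpec:
    kind: str
    n_learners: int = 30
    subspace_dim: int = 1024
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ConfigurationError(
                f"unknown classifier {self.kind!r}; choose from {CLASSIFIER_KINDS}"
            )
        if self.n_learners < 1:
            raise ConfigurationError("n_learners must be >= 1")
        if self.subspace_dim < 1:
            raise ConfigurationError("subspace_dim must be >= 1")


class SubspaceDiscriminantEnsemble(BaseEstimator, ClassifierMixin):
    """Random-subspace ensemble of linear discriminants.

    Each learner sees a random feature subset of size ``min(subspace_dim, d)``
    drawn without replacement from a generator seeded by ``random_state``;
    prediction averages the learners' class posteriors and takes the arg-max.
    """

    def __init__(self, n_learners: int = 30, subspace_dim: int = 1024, random_state: int = 0):
        self.n_learners = n_learners
        self.subspace_dim = subspace_dim
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        d = X.shape[1]
        dim = min(self.subspace_dim, d)
        rng = np.random.default_rng(self.random_state)
        self.subspaces_ = [np.sort(rng.choice(d, size=dim, replace=False))
                           for _ in range(self.n_learners)]
        self.learners_ = []
        for sub in self.subspaces_:
            lda = LinearDiscriminantAnalysis(solver="svd")
            lda.fit(X[:, sub], y)
            self.learners_.append(lda)
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "learners_")
        X = np.asarray(X, dtype=np.float64)
        proba = np.zeros((X.shape[0], len(self.classes_)))
        for sub, lda in zip(self.subspaces_, self.learners_):
            proba += lda.predict_proba(X[:, sub])
        return proba / len(self.learners_)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def make_estimator(spec: ClassifierSpec):
    """Unfitted scikit-learn estimator for a classifier spec."""
    if spec.kind == "svm_linear":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("svm", SVC(kernel="linear", C=1.0, decision_function_shape="ovo")),
            ]
        )
    if spec.kind == "svm_cubic":
        # gamma='auto' is 1/d, giving the kernel (x.x'/d + 1)^3
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("svm", SVC(kernel="poly", degree=3, gamma="auto", coef0=1.0, C=1.0,
                            decision_function_shape="ovo")),
            ]
        )
    if spec.kind == "knn1":
        return KNeighborsClassifier(n_neighbors=1, metric="euclidean", algorithm="brute")
    if spec.kind == "lda":
        return LinearDiscriminantAnalysis(solver="svd")
    return SubspaceDiscriminantEnsemble(
        n_learners=spec.n_learners, subspace_dim=spec.subspace_dim, random_state=spec.seed
    )


@dataclass
class FittedClassifier:
    """A fitted estimator plus the lineage needed for leakage audits."""

    spec: ClassifierSpec
    estimator: Any
    n_features: int
    fit_sample_ids: list[str] = field(default_factory=list)


def fit(spec: ClassifierSpec, x_train: FeatureMatrix, y_train) -> FittedClassifier:
    y = np.asarray(y_train)
    if len(np.unique(y)) < 2:
        raise ConfigurationError("training fold contains a single class")
    est = make_estimator(spec)
    est.fit(x_train.values, y)
    return FittedClassifier(spec, est, x_train.width, list(x_train.sample_ids))


def predict(model: FittedClassifier, x: FeatureMatrix) -> np.ndarray:
    if x.width != model.n_features:
        raise DataError(f"feature width {x.width} != fit-time width {model.n_features}")
    return np.asarray(model.estimator.predict(x.values))
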
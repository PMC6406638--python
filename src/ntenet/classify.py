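"""Wrapper feature selection and novice/expert classification.

Sequential forward search (SFS) greedily adds the feature that maximizes
stratified 5-fold cross-validated accuracy of a chosen classifier (the
wrapper criterion), breaking ties toward the lower feature index and
stopping when no candidate improves the accuracy. Classification reports
use the novice class as positive; MSE of hard 0/1 predictions equals
1 - accuracy by definition.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, MetaEstimatorMixin, clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

CLASSIFIER_NAMES = ("lda", "knn", "nb", "svm", "tree")
POSITIVE_CLASS = "novice"


def make_classifier(name: str, seed: int = 0, k: int = 3):
    """The five study classifiers; k-NN defaults to k=3."""
    if name == "lda":
        return LinearDiscriminantAnalysis()
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=k)
    if name == "nb":
        return GaussianNB()
    if name == "svm":
        return SVC(random_state=seed)
    if name == "tree":
        return DecisionTreeClassifier(random_state=seed)
    raise ValueError(
        f"unknown classifier {name!r}; expected one of {CLASSIFIER_NAMES}"
    )


def _cv_predictions(estimator, X, y, cv_folds: int, seed: int):
    """Pooled out-of-fold predictions from seeded stratified CV."""
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    pred = np.empty(len(y), dtype=object)
    for train, test in skf.split(X, y):
        est = clone(estimator)
        est.fit(X[train], y[train])
        pred[test] = est.predict(X[test])
    return pred


def _cv_accuracy(estimator, X, y, cv_folds: int, seed: int) -> float:
    return float(np.mean(_cv_predictions(estimator, X, y, cv_folds, seed)
                         == y))


class SequentialForwardSelector(BaseEstimator, MetaEstimatorMixin):
    """Greedy wrapper feature selection by cross-validated accuracy.

    Parameters
    ----------
    classifier : str or estimator, default "knn"
        One of the five study classifiers by name, or any sklearn
        classifier instance.
    cv_folds : int, default 5
    max_features : int or None
        Stop after selecting this many features; None lets the search run
        until no candidate improves the criterion.
    seed : int
        Seeds the CV fold assignment (fixed across all steps, so candidate
        features compete on identical folds) and any stochastic classifier.

    Attributes
    ----------
    selected_features_ : list of int, in selection order
    trace_ : list of float, CV accuracy after each accepted feature
    elapsed_seconds_ : float, wall time of the search (reported only)
    """

    def __init__(self, classifier="knn", cv_folds: int = 5,
                 max_features: int | None = None, seed: int = 0, k: int = 3):
        self.classifier = classifier
        self.cv_folds = cv_folds
        self.max_features = max_features
        self.seed = seed
        self.k = k

    def _estimator(self):
        if isinstance(self.classifier, str):
            return make_classifier(self.classifier, self.seed, self.k)
        return clone(self.classifier)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("need at least two classes to select features")
        est = self._estimator()
        n_feat = X.shape[1]
        limit = n_feat if self.max_features is None else \
            min(self.max_features, n_feat)
        selected: list[int] = []
        trace: list[float] = []
        best = 0.0
        t0 = time.perf_counter()
        while len(selected) < limit:
            best_gain_idx = None
            best_acc = best
            for idx in range(n_feat):  # ascending: ties keep lowest index
                if idx in selected:
                    continue
                acc = _cv_accuracy(est, X[:, selected + [idx]], y,
                                   self.cv_folds, self.seed)
                if acc > best_acc:
                    best_acc = acc
                    best_gain_idx = idx
            if best_gain_idx is None:
                break
            selected.append(best_gain_idx)
            trace.append(best_acc)
            best = best_acc
        self.elapsed_seconds_ = time.perf_counter() - t0
        self.selected_features_ = selected
        self.trace_ = trace
        self.n_features_in_ = n_feat
        return self

    def get_support(self, indices: bool = False):
        if indices:
            return np.array(self.selected_features_)
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.selected_features_] = True
        return mask

    def transform(self, X):
        return np.asarray(X)[:, self.selected_features_]


def sequential_forward_search(
    X, y, classifier: str = "knn", cv_folds: int = 5,
    max_features: int | None = None, seed: int = 0,
) -> tuple[list[int], list[float], float]:
    """Functional form of :class:`SequentialForwardSelector`."""
    sfs = SequentialForwardSelector(classifier, cv_folds, max_features, seed)
    sfs.fit(X, y)
    return sfs.selected_features_, sfs.trace_, sfs.elapsed_seconds_


@dataclass
class EvaluationReport:
    """Pooled stratified-CV metrics; novice is the positive class."""

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f_measure: float
    mse: float
    selected_features: list[int]
    fold_accuracies: list[float] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "precision": self.precision,
            "f_measure": self.f_measure, "mse": self.mse,
            "selected_features": list(self.selected_features),
            "fold_accuracies": list(self.fold_accuracies),
        }


def evaluate(
    X, y, classifier: str = "knn", feature_subset=None, cv_folds: int = 5,
    seed: int = 0, positive_class: str = POSITIVE_CLASS,
) -> EvaluationReport:
    """Stratified k-fold evaluation on a feature subset.

    Metrics are pooled over the out-of-fold predictions; MSE is the mean
    squared 0/1 label error, identical to 1 - accuracy for hard
    predictions.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if feature_subset is not None:
        if len(feature_subset) == 0:
            raise ValueError("feature_subset must be non-empty")
        X = X[:, list(feature_subset)]
    est = make_classifier(classifier, seed) if isinstance(classifier, str) \
        else classifier
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    pred = np.empty(len(y), dtype=object)
    fold_acc = []
    for train, test in skf.split(X, y):
        fitted = clone(est).fit(X[train], y[train])
        p = fitted.predict(X[test])
        pred[test] = p
        fold_acc.append(float(np.mean(p == y[test])))
    pos = pred == positive_class
    actual_pos = y == positive_class
    tp = int(np.sum(pos & actual_pos))
    tn = int(np.sum(~pos & ~actual_pos))
    fp = int(np.sum(pos & ~actual_pos))
    fn = int(np.sum(~pos & actual_pos))
    acc = (tp + tn) / len(y)
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    f = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    return EvaluationReport(
        accuracy=acc, sensitivity=sens, specificity=spec, precision=prec,
        f_measure=f, mse=1.0 - acc,
        selected_features=list(feature_subset) if feature_subset is not None
        else list(range(X.shape[1])),
        fold_accuracies=fold_acc,
    )
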
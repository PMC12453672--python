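"""The ploidy classifier: Random Forest primary, SVM/logistic baselines.

`PloidyClassifier` is a scikit-learn-style estimator.  ``predict`` follows
the sklearn contract (labels from ``classes_``); the clinical four-way
call with an *indeterminable* outcome is :meth:`PloidyClassifier.call`:
a sample is indeterminable when QC failed upstream, when the top vote
fraction falls below the confidence threshold tau, or when the vote is
tied.  For the Random Forest, class probabilities are tree-vote fractions
(majority-vote semantics); the baselines use their native probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (auc, confusion_matrix, precision_recall_fscore_support,
                             roc_curve)
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.multiclass import unique_labels
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

INDETERMINABLE = "indeterminable"
DEFAULT_TAU = 0.6


class PloidyClassifier(ClassifierMixin, BaseEstimator):
    """Four-way ploidy caller over the engineered feature vector.

    Parameters
    ----------
    algorithm : {'random_forest', 'svm', 'logistic'}
    n_trees, max_depth, min_samples_split, min_samples_leaf, max_features :
        forest shape (100 trees, depth 15 by default; bootstrap subsamples
        per tree with per-class balancing).
    tau : float in [0.25, 1)
        confidence threshold below which :meth:`call` reports
        indeterminable.
    """

    def __init__(self, algorithm: str = "random_forest", n_trees: int = 100,
                 max_depth: int = 15, min_samples_split: int = 4,
                 min_samples_leaf: int = 2, max_features="sqrt",
                 tau: float = DEFAULT_TAU, random_state: int | None = None):
        self.algorithm = algorithm
        self.n_trees = n_trees
        self.max_depth = max_depth
        self.min_samples_split = min_samples_split
        self.min_samples_leaf = min_samples_leaf
        self.max_features = max_features
        self.tau = tau
        self.random_state = random_state

    def _make_model(self):
        if self.algorithm == "random_forest":
            return RandomForestClassifier(
                n_estimators=self.n_trees, max_depth=self.max_depth,
                min_samples_split=self.min_samples_split,
                min_samples_leaf=self.min_samples_leaf,
                max_features=self.max_features, bootstrap=True,
                class_weight="balanced_subsample",
                random_state=self.random_state)
        if self.algorithm == "svm":
            return Pipeline([("scale", StandardScaler()),
                             ("svm", SVC(probability=True, class_weight="balanced",
                                         random_state=self.random_state))])
        if self.algorithm == "logistic":
            return Pipeline([("scale", StandardScaler()),
                             ("logistic", LogisticRegression(
                                 max_iter=5000, class_weight="balanced",
                                 random_state=self.random_state))])
        raise ValueError(f"unknown algorithm {self.algorithm!r}")

    def fit(self, X, y):
        if not (0.25 <= self.tau < 1):
            raise ValueError("tau must be in [0.25, 1)")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        feature_names = list(X.columns) if hasattr(X, "columns") else None
        X, y = check_X_y(X, y, dtype=float)
        self.classes_ = unique_labels(y)
        if len(self.classes_) < 2:
            raise ValueError("training labels contain a single class")
        counts = pd.Series(y).value_counts()
        if (counts < 10).any():
            import warnings
            warnings.warn("fewer than 10 training samples in some class",
                          UserWarning, stacklevel=2)
        self.model_ = self._make_model()
        self.model_.fit(X, y)
        self.n_features_in_ = X.shape[1]
        if feature_names is not None:
            self.feature_names_ = feature_names
        return self

    def _check_features(self, X):
        if hasattr(X, "columns") and hasattr(self, "feature_names_"):
            missing = [c for c in self.feature_names_ if c not in X.columns]
            if missing:
                raise ValueError(f"missing features at predict time: {missing}")
            X = X[self.feature_names_]
        return check_array(X, dtype=float)

    def predict_proba(self, X):
        """Per-class probabilities; tree-vote fractions for the forest."""
        check_is_fitted(self, "model_")
        X = self._check_features(X)
        if self.algorithm == "random_forest":
            rf = self.model_
            votes = np.stack([est.predict(X).astype(int) for est in rf.estimators_])
            n_classes = len(rf.classes_)
            frac = np.stack([
                np.bincount(votes[:, i], minlength=n_classes) / votes.shape[0]
                for i in range(X.shape[0])])
            return frac
        return self.model_.predict_proba(X)

    def predict(self, X):
        check_is_fitted(self, "model_")
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]

    def call(self, X, qc_fail=None, tau: float | None = None) -> pd.DataFrame:
        """Four-way calls with the indeterminable rule.

        ``qc_fail`` is an optional boolean mask; QC-failed samples
        short-circuit to indeterminable without model invocation.
        Ties in the vote are indeterminable as well.
        """
        check_is_fitted(self, "model_")
        tau = self.tau if tau is None else tau
        index = X.index if hasattr(X, "index") else pd.RangeIndex(len(X))
        proba = self.predict_proba(X)
        top = proba.max(axis=1)
        tied = (proba == top[:, None]).sum(axis=1) > 1
        labels = self.classes_[np.argmax(proba, axis=1)].astype(object)
        labels[(top < tau) | tied] = INDETERMINABLE
        flags = np.where(tied, "tied_vote",
                         np.where(top < tau, "low_confidence", ""))
        if qc_fail is not None:
            qc_fail = np.asarray(qc_fail, dtype=bool)
            labels[qc_fail] = INDETERMINABLE
            flags = np.where(qc_fail, "qc_fail", flags)
        out = pd.DataFrame({"label": labels, "qc_flags": flags}, index=index)
        for i, cls in enumerate(self.classes_):
            out[f"p_{cls}"] = proba[:, i]
        return out


# -- evaluation -----------------------------------------------------------


@dataclass
class EvalReport:
    auc: dict
    precision: dict
    recall: dict
    f1: dict
    confusion: pd.DataFrame
    accuracy: float
    notes: list = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        rows = {c: {"auc": self.auc.get(c), "precision": self.precision.get(c),
                    "recall": self.recall.get(c), "f1": self.f1.get(c)}
                for c in self.confusion.index}
        return pd.DataFrame(rows).T


def evaluate(clf: PloidyClassifier, X, y) -> EvalReport:
    """One-vs-rest trapezoidal AUC plus P/R/F1 at the majority-vote call."""
    y = np.asarray(y)
    proba = clf.predict_proba(X)
    pred = clf.predict(X)
    classes = list(clf.classes_)
    aucs, notes = {}, {}
    note_list = []
    for i, cls in enumerate(classes):
        pos = y == cls
        if pos.all() or not pos.any():
            aucs[cls] = None
            note_list.append(f"class {cls} absent from labels; AUC null")
            continue
        fpr, tpr, _ = roc_curve(pos.astype(int), proba[:, i])
        aucs[cls] = float(auc(fpr, tpr))
    prec, rec, f1, _ = precision_recall_fscore_support(
        y, pred, labels=classes, zero_division=0)
    conf = pd.DataFrame(confusion_matrix(y, pred, labels=classes),
                        index=classes, columns=classes)
    return EvalReport(
        auc=aucs, precision=dict(zip(classes, prec.tolist())),
        recall=dict(zip(classes, rec.tolist())), f1=dict(zip(classes, f1.tolist())),
        confusion=conf, accuracy=float((pred == y).mean()), notes=note_list)


def train(matrix: pd.DataFrame, labels, **params) -> PloidyClassifier:
    """Convenience wrapper: fit a PloidyClassifier on a feature matrix."""
    clf = PloidyClassifier(**params)
    return clf.fit(matrix, labels)


def compare_algorithms(matrix: pd.DataFrame, labels, algorithms=("random_forest", "svm", "logistic"),
                       cv_iterations: int = 10, seed: int = 0, **params) -> pd.DataFrame:
    """Paired cross-validated comparison with identical folds per algorithm."""
    y = np.asarray(labels)
    X = matrix.to_numpy(float) if hasattr(matrix, "to_numpy") else np.asarray(matrix)
    n_splits = min(cv_iterations, int(pd.Series(y).value_counts().min()))
    n_splits = max(n_splits, 2)
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    folds = list(cv.split(X, y))
    rows = []
    for algo in algorithms:
        base = PloidyClassifier(algorithm=algo, random_state=seed, **params)
        for k, (tr, te) in enumerate(folds):
            clf = clone(base).fit(pd.DataFrame(X[tr], columns=matrix.columns), y[tr])
            rep = evaluate(clf, pd.DataFrame(X[te], columns=matrix.columns), y[te])
            row = {"algorithm": algo, "fold": k, "accuracy": rep.accuracy}
            for cls, a in rep.auc.items():
                row[f"auc_{cls}"] = a
            rows.append(row)
    return pd.DataFrame(rows)
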
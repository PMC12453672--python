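"""Feature selection: Gini importance, correlation grouping, VIF filtering.

Procedure: (i) rank candidates by Random-Forest Gini importance (mean
decrease in impurity, normalised to sum 1); (ii) build a graph with an
edge for every feature pair with |Pearson r| > 0.8 and keep, per connected
component, only the highest-importance member; (iii) for the remaining
ungrouped features compute the variance inflation factor against the other
survivors and drop a feature iff VIF > 10 AND its importance is below the
global median reference (0.033 by default).

`CorrelationVIFSelector` packages the procedure as a scikit-learn
transformer so it composes with pipelines; `gini_importance` and
`decorrelate` are the underlying functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

R_THRESHOLD = 0.8
VIF_THRESHOLD = 10.0
IMPORTANCE_FLOOR = 0.033


def gini_importance(matrix: pd.DataFrame, labels, n_trees: int = 200,
                    seed: int = 0) -> pd.Series:
    """Normalised mean-decrease-in-Gini importances, sorted descending."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("Gini importance needs at least 2 classes")
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    rf.fit(matrix.to_numpy(float), y)
    imp = pd.Series(rf.feature_importances_, index=matrix.columns)
    imp = imp / imp.sum()
    return imp.sort_values(ascending=False)


def _vif(X: np.ndarray, j: int) -> float:
    """VIF of column j against the others; ridge-stabilised on singularity."""
    others = np.delete(X, j, axis=1)
    A = np.column_stack([np.ones(len(X)), others])
    y = X[:, j]
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot <= 0:
        return 1.0
    r2 = 1.0 - ss_res / ss_tot
    return 1.0 / max(1.0 - r2, 1e-12)


def vif_table(matrix: pd.DataFrame) -> pd.Series:
    X = matrix.to_numpy(float)
    if X.shape[1] < 2:
        return pd.Series(1.0, index=matrix.columns)
    return pd.Series([_vif(X, j) for j in range(X.shape[1])], index=matrix.columns)


@dataclass
class SelectionReport:
    importances: pd.Series
    correlation: pd.DataFrame
    groups: list
    vif_before: pd.Series
    vif_after: pd.Series
    retained: list
    dropped_constant: list = field(default_factory=list)
    singular: bool = False
    thresholds: dict = field(default_factory=dict)

    @property
    def mean_vif_before(self) -> float:
        return float(self.vif_before.mean())

    @property
    def mean_vif_after(self) -> float:
        return float(self.vif_after.mean())

    def to_dict(self) -> dict:
        return {
            "importances": self.importances.to_dict(),
            "groups": [sorted(g) for g in self.groups],
            "retained": list(self.retained),
            "dropped_constant": list(self.dropped_constant),
            "mean_vif_before": self.mean_vif_before,
            "mean_vif_after": self.mean_vif_after,
            "thresholds": self.thresholds,
        }


def decorrelate(matrix: pd.DataFrame, importances: pd.Series,
                r_threshold: float = R_THRESHOLD,
                vif_threshold: float = VIF_THRESHOLD,
                importance_floor: float = IMPORTANCE_FLOOR) -> SelectionReport:
    """Correlation-component pruning followed by VIF filtering.

    Ties on importance within a group break lexicographically on the
    feature name, for determinism.
    """
    if matrix.shape[1] < 2:
        raise ValueError("decorrelate needs at least 2 features")
    const = [c for c in matrix.columns if matrix[c].nunique() <= 1]
    mat = matrix.drop(columns=const)
    imp = importances.reindex(mat.columns).fillna(0.0)

    corr = mat.corr()
    g = nx.Graph()
    g.add_nodes_from(mat.columns)
    cols = list(mat.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            if abs(corr.loc[a, b]) > r_threshold:
                g.add_edge(a, b)
    components = [set(c) for c in nx.connected_components(g)]
    groups = [c for c in components if len(c) > 1]

    vif_before = vif_table(mat)
    retained = []
    for comp in components:
        best = sorted(comp, key=lambda f: (-imp[f], f))[0]
        retained.append(best)
    retained = [c for c in cols if c in set(retained)]  # column order

    grouped = set().union(*groups) if groups else set()
    survivors = list(retained)
    singular = bool((vif_before[survivors] > 1e10).any())
    for feat in list(survivors):
        if feat in grouped:
            continue  # standalone rule only applies to ungrouped features
        v = _vif(mat[survivors].to_numpy(float), survivors.index(feat))
        if v > vif_threshold and imp[feat] < importance_floor:
            survivors.remove(feat)

    vif_after = vif_table(mat[survivors])
    return SelectionReport(
        importances=imp.sort_values(ascending=False), correlation=corr,
        groups=groups, vif_before=vif_before, vif_after=vif_after,
        retained=survivors, dropped_constant=const, singular=singular,
        thresholds={"r": r_threshold, "vif": vif_threshold,
                    "importance_floor": importance_floor})


class CorrelationVIFSelector(BaseEstimator, TransformerMixin):
    """Scikit-learn transformer wrapping the selection procedure.

    Parameters mirror the procedure's thresholds.  Fitted attributes:
    ``retained_`` (feature names), ``report_`` (:class:`SelectionReport`),
    ``support_`` (boolean mask over input columns).
    """

    def __init__(self, r_threshold: float = R_THRESHOLD,
                 vif_threshold: float = VIF_THRESHOLD,
                 importance_floor: float = IMPORTANCE_FLOOR,
                 n_trees: int = 200, random_state: int = 0):
        self.r_threshold = r_threshold
        self.vif_threshold = vif_threshold
        self.importance_floor = importance_floor
        self.n_trees = n_trees
        self.random_state = random_state

    def fit(self, X, y):
        X = pd.DataFrame(X)
        imp = gini_importance(X, y, n_trees=self.n_trees, seed=self.random_state)
        self.report_ = decorrelate(X, imp, self.r_threshold,
                                   self.vif_threshold, self.importance_floor)
        self.retained_ = list(self.report_.retained)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.support_ = np.array([c in set(self.retained_) for c in X.columns])
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "retained_")
        X = pd.DataFrame(X)
        if list(X.columns) != list(self.feature_names_in_) and X.shape[1] == self.n_features_in_:
            X.columns = self.feature_names_in_
        return X[self.retained_]

    def get_support(self):
        check_is_fitted(self, "support_")
        return self.support_
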
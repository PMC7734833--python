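"""The eight-model candidate zoo and importance extraction.

Every candidate is a scikit-learn-compatible classifier with a fixed
hyperparameter configuration (tuned once by five-fold cross-validation in the
motivating study) and a notion of feature importance, which the embedded
feature-selection stage requires: impurity importances for tree ensembles,
absolute coefficient weights for linear models. Importance-free learners
(neural nets, kernel SVMs) are deliberately outside the zoo.

Zoo order is fixed and doubles as the tie-break order wherever candidates
compare equal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

__all__ = [
    "LinearSVMProbability",
    "CandidateModelSpec",
    "candidate_model_zoo",
    "ZOO_ORDER",
    "extract_importances",
]

ZOO_ORDER = ("DT", "SVM", "RF", "ET", "GBDT", "ADB", "Bagging", "XGB")


class LinearSVMProbability(BaseEstimator, ClassifierMixin):
    """Linear-kernel SVM emitting probabilities through a logistic link.

    A linear SVC has no native probability output; after fitting the margin,
    a one-dimensional logistic regression is fitted on the training rows'
    decision-function values so that ``predict_proba`` returns scores in
    [0, 1] that preserve the SVM ranking. ``coef_`` exposes the underlying
    hyperplane weights for importance extraction.
    """

    def __init__(self, C: float = 0.001, tol: float = 0.0001) -> None:
        self.C = C
        self.tol = tol

    def fit(self, X, y):
        self.svc_ = SVC(kernel="linear", C=self.C, tol=self.tol)
        self.svc_.fit(X, y)
        self.classes_ = self.svc_.classes_
        scores = self.svc_.decision_function(X).reshape(-1, 1)
        self.link_ = LogisticRegression()
        self.link_.fit(scores, y)
        return self

    @property
    def coef_(self) -> np.ndarray:
        return self.svc_.coef_

    def decision_function(self, X) -> np.ndarray:
        return self.svc_.decision_function(X)

    def predict_proba(self, X) -> np.ndarray:
        scores = self.svc_.decision_function(X).reshape(-1, 1)
        return self.link_.predict_proba(scores)

    def predict(self, X) -> np.ndarray:
        return self.svc_.predict(X)


_ZOO_PARAMS: dict[str, dict[str, Any]] = {
    "DT": dict(max_depth=10, min_samples_leaf=20, min_samples_split=300, random_state=1),
    "SVM": dict(C=0.001, tol=0.0001),
    "RF": dict(bootstrap=True, max_depth=5, n_estimators=50, random_state=1),
    "ET": dict(bootstrap=False, max_depth=3, n_estimators=50, random_state=1),
    "GBDT": dict(
        learning_rate=0.05, max_depth=3, n_estimators=50, subsample=0.6, random_state=1
    ),
    "ADB": dict(base_max_depth=3, learning_rate=0.01, n_estimators=100, random_state=1),
    "Bagging": dict(
        base_max_depth=5,
        n_estimators=300,
        bootstrap=True,
        max_features=0.6,
        max_samples=0.6,
        random_state=1,
    ),
    "XGB": dict(
        learning_rate=0.01,
        max_depth=5,
        n_estimators=200,
        subsample=0.6,
        colsample_bytree=0.8,
        random_state=1,
    ),
}


def _build(name: str, params: dict[str, Any]):
    p = dict(params)
    if name == "DT":
        return DecisionTreeClassifier(**p)
    if name == "SVM":
        return LinearSVMProbability(**p)
    if name == "RF":
        return RandomForestClassifier(**p)
    if name == "ET":
        return ExtraTreesClassifier(**p)
    if name == "GBDT":
        return GradientBoostingClassifier(**p)
    if name == "ADB":
        depth = p.pop("base_max_depth")
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=depth), **p
        )
    if name == "Bagging":
        depth = p.pop("base_max_depth")
        return BaggingClassifier(
            estimator=DecisionTreeClassifier(max_depth=depth), **p
        )
    if name == "XGB":
        return XGBClassifier(eval_metric="logloss", **p)
    raise KeyError(f"unknown candidate model {name!r}")


@dataclass
class CandidateModelSpec:
    """One configured candidate learner, plus its selected feature subset.

    ``selected_subset`` is attached by the feature-selection stage; until
    then it is None. ``build()`` returns a fresh unfitted estimator so the
    spec itself never holds fitted state.
    """

    name: str
    params: dict[str, Any] = field(default_factory=dict)
    selected_subset: Any = None  # FeatureSubset, set after feature selection

    def build(self):
        return _build(self.name, self.params)

    def with_subset(self, subset) -> "CandidateModelSpec":
        return replace(self, selected_subset=subset)


def candidate_model_zoo(
    overrides: dict[str, dict[str, Any]] | None = None
) -> list[CandidateModelSpec]:
    """The eight configured candidates, in fixed zoo order.

    ``overrides`` maps model name to hyperparameter overrides; unknown model
    names or parameter keys raise rather than being silently ignored.
    """
    overrides = overrides or {}
    unknown = set(overrides) - set(ZOO_ORDER)
    if unknown:
        raise KeyError(f"unknown candidate model(s) in overrides: {sorted(unknown)}")
    specs = []
    for name in ZOO_ORDER:
        params = dict(_ZOO_PARAMS[name])
        extra = overrides.get(name, {})
        bad = set(extra) - set(params)
        if bad:
            raise KeyError(f"unknown hyperparameter(s) for {name}: {sorted(bad)}")
        params.update(extra)
        specs.append(CandidateModelSpec(name, params))
    return specs


def extract_importances(fitted, n_features: int) -> np.ndarray:
    """Per-feature nonnegative importance scores from a fitted candidate.

    Tree ensembles expose impurity importances; linear models contribute
    absolute coefficient weights. Bagging subsamples features per estimator,
    so its importances are per-tree importances averaged after mapping each
    tree's feature slice back to the full column space.
    """
    if isinstance(fitted, BaggingClassifier):
        total = np.zeros(n_features)
        for est, feats in zip(fitted.estimators_, fitted.estimators_features_):
            total[np.asarray(feats)] += est.feature_importances_
        return total / len(fitted.estimators_)
    if hasattr(fitted, "feature_importances_"):
        imp = np.asarray(fitted.feature_importances_, dtype=float)
    elif hasattr(fitted, "coef_"):
        imp = np.abs(np.asarray(fitted.coef_, dtype=float)).ravel()
    else:
        raise TypeError(
            f"{type(fitted).__name__} exposes neither feature_importances_ nor "
            "coef_; importance-free models are not supported"
        )
    if imp.shape[0] != n_features:
        raise ValueError("importance vector length mismatch")
    if not np.all(np.isfinite(imp)):
        raise ValueError("importances must be finite")
    return imp
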
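"""Embedded feature selection by importance-threshold traversal.

For each candidate model: fit it on the full training set to obtain one
importance score per encoded column, then sweep a threshold over every
distinct importance value. Each threshold keeps the columns whose importance
is greater than or equal to it, producing a nested family of candidate
subsets from the single top-ranked column down to all columns. Every subset
is scored by stratified k-fold cross-validated AUC (k = 5 by default) and the
subset with the best mean AUC wins; ties prefer the smaller subset.

Inclusion at the threshold is >= rather than strictly greater so that the
largest threshold still yields a non-empty, trainable subset. Folds are drawn
once per model and shared across all its subsets so subset scores are
comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .models import CandidateModelSpec, extract_importances
from .ncr import LabeledDataset

__all__ = [
    "FeatureSubset",
    "fit_importances",
    "enumerate_threshold_subsets",
    "select_best_subset",
    "select_features_for_model",
]


@dataclass
class FeatureSubset:
    """A named set of encoded feature columns with its attained CV AUC."""

    name: str
    columns: list[str]
    cv_auc: float | None = None

    def __post_init__(self) -> None:
        if not self.columns:
            raise ValueError("a feature subset must be non-empty")

    def __len__(self) -> int:
        return len(self.columns)

    def column_set(self) -> frozenset:
        return frozenset(self.columns)


def fit_importances(
    model: CandidateModelSpec, train: LabeledDataset
) -> np.ndarray:
    """Fit the model on the full training set; return one score per column."""
    est = model.build()
    est.fit(train.X, train.y)
    return extract_importances(est, train.matrix.n_columns)


def enumerate_threshold_subsets(
    importances: np.ndarray,
    column_names: list[str],
    name_prefix: str = "f",
    max_subsets: int | None = None,
) -> list[FeatureSubset]:
    """One subset per distinct importance value, smallest subset first.

    The threshold sweeps the distinct importance values from highest to
    lowest; subset t = {columns with importance >= t}. Consecutive subsets
    are strictly nested and the last one contains every column. If
    ``max_subsets`` caps the traversal, thresholds are thinned evenly across
    the sorted distinct values, always retaining the smallest and the largest
    subset.
    """
    importances = np.asarray(importances, dtype=float)
    if importances.ndim != 1 or importances.size == 0:
        raise ValueError("importances must be a non-empty 1-D vector")
    if importances.size != len(column_names):
        raise ValueError("importances length must match column count")
    thresholds = np.unique(importances)[::-1]  # descending
    if max_subsets is not None and max_subsets >= 1 and len(thresholds) > max_subsets:
        pick = np.unique(
            np.linspace(0, len(thresholds) - 1, max_subsets).round().astype(int)
        )
        thresholds = thresholds[pick]
    subsets = []
    cols = np.asarray(column_names, dtype=object)
    for j, t in enumerate(thresholds):
        keep = cols[importances >= t]
        subsets.append(FeatureSubset(f"{name_prefix}_{j + 1}", list(keep)))
    return subsets


def _cv_mean_auc(
    model: CandidateModelSpec,
    X: np.ndarray,
    y: np.ndarray,
    folds: int,
    seed: int,
) -> float:
    """Mean out-of-fold AUC over a stratified k-fold schedule."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    aucs = []
    for tr, va in skf.split(X, y):
        if len(np.unique(y[va])) < 2 or len(np.unique(y[tr])) < 2:
            raise ValueError("a CV fold lost a class; reduce folds or rebalance")
        est = model.build()
        est.fit(X[tr], y[tr])
        probs = est.predict_proba(X[va])[:, 1]
        aucs.append(roc_auc_score(y[va], probs))
    return float(np.mean(aucs))


def select_best_subset(
    model: CandidateModelSpec,
    train: LabeledDataset,
    subsets: list[FeatureSubset],
    folds: int = 5,
    seed: int = 0,
) -> FeatureSubset:
    """Score every subset by mean stratified k-fold AUC; return the best.

    Folds are fixed once (from ``seed``) and shared across subsets. Ties in
    mean AUC go to the subset with fewer columns.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if not subsets:
        raise ValueError("no candidate subsets supplied")
    best: FeatureSubset | None = None
    for subset in subsets:
        X = train.matrix.restrict_columns(subset.columns)
        auc = _cv_mean_auc(model, X, train.y, folds, seed)
        scored = FeatureSubset(subset.name, list(subset.columns), cv_auc=auc)
        if (
            best is None
            or scored.cv_auc > best.cv_auc
            or (scored.cv_auc == best.cv_auc and len(scored) < len(best))
        ):
            best = scored
    return best


def select_features_for_model(
    model: CandidateModelSpec,
    train: LabeledDataset,
    folds: int = 5,
    seed: int = 0,
    max_subsets: int | None = None,
    name: str | None = None,
) -> FeatureSubset:
    """Full embedded selection for one candidate: importances -> traversal ->
    CV scoring -> best subset."""
    importances = fit_importances(model, train)
    subsets = enumerate_threshold_subsets(
        importances,
        train.matrix.column_names,
        name_prefix=name or f"f_{model.name}",
        max_subsets=max_subsets,
    )
    return select_best_subset(model, train, subsets, folds=folds, seed=seed)
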
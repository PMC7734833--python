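"""Self-adaptive three-layer stacked generalization.

Architecture
------------
From the eight candidates, the three with the best five-fold CV AUC on their
own selected feature subsets become the base classifiers M_t1..M_t3 (the
"self-adaptive" step — no fixed trio is hard-wired).

Layer 1: each base classifier, on its own feature subset, produces an
out-of-fold prediction column for the training set (every training row is
predicted by the one fold-model that did not see it) and a fold-averaged
prediction column for the test set.

Layer 2: each base classifier is re-trained by the same five-fold stacking
scheme, but its input is its own layer-1 prediction column concatenated with
f_in, the intersection of the three selected feature subsets — a small core
of features every base classifier agreed matters.

Layer 3 (meta): an L2-regularized logistic regression fitted on the three
layer-2 training columns produces the final readmission probability.

All meta-features are predicted probabilities of the positive class, never
hard labels. No fitting step ever receives test labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from ._seeds import derive_seed
from .features import FeatureSubset, _cv_mean_auc
from .models import CandidateModelSpec
from .ncr import LabeledDataset
from .preprocess import DesignMatrix

__all__ = [
    "BaseClassifierSet",
    "StackPredictions",
    "select_top_k",
    "rank_candidates",
    "kfold_stack_predictions",
    "build_layer2_inputs",
    "fit_stacked_model",
    "StackedModelResult",
]


@dataclass
class StackPredictions:
    """Out-of-fold train column and fold-averaged test column for one
    classifier in one layer."""

    source: str
    layer: int
    train_column: np.ndarray
    test_column: np.ndarray

    def __post_init__(self) -> None:
        for arr in (self.train_column, self.test_column):
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError("stack predictions must be probabilities in [0, 1]")


@dataclass
class BaseClassifierSet:
    """The adaptively selected trio and the intersection of their subsets."""

    members: list[CandidateModelSpec]
    intersection: FeatureSubset | None
    cv_aucs: dict[str, float]

    def __post_init__(self) -> None:
        if len(self.members) != 3:
            raise ValueError("exactly three base classifiers are required")


def select_top_k(names: list[str], scores: list[float], k: int = 3) -> list[str]:
    """Top-k names by score; ties keep the earlier (zoo-order) name."""
    order = sorted(range(len(names)), key=lambda i: (-scores[i], i))
    return [names[i] for i in order[:k]]


def rank_candidates(
    train: LabeledDataset,
    specs: list[CandidateModelSpec],
    folds: int = 5,
    seed: int = 0,
) -> BaseClassifierSet:
    """Five-fold CV AUC per candidate on its own subset; keep the top three.

    Every spec must already carry its selected feature subset. The
    intersection f_in of the three winners' subsets is computed here; it may
    be empty, in which case layer 2 falls back to prediction-only input.
    """
    if len(specs) < 3:
        raise ValueError("need at least three candidates to select a base trio")
    for spec in specs:
        if spec.selected_subset is None:
            raise ValueError(f"candidate {spec.name} has no selected feature subset")
    aucs: dict[str, float] = {}
    for spec in specs:
        X = train.matrix.restrict_columns(spec.selected_subset.columns)
        aucs[spec.name] = _cv_mean_auc(spec, X, train.y, folds, seed)
    winners = select_top_k([s.name for s in specs], [aucs[s.name] for s in specs], 3)
    members = [s for s in specs if s.name in set(winners)]
    common = frozenset.intersection(
        *[m.selected_subset.column_set() for m in members]
    )
    if common:
        # Preserve design-matrix column order for determinism.
        ordered = [c for c in train.matrix.column_names if c in common]
        intersection = FeatureSubset("f_in", ordered)
    else:
        intersection = None
    return BaseClassifierSet(members, intersection, aucs)


def kfold_stack_predictions(
    model: CandidateModelSpec,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    folds: int = 5,
    seed: int = 0,
    layer: int = 1,
) -> StackPredictions:
    """Five-fold stacking for one classifier.

    The training set is split into stratified folds; in each iteration the
    classifier trains on k-1 folds, predicts the held-out fold (assembling
    the out-of-fold training column) and predicts the full test set. The test
    column is the arithmetic mean of the per-fold test predictions.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    oof = np.full(len(y_train), np.nan)
    test_parts = []
    for tr, held in skf.split(X_train, y_train):
        if len(np.unique(y_train[tr])) < 2:
            raise ValueError("a stacking fold lost a class")
        est = model.build()
        est.fit(X_train[tr], y_train[tr])
        oof[held] = est.predict_proba(X_train[held])[:, 1]
        test_parts.append(est.predict_proba(X_test)[:, 1])
    assert not np.isnan(oof).any(), "out-of-fold coverage gap"
    return StackPredictions(
        source=model.name,
        layer=layer,
        train_column=oof,
        test_column=np.mean(test_parts, axis=0),
    )


def build_layer2_inputs(
    layer1: dict[str, StackPredictions],
    f_in: FeatureSubset | None,
    train: LabeledDataset,
    test: DesignMatrix,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per base classifier: [own layer-1 prediction column ‖ f_in columns].

    Each base classifier sees only its own layer-1 column, not the other
    members'. With an empty intersection the input degenerates to the single
    prediction column (warned, not fatal).
    """
    if f_in is None:
        warnings.warn(
            "feature-subset intersection f_in is empty; layer-2 inputs reduce "
            "to the layer-1 prediction column alone",
            stacklevel=2,
        )
        train_extra = np.empty((train.n_rows, 0))
        test_extra = np.empty((test.n_rows, 0))
    else:
        train_extra = train.matrix.restrict_columns(f_in.columns)
        test_extra = test.restrict_columns(f_in.columns)
    inputs = {}
    for name, preds in layer1.items():
        X2_train = np.hstack([preds.train_column[:, None], train_extra])
        X2_test = np.hstack([preds.test_column[:, None], test_extra])
        inputs[name] = (X2_train, X2_test)
    return inputs


@dataclass
class StackedModelResult:
    """Fitted artifacts and predictions of the three-layer stack."""

    bases: BaseClassifierSet
    layer1: dict[str, StackPredictions]
    layer2: dict[str, StackPredictions]
    meta_model: LogisticRegression
    train_probabilities: np.ndarray
    test_probabilities: np.ndarray


def fit_stacked_model(
    train: LabeledDataset,
    test: DesignMatrix,
    bases: BaseClassifierSet,
    folds: int = 5,
    seed: int = 0,
    meta_C: float = 1.0,
) -> StackedModelResult:
    """Fit the full three-layer stack; return final test probabilities.

    Layer 1 and layer 2 use fresh stratified fold partitions derived from the
    same master ``seed`` (tags "layer1"/"layer2"), so the whole stack is
    reproducible bit-for-bit at the level of fold assignments.
    """
    layer1: dict[str, StackPredictions] = {}
    for member in bases.members:
        X1_train = train.matrix.restrict_columns(member.selected_subset.columns)
        X1_test = test.restrict_columns(member.selected_subset.columns)
        layer1[member.name] = kfold_stack_predictions(
            member,
            X1_train,
            train.y,
            X1_test,
            folds=folds,
            seed=derive_seed(seed, "layer1", member.name),
            layer=1,
        )

    inputs2 = build_layer2_inputs(layer1, bases.intersection, train, test)
    layer2: dict[str, StackPredictions] = {}
    for member in bases.members:
        X2_train, X2_test = inputs2[member.name]
        layer2[member.name] = kfold_stack_predictions(
            member,
            X2_train,
            train.y,
            X2_test,
            folds=folds,
            seed=derive_seed(seed, "layer2", member.name),
            layer=2,
        )

    names = [m.name for m in bases.members]
    meta_train = np.column_stack([layer2[n].train_column for n in names])
    meta_test = np.column_stack([layer2[n].test_column for n in names])
    # L2 penalty is sklearn's default; only the strength is exposed.
    meta = LogisticRegression(C=meta_C, max_iter=1000)
    meta.fit(meta_train, train.y)
    return StackedModelResult(
        bases=bases,
        layer1=layer1,
        layer2=layer2,
        meta_model=meta,
        train_probabilities=meta.predict_proba(meta_train)[:, 1],
        test_probabilities=meta.predict_proba(meta_test)[:, 1],
    )
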
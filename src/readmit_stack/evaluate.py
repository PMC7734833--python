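"""Evaluation metrics, the repeated-split protocol, and significance tests.

Discrimination is summarized by AUC (the probability that a random
readmitted admission outranks a random non-readmitted one; ties count ½) and
by threshold metrics at a fixed probability cut-off:

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)

Because single stratified splits of a few thousand rows are noisy, the
protocol re-splits the cohort with a fresh derived seed ``n_repeats`` times
(default 10), runs the entire pipeline per repeat, and reports mean ± sample
standard deviation per model and metric, plus paired significance of the
stacked model against every candidate across repeats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from ._seeds import derive_seed
from .cohort import CohortTable
from .features import select_features_for_model
from .models import candidate_model_zoo
from .ncr import LabeledDataset, ncr_undersample
from .preprocess import SplitPlan, preprocess_cohort
from .stacking import fit_stacked_model, rank_candidates

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_metrics",
    "auc",
    "paired_significance",
    "evaluate_probabilities",
    "run_single_split",
    "repeated_protocol",
    "ncr_comparison",
    "STACKED",
]

STACKED = "Stacking"
METRICS = ("auc", "accuracy", "sensitivity", "specificity")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_metrics(
    labels: np.ndarray, probabilities: np.ndarray, threshold: float = 0.5
) -> tuple[ConfusionCounts, float, float, float]:
    """Confusion counts and (accuracy, sensitivity, specificity) at a cut-off.

    A ratio with zero denominator is reported as NaN with a warning rather
    than raising — e.g. sensitivity is undefined when no positives were
    evaluated.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie in (0, 1)")
    labels = np.asarray(labels)
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary (0/1)")
    pred = np.asarray(probabilities) >= threshold
    pos = labels == 1
    counts = ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator)", stacklevel=3)
            return float("nan")
        return num / den

    accuracy = ratio(counts.tp + counts.tn, counts.total, "accuracy")
    sensitivity = ratio(counts.tp, counts.tp + counts.fn, "sensitivity")
    specificity = ratio(counts.tn, counts.tn + counts.fp, "specificity")
    return counts, accuracy, sensitivity, specificity


def auc(labels: np.ndarray, probabilities: np.ndarray) -> float:
    """Area under the ROC curve (Mann–Whitney pairwise-ranking probability)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC requires both classes to be present")
    return float(roc_auc_score(labels, probabilities))


def paired_significance(
    values_a: np.ndarray, values_b: np.ndarray, method: str = "t"
) -> float:
    """Two-sided paired-difference p-value across repeats.

    ``method="t"`` (default) is the paired t-test on per-repeat differences;
    ``method="wilcoxon"`` the exact signed-rank test. Identical vectors give
    p = 1.0 by convention (no evidence of any difference).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    if a.size < 2:
        raise ValueError("need at least two paired values")
    diffs = a - b
    if np.allclose(diffs, 0):
        return 1.0
    if method == "t":
        with warnings.catch_warnings():
            # constant nonzero differences give t = inf, p = 0; the scipy
            # precision warning is expected there
            warnings.simplefilter("ignore", RuntimeWarning)
            return float(stats.ttest_rel(a, b).pvalue)
    if method == "wilcoxon":
        return float(stats.wilcoxon(a, b, mode="exact").pvalue)
    raise ValueError(f"unknown significance method {method!r}")


def evaluate_probabilities(
    labels: np.ndarray, probabilities: np.ndarray, threshold: float = 0.5
) -> dict[str, float]:
    _, accuracy, sensitivity, specificity = confusion_metrics(
        labels, probabilities, threshold
    )
    return {
        "auc": auc(labels, probabilities),
        "accuracy": accuracy,
        "sensitivity": sensitivity,
        "specificity": specificity,
    }


@dataclass
class MetricsReport:
    """Per-repeat metrics, aggregates, and pairwise significance.

    ``per_repeat`` has one row per (repeat, model) with the four metrics;
    ``summary`` holds mean and sample sd (ddof=1) per model/metric;
    ``p_values`` compares the stacked model against each candidate, paired by
    repeat, on each metric.
    """

    per_repeat: pd.DataFrame
    summary: pd.DataFrame
    p_values: pd.DataFrame

    def formatted_summary(self) -> pd.DataFrame:
        """Mean ± sd strings, models × metrics."""
        out = {}
        for metric in METRICS:
            mean = self.summary[(metric, "mean")]
            sd = self.summary[(metric, "sd")]
            out[metric] = [
                f"{m:.3f} ± {s:.2f}" for m, s in zip(mean, sd)
            ]
        return pd.DataFrame(out, index=self.summary.index)


def run_single_split(
    cohort: CohortTable,
    seed: int,
    train_fraction: float = 0.8,
    missing_filter_threshold: float = 0.20,
    bucket_threshold: float = 0.30,
    balancer: str = "ncr",
    ncr_k: int = 3,
    fs_folds: int = 5,
    rank_folds: int = 5,
    stack_folds: int = 5,
    max_subsets: int | None = None,
    meta_C: float = 1.0,
    threshold: float = 0.5,
    include_stack: bool = True,
    model_overrides: dict | None = None,
) -> dict[str, object]:
    """One end-to-end pipeline pass on a single stratified split.

    Returns per-model test metrics for the stacked model and all eight
    candidates, plus the fitted artifacts (selected subsets, base trio, NCR
    removal count) for inspection.
    """
    if balancer not in ("ncr", "none"):
        raise ValueError("balancer must be 'ncr' or 'none'")
    plan = SplitPlan(train_fraction=train_fraction, seed=derive_seed(seed, "split"))
    train_dm, test_dm, dropped = preprocess_cohort(
        cohort,
        plan,
        missing_filter_threshold=missing_filter_threshold,
        bucket_threshold=bucket_threshold,
    )
    train = LabeledDataset.from_matrix(train_dm)
    removed = 0
    if balancer == "ncr":
        train, removed = ncr_undersample(train, k=ncr_k)

    specs = candidate_model_zoo(model_overrides)
    fitted_specs = []
    for spec in specs:
        subset = select_features_for_model(
            spec,
            train,
            folds=fs_folds,
            seed=derive_seed(seed, "fs", spec.name),
            max_subsets=max_subsets,
        )
        fitted_specs.append(spec.with_subset(subset))

    bases = stack = None
    metrics: dict[str, dict[str, float]] = {}
    if include_stack:
        bases = rank_candidates(
            train, fitted_specs, folds=rank_folds, seed=derive_seed(seed, "rank")
        )
        stack = fit_stacked_model(
            train,
            test_dm,
            bases,
            folds=stack_folds,
            seed=derive_seed(seed, "stack"),
            meta_C=meta_C,
        )
        metrics[STACKED] = evaluate_probabilities(
            test_dm.labels, stack.test_probabilities, threshold
        )
    for spec in fitted_specs:
        est = spec.build()
        est.fit(
            train.matrix.restrict_columns(spec.selected_subset.columns), train.y
        )
        probs = est.predict_proba(
            test_dm.restrict_columns(spec.selected_subset.columns)
        )[:, 1]
        metrics[spec.name] = evaluate_probabilities(test_dm.labels, probs, threshold)

    return {
        "metrics": metrics,
        "bases": bases,
        "stack": stack,
        "specs": fitted_specs,
        "ncr_removed": removed,
        "dropped_columns": dropped,
        "train_rows": train.n_rows,
        "test_rows": test_dm.n_rows,
    }


def repeated_protocol(
    cohort: CohortTable,
    n_repeats: int = 10,
    master_seed: int = 0,
    significance_method: str = "t",
    **pipeline_kwargs,
) -> MetricsReport:
    """Run the whole pipeline over ``n_repeats`` fresh stratified splits.

    Repeat r uses seed ``derive_seed(master_seed, "repeat", r)`` for every
    random choice inside the pass, so the report is fully reproducible from
    the master seed alone.
    """
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    rows = []
    for r in range(n_repeats):
        result = run_single_split(
            cohort, seed=derive_seed(master_seed, "repeat", r), **pipeline_kwargs
        )
        for model, m in result["metrics"].items():
            rows.append({"repeat": r, "model": model, **m})
    per_repeat = pd.DataFrame(rows)

    present = list(per_repeat["model"].unique())
    model_order = ([STACKED] if STACKED in present else []) + [
        m for m in present if m != STACKED
    ]
    agg = {}
    for metric in METRICS:
        pivot = per_repeat.pivot(index="repeat", columns="model", values=metric)
        agg[(metric, "mean")] = pivot.mean(axis=0)
        agg[(metric, "sd")] = pivot.std(axis=0, ddof=1)
    summary = pd.DataFrame(agg).loc[model_order]
    summary.columns = pd.MultiIndex.from_tuples(summary.columns)

    p_rows = []
    if STACKED in present:
        stacked = per_repeat[per_repeat["model"] == STACKED].sort_values("repeat")
        for model in model_order[1:]:
            other = per_repeat[per_repeat["model"] == model].sort_values("repeat")
            entry = {"model": model}
            for metric in METRICS:
                entry[metric] = paired_significance(
                    stacked[metric].to_numpy(),
                    other[metric].to_numpy(),
                    method=significance_method,
                )
            p_rows.append(entry)
    p_values = (
        pd.DataFrame(p_rows).set_index("model")
        if p_rows
        else pd.DataFrame(columns=list(METRICS))
    )
    return MetricsReport(per_repeat=per_repeat, summary=summary, p_values=p_values)


def ncr_comparison(
    cohort: CohortTable,
    n_repeats: int = 10,
    master_seed: int = 0,
    significance_method: str = "t",
    **pipeline_kwargs,
) -> pd.DataFrame:
    """Candidate metrics with and without NCR on the same repeated splits.

    Returns one row per candidate with before/after mean ± sd for AUC and
    sensitivity and the paired p-value per metric — the layout used to judge
    whether under-sampling helps each learner. Runs the candidate pipeline
    twice per repeat (stacking skipped), so it costs roughly twice a plain
    repeated run.
    """
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    pipeline_kwargs.pop("balancer", None)
    pipeline_kwargs.pop("include_stack", None)
    records: dict[str, dict[str, list[float]]] = {}
    for r in range(n_repeats):
        seed = derive_seed(master_seed, "repeat", r)
        for balancer in ("none", "ncr"):
            result = run_single_split(
                cohort,
                seed=seed,
                balancer=balancer,
                include_stack=False,
                **pipeline_kwargs,
            )
            for model, m in result["metrics"].items():
                store = records.setdefault(model, {})
                for metric in ("auc", "sensitivity"):
                    store.setdefault(f"{metric}_{balancer}", []).append(m[metric])
    rows = []
    for model, store in records.items():
        row: dict[str, object] = {"model": model}
        for metric in ("auc", "sensitivity"):
            before = np.asarray(store[f"{metric}_none"])
            after = np.asarray(store[f"{metric}_ncr"])
            row[f"{metric}_before_mean"] = before.mean()
            row[f"{metric}_before_sd"] = before.std(ddof=1)
            row[f"{metric}_after_mean"] = after.mean()
            row[f"{metric}_after_sd"] = after.std(ddof=1)
            row[f"{metric}_p_value"] = paired_significance(
                before, after, method=significance_method
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("model")
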
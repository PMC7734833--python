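"""Preprocessing: from raw cohort table to train/test design matrices.

The canonical order is::

    aggregate repeated labs -> drop high-missing columns -> bucket sparse
    ranged columns -> stratified 8:2 split -> impute (fit on train) ->
    one-hot encode -> z-score normalize (fit on train)

Splitting precedes imputation and normalization so that no statistic fitted
on test rows ever touches the training pipeline; missing-rate filtering and
bucketing use whole-table missing rates because they describe measurement
availability, not the label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import (
    CATEGORICAL,
    CONTINUOUS,
    REPEATED_LAB,
    CohortTable,
    ColumnInfo,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DesignMatrix",
    "SplitPlan",
    "aggregate_repeated_measurements",
    "filter_by_missing_rate",
    "bucket_high_missing_features",
    "impute",
    "one_hot_encode",
    "normalize",
    "stratified_split_indices",
    "stratified_split",
    "preprocess_cohort",
]

UNKNOWN = "unknown"


@dataclass
class DesignMatrix:
    """Fully numeric encoded feature matrix with provenance.

    ``column_map`` maps every encoded column name to ``(raw feature name,
    tag)`` where the tag is a one-hot category or an aggregate label
    (``median``/``min``/``max``) or ``"continuous"``. ``normalization_params``
    holds the per-column mean and population standard deviation fitted on the
    training rows once :func:`normalize` has run.
    """

    values: np.ndarray
    column_names: list[str]
    column_map: dict[str, tuple[str, str]]
    labels: np.ndarray
    normalization_params: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.shape[0] != self.labels.shape[0]:
            raise ValueError("labels length must equal row count")
        if self.values.shape[1] != len(self.column_names):
            raise ValueError("column_names length must equal column count")
        missing = set(self.column_names) - set(self.column_map)
        if missing:
            raise ValueError(f"column_map misses columns: {sorted(missing)}")
        if np.isnan(self.values).any():
            raise ValueError("design matrix must not contain missing values")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    def column_index(self, names: list[str]) -> np.ndarray:
        pos = {c: i for i, c in enumerate(self.column_names)}
        return np.array([pos[n] for n in names], dtype=int)

    def restrict_columns(self, names: list[str]) -> np.ndarray:
        return self.values[:, self.column_index(names)]

    def subset_rows(self, index: np.ndarray) -> "DesignMatrix":
        return DesignMatrix(
            self.values[index],
            list(self.column_names),
            dict(self.column_map),
            self.labels[index],
            self.normalization_params,
        )

    def column_map_frame(self) -> pd.DataFrame:
        """Sidecar table (encoded_name, raw_name, tag) for serialization."""
        return pd.DataFrame(
            [(c, *self.column_map[c]) for c in self.column_names],
            columns=["encoded_name", "raw_name", "tag"],
        )


@dataclass(frozen=True)
class SplitPlan:
    """Stratified train/test split plan (default 8:2)."""

    train_fraction: float = 0.8
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must lie in (0, 1)")
        if not self.stratified:
            raise ValueError("only stratified splitting is supported")


def aggregate_repeated_measurements(table: CohortTable) -> CohortTable:
    """Replace each repeated-lab column by median/min/max summary columns.

    Repeated measurements of the same laboratory test during one admission are
    collapsed into three continuous features capturing the trend of change.
    All-missing cells stay missing in all three derived columns.
    """
    data = {}
    columns: dict[str, ColumnInfo] = {}
    for col in table.data.columns:
        info = table.columns[col]
        if info.kind != REPEATED_LAB:
            data[col] = table.data[col]
            columns[col] = info
            continue
        med, lo, hi = [], [], []
        for cell in table.data[col]:
            if isinstance(cell, (list, tuple, np.ndarray)) and len(cell) > 0:
                arr = np.asarray(cell, dtype=float)
                med.append(float(np.median(arr)))
                lo.append(float(np.min(arr)))
                hi.append(float(np.max(arr)))
            else:
                med.append(np.nan)
                lo.append(np.nan)
                hi.append(np.nan)
        for tag, vals in (("median", med), ("min", lo), ("max", hi)):
            name = f"{col}_{tag}"
            data[name] = vals
            columns[name] = ColumnInfo(
                CONTINUOUS,
                normal_range=info.normal_range,
                informative=info.informative,
            )
    frame = pd.DataFrame(data, index=table.data.index)
    return CohortTable(frame, columns, table.label)


def filter_by_missing_rate(
    table: CohortTable, threshold: float = 0.20, exempt_ranged: bool = True
) -> tuple[CohortTable, list[str]]:
    """Drop columns whose missing fraction strictly exceeds ``threshold``.

    Returns the filtered table and the names of dropped columns. A column at
    exactly the threshold is retained. Columns that declare a clinical normal
    range are exempt by default: they are clinically important despite sparse
    measurement and are handled downstream by
    :func:`bucket_high_missing_features` instead of being eliminated.
    """
    if not (0 <= threshold <= 1):
        raise ValueError("threshold must lie in [0, 1]")
    dropped = [
        c
        for c in table.data.columns
        if table.missing_fraction(c) > threshold
        and not (exempt_ranged and table.columns[c].normal_range is not None)
    ]
    if dropped:
        logger.info("missing-rate filter dropped %d columns", len(dropped))
    kept = [c for c in table.data.columns if c not in set(dropped)]
    frame = table.data[kept]
    columns = {c: table.columns[c] for c in kept}
    return CohortTable(frame, columns, table.label), dropped


def bucket_high_missing_features(
    table: CohortTable, threshold: float = 0.30
) -> CohortTable:
    """Convert sparse ranged continuous columns to 3-level categoricals.

    Columns with missing fraction > ``threshold`` and a declared normal range
    become categorical: in-range values map to ``"normal"``, out-of-range to
    ``"abnormalities"``, missing to ``"unknown"``. Keeps clinically important
    but sparsely measured features (e.g. ultrasonic measurements) that a plain
    missing-rate filter would discard.
    """
    data = {}
    columns: dict[str, ColumnInfo] = {}
    for col in table.data.columns:
        info = table.columns[col]
        flagged = (
            info.kind == CONTINUOUS and table.missing_fraction(col) > threshold
        )
        if not flagged:
            data[col] = table.data[col]
            columns[col] = info
            continue
        if info.normal_range is None:
            raise ValueError(
                f"column {col!r} exceeds the bucketing threshold but declares "
                "no normal range"
            )
        lo, hi = info.normal_range
        vals = table.data[col]
        bucketed = np.where(
            vals.isna(),
            UNKNOWN,
            np.where((vals >= lo) & (vals <= hi), "normal", "abnormalities"),
        )
        data[col] = bucketed
        columns[col] = ColumnInfo(CATEGORICAL, informative=info.informative)
    return CohortTable(pd.DataFrame(data, index=table.data.index), columns, table.label)


def impute(table: CohortTable, fit_on: np.ndarray) -> CohortTable:
    """Fill remaining missing cells.

    Categorical gaps become the literal category ``"unknown"``; continuous
    gaps become the mean of the feature over the ``fit_on`` (training) rows
    only, so test-row values never leak into training statistics.
    """
    fit_on = np.asarray(fit_on, dtype=int)
    data = {}
    for col in table.data.columns:
        info = table.columns[col]
        series = table.data[col]
        if info.kind == CATEGORICAL:
            data[col] = series.where(series.notna(), UNKNOWN)
        elif info.kind == CONTINUOUS:
            train_vals = series.iloc[fit_on]
            if series.isna().any():
                if train_vals.isna().all():
                    raise ValueError(
                        f"continuous column {col!r} is entirely missing in the "
                        "fitting rows; cannot impute"
                    )
                data[col] = series.fillna(float(train_vals.mean()))
            else:
                data[col] = series
        else:
            raise ValueError(
                f"repeated-lab column {col!r} must be aggregated before imputation"
            )
    return CohortTable(pd.DataFrame(data, index=table.data.index), table.columns, table.label)


def one_hot_encode(table: CohortTable) -> DesignMatrix:
    """Encode categoricals as one-hot vectors; continuous columns pass through.

    A categorical feature with n observed categories yields n binary columns
    (exactly one of which is 1 per row). Levels are those observed in the
    given table, so encoding the full table before any row split guarantees a
    shared train/test column space.
    """
    blocks: list[np.ndarray] = []
    names: list[str] = []
    column_map: dict[str, tuple[str, str]] = {}
    for col in table.data.columns:
        info = table.columns[col]
        if info.kind == CONTINUOUS:
            vals = table.data[col].to_numpy(dtype=float)
            if np.isnan(vals).any():
                raise ValueError(f"continuous column {col!r} still has missing cells")
            blocks.append(vals[:, None])
            names.append(col)
            column_map[col] = (col, "continuous")
        elif info.kind == CATEGORICAL:
            series = table.data[col].astype(str)
            levels = sorted(series.unique())
            onehot = (series.to_numpy()[:, None] == np.array(levels)[None, :]).astype(float)
            blocks.append(onehot)
            for lv in levels:
                name = f"{col}={lv}"
                names.append(name)
                column_map[name] = (col, lv)
        else:
            raise ValueError(f"repeated-lab column {col!r} must be aggregated first")
    values = np.hstack(blocks) if blocks else np.empty((table.n_rows, 0))
    return DesignMatrix(values, names, column_map, table.label.to_numpy())


def normalize(matrix: DesignMatrix, fit_on: np.ndarray) -> DesignMatrix:
    """Z-score every column: x* = (x - mean) / sigma.

    Mean and population standard deviation are computed on the ``fit_on``
    (training) rows and applied to all rows; the parameters are stored on the
    returned matrix. Zero-variance columns map to all zeros.
    """
    fit_on = np.asarray(fit_on, dtype=int)
    if fit_on.size == 0:
        raise ValueError("fit_on must identify at least one row")
    means = matrix.values[fit_on].mean(axis=0)
    sigmas = matrix.values[fit_on].std(axis=0)  # population sigma (ddof=0)
    safe = np.where(sigmas > 0, sigmas, 1.0)
    transformed = (matrix.values - means) / safe
    transformed[:, sigmas == 0] = 0.0
    return DesignMatrix(
        transformed,
        list(matrix.column_names),
        dict(matrix.column_map),
        matrix.labels,
        normalization_params=(means, sigmas),
    )


def stratified_split_indices(
    labels: np.ndarray, plan: SplitPlan
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class allocation: floor(class_count * train_fraction) rows to
    train, the remainder to test. Deterministic for a fixed seed."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present to split")
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 members to split")
    rng = np.random.default_rng(plan.seed)
    train_parts, test_parts = [], []
    for cls in classes:
        idx = np.where(labels == cls)[0]
        perm = rng.permutation(idx)
        n_train = int(np.floor(len(idx) * plan.train_fraction))
        train_parts.append(perm[:n_train])
        test_parts.append(perm[n_train:])
    train = np.sort(np.concatenate(train_parts))
    test = np.sort(np.concatenate(test_parts))
    return train, test


def stratified_split(
    matrix: DesignMatrix, plan: SplitPlan
) -> tuple[DesignMatrix, DesignMatrix]:
    """Split an encoded matrix into stratified train/test row subsets."""
    train_idx, test_idx = stratified_split_indices(matrix.labels, plan)
    return matrix.subset_rows(train_idx), matrix.subset_rows(test_idx)


def preprocess_cohort(
    table: CohortTable,
    plan: SplitPlan,
    missing_filter_threshold: float = 0.20,
    bucket_threshold: float = 0.30,
) -> tuple[DesignMatrix, DesignMatrix, list[str]]:
    """Run the full preprocessing chain and return (train, test, dropped).

    Order: aggregate -> filter -> bucket -> split -> impute(fit on train) ->
    encode -> normalize(fit on train). One-hot levels come from the full
    table (pre-split) so train and test share a column space.
    """
    if table.feature_names(REPEATED_LAB):
        table = aggregate_repeated_measurements(table)
    table, dropped = filter_by_missing_rate(table, missing_filter_threshold)
    table = bucket_high_missing_features(table, bucket_threshold)
    train_idx, test_idx = stratified_split_indices(table.label.to_numpy(), plan)
    table = impute(table, fit_on=train_idx)
    matrix = one_hot_encode(table)
    matrix = normalize(matrix, fit_on=train_idx)
    return matrix.subset_rows(train_idx), matrix.subset_rows(test_idx), dropped
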
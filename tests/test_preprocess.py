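"""Preprocessing: aggregation, filtering, bucketing, imputation, encoding,
normalization and the stratified split."""

import numpy as np
import pandas as pd
import pytest

from readmit_stack import (
    DesignMatrix,
    SplitPlan,
    aggregate_repeated_measurements,
    bucket_high_missing_features,
    filter_by_missing_rate,
    impute,
    normalize,
    one_hot_encode,
    preprocess_cohort,
    stratified_split,
    stratified_split_indices,
)
from readmit_stack.cohort import (
    CATEGORICAL,
    CONTINUOUS,
    REPEATED_LAB,
    CohortTable,
    ColumnInfo,
)


def table_of(data: dict, kinds: dict, label, ranges: dict | None = None):
    ranges = ranges or {}
    cols = {
        name: ColumnInfo(kinds[name], normal_range=ranges.get(name))
        for name in data
    }
    return CohortTable(pd.DataFrame(data), cols, label)


def balanced_label(n):
    return [1, 0] * (n // 2) + [1] * (n % 2)


class TestAggregation:
    def test_median_min_max(self):
        t = table_of(
            {"lab": [[3.1, 2.9, 3.5], [4.0], np.nan, [1.0, 2.0]]},
            {"lab": REPEATED_LAB},
            [1, 0, 1, 0],
        )
        out = aggregate_repeated_measurements(t)
        assert list(out.data.columns) == ["lab_median", "lab_min", "lab_max"]
        assert out.data.loc[0].tolist() == [3.1, 2.9, 3.5]
        # single measurement: median = min = max
        assert out.data.loc[1].tolist() == [4.0, 4.0, 4.0]
        # all-missing cell stays missing in all three
        assert out.data.loc[2].isna().all()
        assert out.columns["lab_median"].kind == CONTINUOUS

    def test_non_lab_columns_pass_through(self):
        t = table_of(
            {"age": [60.0, 70.0, 65.0, 80.0], "lab": [[1.0]] * 4},
            {"age": CONTINUOUS, "lab": REPEATED_LAB},
            [1, 0, 1, 0],
        )
        out = aggregate_repeated_measurements(t)
        assert out.data["age"].tolist() == [60.0, 70.0, 65.0, 80.0]

    def test_three_aggregates_per_lab(self):
        n_labs = 4
        t = table_of(
            {f"lab{i}": [[1.0], [2.0], [3.0], [4.0]] for i in range(n_labs)},
            {f"lab{i}": REPEATED_LAB for i in range(n_labs)},
            [1, 0, 1, 0],
        )
        assert aggregate_repeated_measurements(t).data.shape[1] == 3 * n_labs


class TestMissingRateFilter:
    def test_drops_strictly_above_threshold(self):
        vals = [1.0, np.nan] + [2.0] * 2  # 25% missing
        t = table_of({"x": vals, "y": [1.0] * 4}, {"x": CONTINUOUS, "y": CONTINUOUS}, [1, 0, 1, 0])
        out, dropped = filter_by_missing_rate(t, 0.20)
        assert dropped == ["x"]
        assert list(out.data.columns) == ["y"]

    def test_threshold_one_keeps_everything(self):
        t = table_of({"x": [np.nan] * 3 + [1.0]}, {"x": CONTINUOUS}, [1, 0, 1, 0])
        out, dropped = filter_by_missing_rate(t, 1.0)
        assert dropped == []

    def test_exactly_at_threshold_is_retained(self):
        # 2 of 10 missing = 0.20, not > 0.20
        vals = [np.nan, np.nan] + list(range(8))
        t = table_of({"x": vals}, {"x": CONTINUOUS}, balanced_label(10))
        out, dropped = filter_by_missing_rate(t, 0.20)
        assert dropped == []

    def test_ranged_columns_exempt_by_default(self):
        vals = [np.nan] * 3 + [1.0]
        t = table_of(
            {"us": vals}, {"us": CONTINUOUS}, [1, 0, 1, 0], ranges={"us": (0, 2)}
        )
        _, dropped = filter_by_missing_rate(t, 0.20)
        assert dropped == []
        _, dropped = filter_by_missing_rate(t, 0.20, exempt_ranged=False)
        assert dropped == ["us"]


class TestBucketing:
    def make(self, vals, rng=(-1.0, 1.0)):
        return table_of(
            {"us": vals}, {"us": CONTINUOUS}, balanced_label(len(vals)), ranges={"us": rng}
        )

    def test_buckets_sparse_ranged_column(self):
        vals = [0.5, 2.0, np.nan, np.nan, 0.0, np.nan]
        out = bucket_high_missing_features(self.make(vals), 0.30)
        assert out.columns["us"].kind == CATEGORICAL
        assert out.data["us"].tolist() == [
            "normal", "abnormalities", "unknown", "unknown", "normal", "unknown",
        ]

    def test_low_missing_column_untouched(self):
        vals = [0.5, 2.0, np.nan, 0.1, 0.0, 0.3, 0.2, 0.4, 0.6, 0.7]  # 10% missing
        out = bucket_high_missing_features(self.make(vals), 0.30)
        assert out.columns["us"].kind == CONTINUOUS

    def test_missing_normal_range_is_an_error(self):
        vals = [np.nan, np.nan, np.nan, 1.0]
        t = table_of({"x": vals}, {"x": CONTINUOUS}, [1, 0, 1, 0])
        with pytest.raises(ValueError, match="normal range"):
            bucket_high_missing_features(t, 0.30)


class TestImpute:
    def test_categorical_gap_becomes_unknown(self):
        t = table_of({"c": ["a", None, "b", "a"]}, {"c": CATEGORICAL}, [1, 0, 1, 0])
        out = impute(t, fit_on=np.arange(4))
        assert out.data["c"].tolist() == ["a", "unknown", "b", "a"]

    def test_continuous_mean_from_training_rows_only(self):
        # train rows hold 2 and 4 -> the gap (a test row) becomes 3.0, not the
        # whole-column mean
        t = table_of({"x": [2.0, 4.0, np.nan, 10.0]}, {"x": CONTINUOUS}, [1, 0, 1, 0])
        out = impute(t, fit_on=np.array([0, 1]))
        assert out.data["x"].tolist() == [2.0, 4.0, 3.0, 10.0]

    def test_no_gaps_is_identity(self):
        t = table_of({"x": [1.0, 2.0, 3.0, 4.0]}, {"x": CONTINUOUS}, [1, 0, 1, 0])
        out = impute(t, fit_on=np.arange(4))
        pd.testing.assert_frame_equal(out.data, t.data)

    def test_all_missing_in_training_rows_raises(self):
        t = table_of({"x": [np.nan, np.nan, 1.0, 2.0]}, {"x": CONTINUOUS}, [1, 0, 1, 0])
        with pytest.raises(ValueError, match="'x'"):
            impute(t, fit_on=np.array([0, 1]))


class TestOneHot:
    def test_three_level_identity_pattern(self):
        t = table_of({"c": ["L0", "L1", "L2", "L1"]}, {"c": CATEGORICAL}, [1, 0, 1, 0])
        dm = one_hot_encode(t)
        assert dm.column_names == ["c=L0", "c=L1", "c=L2"]
        np.testing.assert_array_equal(dm.values[1], [0, 1, 0])

    def test_single_level_gives_all_ones(self):
        t = table_of({"c": ["only"] * 4}, {"c": CATEGORICAL}, [1, 0, 1, 0])
        dm = one_hot_encode(t)
        np.testing.assert_array_equal(dm.values[:, 0], 1.0)

    def test_column_count_and_map(self):
        t = table_of(
            {
                "a": ["x", "y", "z", "x"],
                "b": ["p", "q", "p", "q"],
                "v": [1.0, 2.0, 3.0, 4.0],
            },
            {"a": CATEGORICAL, "b": CATEGORICAL, "v": CONTINUOUS},
            [1, 0, 1, 0],
        )
        dm = one_hot_encode(t)
        assert dm.n_columns == 3 + 2 + 1
        assert dm.column_map["a=x"] == ("a", "x")
        assert dm.column_map["v"] == ("v", "continuous")

    def test_per_feature_row_sums_equal_one(self):
        rng = np.random.default_rng(3)
        t = table_of(
            {"c": rng.choice(list("abcd"), 40).tolist()},
            {"c": CATEGORICAL},
            balanced_label(40),
        )
        dm = one_hot_encode(t)
        np.testing.assert_allclose(dm.values.sum(axis=1), 1.0)


class TestNormalize:
    def dm(self, col):
        col = np.asarray(col, dtype=float)
        return DesignMatrix(
            col[:, None], ["x"], {"x": ("x", "continuous")}, balanced_label(len(col))
        )

    def test_hand_computed_z_scores(self):
        out = normalize(self.dm([1, 2, 3]), fit_on=np.arange(3))
        np.testing.assert_allclose(
            out.values[:, 0], [-1.224745, 0.0, 1.224745], atol=1e-6
        )

    def test_constant_column_maps_to_zeros(self):
        out = normalize(self.dm([5, 5, 5, 5]), fit_on=np.arange(4))
        np.testing.assert_array_equal(out.values[:, 0], 0.0)

    def test_idempotent_on_fitted_rows(self):
        once = normalize(self.dm([1.0, 4.0, -2.0, 7.0]), fit_on=np.arange(4))
        twice = normalize(once, fit_on=np.arange(4))
        np.testing.assert_allclose(once.values, twice.values, atol=1e-12)

    def test_fitted_moments_are_zero_one(self):
        rng = np.random.default_rng(11)
        X = rng.normal(3.0, 2.5, size=(60, 4))
        dm = DesignMatrix(
            X,
            [f"c{i}" for i in range(4)],
            {f"c{i}": (f"c{i}", "continuous") for i in range(4)},
            balanced_label(60),
        )
        fit_rows = np.arange(45)
        out = normalize(dm, fit_on=fit_rows)
        fitted = out.values[fit_rows]
        np.testing.assert_allclose(fitted.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(fitted.var(axis=0), 1.0, atol=1e-9)

    def test_empty_fit_rows_rejected(self):
        with pytest.raises(ValueError, match="fit_on"):
            normalize(self.dm([1, 2, 3]), fit_on=np.array([], dtype=int))


class TestStratifiedSplit:
    def test_study_scale_allocation(self):
        # 3283 rows, 425 positive, train fraction 0.8: per-class floor gives a
        # 2626/657 split with 2286 majority rows in training.
        labels = np.array([1] * 425 + [0] * 2858)
        train, test = stratified_split_indices(labels, SplitPlan(0.8, seed=1))
        assert len(train) == 2626
        assert len(test) == 657
        assert int((labels[train] == 0).sum()) == 2286
        assert int((labels[train] == 1).sum()) == 340

    def test_small_balanced_allocation(self):
        labels = np.array([1, 0] * 5)
        train, test = stratified_split_indices(labels, SplitPlan(0.8, seed=0))
        assert len(train) == 8
        assert int(labels[train].sum()) == 4

    def test_partition_is_disjoint_and_exhaustive(self):
        rng = np.random.default_rng(2)
        labels = (rng.random(137) < 0.2).astype(int)
        labels[:2] = 1  # ensure both classes
        train, test = stratified_split_indices(labels, SplitPlan(0.8, seed=9))
        combined = np.sort(np.concatenate([train, test]))
        np.testing.assert_array_equal(combined, np.arange(137))

    def test_deterministic_for_fixed_seed(self):
        labels = np.array([1, 0] * 20)
        a = stratified_split_indices(labels, SplitPlan(0.8, seed=5))
        b = stratified_split_indices(labels, SplitPlan(0.8, seed=5))
        np.testing.assert_array_equal(a[0], b[0])

    def test_tiny_class_rejected(self):
        labels = np.array([1] + [0] * 9)
        with pytest.raises(ValueError, match="at least 2"):
            stratified_split_indices(labels, SplitPlan(0.8, seed=0))

    def test_matrix_split_matches_indices(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 2))
        labels = np.array([1, 0, 0] * 10)
        dm = DesignMatrix(
            X, ["a", "b"], {"a": ("a", "continuous"), "b": ("b", "continuous")}, labels
        )
        train, test = stratified_split(dm, SplitPlan(0.8, seed=3))
        assert train.n_rows + test.n_rows == 30
        idx_train, _ = stratified_split_indices(labels, SplitPlan(0.8, seed=3))
        np.testing.assert_allclose(train.values, X[idx_train])


class TestFullChain:
    def test_pipeline_produces_clean_matrices(self, small_cohort):
        train, test, dropped = preprocess_cohort(small_cohort, SplitPlan(0.8, seed=7))
        assert train.n_rows + test.n_rows == small_cohort.n_rows
        assert train.n_columns == test.n_columns
        assert not np.isnan(train.values).any()
        assert not np.isnan(test.values).any()
        # shared column space and recorded normalization parameters
        assert train.column_names == test.column_names
        assert train.normalization_params is not None
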
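"""Three-layer stacking: adaptive base selection, out-of-fold schedules,
layer-2 input wiring and the logistic meta-layer."""

import numpy as np
import pytest

from readmit_stack import (
    CohortSpec,
    FeatureSubset,
    LabeledDataset,
    SplitPlan,
    build_layer2_inputs,
    candidate_model_zoo,
    fit_stacked_model,
    generate_cohort,
    kfold_stack_predictions,
    make_toy_fixture,
    ncr_undersample,
    one_hot_encode,
    preprocess_cohort,
    rank_candidates,
    select_features_for_model,
    select_top_k,
)
from readmit_stack.stacking import StackPredictions

from conftest import FAST_OVERRIDES, labeled_dataset


class EchoFirstFeature:
    """Stub classifier predicting its first input feature (clipped to [0,1]).

    Training-independent, so out-of-fold assembly must reproduce the feature
    column exactly — any row-index permutation bug becomes visible.
    """

    name = "Echo"
    selected_subset = None

    def build(self):
        return self

    def fit(self, X, y):
        return self

    def predict_proba(self, X):
        p = np.clip(X[:, 0], 0.0, 1.0)
        return np.column_stack([1 - p, p])


class ConstantProb:
    name = "Const"

    def __init__(self, c):
        self.c = c

    def build(self):
        return self

    def fit(self, X, y):
        return self

    def predict_proba(self, X):
        p = np.full(len(X), self.c)
        return np.column_stack([1 - p, p])


def tiny_train_test():
    from readmit_stack import DesignMatrix

    table = make_toy_fixture("tiny-stack")
    X = table.data.to_numpy()
    y = table.label.to_numpy()
    names = list(table.data.columns)
    cmap = {n: (n, "continuous") for n in names}
    train = LabeledDataset.from_matrix(DesignMatrix(X, names, cmap, y))
    test = DesignMatrix(X[::-1] * 0.9, names, cmap, y[::-1])
    return train, test


class TestTopKSelection:
    def test_top3_by_value(self):
        aucs = [0.70, 0.71, 0.66, 0.709, 0.702, 0.68, 0.705, 0.706]
        names = [f"M{i}" for i in range(1, 9)]
        assert select_top_k(names, aucs, 3) == ["M2", "M4", "M8"]

    def test_exactly_three_candidates_all_selected(self):
        assert select_top_k(["a", "b", "c"], [0.5, 0.4, 0.3], 3) == ["a", "b", "c"]

    def test_tie_keeps_zoo_order(self):
        assert select_top_k(["a", "b", "c", "d"], [0.7, 0.8, 0.8, 0.8], 3) == [
            "b",
            "c",
            "d",
        ]


class TestRankCandidates:
    def test_subset_intersection(self):
        train, _ = tiny_train_test()
        specs = []
        for name, cols in [
            ("DT", ["a", "b", "c"]),
            ("RF", ["b", "c", "d"]),
            ("ET", ["b", "c"]),
        ]:
            spec = next(s for s in candidate_model_zoo(FAST_OVERRIDES) if s.name == name)
            specs.append(spec.with_subset(FeatureSubset(f"f_{name}", cols)))
        bases = rank_candidates(train, specs, folds=4, seed=0)
        assert len(bases.members) == 3
        assert bases.intersection.columns == ["b", "c"]

    def test_fewer_than_three_candidates_rejected(self):
        train, _ = tiny_train_test()
        spec = candidate_model_zoo(FAST_OVERRIDES)[0].with_subset(
            FeatureSubset("f", ["a"])
        )
        with pytest.raises(ValueError, match="three"):
            rank_candidates(train, [spec, spec], folds=4)

    def test_missing_subset_rejected(self):
        train, _ = tiny_train_test()
        specs = candidate_model_zoo(FAST_OVERRIDES)[:3]
        with pytest.raises(ValueError, match="subset"):
            rank_candidates(train, specs, folds=4)


class TestKFoldStackPredictions:
    def test_constant_classifier_gives_constant_columns(self):
        train, test = tiny_train_test()
        preds = kfold_stack_predictions(
            ConstantProb(0.4), train.X, train.y, test.values, folds=5, seed=0
        )
        np.testing.assert_allclose(preds.train_column, 0.4)
        np.testing.assert_allclose(preds.test_column, 0.4)

    def test_out_of_fold_assembly_preserves_row_order(self):
        train, test = tiny_train_test()
        Xtr = np.abs(train.X) / 10.0  # distinct values in [0,1] per row
        preds = kfold_stack_predictions(
            EchoFirstFeature(), Xtr, train.y, test.values, folds=5, seed=3
        )
        np.testing.assert_allclose(preds.train_column, Xtr[:, 0])
        np.testing.assert_allclose(
            preds.test_column, np.clip(test.values[:, 0], 0, 1)
        )

    def test_every_row_held_out_exactly_once(self):
        train, test = tiny_train_test()

        held = []

        class Recorder(ConstantProb):
            def __init__(self):
                super().__init__(0.5)
                self.train_rows = None

            def fit(self, X, y):
                self.train_rows = len(X)
                return self

            def predict_proba(self, X):
                if len(X) != 20:  # held-out folds, not the 20-row test set
                    held.append(len(X))
                return super().predict_proba(X)

        kfold_stack_predictions(
            Recorder(), train.X, train.y, test.values, folds=5, seed=1
        )
        assert sum(held) == train.n_rows
        assert len(held) == 5

    def test_fold_schedule_deterministic(self):
        train, test = tiny_train_test()
        model = next(s for s in candidate_model_zoo(FAST_OVERRIDES) if s.name == "RF")
        a = kfold_stack_predictions(model, train.X, train.y, test.values, seed=9)
        b = kfold_stack_predictions(model, train.X, train.y, test.values, seed=9)
        np.testing.assert_array_equal(a.train_column, b.train_column)
        np.testing.assert_array_equal(a.test_column, b.test_column)


class TestLayer2Inputs:
    def make_layer1(self, train, test):
        return {
            name: StackPredictions(
                source=name,
                layer=1,
                train_column=np.full(train.n_rows, c),
                test_column=np.full(test.n_rows, c),
            )
            for name, c in [("DT", 0.2), ("RF", 0.5), ("ET", 0.8)]
        }

    def test_width_is_one_plus_intersection(self):
        train, test = tiny_train_test()
        layer1 = self.make_layer1(train, test)
        f_in = FeatureSubset("f_in", ["a", "b"])
        inputs = build_layer2_inputs(layer1, f_in, train, test)
        for name, (X2tr, X2te) in inputs.items():
            assert X2tr.shape == (train.n_rows, 3)
            assert X2te.shape == (test.n_rows, 3)

    def test_each_classifier_sees_only_its_own_column(self):
        train, test = tiny_train_test()
        layer1 = self.make_layer1(train, test)
        inputs = build_layer2_inputs(layer1, FeatureSubset("f_in", ["a"]), train, test)
        np.testing.assert_allclose(inputs["DT"][0][:, 0], 0.2)
        np.testing.assert_allclose(inputs["RF"][0][:, 0], 0.5)
        np.testing.assert_allclose(inputs["ET"][0][:, 0], 0.8)

    def test_empty_intersection_warns_and_degrades_to_width_one(self):
        train, test = tiny_train_test()
        layer1 = self.make_layer1(train, test)
        with pytest.warns(UserWarning, match="f_in"):
            inputs = build_layer2_inputs(layer1, None, train, test)
        assert inputs["DT"][0].shape == (train.n_rows, 1)


class TestFitStackedModel:
    def prepared(self, seed=0):
        spec = CohortSpec(
            n_samples=300,
            minority_fraction=0.3,
            n_informative=4,
            n_noise_continuous=6,
            n_categorical=0,
            n_repeated_labs=0,
            n_bucketable=0,
            missingness=0.0,
            effect_size=3.0,
            seed=seed,
        )
        cohort = generate_cohort(spec)
        train_dm, test_dm, _ = preprocess_cohort(cohort, SplitPlan(0.8, seed=seed))
        train = LabeledDataset.from_matrix(train_dm)
        train, _ = ncr_undersample(train)
        specs = []
        for model in candidate_model_zoo(FAST_OVERRIDES)[:4]:
            subset = select_features_for_model(
                model, train, folds=5, seed=seed, max_subsets=6
            )
            specs.append(model.with_subset(subset))
        bases = rank_candidates(train, specs, folds=5, seed=seed)
        return train, test_dm, bases

    def test_meta_layer_uses_three_columns(self):
        train, test, bases = self.prepared()
        result = fit_stacked_model(train, test, bases, seed=1)
        assert result.meta_model.coef_.shape == (1, 3)
        assert len(result.layer1) == 3 and len(result.layer2) == 3

    def test_probabilities_bounded_and_strong_on_separable_data(self):
        from readmit_stack import auc

        train, test, bases = self.prepared()
        result = fit_stacked_model(train, test, bases, seed=1)
        assert np.all((result.test_probabilities >= 0) & (result.test_probabilities <= 1))
        assert auc(test.labels, result.test_probabilities) >= 0.9

    def test_test_labels_never_influence_fit(self):
        from readmit_stack import DesignMatrix

        train, test, bases = self.prepared()
        blinded = DesignMatrix(
            test.values,
            list(test.column_names),
            dict(test.column_map),
            np.zeros(test.n_rows, dtype=int),
        )
        a = fit_stacked_model(train, test, bases, seed=2)
        b = fit_stacked_model(train, blinded, bases, seed=2)
        np.testing.assert_array_equal(a.test_probabilities, b.test_probabilities)

    def test_meta_layer_close_to_layer2_average_on_separable_data(self):
        from readmit_stack import auc

        train, test, bases = self.prepared()
        result = fit_stacked_model(train, test, bases, seed=3)
        averaged = np.mean(
            [sp.test_column for sp in result.layer2.values()], axis=0
        )
        auc_meta = auc(test.labels, result.test_probabilities)
        auc_avg = auc(test.labels, averaged)
        assert abs(auc_meta - auc_avg) <= 0.05

    def test_reproducible_for_fixed_seed(self):
        train, test, bases = self.prepared()
        a = fit_stacked_model(train, test, bases, seed=5)
        b = fit_stacked_model(train, test, bases, seed=5)
        np.testing.assert_array_equal(a.test_probabilities, b.test_probabilities)
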
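import numpy as np
import pytest

from readmit_stack import (
    CohortSpec,
    DesignMatrix,
    LabeledDataset,
    generate_cohort,
)

# Slim ensemble sizes for tests of wiring, determinism and report structure,
# where the default estimator counts only add runtime. Tests of the selection
# and stacking behaviour itself use the default configurations.
FAST_OVERRIDES = {
    "DT": {"min_samples_split": 10, "min_samples_leaf": 2},
    "RF": {"n_estimators": 10},
    "ET": {"n_estimators": 10},
    "GBDT": {"n_estimators": 10},
    "ADB": {"n_estimators": 10},
    "Bagging": {"n_estimators": 10},
    "XGB": {"n_estimators": 20},
}


@pytest.fixture(scope="session")
def small_cohort():
    """A compact, strongly separable cohort exercising every column kind."""
    spec = CohortSpec(
        n_samples=200,
        minority_fraction=0.3,
        n_informative=4,
        n_noise_continuous=6,
        n_categorical=3,
        n_repeated_labs=2,
        n_bucketable=1,
        missingness=0.05,
        effect_size=3.0,
        seed=42,
    )
    return generate_cohort(spec)


def labeled_dataset(X, y) -> LabeledDataset:
    """Wrap plain arrays as a LabeledDataset for NCR/stacking tests."""
    X = np.asarray(X, dtype=float)
    names = [f"c{i}" for i in range(X.shape[1])]
    matrix = DesignMatrix(
        X, names, {n: (n, "continuous") for n in names}, np.asarray(y, dtype=int)
    )
    return LabeledDataset.from_matrix(matrix)
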
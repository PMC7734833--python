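"""Neighborhood cleaning rule on a hand-sized 2-D dataset.

One minority point at the origin has two tight majority neighbours and one
distant majority cluster; the minority rule deletes the majority points that
crowd it.
"""

from readmit_stack import (
    CohortSpec,
    LabeledDataset,
    SplitPlan,
    generate_cohort,
    make_toy_fixture,
    ncr_undersample,
    preprocess_cohort,
)
from readmit_stack.preprocess import DesignMatrix

table = make_toy_fixture("ncr-2d")
names = list(table.data.columns)
matrix = DesignMatrix(
    table.data.to_numpy(),
    names,
    {n: (n, "continuous") for n in names},
    table.label.to_numpy(),
)
dataset = LabeledDataset.from_matrix(matrix)
reduced, removed = ncr_undersample(dataset)
print("toy fixture:")
print(f"  before: {dataset.n_rows} rows, IR 1:{dataset.imbalance_ratio:.1f}")
print(f"  removed {removed} majority rows")
print(f"  after:  {reduced.n_rows} rows, IR 1:{reduced.imbalance_ratio:.1f}")

# On a realistic imbalanced cohort the rule trims boundary majority samples.
cohort = generate_cohort(
    CohortSpec(n_samples=600, minority_fraction=0.15, n_informative=4,
               n_noise_continuous=8, n_categorical=0, n_repeated_labs=0,
               n_bucketable=0, effect_size=1.0, seed=5)
)
train, _, _ = preprocess_cohort(cohort, SplitPlan(seed=2))
ds = LabeledDataset.from_matrix(train)
red, rem = ncr_undersample(ds)
print("synthetic cohort training set:")
print(f"  before: IR 1:{ds.imbalance_ratio:.2f}   after: IR 1:{red.imbalance_ratio:.2f} "
      f"({rem} majority rows removed; minority count unchanged)")
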
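"""Generate a synthetic readmission cohort and inspect its structure.

The generator emulates an imbalanced clinical table: a rare positive class
(30-day readmission), informative and noise features, repeated lab
measurements, and missingness.
"""

from readmit_stack import CohortSpec, generate_cohort

spec = CohortSpec(
    n_samples=500,
    minority_fraction=425 / 3283,  # the motivating cohort's imbalance
    n_informative=5,
    n_noise_continuous=10,
    n_categorical=4,
    n_repeated_labs=3,
    n_bucketable=2,
    missingness=0.08,
    effect_size=1.0,
    seed=7,
)
cohort = generate_cohort(spec)

print(f"rows: {cohort.n_rows}  (minority {cohort.n_minority}, "
      f"majority {cohort.n_majority})")
print(f"imbalance ratio: 1:{cohort.n_majority / cohort.n_minority:.2f}")
print(f"columns: {len(cohort.data.columns)}")
print(f"informative: {cohort.informative_features()}")
lab = cohort.feature_names("repeated_lab")[0]
print(f"example repeated-lab cell ({lab}): {cohort.data[lab].iloc[0]}")
frac = cohort.missing_fraction("sparse_00")
print(f"missing fraction of ranged column sparse_00: {frac:.2f}")
# The minority count is exact by construction; the repeated-lab cell holds
# 1-5 measurements that preprocessing will collapse to median/min/max.
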
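# Methods

## Problem setting

Thirty-day unplanned readmission is a rare outcome: in the motivating
single-centre cardiology setting roughly one admission in 7.7 is followed by
a readmission within 30 days. A classifier trained naively on such a table
concentrates on the majority class and yields near-zero sensitivity. The
package combines three counter-measures — under-sampling, per-model feature
selection, and stacked generalization with adaptive base-classifier choice —
behind a single reproducible protocol.

## Synthetic cohorts

Real admission-level tables are rarely shareable, so all tests and examples
run on generated cohorts. The generator (`readmit_stack.cohort`) emulates
the statistical structure the pipeline assumes, with defaults mirroring the
motivating study's scale: 3,283 admissions, minority fraction 425/3283,
293 analysis columns (10 informative continuous, 49 noise continuous, 6
sparsely measured ranged features, 60 categoricals, 56 repeated labs × 3
aggregates) expanding to 392 one-hot-encoded columns.

* **Informative continuous features** follow a two-class Gaussian
  mean-shift: class-conditional means differ by `effect_size` standard
  deviations (default 0.5 — chosen so that study-scale discrimination lands
  near the modest AUC ≈ 0.7 regime typical of readmission models rather
  than a trivially separable problem). Informative categoricals (optional)
  tilt level probabilities by class.
* **Repeated labs** draw 1–5 measurements per admission around a per-lab
  baseline, exercising the median/min/max aggregation path.
* **Missingness** is cell-wise Bernoulli per feature (default 5%; 35% for
  the ranged "ultrasonic-like" features so the bucketing path fires).
  Informative features stay complete so the label signal is not confounded
  with availability.

What the generator does **not** emulate: real ICD-code distributions, lab
reference ranges, correlations among clinical variables, informative
missingness, or temporal structure. Passing tests therefore demonstrate
that the machinery recovers planted signal under the stated noise model —
not that any particular clinical performance level transfers to real data.

Seeds: every random choice derives from one master seed through
`derive_seed(master, *tags)` (SHA-256 of the tag path, mod 2^31), so the
whole 10-repeat protocol is reproducible from a single integer and child
seeds never collide by construction of the tag paths.

## Preprocessing

Order: aggregate repeated labs → missing-rate filter → bucket ranged
columns → stratified split → impute → one-hot encode → normalize.

* The split happens before any statistic is fitted: imputation means and
  normalization parameters come from training rows only. Missing-rate
  filtering and bucketing use whole-table missing rates — they describe
  measurement availability, not the label.
* The filter drops columns strictly above 20% missing but exempts columns
  declaring a clinical normal range; those are instead bucketed to
  `normal`/`abnormalities`/`unknown` when above 30% missing. Without the
  exemption the bucketing stage would be unreachable (every >30% column is
  also >20%), and sparse-but-important measurements would be lost.
* Normalization uses the population standard deviation; zero-variance
  columns map to all zeros (no information, no division by zero).
  One-hot levels are those observed in the full table, so train and test
  share a column space and unseen-at-train levels cannot occur.
* Stratified allocation is per-class floor(count × fraction) to train,
  remainder to test — at study scale (425/2858, fraction 0.8) this yields
  exactly 2626 training rows (2286 majority) and 657 test rows.

## Neighborhood cleaning rule

Both deletion rules are evaluated against the *original* training set and
the union of marks is applied at once. The step-wise prose of the procedure
is otherwise order-ambiguous; mark-then-remove makes the result independent
of row iteration order. Distances are Euclidean on the normalized encoded
matrix (normalization makes the metric scale-free); neighbour ties break by
ascending row index for determinism. k is fixed at 3 by default and exposed
in config; for other k the majority rule fires on a strict neighbour
majority. A second pass could remove further rows; the pipeline applies
exactly one pass, before any cross-validation. The leakage this introduces
into CV estimates (fold models have seen the cleaned geometry) is inherent
to the design and documented rather than "fixed".

## Embedded feature selection

Inclusion at the threshold is `importance ≥ t` (not strictly greater) so the
top threshold yields a non-empty, trainable subset. Thresholds are the
distinct importance values, highest first, giving strictly nested subsets;
`max_subsets` optionally thins the thresholds evenly while always retaining
the smallest and the full subset. CV folds are drawn once per model and
shared across its subsets so subset scores are comparable; ties in mean AUC
prefer the smaller subset (parsimony). Selection operates on encoded
columns; an importance-free learner raises rather than being silently
scored, which is why the zoo contains only importance-bearing models.

Bagging exposes no aggregate importances in scikit-learn; the package
averages per-estimator tree importances after mapping each estimator's
feature slice (`estimators_features_`) back to the full column space.

## Candidate zoo and stacking

The eight candidates carry fixed hyperparameters (see
`readmit_stack.models._ZOO_PARAMS`); config can override any of them, and
unknown names or keys raise. Two consequences of the fixed configurations
worth knowing: the decision tree requires 300 samples to split a node and
therefore degenerates to a stump on small cohorts (this is faithful, not a
bug), and the linear SVM has no native probability — it is wrapped with a
one-dimensional logistic link fitted on the training rows' decision-function
values, preserving the margin ranking while emitting scores in [0, 1].

Meta-features are predicted probabilities, never hard labels (averaging
test-fold predictions is only meaningful for scores). Layer 1 and layer 2
use fresh stratified 5-fold partitions derived from the master seed with
distinct tags; the adaptive top-3 selection breaks ties by fixed zoo order.
An empty subset intersection f_in degrades layer-2 input to the single
prediction column with a warning. The meta-learner is scikit-learn's
logistic regression with its default L2 penalty; the strength `C` is
exposed (`meta_C`, default 1.0). No fitting step receives test labels; the
test-blindness is asserted behaviorally in the suite (replacing test labels
by zeros leaves every prediction bit-identical).

## Evaluation

Threshold metrics use a 0.5 probability cut-off (configurable); ratios with
zero denominators are NaN with a warning. AUC is the Mann–Whitney pairwise
probability with ties counting ½. Aggregates use the sample standard
deviation (ddof = 1), conventional for mean ± sd over repeats. Paired
significance defaults to the t-test on per-repeat differences with an exact
signed-rank alternative; identical vectors give p = 1.0 by convention. The
before/after under-sampling comparison (`ncr_comparison`) runs each
candidate with and without NCR on the same repeated splits and is opt-in
because it doubles runtime.

## Problem sizes in tests and the acceptance script

The suite exercises study-scale arithmetic (3,283 rows) where only counting
is involved, and compact cohorts (140–600 rows, ~12–30 encoded columns)
wherever models are fitted; signal-recovery checks use effect size 3.0 and
600 rows over ten seeded replicates. The acceptance script's repeated run
uses 800 admissions, the study's imbalance, effect size 0.8 and two
repeats. These sizes are the package's own choice of smallest cohorts that
still exercise every code path with stable statistics. Structural tests
(determinism, report shape) shrink the ensemble sizes via config overrides;
tests of selection and stacking behaviour keep the default configurations.

## Known limitations

* The generator's independence assumptions (features uncorrelated within
  class) make feature selection easier than on collinear clinical data.
* NCR is O(n²) in training rows via full pairwise distances — fine to a few
  thousand rows, not for much larger cohorts.
* With two repeats the reported sd is a rough scale indicator only; the
  protocol default of ten repeats is the intended operating point.
* The fixed candidate hyperparameters were tuned for a cohort of ~2,600
  training rows; on much smaller or larger tables some candidates (notably
  DT and SVM's C = 0.001) are far from their best configurations.
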
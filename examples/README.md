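# Examples

One narrative script per capability, each building a small synthetic input,
running one stage of the pipeline and printing what it computes:

| script | capability |
| --- | --- |
| `01_generate_cohort.py` | synthetic imbalanced cohort with labs and missingness |
| `02_preprocess.py` | aggregation, filtering, bucketing, split, impute, encode, normalize |
| `03_ncr_undersampling.py` | neighborhood cleaning rule on a hand-sized fixture and a cohort |
| `04_feature_selection.py` | importance-threshold traversal with 5-fold CV AUC |
| `05_stacked_model.py` | the full adaptive three-layer stack on one split (~1.5 min) |
| `06_repeated_protocol.py` | repeated-split evaluation, mean ± sd and paired tests (~3 min) |

Run any of them from this directory: `python 01_generate_cohort.py`.
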
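"""End-to-end pipeline runner: config in, artifacts on disk out.

Given a :class:`~readmit_stack.config.PipelineConfig`, this module acquires
the cohort (loading a CSV or generating a synthetic one), runs the repeated
evaluation protocol, and writes a self-contained artifact set:

* ``manifest.txt`` — flat key=value echo of the effective config and seeds;
  every number in every report is recomputable from this file alone.
* ``summary.csv`` / ``per_repeat.csv`` / ``p_values.csv`` — the model
  comparison (stacked model + eight candidates, mean ± sd over repeats).
* ``ncr_comparison.csv`` — optional before/after under-sampling table.
* ``selected_subsets.csv``, ``base_ranking.csv``, ``test_predictions.csv`` —
  feature subsets, candidate CV AUCs and final probabilities from a
  representative single split (repeat 0's seed).
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from ._seeds import derive_seed
from .cohort import CohortTable, generate_cohort
from .config import PipelineConfig
from .evaluate import ncr_comparison, repeated_protocol, run_single_split

logger = logging.getLogger(__name__)

__all__ = ["load_cohort", "run_pipeline"]


def load_cohort(config: PipelineConfig) -> CohortTable:
    if config.simulate is not None:
        logger.info("generating synthetic cohort (n=%d)", config.simulate.n_samples)
        return generate_cohort(config.simulate)
    path = Path(config.input_csv)
    if not path.exists():
        raise FileNotFoundError(f"input CSV not found: {path}")
    # Column metadata for external CSVs: everything numeric is continuous,
    # ';'-containing cells are repeated labs, the rest categorical.
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "label" not in raw.columns:
        raise ValueError(f"{path} has no 'label' column")
    from .cohort import CATEGORICAL, CONTINUOUS, REPEATED_LAB, ColumnInfo

    columns = {}
    for col in raw.columns:
        if col == "label":
            continue
        cells = raw[col][raw[col] != ""]
        if cells.str.contains(";").any():
            columns[col] = ColumnInfo(REPEATED_LAB)
        else:
            try:
                pd.to_numeric(cells)
                columns[col] = ColumnInfo(CONTINUOUS)
            except (ValueError, TypeError):
                columns[col] = ColumnInfo(CATEGORICAL)
    return CohortTable.from_csv(path, columns)


def _write_manifest(path: Path, config: PipelineConfig) -> None:
    lines = [f"{k}={v}" for k, v in config.manifest_items()]
    lines.append(f"repeat_seeds={[derive_seed(config.master_seed, 'repeat', r) for r in range(config.n_repeats)]}")
    path.write_text("\n".join(lines) + "\n")


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full protocol and write all artifacts; returns the
    output directory."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    cohort = load_cohort(config)
    logger.info(
        "cohort: %d rows (%d minority / %d majority)",
        cohort.n_rows,
        cohort.n_minority,
        cohort.n_majority,
    )
    _write_manifest(out / "manifest.txt", config)

    kwargs = config.pipeline_kwargs()
    report = repeated_protocol(
        cohort,
        n_repeats=config.n_repeats,
        master_seed=config.master_seed,
        significance_method=config.significance_method,
        **kwargs,
    )
    summary = report.summary.copy()
    summary.columns = [f"{m}_{s}" for m, s in summary.columns]
    summary.to_csv(out / "summary.csv")
    report.per_repeat.to_csv(out / "per_repeat.csv", index=False)
    report.p_values.to_csv(out / "p_values.csv")

    if config.compare_ncr:
        ncr_comparison(
            cohort,
            n_repeats=config.n_repeats,
            master_seed=config.master_seed,
            significance_method=config.significance_method,
            **{k: v for k, v in kwargs.items() if k != "balancer"},
        ).to_csv(out / "ncr_comparison.csv")

    # Representative single split (repeat 0) for inspectable artifacts.
    result = run_single_split(
        cohort, seed=derive_seed(config.master_seed, "repeat", 0), **kwargs
    )
    subset_rows = []
    for spec in result["specs"]:
        subset_rows.append(
            {
                "model": spec.name,
                "n_features": len(spec.selected_subset),
                "cv_auc": spec.selected_subset.cv_auc,
                "columns": "|".join(spec.selected_subset.columns),
            }
        )
    pd.DataFrame(subset_rows).to_csv(out / "selected_subsets.csv", index=False)

    bases = result["bases"]
    pd.DataFrame(
        sorted(bases.cv_aucs.items(), key=lambda kv: -kv[1]),
        columns=["model", "cv_auc"],
    ).assign(selected=lambda df: df["model"].isin([m.name for m in bases.members])).to_csv(
        out / "base_ranking.csv", index=False
    )
    stack = result["stack"]
    preds = pd.DataFrame({"probability": stack.test_probabilities})
    for name, sp in stack.layer2.items():
        preds[f"layer2_{name}"] = sp.test_column
    preds.to_csv(out / "test_predictions.csv", index=False)

    logger.info("artifacts written to %s", out)
    return out
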
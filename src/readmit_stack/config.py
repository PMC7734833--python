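"""Flat pipeline configuration.

A single dataclass collects every tunable knob of the pipeline. Configs load
from YAML (a flat mapping, plus an optional nested ``simulate`` block that
parameterizes the synthetic-cohort generator); unknown keys are rejected so
typos never silently fall back to defaults. The effective configuration is
echoed into every run manifest.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cohort import CohortSpec

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    # data source: either an input CSV or a simulate block
    input_csv: str | None = None
    simulate: CohortSpec | None = None
    # preprocessing
    missing_filter_threshold: float = 0.20
    bucket_threshold: float = 0.30
    train_fraction: float = 0.8
    # balancing
    balancer: str = "ncr"  # "ncr" | "none"
    ncr_k: int = 3
    # feature selection
    fs_folds: int = 5
    max_subsets: int | None = None
    # stacking
    rank_folds: int = 5
    stack_folds: int = 5
    meta_C: float = 1.0
    model_overrides: dict | None = None
    # evaluation
    threshold: float = 0.5
    n_repeats: int = 10
    significance_method: str = "t"
    compare_ncr: bool = False
    # bookkeeping
    master_seed: int = 0
    output_dir: str = "run-output"

    def validate(self) -> None:
        if self.balancer not in ("ncr", "none"):
            raise ValueError("balancer must be 'ncr' or 'none'")
        if self.input_csv is None and self.simulate is None:
            raise ValueError("config needs either input_csv or a simulate block")
        if self.simulate is not None:
            self.simulate.validate()

    def pipeline_kwargs(self) -> dict:
        """Keyword arguments for run_single_split / repeated_protocol."""
        return dict(
            train_fraction=self.train_fraction,
            missing_filter_threshold=self.missing_filter_threshold,
            bucket_threshold=self.bucket_threshold,
            balancer=self.balancer,
            ncr_k=self.ncr_k,
            fs_folds=self.fs_folds,
            rank_folds=self.rank_folds,
            stack_folds=self.stack_folds,
            max_subsets=self.max_subsets,
            meta_C=self.meta_C,
            threshold=self.threshold,
            model_overrides=self.model_overrides,
        )

    def manifest_items(self) -> list[tuple[str, str]]:
        """Flat key=value pairs echoing the full effective configuration."""
        items: list[tuple[str, str]] = []
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if f.name == "simulate":
                if value is None:
                    items.append(("simulate", "none"))
                else:
                    for sf in dataclasses.fields(value):
                        items.append(
                            (f"simulate.{sf.name}", str(getattr(value, sf.name)))
                        )
            else:
                items.append((f.name, str(value)))
        return items

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw or {})
        simulate = raw.pop("simulate", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise KeyError(f"unknown config key(s): {sorted(unknown)}")
        if simulate is not None:
            spec_known = {f.name for f in dataclasses.fields(CohortSpec)}
            bad = set(simulate) - spec_known
            if bad:
                raise KeyError(f"unknown simulate key(s): {sorted(bad)}")
            if "categorical_levels" in simulate and simulate["categorical_levels"] is not None:
                simulate["categorical_levels"] = tuple(simulate["categorical_levels"])
            simulate = CohortSpec(**simulate)
        config = cls(simulate=simulate, **raw)
        config.validate()
        return config


def load_config(path: str | Path, **cli_overrides) -> PipelineConfig:
    """Load YAML config; CLI overrides (not None) take precedence."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    for key, value in cli_overrides.items():
        if value is not None:
            raw[key] = value
    return PipelineConfig.from_dict(raw)
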
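"""Structured run configuration (YAML) with validated keys and defaults.

Every threshold of the processing cascade is controlled here; defaults are
the workflow's canonical values (80% presence, 30% sparsity, 70% QC
presence, 30% QC RSD, ±5 ppm, k = 3/2 MAD multipliers, kNN k = 5, 95% PCA
confidence).  Unknown keys are a startup error, not a warning.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .mass import ISConfig
from .pipeline import PipelineConfig
from .synthetic import StudyConfig

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Top-level run configuration.

    ``mode`` selects the threshold set: ``assessment`` (workflow
    evaluation) or ``ht`` (high-throughput: looser presence/sparsity
    filters, k = 3 screening for all classes, m/z and signal drift
    correction enabled).
    """

    mode: str = "assessment"
    assay: str = "polar_pos"
    seed: int = 0
    study: StudyConfig = field(default_factory=StudyConfig)
    internal_standard: ISConfig = field(default_factory=ISConfig)
    pipeline: PipelineConfig | None = None
    drift_r_threshold: float = 0.7
    matrix_path: str | None = None       # user data instead of synthetic
    sample_meta_path: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("assessment", "ht"):
            raise ValueError(f"unknown mode: {self.mode!r}")
        if self.pipeline is None:
            self.pipeline = (PipelineConfig.ht(self.assay) if self.mode == "ht"
                             else PipelineConfig.assessment())
        if self.mode == "ht":
            # Eq-(3)-style screening: 3×MAD for every class
            self.internal_standard.k_study = 3.0
        self.study.seed = self.seed

    def snapshot(self) -> dict:
        d = dataclasses.asdict(self)
        d["study"]["mz_range"] = list(d["study"]["mz_range"])
        d["pipeline"]["signal_drift_lambda_grid"] = list(
            d["pipeline"]["signal_drift_lambda_grid"])
        return d


def _build(cls, section: dict, name: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise ValueError(f"unknown key(s) in config section '{name}': "
                         f"{sorted(unknown)}")
    return cls(**section)


def load_config(path: str | Path | None = None, overrides: dict | None = None
                ) -> RunConfig:
    """Load a YAML config; missing keys fall back to defaults.

    ``overrides`` (top-level keys) take precedence over the file.
    """
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    raw.update(overrides or {})

    top_known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - top_known
    if unknown:
        raise ValueError(f"unknown top-level config key(s): {sorted(unknown)}")

    kwargs: dict = {}
    for key, val in raw.items():
        if key == "study":
            if "mz_range" in val:
                val = {**val, "mz_range": tuple(val["mz_range"])}
            kwargs[key] = _build(StudyConfig, val, "study")
        elif key == "internal_standard":
            kwargs[key] = _build(ISConfig, val, "internal_standard")
        elif key == "pipeline":
            kwargs[key] = _build(PipelineConfig, val, "pipeline")
        else:
            kwargs[key] = val
    return RunConfig(**kwargs)
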
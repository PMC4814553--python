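"""Pipeline configuration: schema-validated YAML with explicit seeds."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class ROIConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    center_mm: tuple[float, float, float]
    radius_mm: float = 8.0


class InversionConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    max_iter: int = 64
    tol: float = 1e-2
    ar_coef: float = 0.8
    fd_step: float = 1e-4


class BMSConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    prior_concentration: float = 1.0
    n_draws: int = 1_000_000
    seed: int = 7


class CohortSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_young: int = 14
    n_older: int = 16
    master_seed: int = 2026


class PipelineConfig(BaseModel):
    """Top-level configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    data_dir: str = "data"
    results_dir: str = "results"
    tr: float = 2.0
    microtime_bins: int = 16
    include_block2_input: bool = False  # Block 2 contributes no DCM input
    rois: list[ROIConfig] = Field(default_factory=list)
    models: list[str] = Field(
        default_factory=lambda: ["model1", "model2", "model3", "model4"])
    cohort: CohortSection = Field(default_factory=CohortSection)
    inversion: InversionConfig = Field(default_factory=InversionConfig)
    bms: BMSConfig = Field(default_factory=BMSConfig)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig.model_validate(raw)


def default_config() -> PipelineConfig:
    return PipelineConfig()
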
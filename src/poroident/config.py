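"""Study configuration: a single structured YAML file, schema-validated.

Unknown keys are rejected before any computation so that typos in a
study file fail loudly, and seeds are mandatory for stochastic blocks.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .constitutive import Environment
from .parameters import ParameterSpace
from .simulator import Grid1D, Protocol


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ParameterRangeConfig(_Strict):
    name: str
    min: float
    max: float
    units: str = "-"


class ProtocolConfig(_Strict):
    initial_height: float = 1.1
    initial_diameter: float = 4.0
    n_increments: int = 3
    increment_strain: float = 0.05
    ramp_duration: float = 60.0
    hold_duration: float = 2700.0
    points_per_ramp: int = 9
    points_per_hold: int = 15
    equilibration_duration: float = 2700.0

    def build(self) -> Protocol:
        return Protocol(**self.model_dump())


class GridConfig(_Strict):
    n_nodes: int = 21

    def build(self) -> Grid1D:
        return Grid1D(self.n_nodes)


class EnvironmentConfig(_Strict):
    T: float = 294.0
    c_star: float = 300.0

    def build(self) -> Environment:
        return Environment(T=self.T, c_star=self.c_star)


class GlobalConfig(_Strict):
    levels: int = 3
    threshold_pct: float = 1.0
    substeps: int = 1
    free_parameters: list[str] | None = None  # None = all ten


class LocalConfig(_Strict):
    n_truths: int = 10
    step: float = 0.01
    noise_floor: float = 1e-2
    substeps: int = 1
    sweep: bool = False


class OptimizeConfig(_Strict):
    n_truths: int = 10
    methods: list[str] = Field(default_factory=lambda: ["nelder-mead"])
    max_fev: int | None = None  # None = 200 evaluations per parameter
    substeps: int = 1

    @field_validator("methods")
    @classmethod
    def _known(cls, v):
        for m in v:
            if m not in ("nelder-mead", "trust-constr"):
                raise ValueError(f"unknown optimizer method {m!r}")
        return v


class SimulateConfig(_Strict):
    theta: list[float] | None = None  # canonical order; None = midpoint
    substeps: int = 2


class StudyConfig(_Strict):
    """Top-level study definition."""

    seed: int
    output_dir: str = "study_out"
    parameters: list[ParameterRangeConfig] | None = None
    protocol: ProtocolConfig = Field(default_factory=ProtocolConfig)
    grid: GridConfig = Field(default_factory=GridConfig)
    environment: EnvironmentConfig = Field(default_factory=EnvironmentConfig)
    simulate: SimulateConfig | None = None
    global_analysis: GlobalConfig | None = Field(None, alias="global")
    local_analysis: LocalConfig | None = Field(None, alias="local")
    optimize: OptimizeConfig | None = None

    model_config = ConfigDict(extra="forbid", populate_by_name=True)

    def space(self) -> ParameterSpace:
        if self.parameters is None:
            return ParameterSpace.default()
        return ParameterSpace.from_dict(
            [p.model_dump() for p in self.parameters])

    def content_hash(self) -> str:
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


def load_config(path: str | Path) -> StudyConfig:
    """Parse and validate a YAML study file; report field paths on error."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    return StudyConfig.model_validate(raw)
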
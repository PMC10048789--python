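"""Run configuration: validated YAML blocks for scenarios, engine and paths."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .sd_engine import SimulationConfig

__all__ = ["RunConfig", "ScenarioBlock", "EngineBlock", "load_config", "save_config"]


class ScenarioBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    label: str = "scenario"
    hv: float = 0.0
    av: float = 60.0
    hv_grid: Optional[list[float]] = None
    av_grid: Optional[list[float]] = None
    overrides: dict[str, float] = Field(default_factory=dict)

    @field_validator("hv")
    @classmethod
    def _hv_range(cls, v):
        if not 0 <= v <= 1:
            raise ValueError(f"hv={v} outside [0, 1]")
        return v

    @field_validator("av")
    @classmethod
    def _av_range(cls, v):
        if not 0 <= v <= 100:
            raise ValueError(f"av={v} outside [0, 100]")
        return v


class EngineBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    t0: float = 0.0
    t_end: float = 24.0
    dt: float = 0.25
    sm1: str = "exogenous"
    sa_damping: str = "sm"
    ua_outflow: str = "none"
    delay_init: str = "steady"

    @model_validator(mode="after")
    def _grid_closes(self):
        SimulationConfig(t0=self.t0, t_end=self.t_end, dt=self.dt)  # raises
        from .model24 import ModelOptions

        ModelOptions(sm1=self.sm1, sa_damping=self.sa_damping,
                     ua_outflow=self.ua_outflow, delay_init=self.delay_init)
        return self

    def simulation_config(self) -> SimulationConfig:
        return SimulationConfig(t0=self.t0, t_end=self.t_end, dt=self.dt)

    def model_options(self):
        from .model24 import ModelOptions

        return ModelOptions(sm1=self.sm1, sa_damping=self.sa_damping,
                            ua_outflow=self.ua_outflow,
                            delay_init=self.delay_init)


class RunConfig(BaseModel):
    """Fully validated run configuration with defaults filled."""

    model_config = ConfigDict(extra="forbid")

    params_file: Optional[Path] = None
    records_file: Optional[Path] = None
    out_dir: Path = Path("runs")
    scenario: ScenarioBlock = Field(default_factory=ScenarioBlock)
    engine: EngineBlock = Field(default_factory=EngineBlock)
    seed: Optional[int] = None
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _paths_exist(self):
        for name in ("params_file", "records_file"):
            p = getattr(self, name)
            if p is not None and not Path(p).is_file():
                raise ValueError(f"{name} does not exist: {p}")
        return self


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration; unknown keys rejected."""
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return RunConfig.model_validate(data)


def save_config(config: RunConfig, path) -> None:
    data = config.model_dump(mode="json", exclude_none=True)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
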
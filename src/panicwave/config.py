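"""Run configuration: schema, defaults, validation, YAML loading.

All defaults equal the model's reference setting: 1000-node BA network with
m = 3, need weights a = 0.6 / b = 0.4, conformity ~ N(0.5, 0.15) truncated
to [0, 1], 6% initially infected, interaction parameters mu1 = mu2 = 0.2,
d1 = 0.2, d2 = 0.6, forgetting parameters c1 = 1, c2 = 0.01.  Unknown keys
are rejected so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .emotion import InteractionParams, NeedWeights
from .information import InformationPoint, InformationSchedule
from .parameters import ForgettingParams, ModelParameters

__all__ = ["RunConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class NetworkSection(_Strict):
    n: int = Field(1000, ge=2)
    m: int = Field(3, ge=1)

    @model_validator(mode="after")
    def _n_exceeds_m(self):
        if self.n <= self.m:
            raise ValueError("network.n must exceed network.m")
        return self


class ScheduleSegment(_Strict):
    start_step: int = Field(ge=0)
    im_pos: float = Field(0.0, ge=0.0, le=1.0)
    im_neg: float = Field(0.0, ge=0.0, le=1.0)
    is_pos: float = Field(0.0, ge=0.0, le=1.0)
    is_neg: float = Field(0.0, ge=0.0, le=1.0)


class ParametersSection(_Strict):
    a: float = 0.6
    b: float = 0.4
    mu1: float = 0.2
    mu2: float = 0.2
    d1: float = 0.2
    d2: float = 0.6
    c1: float = 1.0
    c2: float = 0.01
    conformity_mean: float = 0.5
    conformity_sd: float = 0.15
    initial_infected_fraction: float = Field(0.06, ge=0.0, le=1.0)
    horizon: int = Field(60, ge=0)
    replications: int = Field(100, ge=1)
    panic_update_mode: Literal["recompute", "incremental"] = "recompute"
    polarizability_threshold: float = Field(0.9, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _domain_constraints(self):
        # delegate to the dataclasses so config and API enforce identical rules
        NeedWeights(self.a, self.b)
        InteractionParams(self.mu1, self.mu2, self.d1, self.d2)
        ForgettingParams(self.c1, self.c2)
        return self


class OutputSection(_Strict):
    directory: str = "runs"
    formats: list[Literal["csv", "json"]] = ["csv", "json"]


class ExperimentSection(_Strict):
    family: Literal["baseline", "needs", "conformity", "edges", "timing"] = "baseline"
    n_experiments: int = Field(100, ge=1)
    conformity_means: list[float] = [0.2, 0.5, 0.8]
    m_values: list[int] = [1, 3, 6]
    change_times: list[int] = [2, 10, 15, 20, 30, 40]


class RunConfig(_Strict):
    """Validated simulation configuration (YAML-loadable)."""

    network: NetworkSection = NetworkSection()
    schedule: list[ScheduleSegment] = [ScheduleSegment(start_step=0, im_neg=0.2, is_neg=0.6)]
    parameters: ParametersSection = ParametersSection()
    output: OutputSection = OutputSection()
    experiment: ExperimentSection = ExperimentSection()
    seed: int = 0

    def to_model_parameters(self) -> ModelParameters:
        p = self.parameters
        return ModelParameters(
            need_weights=NeedWeights(p.a, p.b),
            interaction=InteractionParams(p.mu1, p.mu2, p.d1, p.d2),
            forgetting=ForgettingParams(p.c1, p.c2),
            conformity_mean=p.conformity_mean,
            conformity_sd=p.conformity_sd,
            initial_infected_fraction=p.initial_infected_fraction,
            horizon=p.horizon,
            replications=p.replications,
            panic_update_mode=p.panic_update_mode,
            polarizability_threshold=p.polarizability_threshold,
        )

    def to_schedule(self) -> InformationSchedule:
        return InformationSchedule(
            tuple(
                (
                    seg.start_step,
                    InformationPoint(seg.im_pos, seg.im_neg, seg.is_pos, seg.is_neg),
                )
                for seg in self.schedule
            )
        )


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML config; an empty file yields all defaults."""
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        return RunConfig()
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    return RunConfig(**data)
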
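"""Run configuration: schema-validated loading, defaulting and snapshots.

A run is described by a YAML/JSON document with a ``population:`` block (or a
``cohort_path``), a ``strategies:`` list, and scalar knobs (n, seed, discount
rate, flags).  Unknown keys are rejected; every run can write back a resolved
snapshot that reloads to an identical configuration.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .defaults import (default_age_trends, default_parameter_set, default_population_config)
from .errors import ConfigurationError
from .population import (AgeTrendModel, ContinuousSpec, PopulationConfig, SexMarginals,
                         read_cohort_csv)
from .strategies import StrategyDefinition, preset_strategies

__all__ = ["RunConfig", "load_and_validate_config", "write_snapshot", "config_hash"]


class StrategySpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    threshold: float | None = None
    discontinuation: float = 0.40
    rules: list[str] = Field(default_factory=list)


class ContinuousSpecModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    mean: float
    sd: float
    lower: float
    upper: float


class SexBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    age: ContinuousSpecModel
    sbp: ContinuousSpecModel
    tc: ContinuousSpecModel
    hdl: ContinuousSpecModel
    ldl: ContinuousSpecModel
    wc: ContinuousSpecModel
    smoking_prevalence: float
    diabetes_prevalence: float
    antihtn_prevalence: float


class PopulationBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    male: SexBlock | None = None
    female: SexBlock | None = None
    male_fraction: float = 0.47
    min_age: int = 45
    correlation: list[list[float]] | None = None


class RunConfig(BaseModel):
    """Validated run description with all defaults resolved."""

    model_config = ConfigDict(extra="forbid", arbitrary_types_allowed=True)

    seed: int
    n: int = 10_000
    discount_rate: float = 0.03
    population: PopulationBlock | None = None
    cohort_path: str | None = None
    strategies: list[StrategySpec] = Field(default_factory=list)
    out_dir: str = "results"
    allow_recurrence: bool = False
    common_random_numbers: bool = True
    psa_draws: int = 1000
    dsa_parameters: list[str] = Field(default_factory=list)

    @field_validator("n")
    @classmethod
    def _n_positive(cls, v):
        if v < 1:
            raise ValueError("n must be >= 1")
        return v

    @field_validator("discount_rate")
    @classmethod
    def _rate_nonneg(cls, v):
        if v < 0:
            raise ValueError("discount_rate must be >= 0")
        return v

    @model_validator(mode="after")
    def _population_xor_cohort(self):
        if self.population is not None and self.cohort_path is not None:
            raise ValueError("give exactly one of 'population' and 'cohort_path', not both")
        return self

    def resolved_strategies(self) -> list[StrategyDefinition]:
        if not self.strategies:
            return preset_strategies()
        return [
            StrategyDefinition(s.name, s.threshold, s.discontinuation, tuple(s.rules))
            for s in self.strategies
        ]

    def resolved_population(self) -> PopulationConfig:
        if self.cohort_path is not None:
            raise ConfigurationError("config uses an external cohort, not a population block")
        if self.population is None:
            return default_population_config()
        block = self.population
        base = default_population_config(min_age=block.min_age)

        def to_marginals(sex_block: SexBlock | None, fallback: SexMarginals) -> SexMarginals:
            if sex_block is None:
                return fallback
            kwargs = {}
            for f in ("age", "sbp", "tc", "hdl", "ldl", "wc"):
                m = getattr(sex_block, f)
                kwargs[f] = ContinuousSpec(m.mean, m.sd, m.lower, m.upper)
            for f in ("smoking_prevalence", "diabetes_prevalence", "antihtn_prevalence"):
                kwargs[f] = getattr(sex_block, f)
            return SexMarginals(**kwargs)

        corr = np.asarray(block.correlation, dtype=float) if block.correlation is not None else None
        return PopulationConfig(
            male=to_marginals(block.male, base.male),
            female=to_marginals(block.female, base.female),
            male_fraction=block.male_fraction,
            correlation=corr,
        )

    def resolved_cohort(self):
        from .population import generate_cohort

        if self.cohort_path is not None:
            return read_cohort_csv(self.cohort_path)
        return generate_cohort(self.n, self.resolved_population(), seed=self.seed)

    def resolved_parameters(self):
        return default_parameter_set(discount_rate=self.discount_rate)


def load_and_validate_config(path) -> RunConfig:
    """Load and schema-validate a YAML or JSON run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    if payload is None:
        payload = {}
    try:
        return RunConfig.model_validate(payload)
    except Exception as exc:  # pydantic ValidationError carries field + constraint
        raise ConfigurationError(f"invalid configuration {path}: {exc}") from exc


def write_snapshot(config: RunConfig, path) -> None:
    """Write the resolved configuration so the run can be reproduced exactly."""
    with open(path, "w") as fh:
        yaml.safe_dump(json.loads(config.model_dump_json()), fh, sort_keys=True)


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(json.loads(config.model_dump_json()), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
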
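"""Experiment configuration: schema, (de)serialization, shipped fixtures.

A single flat JSON document (YAML is accepted as a read convenience)
records everything needed to regenerate a run: the model (per-regime rates,
generator, incidence exponent), the initial condition, and the numerics.
Unknown keys are rejected so stale or misspelled fields fail loudly.

The two-regime reference parameterization ships in three noise cases:

    case a: sigma^2 = (0.4, 0.2)  -> R0S ~ 1.086 > 1, persistent
    case b: sigma^2 = (0.8, 0.6)  -> Rbar ~ 0.731 < 1, extinct
    case c: sigma^2 = (0.4, 0.4)  -> see the note carried by the fixture

with shared values Lambda=(0.3, 0.5), mu=(0.1, 0.2), beta=(0.8, 0.6),
alpha=(0.2, 0.1), gamma=(0.3, 0.2), epsilon=(0.1, 0.2), h=0.002, generator
[[-0.2, 0.2], [0.8, -0.8]] and initial state (S0, I0, r0) = (0.3, 0.2, 1).
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import regime_chain
from .model_core import RegimeParameters, SwitchingModel

__all__ = [
    "ExperimentConfig",
    "load_config",
    "example31",
    "EXAMPLE_CASES",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class RegimeConfig(_Strict):
    """One regime's rate constants (see RegimeParameters for units)."""

    Lambda: float = Field(gt=0)
    mu: float = Field(gt=0)
    beta: float = Field(gt=0)
    alpha: float = Field(gt=0)
    gamma: float = Field(gt=0)
    epsilon: float = Field(gt=0)
    sigma2: float = Field(ge=0)

    def to_params(self) -> RegimeParameters:
        return RegimeParameters(**self.model_dump())


class ModelConfig(_Strict):
    regimes: list[RegimeConfig] = Field(min_length=1)
    generator: list[list[float]]
    h: float = Field(gt=0)
    l: Optional[float] = Field(default=None, gt=0)

    @field_validator("generator")
    @classmethod
    def _valid_generator(cls, v):
        try:
            regime_chain.validate_generator(v)
        except ValueError as exc:
            raise ValueError(f"generator: {exc}") from exc
        return v


class InitialConfig(_Strict):
    S0: float = Field(gt=0)
    I0: float = Field(ge=0)
    r0: int = Field(default=1, ge=1)


class NumericsConfig(_Strict):
    """Simulation controls; defaults match the reference experiment
    (horizon t = 1000)."""

    T: float = Field(default=1000.0, gt=0)
    dt: float = Field(default=0.01, gt=0)
    n_paths: int = Field(default=200, ge=1)
    seed: int = 0
    extinction_floor: float = Field(default=1e-4, gt=0)
    hist_bins: int = Field(default=40, ge=2)
    hist_s_range: tuple[float, float] = (0.0, 3.5)
    hist_i_range: tuple[float, float] = (0.0, 3.5)
    window: Optional[tuple[float, float]] = None  # defaults to [T/2, T]


class OutputsConfig(_Strict):
    trajectory_csv: Optional[str] = None
    summary_json: Optional[str] = None


class ExperimentConfig(_Strict):
    """Complete, serializable description of one experiment."""

    model: ModelConfig
    initial: InitialConfig
    numerics: NumericsConfig = NumericsConfig()
    outputs: OutputsConfig = OutputsConfig()
    label: Optional[str] = None
    notes: list[str] = Field(default_factory=list)

    def build_model(self) -> SwitchingModel:
        return SwitchingModel(
            regimes=[r.to_params() for r in self.model.regimes],
            generator=self.model.generator,
            h=self.model.h,
            l=self.model.l)

    def to_json(self, indent: int = 2) -> str:
        return self.model_dump_json(indent=indent)

    def save(self, path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def load_config(path) -> ExperimentConfig:
    """Load and fully validate a JSON (or YAML) experiment configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return ExperimentConfig.model_validate(data)


def loads_config(text: str) -> ExperimentConfig:
    """Parse a JSON string (round-trip counterpart of ``to_json``)."""
    return ExperimentConfig.model_validate(json.loads(text))


# ---------------------------------------------------------------------------
# reference two-regime fixtures
# ---------------------------------------------------------------------------

EXAMPLE_CASES = ("a", "b", "c")

_SIGMA2 = {"a": (0.4, 0.2), "b": (0.8, 0.6), "c": (0.4, 0.4)}

_CASE_C_NOTE = (
    "case c: the reference analysis reports this parameterization as "
    "sub-threshold (R0S = 0.76 < 1), but direct evaluation of the R0S "
    "formula gives 19/18 ~ 1.056 > 1 (0.76 is the numerator alone); the "
    "computed formula value is reported here")


def example31(case: str) -> ExperimentConfig:
    """The shipped two-regime reference parameterization, noise case a/b/c."""
    case = case.lower().removeprefix("3.1")
    if case not in EXAMPLE_CASES:
        raise ValueError(f"unknown case {case!r}; expected one of "
                         f"{EXAMPLE_CASES}")
    s2 = _SIGMA2[case]
    shared = dict(Lambda=(0.3, 0.5), mu=(0.1, 0.2), beta=(0.8, 0.6),
                  alpha=(0.2, 0.1), gamma=(0.3, 0.2), epsilon=(0.1, 0.2))
    regimes = [
        RegimeConfig(**{k: v[i] for k, v in shared.items()}, sigma2=s2[i])
        for i in range(2)
    ]
    return ExperimentConfig(
        model=ModelConfig(regimes=regimes,
                          generator=[[-0.2, 0.2], [0.8, -0.8]],
                          h=0.002),
        initial=InitialConfig(S0=0.3, I0=0.2, r0=1),
        numerics=NumericsConfig(),
        label=f"two-regime reference, case {case}",
        notes=[_CASE_C_NOTE] if case == "c" else [],
    )


def shipped_config_path(case: str) -> Path:
    """Path of the packaged JSON fixture for a reference case."""
    if case not in EXAMPLE_CASES:
        raise ValueError(f"unknown case {case!r}")
    return Path(str(resources.files("switchsir").joinpath(
        f"data/example_case_{case}.json")))
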
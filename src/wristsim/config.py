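"""Run configuration: schema-validated, fully defaulted, YAML-backed.

Every field has a default that reproduces the reference experiment: a
seven-specimen cohort, the four cyclic motions, five cycles each at a
4.5 ms control step, APL ablated in the comparison condition, tendon-
excursion-estimated moment arms, and the normalized-effort solver.
Unknown keys are rejected with the offending field path.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from .errors import ConfigurationError

__all__ = ["RunConfig", "validate_config", "load_config"]

_MOTIONS = ("FE5030", "RUD15", "CCD_CW", "CCD_ACW")


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class CohortConfig(_Strict):
    n: int = Field(7, ge=1, description="cohort size")
    base_seed: int = Field(42, ge=0)
    cv: float = Field(0.15, ge=0, description="inter-specimen CV of PCSA and moment arms")
    specific_tension: float = Field(35.0, gt=0, description="N/cm^2")
    min_activity: float = Field(0.025, ge=0, lt=1)
    pcsa_mean: dict[str, float] | None = Field(None, description="override cohort PCSA means (cm^2)")
    neutral_ma_mean: dict[str, tuple[float, float]] | None = Field(
        None, description="override neutral (FE, RUD) moment-arm means (mm)"
    )

    @field_validator("pcsa_mean")
    @classmethod
    def _positive_pcsa(cls, v):
        if v is not None:
            for name, val in v.items():
                if not val > 0:
                    raise ValueError(f"pcsa_mean[{name}] must be > 0, got {val}")
        return v

    def params_kwargs(self) -> dict:
        kwargs = {
            "cv": self.cv,
            "specific_tension": self.specific_tension,
            "min_activity": self.min_activity,
        }
        if self.pcsa_mean is not None:
            kwargs["pcsa_mean"] = self.pcsa_mean
        if self.neutral_ma_mean is not None:
            kwargs["neutral_ma_mean"] = {k: tuple(v) for k, v in self.neutral_ma_mean.items()}
        return kwargs


class TrajectoryConfig(_Strict):
    cycles: int = Field(5, ge=1)
    period: float = Field(4.0, gt=0, description="seconds per cycle")
    dt: float = Field(0.0045, gt=0, description="control step, seconds")


class ControllerSection(_Strict):
    kp: float | None = Field(None, ge=0, description="N*mm/deg; None = pole placement")
    kd: float | None = Field(None, ge=0, description="N*mm*s/deg; None = pole placement")
    dt: float = Field(0.0045, gt=0)
    gravity_on: bool = True
    gravity_feedforward: bool = True
    mode: Literal["dynamic", "quasi_static"] = "dynamic"
    natural_freq_hz: float = Field(3.0, gt=0)
    allow_coarse_dt: bool = False


class SolverConfig(_Strict):
    criterion: Literal["normalized_quadratic", "cubed_stress"] = "normalized_quadratic"


class MomentArmConfig(_Strict):
    source: Literal["true", "estimated"] = "estimated"
    fit_degree: int = Field(2, ge=1)
    n_points: int = Field(25, ge=4)
    noise_sigma: float = Field(0.1, ge=0, description="excursion noise sd, mm")


class StatsConfig(_Strict):
    alpha: float = Field(0.05, gt=0, lt=1)
    p_method: Literal["exact", "asymptotic"] = "asymptotic"
    window_deg: float = Field(1.0, gt=0, description="grid phase-window half-width, deg")
    zero_method: Literal["wilcox", "pratt"] = "wilcox"


class RunConfig(_Strict):
    cohort: CohortConfig = Field(default_factory=CohortConfig)
    motions: list[Literal["FE5030", "RUD15", "CCD_CW", "CCD_ACW"]] = Field(
        default_factory=lambda: list(_MOTIONS)
    )
    ablation: list[str] = Field(default_factory=lambda: ["APL"])
    trajectory: TrajectoryConfig = Field(default_factory=TrajectoryConfig)
    controller: ControllerSection = Field(default_factory=ControllerSection)
    solver: SolverConfig = Field(default_factory=SolverConfig)
    moment_arms: MomentArmConfig = Field(default_factory=MomentArmConfig)
    stats: StatsConfig = Field(default_factory=StatsConfig)
    output_dir: str = "results"

    @field_validator("motions")
    @classmethod
    def _nonempty_unique(cls, v):
        if not v:
            raise ValueError("motions must be non-empty")
        if len(set(v)) != len(v):
            raise ValueError("motions must be unique")
        return v

    @field_validator("controller")
    @classmethod
    def _dt_range(cls, v):
        if not v.allow_coarse_dt and not (0.004 <= v.dt <= 0.005):
            raise ValueError(
                f"controller.dt = {v.dt} s is outside the 4-5 ms control-loop range "
                "(set controller.allow_coarse_dt to override)"
            )
        return v


def _format_pydantic_error(exc: ValidationError) -> str:
    parts = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<root>"
        parts.append(f"{loc}: {err['msg']}")
    return "; ".join(parts)


def load_config(data: dict | None) -> RunConfig:
    """Build a validated RunConfig from a (possibly empty) mapping."""
    try:
        return RunConfig.model_validate(data or {})
    except ValidationError as exc:
        raise ConfigurationError(_format_pydantic_error(exc)) from None


def validate_config(path: str | Path) -> RunConfig:
    """Parse, default, and validate a YAML config file.

    An empty file yields the full-default configuration; unknown keys and
    out-of-range values raise :class:`ConfigurationError` naming the field.
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise ConfigurationError(f"cannot read config file {path}: {exc}") from None
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"YAML parse error in {path}: {exc}") from None
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"config root must be a mapping, got {type(data).__name__}")
    return load_config(data)
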
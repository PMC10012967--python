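"""Run configuration: JSON/TOML loading, validation, angle syntax.

Angles in configs and on the command line may be written either as raw
radians (floats) or as multiples of pi with a literal ``pi`` suffix,
e.g. ``"-0.28pi"`` or ``"pi"``; they are stored internally in radians.
Unknown keys are rejected.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import List, Optional, Tuple, Union

from pydantic import BaseModel, ConfigDict, Field, field_validator

from .ensemble import SWEEPABLE, SweepSpec
from .exceptions import ParameterError
from .initial import InitialConditionSpec
from .model import ModelParams

__all__ = ["RunConfig", "load_config", "save_config", "parse_angle"]

Angle = Union[float, int, str]


def parse_angle(value: Angle) -> float:
    """Parse an angle given in radians or as a multiple of pi.

    ``0.5``, ``"0.5"`` -> 0.5 rad; ``"0.5pi"``, ``"-0.28pi"``, ``"pi"``
    -> that multiple of pi.
    """
    if isinstance(value, (int, float)):
        return float(value)
    s = str(value).strip().lower().replace(" ", "")
    if s.endswith("pi"):
        head = s[:-2]
        if head in ("", "+"):
            factor = 1.0
        elif head == "-":
            factor = -1.0
        else:
            try:
                factor = float(head)
            except ValueError as exc:
                raise ParameterError("angle", f"cannot parse angle {value!r}") from exc
        return factor * math.pi
    try:
        return float(s)
    except ValueError as exc:
        raise ParameterError("angle", f"cannot parse angle {value!r}") from exc


class ModelSection(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_default=True)

    n: int = 200
    omega1: float = 0.0
    omega2: float = 0.0
    alpha11: Angle = "-0.28pi"
    alpha22: Angle = "-0.28pi"
    alpha12: Angle = 0.0
    alpha21: Angle = 0.0
    beta: Angle = "0.5pi"
    eps1: float = Field(0.03, ge=0)
    eps2: float = Field(0.3, ge=0)
    sigma: float = Field(1.0, ge=0)

    @field_validator("alpha11", "alpha22", "alpha12", "alpha21", "beta")
    @classmethod
    def _angles(cls, v):
        return parse_angle(v)


class InitSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    c: int = 40
    seed: int = 0


class IntegratorSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    t_end: float = Field(2000.0, gt=0)
    window: float = Field(1000.0, gt=0)
    sampling: float = Field(0.5, gt=0)
    rtol: float = Field(1e-6, gt=0)
    atol: float = Field(1e-8, gt=0)
    method: str = "RK45"


class SweepSection(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_default=True)

    axis1_name: str
    axis1_values: List[Angle]
    axis2_name: Optional[str] = None
    axis2_values: Optional[List[Angle]] = None
    n_e: int = Field(10, ge=1)
    master_seed: int = 0
    full_scale: bool = False

    @field_validator("axis1_name", "axis2_name")
    @classmethod
    def _names(cls, v):
        if v is not None and v not in SWEEPABLE:
            raise ValueError(f"sweepable parameters are {SWEEPABLE}, got {v!r}")
        return v

    @field_validator("axis1_values", "axis2_values")
    @classmethod
    def _values(cls, v):
        return None if v is None else [parse_angle(x) for x in v]


class RunConfig(BaseModel):
    """Validated top-level configuration; defaults are the reference
    regime-map parameter set (N = 200, C = 40, t_end = 2000)."""

    model_config = ConfigDict(extra="forbid")

    model: ModelSection = Field(default_factory=ModelSection)
    init: InitSection = Field(default_factory=InitSection)
    integrator: IntegratorSection = Field(default_factory=IntegratorSection)
    sweep: Optional[SweepSection] = None
    output_dir: str = "out"
    log_level: str = "INFO"

    def to_model_params(self) -> ModelParams:
        m = self.model
        return ModelParams(
            n=m.n, omega1=m.omega1, omega2=m.omega2,
            alpha11=m.alpha11, alpha22=m.alpha22,
            alpha12=m.alpha12, alpha21=m.alpha21,
            beta=m.beta, eps1=m.eps1, eps2=m.eps2, sigma=m.sigma,
        )

    def to_init_spec(self, seed: Optional[int] = None) -> InitialConditionSpec:
        return InitialConditionSpec(
            n=self.model.n, c=self.init.c,
            seed=self.init.seed if seed is None else seed,
        )

    def to_sweep_spec(self) -> SweepSpec:
        if self.sweep is None:
            raise ParameterError("sweep", "config has no sweep section")
        s = self.sweep
        axis2 = None
        if s.axis2_name is not None:
            if s.axis2_values is None:
                raise ParameterError("sweep.axis2_values", "axis2_name given without values")
            axis2 = (s.axis2_name, tuple(s.axis2_values))
        frac = self.init.c / self.model.n
        return SweepSpec(
            axis1=(s.axis1_name, tuple(s.axis1_values)),
            axis2=axis2,
            n_e=s.n_e,
            master_seed=s.master_seed,
            n=self.model.n,
            c_frac=frac,
            t_end=self.integrator.t_end,
            window=self.integrator.window,
            sampling=self.integrator.sampling,
            base_params=self.to_model_params(),
            full_scale=s.full_scale,
        )


def load_config(path) -> RunConfig:
    """Load and validate a JSON or TOML run configuration."""
    path = Path(path)
    if not path.exists():
        raise ParameterError("path", f"config file not found: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".toml":
        import tomllib

        data = tomllib.loads(text)
    else:
        data = json.loads(text) if text.strip() else {}
    return RunConfig.model_validate(data)


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(json.dumps(cfg.model_dump(), indent=2, sort_keys=True))
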
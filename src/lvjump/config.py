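"""Run configuration: YAML schema, validation, and translation to domain types.

A run configuration has four sections — ``model``, ``noise``, ``numerics``
and ``output`` (plus ``simulation`` for Monte Carlo runs).  Unknown keys
are rejected.  Gaussian noise can be given either as the effective
half-intensity pair ``D_eff`` or as the quoted-convention full intensities
``two_eps2_D`` (halved internally); the two keys are mutually exclusive.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .averaging import NoiseParams
from .exceptions import ConfigurationError
from .mcsim import SimulationConfig
from .model import RawModelParams
from .pipeline import SolverOptions

__all__ = ["RunConfig", "load_config", "to_raw_params", "to_noise_params",
           "to_solver_options", "to_simulation_config"]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ModelSection(_Section):
    case: Literal["saturation", "competition"]
    a: float = Field(gt=0)
    b: float = Field(gt=0)
    c: float = Field(gt=0)
    f: float = Field(gt=0)
    s_eff: float = Field(default=0.0, ge=0)
    A_eff: float = Field(default=0.0, ge=0)
    B_eff: float = Field(default=0.0, ge=0)


class NoiseSection(_Section):
    D_eff: tuple[float, float] | None = None
    two_eps2_D: tuple[float, float] | None = None
    lam: tuple[float, float] = (0.0, 0.0)
    jump_var: tuple[float, float] = (0.0, 0.0)
    #: constant Poisson intensity λ·E[Y²] used by λ-scans (jump_var is then derived)
    jump_intensity: float | None = None

    @model_validator(mode="after")
    def _exclusive_gaussian_keys(self):
        if self.D_eff is not None and self.two_eps2_D is not None:
            raise ValueError("give either 'D_eff' or 'two_eps2_D', not both")
        return self


class NumericsSection(_Section):
    n_levels: int = Field(default=160, ge=50)
    n_r: int = Field(default=2400, ge=200)
    r_max: float | None = Field(default=None, gt=0)
    tail_tol: float = Field(default=1e-8, gt=0)
    marginal_points: int = Field(default=400, ge=50)
    quad_points: int = Field(default=1201, ge=101)
    r_cut_mass: float = Field(default=1e-6, gt=0, lt=1e-2)
    seed: int = 0


class SimulationSection(_Section):
    dt: float | None = Field(default=None, gt=0)
    t_total: float = Field(default=2000.0, gt=0)
    t_burn: float = Field(default=400.0, ge=0)
    n_paths: int = Field(default=100, ge=1)
    record_stride: int = Field(default=5, ge=1)
    bins: int = Field(default=200, ge=10)


class OutputSection(_Section):
    directory: str = "out"


class RunConfig(_Section):
    model: ModelSection
    noise: NoiseSection = NoiseSection()
    numerics: NumericsSection = NumericsSection()
    simulation: SimulationSection = SimulationSection()
    output: OutputSection = OutputSection()


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Raises :class:`ConfigurationError` with the offending key path(s) in
    the message on schema violations.
    """
    path = Path(path)
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"invalid YAML in {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigurationError(f"configuration {path} must be a mapping")
    try:
        return RunConfig.model_validate(data)
    except ValidationError as exc:
        lines = [
            f"  {'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
            for err in exc.errors()
        ]
        raise ConfigurationError(
            f"invalid configuration {path}:\n" + "\n".join(lines)
        ) from exc


def to_raw_params(cfg: RunConfig) -> RawModelParams:
    m = cfg.model
    return RawModelParams(
        case=m.case, a=m.a, b=m.b, c=m.c, f=m.f,
        s_eff=m.s_eff, A_eff=m.A_eff, B_eff=m.B_eff,
    )


def to_noise_params(cfg: RunConfig) -> NoiseParams:
    n = cfg.noise
    if n.two_eps2_D is not None:
        D = (0.5 * n.two_eps2_D[0], 0.5 * n.two_eps2_D[1])
    else:
        D = n.D_eff or (0.0, 0.0)
    jump_var = n.jump_var
    if n.jump_intensity is not None:
        if min(n.lam) <= 0:
            raise ConfigurationError("'jump_intensity' requires positive 'lam'")
        jump_var = (n.jump_intensity / n.lam[0], n.jump_intensity / n.lam[1])
    return NoiseParams(
        D1=D[0], D2=D[1], lam1=n.lam[0], lam2=n.lam[1], m1=jump_var[0], m2=jump_var[1]
    )


def to_solver_options(cfg: RunConfig) -> SolverOptions:
    n = cfg.numerics
    return SolverOptions(
        n_levels=n.n_levels, n_r=n.n_r, r_max=n.r_max, tail_tol=n.tail_tol,
        marginal_points=n.marginal_points, quad_points=n.quad_points,
        r_cut_mass=n.r_cut_mass,
    )


def to_simulation_config(cfg: RunConfig) -> SimulationConfig:
    s = cfg.simulation
    return SimulationConfig(
        dt=s.dt, t_total=s.t_total, t_burn=s.t_burn, n_paths=s.n_paths,
        seed=cfg.numerics.seed, record_stride=s.record_stride,
    )
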
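"""Deterministic predator–prey models and their unified reparametrisation.

Two generalisations of the classic Lotka–Volterra system are covered:

* **predator saturation** ("Case 1", abundant prey): the interaction terms
  ``b x1 x2 / (1 + A x1)`` and ``f x1 x2 / (1 + A x1)`` saturate in prey
  density, so per-predator consumption is limited by handling rather than
  by prey supply;
* **predator competition** ("Case 2", large predator population): the
  interaction terms ``b x1 x2 / (1 + B x2)`` and ``f x1 x2 / (1 + B x2)``
  saturate in predator density, modelling predators competing for a
  limited prey supply.

Both models, together with a weak prey self-competition term ``-s x1**2``,
can be rewritten in a single *unified* form

    dx1/dt = x1 [ ā − b̄ x2 − (s/f̄)(−c + f̄ x1) + g1(x1, x2) ],
    dx2/dt = x2 [ −c + f̄ x1 + g2(x1, x2) ],

where the barred parameters (ā, b̄, f̄) absorb the leading effect of the
saturation/competition parameter and ``g1, g2`` are the exact residual
correction rates.  The self-competition, saturation and competition
parameters are *effective* (perturbation-order-absorbed) quantities
``s_eff``, ``A_eff``, ``B_eff``; no explicit bookkeeping of the formal
small parameter is carried anywhere in this package.

For the saturation case the barred parameters are explicit:

    f̄ = f − c·A_eff,   b̄ = b·f̄/f,   ā = a − s_eff·c/f̄.

For the competition case they solve the coupled system
``ā = a − s_eff·c/f̄``, ``b̄ = b − ā·B_eff``, ``f̄ = f·b̄/b``, which reduces
to one quadratic in b̄ (positive root).  Both choices are pinned down by the
requirement that the unified form reproduces the original per-capita rates
*identically*, which the test-suite enforces at 1e-12.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .exceptions import InvalidParameterError

__all__ = [
    "Case",
    "RawModelParams",
    "EffectiveParams",
    "make_effective_params",
    "percapita_drift",
    "unified_percapita_drift",
    "g_corrections",
]


class Case(str, Enum):
    """Which interaction nonlinearity the model uses."""

    SATURATION = "saturation"
    COMPETITION = "competition"


@dataclass(frozen=True)
class RawModelParams:
    """Parameters of one ecosystem in the original (unbarred) form.

    Parameters
    ----------
    case
        ``Case.SATURATION`` (abundant prey) or ``Case.COMPETITION``
        (large predator population).
    a
        Prey birth rate (1/time, > 0).
    b
        Predation coefficient (> 0).
    c
        Predator death rate (1/time, > 0).
    f
        Prey-to-predator conversion coefficient (> 0).
    s_eff
        Effective prey self-competition coefficient (>= 0).
    A_eff
        Effective predator-saturation parameter (>= 0, saturation case only).
    B_eff
        Effective predator-competition parameter (>= 0, competition case only).
    """

    case: Case
    a: float
    b: float
    c: float
    f: float
    s_eff: float = 0.0
    A_eff: float = 0.0
    B_eff: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "case", Case(self.case))
        for name in ("a", "b", "c", "f"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"rate '{name}' must be strictly positive")
        for name in ("s_eff", "A_eff", "B_eff"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"'{name}' must be nonnegative")
        if self.case is Case.SATURATION and self.B_eff != 0.0:
            raise InvalidParameterError("B_eff is meaningless in the saturation case")
        if self.case is Case.COMPETITION and self.A_eff != 0.0:
            raise InvalidParameterError("A_eff is meaningless in the competition case")
        if self.case is Case.SATURATION and not self.f - self.c * self.A_eff > 0:
            raise InvalidParameterError(
                "f_bar = f - c*A_eff must be strictly positive "
                f"(got {self.f - self.c * self.A_eff:g})"
            )


@dataclass(frozen=True)
class EffectiveParams:
    """Barred parameters of the unified form plus the raw parameters."""

    a_bar: float
    b_bar: float
    f_bar: float
    c: float
    raw: RawModelParams = field(repr=False)

    def __post_init__(self) -> None:
        for name in ("a_bar", "b_bar", "f_bar"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(
                    f"effective parameter '{name}' is not strictly positive"
                )

    @property
    def x1_star(self) -> float:
        """Prey density at the interior equilibrium, c / f̄."""
        return self.c / self.f_bar

    @property
    def x2_star(self) -> float:
        """Predator density at the interior equilibrium, ā / b̄."""
        return self.a_bar / self.b_bar

    def competition_residuals(self) -> tuple[float, float, float]:
        """Residuals of the three defining equations of the competition case.

        All three are zero (to round-off) for parameters produced by
        :func:`make_effective_params`; useful as a self-check.
        """
        raw = self.raw
        return (
            self.a_bar - (raw.a - raw.s_eff * raw.c / self.f_bar),
            self.b_bar - (raw.b - self.a_bar * raw.B_eff),
            self.f_bar - raw.f * self.b_bar / (self.b_bar + self.a_bar * raw.B_eff),
        )


def make_effective_params(raw: RawModelParams) -> EffectiveParams:
    """Compute the barred parameters (ā, b̄, f̄) of the unified form.

    Saturation case: closed form.  Competition case: positive root of
    ``b̄² + (a·B_eff − b)·b̄ − s_eff·c·b·B_eff/f = 0`` (the other root is
    nonpositive for valid inputs), then ā = (b − b̄)/B_eff and f̄ = f·b̄/b.

    Raises
    ------
    InvalidParameterError
        If any barred parameter comes out nonpositive (the error names the
        offending quantity).
    """
    a, b, c, f = raw.a, raw.b, raw.c, raw.f
    if raw.case is Case.SATURATION:
        f_bar = f - c * raw.A_eff
        b_bar = b * f_bar / f
        a_bar = a - raw.s_eff * c / f_bar
    else:
        if raw.B_eff == 0.0:
            b_bar = b
        else:
            half_p = 0.5 * (b - a * raw.B_eff)
            q = raw.s_eff * c * b * raw.B_eff / f
            b_bar = half_p + math.sqrt(half_p * half_p + q)
        f_bar = f * b_bar / b
        a_bar = a - raw.s_eff * c / f_bar
    return EffectiveParams(a_bar=a_bar, b_bar=b_bar, f_bar=f_bar, c=c, raw=raw)


def percapita_drift(ep: EffectiveParams, x1, x2):
    """Per-capita growth rates (h1, h2) of the *original* model.

    These are the exact deterministic drifts dln(x1)/dt and dln(x2)/dt of
    the unperturbed original equations, used as ground truth for the
    unified-form consistency check and as the simulator drift.  Accepts
    scalars or broadcastable arrays of strictly positive densities.
    """
    raw = ep.raw
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if np.any(x1 <= 0) or np.any(x2 <= 0):
        raise InvalidParameterError("population densities must be strictly positive")
    if raw.case is Case.SATURATION:
        denom = 1.0 + raw.A_eff * x1
    else:
        denom = 1.0 + raw.B_eff * x2
    h1 = raw.a - raw.s_eff * x1 - raw.b * x2 / denom
    h2 = -raw.c + raw.f * x1 / denom
    return h1, h2


def g_corrections(ep: EffectiveParams, x1, x2):
    """Residual correction rates (g1, g2) of the unified form.

    Saturation:  g1 = (b̄/f̄)·A_eff·x2·(f̄x1−c)/(1+A_eff·x1),
                 g2 = −A_eff·x1·(f̄x1−c)/(1+A_eff·x1).
    Competition: g1 = −B_eff·x2·(ā−b̄x2)/(1+B_eff·x2),
                 g2 = (f̄/b̄)·B_eff·x1·(ā−b̄x2)/(1+B_eff·x2).

    Both vanish on the equilibrium nullclines x1 = c/f̄ (saturation) and
    x2 = ā/b̄ (competition), and identically when the saturation or
    competition parameter is zero.
    """
    raw = ep.raw
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if raw.case is Case.SATURATION:
        q = (ep.f_bar * x1 - ep.c) / (1.0 + raw.A_eff * x1)
        g1 = (ep.b_bar / ep.f_bar) * raw.A_eff * x2 * q
        g2 = -raw.A_eff * x1 * q
    else:
        q = (ep.a_bar - ep.b_bar * x2) / (1.0 + raw.B_eff * x2)
        g1 = -raw.B_eff * x2 * q
        g2 = (ep.f_bar / ep.b_bar) * raw.B_eff * x1 * q
    return g1, g2


def unified_percapita_drift(ep: EffectiveParams, x1, x2):
    """Per-capita rates evaluated through the unified (barred) form.

    Algebraically identical to :func:`percapita_drift`; kept separate so the
    identity can be asserted numerically.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    g1, g2 = g_corrections(ep, x1, x2)
    s = ep.raw.s_eff
    h1 = ep.a_bar - ep.b_bar * x2 - (s / ep.f_bar) * (-ep.c + ep.f_bar * x1) + g1
    h2 = -ep.c + ep.f_bar * x1 + g2
    return h1, h2
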
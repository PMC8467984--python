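"""Population-density observables derived from the stationary level density.

The stationary joint PDF of the two population densities follows from the
level density p_R and the quasi-period by the orbit-uniformity argument:
conditioned on the level r, the state is distributed along the orbit with
weight dt/T(r), and in log coordinates the level/orbit-time pair is a
canonical change of variables, giving

    p(x1, x2) = p_R(r(x1, x2)) / (T(r(x1, x2)) · x1 · x2).

Marginals are one-dimensional integrals of the joint PDF over the
companion coordinate; moments reuse the tabulated orbit averages
(E[h] = ∫ p_R(r)·⟨h⟩(r) dr), which is both cheaper and better conditioned
than integrating the marginals.  The discrepancy between the perturbation
and Gaussian-approximation marginals is measured by the squared-L2 norm
∫ (p_a − p_b)² dx.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy.integrate import simpson, trapezoid

from .exceptions import AccuracyError, InvalidParameterError
from .gfpk import StationarySolution
from .orbit import OrbitTable, first_integral, level_extents, phi1, phi2

__all__ = [
    "Axis",
    "MarginalPDF",
    "MomentSummary",
    "joint_pdf",
    "marginal_pdf",
    "moments",
    "l2_error",
]


class Axis(str, Enum):
    PREY = "prey"
    PREDATOR = "predator"


@dataclass
class MarginalPDF:
    """A one-dimensional population-density PDF on a positive grid."""

    axis: Axis
    x: np.ndarray
    density: np.ndarray
    provenance: str  # 'perturbation' | 'gaussian' | 'monte_carlo'

    def mass(self) -> float:
        return float(trapezoid(self.density, self.x))

    def peak(self) -> float:
        return float(np.max(self.density))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"axis": self.axis.value, "x": self.x, "density": self.density,
             "provenance": self.provenance}
        )


@dataclass
class MomentSummary:
    """First and second moments plus dimensionless spread measures.

    ``relfluct`` is the coefficient of variation sqrt(Var)/E (the
    dimensionless reading of "relative fluctuation"); ``var_over_mean`` is
    the alternative Var/E reading, exported so either convention can be
    inspected.
    """

    mean_x1: float
    mean_x2: float
    var_x1: float
    var_x2: float
    relfluct_x1: float
    relfluct_x2: float
    var_over_mean_x1: float
    var_over_mean_x2: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def joint_pdf(
    sol: StationarySolution,
    table: OrbitTable,
    x1,
    x2,
    which: str = "perturbation",
):
    """Joint stationary PDF p(x1, x2) = p_R(r)/(T(r)·x1·x2)."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    r = first_integral(table.ep, x1, x2)
    return sol.density(r, which=which) / (table.period(r) * x1 * x2)


def _axis_extents(table: OrbitTable, axis: Axis, r_cut: float):
    x1_lo, x1_hi, x2_lo, x2_hi = level_extents(table.ep, r_cut)
    return (x1_lo, x1_hi) if axis is Axis.PREY else (x2_lo, x2_hi)


def marginal_pdf(
    sol: StationarySolution,
    table: OrbitTable,
    axis: Axis | str,
    x_grid: np.ndarray | None = None,
    n_x: int = 400,
    n_quad: int = 1201,
    which: str = "perturbation",
    r_cut_mass: float = 1e-6,
    check_mass: bool = True,
) -> MarginalPDF:
    """Marginal PDF of one population density.

    The companion coordinate is integrated on a fixed log-spaced Simpson
    grid spanning its extent at the cutoff level r_cut (the level below
    which all but ``r_cut_mass`` of the p_R mass lies); the level density
    evaluates to zero above the tabulated range, so the sharp cutoff only
    discards negligible tail mass.
    """
    axis = Axis(axis)
    ep = table.ep
    r_cut = min(sol.cumulative_level(1.0 - r_cut_mass), table.r_max)
    if x_grid is None:
        lo, hi = _axis_extents(table, axis, r_cut)
        x_grid = np.linspace(lo, hi, n_x)
    comp_axis = Axis.PREDATOR if axis is Axis.PREY else Axis.PREY
    c_lo, c_hi = _axis_extents(table, comp_axis, r_cut)
    y = np.geomspace(c_lo, c_hi, n_quad)

    if axis is Axis.PREY:
        r = phi1(ep, x_grid)[:, None] + phi2(ep, y)[None, :]
    else:
        r = phi2(ep, x_grid)[:, None] + phi1(ep, y)[None, :]
    pr = sol.density(r, which=which)
    integrand = pr / (table.period(r) * x_grid[:, None] * y[None, :])
    density = simpson(integrand, x=y, axis=1)
    out = MarginalPDF(
        axis=axis,
        x=x_grid,
        density=density,
        provenance="perturbation" if which == "perturbation" else "gaussian",
    )
    if check_mass and not 0.99 <= out.mass() <= 1.01:
        raise AccuracyError(
            f"marginal mass {out.mass():.4f} outside [0.99, 1.01] "
            f"(axis={axis.value}, variant={which})"
        )
    return out


def moments(
    sol: StationarySolution,
    table: OrbitTable,
    which: str = "perturbation",
) -> MomentSummary:
    """Moments via the orbit-average route E[h] = ∫ p_R(r)·⟨h⟩(r) dr."""
    r = sol.r_grid
    p = sol.pR if which == "perturbation" else sol.pG
    e = {}
    for name in ("x1", "x2", "x1_sq", "x2_sq"):
        e[name] = float(trapezoid(p * table.average(name, r), r))
    var1 = e["x1_sq"] - e["x1"] ** 2
    var2 = e["x2_sq"] - e["x2"] ** 2
    for v in (var1, var2):
        if v < -1e-10:
            raise AccuracyError(f"negative variance {v:.3g} beyond tolerance")
    var1, var2 = max(var1, 0.0), max(var2, 0.0)
    return MomentSummary(
        mean_x1=e["x1"],
        mean_x2=e["x2"],
        var_x1=var1,
        var_x2=var2,
        relfluct_x1=np.sqrt(var1) / e["x1"],
        relfluct_x2=np.sqrt(var2) / e["x2"],
        var_over_mean_x1=var1 / e["x1"],
        var_over_mean_x2=var2 / e["x2"],
    )


def l2_error(pdf_a: MarginalPDF, pdf_b: MarginalPDF) -> float:
    """Squared-L2 discrepancy ∫ (p_a − p_b)² dx on the union grid."""
    if pdf_a.axis is not pdf_b.axis:
        raise InvalidParameterError("l2_error requires marginals on the same axis")
    if pdf_a.x.shape == pdf_b.x.shape and np.allclose(pdf_a.x, pdf_b.x):
        x = pdf_a.x
        diff = pdf_a.density - pdf_b.density
    else:
        x = np.union1d(pdf_a.x, pdf_b.x)
        x = x[(x >= max(pdf_a.x[0], pdf_b.x[0])) & (x <= min(pdf_a.x[-1], pdf_b.x[-1]))]
        diff = np.interp(x, pdf_a.x, pdf_a.density) - np.interp(x, pdf_b.x, pdf_b.density)
    return float(trapezoid(diff * diff, x))
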
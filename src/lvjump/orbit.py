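"""Level-set geometry and orbit averaging for the Lotka–Volterra core.

The unperturbed unified model (no noise, no self-competition, no
correction rates) is the classic Lotka–Volterra system

    dx1/dt = x1 (ā − b̄ x2),    dx2/dt = x2 (−c + f̄ x1),

whose orbits are the level sets of the first integral

    r(x1, x2) = φ1(x1) + φ2(x2),
    φ1(x) = f̄x − c − c·ln(f̄x/c),     φ2(y) = b̄y − ā − ā·ln(b̄y/ā).

Each φ is strictly convex with minimum 0 at the equilibrium coordinate, so
r >= 0 with equality only at the coexistence point (c/f̄, ā/b̄).  In log
coordinates (u, v) = (ln x1, ln x2) the system is canonical Hamiltonian
with Hamiltonian r, which is why all integrations here run in (u, v):
conservation is excellent and positivity is automatic.

The slow noise-driven drift of r motivates averaging state functions over
one closed orbit ("quasi-period" T(r)).  :func:`trace_orbit` computes
T(r) and the time averages ⟨h⟩(r) = (1/T)∮h dt of arbitrary registered
state functions by integrating around the orbit once with return-section
event detection; :func:`build_orbit_table` tabulates them on a level grid
that is log-dense near r = 0 and attaches interpolants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq

from .exceptions import InvalidParameterError, NumericalError
from .model import EffectiveParams

__all__ = [
    "phi1",
    "phi2",
    "first_integral",
    "harmonic_period",
    "level_extents",
    "trace_orbit",
    "OrbitTable",
    "build_orbit_table",
]

#: callables h(x1, x2) -> value, averaged along orbits
Integrand = Callable[[np.ndarray, np.ndarray], np.ndarray]


def phi1(ep: EffectiveParams, x1):
    """Prey part of the first integral, f̄x1 − c − c·ln(f̄x1/c) >= 0."""
    x1 = np.asarray(x1, dtype=float)
    z = ep.f_bar * x1 / ep.c
    return ep.c * (z - 1.0 - np.log(z))


def phi2(ep: EffectiveParams, x2):
    """Predator part of the first integral, b̄x2 − ā − ā·ln(b̄x2/ā) >= 0."""
    x2 = np.asarray(x2, dtype=float)
    z = ep.b_bar * x2 / ep.a_bar
    return ep.a_bar * (z - 1.0 - np.log(z))


def first_integral(ep: EffectiveParams, x1, x2):
    """First integral r(x1, x2); zero exactly at the coexistence point."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if np.any(x1 <= 0) or np.any(x2 <= 0):
        raise InvalidParameterError("first_integral requires strictly positive state")
    return phi1(ep, x1) + phi2(ep, x2)


def harmonic_period(ep: EffectiveParams) -> float:
    """Small-orbit (linearised) period 2π/sqrt(ā c)."""
    return 2.0 * math.pi / math.sqrt(ep.a_bar * ep.c)


def _convex_roots(value_star: float, coef: float, r: float) -> tuple[float, float]:
    """Roots of coef*(z − 1 − ln z) = r around z = 1, scaled by value_star.

    Used for both φ1 (value_star = c/f̄, coef = c) and φ2.  Returns the
    (lower, upper) roots in the original coordinate.
    """
    # work in z = x/x_star; g(z) = coef*(z - 1 - ln z) - r
    def g(z: float) -> float:
        return coef * (z - 1.0 - math.log(z)) - r

    # upper root: g convex increasing on (1, inf)
    hi = 2.0
    while g(hi) < 0.0:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - absurd level
            raise NumericalError("failed to bracket upper level-curve extent")
    z_hi = brentq(g, 1.0, hi, xtol=1e-300, rtol=1e-15, maxiter=200)
    # lower root: g decreasing towards 1 from the left, -> +inf as z -> 0+
    lo = 0.5
    while g(lo) < 0.0:
        lo *= 0.5
        if lo < 1e-300:  # pragma: no cover
            raise NumericalError("failed to bracket lower level-curve extent")
    z_lo = brentq(g, lo, 1.0, xtol=1e-300, rtol=1e-15, maxiter=200)
    return value_star * z_lo, value_star * z_hi


def level_extents(ep: EffectiveParams, r: float) -> tuple[float, float, float, float]:
    """Extents (x1_min, x1_max, x2_min, x2_max) of the level curve r.

    The four numbers solve φ1(x1_min) = φ1(x1_max) = φ2(x2_min) =
    φ2(x2_max) = r, bracketing the equilibrium coordinates.
    """
    if not r > 0:
        raise InvalidParameterError("level_extents requires r > 0")
    x1_lo, x1_hi = _convex_roots(ep.x1_star, ep.c, float(r))
    x2_lo, x2_hi = _convex_roots(ep.x2_star, ep.a_bar, float(r))
    return x1_lo, x1_hi, x2_lo, x2_hi


def trace_orbit(
    ep: EffectiveParams,
    r: float,
    integrands: list[Integrand] | None = None,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> tuple[float, np.ndarray]:
    """Period T(r) and orbit averages ⟨h⟩(r) for each integrand.

    Integrates the unperturbed system in log coordinates from the section
    point (x1_max(r), ā/b̄), accumulating ∮dt and ∮h dt simultaneously,
    until the first return to the section {x2 = ā/b̄, dx2/dt > 0}.

    Returns
    -------
    (T, averages)
        T is the quasi-period; ``averages[i] = (1/T)∮ h_i dt``.
    """
    integrands = integrands or []
    a_bar, b_bar, c, f_bar = ep.a_bar, ep.b_bar, ep.c, ep.f_bar
    _, x1_max, _, _ = level_extents(ep, r)
    v0 = math.log(ep.x2_star)
    y0 = np.array([math.log(x1_max), v0] + [0.0] * len(integrands))

    def rhs(t, y):
        x1 = math.exp(y[0])
        x2 = math.exp(y[1])
        out = np.empty_like(y)
        out[0] = a_bar - b_bar * x2
        out[1] = -c + f_bar * x1
        for i, h in enumerate(integrands):
            out[2 + i] = h(x1, x2)
        return out

    def section(t, y):
        return y[1] - v0

    section.terminal = True
    section.direction = 1.0

    # The start point lies exactly on the section, which would register a
    # spurious event at t = 0; integrate a short arming segment first (the
    # predator density rises monotonically through the first quarter-orbit,
    # so the section function is safely positive at the hand-over point).
    T0 = harmonic_period(ep)
    delta = 1e-3 * T0
    pre = solve_ivp(rhs, (0.0, delta), y0, method="DOP853", rtol=rtol, atol=atol)
    if not pre.success:  # pragma: no cover - defensive
        raise NumericalError("orbit arming segment failed", diagnostics={"r": r})

    horizon = 50.0 * T0
    sol = solve_ivp(
        rhs,
        (delta, horizon),
        pre.y[:, -1],
        method="DOP853",
        events=section,
        rtol=rtol,
        atol=atol,
        dense_output=False,
    )
    if not sol.success or len(sol.t_events[0]) == 0:
        raise NumericalError(
            "orbit failed to close within the safety horizon",
            diagnostics={"r": r, "horizon": horizon, "status": sol.status},
        )
    T = float(sol.t_events[0][0])
    y_end = sol.y_events[0][0]
    averages = np.asarray(y_end[2:]) / T
    return T, averages


def period_quadrature(ep: EffectiveParams, r: float, epsabs: float = 1e-12) -> float:
    """T(r) by quadrature over the prey coordinate (independent route).

    Evaluates T = ∮ dx1 / (x1(ā − b̄x2)) with the level curve split into
    its lower and upper predator branches and the turning-point square-root
    singularity removed by the substitution x1(θ) = m − h·cosθ.  Retained
    as a cross-check for :func:`trace_orbit`; the time-integration route is
    the production path.
    """
    from scipy.integrate import quad

    x1_lo, x1_hi, _, _ = level_extents(ep, r)
    mid, half = 0.5 * (x1_hi + x1_lo), 0.5 * (x1_hi - x1_lo)
    a_bar, b_bar = ep.a_bar, ep.b_bar

    def x2_branch(x1: float, upper: bool) -> float:
        rem = r - float(phi1(ep, x1))
        rem = max(rem, 0.0)
        if rem == 0.0:
            return ep.x2_star
        lo, hi = _convex_roots(ep.x2_star, a_bar, rem)
        return hi if upper else lo

    def integrand(theta: float) -> float:
        x1 = mid - half * math.cos(theta)
        dx1 = half * math.sin(theta)
        lo = x2_branch(x1, upper=False)
        hi = x2_branch(x1, upper=True)
        # lower branch traversed left->right, upper branch right->left
        return dx1 * (1.0 / (x1 * (a_bar - b_bar * lo)) - 1.0 / (x1 * (a_bar - b_bar * hi)))

    val, _ = quad(integrand, 0.0, math.pi, epsabs=epsabs, epsrel=1e-10, limit=200)
    return val


@dataclass
class OrbitTable:
    """Tabulated per-level quantities: T(r) and registered orbit averages.

    The grid includes the analytic r = 0 node, where T is the harmonic
    limit 2π/sqrt(ā c) and every average equals the integrand evaluated at
    the equilibrium (the orbit degenerates to the point).  Columns are
    interpolated with cubic splines over the full grid.
    """

    ep: EffectiveParams
    r_grid: np.ndarray  # increasing, starts at 0
    T: np.ndarray
    averages: dict[str, np.ndarray]
    _splines: dict[str, CubicSpline] = field(default_factory=dict, repr=False)

    @property
    def r_max(self) -> float:
        return float(self.r_grid[-1])

    def spline(self, name: str) -> CubicSpline:
        """Cubic-spline interpolant of column ``name`` ('T' or an average)."""
        if name not in self._splines:
            col = self.T if name == "T" else self.averages[name]
            self._splines[name] = CubicSpline(self.r_grid, col)
        return self._splines[name]

    def period(self, r) -> np.ndarray:
        """T(r); values below the grid floor use the harmonic limit."""
        r = np.asarray(r, dtype=float)
        return np.asarray(self.spline("T")(np.clip(r, 0.0, self.r_max)))

    def average(self, name: str, r) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        return np.asarray(self.spline(name)(np.clip(r, 0.0, self.r_max)))

    def to_frame(self) -> pd.DataFrame:
        data = {"r": self.r_grid, "T": self.T}
        for name, col in self.averages.items():
            data[f"avg_{name}"] = col
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path, ep: EffectiveParams) -> "OrbitTable":
        df = pd.read_csv(path)
        averages = {
            name[4:]: df[name].to_numpy() for name in df.columns if name.startswith("avg_")
        }
        return cls(ep=ep, r_grid=df["r"].to_numpy(), T=df["T"].to_numpy(), averages=averages)


def build_orbit_table(
    ep: EffectiveParams,
    r_max: float,
    n_levels: int = 160,
    integrands: Mapping[str, Integrand] | None = None,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> OrbitTable:
    """Tabulate T and orbit averages on a log-dense-near-zero level grid.

    The grid is ``n_levels`` log-spaced levels between ``1e-4·ā·c`` and
    ``r_max``, preceded by the analytic r = 0 node.
    """
    if not r_max > 0:
        raise InvalidParameterError("r_max must be positive")
    if n_levels < 50:
        raise InvalidParameterError("n_levels must be at least 50")
    if integrands is None:
        from .averaging import standard_integrands

        integrands = standard_integrands(ep)
    names = list(integrands)
    fns = [integrands[k] for k in names]

    r_lo = 1e-4 * ep.a_bar * ep.c
    r_pos = np.geomspace(r_lo, r_max, n_levels)
    r_grid = np.concatenate([[0.0], r_pos])

    T = np.empty_like(r_grid)
    cols = {k: np.empty_like(r_grid) for k in names}
    # analytic r = 0 node: point orbit at the equilibrium
    T[0] = harmonic_period(ep)
    for k, h in zip(names, fns):
        cols[k][0] = float(h(ep.x1_star, ep.x2_star))
    for j, r in enumerate(r_pos, start=1):
        Tj, avg = trace_orbit(ep, float(r), fns, rtol=rtol, atol=atol)
        T[j] = Tj
        for k, val in zip(names, avg):
            cols[k][j] = val
    return OrbitTable(ep=ep, r_grid=r_grid, T=T, averages=cols)
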
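"""Independent numerical oracles used by the test-suite.

Each oracle recomputes a pipeline quantity by a different route
(finite differences, fixed-step integration, sparse boundary-value
solves) so that agreement is evidence of correctness rather than
repetition.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import trapezoid
from scipy.interpolate import CubicSpline
from scipy.sparse import lil_matrix
from scipy.sparse.linalg import spsolve

from lvjump.model import Case, EffectiveParams, g_corrections
from lvjump.orbit import first_integral, harmonic_period, level_extents


def fd_generator_U0(ep: EffectiveParams, noise, x1: float, x2: float) -> float:
    """Drift of R from the Itô generator with finite-difference derivatives.

    Applies the generator of the correction-drift + Gaussian-diffusion part
    of the stochastic model to R(x1, x2), with first/second derivatives of R
    estimated by Richardson-extrapolated central differences.  The leading
    Lotka–Volterra drift is included as well; it contributes zero because R
    is a first integral, which doubles as a sanity check on the oracle.
    """
    raw = ep.raw

    def R(p1: float, p2: float) -> float:
        return float(first_integral(ep, p1, p2))

    def d1(g, x, h):
        return (g(x + h) - g(x - h)) / (2 * h)

    def d2(g, x, h):
        return (g(x + h) - 2.0 * g(x) + g(x - h)) / (h * h)

    def richardson(d, g, x, h):
        return (4.0 * d(g, x, h / 2) - d(g, x, h)) / 3.0

    g1, g2 = g_corrections(ep, x1, x2)
    s = raw.s_eff
    # full drift of each log-population times the population (Ito form)
    drift1 = x1 * (
        ep.a_bar - ep.b_bar * x2
        - (s / ep.f_bar) * (-ep.c + ep.f_bar * x1)
        + float(g1) + noise.D1
    )
    drift2 = x2 * (-ep.c + ep.f_bar * x1 + float(g2) + noise.D2)

    h1 = 2e-3 * x1
    h2 = 2e-3 * x2
    R1 = richardson(d1, lambda z: R(z, x2), x1, h1)
    R2 = richardson(d1, lambda z: R(x1, z), x2, h2)
    R11 = richardson(d2, lambda z: R(z, x2), x1, h1)
    R22 = richardson(d2, lambda z: R(x1, z), x2, h2)
    return (
        R1 * drift1
        + R2 * drift2
        + 0.5 * R11 * 2.0 * noise.D1 * x1 * x1
        + 0.5 * R22 * 2.0 * noise.D2 * x2 * x2
    )


def rk4_orbit_averages(
    ep: EffectiveParams,
    r: float,
    integrands: list,
    n_periods: int = 10,
    steps_per_period: int = 2500,
) -> tuple[float, np.ndarray]:
    """Period and orbit averages by long fixed-step RK4 integration.

    Integrates the unperturbed flow in log coordinates with a fixed-step
    classical RK4 scheme, counts upward crossings of the predator section,
    and stops at the ``n_periods``-th crossing with the final partial step
    linearly interpolated.  Completely independent of the adaptive
    event-detection route used in production.
    """
    a_bar, b_bar, c, f_bar = ep.a_bar, ep.b_bar, ep.c, ep.f_bar
    _, x1_max, _, _ = level_extents(ep, r)
    v0 = math.log(ep.x2_star)
    u, v = math.log(x1_max), v0
    acc = np.zeros(len(integrands))
    dt = harmonic_period(ep) * (1.0 + r) / steps_per_period  # crude period scale

    def f(u_, v_):
        return a_bar - b_bar * math.exp(v_), -c + f_bar * math.exp(u_)

    def vals(u_, v_):
        x1_, x2_ = math.exp(u_), math.exp(v_)
        return np.array([h(x1_, x2_) for h in integrands])

    t = 0.0
    crossings = 0
    max_steps = steps_per_period * (n_periods + 2) * 60
    for _ in range(max_steps):
        k1u, k1v = f(u, v)
        k2u, k2v = f(u + 0.5 * dt * k1u, v + 0.5 * dt * k1v)
        k3u, k3v = f(u + 0.5 * dt * k2u, v + 0.5 * dt * k2v)
        k4u, k4v = f(u + dt * k3u, v + dt * k3v)
        un = u + (dt / 6) * (k1u + 2 * k2u + 2 * k3u + k4u)
        vn = v + (dt / 6) * (k1v + 2 * k2v + 2 * k3v + k4v)
        # trapezoid accumulation of the integrands
        acc_step = 0.5 * dt * (vals(u, v) + vals(un, vn))
        if t > 0 and v < v0 <= vn and (vn - v) > 0:
            # upward crossing inside this step: linear fraction
            frac = (v0 - v) / (vn - v)
            crossings += 1
            if crossings == n_periods:
                t_cross = t + frac * dt
                acc += frac * acc_step  # proportional share of the step
                return t_cross / n_periods, acc / t_cross
        u, v = un, vn
        t += dt
        acc += acc_step
    raise RuntimeError("RK4 oracle failed to accumulate the requested periods")


def fd_bvp_p0(coeffs, n: int = 4000, r_lo: float = 0.01):
    """p0 by a sparse finite-difference two-point boundary-value solve.

    Discretizes −(Ā₁₁p)' + (1/2)(Ā₂₁p)'' = 0 on a uniform grid with a
    one-sided zero-flux condition at the left edge and p = 0 at the right
    edge, then normalizes to unit mass *on its own domain*.  The left edge
    sits away from the r = 0 singular point of the diffusion coefficient
    (the zero-flux relation holds at every interior level, so it is a
    valid boundary condition anywhere).  Returns (r, p0_fd).
    """
    r = np.linspace(r_lo, coeffs.r_max, n)
    h = r[1] - r[0]
    A11 = coeffs.spline("A11bar")(r)
    A21 = coeffs.spline("A21bar")(r)

    M = lil_matrix((n, n))
    # interior: 0.5*(A21 p)'' - (A11 p)'
    for i in range(1, n - 1):
        M[i, i - 1] = 0.5 * A21[i - 1] / h**2 + A11[i - 1] / (2 * h)
        M[i, i] = -A21[i] / h**2
        M[i, i + 1] = 0.5 * A21[i + 1] / h**2 - A11[i + 1] / (2 * h)
    # left zero flux: A11 p - 0.5 (A21 p)' = 0 with one-sided 2nd-order derivative
    M[0, 0] = A11[0] - 0.5 * (-1.5 * A21[0]) / h
    M[0, 1] = -0.5 * (2.0 * A21[1]) / h
    M[0, 2] = -0.5 * (-0.5 * A21[2]) / h
    # right: p = 0 replaced below by normalization; enforce decay via p[n-1]=0
    M[n - 1, n - 1] = 1.0

    # singular homogeneous system: replace one interior row by normalization
    M = M.tocsr().tolil()
    w = np.full(n, h)
    w[0] = w[-1] = h / 2
    M[n // 2] = w
    b = np.zeros(n)
    b[n // 2] = 1.0
    p = spsolve(M.tocsr(), b)
    p /= trapezoid(p, r)
    return r, p


def fd_bvp_p2(coeffs, sol, n: int = 6000, r_lo: float = 0.01):
    """p2 by a sparse finite-difference boundary-value solve.

    Discretizes the full second-order correction equation
    −(Ā₁₁p₂)' + (1/2)(Ā₂₁p₂)'' = RHS on a uniform grid away from the
    r = 0 singular point, with the RHS derivatives of the coefficient·p₀
    products estimated by repeated second-order finite differences
    (no analytic log-derivative chains anywhere).  Boundary conditions:
    the once-integrated zero-flux relation at the left edge and p₂ = 0 at
    the right edge.  On a sub-domain the global zero-mass condition is not
    expressible, so the returned correction is determined only up to the
    homogeneous direction; moreover the left flux condition cannot pin
    that direction at all (p₀ has identically zero flux), so the discrete
    solve carries an arbitrary multiple of its own *discrete* homogeneous
    solution.  Callers must compare equivalence classes: project the
    difference onto span{p₀, p₀_fd} and inspect the remainder.
    Returns (r, p2_fd, p0_on_r).
    """
    r = np.linspace(r_lo, sol.r_max, n)
    h = r[1] - r[0]
    p0 = CubicSpline(sol.r_grid, sol.p0)(r)
    A11 = coeffs.spline("A11bar")(r)
    A21 = coeffs.spline("A21bar")(r)

    def deriv(f, k):
        out = np.asarray(f, dtype=float)
        for _ in range(k):
            out = np.gradient(out, h, edge_order=2)
        return out

    rhs_full = deriv(coeffs.spline("A12bar")(r) * p0, 1) - 0.5 * deriv(
        coeffs.spline("A22bar")(r) * p0, 2
    ) + deriv(coeffs.spline("A31bar")(r) * p0, 3) / 6.0 - deriv(
        coeffs.spline("A41bar")(r) * p0, 4
    ) / 24.0
    S_left = (
        coeffs.spline("A12bar")(r) * p0
        - 0.5 * deriv(coeffs.spline("A22bar")(r) * p0, 1)
        + deriv(coeffs.spline("A31bar")(r) * p0, 2) / 6.0
        - deriv(coeffs.spline("A41bar")(r) * p0, 3) / 24.0
    )[0]

    M = lil_matrix((n, n))
    b = np.zeros(n)
    for i in range(1, n - 1):
        M[i, i - 1] = 0.5 * A21[i - 1] / h**2 + A11[i - 1] / (2 * h)
        M[i, i] = -A21[i] / h**2
        M[i, i + 1] = 0.5 * A21[i + 1] / h**2 - A11[i + 1] / (2 * h)
        b[i] = rhs_full[i]
    # left edge: −Ā₁₁p₂ + (1/2)(Ā₂₁p₂)' = S (once-integrated relation)
    M[0, 0] = -A11[0] + 0.5 * (-1.5 * A21[0]) / h
    M[0, 1] = 0.5 * (2.0 * A21[1]) / h
    M[0, 2] = 0.5 * (-0.5 * A21[2]) / h
    b[0] = S_left
    M[n - 1, n - 1] = 1.0
    p2 = spsolve(M.tocsr(), b)
    return r, p2, p0
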
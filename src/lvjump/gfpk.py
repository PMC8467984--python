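"""Stationary solution of the averaged GFPK equation by perturbation.

The stationary density p_R(r) of the averaged first-integral process obeys

    0 = −(Ā₁ p)' + (1/2)(Ā₂ p)'' − (1/6)(Ā₃ p)''' + (1/24)(Ā₄ p)'''' ,

with the drift/diffusion split Ā₁ = Ā₁₁ + Ā₁₂, Ā₂ = Ā₂₁ + Ā₂₂ into the
leading (Gaussian-equivalent) pair and the higher-order jump terms.  The
expansion p_R = p₀ + p₂ (the odd-order term vanishes, see below) gives:

* **p₀** — the zero-probability-flux solution of the leading pair,
  ``p₀(r) ∝ exp(∫ 2Ā₁₁/Ā₂₁) / Ā₂₁``.  This is exactly the stationary
  density of the system driven by Gaussian noise of the same total
  intensity: the *Gaussian approximation* p_G.
* **p₂** — the jump correction.  Integrating its equation once in r (the
  integration constant vanishes because everything decays at infinity)
  leaves the first-order linear ODE

      (1/2)Ā₂₁ p₂' + ((1/2)Ā₂₁' − Ā₁₁) p₂ = S(r),
      S = Ā₁₂p₀ − (1/2)(Ā₂₂p₀)' + (1/6)(Ā₃₁p₀)'' − (1/24)(Ā₄₁p₀)''' ,

  solved by variation of constants with p₀ as the homogeneous solution:
  ``p₂ = p₀·(K + ∫ 2S/(Ā₂₁p₀))``.  The admissible homogeneous admixture K
  is fixed by the mass condition ∫p₂ dr = 0.

The odd-order density p₁ solves the same homogeneous equation as p₀ with
the same boundary conditions, so it is a multiple of p₀; the order-matched
normalisation of p_R forces that multiple to zero, hence p₁ ≡ 0.

Boundary conditions are zero probability flux at r → 0⁺ and vanishing
density (with derivatives) at r → ∞ — the standard choice for a
nonnegative first-integral process with an inaccessible boundary.

Numerically, all derivatives of coefficient·p₀ products are expanded via
the *analytic* log-derivative of p₀ (L = p₀'/p₀ = 2Ā₁₁/Ā₂₁ − Ā₂₁'/Ā₂₁)
combined with spline derivatives of the coefficients, which avoids
amplifying grid noise through repeated numeric differentiation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid, trapezoid
from scipy.interpolate import CubicSpline

from .averaging import AveragedCoefficients
from .exceptions import GridExtensionNeeded, ModelRegimeError, NumericalError

__all__ = ["StationarySolution", "solve_p0", "solve_p2", "assemble"]

logger = logging.getLogger(__name__)


def _dense_grid(coeffs: AveragedCoefficients, n_r: int) -> np.ndarray:
    """Log-dense solution grid: the analytic 0 node plus n_r log-spaced nodes."""
    r_pos = coeffs.r_grid[coeffs.r_grid > 0]
    return np.concatenate([[0.0], np.geomspace(r_pos[0], coeffs.r_max, n_r)])


def _is_singular_at_zero(coeffs: AveragedCoefficients) -> bool:
    """True when the diffusion coefficient vanishes at r = 0 (model regime)."""
    a21 = coeffs.A21bar
    return abs(a21[0]) <= 1e-10 * max(np.max(np.abs(a21)), 1e-300)


@dataclass
class StationarySolution:
    """Stationary densities of the first-integral level r.

    ``pG`` is the normalized Gaussian approximation (p₀ alone), ``pR`` the
    normalized second-order perturbation solution p₀ + p₂.  ``p2`` carries
    the (signed) jump correction with ∫p₂ dr = 0.
    """

    r_grid: np.ndarray
    p0: np.ndarray
    p2: np.ndarray
    pR: np.ndarray
    pG: np.ndarray
    kappa: float | None
    diagnostics: dict
    _splines: dict[str, CubicSpline] = field(default_factory=dict, repr=False)

    @property
    def r_max(self) -> float:
        return float(self.r_grid[-1])

    def _density(self, name: str, r) -> np.ndarray:
        if name not in self._splines:
            self._splines[name] = CubicSpline(self.r_grid, getattr(self, name))
        r = np.asarray(r, dtype=float)
        out = np.asarray(self._splines[name](np.clip(r, 0.0, self.r_max)))
        return np.where(r > self.r_max, 0.0, out)

    def density(self, r, which: str = "perturbation") -> np.ndarray:
        """Evaluate pR (``which='perturbation'``) or pG (``'gaussian'``).

        Returns 0 beyond the tabulated range (the tail mass there is below
        the solver's tail tolerance).
        """
        if which == "perturbation":
            return self._density("pR", r)
        if which == "gaussian":
            return self._density("pG", r)
        raise ValueError(f"unknown density variant {which!r}")

    def cumulative_level(self, mass: float) -> float:
        """Smallest level r whose pR mass below it reaches ``mass``."""
        cdf = cumulative_trapezoid(self.pR, self.r_grid, initial=0.0)
        cdf /= cdf[-1]
        idx = int(np.searchsorted(cdf, mass))
        return float(self.r_grid[min(idx, len(self.r_grid) - 1)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"r": self.r_grid, "p0": self.p0, "p2": self.p2, "pR": self.pR, "pG": self.pG}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    def summary(self) -> dict:
        return {
            "kappa": self.kappa,
            "r_max": self.r_max,
            **{k: v for k, v in self.diagnostics.items()},
        }


def solve_p0(
    coeffs: AveragedCoefficients,
    n_r: int = 2400,
    tail_tol: float | None = 1e-8,
) -> tuple[np.ndarray, np.ndarray, float | None, dict]:
    """Normalized zero-flux solution p₀ of the leading drift/diffusion pair.

    Returns ``(r_grid, p0, kappa, diagnostics)``.  ``kappa`` is the
    boundary exponent 2Ā₁₁(0)/Ā₂₁'(0) when the diffusion vanishes at the
    origin (p₀ ~ r^(κ−1) there), else ``None``.

    Raises
    ------
    ModelRegimeError
        If the density is non-normalizable (κ <= 0, or no decay at the
        far end of the grid).
    GridExtensionNeeded
        If the estimated tail mass beyond the grid exceeds ``tail_tol``.
    """
    r = _dense_grid(coeffs, n_r)
    r_pos = r[1:]
    sA11 = coeffs.spline("A11bar")
    sA21 = coeffs.spline("A21bar")
    A11 = sA11(r_pos)
    A21 = sA21(r_pos)
    if np.any(A21 <= 0):
        raise NumericalError("A21bar must be positive on the open level grid")

    diagnostics: dict = {}
    if _is_singular_at_zero(coeffs):
        slope0 = float(sA21.derivative()(0.0))
        if slope0 <= 0:
            raise ModelRegimeError("diffusion coefficient has nonpositive slope at r=0")
        kappa = 2.0 * float(coeffs.A11bar[0]) / slope0
        if kappa <= 0:
            raise ModelRegimeError(
                f"boundary exponent kappa={kappa:.3g} <= 0: stationary density "
                "is not normalizable in this regime"
            )
        # regularized exponent: psi = 2*A11/A21 = kappa/r + psi_reg(r)
        psi_reg = 2.0 * A11 / A21 - kappa / r_pos
        i0 = len(r_pos) // 2
        phi_reg = cumulative_trapezoid(psi_reg, r_pos, initial=0.0)
        phi_reg -= phi_reg[i0]
        log_q = phi_reg + kappa * np.log(r_pos / r_pos[i0])
        log_p0_pos = log_q - np.log(A21)
    else:
        kappa = None
        A11_full = sA11(r)
        A21_full = sA21(r)
        psi = 2.0 * A11_full / A21_full
        phi = cumulative_trapezoid(psi, r, initial=0.0)
        log_p0_full = phi - np.log(A21_full)
        log_p0_pos = log_p0_full[1:]

    p0 = np.empty_like(r)
    if kappa is None:
        shift = np.max(log_p0_full)
        p0[:] = np.exp(log_p0_full - shift)
    else:
        p0[1:] = np.exp(log_p0_pos - np.max(log_p0_pos))
    if kappa is None:
        pass
    elif kappa > 1.05:
        p0[0] = 0.0
    else:
        if kappa < 0.95:
            diagnostics["kappa_warning"] = (
                f"kappa={kappa:.4g} < 1: p0 diverges (integrably) at r=0; "
                "the origin node uses the first-grid-node value"
            )
            logger.warning(diagnostics["kappa_warning"])
        p0[0] = p0[1]

    norm = trapezoid(p0, r)
    if not np.isfinite(norm) or norm <= 0:
        raise ModelRegimeError("p0 normalization failed (non-finite mass)")
    p0 /= norm

    # tail diagnostics: local exponential decay rate at the last node
    dlogp_end = 2.0 * A11[-1] / A21[-1] - float(sA21.derivative()(r[-1])) / A21[-1]
    if dlogp_end >= 0:
        raise ModelRegimeError(
            "p0 is not decaying at the end of the level grid; "
            "no normalizable stationary density (or r_max far too small)"
        )
    tail_mass = p0[-1] / (-dlogp_end)
    diagnostics["tail_mass_estimate"] = float(tail_mass)
    diagnostics["p0_norm_constant"] = float(norm)
    if tail_tol is not None and tail_mass > tail_tol:
        raise GridExtensionNeeded(
            f"estimated p0 tail mass {tail_mass:.3g} beyond r_max={r[-1]:.3g} "
            f"exceeds {tail_tol:.1g}",
            suggested_r_max=float(r[-1]) * 1.6,
        )
    return r, p0, kappa, diagnostics


def _log_derivative_terms(coeffs: AveragedCoefficients, r_pos: np.ndarray):
    """L = p0'/p0 and its first two derivatives on the positive grid."""
    sA11 = coeffs.spline("A11bar")
    sA21 = coeffs.spline("A21bar")
    A11, dA11, d2A11 = sA11(r_pos), sA11(r_pos, 1), sA11(r_pos, 2)
    A21 = sA21(r_pos)
    dA21, d2A21, d3A21 = sA21(r_pos, 1), sA21(r_pos, 2), sA21(r_pos, 3)
    N = 2.0 * A11 - dA21
    dN = 2.0 * dA11 - d2A21
    d2N = 2.0 * d2A11 - d3A21
    L = N / A21
    dL = dN / A21 - N * dA21 / A21**2
    d2L = (
        d2N / A21
        - 2.0 * dN * dA21 / A21**2
        - N * d2A21 / A21**2
        + 2.0 * N * dA21**2 / A21**3
    )
    return A21, L, dL, d2L


def solve_p2(
    coeffs: AveragedCoefficients,
    r_grid: np.ndarray,
    p0: np.ndarray,
) -> np.ndarray:
    """Signed jump correction p₂ on the p₀ grid, with ∫p₂ dr = 0.

    Implements the variation-of-constants construction described in the
    module docstring.  The ratio S/p₀ is evaluated analytically (derivative
    chains through L = p₀'/p₀), so the computation stays well-conditioned
    where p₀ underflows.
    """
    r_pos = r_grid[1:]
    A21, L, dL, d2L = _log_derivative_terms(coeffs, r_pos)

    # S/p0 assembled from (G·p0)^(k)/p0 chains
    def chain1(G, dG):
        return dG + G * L

    def chain2(G, dG, d2G):
        return d2G + 2.0 * dG * L + G * (dL + L * L)

    def chain3(G, dG, d2G, d3G):
        return (
            d3G
            + 3.0 * d2G * L
            + 3.0 * dG * (dL + L * L)
            + G * (d2L + 3.0 * L * dL + L**3)
        )

    s12 = coeffs.spline("A12bar")
    s22 = coeffs.spline("A22bar")
    s31 = coeffs.spline("A31bar")
    s41 = coeffs.spline("A41bar")
    S_over_p0 = (
        s12(r_pos)
        - 0.5 * chain1(s22(r_pos), s22(r_pos, 1))
        + chain2(s31(r_pos), s31(r_pos, 1), s31(r_pos, 2)) / 6.0
        - chain3(s41(r_pos), s41(r_pos, 1), s41(r_pos, 2), s41(r_pos, 3)) / 24.0
    )
    if not np.all(np.isfinite(S_over_p0)):
        raise NumericalError(
            "non-finite inhomogeneity in the jump-correction equation",
            diagnostics={"n_bad": int(np.sum(~np.isfinite(S_over_p0)))},
        )

    dw = 2.0 * S_over_p0 / A21
    w = cumulative_trapezoid(dw, r_pos, initial=0.0)
    w_full = np.concatenate([[w[0]], w])  # constant continuation onto the 0 node
    # homogeneous admixture K·p0 fixed by zero total mass of p2
    mass_p0 = trapezoid(p0, r_grid)
    K = -trapezoid(p0 * w_full, r_grid) / mass_p0
    return p0 * (w_full + K)


def assemble(
    coeffs: AveragedCoefficients,
    n_r: int = 2400,
    tail_tol: float | None = 1e-8,
) -> StationarySolution:
    """Full second-order stationary solution (p₀, p₂, p_R, p_G)."""
    r, p0, kappa, diagnostics = solve_p0(coeffs, n_r=n_r, tail_tol=tail_tol)
    if np.all(coeffs.A12bar == 0) and np.all(coeffs.A41bar == 0):
        p2 = np.zeros_like(p0)  # pure-Gaussian reduction
    else:
        p2 = solve_p2(coeffs, r, p0)
    residual_mass = trapezoid(p2, r)
    diagnostics["p2_mass_residual"] = float(residual_mass)

    pR = p0 + p2
    norm = trapezoid(pR, r)
    pR = pR / norm
    neg = np.clip(-pR, 0.0, None)
    neg_mass = trapezoid(neg, r) / trapezoid(np.abs(pR), r)
    diagnostics["pR_negative_mass_fraction"] = float(neg_mass)
    if neg_mass > 1e-4:
        logger.warning(
            "perturbation density has negative mass fraction %.3g "
            "(retained, not clipped)",
            neg_mass,
        )
    return StationarySolution(
        r_grid=r, p0=p0, p2=p2, pR=pR, pG=p0, kappa=kappa, diagnostics=diagnostics
    )
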
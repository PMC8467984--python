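"""Averaged drift/diffusion/jump coefficients of the first-integral process.

Under weak combined Gaussian and Poisson white noise (acting on the prey
growth rate and the predator death rate), the first integral R(t) drifts
slowly; averaging its generator over one unperturbed orbit yields a scalar
generalized Fokker–Planck–Kolmogorov (GFPK) equation in r whose
coefficients are the orbit averages assembled here:

    Ā₁₁(r) = ⟨U0⟩ + ⟨A12⟩ λ₁m₁ + ⟨A22⟩ λ₂m₂              (drift)
    Ā₂₁(r) = ⟨A11²⟩ (2D₁+λ₁m₁) + ⟨A21²⟩ (2D₂+λ₂m₂)        (diffusion)
    Ā₁₂(r) = 3m₁²λ₁ ⟨A14⟩ + 3m₂²λ₂ ⟨A24⟩                  (jump drift)
    Ā₂₂(r) = 3m₁²λ₁ ⟨A12²+2A11A13⟩ + 3m₂²λ₂ ⟨A22²+2A21A23⟩
    Ā₃₁(r) = 3m₁²λ₁ ⟨3A11²A12⟩ + 3m₂²λ₂ ⟨3A21²A22⟩
    Ā₄₁(r) = 3m₁²λ₁ ⟨A11⁴⟩ + 3m₂²λ₂ ⟨A21⁴⟩

where A1k, A2k are the Taylor coefficients of the jump response of R
(a jump multiplies a population by e^Y, so ΔR expands in powers of the
jump magnitude), mᵢ is the effective jump-magnitude variance, and the
fourth moments are 3mᵢ² because magnitudes are zero-mean Gaussian.  U0 is
the order-matched drift correction of R produced by self-competition, the
unified-form residual rates g1/g2, and the Wong–Zakai/Itô terms of the
Gaussian noise.

All quantities are *effective*: the formal perturbation parameter is
absorbed into s_eff, A_eff/B_eff, Dᵢ and mᵢ, exactly as they would be
quoted for a concrete ecosystem.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .exceptions import ConfigurationError, InvalidParameterError
from .model import EffectiveParams, g_corrections
from .orbit import OrbitTable

__all__ = [
    "NoiseParams",
    "jump_polynomials",
    "drift_correction_U0",
    "standard_integrands",
    "AveragedCoefficients",
    "coefficient_functions",
]

#: orbit-average columns required by :func:`coefficient_functions`
REQUIRED_INTEGRANDS = (
    "x1",
    "x2",
    "x1_sq",
    "x2_sq",
    "u0_sg",
    "a11_sq",
    "a21_sq",
    "a11_p4",
    "a21_p4",
    "jump2_1",
    "jump2_2",
    "jump3_1",
    "jump3_2",
)


@dataclass(frozen=True)
class NoiseParams:
    """Effective noise parameters.

    Parameters
    ----------
    D1, D2
        Effective Gaussian *half*-intensities (the autocorrelation of each
        Gaussian forcing is ``2·Dᵢ·δ(τ)``; parameter sets in the ecology
        literature often quote the full intensity ``2Dᵢ`` — use
        :meth:`from_printed` for that convention).
    lam1, lam2
        Poisson mean arrival rates (jumps per unit time, >= 0).
    m1, m2
        Effective jump-magnitude variances E[Y²] (>= 0).  Magnitudes are
        zero-mean Gaussian, so fourth moments are ``3·mᵢ²`` throughout.
    """

    D1: float = 0.0
    D2: float = 0.0
    lam1: float = 0.0
    lam2: float = 0.0
    m1: float = 0.0
    m2: float = 0.0

    def __post_init__(self) -> None:
        for name in ("D1", "D2", "lam1", "lam2", "m1", "m2"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"noise parameter '{name}' must be >= 0")

    @classmethod
    def from_printed(
        cls,
        two_D: tuple[float, float] = (0.0, 0.0),
        lam: tuple[float, float] = (0.0, 0.0),
        jump_var: tuple[float, float] = (0.0, 0.0),
    ) -> "NoiseParams":
        """Build from the quoted-convention Gaussian intensities ``2Dᵢ``."""
        return cls(
            D1=0.5 * two_D[0],
            D2=0.5 * two_D[1],
            lam1=lam[0],
            lam2=lam[1],
            m1=jump_var[0],
            m2=jump_var[1],
        )

    @property
    def intensity1(self) -> float:
        """Total effective intensity of channel 1, 2D₁ + λ₁m₁."""
        return 2.0 * self.D1 + self.lam1 * self.m1

    @property
    def intensity2(self) -> float:
        return 2.0 * self.D2 + self.lam2 * self.m2

    @property
    def is_pure_gaussian(self) -> bool:
        return self.lam1 * self.m1 == 0.0 and self.lam2 * self.m2 == 0.0


def jump_polynomials(ep: EffectiveParams, x1, x2) -> dict[str, np.ndarray]:
    """Taylor coefficients A11..A24 of the jump response of R.

    A type-1 jump sends x1 -> x1·e^Y, so ΔR = f̄x1(e^Y − 1) − cY expands as
    A11·Y + A12·Y² + A13·Y³ + A14·Y⁴ + ... with A11 = f̄x1 − c and
    A1k = f̄x1/k! for k >= 2; analogously for the predator channel.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    fx1 = ep.f_bar * x1
    bx2 = ep.b_bar * x2
    return {
        "A11": fx1 - ep.c,
        "A12": fx1 / 2.0,
        "A13": fx1 / 6.0,
        "A14": fx1 / 24.0,
        "A21": bx2 - ep.a_bar,
        "A22": bx2 / 2.0,
        "A23": bx2 / 6.0,
        "A24": bx2 / 24.0,
    }


def drift_correction_U0(ep: EffectiveParams, noise: NoiseParams, x1, x2):
    """Order-matched drift of R from the continuous (non-jump) corrections.

    U0 = (f̄x1−c)·[−(s_eff/f̄)(f̄x1−c) + g1 + D1] + c·D1
       + (b̄x2−ā)·[g2 + D2] + ā·D2.

    Equals the Itô generator of the correction drift and Gaussian diffusion
    applied to R(x1, x2); the test-suite verifies this against a
    finite-difference generator.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    g1, g2 = g_corrections(ep, x1, x2)
    a11 = ep.f_bar * x1 - ep.c
    a21 = ep.b_bar * x2 - ep.a_bar
    s = ep.raw.s_eff
    return (
        a11 * (-(s / ep.f_bar) * a11 + g1 + noise.D1)
        + ep.c * noise.D1
        + a21 * (g2 + noise.D2)
        + ep.a_bar * noise.D2
    )


def standard_integrands(ep: EffectiveParams) -> dict[str, Callable]:
    """The noise-independent state functions the averaged coefficients need.

    ``u0_sg`` is the noise-free part of U0 (self-competition plus g-rates);
    the Gaussian D-terms of ⟨U0⟩ reduce analytically to
    ``D1·f̄⟨x1⟩ + D2·b̄⟨x2⟩`` and are added in
    :func:`coefficient_functions`, which keeps one orbit table valid for
    every noise setting.
    """
    f_bar, b_bar, c, a_bar = ep.f_bar, ep.b_bar, ep.c, ep.a_bar
    s = ep.raw.s_eff

    def u0_sg(x1, x2):
        g1, g2 = g_corrections(ep, x1, x2)
        a11 = f_bar * x1 - c
        a21 = b_bar * x2 - a_bar
        return a11 * (-(s / f_bar) * a11 + g1) + a21 * g2

    return {
        "x1": lambda x1, x2: x1,
        "x2": lambda x1, x2: x2,
        "x1_sq": lambda x1, x2: x1 * x1,
        "x2_sq": lambda x1, x2: x2 * x2,
        "u0_sg": u0_sg,
        "a11_sq": lambda x1, x2: (f_bar * x1 - c) ** 2,
        "a21_sq": lambda x1, x2: (b_bar * x2 - a_bar) ** 2,
        "a11_p4": lambda x1, x2: (f_bar * x1 - c) ** 4,
        "a21_p4": lambda x1, x2: (b_bar * x2 - a_bar) ** 4,
        # A12² + 2·A11·A13 and the predator analogue
        "jump2_1": lambda x1, x2: (f_bar * x1 / 2.0) ** 2
        + 2.0 * (f_bar * x1 - c) * (f_bar * x1 / 6.0),
        "jump2_2": lambda x1, x2: (b_bar * x2 / 2.0) ** 2
        + 2.0 * (b_bar * x2 - a_bar) * (b_bar * x2 / 6.0),
        # 3·A11²·A12 and the predator analogue
        "jump3_1": lambda x1, x2: 3.0 * (f_bar * x1 - c) ** 2 * (f_bar * x1 / 2.0),
        "jump3_2": lambda x1, x2: 3.0 * (b_bar * x2 - a_bar) ** 2 * (b_bar * x2 / 2.0),
    }


@dataclass
class AveragedCoefficients:
    """Averaged GFPK coefficients on the level grid, with interpolants.

    ``A11bar``/``A21bar`` are the leading drift/diffusion pair; ``A12bar``,
    ``A22bar``, ``A31bar`` and ``A41bar`` are the higher-order jump-noise
    contributions (all identically zero for pure Gaussian forcing).
    """

    r_grid: np.ndarray
    A11bar: np.ndarray
    A12bar: np.ndarray
    A21bar: np.ndarray
    A22bar: np.ndarray
    A31bar: np.ndarray
    A41bar: np.ndarray
    _splines: dict[str, CubicSpline] = field(default_factory=dict, repr=False)

    NAMES = ("A11bar", "A12bar", "A21bar", "A22bar", "A31bar", "A41bar")

    @property
    def A1bar(self) -> np.ndarray:
        """Total averaged drift Ā₁ = Ā₁₁ + Ā₁₂."""
        return self.A11bar + self.A12bar

    @property
    def r_max(self) -> float:
        return float(self.r_grid[-1])

    def spline(self, name: str) -> CubicSpline:
        if name not in self._splines:
            self._splines[name] = CubicSpline(self.r_grid, getattr(self, name))
        return self._splines[name]

    def to_frame(self) -> pd.DataFrame:
        data = {"r": self.r_grid}
        for name in self.NAMES:
            data[name] = getattr(self, name)
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


def coefficient_functions(
    ep: EffectiveParams, noise: NoiseParams, table: OrbitTable
) -> AveragedCoefficients:
    """Assemble the averaged coefficients from an orbit table and noise set."""
    missing = [k for k in REQUIRED_INTEGRANDS if k not in table.averages]
    if missing:
        raise ConfigurationError(
            f"orbit table lacks required averaged integrands: {missing}"
        )
    avg = table.averages
    f_bar, b_bar, c, a_bar = ep.f_bar, ep.b_bar, ep.c, ep.a_bar
    D1, D2 = noise.D1, noise.D2
    lm1, lm2 = noise.lam1 * noise.m1, noise.lam2 * noise.m2
    # fourth-moment weights λᵢ·E[Yᵢ⁴] = 3·mᵢ²·λᵢ (Gaussian magnitudes)
    w4_1 = 3.0 * noise.m1**2 * noise.lam1
    w4_2 = 3.0 * noise.m2**2 * noise.lam2

    mean_U0 = avg["u0_sg"] + D1 * f_bar * avg["x1"] + D2 * b_bar * avg["x2"]
    A11bar = mean_U0 + 0.5 * f_bar * avg["x1"] * lm1 + 0.5 * b_bar * avg["x2"] * lm2
    A12bar = w4_1 * f_bar * avg["x1"] / 24.0 + w4_2 * b_bar * avg["x2"] / 24.0
    A21bar = avg["a11_sq"] * (2.0 * D1 + lm1) + avg["a21_sq"] * (2.0 * D2 + lm2)
    A22bar = w4_1 * avg["jump2_1"] + w4_2 * avg["jump2_2"]
    A31bar = w4_1 * avg["jump3_1"] + w4_2 * avg["jump3_2"]
    A41bar = w4_1 * avg["a11_p4"] + w4_2 * avg["a21_p4"]
    return AveragedCoefficients(
        r_grid=np.array(table.r_grid, copy=True),
        A11bar=A11bar,
        A12bar=A12bar,
        A21bar=A21bar,
        A22bar=A22bar,
        A31bar=A31bar,
        A41bar=A41bar,
    )
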
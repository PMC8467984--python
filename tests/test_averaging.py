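"""Tests of the averaged GFPK coefficients against independent oracles."""

import numpy as np
import pytest

from lvjump import (
    ConfigurationError,
    NoiseParams,
    coefficient_functions,
    drift_correction_U0,
    jump_polynomials,
    standard_integrands,
)
from lvjump.orbit import OrbitTable

from conftest import random_valid_params
from oracles import fd_generator_U0, rk4_orbit_averages
from lvjump import make_effective_params


class TestJumpPolynomials:
    def test_vanishing_linear_terms_at_equilibrium(self, ep_case1):
        A = jump_polynomials(ep_case1, ep_case1.x1_star, ep_case1.x2_star)
        assert A["A11"] == pytest.approx(0.0, abs=1e-15)
        assert A["A21"] == pytest.approx(0.0, abs=1e-15)
        assert A["A12"] == pytest.approx(ep_case1.c / 2.0, rel=1e-15)
        assert A["A22"] == pytest.approx(ep_case1.a_bar / 2.0, rel=1e-15)

    def test_taylor_factor_ratios(self, ep_case1, rng):
        x1 = rng.uniform(0.2, 3.0, 20)
        x2 = rng.uniform(0.2, 3.0, 20)
        A = jump_polynomials(ep_case1, x1, x2)
        assert np.allclose(A["A13"] / A["A12"], 1.0 / 3.0, rtol=1e-14)
        assert np.allclose(A["A14"] / A["A12"], 1.0 / 12.0, rtol=1e-14)
        assert np.allclose(A["A23"] / A["A22"], 1.0 / 3.0, rtol=1e-14)

    def test_explicit_value(self, ep_case1):
        A = jump_polynomials(ep_case1, 1.2, 0.8)
        assert A["A11"] == pytest.approx(0.475 * 1.2 - 0.5, rel=1e-14)


class TestDriftCorrectionU0:
    def test_identically_zero_without_perturbations(self):
        from lvjump import RawModelParams

        raw = RawModelParams(case="saturation", a=1.0, b=1.0, c=0.5, f=0.5)
        ep = make_effective_params(raw)
        noise = NoiseParams()
        assert drift_correction_U0(ep, noise, 1.3, 0.7) == 0.0

    def test_equilibrium_value_is_ito_constant(self, ep_case1, noise_jump1):
        val = drift_correction_U0(ep_case1, noise_jump1, ep_case1.x1_star, ep_case1.x2_star)
        expected = ep_case1.c * noise_jump1.D1 + ep_case1.a_bar * noise_jump1.D2
        assert val == pytest.approx(expected, rel=1e-13)

    @pytest.mark.parametrize("case", ["saturation", "competition"])
    def test_against_finite_difference_generator(self, case, rng):
        """U0 must equal the Itô generator of the correction dynamics
        applied to the first integral R."""
        noise = NoiseParams(D1=0.0007, D2=0.0004)
        for _ in range(5):
            raw = random_valid_params(rng, case)
            ep = make_effective_params(raw)
            x1 = float(rng.uniform(0.4, 2.5))
            x2 = float(rng.uniform(0.4, 2.5))
            u0 = float(drift_correction_U0(ep, noise, x1, x2))
            u0_fd = fd_generator_U0(ep, noise, x1, x2)
            assert abs(u0 - u0_fd) <= 1e-8 * (1.0 + abs(u0))


class TestCoefficientFunctions:
    def test_pure_gaussian_reduction(self, ep_case1, table_case1):
        noise = NoiseParams(D1=0.0025, D2=0.0025)
        coeffs = coefficient_functions(ep_case1, noise, table_case1)
        for name in ("A12bar", "A22bar", "A31bar", "A41bar"):
            assert np.all(getattr(coeffs, name) == 0.0)
        assert np.all(coeffs.A21bar[1:] > 0)

    def test_coefficients_vanish_at_zero_level(self, coeffs_case1):
        assert coeffs_case1.A21bar[0] == pytest.approx(0.0, abs=1e-14)
        assert coeffs_case1.A41bar[0] == pytest.approx(0.0, abs=1e-14)
        assert coeffs_case1.A31bar[0] == pytest.approx(0.0, abs=1e-14)

    def test_missing_integrand_is_configuration_error(self, ep_case1, noise_jump1, table_case1):
        crippled = OrbitTable(
            ep=table_case1.ep,
            r_grid=table_case1.r_grid,
            T=table_case1.T,
            averages={"x1": table_case1.averages["x1"]},
        )
        with pytest.raises(ConfigurationError, match="u0_sg"):
            coefficient_functions(ep_case1, noise_jump1, crippled)

    def test_diffusion_depends_only_on_total_intensities(self, ep_case1, table_case1):
        """Trading Gaussian for Poisson intensity at fixed 2D + λm leaves
        Ā₂₁ invariant (and Ā₁₁ too when the D-terms of ⟨U0⟩ are matched)."""
        total = 0.009
        mixes = [
            NoiseParams(D1=total / 2, D2=total / 2),  # pure Gaussian
            NoiseParams(D1=0.0005, D2=0.0005, lam1=0.1, lam2=0.1, m1=0.08, m2=0.08),
            NoiseParams(lam1=0.3, lam2=0.3, m1=total / 0.3, m2=total / 0.3),
        ]
        ref = coefficient_functions(ep_case1, mixes[0], table_case1)
        for noise in mixes[1:]:
            assert noise.intensity1 == pytest.approx(total)
            other = coefficient_functions(ep_case1, noise, table_case1)
            assert np.allclose(other.A21bar, ref.A21bar, rtol=1e-13)

    def test_higher_coefficients_scale_in_rate_and_magnitude(
        self, ep_case1, table_case1
    ):
        base = NoiseParams(lam1=0.2, lam2=0.2, m1=0.05, m2=0.05)
        c0 = coefficient_functions(ep_case1, base, table_case1)
        double_rate = NoiseParams(lam1=0.4, lam2=0.4, m1=0.05, m2=0.05)
        c1 = coefficient_functions(ep_case1, double_rate, table_case1)
        double_mag = NoiseParams(lam1=0.2, lam2=0.2, m1=0.1, m2=0.1)
        c2 = coefficient_functions(ep_case1, double_mag, table_case1)
        for name in ("A12bar", "A22bar", "A31bar", "A41bar"):
            assert np.allclose(getattr(c1, name), 2.0 * getattr(c0, name), rtol=1e-13)
            assert np.allclose(getattr(c2, name), 4.0 * getattr(c0, name), rtol=1e-13)

    @pytest.mark.parametrize("r", [0.02, 0.1, 0.4, 1.0, 2.0])
    def test_against_long_rk4_orbit_averaging(
        self, ep_case1, noise_jump1, coeffs_case1, r
    ):
        """Every averaged coefficient must match a long fixed-step RK4
        time-average of its integrand along the unperturbed orbit."""
        ep, noise = ep_case1, noise_jump1
        reg = standard_integrands(ep)
        names = list(reg)
        _, avg = rk4_orbit_averages(ep, r, [reg[k] for k in names])
        avg = dict(zip(names, avg))
        lm1, lm2 = noise.lam1 * noise.m1, noise.lam2 * noise.m2
        w4_1 = 3.0 * noise.m1**2 * noise.lam1
        w4_2 = 3.0 * noise.m2**2 * noise.lam2
        expected = {
            "A11bar": avg["u0_sg"]
            + noise.D1 * ep.f_bar * avg["x1"]
            + noise.D2 * ep.b_bar * avg["x2"]
            + 0.5 * ep.f_bar * avg["x1"] * lm1
            + 0.5 * ep.b_bar * avg["x2"] * lm2,
            "A12bar": w4_1 * ep.f_bar * avg["x1"] / 24.0
            + w4_2 * ep.b_bar * avg["x2"] / 24.0,
            "A21bar": avg["a11_sq"] * (2 * noise.D1 + lm1)
            + avg["a21_sq"] * (2 * noise.D2 + lm2),
            "A22bar": w4_1 * avg["jump2_1"] + w4_2 * avg["jump2_2"],
            "A31bar": w4_1 * avg["jump3_1"] + w4_2 * avg["jump3_2"],
            "A41bar": w4_1 * avg["a11_p4"] + w4_2 * avg["a21_p4"],
        }
        for name, want in expected.items():
            got = float(coeffs_case1.spline(name)(r))
            assert got == pytest.approx(want, rel=5e-3), name
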
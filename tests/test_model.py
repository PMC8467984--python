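"""Unit and property tests for the deterministic models and unified form."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lvjump import (
    Case,
    InvalidParameterError,
    RawModelParams,
    g_corrections,
    make_effective_params,
    percapita_drift,
    unified_percapita_drift,
)

from conftest import random_valid_params


class TestEffectiveParams:
    def test_saturation_collapses_when_A_zero(self):
        ep = make_effective_params(
            RawModelParams(case="saturation", a=1.0, b=1.0, c=0.5, f=0.5, s_eff=0.1)
        )
        assert ep.f_bar == 0.5
        assert ep.b_bar == 1.0
        assert ep.a_bar == pytest.approx(0.9, abs=1e-15)

    def test_saturation_barred_values(self):
        ep = make_effective_params(
            RawModelParams(
                case="saturation", a=1.0, b=1.0, c=0.5, f=0.5, s_eff=0.1, A_eff=0.05
            )
        )
        assert ep.f_bar == pytest.approx(0.475, abs=1e-15)
        assert ep.b_bar == pytest.approx(0.95, abs=1e-15)
        assert ep.a_bar == pytest.approx(1.0 - 0.05 / 0.475, rel=1e-14)

    def test_competition_fixed_point_residuals(self):
        raw = RawModelParams(
            case="competition", a=1.0, b=1.0, c=0.5, f=0.5, s_eff=0.08, B_eff=0.05
        )
        ep = make_effective_params(raw)
        for res in ep.competition_residuals():
            assert abs(res) <= 1e-12

    def test_competition_matches_damped_fixed_point_iteration(self):
        raw = RawModelParams(
            case="competition", a=1.0, b=1.0, c=0.5, f=0.5, s_eff=0.08, B_eff=0.05
        )
        ep = make_effective_params(raw)
        # independent oracle: damped fixed-point iteration on (a_bar, b_bar, f_bar)
        a_bar, b_bar, f_bar = raw.a, raw.b, raw.f
        for _ in range(2000):
            a_new = raw.a - raw.s_eff * raw.c / f_bar
            b_new = raw.b - a_new * raw.B_eff
            f_new = raw.f * b_new / (b_new + a_new * raw.B_eff)
            a_bar = 0.5 * a_bar + 0.5 * a_new
            b_bar = 0.5 * b_bar + 0.5 * b_new
            f_bar = 0.5 * f_bar + 0.5 * f_new
        assert ep.a_bar == pytest.approx(a_bar, rel=1e-13)
        assert ep.b_bar == pytest.approx(b_bar, rel=1e-13)
        assert ep.f_bar == pytest.approx(f_bar, rel=1e-13)

    def test_competition_limit_B_zero(self):
        raw = RawModelParams(case="competition", a=1.0, b=1.2, c=0.5, f=0.5, s_eff=0.1)
        ep = make_effective_params(raw)
        assert ep.b_bar == raw.b
        assert ep.f_bar == raw.f
        assert ep.a_bar == pytest.approx(raw.a - raw.s_eff * raw.c / raw.f, rel=1e-15)

    @pytest.mark.parametrize(
        "kwargs, name",
        [
            (dict(case="saturation", a=-1.0, b=1, c=0.5, f=0.5), "a"),
            (dict(case="saturation", a=1.0, b=1, c=0.5, f=0.5, s_eff=-0.1), "s_eff"),
            (dict(case="saturation", a=1.0, b=1, c=0.5, f=0.5, A_eff=1.1), "f_bar"),
            (dict(case="saturation", a=1.0, b=1, c=0.5, f=0.5, B_eff=0.1), "B_eff"),
            (dict(case="competition", a=1.0, b=1, c=0.5, f=0.5, A_eff=0.1), "A_eff"),
        ],
    )
    def test_invalid_parameters_name_the_offender(self, kwargs, name):
        with pytest.raises(InvalidParameterError, match=name):
            make_effective_params(RawModelParams(**kwargs))

    def test_nonpositive_effective_growth_is_rejected(self):
        # huge self-competition drives a_bar <= 0
        raw = RawModelParams(
            case="saturation", a=0.1, b=1.0, c=1.0, f=0.5, s_eff=0.5
        )
        with pytest.raises(InvalidParameterError, match="a_bar"):
            make_effective_params(raw)


class TestDriftAndCorrections:
    def test_classic_lv_equilibrium_has_zero_drift(self):
        raw = RawModelParams(case="saturation", a=1.0, b=1.0, c=0.5, f=0.5)
        ep = make_effective_params(raw)
        h1, h2 = percapita_drift(ep, raw.c / raw.f, raw.a / raw.b)
        assert abs(h1) < 1e-15 and abs(h2) < 1e-15

    def test_saturation_rates_at_unit_state(self):
        raw = RawModelParams(
            case="saturation", a=1.0, b=1.0, c=0.5, f=0.5, s_eff=0.1, A_eff=0.05
        )
        ep = make_effective_params(raw)
        h1, h2 = percapita_drift(ep, 1.0, 1.0)
        assert h1 == pytest.approx(1.0 - 0.1 - 1.0 / 1.05, rel=1e-14)
        assert h2 == pytest.approx(-0.5 + 0.5 / 1.05, rel=1e-14)

    def test_corrections_vanish_on_nullclines(self, ep_case1, ep_case2):
        g1, g2 = g_corrections(ep_case1, ep_case1.x1_star, 1.7)
        assert abs(g1) < 1e-15 and abs(g2) < 1e-15
        g1, g2 = g_corrections(ep_case2, 1.7, ep_case2.x2_star)
        assert abs(g1) < 1e-15 and abs(g2) < 1e-15

    def test_corrections_vanish_without_saturation(self):
        raw = RawModelParams(case="saturation", a=1.0, b=1.0, c=0.5, f=0.5, s_eff=0.1)
        ep = make_effective_params(raw)
        g1, g2 = g_corrections(ep, 1.3, 0.7)
        assert g1 == 0.0 and g2 == 0.0

    @pytest.mark.parametrize("case", ["saturation", "competition"])
    def test_unified_form_identity_random_draws(self, case, rng):
        """The barred reparametrisation must reproduce the original
        per-capita rates identically (pins down the b̄ = b·f̄/f choice)."""
        for _ in range(20):
            raw = random_valid_params(rng, case)
            ep = make_effective_params(raw)
            x1 = rng.uniform(0.05, 4.0, size=50)
            x2 = rng.uniform(0.05, 4.0, size=50)
            h1, h2 = percapita_drift(ep, x1, x2)
            u1, u2 = unified_percapita_drift(ep, x1, x2)
            assert np.all(np.abs(h1 - u1) <= 1e-12 * (1.0 + np.abs(h1)))
            assert np.all(np.abs(h2 - u2) <= 1e-12 * (1.0 + np.abs(h2)))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        a=st.floats(0.5, 2.0),
        c=st.floats(0.2, 1.0),
        s=st.floats(0.0, 0.2),
        sat=st.floats(0.0, 0.7),
        x1=st.floats(0.05, 4.0),
        x2=st.floats(0.05, 4.0),
        case=st.sampled_from([Case.SATURATION, Case.COMPETITION]),
    )
    def test_unified_form_identity_property(self, a, c, s, sat, x1, x2, case):
        kwargs = dict(case=case, a=a, b=1.0, c=c, f=0.8, s_eff=s)
        if case is Case.SATURATION:
            kwargs["A_eff"] = sat * 0.8 / c  # keeps f_bar positive
        else:
            kwargs["B_eff"] = sat * 0.3
        try:
            ep = make_effective_params(RawModelParams(**kwargs))
        except InvalidParameterError:
            return  # draw outside the admissible regime
        h1, h2 = percapita_drift(ep, x1, x2)
        u1, u2 = unified_percapita_drift(ep, x1, x2)
        assert abs(h1 - u1) <= 1e-12 * (1.0 + abs(h1))
        assert abs(h2 - u2) <= 1e-12 * (1.0 + abs(h2))

    def test_saturation_limit_A_to_zero_pointwise(self):
        base = dict(case="saturation", a=1.0, b=1.0, c=0.5, f=0.5, s_eff=0.1)
        x1, x2 = 1.3, 0.8
        g_mags = []
        for A in (1e-2, 1e-4, 1e-6):
            ep = make_effective_params(RawModelParams(**base, A_eff=A))
            g1, g2 = g_corrections(ep, x1, x2)
            g_mags.append(abs(g1) + abs(g2))
        assert g_mags[0] > g_mags[1] > g_mags[2]
        assert g_mags[2] < 1e-5
        ep0 = make_effective_params(RawModelParams(**base))
        epA = make_effective_params(RawModelParams(**base, A_eff=1e-8))
        assert epA.f_bar == pytest.approx(ep0.f_bar, rel=1e-7)
        assert epA.b_bar == pytest.approx(ep0.b_bar, rel=1e-7)
        assert epA.a_bar == pytest.approx(ep0.a_bar, rel=1e-7)
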
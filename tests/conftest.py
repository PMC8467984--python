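"""Shared fixtures: reference parameter sets and cached heavy objects.

Two reference ecosystems are used throughout, one per interaction type:

* the *sparse-jump* sets (weak Gaussian noise 2D = 0.001 per channel and
  Poisson intensity λ·E[Y²] = 0.008 carried by rare large jumps) where
  the jump corrections are prominent, and
* the *base* sets (2D = 0.005, λ = 0.5, E[Y²] = 0.02) with milder jumps.

Orbit tables and stationary solves are expensive enough to share at
session scope; they are read-only for all consumers.
"""

from __future__ import annotations

import numpy as np
import pytest

from lvjump import (
    NoiseParams,
    RawModelParams,
    SolverOptions,
    coefficient_functions,
    make_effective_params,
    solve_stationary,
)


@pytest.fixture(scope="session")
def raw_case1():
    """Predator-saturation model, sparse-jump noise regime."""
    return RawModelParams(
        case="saturation", a=1.0, b=1.0, c=0.5, f=0.5, s_eff=0.1, A_eff=0.05
    )


@pytest.fixture(scope="session")
def raw_case2():
    """Predator-competition model, sparse-jump noise regime."""
    return RawModelParams(
        case="competition", a=1.0, b=1.0, c=0.5, f=0.5, s_eff=0.08, B_eff=0.05
    )


@pytest.fixture(scope="session")
def noise_jump1():
    return NoiseParams(D1=0.0005, D2=0.0005, lam1=0.1, lam2=0.1, m1=0.08, m2=0.08)


@pytest.fixture(scope="session")
def noise_jump2():
    return NoiseParams(D1=0.0005, D2=0.0005, lam1=0.2, lam2=0.2, m1=0.04, m2=0.04)


@pytest.fixture(scope="session")
def noise_base():
    return NoiseParams(D1=0.0025, D2=0.0025, lam1=0.5, lam2=0.5, m1=0.02, m2=0.02)


@pytest.fixture(scope="session")
def ep_case1(raw_case1):
    return make_effective_params(raw_case1)


@pytest.fixture(scope="session")
def ep_case2(raw_case2):
    return make_effective_params(raw_case2)


@pytest.fixture(scope="session")
def result_case1(raw_case1, noise_jump1):
    """Full stationary solve of the saturation model (shared, read-only)."""
    return solve_stationary(raw_case1, noise_jump1)


@pytest.fixture(scope="session")
def result_case2(raw_case2, noise_jump2):
    return solve_stationary(raw_case2, noise_jump2)


@pytest.fixture(scope="session")
def table_case1(result_case1):
    return result_case1.table


@pytest.fixture(scope="session")
def coeffs_case1(ep_case1, noise_jump1, table_case1):
    return coefficient_functions(ep_case1, noise_jump1, table_case1)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260925)


def random_valid_params(rng, case: str) -> RawModelParams:
    """Random strictly-valid parameter draw for property tests."""
    a = rng.uniform(0.5, 2.0)
    b = rng.uniform(0.5, 2.0)
    c = rng.uniform(0.2, 1.0)
    f = rng.uniform(0.3, 1.5)
    s = rng.uniform(0.0, 0.2)
    if case == "saturation":
        A = rng.uniform(0.0, 0.8 * f / c)  # keep f_bar > 0 with margin
        return RawModelParams(case=case, a=a, b=b, c=c, f=f, s_eff=s, A_eff=A)
    B = rng.uniform(0.0, 0.3)
    raw = RawModelParams(case=case, a=a, b=b, c=c, f=f, s_eff=s, B_eff=B)
    # reject draws whose effective growth rate would go nonpositive
    try:
        make_effective_params(raw)
    except Exception:
        return random_valid_params(rng, case)
    return raw
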
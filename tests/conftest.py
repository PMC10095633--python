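"""Shared fixtures: an independent mass-balance oracle and parameter draws."""

import numpy as np
import pytest
from scipy.optimize import brentq


def mass_balance_oracle(keq, kp, pt, lt, alpha_lb, alpha_p=0.0, general=False):
    """Free aqueous ligand by bisection on the scalar mass-balance residual.

    Root-finds x = L_W/L_T of
        gamma*x*LT + PT*keq_eff*x*LT/(1 + keq_eff*x*LT) - LT = 0
    on [0, 1]; independent of the closed-form quadratic it checks.
    Returns (l_w, l_lb, l_p) per total volume.
    """
    if lt == 0:
        return 0.0, 0.0, 0.0
    alpha_w = 1.0 - alpha_lb - alpha_p
    gamma = 1.0 + kp * alpha_lb / alpha_w
    keq_eff = keq / alpha_w if general else keq

    def residual(x):
        lw = x * lt
        lp = pt * keq_eff * lw / (1.0 + keq_eff * lw) if keq_eff > 0 else 0.0
        return gamma * lw + lp - lt

    x = brentq(residual, 0.0, 1.0, xtol=1e-20, rtol=8.9e-16, maxiter=200)
    lw = x * lt
    llb = lw * kp * alpha_lb / alpha_w
    return lw, llb, lt - lw - llb


@pytest.fixture(scope="session")
def oracle():
    return mass_balance_oracle


@pytest.fixture()
def rng():
    return np.random.default_rng(20230331)


@pytest.fixture(scope="session")
def random_systems():
    """1000 log-uniform parameter draws spanning the solver's working range."""
    gen = np.random.default_rng(7)
    n = 1000
    return {
        "keq": 10.0 ** gen.uniform(2, 10, n),
        "kp": 10.0 ** gen.uniform(-2, 6, n),
        "alpha_lb": gen.uniform(0.0, 0.15, n),
        "pt": 10.0 ** gen.uniform(-8, -3, n),
        "lt": 10.0 ** gen.uniform(-8, -3, n),
    }
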
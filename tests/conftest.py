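"""Shared fixtures and independent numerical oracles.

The thermodynamic oracle here never reuses the closed-form ratio
expressions from the package: it equilibrates chemical potentials
numerically (root-finding on the extracellular concentration) so the
closed forms can be checked against an independent route.
"""

import math

import numpy as np
import pytest
from hypothesis import settings
from scipy.optimize import brentq

from symporteq import LACTIC_ACID, TransmembraneState, WeakAcid

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

LN10 = math.log(10.0)


def oracle_anion_ratio(pH_in: float, pH_out: float) -> float:
    """Equilibrium in/out anion ratio by numeric chemical-potential balance.

    Solves mu_in(c_in) + mu_H_in = mu_out(c_out) + mu_H_out for c_out at
    fixed c_in = 1, where mu = RT ln c for the anion and the proton
    electrochemical term reduces to -RT ln(10) pH for the electroneutral
    pair.  Bisection is done on log10 c_out.
    """
    c_in = 1.0

    def imbalance(log10_c_out):
        # inward (anion + H+) potential difference, units of RT
        return (math.log(c_in) - LN10 * pH_in) - (
            math.log(10.0**log10_c_out) - LN10 * pH_out
        )

    log_c = brentq(imbalance, -12.0, 12.0, xtol=1e-14, rtol=8.9e-16)
    return c_in / 10.0**log_c


def oracle_total_ratio(pH_in: float, pH_out: float, pKa: float) -> float:
    """Equilibrium in/out total-acid ratio via numeric equilibration.

    Bisection on the total extracellular acid; the equilibrated species
    is the anion, whose concentration at a given pH follows from the
    acid-base equilibrium c_anion = c_total / (1 + 10**(pKa - pH)).
    """
    t_in = 1.0

    def anion(total, pH):
        return total / (1.0 + 10.0 ** (pKa - pH))

    def imbalance(log10_t_out):
        return (math.log(anion(t_in, pH_in)) - LN10 * pH_in) - (
            math.log(anion(10.0**log10_t_out, pH_out)) - LN10 * pH_out
        )

    log_t = brentq(imbalance, -12.0, 12.0, xtol=1e-14, rtol=8.9e-16)
    return t_in / 10.0**log_t


@pytest.fixture
def oracle_ratios():
    return oracle_anion_ratio, oracle_total_ratio


@pytest.fixture
def lactic():
    return LACTIC_ACID


@pytest.fixture
def acidic_state():
    """pH_in 7, pH_out 5: the reference accumulative-uptake condition."""
    return TransmembraneState(pH_in=7.0, pH_out=5.0)


@pytest.fixture
def quick_config():
    """Small chemostat configuration used across simulator tests."""
    from symporteq import ChemostatConfig

    return ChemostatConfig(settle_time=5.0)
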
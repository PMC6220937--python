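"""Shared fixtures.

The cardiac runs and the hot-exposure ladder are expensive (tens of
seconds), so they are session-scoped and shared between the module tests
and the acceptance tests.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from hemotherm.driver import ExperimentConfig, run_flow_experiment, run_ladder
from hemotherm.network import (ArterialNetwork, Vessel,
                               beta_from_wave_speed,
                               generate_synthetic_network)

RHO = 1.06
INVISCID_FLUID = {"rho": RHO, "mu": 0.0, "alpha": 0.0121, "cp": 3.9,
                  "h_in": 0.1, "p_ext_mmHg": 0.0}


def uniform_vessel(vid="v0", length=80.0, A0=1.0, c0=400.0, n_elements=400):
    beta = beta_from_wave_speed(c0, A0, RHO)
    return Vessel(id=vid, length=length, n_elements=n_elements,
                  A0_prox=A0, A0_dist=A0, beta_prox=beta, beta_dist=beta)


def single_vessel_network(R_R=0.0, mu=0.0, **kwargs) -> ArterialNetwork:
    v = uniform_vessel(**kwargs)
    fluid = dict(INVISCID_FLUID)
    fluid["mu"] = mu
    return ArterialNetwork(vessels={v.id: v}, junctions=[], inlet=v.id,
                           terminals={v.id: R_R}, fluid=fluid).require_valid()


def gaussian_w1(c0=400.0, amp=2.0, t0=0.06, sig=0.02):
    w10 = 4.0 * c0
    return lambda t: w10 + amp * math.exp(-((t - t0) / sig) ** 2)


@pytest.fixture(scope="session")
def synthetic_net():
    return generate_synthetic_network(2, seed=0)


@pytest.fixture(scope="session")
def cardiac30():
    """Converged LV-driven run at 30 years on the small synthetic tree."""
    return run_flow_experiment(30, n_generations=1, seed=0, n_cycles=8,
                               dt=2e-4)


@pytest.fixture(scope="session")
def cardiac80():
    """Same network and discretisation, aged to 80 years."""
    return run_flow_experiment(80, n_generations=1, seed=0, n_cycles=8,
                               dt=2e-4)


@pytest.fixture(scope="session")
def hot_ladder():
    """Hot-exposure (40 degC, 42% RH, 1 h) ageing-toggle ladder at 80 y."""
    base = ExperimentConfig(age=80, T_air=40.0, RH=42.0, duration=3600.0,
                            dt_thermal=1.0, flow_mode="pool")
    return run_ladder(base)
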
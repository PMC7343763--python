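import numpy as np
import pytest

from ddlswitch import (
    DDLParameters,
    StateSpace,
    build_transition_system,
    choose_truncation,
    reference_params,
    stationary_distribution,
    stationary_solve,
)

# (a, k3) nodes of the reference grid used throughout the suite
FIXTURE_GRID = [(a, k3) for a in (0.5, 1.0, 2.0, 4.0) for k3 in (1.5, 5.0)]


@pytest.fixture
def ref_params() -> DDLParameters:
    """Reference parameters at a=1, k3=5 (Mode I)."""
    return reference_params()


@pytest.fixture
def decoupled_params() -> DDLParameters:
    """k1 = k2 = 0: gene and copy-number dynamics are independent."""
    return DDLParameters(k1=0.0, k2=0.0, k3=3.0, kon=2.0, koff=1.0, a=1.0)


def truncated_space(params: DDLParameters, tail_tol: float = 1e-12) -> StateSpace:
    return StateSpace(choose_truncation(params, tail_tol))


def analytic_dist(params: DDLParameters, tail_tol: float = 1e-12):
    return stationary_distribution(params, truncated_space(params, tail_tol))


def cme_dist(params: DDLParameters, tail_tol: float = 1e-12):
    space = truncated_space(params, tail_tol)
    return stationary_solve(build_transition_system(params, space))


def product_form(params: DDLParameters, m_max: int):
    """Independent two-state x Poisson stationary distribution (k1 = k2 = 0)."""
    from scipy.stats import poisson

    assert params.gene_decoupled
    pois = poisson.pmf(np.arange(m_max + 1), params.m_s)
    on_mass = params.kon / (params.kon + params.koff)
    return (1.0 - on_mass) * pois, on_mass * pois
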
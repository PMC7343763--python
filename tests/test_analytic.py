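import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import poisson

from ddlswitch import (
    DDLParameters,
    StateSpace,
    analytic_coefficients,
    hyp1f1,
    marginal_poisson,
    normalization_A0,
    pochhammer,
    reference_params,
    stationary_distribution,
    stationary_p0,
    stationary_p1,
    total_variation,
)

from conftest import FIXTURE_GRID, analytic_dist, cme_dist, product_form, truncated_space


class TestPochhammer:
    @given(gamma=st.floats(-10, 10), l=st.just(0))
    def test_empty_product(self, gamma, l):
        assert pochhammer(gamma, l) == 1.0

    def test_integer_case(self):
        assert pochhammer(3, 4) == pytest.approx(360.0)  # 3*4*5*6

    def test_half_integer_case(self):
        assert pochhammer(0.5, 3) == pytest.approx(0.5 * 1.5 * 2.5)

    @given(gamma=st.floats(0.1, 20), l=st.integers(0, 30))
    @settings(max_examples=100)
    def test_recurrence(self, gamma, l):
        assert pochhammer(gamma, l + 1) == pytest.approx(
            pochhammer(gamma, l) * (gamma + l), rel=1e-12
        )


class TestHyp1f1:
    @given(alpha=st.floats(0.2, 10), omega=st.floats(-20, 20))
    @settings(max_examples=100)
    def test_equal_parameters_give_exponential(self, alpha, omega):
        assert hyp1f1(alpha, alpha, omega) == pytest.approx(math.exp(omega), rel=1e-11)

    def test_closed_form_1_2(self):
        assert hyp1f1(1, 2, 1) == pytest.approx(math.e - 1, rel=1e-12)

    def test_negative_argument_against_arbitrary_precision_series(self):
        import mpmath

        with mpmath.workdps(50):
            # brute-force series of the Kummer-transformed argument
            expected = float(mpmath.exp(-4) * mpmath.nsum(
                lambda n: mpmath.rf(1.0, n) / mpmath.rf(3.5, n) * mpmath.mpf(4) ** n
                / mpmath.factorial(n), [0, mpmath.inf]))
        assert hyp1f1(2.5, 3.5, -4.0) == pytest.approx(expected, rel=1e-12)

    def test_rejects_nonpositive_integer_beta(self):
        with pytest.raises(ValueError):
            hyp1f1(1.0, -2.0, 0.5)

    @given(alpha=st.floats(0.5, 8), beta_shift=st.floats(0.5, 4), omega=st.floats(-10, 10))
    @settings(max_examples=60)
    def test_matches_scipy(self, alpha, beta_shift, omega):
        from scipy import special

        beta = alpha + beta_shift
        assert hyp1f1(alpha, beta, omega) == pytest.approx(
            float(special.hyp1f1(alpha, beta, omega)), rel=1e-8
        )


class TestCoefficients:
    def test_hand_arithmetic_example(self):
        p = DDLParameters(k1=2.1, k2=1.0, k3=5.0, kon=1.0, koff=1.0, a=1.0)
        c = analytic_coefficients(p)
        assert c.alpha == pytest.approx(3.3)
        assert c.beta == pytest.approx(4.3)
        assert c.omega2 == pytest.approx(-1.25)
        assert c.omega1 == pytest.approx(1.25)

    def test_k2_zero_limit(self):
        p = DDLParameters(k1=0.7, k2=0.0, k3=2.0, kon=0.5, koff=0.3, a=2.0)
        c = analytic_coefficients(p)
        assert c.omega1 == 0.0 and c.omega2 == 0.0
        assert c.alpha == pytest.approx(p.kon + p.koff + p.a * p.k1)

    def test_a_zero_limit(self):
        p = DDLParameters(k1=1.0, k2=2.0, k3=2.0, kon=0.5, koff=0.3, a=0.0)
        c = analytic_coefficients(p)
        assert c.omega1 == 0.0 and c.omega2 == 0.0
        assert c.alpha == pytest.approx((p.kon + p.koff) / (p.k2 + 1))

    def test_omega2_nonpositive_and_beta(self):
        for a, k3 in FIXTURE_GRID:
            c = analytic_coefficients(reference_params(a=a, k3=k3))
            assert c.omega2 <= 0
            assert c.beta == c.alpha + 1


class TestNormalization:
    def test_brute_force_renormalization(self, ref_params):
        # oracle: normalize the unnormalized series numerically
        a0 = normalization_A0(ref_params)
        space = truncated_space(ref_params, 1e-14)
        dist = stationary_distribution(ref_params, space)
        unnorm = (dist.p0.sum() + dist.p1.sum()) / a0
        assert a0 == pytest.approx(1.0 / unnorm, rel=1e-8)

    def test_product_form_normalization(self, decoupled_params):
        dist = analytic_dist(decoupled_params)
        assert dist.mass == pytest.approx(1.0, abs=1e-10)

    def test_zero_activation_rejected(self):
        p = DDLParameters(k1=0.0, k2=1.0, k3=2.0, kon=0.0, koff=1.0, a=1.0)
        with pytest.raises(ValueError, match="kon"):
            normalization_A0(p)


class TestStationaryPointwise:
    def test_p1_vanishes_without_synthesis(self):
        p = DDLParameters(k1=1.0, k2=1.0, k3=0.0, kon=1.0, koff=1.0, a=1.0)
        assert stationary_p1(p, 3) == 0.0
        assert stationary_p0(p, 2) == 0.0
        assert stationary_p0(p, 0) + stationary_p1(p, 0) == pytest.approx(1.0)

    def test_product_form_pointwise(self, decoupled_params):
        p = decoupled_params
        on_mass = p.kon / (p.kon + p.koff)
        for m in (0, 1, 3, 6):
            pois = poisson.pmf(m, p.m_s)
            assert stationary_p1(p, m) == pytest.approx(on_mass * pois, rel=1e-10)
            assert stationary_p0(p, m) == pytest.approx((1 - on_mass) * pois, rel=1e-10)

    def test_matches_cme_oracle_at_m5(self, ref_params):
        oracle = cme_dist(ref_params, 1e-14)
        assert stationary_p0(ref_params, 5) == pytest.approx(oracle.p0[5], abs=1e-8)
        assert stationary_p1(ref_params, 5) == pytest.approx(oracle.p1[5], abs=1e-8)

    def test_negative_m_rejected(self, ref_params):
        with pytest.raises(ValueError):
            stationary_p0(ref_params, -1)


class TestMarginalPoisson:
    def test_pmf_values(self):
        p = DDLParameters(k1=1, k2=1, k3=5, kon=1, koff=1, a=1.0)
        assert marginal_poisson(p, 0) == pytest.approx(math.exp(-5), rel=1e-12)
        assert marginal_poisson(p, 5) == pytest.approx(5**5 * math.exp(-5) / 120, rel=1e-12)

    def test_degenerate_at_zero(self):
        p = DDLParameters(k1=1, k2=1, k3=5, kon=1, koff=1, a=0.0)
        assert marginal_poisson(p, 0) == 1.0


class TestStationaryDistribution:
    @pytest.mark.parametrize("a,k3", FIXTURE_GRID)
    def test_marginal_is_poisson(self, a, k3):
        dist = analytic_dist(reference_params(a=a, k3=k3))
        pois = poisson.pmf(np.arange(dist.m_max + 1), a * k3)
        assert np.abs(dist.total - pois).max() <= 1e-8

    @pytest.mark.parametrize("a,k3", FIXTURE_GRID)
    def test_matches_cme_oracle(self, a, k3):
        params = reference_params(a=a, k3=k3)
        assert total_variation(analytic_dist(params), cme_dist(params)) <= 1e-8

    def test_mode_location_is_poisson_mode(self, ref_params):
        dist = analytic_dist(ref_params)
        lam = ref_params.m_s
        modes = {int(math.floor(lam))}
        if lam == math.floor(lam):
            modes.add(int(lam) - 1)
        assert int(np.argmax(dist.total)) in modes

    def test_decoupled_product_form(self, decoupled_params):
        dist = analytic_dist(decoupled_params)
        p0, p1 = product_form(decoupled_params, dist.m_max)
        assert np.abs(dist.p0 - p0).max() < 1e-10
        assert np.abs(dist.p1 - p1).max() < 1e-10

    def test_inadequate_truncation_raises(self, ref_params):
        with pytest.raises(ValueError, match="truncation"):
            stationary_distribution(ref_params, StateSpace(2))

    def test_nonnegative_and_normalized(self, ref_params):
        dist = analytic_dist(ref_params)
        assert dist.p0.min() >= 0 and dist.p1.min() >= 0
        assert dist.mass == pytest.approx(1.0, abs=1e-8)

    def test_to_frame_columns(self, ref_params):
        frame = analytic_dist(ref_params).to_frame()
        assert list(frame.columns) == ["m", "P0", "P1", "P_total"]
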
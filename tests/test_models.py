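"""Closed-form observables of the mechanistic TAF models."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tafsim.models import (
    InvalidModelError,
    ModelSpec,
    delta_from_lifetime_fraction,
    frac_taf_positive_analytic,
    max_frac_positive_bound,
    mean_nontaf_analytic,
    mean_taf_analytic,
)


class TestModelSpecValidation:
    def test_negative_rate_rejected(self):
        with pytest.raises(InvalidModelError):
            ModelSpec(lambda_T=-0.1)

    def test_nontaf_gain_requires_repair(self):
        with pytest.raises(InvalidModelError):
            ModelSpec(lambda_N=1.0, rho=0.0)

    def test_mechanism_channel_consistency(self):
        with pytest.raises(InvalidModelError):
            ModelSpec(mechanism="stress", delta_c=0.1, mu_d=1.0)
        with pytest.raises(InvalidModelError):
            ModelSpec(mechanism="proliferation", lambda_T=0.1)

    def test_json_round_trip(self):
        m = ModelSpec(mechanism="hybrid", lambda_T=0.03, delta_c=0.006,
                      mu_d=2.0, lambda_N=7.0, rho=2.0)
        assert ModelSpec.from_json(m.to_json()) == m


class TestMeanTaf:
    def test_linear_accrual(self):
        m = ModelSpec(mechanism="stress", lambda_T=0.05)
        assert mean_taf_analytic(m, 27.0) == pytest.approx(1.35)

    def test_all_rates_zero_returns_initial(self):
        m = ModelSpec(initial_mean_taf=0.7)
        for t in (0.0, 5.0, 27.0):
            assert mean_taf_analytic(m, t) == 0.7

    def test_proliferation_mean_from_lifetime_fraction(self):
        # 15% of cells divide over 27 months, 2 TAF per division on average
        delta = delta_from_lifetime_fraction(0.15, 27.0)
        m = ModelSpec(mechanism="proliferation", delta_c=delta, mu_d=2.0)
        assert mean_taf_analytic(m, 27.0) == pytest.approx(
            2.0 * -math.log(0.85), rel=1e-12
        )

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            mean_taf_analytic(ModelSpec(), -1.0)

    @given(
        lam=st.floats(0, 0.2),
        delta=st.floats(0, 0.02),
        mu=st.floats(0, 5),
        init=st.floats(0, 2),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_mean_nondecreasing_in_time(self, lam, delta, mu, init):
        m = ModelSpec(mechanism="hybrid", lambda_T=lam, delta_c=delta,
                      mu_d=mu, initial_mean_taf=init)
        ts = np.linspace(0, 30, 16)
        means = [mean_taf_analytic(m, t) for t in ts]
        assert all(b >= a for a, b in zip(means, means[1:]))


class TestFracPositive:
    def test_stress_closed_form(self):
        m = ModelSpec(mechanism="stress", lambda_T=0.05)
        assert frac_taf_positive_analytic(m, 27.0) == pytest.approx(
            1.0 - math.exp(-1.35), rel=1e-12
        )

    def test_zero_time_zero_initial(self):
        m = ModelSpec(mechanism="stress", lambda_T=0.05)
        assert frac_taf_positive_analytic(m, 0.0) == 0.0

    def test_large_mu_limit_is_division_fraction(self):
        delta = delta_from_lifetime_fraction(0.15, 27.0)
        m = ModelSpec(mechanism="proliferation", delta_c=delta, mu_d=1e3)
        assert frac_taf_positive_analytic(m, 27.0) == pytest.approx(
            1.0 - math.exp(-delta * 27.0), rel=1e-9
        )

    @given(
        lam=st.floats(0, 0.2),
        delta=st.floats(0, 0.02),
        mu=st.floats(0, 5),
        t=st.floats(0, 30),
    )
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_markov_bound(self, lam, delta, mu, t):
        m = ModelSpec(mechanism="hybrid", lambda_T=lam, delta_c=delta, mu_d=mu)
        frac = frac_taf_positive_analytic(m, t)
        assert 0 <= frac <= min(1.0, mean_taf_analytic(m, t)) + 1e-12


class TestNonTaf:
    def test_stationary_limit(self):
        m = ModelSpec(lambda_N=4.0, rho=2.0)
        assert mean_nontaf_analytic(m, 1e6) == pytest.approx(2.0)

    def test_pure_decay_half_life(self):
        m = ModelSpec(rho=1.0)
        assert mean_nontaf_analytic(m, math.log(2), initial_mean_nontaf=3.0) \
            == pytest.approx(1.5)

    def test_relaxation_value(self):
        m = ModelSpec(lambda_N=4.0, rho=2.0)
        assert mean_nontaf_analytic(m, 1.0) == pytest.approx(
            2.0 * (1.0 - math.exp(-2.0)), rel=1e-12
        )


class TestProliferationBound:
    def test_bound_equals_lifetime_division_fraction(self):
        delta = delta_from_lifetime_fraction(0.15, 27.0)
        m = ModelSpec(mechanism="proliferation", delta_c=delta, mu_d=1.0)
        assert max_frac_positive_bound(m, 27.0) == pytest.approx(0.15)

    def test_no_division_no_taf(self):
        m = ModelSpec(mechanism="proliferation", delta_c=0.0)
        assert max_frac_positive_bound(m, 27.0) == 0.0

    def test_half_horizon_value(self):
        delta = delta_from_lifetime_fraction(0.04, 27.0)
        m = ModelSpec(mechanism="proliferation", delta_c=delta)
        assert max_frac_positive_bound(m, 13.5) == pytest.approx(
            1.0 - 0.96 ** 0.5, rel=1e-12
        )

    def test_rejects_non_proliferation_model(self):
        with pytest.raises(InvalidModelError):
            max_frac_positive_bound(ModelSpec(mechanism="stress"), 10.0)

    @given(mu=st.floats(0, 50), t=st.floats(0, 30))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_bound_dominates_frac_positive_for_all_mu(self, mu, t):
        delta = delta_from_lifetime_fraction(0.15, 27.0)
        m = ModelSpec(mechanism="proliferation", delta_c=delta, mu_d=mu)
        assert frac_taf_positive_analytic(m, t) <= \
            max_frac_positive_bound(m, t) + 1e-12


class TestDeltaFromLifetimeFraction:
    def test_zero_fraction(self):
        assert delta_from_lifetime_fraction(0.0, 27.0) == 0.0

    def test_fifteen_percent_over_27_months(self):
        assert delta_from_lifetime_fraction(0.15, 27.0) == pytest.approx(
            -math.log(0.85) / 27.0, rel=1e-12
        )

    @pytest.mark.parametrize("f", [0.04, 0.10, 0.15])
    def test_round_trip_identity(self, f):
        d = delta_from_lifetime_fraction(f, 27.0)
        assert 1.0 - math.exp(-d * 27.0) == pytest.approx(f, rel=1e-12)

    def test_fraction_one_rejected(self):
        with pytest.raises(ValueError):
            delta_from_lifetime_fraction(1.0, 27.0)


def test_hybrid_mean_is_sum_of_channels():
    stress = ModelSpec(mechanism="stress", lambda_T=0.03)
    prolif = ModelSpec(mechanism="proliferation", delta_c=0.006, mu_d=2.0)
    hybrid = ModelSpec(mechanism="hybrid", lambda_T=0.03, delta_c=0.006, mu_d=2.0)
    for t in (0.0, 10.0, 27.0):
        assert mean_taf_analytic(hybrid, t) == pytest.approx(
            mean_taf_analytic(stress, t) + mean_taf_analytic(prolif, t)
        )
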
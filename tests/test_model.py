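"""Reaction kinetics, steady state, linearization and Turing criteria."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pollenpat.model import (
    GMParameters,
    reaction_terms,
    steady_state,
    linearize,
    turing_check,
    dispersion_rate,
    scale_parameter,
    turing_factor_interval,
    SCALABLE_PARAMETERS,
)


def log_uniform(lo, hi):
    return st.floats(np.log(lo), np.log(hi)).map(np.exp)


def random_params_strategy():
    return st.builds(
        GMParameters,
        D_A=log_uniform(0.1, 10),
        D_H=log_uniform(1, 500),
        mu_A=log_uniform(0.01, 2),
        mu_H=log_uniform(0.01, 2),
        rho_1=log_uniform(0.01, 2),
        rho_2=log_uniform(0.01, 2),
        rho_A=log_uniform(1e-4, 0.1),
        rho_H=log_uniform(1e-6, 0.01),
    )


class TestReactionTerms:
    def test_zero_activator(self, params):
        dA, dH = reaction_terms(params, 0.0, 1.0)
        assert dA == pytest.approx(params.rho_1 * params.rho_A**2)
        assert dH == pytest.approx(params.rho_H - params.mu_H)

    def test_no_basal_terms_zero_activator(self):
        p = GMParameters(rho_A=1e-300, rho_H=1e-300)
        dA, dH = reaction_terms(p, 0.0, 1.0)
        assert dA == pytest.approx(0.0, abs=1e-30)
        assert dH == pytest.approx(-p.mu_H)

    def test_vanishes_at_steady_state(self, params, ss):
        dA, dH = reaction_terms(params, ss.A_star, ss.H_star)
        assert abs(dA) < 1e-10 and abs(dH) < 1e-10

    def test_nonpositive_inhibitor_rejected(self, params):
        with pytest.raises(ValueError, match="inhibitor"):
            reaction_terms(params, 1.0, 0.0)


class TestSteadyState:
    def test_closed_form_without_basal_terms(self):
        p = GMParameters(rho_A=1e-300, rho_H=1e-300)
        ss = steady_state(p)
        A_expect = p.rho_1 * p.mu_H / (p.rho_2 * p.mu_A)
        assert ss.A_star == pytest.approx(A_expect, rel=1e-9)
        assert ss.H_star == pytest.approx(p.rho_2 * A_expect**2 / p.mu_H, rel=1e-9)

    def test_default_parameters_near_closed_form(self, ss):
        assert ss.A_star == pytest.approx(0.2 * 0.6 / (0.2 * 0.21), rel=0.01)
        assert ss.H_star == pytest.approx(0.2 * (0.2 * 0.6 / (0.2 * 0.21)) ** 2 / 0.6, rel=0.01)

    def test_positive(self, ss):
        assert ss.A_star > 0 and ss.H_star > 0

    def test_zero_decay_is_invalid_parameters(self):
        # no finite activator balance without decay; rejected at construction
        with pytest.raises(ValueError, match="mu_A"):
            GMParameters(mu_A=0.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(random_params_strategy())
    def test_residual_below_tolerance(self, p):
        try:
            ss = steady_state(p)
        except ValueError:
            return  # no positive root for this corner of parameter space
        dA, dH = reaction_terms(p, ss.A_star, ss.H_star)
        assert max(abs(dA), abs(dH)) < 1e-10


class TestLinearize:
    def test_sign_structure(self, params, ss):
        lin = linearize(params, ss)
        assert lin.f_A > 0 and lin.f_H < 0 and lin.g_A > 0
        assert lin.g_H == -params.mu_H
        assert lin.trace == pytest.approx(lin.f_A + lin.g_H)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(random_params_strategy())
    def test_matches_finite_differences(self, p):
        try:
            ss = steady_state(p)
        except ValueError:
            return
        lin = linearize(p, ss)
        # A-steps scaled up to avoid catastrophic cancellation at tiny
        # steady states (the A-dependences are polynomial, so central
        # differences carry no truncation error); the H-step stays
        # relative to H* to control truncation of the 1/H nonlinearity
        hA, hH = 1e-6 * (1 + ss.A_star), 1e-6 * ss.H_star
        fA = (reaction_terms(p, ss.A_star + hA, ss.H_star)[0]
              - reaction_terms(p, ss.A_star - hA, ss.H_star)[0]) / (2 * hA)
        fH = (reaction_terms(p, ss.A_star, ss.H_star + hH)[0]
              - reaction_terms(p, ss.A_star, ss.H_star - hH)[0]) / (2 * hH)
        gA = (reaction_terms(p, ss.A_star + hA, ss.H_star)[1]
              - reaction_terms(p, ss.A_star - hA, ss.H_star)[1]) / (2 * hA)
        assert lin.f_A == pytest.approx(fA, rel=1e-6, abs=1e-12)
        assert lin.f_H == pytest.approx(fH, rel=1e-6)
        assert lin.g_A == pytest.approx(gA, rel=1e-6, abs=1e-12)


class TestTuringCheck:
    def test_default_parameters_satisfy(self, params):
        assert turing_check(params).satisfied

    def test_equal_diffusivities_fail(self, params):
        p = scale_parameter(params, "D_H", params.D_A / params.D_H)
        assert p.D_A == pytest.approx(p.D_H)
        assert not turing_check(p).satisfied

    def test_band_matches_quadratic_roots(self, params, ss):
        rep = turing_check(params)
        lin = linearize(params, ss)
        roots = np.roots(
            [params.D_A * params.D_H, -(params.D_H * lin.f_A + params.D_A * lin.g_H), lin.det]
        )
        lo, hi = sorted(roots)
        assert rep.k2_minus == pytest.approx(lo)
        assert rep.k2_plus == pytest.approx(hi)

    def test_band_consistent_with_dispersion_sign(self, params, ss):
        rep = turing_check(params)
        for k2 in np.linspace(0, 2 * rep.k2_plus, 80):
            rate = dispersion_rate(params, ss, k2)
            inside = rep.k2_minus < k2 < rep.k2_plus
            if abs(k2 - rep.k2_minus) > 1e-6 and abs(k2 - rep.k2_plus) > 1e-6:
                assert (rate > 0) == inside


class TestDispersionRate:
    def test_homogeneous_mode_stable(self, params, ss):
        assert dispersion_rate(params, ss, 0.0) < 0

    def test_large_wavenumber_strongly_damped(self, params, ss):
        assert dispersion_rate(params, ss, 1e4) < -100

    def test_negative_wavenumber_rejected(self, params, ss):
        with pytest.raises(ValueError):
            dispersion_rate(params, ss, -1.0)


class TestScaleParameter:
    def test_identity(self, params):
        assert scale_parameter(params, "D_A", 1.0) == params

    def test_single_parameter(self, params):
        assert scale_parameter(params, "mu_A", 0.4).mu_A == pytest.approx(0.084)

    def test_joint_rho(self, params):
        p = scale_parameter(params, "rho", 2.0)
        assert p.rho_1 == pytest.approx(0.4) and p.rho_2 == pytest.approx(0.4)
        assert p.mu_A == params.mu_A

    def test_unknown_name(self, params):
        with pytest.raises(ValueError, match="unknown"):
            scale_parameter(params, "sigma", 1.0)


class TestTuringFactorInterval:
    @pytest.mark.parametrize("name", SCALABLE_PARAMETERS)
    def test_interval_contains_reference_robustness_range(self, params, name):
        low, high = turing_factor_interval(params, name)
        assert low <= 0.40 and high >= 2.70
        assert low < 1.0 < high

    def test_basal_inhibitor_interval_is_wide(self, params):
        low, high = turing_factor_interval(params, "rho_H")
        assert high / low > 100


def test_parameters_text_round_trip(params):
    assert GMParameters.from_text(params.to_text()) == params


def test_turing_report_json(params):
    import json

    doc = json.loads(turing_check(params).to_json())
    assert doc["satisfied"] is True and doc["k2_minus"] < doc["k2_plus"]
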
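"""Unit and property tests for the cell-level model right-hand sides."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import isletsim as s
from isletsim.model import (
    NetSignals,
    PoolState,
    SignalState,
    pool_steady_state,
)


def hill_direct(x, m, h, n):
    """Independent closed-form oracle: plain power arithmetic."""
    return m * x**n / (x**n + h**n)


class TestHill:
    def test_half_max_at_h(self, params):
        assert s.hill(3.97, 103.0, 3.97, 4.84) == pytest.approx(51.5)
        assert s.hill(1.06, 2.24, 1.06, 3.5) == pytest.approx(1.12)

    def test_zero_input_gives_zero(self):
        assert s.hill(0.0, 2.24, 1.06, 3.5) == 0.0

    @pytest.mark.parametrize(
        "x,m,h,n,expected",
        [
            # frozen values from the direct power-arithmetic oracle
            (5.40, 2.24, 1.06, 3.5, 2.2325185213726657),
            (3.713, 0.336, 3.75, 9.97, 0.15970258560074851),
            (3.713, 103.0, 3.97, 4.84, 43.23119695146411),
        ],
    )
    def test_matches_direct_evaluation(self, x, m, h, n, expected):
        assert s.hill(x, m, h, n) == pytest.approx(expected, rel=1e-12)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            s.hill(1.0, 1.0, -1.0, 2.0)
        with pytest.raises(ValueError):
            s.hill(1.0, 1.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            s.hill(-0.5, 1.0, 1.0, 2.0)

    @given(
        x=st.floats(1e-6, 1e6),
        m=st.floats(0.01, 1e3),
        h=st.floats(1e-3, 1e3),
        n=st.floats(0.1, 12.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_bounded_and_agrees_with_direct_form(self, x, m, h, n):
        v = s.hill(x, m, h, n)
        assert 0.0 <= v <= m
        # log-space evaluation must agree with the naive form wherever
        # the naive form does not overflow
        try:
            direct = hill_direct(x, m, h, n)
        except OverflowError:
            return
        if math.isfinite(direct):
            assert v == pytest.approx(direct, rel=1e-9, abs=1e-12)

    def test_no_overflow_at_steep_exponent_large_x(self):
        # naive x**n overflows here; log-space evaluation must not
        v = s.hill(1e40, 0.336, 3.75, 9.97)
        assert v == pytest.approx(0.336)

    @given(x=st.floats(0.01, 100.0), dx=st.floats(0.01, 10.0))
    @settings(max_examples=100, deadline=None)
    def test_strictly_increasing(self, x, dx):
        assert s.hill(x + dx, 103.0, 3.97, 4.84) > s.hill(x, 103.0, 3.97, 4.84)


class TestSecretionRates:
    def test_insulin_half_max_and_extremes(self, params):
        assert s.insulin_secretion_rate(params.h_I, params) == pytest.approx(51.5)
        assert s.insulin_secretion_rate(0.0, params) == 0.0
        assert s.insulin_secretion_rate(3.713, params) == pytest.approx(
            43.23119695146411, rel=1e-12
        )

    def test_glucagon_half_max_and_saturation(self, params):
        assert s.glucagon_secretion_rate(params.h_G, params) == pytest.approx(1.12)
        assert s.glucagon_secretion_rate(0.0, params) == 0.0
        v = s.glucagon_secretion_rate(5.40, params)
        assert v == pytest.approx(2.2325185213726657, rel=1e-12)
        assert v / params.m_G == pytest.approx(0.99666, rel=1e-4)

    @given(X=st.floats(0.0, 1e4))
    @settings(max_examples=100, deadline=None)
    def test_rates_bounded_by_maxima(self, params, X):
        assert 0.0 <= s.insulin_secretion_rate(X, params) <= params.m_I
        assert 0.0 <= s.glucagon_secretion_rate(X, params) <= params.m_G


class TestNetSignals:
    def test_beta_background_only(self, params):
        assert s.beta_net_signal(0.0, 0.0, params) == pytest.approx(2.60)

    def test_beta_no_glucagon_term_at_zero_glucagon(self, params):
        assert s.beta_net_signal(1.0, 0.0, params) == pytest.approx(3.60)

    def test_beta_with_glucagon_matches_direct_evaluation(self, params):
        # oracle: plain power arithmetic on the closed form
        assert s.beta_net_signal(1.0, 59.0, params) == pytest.approx(
            3.713006671295803, rel=1e-12
        )

    def test_alpha_extremes(self, params):
        assert s.alpha_net_signal(1.0, 0.0, params) == pytest.approx(5.40)
        assert s.alpha_net_signal(0.0, 0.0, params) == pytest.approx(4.40)
        # insulin saturation removes m_g of the glucose signal and all of X_A0
        assert s.alpha_net_signal(1.0, 1e12, params) == pytest.approx(0.40, rel=1e-4)

    @given(X_gB=st.floats(0, 50), X_G=st.floats(0, 1e4), d=st.floats(0.01, 10))
    @settings(max_examples=100, deadline=None)
    def test_beta_monotone_in_both_inputs(self, params, X_gB, X_G, d):
        base = s.beta_net_signal(X_gB, X_G, params)
        assert s.beta_net_signal(X_gB + d, X_G, params) >= base
        assert s.beta_net_signal(X_gB, X_G + d, params) >= base
        assert base >= params.X_B0

    @given(X_gA=st.floats(0, 50), X_I=st.floats(0, 1e6))
    @settings(max_examples=200, deadline=None)
    def test_alpha_signal_within_stated_band(self, params, X_gA, X_I):
        v = s.alpha_net_signal(X_gA, X_I, params)
        lo = X_gA * (1 - params.m_g)
        hi = X_gA + params.X_A0
        assert lo - 1e-12 <= v <= hi + 1e-12

    @given(X_gA=st.floats(0, 50), X_I=st.floats(0, 1e5), d=st.floats(0.01, 100))
    @settings(max_examples=100, deadline=None)
    def test_alpha_non_increasing_in_insulin(self, params, X_gA, X_I, d):
        assert s.alpha_net_signal(X_gA, X_I + d, params) <= s.alpha_net_signal(
            X_gA, X_I, params
        ) + 1e-12


class TestSignalKinetics:
    def test_fixed_point_has_zero_derivative(self, params):
        st8 = SignalState(2.0, 0.5, 2.0, 0.5)
        d = s.signal_rhs(st8, 2.0, 0.5, 0.5, params)
        # X_gB and X_gA share the glucose input; X_G, X_I match theirs
        np.testing.assert_allclose(d, 0.0, atol=1e-15)

    def test_matches_closed_form_exponential(self, params):
        # dX/dt = k (u - X), X(0)=1, u=3  ->  X(t) = 3 - 2 exp(-k t)
        from scipy.integrate import solve_ivp

        k = params.k_gB
        sol = solve_ivp(
            lambda t, y: s.signal_rhs(
                SignalState(y[0], 0, 0, 0), 3.0, 0.0, 0.0, params
            )[:1],
            (0, 10),
            [1.0],
            rtol=1e-12,
            atol=1e-14,
            dense_output=True,
        )
        t_check = np.array([0.5, 1 / k, 5.0, 10.0])
        exact = 3 - 2 * np.exp(-k * t_check)
        num = sol.sol(t_check)[0]
        assert np.max(np.abs(num - exact) / exact) < 1e-8
        assert exact[1] == pytest.approx(2.2642411176571153)

    def test_rate_constant_sets_relaxation_speed(self, params):
        # doubling k halves the time to cover half the gap to the asymptote
        t_half = math.log(2) / params.k_I
        p2 = params.replace(k_I=2 * params.k_I)
        t_half2 = math.log(2) / p2.k_I
        assert t_half2 == pytest.approx(t_half / 2)


class TestPools:
    def test_steady_state_efflux_equals_secretion_rate(self, params):
        X_B, X_A = 3.713, 2.0
        pools = pool_steady_state(X_B, X_A, params)
        d, r_I, r_G = s.pool_rhs(pools, X_B, X_A, params)
        np.testing.assert_allclose(d, 0.0, atol=1e-10)
        assert r_I == pytest.approx(s.insulin_secretion_rate(X_B, params), rel=1e-12)
        assert r_G == pytest.approx(s.glucagon_secretion_rate(X_A, params), rel=1e-12)

    def test_zero_signal_freezes_pools(self, params):
        pools = PoolState(10.0, 5.0, 2.0, 1.0)
        d, r_I, r_G = s.pool_rhs(pools, 0.0, 0.0, params)
        np.testing.assert_allclose(d, 0.0)
        assert r_I == 0.0 and r_G == 0.0

    def test_transfer_coefficient_value(self, params):
        from isletsim.model import _transfer_coefficients

        k1_I, _, _, _ = _transfer_coefficients(3.713, 0.0, params)
        assert k1_I == pytest.approx(0.15970258560074851, rel=1e-12)

    @given(c=st.floats(0.1, 10.0), X_B=st.floats(2.0, 8.0))
    @settings(max_examples=50, deadline=None)
    def test_pool_subsystem_linear_in_secretion_maximum(self, params, c, X_B):
        # scaling m_I by c scales R_I, steady pools and efflux by exactly c
        p2 = params.replace(m_I=c * params.m_I)
        pools1 = pool_steady_state(X_B, 1.0, params)
        pools2 = pool_steady_state(X_B, 1.0, p2)
        assert pools2.I1 == pytest.approx(c * pools1.I1, rel=1e-12)
        assert pools2.I2 == pytest.approx(c * pools1.I2, rel=1e-12)
        _, r1, _ = s.pool_rhs(pools1, X_B, 1.0, params)
        _, r2, _ = s.pool_rhs(pools2, X_B, 1.0, p2)
        assert r2 == pytest.approx(c * r1, rel=1e-12)


class TestParameterContainer:
    def test_replace_and_lookup(self, params):
        p2 = params.replace(m_I=50.0)
        assert p2.m_I == 50.0 and params.m_I == 103.0
        assert p2["h_IA"] == 10.0
        with pytest.raises(KeyError):
            params.replace(nonexistent=1.0)

    def test_validation_rejects_bad_values(self):
        with pytest.raises(ValueError):
            s.ModelParameters(h_I=-1.0)
        with pytest.raises(ValueError):
            s.ModelParameters(k_gB=0.0)
        with pytest.warns(UserWarning):
            s.ModelParameters(m_g=1.2)

    def test_yaml_round_trip(self, params, tmp_path):
        path = tmp_path / "params.yaml"
        params.to_yaml(path)
        assert s.ModelParameters.from_yaml(path) == params

    def test_basal_validation(self):
        with pytest.raises(ValueError):
            s.BasalState(g_ba=0.0)
        assert s.BasalState(I_ba=0.0).I_ba == 0.0  # diabetic limit allowed
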
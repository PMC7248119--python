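"""Signal equilibria, response logic and the mass-transfer threshold."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from quorumevo.core_dynamics import (
    DynamicsParams,
    SignalEnvironment,
    equilibrium_auto,
    equilibrium_auto_array,
    equilibrium_no_auto,
    integrate_signal_ode,
    mass_transfer_threshold,
    response_state,
)

loads = st.floats(min_value=1e-8, max_value=1e3)
rates = st.floats(min_value=1e-6, max_value=1.0)
halfsats = st.floats(min_value=1e-2, max_value=1e2)


class TestEquilibriumNoAuto:
    @pytest.mark.parametrize(
        "p, N, u, m, expected",
        [
            # evolved clonal strain at the critical density: S* = pN/u
            (4.37e-9, 5.0016e4, 1e-4, 0.0, 2.1857),
            # same strain at quorate density with equal mass-transfer loss
            (4.37e-9, 8.5e4, 1e-4, 1e-4, 1.857),
        ],
    )
    def test_printed_strain_equilibria(self, p, N, u, m, expected):
        env = SignalEnvironment(N=N, u=u, m=m)
        assert equilibrium_no_auto(p * N, env) == pytest.approx(expected, rel=1e-3)

    def test_zero_production_gives_zero_signal(self):
        env = SignalEnvironment(N=1e4, u=1e-4)
        assert equilibrium_no_auto(0.0, env) == 0.0

    @pytest.mark.parametrize("bad", [float("nan"), float("inf"), -1.0])
    def test_invalid_load_rejected(self, bad):
        env = SignalEnvironment(N=1e4, u=1e-4)
        with pytest.raises(ValueError):
            equilibrium_no_auto(bad, env)

    def test_invalid_environment_rejected(self):
        with pytest.raises(ValueError):
            SignalEnvironment(N=0.0, u=1e-4)
        with pytest.raises(ValueError):
            SignalEnvironment(N=1.0, u=0.0)
        with pytest.raises(ValueError):
            SignalEnvironment(N=1.0, u=1e-4, m=-1e-5)


class TestEquilibriumAuto:
    def test_hand_solved_quadratic(self):
        # loss S^2 + (loss K - A - B) S - A K = 0 with these values reduces
        # to S^2 - 44 S - 5 = 0, positive root (44 + sqrt(1956)) / 2
        env = SignalEnvironment(N=5e4, u=1e-4)
        s = equilibrium_auto(5e-4, 4e-3, DynamicsParams(K=1.0), env)
        assert s == pytest.approx((44 + math.sqrt(1956)) / 2, rel=1e-12)

    def test_no_basal_production_stays_dark(self):
        # without basal production the feedback loop is never primed
        env = SignalEnvironment(N=5e4, u=1e-4)
        assert equilibrium_auto(0.0, 1.0, DynamicsParams(K=1.0), env) == 0.0
        assert equilibrium_auto(0.0, 0.0, DynamicsParams(K=1.0), env) == 0.0

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(A=loads, u=rates, m=st.floats(min_value=0, max_value=1.0), K=halfsats)
    def test_feedback_free_case_is_bit_identical(self, A, u, m, K):
        env = SignalEnvironment(N=1.0, u=u, m=m)
        assert equilibrium_auto(A, 0.0, DynamicsParams(K=K), env) == equilibrium_no_auto(A, env)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        A=loads,
        B=loads,
        u=rates,
        K=halfsats,
        eps=st.floats(min_value=1.01, max_value=2.0),
    )
    def test_monotone_in_loads_and_parameters(self, A, B, u, K, eps):
        env = SignalEnvironment(N=1.0, u=u)
        dyn = DynamicsParams(K=K)
        s = equilibrium_auto(A, B, dyn, env)
        tol = 1e-12 * max(s, 1.0)  # quadratic-root rounding noise
        assert equilibrium_auto(A * eps, B, dyn, env) >= s - tol
        assert equilibrium_auto(A, B * eps, dyn, env) >= s - tol
        assert equilibrium_auto(A, B, dyn, SignalEnvironment(N=1.0, u=u * eps)) <= s + tol
        assert equilibrium_auto(A, B, dyn, SignalEnvironment(N=1.0, u=u, m=u * eps)) <= s + tol
        assert equilibrium_auto(A, B, DynamicsParams(K=K * eps), env) <= s + tol

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(A=loads, B=loads, u=rates, K=halfsats)
    def test_root_is_nonnegative_and_unique(self, A, B, u, K):
        # with A > 0 the quadratic's root product is -AK/loss < 0, so
        # exactly one root is non-negative
        env = SignalEnvironment(N=1.0, u=u)
        s = equilibrium_auto(A, B, DynamicsParams(K=K), env)
        assert s >= 0.0
        other = -A * K / u / s if s > 0 else -1.0
        assert other <= 0.0

    def test_array_form_agrees_with_scalar(self, rng):
        A = rng.uniform(1e-6, 1e2, size=50)
        B = rng.uniform(0.0, 1e2, size=50)
        B[::5] = 0.0
        out = equilibrium_auto_array(A, B, K=3.0, loss=2e-4)
        env = SignalEnvironment(N=1.0, u=2e-4)
        expected = [equilibrium_auto(a, b, DynamicsParams(K=3.0), env) for a, b in zip(A, B)]
        np.testing.assert_array_equal(out, expected)


class TestOdeOracle:
    def test_relaxation_to_feedback_free_equilibrium(self):
        env = SignalEnvironment(N=1.0, u=1e-4)
        state = integrate_signal_ode(5e-4, 0.0, DynamicsParams(K=1.0), env, S0=0.0)
        assert state.S_star == pytest.approx(5.0, rel=1e-6)

    def test_trajectory_started_at_equilibrium_is_flat(self):
        env = SignalEnvironment(N=1.0, u=1e-4)
        state = integrate_signal_ode(5e-4, 0.0, DynamicsParams(K=1.0), env, S0=5.0)
        assert np.allclose(state.trajectory[:, 1], 5.0, rtol=1e-6)

    def test_endpoint_matches_auto_equilibrium(self):
        env = SignalEnvironment(N=5e4, u=1e-4)
        dyn = DynamicsParams(K=1.0)
        state = integrate_signal_ode(5e-4, 4e-3, dyn, env)
        assert state.S_star == pytest.approx(equilibrium_auto(5e-4, 4e-3, dyn, env), rel=1e-6)


class TestResponseState:
    def test_strain_above_threshold_turns_on(self):
        # S* = 2.19 vs evolved threshold 2.15
        assert response_state(2.19, 2.15)

    def test_tie_stays_off(self):
        assert not response_state(2.15, 2.15)

    def test_no_signal_stays_off(self):
        assert not response_state(0.0, 5.0)

    def test_noise_requires_rng_and_is_reproducible(self):
        with pytest.raises(ValueError):
            response_state(1.0, 1.0, noise_sd=0.5)
        draws = [
            response_state(1.0, 1.0, rng=np.random.default_rng(3), noise_sd=0.5)
            for _ in range(2)
        ]
        assert draws[0] == draws[1]


class TestMassTransferThreshold:
    @pytest.mark.parametrize(
        "p, S_Th, expected",
        [
            (4.37e-9, 2.15, 7.277e-5),  # clonal density sensor
            (9.27e-9, 4.63, 7.018e-5),  # intermediate relatedness
            (8.71e-9, 7.27, 1.836e-6),  # low relatedness, threshold inflated
        ],
    )
    def test_evolved_strains(self, p, S_Th, expected):
        m_star = mass_transfer_threshold(p, 8.5e4, 1e-4, S_Th)
        assert m_star == pytest.approx(p * 8.5e4 / S_Th - 1e-4, rel=1e-12)
        assert m_star == pytest.approx(expected, rel=1e-3)

    def test_never_on_when_threshold_unreachable(self):
        # S_Th above pN/u: even a closed environment cannot trigger
        assert mass_transfer_threshold(1e-9, 1e4, 1e-4, 1.0) is None
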
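"""Single-neuron dynamics and cascade resolution."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from mfesim import (NeuronParams, NeuronState, SynapticKernels, apply_reset,
                    relax, resolve_cascade, voltage_jump)

from _oracles import finite_tau_cascades


class TestVoltageJump:
    def test_zero_weight_is_identity(self):
        assert voltage_jump(0.5, 0.0, 14 / 3) == 0.5

    def test_reversal_is_fixed_point(self):
        assert voltage_jump(14 / 3, 5.0, 14 / 3) == pytest.approx(14 / 3)

    def test_closed_form_half_distance(self):
        # w = tau_V ln 2 halves the distance to the reversal
        assert voltage_jump(0.0, 20 * np.log(2), 14 / 3, tau_V=20.0) == \
            pytest.approx(7 / 3, abs=1e-12)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            voltage_jump(0.5, -0.1, 14 / 3)

    def test_finite_tau_ode_converges_to_jump(self, params):
        # integrate the membrane equation with a finite-timescale fast
        # conductance pulse of area w; as tau_fast shrinks the result
        # approaches the instantaneous-jump formula
        w, v0 = 0.4, 0.2
        target = voltage_jump(v0, w, params.V_E, params.tau_V)
        errs = []
        for tau in (1e-2, 1e-3):
            def rhs(t, y):
                g = w / tau * np.exp(-t / tau)
                return (-(y[0] - params.V_L)
                        - g * (y[0] - params.V_E)) / params.tau_V
            sol = solve_ivp(rhs, (0.0, 30 * tau), [v0], rtol=1e-10,
                            atol=1e-12, method="LSODA")
            errs.append(abs(sol.y[0, -1] - target))
        assert errs[1] < errs[0]
        assert errs[1] < 1e-3

    def test_pure_synaptic_ode_matches_exactly(self, params):
        # with the leak switched off (the zero-measure limit), quadrature of
        # the conductance ODE reproduces the jump formula to 1e-6
        w, v0 = 0.7, 0.35
        tau = 1e-3

        def rhs(t, y):
            g = w / tau * np.exp(-t / tau)
            return -g * (y[0] - params.V_E) / params.tau_V

        sol = solve_ivp(rhs, (0.0, 40 * tau), [v0], rtol=1e-11, atol=1e-13,
                        method="LSODA")
        assert sol.y[0, -1] == pytest.approx(
            voltage_jump(v0, w, params.V_E, params.tau_V), abs=1e-6)

    @given(v=st.floats(-0.6, 0.99), w1=st.floats(0.01, 3.0),
           dw=st.floats(0.01, 3.0), toward_E=st.booleans())
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_jump_monotone_in_weight_and_never_past_reversal(self, v, w1, dw,
                                                             toward_E):
        rev = 14 / 3 if toward_E else -2 / 3
        a = voltage_jump(v, w1, rev)
        b = voltage_jump(v, w1 + dw, rev)
        assert abs(b - rev) < abs(a - rev)
        # strictly toward, never past
        assert min(v, rev) <= a <= max(v, rev)


class TestRelax:
    def test_dt_zero_is_identity(self, params, kernels):
        s = NeuronState(V=0.7, g_slow=0.3)
        out, cross = relax(s, params, kernels, 0.0)
        assert (out.V, out.g_slow) == (0.7, 0.3)
        assert cross is None

    def test_free_decay_matches_membrane_time_constant(self, params, kernels):
        s = NeuronState(V=0.9, g_slow=0.0)
        out, _ = relax(s, params, kernels, 37.0)
        assert out.V == pytest.approx(0.9 * np.exp(-37.0 / 20.0), abs=1e-9)

    def test_free_decay_matches_ode(self, params, kernels):
        s = NeuronState(V=0.9, g_slow=0.4)
        dt = 25.0
        out, _ = relax(s, params, kernels, dt, threshold=False)

        def rhs(t, y):
            g = 0.4 * np.exp(-t / kernels.tau_slow)
            return (-(y[0] - params.V_L) - g * (y[0] - params.V_E)) / params.tau_V

        sol = solve_ivp(rhs, (0, dt), [0.9], rtol=1e-11, atol=1e-13)
        assert out.V == pytest.approx(sol.y[0, -1], abs=1e-6)

    def test_clamped_conductance_equilibrium(self, params):
        # with g_slow held at 1 (decay timescale effectively infinite) and
        # the threshold disabled, V settles at (V_L + g V_E)/(1 + g) = 7/3
        frozen = SynapticKernels(tau_slow=1e12)
        s = NeuronState(V=0.0, g_slow=1.0)
        out, _ = relax(s, params, frozen, 400.0, threshold=False)
        assert out.V == pytest.approx(7 / 3, abs=1e-6)

    def test_threshold_crossing_interpolated(self, params):
        frozen = SynapticKernels(tau_slow=1e12)
        s = NeuronState(V=0.5, g_slow=2.0)   # equilibrium 28/9 > V_T
        out, t_cross = relax(s, params, frozen, 50.0)
        assert t_cross is not None
        assert 0.0 < t_cross < 50.0
        assert out.V == params.V_T
        # closed-form crossing of the frozen-conductance solution
        g = 2.0
        vinf = (params.V_L + g * params.V_E) / (1 + g)
        t_exact = -params.tau_V / (1 + g) * np.log((params.V_T - vinf) /
                                                   (0.5 - vinf))
        assert t_cross == pytest.approx(t_exact, abs=2e-3)

    def test_refractory_hold_then_resume(self, params, kernels):
        s = NeuronState(V=0.9, g_slow=0.0, refractory_until=10.0)
        out, _ = relax(s, params, kernels, 4.0, t0=8.0)
        # held at reset for 2 ms, then 2 ms of free decay from reset
        assert out.V == pytest.approx(params.V_reset * np.exp(-0.1), abs=1e-12)


class TestApplyReset:
    def test_reset_fields(self, params):
        s = NeuronState(V=1.0, g_slow=0.2)
        out = apply_reset(s, 10.0, params)
        assert out.V == params.V_reset
        assert out.refractory_until == 10.0 + params.tau_ref
        assert out.g_slow == 0.2


class TestResolveCascade:
    def _weights(self, N):
        return np.zeros((N, N)), np.zeros((N, N))

    def test_singleton_when_targets_far_from_threshold(self, params, rng):
        V = np.array([1.01, 0.4, 0.3])
        is_E = np.array([True, True, False])
        Wf, Ws = self._weights(3)
        Wf[1, 0] = Wf[2, 0] = 0.5
        res = resolve_cascade(V, is_E, Wf, Ws, params, rng)
        assert res.magnitude == 1 and res.fired_E == [0]

    def test_three_neuron_chain_with_inhibitory_suppression(self, params, rng):
        # E1 fires; its jumps push E2 (0.99) and I1 (0.995) over threshold;
        # I1 fires before E2 (larger surplus) and suppresses E3 (0.98)
        V = np.array([1.0, 0.99, 0.995, 0.98])
        is_E = np.array([True, True, False, True])
        Wf, Ws = self._weights(4)
        Wf[1, 0] = 0.1   # E1 -> E2
        Wf[2, 0] = 0.1   # E1 -> I1
        Wf[3, 2] = 0.5   # I1 -> E3
        res = resolve_cascade(V, is_E, Wf, Ws, params, rng, initiating=0)
        assert set(res.fired_E) == {0, 1}
        assert res.fired_I == [2]
        assert res.order[1] == 2          # I1 before E2: larger surplus
        assert res.V_post[3] < 0.98

    def test_fired_set_matches_finite_tau_oracle(self, params, rng):
        from conftest import random_cascade_instance
        for _ in range(25):
            V, is_E, W = random_cascade_instance(rng)
            res = resolve_cascade(V.copy(), is_E, W, np.zeros_like(W),
                                  params, rng)
            fired = np.zeros(len(V), bool)
            fired[res.fired_E + res.fired_I] = True
            oracle = finite_tau_cascades(V[None], is_E, W[None], params,
                                         tau_fast=1e-4)[0]
            assert np.array_equal(fired, oracle)

    def test_inhibition_dominated_cascade_suppresses_nonfirers(self, params,
                                                               rng):
        # I weights strong enough that inhibition dominates after the
        # distance-to-reversal asymmetry is accounted for (near threshold
        # the excitatory driving force is ~3.6x the inhibitory one)
        N = 6
        V = np.concatenate(([1.001], np.array([0.6, 0.7, 0.99, 0.8, 0.75])))
        is_E = np.array([True, True, True, False, True, True])
        Wf = np.zeros((N, N))
        Wf[3, 0] = 0.3                    # initiator recruits the I cell
        Wf[[1, 2, 4, 5], 0] = 0.05        # weak E onto the rest
        Wf[[1, 2, 4, 5], 3] = 1.5         # strong I onto the rest
        res = resolve_cascade(V, is_E, Wf, np.zeros((N, N)), params, rng,
                              initiating=0)
        assert 3 in res.fired_I
        for n in (1, 2, 4, 5):
            if n not in res.fired_E:
                assert res.V_post[n] <= res.V_pre[n]

    def test_single_firing_and_voltage_bounds(self, params, rng):
        from conftest import random_cascade_instance
        for _ in range(200):
            V, is_E, W = random_cascade_instance(rng)
            res = resolve_cascade(V, is_E, W, np.zeros_like(W), params, rng)
            fired = res.fired_E + res.fired_I
            assert len(fired) == len(set(fired)) <= len(V)
            assert res.magnitude >= 1
            not_fired = np.setdiff1d(np.arange(len(V)), fired)
            assert np.all(res.V_post[not_fired] < params.V_T)
            assert np.all(res.V_post >= params.V_I - 1e-12)

    def test_slow_increments_accumulated_not_applied(self, params, rng):
        V = np.array([1.2, 0.2])
        is_E = np.array([True, True])
        Wf = np.zeros((2, 2))
        Ws = np.zeros((2, 2))
        Ws[1, 0] = 2.5
        res = resolve_cascade(V, is_E, Wf, Ws, params, rng)
        assert res.g_slow_increment[1] == 2.5
        assert res.V_post[1] == 0.2       # no fast weight, voltage untouched

    def test_refractory_neurons_ignored(self, params, rng):
        V = np.array([1.1, 2.0])
        is_E = np.array([True, True])
        Wf, Ws = self._weights(2)
        refr = np.array([False, True])
        res = resolve_cascade(V, is_E, Wf, Ws, params, rng, refractory=refr)
        assert res.fired_E == [0]
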
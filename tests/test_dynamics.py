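"""Leaky-unit integration, input summation and transfer function."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fearcircuit import (
    CircuitModel,
    Connection,
    SimConfig,
    UnitSpec,
    UnitState,
    euler_step,
    network_step,
    remap_potential,
    summed_input,
    transfer,
    unmap_potential,
)
from fearcircuit.dynamics import U_MAX
from fearcircuit.engine import CompiledNetwork


class TestEulerStep:
    def test_dt_equal_tau_jumps_to_fixed_point(self):
        assert euler_step(0.0, tonic=1.0, input_sum=2.0, tau=10.0, dt=10.0) == pytest.approx(3.0)

    def test_fixed_point_is_stationary(self):
        # at u = T + I the derivative vanishes (before clamping to pi)
        u = euler_step(2.0, tonic=2.0, input_sum=0.0, tau=20.0, dt=10.0)
        assert u == pytest.approx(2.0)

    def test_matches_exponential_relaxation_at_small_dt(self):
        # closed form: u(t) = u* + (u0 - u*) exp(-t / tau)
        tau, dt = 7.7, 0.1
        u0, target = 0.5, 0.1 + 0.2
        u = u0
        for _ in range(1000):
            u = euler_step(u, tonic=0.1, input_sum=0.2, tau=tau, dt=dt)
        exact = target + (u0 - target) * np.exp(-1000 * dt / tau)
        assert u == pytest.approx(exact, rel=0.01)

    def test_clamped_to_valid_range(self):
        assert euler_step(3.0, tonic=10.0, input_sum=0.0, tau=10.0, dt=10.0) == pytest.approx(U_MAX)
        assert euler_step(0.1, tonic=0.0, input_sum=-10.0, tau=10.0, dt=10.0) == 0.0

    @pytest.mark.parametrize("tau,dt", [(0.0, 10.0), (-1.0, 10.0), (10.0, 0.0)])
    def test_invalid_parameters_rejected(self, tau, dt):
        with pytest.raises(ValueError):
            euler_step(0.0, 0.0, 0.0, tau, dt)


class TestSummedInput:
    def test_empty_sum_is_zero(self):
        assert summed_input([], []) == 0.0

    def test_signed_dot_product(self):
        assert summed_input([2.0, -1.0], [3.0, 4.0]) == pytest.approx(2.0)

    def test_inhibitory_weight_contributes_negatively(self):
        # a 0.7 basket-cell synapse at 10 Hz presynaptic rate
        assert summed_input([-0.7], [10.0]) == pytest.approx(-7.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            summed_input([1.0], [1.0, 2.0])


class TestTransfer:
    def test_zero_at_threshold_and_below(self):
        assert transfer(0.5, psi=0.5, phi=40.0) == 0.0
        assert transfer(0.2, psi=0.5, phi=40.0) == 0.0

    def test_saturates_at_phi(self):
        assert transfer(50.0, psi=0.0, phi=40.0) == pytest.approx(40.0, rel=1e-6)

    def test_tanh_evaluation(self):
        assert transfer(1.5, psi=0.5, phi=40.0) == pytest.approx(40.0 * np.tanh(1.0))

    @given(u=st.floats(0, float(U_MAX)), psi=st.floats(0, 3.0), phi=st.floats(0.01, 200.0))
    @settings(max_examples=200, deadline=None)
    def test_output_bounded_by_phi(self, u, psi, phi):
        a = transfer(u, psi, phi)
        assert 0.0 <= a <= phi


class TestRemap:
    def test_boundaries(self):
        assert remap_potential(-70.0) == 0.0
        assert remap_potential(30.0) == pytest.approx(U_MAX)
        assert remap_potential(-20.0) == pytest.approx(U_MAX / 2)

    def test_out_of_range_clamped(self):
        assert remap_potential(-100.0) == 0.0
        assert remap_potential(100.0) == pytest.approx(U_MAX)

    @given(v=st.floats(-70.0, 30.0))
    @settings(max_examples=100, deadline=None)
    def test_round_trip(self, v):
        assert unmap_potential(remap_potential(v)) == pytest.approx(v, abs=1e-9)


def _tiny_circuit(w=1.0, tonic_a=0.0, tonic_b=0.0):
    units = [
        UnitSpec("a", tau=10.0, tonic=tonic_a, phi=1.0, psi=0.0),
        UnitSpec("b", tau=20.0, tonic=tonic_b, phi=1.0, psi=0.0),
    ]
    return CircuitModel(units=units, connections=[Connection("a", "b", w)])


class TestNetworkStep:
    def test_decay_to_zero_without_drive(self):
        circuit = _tiny_circuit(w=0.0)
        states = {"a": UnitState(u=1.0), "b": UnitState(u=2.0)}
        for _ in range(200):
            states = network_step(states, circuit, {}, SimConfig(dt=5.0))
        assert states["a"].u == pytest.approx(0.0, abs=1e-6)
        assert states["b"].u == pytest.approx(0.0, abs=1e-6)

    def test_constant_drive_converges_to_transfer_of_fixed_point(self):
        circuit = _tiny_circuit(w=0.0)
        states = {"a": UnitState(), "b": UnitState()}
        for _ in range(500):
            states = network_step(states, circuit, {"a": 0.8}, SimConfig(dt=5.0))
        assert states["a"].u == pytest.approx(0.8, abs=1e-6)
        assert states["a"].a == pytest.approx(np.tanh(0.8), abs=1e-6)

    def test_unknown_unit_in_external_drive_rejected(self):
        circuit = _tiny_circuit()
        states = {"a": UnitState(), "b": UnitState()}
        with pytest.raises(KeyError):
            network_step(states, circuit, {"nope": 1.0}, SimConfig())

    def test_states_must_cover_circuit(self):
        circuit = _tiny_circuit()
        with pytest.raises(KeyError):
            network_step({"a": UnitState()}, circuit, {}, SimConfig())

    def test_chain_steady_state_dt_robust(self):
        # two-unit excitatory chain: steady state at dt=1 ms vs dt=10 ms
        circuit = _tiny_circuit(w=1.5, tonic_a=0.6)
        finals = {}
        for dt in (1.0, 10.0):
            net = CompiledNetwork(circuit, SimConfig(dt=dt))
            for _ in range(int(2000 / dt)):
                net.step()
            finals[dt] = net.a.copy()
        assert finals[1.0] == pytest.approx(finals[10.0], rel=0.05)


class TestDefaultCircuitDynamics:
    def test_activations_and_potentials_bounded(self, model):
        from fearcircuit.protocols import Simulation, make_conditioning

        sim = Simulation(model)
        trace = sim.run(make_conditioning(n_trials=1))
        phi = np.array([u.phi for u in model.units])
        assert (trace.activations >= 0.0).all()
        assert (trace.activations <= phi + 1e-12).all()
        assert (sim.net.u >= 0.0).all() and (sim.net.u <= U_MAX).all()

    def test_single_unit_engine_matches_closed_form(self, model):
        # dt <= tau/10: the compiled network tracks the exponential
        spec = model.unit("CeM")
        circuit = CircuitModel(
            units=[UnitSpec("x", tau=spec.tau, tonic=0.3, phi=spec.phi, psi=spec.psi)],
            connections=[],
        )
        dt = spec.tau / 10.0
        net = CompiledNetwork(circuit, SimConfig(dt=dt))
        n = 400
        for _ in range(n):
            net.step()
        exact = 0.3 * (1.0 - np.exp(-n * dt / spec.tau))
        assert net.u[0] == pytest.approx(exact, rel=0.01)
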
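"""Hebbian LTP/LTD and endocannabinoid DSI/DSE rules."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fearcircuit import SimConfig, Simulation, make_extinction
from fearcircuit.engine import CompiledNetwork
from fearcircuit.plasticity import (
    Blockade,
    PlasticityState,
    apply_plasticity,
    dsi_dse_delta,
    ltp_ltd_delta,
    update_depolarization_timer,
)


class TestLtpLtdDelta:
    def test_zero_at_postsynaptic_threshold(self):
        assert ltp_ltd_delta(w=1.0, pre=1.0, post=0.5, eta=0.01, M=3.0, sigma=0.5, phi=1.0) == 0.0

    def test_zero_at_weight_ceiling(self):
        assert ltp_ltd_delta(w=3.0, pre=1.0, post=2.0, eta=0.01, M=3.0, sigma=0.5, phi=1.0) == 0.0

    def test_zero_without_presynaptic_firing(self):
        assert ltp_ltd_delta(w=1.0, pre=0.0, post=2.0, eta=0.01, M=3.0, sigma=0.5, phi=1.0) == 0.0

    def test_direct_substitution(self):
        # eta*(M-w)*(post - phi*sigma)*pre = 0.01*2*1*1
        assert ltp_ltd_delta(w=1.0, pre=1.0, post=2.0, eta=0.01, M=3.0, sigma=0.5, phi=2.0) == pytest.approx(0.02)

    def test_sign_follows_postsynaptic_activity(self):
        up = ltp_ltd_delta(w=1.0, pre=1.0, post=0.9, eta=0.01, M=3.0, sigma=0.5, phi=1.0)
        down = ltp_ltd_delta(w=1.0, pre=1.0, post=0.1, eta=0.01, M=3.0, sigma=0.5, phi=1.0)
        assert up > 0 > down


class TestDsiDseDelta:
    def test_silent_before_trigger(self):
        assert dsi_dse_delta(w=2.0, pre=1.0, eta=0.1, timer=9.99, trigger_s=10.0) == 0.0

    def test_zero_without_presynaptic_firing(self):
        assert dsi_dse_delta(w=2.0, pre=0.0, eta=0.1, timer=15.0, trigger_s=10.0) == 0.0

    def test_multiplicative_depression(self):
        assert dsi_dse_delta(w=2.0, pre=1.0, eta=0.1, timer=10.0, trigger_s=10.0) == pytest.approx(-0.2)

    @given(w=st.floats(0.001, 10.0), pre=st.floats(0.0, 2.0), eta=st.floats(0.0, 0.4))
    @settings(max_examples=100, deadline=None)
    def test_weight_stays_positive(self, w, pre, eta):
        # per-step multiplicative decay cannot cross zero for eta*pre < 1
        delta = dsi_dse_delta(w, pre, eta, timer=20.0, trigger_s=10.0)
        assert w + delta > 0 or eta * pre >= 1.0


class TestDepolarizationTimer:
    def test_accumulates_to_trigger_in_ten_seconds(self):
        t = 0.0
        for _ in range(1000):  # 1000 steps at 10 ms
            t = update_depolarization_timer(t, post_activation=1.0, phi=1.0, dt=10.0, theta=0.2)
        assert t == pytest.approx(10.0)

    def test_resets_on_subthreshold_dip(self):
        t = 9.0
        t = update_depolarization_timer(t, post_activation=0.05, phi=1.0, dt=10.0, theta=0.2)
        assert t == 0.0

    def test_stays_zero_without_activity(self):
        t = 0.0
        for _ in range(100):
            t = update_depolarization_timer(t, 0.0, 1.0, 10.0)
        assert t == 0.0


def _dsi_pair():
    """Tonic presynaptic interneuron, CS-driven postsynaptic cell, one
    DSI synapse: the minimal setup in which the trigger and the
    multiplicative decay are exactly predictable."""
    from fearcircuit import CircuitModel, Connection, PlasticitySpec, UnitSpec
    from fearcircuit.dynamics import Polarity

    units = [
        UnitSpec("inter", tau=10.0, tonic=1.0, phi=1.0, psi=0.2, polarity=Polarity.INHIBITORY),
        UnitSpec("post", tau=10.0, tonic=0.0, phi=1.0, psi=0.2),
    ]
    conns = [
        Connection("CS", "post", 0.05),
        Connection("inter", "post", 2.0, PlasticitySpec(rule="DSI", eta=0.001, trigger_s=10.0)),
    ]
    return CircuitModel(units=units, connections=conns, dsi_theta=0.2)


class TestEngineRules:
    def test_dsi_triggers_after_ten_seconds_then_decays_multiplicatively(self):
        """W is untouched until 10 s of sustained postsynaptic activity,
        then follows W0 * prod(1 - eta*pre) exactly."""
        net = CompiledNetwork(_dsi_pair(), SimConfig())
        j = net.conn_index["inter->post"]
        eta = net.trans_eta[0]
        w0 = net.w[j]
        pre_idx = net.unit_index["inter"]
        factor = 1.0
        for k in range(1300):  # 13 s of CS drive at dt=10 ms
            net.step(cs=100.0)
            # the step's weight update used the freshly advanced timer
            # and the freshly computed activations
            if net.timers[0] >= 10.0:
                factor *= 1.0 - eta * net.a[pre_idx]
            if k == 950:  # still within the trigger window
                assert net.w[j] == w0
        assert net.timers[0] > 10.0
        assert net.w[j] < w0
        assert net.w[j] == pytest.approx(w0 * factor, rel=1e-9)

    def test_hebbian_weight_respects_ceiling_and_floor(self, model):
        m = model.copy()
        spec = m.connection("CS->LAp1")
        assert spec.ceiling == pytest.approx(3.0 * spec.initial_weight)
        net = CompiledNetwork(m, SimConfig())
        j = net.conn_index["CS->LAp1"]
        for _ in range(3000):
            net.step(cs=100.0, us=100.0)  # saturating co-activation
        assert net.w[j] <= spec.ceiling + 1e-12
        assert (net.w >= 0.0).all()

    def test_frozen_disables_all_updates(self, model):
        sim = Simulation(model)
        w0 = sim.weights()
        sim.run(make_extinction(n_cs=2), frozen=True, record=False)
        assert sim.weights() == w0

    def test_transient_reset_reversibility(self, model):
        """Snapshot -> extinction trials -> transient restore leaves the
        DSI/DSE weights bit-identical while Hebbian changes persist."""
        from fearcircuit import make_conditioning

        sim = Simulation(model)
        sim.run(make_conditioning(), record=False)  # fear established: CS now drives the circuit
        sim.reset_transient()
        before = sim.weights()
        sim.run(make_extinction(n_cs=3), record=False)
        during = sim.weights()
        assert during["BAp5->CeM"] < before["BAp5->CeM"]  # DSE engaged
        assert during["BAcck->BAp2"] < before["BAcck->BAp2"]  # DSI engaged
        sim.reset_transient()
        after = sim.weights()
        for cid in ("BAcck->BAp2", "BAp4->CeM", "BAp5->CeM"):
            assert after[cid] == before[cid]

    def test_learning_rate_scales_with_dt(self, model):
        """Per-step rates are defined at the 10-ms reference step, so the
        same simulated time produces comparable weight change at dt=1."""
        deltas = {}
        for dt in (10.0, 1.0):
            net = CompiledNetwork(model.copy(), SimConfig(dt=dt))
            j = net.conn_index["CS->LAp1"]
            w0 = net.w[j]
            for _ in range(int(2000 / dt)):  # 2 s of CS+US pairing
                net.step(cs=100.0, us=100.0)
            deltas[dt] = net.w[j] - w0
        assert deltas[1.0] == pytest.approx(deltas[10.0], rel=0.1)


class TestApplyPlasticityScalar:
    def test_unknown_blockade_region_rejected(self, model):
        m = model.copy()
        acts = {u.name: 0.0 for u in m.units}
        with pytest.raises(ValueError, match="blockade region"):
            apply_plasticity(m, acts, PlasticityState(), blocked=(Blockade(region="Cortex"),), dt=10.0)

    def test_no_change_without_activity(self, model):
        m = model.copy()
        acts = {u.name: 0.0 for u in m.units}
        before = {c.id: c.weight for c in m.connections}
        apply_plasticity(m, acts, PlasticityState(), dt=10.0)
        assert {c.id: c.weight for c in m.connections} == before

    def test_blockade_pins_targeted_rule(self, model):
        m = model.copy()
        acts = {u.name: 0.3 * u.phi for u in m.units}
        state = PlasticityState(timers={c.post: 100.0 for c in m.plastic_connections})
        w0 = m.connection("BAcck->BAp2").weight
        apply_plasticity(m, acts, state, blocked=(Blockade(rule="DSI", region="BA"),), dt=10.0)
        assert m.connection("BAcck->BAp2").weight == w0
        assert m.connection("BAp4->CeM").weight < 2.0  # DSE unblocked
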
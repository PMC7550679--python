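"""Stimulus schedules and protocol execution."""

import numpy as np
import pytest

from fearcircuit import (
    Protocol,
    SimConfig,
    Simulation,
    StimulusEpoch,
    make_conditioning,
    make_extinction,
    make_reinstatement,
    run_protocol,
    standard_protocol,
)
from fearcircuit.protocols import load_protocol, protocol_from_dict


class TestBuilders:
    def test_conditioning_defaults(self):
        p = make_conditioning()
        cs = p.epochs_of("CS")
        us = p.epochs_of("US")
        assert len(cs) == 3 and len(us) == 3
        for c, u in zip(cs, us):
            assert c.duration == 20.0
            assert u.duration == 0.5
            assert u.t_end == pytest.approx(c.t_end)  # US coterminous with its CS

    def test_empty_and_cs_only_conditioning(self):
        assert make_conditioning(n_trials=0).epochs == []
        p = make_conditioning(us_s=0.0)
        assert p.epochs_of("US") == []
        assert len(p.epochs_of("CS")) == 3

    def test_us_longer_than_cs_rejected(self):
        with pytest.raises(ValueError):
            make_conditioning(cs_s=10.0, us_s=11.0)

    def test_extinction_defaults(self):
        p = make_extinction()
        assert len(p.epochs_of("CS")) == 20
        assert p.epochs_of("US") == []

    def test_reinstatement_sequence(self):
        p = make_reinstatement()
        kinds = [e.channel for e in sorted(p.epochs, key=lambda e: e.t_start)]
        durs = [e.duration for e in sorted(p.epochs, key=lambda e: e.t_start)]
        assert kinds == ["CS", "US", "CS"]
        assert durs == [20.0, 0.5, 20.0]
        # channels never overlap
        for a, b in zip(p.epochs, p.epochs[1:]):
            assert b.t_start >= a.t_end

    def test_amplitude_override_propagates(self):
        p = make_extinction(n_cs=2, amplitude=50.0)
        assert all(e.amplitude == 50.0 for e in p.epochs)

    def test_chaining_inserts_session_boundary(self):
        p = make_extinction(n_cs=2) + make_extinction(n_cs=2)
        assert len(p.session_boundaries) == 1
        assert p.session_boundaries[0] == pytest.approx(make_extinction(n_cs=2).duration)

    def test_overlapping_epochs_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            Protocol("bad", [StimulusEpoch(0.0, 10.0, "CS"), StimulusEpoch(5.0, 10.0, "CS")])

    def test_standard_protocol_has_four_sessions(self):
        p = standard_protocol()
        assert len(p.session_boundaries) == 3
        assert len(p.epochs_of("CS")) == 3 + 20 + 20 + 2


class TestProtocolConfig:
    def test_named_protocol(self):
        p = protocol_from_dict({"protocol": "standard"})
        assert len(p.epochs_of("CS")) == 45

    def test_session_list_round_trip(self, tmp_path):
        doc = {"sessions": [{"type": "conditioning", "n_trials": 2}, {"type": "extinction", "n_cs": 5}]}
        path = tmp_path / "proto.yaml"
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh)
        p = load_protocol(path)
        assert len(p.epochs_of("CS")) == 7
        assert len(p.session_boundaries) == 1

    def test_unknown_session_type_rejected(self):
        with pytest.raises(ValueError, match="session type"):
            protocol_from_dict({"sessions": [{"type": "renewal"}]})


class TestExecution:
    def test_trace_length_matches_duration(self, model):
        p = make_extinction(n_cs=1)
        trace = run_protocol(model, p, SimConfig(dt=10.0))
        assert len(trace.times) == int(round(p.duration * 100))
        assert trace.activations.shape == (len(trace.times), 21)

    def test_replays_are_bit_identical(self, model):
        t1 = run_protocol(model, make_conditioning(n_trials=1), SimConfig())
        t2 = run_protocol(model, make_conditioning(n_trials=1), SimConfig())
        assert np.array_equal(t1.activations, t2.activations)
        assert np.array_equal(t1.weights, t2.weights)

    def test_empty_protocol_stays_at_baseline(self, model):
        trace = run_protocol(model, Protocol("baseline", [], tail_s=5.0))
        # pyramidal units sit at their (near-zero) tonic level throughout
        for name in ("LAp1", "BAp1", "PLp", "CeM"):
            assert trace.activation(name).max() < 0.05 * model.unit(name).phi

    def test_unknown_perturbation_target_rejected(self, model):
        from fearcircuit.perturb import lesion

        sim = Simulation(model)
        with pytest.raises(ValueError, match="unknown unit"):
            sim.run(make_extinction(n_cs=1), perturbations=[lesion("Thalamus")])

    def test_trace_frame_is_tidy(self, model):
        trace = run_protocol(model, make_extinction(n_cs=1), SimConfig())
        df = trace.to_frame(stride=50)
        assert set(df.columns) == {"time_s", "kind", "name", "value"}
        assert set(df["kind"]) == {"activation", "weight"}
        assert df[df.kind == "activation"]["name"].nunique() == 21
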
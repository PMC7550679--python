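"""Circuit structure, serialization and weight bookkeeping."""

import pytest
import yaml

from fearcircuit import (
    PlasticityRule,
    load_circuit,
    restore_weights,
    save_circuit,
    snapshot_weights,
)
from fearcircuit.circuit import circuit_from_dict, circuit_to_dict
from fearcircuit.dynamics import Polarity


class TestDefaultRoster:
    def test_unit_counts(self, model):
        exc = [u for u in model.units if u.polarity is Polarity.EXCITATORY]
        inh = [u for u in model.units if u.polarity is Polarity.INHIBITORY]
        assert len(model.units) == 21
        assert len(exc) == 9
        assert len(inh) == 12

    def test_pyramidal_units(self, model):
        exc = {u.name for u in model.units if u.polarity is Polarity.EXCITATORY}
        assert exc == {"LAp1", "LAp2", "BAp1", "BAp2", "BAp3", "BAp4", "BAp5", "PLp", "ILp"}

    def test_plastic_connection_roster(self, model):
        rules = {c.id: c.plasticity.rule for c in model.plastic_connections}
        assert rules == {
            "CS->LAp1": PlasticityRule.LTP,
            "LAp2->CeL-ON": PlasticityRule.LTP,
            "PLp->BAp4": PlasticityRule.LTP_LTD,
            "BAp2->ILp": PlasticityRule.LTP_LTD,
            "BAp3->ITC": PlasticityRule.LTP,
            "BAcck->BAp2": PlasticityRule.DSI,
            "BAp4->CeM": PlasticityRule.DSE,
            "BAp5->CeM": PlasticityRule.DSE,
        }

    def test_basket_cell_weights(self, model):
        assert model.connection("BAcck->BAp1").weight == pytest.approx(0.7)
        assert model.connection("BAcck->BAp2").weight == pytest.approx(0.7)

    def test_la_fan_out_weights(self, model):
        assert model.connection("LAp1->BAp1").weight == pytest.approx(7.0)
        assert model.connection("LAp1->BAp2").weight == pytest.approx(5.0)
        assert model.connection("LAp1->BAp5").weight == pytest.approx(3.0)

    def test_stimulus_drive(self, model):
        assert model.external_inputs == {"CS": 100.0, "US": 100.0}

    def test_tau_within_published_bounds(self, model):
        for u in model.units:
            assert 7.7 <= u.tau <= 35.6

    def test_removed_legacy_connections_absent(self, model):
        ids = {c.id for c in model.connections}
        assert "US->CeM" not in ids
        assert not any("BApv2" in i for i in ids)
        assert "BApv2" not in model.unit_names


class TestSerialization:
    def test_round_trip_is_lossless(self, model, tmp_path):
        path = tmp_path / "circuit.yaml"
        save_circuit(model, path)
        again = load_circuit(path)
        assert circuit_to_dict(again) == circuit_to_dict(model)

    def test_unknown_unit_reference_rejected(self, model, tmp_path):
        doc = circuit_to_dict(model)
        doc["connections"].append({"pre": "LAp1", "post": "Nonexistent", "weight": 1.0})
        with pytest.raises(ValueError, match="Nonexistent"):
            circuit_from_dict(doc)

    def test_negative_weight_rejected(self, model):
        doc = circuit_to_dict(model)
        doc["connections"][0]["weight"] = -1.0
        with pytest.raises(ValueError, match="negative weight"):
            circuit_from_dict(doc)

    def test_missing_plasticity_field_names_entry(self, model):
        doc = circuit_to_dict(model)
        doc["connections"] = [{"pre": "CS", "post": "LAp1", "weight": 1.0, "plasticity": {"rule": "LTP"}}]
        with pytest.raises(ValueError, match="CS->LAp1"):
            circuit_from_dict(doc)

    def test_override_single_weight_leaves_rest_unchanged(self, model, tmp_path):
        doc = circuit_to_dict(model)
        for c in doc["connections"]:
            if c["pre"] == "LAp1" and c["post"] == "BAp1":
                c["weight"] = 6.5
        path = tmp_path / "override.yaml"
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh)
        modified = load_circuit(path)
        assert modified.connection("LAp1->BAp1").weight == pytest.approx(6.5)
        for c in model.connections:
            if c.id != "LAp1->BAp1":
                assert modified.connection(c.id).weight == pytest.approx(c.weight)


class TestWeightSnapshots:
    def test_restore_after_no_change_is_identity(self, model):
        m = model.copy()
        table = snapshot_weights(m)
        restore_weights(m, table, only_transient=True)
        assert snapshot_weights(m) == table

    def test_only_transient_restores_dsi_dse_but_keeps_hebbian(self, model):
        m = model.copy()
        table = snapshot_weights(m)
        m.connection("BAcck->BAp2").weight = 0.1  # DSI-weakened
        m.connection("BAp2->ILp").weight = 5.0  # LTP-strengthened
        restore_weights(m, table, only_transient=True)
        assert m.connection("BAcck->BAp2").weight == pytest.approx(table["BAcck->BAp2"])
        assert m.connection("BAp2->ILp").weight == pytest.approx(5.0)

    def test_full_restore_reverts_everything(self, model):
        m = model.copy()
        table = snapshot_weights(m)
        m.connection("BAp2->ILp").weight = 5.0
        restore_weights(m, table, only_transient=False)
        assert m.connection("BAp2->ILp").weight == pytest.approx(table["BAp2->ILp"])

    def test_incomplete_table_rejected(self, model):
        m = model.copy()
        table = snapshot_weights(m)
        table.pop("BAcck->BAp2")
        with pytest.raises(KeyError):
            restore_weights(m, table)
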
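"""Fear-circuit architecture: units, connections, plasticity attachments.

The default model is the amygdala-prefrontal circuit for cued fear:
sensory CS/US inputs reach the lateral amygdala (LA), which drives the
central amygdala output (CeM) through three routes — a persistent route
(LA-BA-CeM and LA-CeL-CeM), a fear route through the prelimbic cortex
(LA-BA-PL-BA-CeM), and an extinction route through the infralimbic
cortex and the intercalated cells (BA-IL-BA-ITC-BA-CeM).

The circuit is serialized as a YAML document (sections ``units``,
``connections``, ``external_inputs``); the calibrated default
configuration ships with the package in ``data/default_circuit.yaml``.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional

import yaml

from .dynamics import NeuronClass, Polarity, UnitSpec

__all__ = [
    "PlasticityRule",
    "PlasticitySpec",
    "Connection",
    "CircuitModel",
    "EXTERNAL_INPUTS",
    "build_default_circuit",
    "default_circuit_path",
    "load_circuit",
    "save_circuit",
    "snapshot_weights",
    "restore_weights",
]

#: Names of the two external stimulus channels.
EXTERNAL_INPUTS = ("CS", "US")

CONFIG_VERSION = 1


class PlasticityRule(str, Enum):
    """Learning rule attached to a connection.

    ``LTP`` is the Hebbian rule restricted to potentiation (connections
    the literature reports as potentiating but never depotentiating,
    e.g. the CS pathway onto LA); ``LTP_LTD`` applies the same rule
    bidirectionally; ``DSI``/``DSE`` are the transient endocannabinoid
    depression of inhibitory/excitatory afferents, engaged after
    sustained postsynaptic depolarization and reset between sessions.
    """

    LTP = "LTP"
    LTP_LTD = "LTP_LTD"
    DSI = "DSI"
    DSE = "DSE"

    @property
    def transient(self) -> bool:
        return self in (PlasticityRule.DSI, PlasticityRule.DSE)

    @property
    def hebbian(self) -> bool:
        return self in (PlasticityRule.LTP, PlasticityRule.LTP_LTD)


@dataclass
class PlasticitySpec:
    """Parameters of the learning rule on one connection.

    ``eta`` (and ``eta_ltd`` for bidirectional Hebbian connections) are
    per-integration-step rate constants; ``M`` is the weight ceiling of
    the Hebbian rule (default 3x the initial weight when left ``None``);
    ``sigma`` is the postsynaptic threshold fraction (LTP above
    ``sigma * phi_post``, LTD below); ``trigger_s`` is the sustained
    depolarization time, in seconds, before DSI/DSE engages.
    """

    rule: PlasticityRule
    eta: float
    eta_ltd: Optional[float] = None
    M: Optional[float] = None
    sigma: Optional[float] = None
    sigma_ltd: Optional[float] = None
    trigger_s: float = 10.0
    #: Hebbian LTD engages only after the (presynaptically active,
    #: postsynaptically sub-threshold) pattern has persisted this long,
    #: in seconds; 0 disables the hold.  Protects against the ~100-ms
    #: feedforward onset transients at stimulus edges.
    ltd_hold_s: float = 0.0

    def __post_init__(self) -> None:
        self.rule = PlasticityRule(self.rule)
        if not self.eta > 0:
            raise ValueError(f"eta must be > 0, got {self.eta}")
        if self.eta_ltd is not None and self.eta_ltd < 0:
            raise ValueError("eta_ltd must be >= 0")
        if self.rule.hebbian:
            if self.sigma is None or not 0 <= self.sigma <= 1:
                raise ValueError(f"sigma must be in [0, 1] for {self.rule}, got {self.sigma}")
            if self.sigma_ltd is not None and not 0 <= self.sigma_ltd <= self.sigma:
                raise ValueError("sigma_ltd must be in [0, sigma]")
            if self.M is not None and not self.M > 0:
                raise ValueError("M must be > 0")
        if self.trigger_s < 0:
            raise ValueError("trigger_s must be >= 0")
        if self.ltd_hold_s < 0:
            raise ValueError("ltd_hold_s must be >= 0")

    @property
    def transient(self) -> bool:
        return self.rule.transient


@dataclass
class Connection:
    """Directed weighted edge; ``pre`` may be a unit or CS/US."""

    pre: str
    post: str
    weight: float
    plasticity: Optional[PlasticitySpec] = None
    initial_weight: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError(f"connection {self.id}: weight must be >= 0, got {self.weight}")
        if self.initial_weight is None:
            self.initial_weight = self.weight

    @property
    def id(self) -> str:
        return f"{self.pre}->{self.post}"

    @property
    def ceiling(self) -> Optional[float]:
        """Hebbian weight cap M (3x the initial weight unless overridden)."""
        if self.plasticity is None or not self.plasticity.rule.hebbian:
            return None
        if self.plasticity.M is not None:
            return self.plasticity.M
        return 3.0 * self.initial_weight


@dataclass
class CircuitModel:
    """The full network: units, connections and stimulus entry points.

    ``external_inputs`` maps CS/US to their step-input drive (100 by
    default); ``dsi_theta`` is the depolarization threshold of the
    endocannabinoid trigger as a fraction of the postsynaptic maximum
    rate.
    """

    units: list[UnitSpec]
    connections: list[Connection]
    external_inputs: dict[str, float] = field(default_factory=lambda: {"CS": 100.0, "US": 100.0})
    dsi_theta: float = 0.2
    description: str = ""

    def __post_init__(self) -> None:
        self.validate()

    # -- lookups -------------------------------------------------------
    def unit(self, name: str) -> UnitSpec:
        for u in self.units:
            if u.name == name:
                return u
        raise KeyError(f"unknown unit {name!r}")

    def connection(self, conn_id: str) -> Connection:
        for c in self.connections:
            if c.id == conn_id:
                return c
        raise KeyError(f"unknown connection {conn_id!r}")

    @property
    def unit_names(self) -> list[str]:
        return [u.name for u in self.units]

    @property
    def plastic_connections(self) -> list[Connection]:
        return [c for c in self.connections if c.plasticity is not None]

    def validate(self) -> None:
        names = self.unit_names
        if len(set(names)) != len(names):
            raise ValueError("duplicate unit names")
        if set(self.external_inputs) != set(EXTERNAL_INPUTS):
            raise ValueError(f"external inputs must be exactly {EXTERNAL_INPUTS}")
        seen = set()
        for c in self.connections:
            if c.pre not in names and c.pre not in EXTERNAL_INPUTS:
                raise ValueError(f"connection {c.id}: unknown presynaptic element {c.pre!r}")
            if c.post not in names:
                raise ValueError(f"connection {c.id}: unknown postsynaptic unit {c.post!r}")
            if c.id in seen:
                raise ValueError(f"duplicate connection {c.id}")
            seen.add(c.id)
        if not 0 < self.dsi_theta < 1:
            raise ValueError("dsi_theta must be in (0, 1)")

    def copy(self) -> "CircuitModel":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# serialization


def _unit_to_dict(u: UnitSpec) -> dict:
    return {
        "name": u.name,
        "tau": u.tau,
        "tonic": u.tonic,
        "phi": u.phi,
        "psi": u.psi,
        "polarity": u.polarity.value,
        "class": u.neuron_class.value,
    }


def _unit_from_dict(d: Mapping) -> UnitSpec:
    try:
        return UnitSpec(
            name=d["name"],
            tau=float(d["tau"]),
            tonic=float(d["tonic"]),
            phi=float(d["phi"]),
            psi=float(d["psi"]),
            polarity=Polarity(d.get("polarity", "excitatory")),
            neuron_class=NeuronClass(d.get("class", "other")),
        )
    except KeyError as e:
        raise ValueError(f"unit entry {d.get('name', d)!r}: missing field {e}") from e


def _plasticity_to_dict(p: PlasticitySpec) -> dict:
    out: dict = {"rule": p.rule.value, "eta": p.eta}
    if p.eta_ltd is not None:
        out["eta_ltd"] = p.eta_ltd
    if p.M is not None:
        out["M"] = p.M
    if p.sigma is not None:
        out["sigma"] = p.sigma
    if p.sigma_ltd is not None:
        out["sigma_ltd"] = p.sigma_ltd
    if p.ltd_hold_s:
        out["ltd_hold_s"] = p.ltd_hold_s
    if p.rule.transient:
        out["trigger_s"] = p.trigger_s
    return out


def _plasticity_from_dict(d: Mapping, conn_id: str) -> PlasticitySpec:
    if "rule" not in d or "eta" not in d:
        raise ValueError(f"plasticity on {conn_id}: 'rule' and 'eta' are required")
    return PlasticitySpec(
        rule=PlasticityRule(d["rule"]),
        eta=float(d["eta"]),
        eta_ltd=float(d["eta_ltd"]) if "eta_ltd" in d else None,
        M=float(d["M"]) if "M" in d else None,
        sigma=float(d["sigma"]) if "sigma" in d else None,
        sigma_ltd=float(d["sigma_ltd"]) if "sigma_ltd" in d else None,
        trigger_s=float(d.get("trigger_s", 10.0)),
        ltd_hold_s=float(d.get("ltd_hold_s", 0.0)),
    )


def circuit_to_dict(model: CircuitModel) -> dict:
    conns = []
    for c in model.connections:
        d: dict = {"pre": c.pre, "post": c.post, "weight": c.weight}
        if c.plasticity is not None:
            d["plasticity"] = _plasticity_to_dict(c.plasticity)
        conns.append(d)
    return {
        "version": CONFIG_VERSION,
        "description": model.description,
        "external_inputs": dict(model.external_inputs),
        "dsi_theta": model.dsi_theta,
        "units": [_unit_to_dict(u) for u in model.units],
        "connections": conns,
    }


def circuit_from_dict(doc: Mapping) -> CircuitModel:
    if doc.get("version", CONFIG_VERSION) != CONFIG_VERSION:
        raise ValueError(f"unsupported config version {doc.get('version')}")
    units = [_unit_from_dict(d) for d in doc.get("units", [])]
    conns = []
    for d in doc.get("connections", []):
        cid = f"{d.get('pre')}->{d.get('post')}"
        if "weight" not in d:
            raise ValueError(f"connection {cid}: missing weight")
        w = float(d["weight"])
        if w < 0:
            raise ValueError(f"connection {cid}: negative weight {w}")
        plast = _plasticity_from_dict(d["plasticity"], cid) if d.get("plasticity") else None
        conns.append(Connection(pre=d["pre"], post=d["post"], weight=w, plasticity=plast))
    return CircuitModel(
        units=units,
        connections=conns,
        external_inputs={k: float(v) for k, v in doc.get("external_inputs", {"CS": 100.0, "US": 100.0}).items()},
        dsi_theta=float(doc.get("dsi_theta", 0.2)),
        description=doc.get("description", ""),
    )


def load_circuit(path) -> CircuitModel:
    """Load a circuit config; raises ``ValueError`` naming any bad entry."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: not a mapping")
    return circuit_from_dict(doc)


def save_circuit(model: CircuitModel, path) -> None:
    """Write the config so that load(save(m)) reproduces ``m`` exactly."""
    with open(path, "w") as fh:
        yaml.safe_dump(circuit_to_dict(model), fh, sort_keys=False)


def default_circuit_path() -> Path:
    return Path(str(resources.files("fearcircuit").joinpath("data/default_circuit.yaml")))


def build_default_circuit() -> CircuitModel:
    """The calibrated default fear circuit (21 units, 2 stimulus channels)."""
    return load_circuit(default_circuit_path())


# ---------------------------------------------------------------------------
# weight snapshots (between-session reset of transient plasticity)


def snapshot_weights(model: CircuitModel) -> dict[str, float]:
    return {c.id: c.weight for c in model.connections}


def restore_weights(model: CircuitModel, table: Mapping[str, float], only_transient: bool = False) -> None:
    """Restore weights from a snapshot.

    With ``only_transient=True`` only DSI/DSE-attached connections are
    restored (the between-session forgetting of endocannabinoid
    depression); Hebbian (LTP/LTD) changes persist.
    """
    missing = {c.id for c in model.connections} - set(table)
    if missing:
        raise KeyError(f"snapshot does not cover connections: {sorted(missing)}")
    for c in model.connections:
        if only_transient and not (c.plasticity is not None and c.plasticity.transient):
            continue
        c.weight = float(table[c.id])
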
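"""Stimulus protocols and protocol execution.

The behavioral paradigm is cued fear conditioning: conditioning pairs
three 20-s CS presentations with a 0.5-s US that terminates with the
CS; extinction presents twenty 20-s CS alone; reinstatement is a 20-s
CS, one unpaired 0.5-s US, and a final 20-s CS.  Sessions are separated
by boundaries at which the transient (DSI/DSE) weight changes are
forgotten.

Inter-trial intervals are not part of the published protocol
description; the default of 5 s is far longer than the slowest membrane
time constant (35.6 ms), so every unit is back at its tonic fixed point
well before the next trial.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .circuit import CircuitModel
from .dynamics import SimConfig
from .engine import CompiledNetwork
from .perturb import Perturbation

__all__ = [
    "StimulusEpoch",
    "Protocol",
    "SessionTrace",
    "Simulation",
    "make_conditioning",
    "make_extinction",
    "make_reinstatement",
    "standard_protocol",
    "run_protocol",
    "DEFAULT_ITI_S",
    "DEFAULT_LEAD_S",
]

DEFAULT_ITI_S = 5.0
DEFAULT_LEAD_S = 2.0


@dataclass(frozen=True)
class StimulusEpoch:
    t_start: float
    duration: float
    channel: str  # CS | US
    amplitude: Optional[float] = None  # None -> circuit's external input drive

    def __post_init__(self) -> None:
        if self.channel not in ("CS", "US"):
            raise ValueError(f"channel must be CS or US, got {self.channel!r}")
        if not self.duration > 0:
            raise ValueError("epoch duration must be > 0")
        if self.amplitude is not None and self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")

    @property
    def t_end(self) -> float:
        return self.t_start + self.duration


@dataclass
class Protocol:
    name: str
    epochs: list[StimulusEpoch] = field(default_factory=list)
    session_boundaries: list[float] = field(default_factory=list)
    tail_s: float = DEFAULT_ITI_S

    def __post_init__(self) -> None:
        for ch in ("CS", "US"):
            eps = sorted((e for e in self.epochs if e.channel == ch), key=lambda e: e.t_start)
            for a, b in zip(eps, eps[1:]):
                if b.t_start < a.t_end:
                    raise ValueError(f"{self.name}: overlapping {ch} epochs at t={b.t_start}")
        if sorted(self.session_boundaries) != list(self.session_boundaries):
            raise ValueError("session boundaries must be sorted")

    @property
    def duration(self) -> float:
        last = max((e.t_end for e in self.epochs), default=0.0)
        return last + self.tail_s

    def epochs_of(self, channel: str) -> list[StimulusEpoch]:
        return sorted((e for e in self.epochs if e.channel == channel), key=lambda e: e.t_start)

    def shifted(self, offset: float) -> "Protocol":
        return Protocol(
            name=self.name,
            epochs=[
                StimulusEpoch(e.t_start + offset, e.duration, e.channel, e.amplitude)
                for e in self.epochs
            ],
            session_boundaries=[b + offset for b in self.session_boundaries],
            tail_s=self.tail_s,
        )

    def __add__(self, other: "Protocol") -> "Protocol":
        """Chain two sessions; a transient-weight reset marks the seam."""
        off = self.duration
        sh = other.shifted(off)
        return Protocol(
            name=f"{self.name}+{other.name}",
            epochs=self.epochs + sh.epochs,
            session_boundaries=self.session_boundaries + [off] + sh.session_boundaries,
            tail_s=other.tail_s,
        )


def make_conditioning(
    n_trials: int = 3,
    cs_s: float = 20.0,
    us_s: float = 0.5,
    iti_s: float = DEFAULT_ITI_S,
    lead_s: float = DEFAULT_LEAD_S,
    amplitude: Optional[float] = None,
) -> Protocol:
    """CS-US pairing: each US occupies the final ``us_s`` seconds of its CS."""
    if us_s > cs_s:
        raise ValueError(f"US duration {us_s} s exceeds CS duration {cs_s} s")
    epochs = []
    t = lead_s
    for _ in range(n_trials):
        epochs.append(StimulusEpoch(t, cs_s, "CS", amplitude))
        if us_s > 0:
            epochs.append(StimulusEpoch(t + cs_s - us_s, us_s, "US", amplitude))
        t += cs_s + iti_s
    return Protocol(name="conditioning", epochs=epochs, tail_s=iti_s)


def make_extinction(
    n_cs: int = 20,
    cs_s: float = 20.0,
    iti_s: float = DEFAULT_ITI_S,
    lead_s: float = DEFAULT_LEAD_S,
    amplitude: Optional[float] = None,
) -> Protocol:
    epochs = []
    t = lead_s
    for _ in range(n_cs):
        epochs.append(StimulusEpoch(t, cs_s, "CS", amplitude))
        t += cs_s + iti_s
    return Protocol(name="extinction", epochs=epochs, tail_s=iti_s)


def make_reinstatement(
    cs_s: float = 20.0,
    us_s: float = 0.5,
    gap_s: float = DEFAULT_ITI_S,
    lead_s: float = DEFAULT_LEAD_S,
    amplitude: Optional[float] = None,
) -> Protocol:
    """One CS, one unpaired US, one final CS."""
    t = lead_s
    epochs = [StimulusEpoch(t, cs_s, "CS", amplitude)]
    t += cs_s + gap_s
    epochs.append(StimulusEpoch(t, us_s, "US", amplitude))
    t += us_s + gap_s
    epochs.append(StimulusEpoch(t, cs_s, "CS", amplitude))
    return Protocol(name="reinstatement", epochs=epochs, tail_s=gap_s)


def standard_protocol(**kwargs) -> Protocol:
    """The full four-session paradigm: conditioning, two extinction
    sessions, reinstatement, with transient-weight resets in between."""
    p = make_conditioning(**kwargs.get("conditioning", {}))
    p = p + make_extinction(**kwargs.get("extinction", {}))
    p = p + make_extinction(**kwargs.get("extinction", {}))
    p = p + make_reinstatement(**kwargs.get("reinstatement", {}))
    p.name = "standard"
    return p


# ---------------------------------------------------------------------------


@dataclass
class SessionTrace:
    """Time-indexed activations and plastic weights for one run."""

    times: np.ndarray
    activations: np.ndarray  # (steps, units)
    unit_names: list[str]
    weights: np.ndarray  # (steps, plastic connections)
    weight_ids: list[str]
    events: list[StimulusEpoch]

    def activation(self, unit: str) -> np.ndarray:
        return self.activations[:, self.unit_names.index(unit)]

    def weight(self, conn_id: str) -> np.ndarray:
        return self.weights[:, self.weight_ids.index(conn_id)]

    def _epoch_mask(self, epoch: StimulusEpoch) -> np.ndarray:
        return (self.times >= epoch.t_start) & (self.times < epoch.t_end)

    #: Settling window skipped at CS onset when scoring a CS response, s.
    ONSET_SKIP_S = 2.0

    def cs_peak(self, unit: str, trial: int, exclude_us: bool = True, onset_skip_s: float | None = None) -> float:
        """Peak activation of ``unit`` during the ``trial``-th CS (1-based).

        The first ``onset_skip_s`` seconds of the CS are skipped so the
        value reflects the sustained response rather than the brief
        onset transient of the feedforward sweep (freezing is scored
        over the bulk of the cue, not its first moments).  With
        ``exclude_us`` the steps overlapping a US epoch are also left
        out, so the value reflects the learned CS response rather than
        the direct US drive.
        """
        if onset_skip_s is None:
            onset_skip_s = self.ONSET_SKIP_S
        cs = [e for e in self.events if e.channel == "CS"]
        epoch = cs[trial - 1]
        mask = self._epoch_mask(epoch)
        skip = min(onset_skip_s, 0.5 * epoch.duration)
        mask &= self.times >= epoch.t_start + skip
        if exclude_us:
            for e in self.events:
                if e.channel == "US":
                    mask &= ~self._epoch_mask(e)
        return float(self.activation(unit)[mask].max())

    @property
    def n_cs(self) -> int:
        return sum(1 for e in self.events if e.channel == "CS")

    def cs_peaks(self, unit: str, exclude_us: bool = True) -> np.ndarray:
        return np.array([self.cs_peak(unit, k + 1, exclude_us) for k in range(self.n_cs)])

    def to_frame(self, stride: int = 1) -> pd.DataFrame:
        """Tidy long-format table (time, kind, name, value)."""
        t = self.times[::stride]
        frames = []
        for i, name in enumerate(self.unit_names):
            frames.append(
                pd.DataFrame(
                    {"time_s": t, "kind": "activation", "name": name, "value": self.activations[::stride, i]}
                )
            )
        for i, cid in enumerate(self.weight_ids):
            frames.append(
                pd.DataFrame({"time_s": t, "kind": "weight", "name": cid, "value": self.weights[::stride, i]})
            )
        return pd.concat(frames, ignore_index=True)


class Simulation:
    """A stateful run of one circuit: weights persist across sessions.

    The simulation owns a private copy of the model, so callers can
    reuse a circuit across experiments.  Probes (single frozen CS,
    PSP measurements) run on a clone and never advance this state.
    """

    def __init__(self, model: CircuitModel, cfg: Optional[SimConfig] = None, settle: bool = True):
        self.model = model.copy()
        self.cfg = cfg or SimConfig()
        self.net = CompiledNetwork(self.model, self.cfg)
        # reference for between-session forgetting of DSI/DSE
        self._transient_ref = self.net.w.copy()
        if settle:
            self.net.settle()

    # -- perturbation plumbing -------------------------------------------
    def _validate(self, perturbations: Sequence[Perturbation]) -> None:
        for p in perturbations:
            if p.kind in ("lesion_unit", "clamp_unit_max"):
                if p.target not in self.net.unit_index:
                    raise ValueError(f"perturbation targets unknown unit {p.target!r}")
            elif p.kind in ("set_connection", "clamp_connection_output"):
                if p.target not in self.net.conn_index:
                    raise ValueError(f"perturbation targets unknown connection {p.target!r}")
            elif p.kind == "zero_region_weights":
                if not any(
                    u.startswith(p.target) for u in self.net.unit_index
                ):
                    raise ValueError(f"region {p.target!r} matches no unit")
            elif p.kind == "block_plasticity":
                b = p.blockade()
                known = {"BA", "CeM", "amygdala", "all"} | set(self.net.conn_index)
                if b.region not in known:
                    raise ValueError(f"unknown blockade region {b.region!r}")

    def _apply_modifiers(self, active: Sequence[Perturbation]) -> None:
        net = self.net
        net.output_clamp[:] = np.nan
        net.weight_mask[:] = 1.0
        net.conn_pre_override[:] = np.nan
        net.plast_blocked[:] = False
        for p in active:
            if p.kind == "lesion_unit":
                net.output_clamp[net.unit_index[p.target]] = 0.0
            elif p.kind == "clamp_unit_max":
                i = net.unit_index[p.target]
                net.output_clamp[i] = net.phi[i]
            elif p.kind == "zero_region_weights":
                for j, c in enumerate(self.model.connections):
                    if c.pre.startswith(p.target) or c.post.startswith(p.target):
                        net.weight_mask[j] = 0.0
            elif p.kind == "block_plasticity":
                b = p.blockade()
                for j, c in enumerate(self.model.connections):
                    if b.matches(c):
                        net.plast_blocked[j] = True
            elif p.kind == "clamp_connection_output":
                j = net.conn_index[p.target]
                if p.value is not None:
                    net.conn_pre_override[j] = p.value
                else:
                    pre = net.pre_idx[j]
                    if pre < 0:
                        raise ValueError(f"{p.target}: explicit value required for external presynaptic channel")
                    net.conn_pre_override[j] = net.phi[pre]

    # -- execution --------------------------------------------------------
    def run(
        self,
        protocol: Protocol,
        perturbations: Sequence[Perturbation] = (),
        record: bool = True,
        frozen: bool = False,
    ) -> Optional[SessionTrace]:
        self._validate(perturbations)
        net = self.net
        dt_s = self.cfg.dt / 1000.0
        n_steps = int(round(protocol.duration / dt_s))
        times = np.arange(n_steps) * dt_s

        # instantaneous weight manipulations apply at run start
        for p in perturbations:
            if p.kind == "set_connection":
                net.set_weight(p.target, float(p.value))
        timed = [p for p in perturbations if p.kind != "set_connection"]

        cs_drive = np.zeros(n_steps)
        us_drive = np.zeros(n_steps)
        for e in protocol.epochs:
            amp = e.amplitude if e.amplitude is not None else self.model.external_inputs[e.channel]
            sel = (times >= e.t_start) & (times < e.t_end)
            (cs_drive if e.channel == "CS" else us_drive)[sel] = amp

        boundary_steps = {int(round(b / dt_s)) for b in protocol.session_boundaries}

        if record:
            act = np.empty((n_steps, net.n_units))
            w_rec = np.empty((n_steps, len(net.trans_idx) + len(net.heb_idx)))
            rec_cols = np.concatenate([net.heb_idx, net.trans_idx]).astype(int) if (len(net.heb_idx) + len(net.trans_idx)) else np.array([], dtype=int)
            rec_ids = [net.conn_ids[j] for j in rec_cols]

        old_frozen = net.frozen
        net.frozen = net.frozen or frozen
        active_key = None
        for k in range(n_steps):
            if k in boundary_steps:
                net.reset_transient_weights(self._transient_ref)
            cs = cs_drive[k]
            us = us_drive[k]
            if timed:
                now = [p for p in timed if p.active(times[k], cs > 0, us > 0)]
                key = tuple(id(p) for p in now)
                if key != active_key:
                    self._apply_modifiers(now)
                    active_key = key
            net.step(cs, us)
            if record:
                act[k] = net.a
                w_rec[k] = net.w[rec_cols]
        if timed:
            self._apply_modifiers(())  # restore
        net.frozen = old_frozen
        net.sync_model_weights()
        if not record:
            return None
        return SessionTrace(
            times=times,
            activations=act,
            unit_names=list(net.unit_names),
            weights=w_rec,
            weight_ids=rec_ids,
            events=list(protocol.epochs),
        )

    # -- session bookkeeping ----------------------------------------------
    def reset_transient(self) -> None:
        """Forget DSI/DSE changes (what happens between sessions)."""
        self.net.reset_transient_weights(self._transient_ref)
        self.net.sync_model_weights()

    def weights(self) -> dict[str, float]:
        return self.net.weights_by_id()

    def set_weight(self, conn_id: str, value: float) -> None:
        """Instantaneous manipulation of one connection weight."""
        self.net.set_weight(conn_id, value)
        self.net.sync_model_weights()

    def clone(self) -> "Simulation":
        """Independent copy with the current weights (for probes)."""
        self.net.sync_model_weights()
        return Simulation(self.model, copy.deepcopy(self.cfg), settle=True)

    def probe_cs(
        self,
        cs_s: float = 20.0,
        perturbations: Sequence[Perturbation] = (),
        reset_transient: bool = True,
    ) -> dict[str, float]:
        """Plasticity-frozen single-CS test; returns per-unit peak rates.

        The probe models a test on a later day: transient DSI/DSE
        changes have decayed (unless ``reset_transient=False``) and no
        learning occurs during the measurement.
        """
        clone = self.clone()
        if reset_transient:
            clone.reset_transient()
            clone.net.settle()
        proto = Protocol(name="probe", epochs=[StimulusEpoch(DEFAULT_LEAD_S, cs_s, "CS")])
        trace = clone.run(proto, perturbations=perturbations, frozen=True)
        return {u: trace.cs_peak(u, 1) for u in trace.unit_names}


_SESSION_BUILDERS = {
    "conditioning": make_conditioning,
    "extinction": make_extinction,
    "reinstatement": make_reinstatement,
}


def protocol_from_dict(doc: dict) -> Protocol:
    """Build a protocol from a config mapping.

    Either ``{"protocol": "standard"}`` / a single session name, or
    ``{"sessions": [{"type": "conditioning", ...}, ...]}`` where each
    entry's extra keys are passed to the corresponding builder and
    consecutive sessions are separated by transient-weight resets.
    """
    if "protocol" in doc:
        name = doc["protocol"]
        if name == "standard":
            return standard_protocol()
        if name in _SESSION_BUILDERS:
            return _SESSION_BUILDERS[name]()
        raise ValueError(f"unknown protocol {name!r}")
    sessions = doc.get("sessions")
    if not sessions:
        raise ValueError("protocol config needs 'protocol' or a non-empty 'sessions' list")
    built = []
    for entry in sessions:
        kw = dict(entry)
        kind = kw.pop("type", None)
        if kind not in _SESSION_BUILDERS:
            raise ValueError(f"unknown session type {kind!r}")
        built.append(_SESSION_BUILDERS[kind](**kw))
    proto = built[0]
    for p in built[1:]:
        proto = proto + p
    return proto


def load_protocol(path) -> Protocol:
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: not a mapping")
    return protocol_from_dict(doc)


def run_protocol(
    model: CircuitModel,
    protocol: Protocol,
    cfg: Optional[SimConfig] = None,
    perturbations: Sequence[Perturbation] = (),
) -> SessionTrace:
    """Settle, run ``protocol`` with plasticity active, return the trace."""
    sim = Simulation(model, cfg)
    return sim.run(protocol, perturbations=perturbations)
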
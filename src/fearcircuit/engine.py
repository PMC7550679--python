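"""Vectorized simulation engine.

Compiles a :class:`~fearcircuit.circuit.CircuitModel` into flat numpy
arrays and advances the whole network one synchronous Euler step at a
time.  The step order is fixed and deterministic:

1. synaptic + external input from the *previous* activations,
2. membrane potential update (clamped to [0, pi]),
3. transfer function,
4. output clamps (lesions / optogenetic-style stimulation),
5. plasticity (depolarization timers, then weight deltas).

Learning-rate constants in the config are expressed per reference step
of 10 ms and scaled linearly with the actual ``dt``, so that a protocol
integrated at dt = 1 ms accumulates the same weight change per unit of
simulated time as at the default dt = 10 ms.
"""

from __future__ import annotations

import numpy as np

from .circuit import CircuitModel, PlasticityRule
from .dynamics import SimConfig, U_MAX

__all__ = ["CompiledNetwork", "REFERENCE_DT_MS"]

#: dt for which config learning rates are calibrated, ms.
REFERENCE_DT_MS = 10.0

_PRE_CS = -1
_PRE_US = -2


class CompiledNetwork:
    """Array representation of a circuit plus mutable runtime state."""

    def __init__(self, model: CircuitModel, cfg: SimConfig):
        self.model = model
        self.cfg = cfg
        self.dt = cfg.dt

        self.unit_names = list(model.unit_names)
        self.unit_index = {n: i for i, n in enumerate(self.unit_names)}
        n = self.n_units = len(self.unit_names)

        self.tau = np.array([u.tau for u in model.units])
        self.tonic = np.array([u.tonic for u in model.units])
        self.phi = np.array([u.phi for u in model.units])
        self.psi = np.array([u.psi for u in model.units])
        self.sign = np.array([u.polarity.sign for u in model.units], dtype=float)

        conns = model.connections
        self.conn_ids = [c.id for c in conns]
        self.conn_index = {cid: j for j, cid in enumerate(self.conn_ids)}
        m = self.n_conns = len(conns)
        self.pre_idx = np.array(
            [
                _PRE_CS if c.pre == "CS" else _PRE_US if c.pre == "US" else self.unit_index[c.pre]
                for c in conns
            ],
            dtype=int,
        )
        self.post_idx = np.array([self.unit_index[c.post] for c in conns], dtype=int)
        self.pre_sign = np.array(
            [1.0 if c.pre in ("CS", "US") else self.sign[self.unit_index[c.pre]] for c in conns]
        )
        self.w = np.array([c.weight for c in conns])
        self.w0 = self.w.copy()

        # plasticity groups ------------------------------------------------
        rate_scale = self.dt / REFERENCE_DT_MS
        heb = [j for j, c in enumerate(conns) if c.plasticity is not None and c.plasticity.rule.hebbian]
        self.heb_idx = np.array(heb, dtype=int)
        self.heb_eta = np.array([conns[j].plasticity.eta * rate_scale for j in heb])
        self.heb_eta_ltd = np.array(
            [
                (conns[j].plasticity.eta_ltd if conns[j].plasticity.eta_ltd is not None else conns[j].plasticity.eta)
                * rate_scale
                for j in heb
            ]
        )
        self.heb_ltd_allowed = np.array(
            [conns[j].plasticity.rule is PlasticityRule.LTP_LTD for j in heb], dtype=bool
        )
        self.heb_M = np.array([conns[j].ceiling for j in heb])
        self.heb_thresh = np.array(
            [conns[j].plasticity.sigma * self.phi[self.post_idx[j]] for j in heb]
        )
        self.heb_thresh_ltd = np.array(
            [
                (conns[j].plasticity.sigma_ltd if conns[j].plasticity.sigma_ltd is not None else conns[j].plasticity.sigma)
                * self.phi[self.post_idx[j]]
                for j in heb
            ]
        )
        self.heb_ltd_hold = np.array([conns[j].plasticity.ltd_hold_s for j in heb])
        self.heb_ltd_timer = np.zeros(len(heb))

        trans = [j for j, c in enumerate(conns) if c.plasticity is not None and c.plasticity.transient]
        self.trans_idx = np.array(trans, dtype=int)
        self.trans_eta = np.array([conns[j].plasticity.eta * rate_scale for j in trans])
        self.trans_trigger = np.array([conns[j].plasticity.trigger_s for j in trans])
        self.transient_conn_ids = [self.conn_ids[j] for j in trans]

        # one endocannabinoid timer per postsynaptic unit with transient afferents
        self.timer_units = sorted({int(self.post_idx[j]) for j in trans})
        self.timer_theta = model.dsi_theta * self.phi[self.timer_units]
        self.timers = np.zeros(len(self.timer_units))
        self.trans_timer_slot = np.array(
            [self.timer_units.index(int(self.post_idx[j])) for j in trans], dtype=int
        )

        # runtime modifiers ------------------------------------------------
        self.frozen = False
        self.plast_blocked = np.zeros(m, dtype=bool)
        self.weight_mask = np.ones(m)  # 0 during region weight zeroing (TTX)
        self.output_clamp = np.full(n, np.nan)  # post-transfer override of A
        self.conn_pre_override = np.full(m, np.nan)  # per-connection presynaptic rate override

        # state ------------------------------------------------------------
        self.u = np.zeros(n)
        self.a = np.zeros(n)
        self._euler = self.dt / self.tau

    # -- helpers ----------------------------------------------------------
    def pre_rates(self, a: np.ndarray, cs: float, us: float) -> np.ndarray:
        """Presynaptic rate per connection (CS/US channels carry the drive)."""
        r = np.where(
            self.pre_idx == _PRE_CS,
            cs,
            np.where(self.pre_idx == _PRE_US, us, a[np.maximum(self.pre_idx, 0)]),
        )
        override = self.conn_pre_override
        mask = ~np.isnan(override)
        if mask.any():
            r = np.where(mask, override, r)
        return r

    def synaptic_input(self, a: np.ndarray, cs: float, us: float) -> np.ndarray:
        contrib = self.pre_sign * self.w * self.weight_mask * self.pre_rates(a, cs, us)
        i = np.zeros(self.n_units)
        np.add.at(i, self.post_idx, contrib)
        return i

    def step_states(self, u, a, ext, cs, us):
        """Pure dynamics step on given state arrays (no plasticity)."""
        i = self.synaptic_input(a, cs, us) + ext
        u_new = np.clip(u + self._euler * (-u + self.tonic + i), 0.0, U_MAX)
        a_new = self.phi * np.maximum(0.0, np.tanh(u_new - self.psi))
        return u_new, a_new

    # -- main step --------------------------------------------------------
    def step(self, cs: float = 0.0, us: float = 0.0, ext: np.ndarray | None = None) -> None:
        i = self.synaptic_input(self.a, cs, us)
        if ext is not None:
            i = i + ext
        self.u = np.clip(self.u + self._euler * (-self.u + self.tonic + i), 0.0, U_MAX)
        a = self.phi * np.maximum(0.0, np.tanh(self.u - self.psi))
        clamp = self.output_clamp
        mask = ~np.isnan(clamp)
        if mask.any():
            a = np.where(mask, clamp, a)
        self.a = a
        self._plasticity_step(cs, us)

    def _plasticity_step(self, cs: float, us: float) -> None:
        # depolarization timers advance even while weight updates are frozen
        if len(self.timer_units):
            above = self.a[self.timer_units] >= self.timer_theta
            self.timers = np.where(above, self.timers + self.dt / 1000.0, 0.0)
        if self.frozen:
            return
        rates = self.pre_rates(self.a, cs, us)
        if len(self.heb_idx):
            j = self.heb_idx
            active = ~(self.plast_blocked[j] | (self.weight_mask[j] == 0.0))
            w = self.w[j]
            post = self.a[self.post_idx[j]]
            up = np.maximum(post - self.heb_thresh, 0.0)
            down = np.maximum(self.heb_thresh_ltd - post, 0.0)
            # LTD-hold: the depressing pattern must persist before LTD bites
            pattern = (down > 0) & (rates[j] > 0)
            self.heb_ltd_timer = np.where(pattern, self.heb_ltd_timer + self.dt / 1000.0, 0.0)
            down = np.where(self.heb_ltd_timer >= self.heb_ltd_hold, down, 0.0)
            # potentiation saturates at the ceiling (M - w); depression is
            # weight-proportional so saturated synapses stay depotentiable
            delta = (self.heb_eta * up * (self.heb_M - w) - self.heb_eta_ltd * down * w) * rates[j]
            delta = np.where((delta < 0) & ~self.heb_ltd_allowed, 0.0, delta)
            w_new = np.clip(w + delta, 0.0, self.heb_M)
            self.w[j] = np.where(active, w_new, w)
        if len(self.trans_idx):
            j = self.trans_idx
            active = ~(self.plast_blocked[j] | (self.weight_mask[j] == 0.0))
            engaged = self.timers[self.trans_timer_slot] >= self.trans_trigger
            w = self.w[j]
            delta = np.where(engaged, -self.trans_eta * w * rates[j], 0.0)
            self.w[j] = np.where(active, np.maximum(w + delta, 0.0), w)

    # -- weight bookkeeping ------------------------------------------------
    def weights_by_id(self) -> dict[str, float]:
        return {cid: float(self.w[j]) for cid, j in self.conn_index.items()}

    def set_weight(self, conn_id: str, value: float) -> None:
        if value < 0:
            raise ValueError(f"negative weight for {conn_id}")
        self.w[self.conn_index[conn_id]] = value

    def reset_transient_weights(self, reference: np.ndarray) -> None:
        """Between-session forgetting: DSI/DSE weights back to ``reference``."""
        j = self.trans_idx
        self.w[j] = reference[j]
        self.timers[:] = 0.0

    def settle(self, seconds: float | None = None) -> None:
        """Relax to the tonic fixed point with no stimuli and no learning."""
        seconds = self.cfg.settle_time if seconds is None else seconds
        frozen = self.frozen
        self.frozen = True
        for _ in range(int(round(seconds * 1000.0 / self.dt))):
            self.step(0.0, 0.0)
        self.frozen = frozen
        self.timers[:] = 0.0

    def sync_model_weights(self) -> None:
        """Write current weights back into the owning CircuitModel."""
        for cid, j in self.conn_index.items():
            self.model.connection(cid).weight = float(self.w[j])
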
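"""Synaptic plasticity rules.

Two rule families act on the plastic connections at every integration
step:

* Hebbian LTP/LTD:  ``dW = eta * (M - W) * (Post - phi*sigma) * Pre``.
  The sign of the postsynaptic term decides the direction: firing above
  ``sigma * phi`` potentiates, below it depresses.  LTP-only
  connections clip negative deltas.  Weights are clamped to ``[0, M]``.

* Endocannabinoid DSI/DSE:  ``dW = -eta * W * Pre`` once the
  postsynaptic unit has been continuously depolarized for the trigger
  time (10 s by default); a multiplicative decay, so the weight stays
  positive.  The depression only touches synapses whose presynaptic
  element is firing, and it is transient: weights return to their
  pre-session values at session boundaries.

The functions here are the scalar reference forms; protocol runs use
the vectorized engine, which mirrors them exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .circuit import CircuitModel, PlasticityRule

__all__ = [
    "PlasticityState",
    "Blockade",
    "ltp_ltd_delta",
    "dsi_dse_delta",
    "update_depolarization_timer",
    "apply_plasticity",
]

#: Blockade region names understood by experiment specifications.
BLOCKADE_REGIONS = ("BA", "CeM", "amygdala", "all")


@dataclass
class PlasticityState:
    """Mutable plasticity bookkeeping for one simulation.

    ``timers`` maps postsynaptic unit name to the accumulated time (s)
    its activation has stayed above the depolarization threshold; the
    timer is shared by all endocannabinoid-sensitive afferents of that
    unit (endocannabinoids are released postsynaptically and diffuse
    retrogradely).  ``frozen`` disables every weight update (used by
    PSP probes and probe-CS measurements).
    """

    timers: dict[str, float] = field(default_factory=dict)
    #: per-connection hold timers for the Hebbian LTD sustained-pattern gate
    ltd_timers: dict[str, float] = field(default_factory=dict)
    frozen: bool = False


@dataclass(frozen=True)
class Blockade:
    """Disable a plasticity rule in a region or on a single connection."""

    rule: str = "all"  # DSI | DSE | LTP_LTD | all
    region: str = "all"  # BA | CeM | amygdala | all | a connection id

    def matches(self, conn) -> bool:
        p = conn.plasticity
        if p is None:
            return False
        if self.rule != "all":
            if self.rule == "LTP_LTD" and not p.rule.hebbian:
                return False
            if self.rule in ("DSI", "DSE") and p.rule.value != self.rule:
                return False
        if self.region == "all":
            return True
        if self.region == "amygdala":
            # every plastic connection of the default model terminates in
            # the amygdala except those onto IL/ITC targets
            return conn.post in ("BAp2", "CeM")
        if self.region == "BA":
            return conn.post.startswith("BA")
        if self.region == "CeM":
            return conn.post == "CeM"
        return conn.id == self.region


def ltp_ltd_delta(w: float, pre: float, post: float, eta: float, M: float, sigma: float, phi: float) -> float:
    """Hebbian weight change ``eta*(M-w)*(post - phi*sigma)*pre``.

    The caller clamps the resulting weight to ``[0, M]``.
    """
    return eta * (M - w) * (post - phi * sigma) * pre


def dsi_dse_delta(w: float, pre: float, eta: float, timer: float, trigger_s: float) -> float:
    """Endocannabinoid depression; zero until the trigger time is reached."""
    if timer < trigger_s:
        return 0.0
    return -eta * w * pre


def update_depolarization_timer(timer: float, post_activation: float, phi: float, dt: float, theta: float = 0.2) -> float:
    """Advance (or reset) the endocannabinoid release timer.

    The timer accumulates while the postsynaptic activation stays at or
    above ``theta * phi`` and resets to zero the moment it dips below:
    the trigger requires *continuous* depolarization.  ``dt`` in ms;
    timer in seconds.
    """
    if post_activation >= theta * phi:
        return timer + dt / 1000.0
    return 0.0


def apply_plasticity(
    model: CircuitModel,
    activations: dict[str, float],
    pstate: PlasticityState,
    blocked: tuple[Blockade, ...] = (),
    dt: float = 10.0,
    cs: float = 0.0,
    us: float = 0.0,
) -> None:
    """One plasticity step over every plastic connection of ``model``.

    ``activations`` maps unit name to current firing rate; CS/US
    presynaptic rates are the external drives ``cs``/``us``.  Timers in
    ``pstate`` are updated for every DSI/DSE postsynaptic unit, then
    each non-blocked connection receives its rule's delta, clamped to
    ``[0, M]`` (Hebbian) or ``[0, inf)`` (DSI/DSE).
    """
    for b in blocked:
        if b.region not in BLOCKADE_REGIONS and b.region not in {c.id for c in model.connections}:
            raise ValueError(f"unknown blockade region {b.region!r}")

    # timers first: per postsynaptic unit of any transient-plastic afferent
    dsi_posts = {c.post for c in model.plastic_connections if c.plasticity.transient}
    for name in dsi_posts:
        phi = model.unit(name).phi
        t = pstate.timers.get(name, 0.0)
        pstate.timers[name] = update_depolarization_timer(t, activations[name], phi, dt, model.dsi_theta)

    if pstate.frozen:
        return

    def rate(pre: str) -> float:
        if pre == "CS":
            return cs
        if pre == "US":
            return us
        return activations[pre]

    for c in model.plastic_connections:
        if any(b.matches(c) for b in blocked):
            continue
        p = c.plasticity
        pre = rate(c.pre)
        if p.rule.hebbian:
            phi = model.unit(c.post).phi
            M = c.ceiling
            post = activations[c.post]
            up = max(post - p.sigma * phi, 0.0)
            s_ltd = p.sigma_ltd if p.sigma_ltd is not None else p.sigma
            down = max(s_ltd * phi - post, 0.0)
            t = pstate.ltd_timers.get(c.id, 0.0)
            t = t + dt / 1000.0 if (down > 0 and pre > 0) else 0.0
            pstate.ltd_timers[c.id] = t
            if t < p.ltd_hold_s:
                down = 0.0
            eta_ltd = p.eta_ltd if p.eta_ltd is not None else p.eta
            delta = (p.eta * up * (M - c.weight) - eta_ltd * down * c.weight) * pre
            if p.rule is PlasticityRule.LTP and delta < 0:
                delta = 0.0
            c.weight = min(max(c.weight + delta, 0.0), M)
        else:
            timer = pstate.timers.get(c.post, 0.0)
            c.weight = max(c.weight + dsi_dse_delta(c.weight, pre, p.eta, timer, p.trigger_s), 0.0)
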
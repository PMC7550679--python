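"""Leaky-unit dynamics: membrane integration, input summation, transfer.

Each unit is a firing-rate leaky integrator representing a neural
population.  Its remapped membrane potential ``U`` lives in ``[0, pi]``
(the biological range (-70, +30) mV mapped linearly, so that the resting
value is 0 and leak pulls the unit back toward rest), and its activation
is a thresholded hyperbolic tangent of ``U``:

    tau * dU/dt = -U + T + I          (Euler-integrated at step dt)
    I           = sum_i  s_i * w_i * A_i
    A           = phi * [tanh(U - psi)]+

where ``T`` is the tonic drive, ``w_i >= 0`` are synaptic efficacies,
``s_i`` is +1/-1 for excitatory/inhibitory presynaptic units, ``psi`` is
the firing threshold and ``phi`` the maximum firing rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "U_MAX",
    "V_MIN_MV",
    "V_MAX_MV",
    "Polarity",
    "NeuronClass",
    "UnitSpec",
    "UnitState",
    "SimConfig",
    "euler_step",
    "summed_input",
    "transfer",
    "remap_potential",
    "unmap_potential",
    "network_step",
]

#: Upper bound of the remapped potential range.
U_MAX = float(np.pi)
#: Biological membrane-potential range mapped onto [0, U_MAX].
V_MIN_MV = -70.0
V_MAX_MV = 30.0


class Polarity(str, Enum):
    EXCITATORY = "excitatory"
    INHIBITORY = "inhibitory"

    @property
    def sign(self) -> int:
        return 1 if self is Polarity.EXCITATORY else -1


class NeuronClass(str, Enum):
    """Broad electrophysiological class; drives default tonic/phi choices."""

    PYRAMIDAL = "pyramidal"
    PARVALBUMIN = "parvalbumin"
    SOMATOSTATIN = "somatostatin"
    VIP = "vip"
    CCK = "cck"
    OTHER = "other"


@dataclass(frozen=True)
class UnitSpec:
    """Electrophysiology of one population.

    Parameters
    ----------
    tau
        Membrane time constant, ms.
    tonic
        Tonic drive ``T`` in remapped-potential units; sets the basal
        activity the population shows without synaptic input.
    phi
        Maximum firing rate, in model rate units (1 unit = 100 Hz).
    psi
        Firing threshold, remapped-potential units.
    """

    name: str
    tau: float
    tonic: float
    phi: float
    psi: float
    polarity: Polarity = Polarity.EXCITATORY
    neuron_class: NeuronClass = NeuronClass.OTHER

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError(f"unit {self.name!r}: tau must be > 0, got {self.tau}")
        if not self.phi > 0:
            raise ValueError(f"unit {self.name!r}: phi must be > 0, got {self.phi}")
        if not 0 <= self.psi < U_MAX:
            raise ValueError(f"unit {self.name!r}: psi must be in [0, pi), got {self.psi}")
        if self.tonic < 0:
            raise ValueError(f"unit {self.name!r}: tonic must be >= 0, got {self.tonic}")


@dataclass
class UnitState:
    """Instantaneous potential and activation of one unit."""

    u: float = 0.0
    a: float = 0.0


@dataclass
class SimConfig:
    """Global integration settings.

    ``dt`` is the Euler step in ms (default 10 ms; coarse relative to the
    smallest tau but stable, since leaky units are low-pass filters).
    ``settle_time`` is a pre-protocol relaxation period in seconds during
    which the network runs with no stimuli so that every unit starts a
    protocol from its tonic fixed point.  ``seed`` is reserved: the
    dynamics are deterministic.
    """

    dt: float = 10.0
    settle_time: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.settle_time < 0:
            raise ValueError(f"settle_time must be >= 0, got {self.settle_time}")


def euler_step(u, tonic, input_sum, tau, dt):
    """One forward-Euler update of the leaky membrane equation.

    Returns ``u + (dt/tau) * (-u + tonic + input_sum)`` clamped to
    ``[0, pi]``.  Accepts scalars or arrays (tau may be per-unit).
    """
    tau = np.asarray(tau, dtype=float)
    if np.any(tau <= 0):
        raise ValueError("tau must be > 0")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    u_new = u + (dt / tau) * (-u + tonic + input_sum)
    return np.clip(u_new, 0.0, U_MAX)


def summed_input(weights, activations):
    """Total synaptic drive: dot product of signed efficacies and rates.

    ``weights`` are signed (negative entries are inhibitory afferents);
    an empty pair of sequences sums to zero.
    """
    w = np.asarray(weights, dtype=float)
    a = np.asarray(activations, dtype=float)
    if w.shape != a.shape:
        raise ValueError(f"length mismatch: {w.shape} weights vs {a.shape} activations")
    if w.size == 0:
        return 0.0
    return float(w @ a)


def transfer(u, psi, phi):
    """Threshold-tanh transfer: ``phi * max(0, tanh(u - psi))``."""
    return phi * np.maximum(0.0, np.tanh(u - psi))


def remap_potential(v_mv):
    """Map a membrane potential in mV onto the model's [0, pi] range.

    Values outside (-70, +30) mV are clamped.  The map is linear.
    """
    v = np.clip(v_mv, V_MIN_MV, V_MAX_MV)
    return (v - V_MIN_MV) / (V_MAX_MV - V_MIN_MV) * U_MAX


def unmap_potential(u):
    """Inverse of :func:`remap_potential`; used for PSP reporting in mV."""
    return np.asarray(u) / U_MAX * (V_MAX_MV - V_MIN_MV) + V_MIN_MV


def network_step(states, circuit, external, cfg):
    """Advance every unit of ``circuit`` by one synchronous Euler step.

    ``states`` maps unit name -> :class:`UnitState`; ``external`` maps
    unit name -> additional drive (e.g. probe current).  CS/US stimuli
    are routed through the circuit's external connections, so ``external``
    here is the per-unit extra drive only.  Returns a new state mapping.

    This is the reference (dict-based) implementation; protocol runs use
    the vectorized engine in :mod:`fearcircuit.engine`, which this
    function mirrors step for step.
    """
    from .engine import CompiledNetwork  # local import to avoid cycle

    missing = set(states) ^ {u.name for u in circuit.units}
    if missing:
        raise KeyError(f"states do not cover circuit units exactly: {sorted(missing)}")
    unknown = set(external) - set(states)
    if unknown:
        raise KeyError(f"external drive for unknown units: {sorted(unknown)}")

    net = CompiledNetwork(circuit, cfg)
    u = np.array([states[n].u for n in net.unit_names])
    a = np.array([states[n].a for n in net.unit_names])
    ext = np.zeros(len(net.unit_names))
    for name, drive in external.items():
        ext[net.unit_index[name]] = drive
    u_new, a_new = net.step_states(u, a, ext, cs=0.0, us=0.0)
    return {n: UnitState(u=float(u_new[i]), a=float(a_new[i])) for i, n in enumerate(net.unit_names)}
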
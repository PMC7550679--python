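"""In-silico manipulations: lesions, clamps, weight zeroing, blockades.

A perturbation is active inside a *window*: the whole run (``None``), a
time interval ``(t0, t1)`` in seconds, or the symbolic windows ``"cs"``
/ ``"us"`` (active only while that stimulus channel is on — used for
manipulations delivered "in coincidence with the CS").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple, Union

from .plasticity import Blockade

__all__ = ["Perturbation", "Window", "lesion", "clamp_max", "zero_region", "block", "clamp_connection"]

Window = Union[None, str, Tuple[float, float]]

_KINDS = (
    "lesion_unit",
    "clamp_unit_max",
    "set_connection",
    "zero_region_weights",
    "block_plasticity",
    "clamp_connection_output",
)


@dataclass(frozen=True)
class Perturbation:
    """One manipulation of the running circuit.

    kind
        ``lesion_unit`` — unit output forced to zero;
        ``clamp_unit_max`` — unit output forced to its maximum rate
        (optogenetic-style depolarization);
        ``set_connection`` — weight set to ``value`` at run start
        (persistent manipulation of a pathway);
        ``zero_region_weights`` — every connection touching units whose
        name starts with ``target`` transmits nothing (TTX-style
        regional inactivation; stored weights are untouched and
        plasticity on the silenced connections is suspended);
        ``block_plasticity`` — disable a plasticity rule in a region
        (``target`` is ``"rule:region"``, e.g. ``"DSI:BA"``,
        ``"all:amygdala"``);
        ``clamp_connection_output`` — the presynaptic rate seen by one
        connection is replaced by ``value`` (``value=None`` means the
        presynaptic maximum), leaving every other efferent untouched.
    """

    kind: str
    target: str
    window: Window = None
    value: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown perturbation kind {self.kind!r}")

    def active(self, t: float, cs_on: bool, us_on: bool) -> bool:
        w = self.window
        if w is None:
            return True
        if w == "cs":
            return cs_on
        if w == "us":
            return us_on
        t0, t1 = w
        return t0 <= t < t1

    def blockade(self) -> Blockade:
        rule, _, region = self.target.partition(":")
        return Blockade(rule=rule or "all", region=region or "all")


# -- small constructors used throughout the experiment registry ----------


def lesion(unit: str, window: Window = None) -> Perturbation:
    return Perturbation("lesion_unit", unit, window)


def clamp_max(unit: str, window: Window = None) -> Perturbation:
    return Perturbation("clamp_unit_max", unit, window)


def zero_region(region: str, window: Window = None) -> Perturbation:
    return Perturbation("zero_region_weights", region, window)


def block(rule: str, region: str, window: Window = None) -> Perturbation:
    return Perturbation("block_plasticity", f"{rule}:{region}", window)


def clamp_connection(conn_id: str, value: Optional[float], window: Window = "cs") -> Perturbation:
    return Perturbation("clamp_connection_output", conn_id, window, value)
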
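"""One-factor-at-a-time (OAT) robustness scan.

Each scanned parameter (a connection weight or a plasticity rate) is
perturbed in 5% steps away from its reference value, in each direction,
with every other parameter held at reference; the scan records the
first value at which at least one registered experiment is lost.  A
parameter whose lower boundary reaches -100% is *removable* (the model
works without it); the upper sweep is capped at +1000%.

The full scan re-evaluates the experiment battery at every step and is
a long-running command; ``fast=True`` uses 25% steps and a small
behavioral subset of the registry, which is the mode exercised by the
test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import pandas as pd

from .circuit import CircuitModel, build_default_circuit
from .dynamics import SimConfig
from .experiments import CriteriaConfig, REGISTRY, run_registry

__all__ = ["ParameterRef", "ParameterReport", "SensitivityReport", "scan_parameters", "oat_scan", "prune_removable", "FAST_SUBSET"]

#: Behaviorally central subset used by the fast scan: acquisition plus
#: within- and between-session extinction, all computable from a single
#: conditioning + two-extinction-session run.
FAST_SUBSET = (
    "fig3_conditioning",
    "fig3_within_session_extinction",
    "fig3_between_session_extinction",
)


@dataclass(frozen=True)
class ParameterRef:
    """One scannable scalar: a weight or a plasticity constant."""

    kind: str  # "weight" | "eta" | "eta_ltd"
    conn_id: str

    @property
    def name(self) -> str:
        return f"{self.kind}:{self.conn_id}"

    def get(self, model: CircuitModel) -> float:
        c = model.connection(self.conn_id)
        if self.kind == "weight":
            return c.weight
        if self.kind == "eta":
            return c.plasticity.eta
        if self.kind == "eta_ltd":
            v = c.plasticity.eta_ltd
            return c.plasticity.eta if v is None else v
        raise ValueError(self.kind)

    def set(self, model: CircuitModel, value: float) -> None:
        c = model.connection(self.conn_id)
        if self.kind == "weight":
            c.weight = value
            c.initial_weight = value  # the ceiling M tracks the initial weight
        elif self.kind == "eta":
            c.plasticity.eta = max(value, 1e-300)
        elif self.kind == "eta_ltd":
            c.plasticity.eta_ltd = value
        else:
            raise ValueError(self.kind)


def scan_parameters(model: CircuitModel, include_plasticity: bool = True) -> list[ParameterRef]:
    """All scannable parameters of a circuit, in declaration order."""
    out = [ParameterRef("weight", c.id) for c in model.connections]
    if include_plasticity:
        for c in model.plastic_connections:
            out.append(ParameterRef("eta", c.id))
            if c.plasticity.eta_ltd is not None:
                out.append(ParameterRef("eta_ltd", c.id))
    return out


@dataclass
class ParameterReport:
    parameter: str
    reference: float
    lower_frac: Optional[float]  # first failing fractional change downward, e.g. -0.35
    upper_frac: Optional[float]  # first failing fractional change upward; None = survived the cap
    lower_lost: str = ""
    upper_lost: str = ""

    @property
    def removable(self) -> bool:
        """The parameter can be set to zero without losing any experiment
        (the downward sweep reached -100% without a failure)."""
        return self.lower_frac is None


@dataclass
class SensitivityReport:
    step_frac: float
    cap_frac: float
    experiment_ids: list[str]
    parameters: list[ParameterReport] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.parameters:
            rows.append(
                {
                    "parameter": p.parameter,
                    "reference": p.reference,
                    "lower_boundary_pct": None if p.lower_frac is None else round(100 * p.lower_frac, 1),
                    "upper_boundary_pct": None if p.upper_frac is None else round(100 * p.upper_frac, 1),
                    "first_lost_lower": p.lower_lost,
                    "first_lost_upper": p.upper_lost,
                    "removable": p.removable,
                }
            )
        return pd.DataFrame(rows)


def _failed_ids(model: CircuitModel, cfg, criteria, ids) -> list[str]:
    results, _ = run_registry(model, cfg, criteria, ids=ids)
    return [r.id for r in results if not r.passed]


def oat_scan(
    model: Optional[CircuitModel] = None,
    cfg: Optional[SimConfig] = None,
    criteria: CriteriaConfig = CriteriaConfig(),
    step_frac: float = 0.05,
    cap_frac: float = 10.0,
    ids: Optional[Sequence[str]] = None,
    parameters: Optional[Sequence[ParameterRef]] = None,
    fast: bool = False,
    progress: Optional[Callable[[str], None]] = None,
) -> SensitivityReport:
    """Scan each parameter in +/-``step_frac`` steps until an experiment is lost.

    The reference configuration must pass every selected experiment,
    otherwise the scan is meaningless and a ``ValueError`` is raised.
    Scans are sequential per direction and stop at the first loss, so a
    reported boundary is always the nearest failing step.
    """
    model = model or build_default_circuit()
    cfg = cfg or SimConfig()
    if fast:
        step_frac = max(step_frac, 0.25)
        ids = list(ids) if ids is not None else list(FAST_SUBSET)
    elif ids is None:
        ids = list(REGISTRY)
    ids = list(ids)

    baseline_failures = _failed_ids(model, cfg, criteria, ids)
    if baseline_failures:
        raise ValueError(f"reference configuration fails {baseline_failures}; OAT scan requires a passing reference")

    params = list(parameters) if parameters is not None else scan_parameters(model)
    report = SensitivityReport(step_frac=step_frac, cap_frac=cap_frac, experiment_ids=ids)

    for ref in params:
        base = ref.get(model)
        lower_frac = upper_frac = None
        lower_lost = upper_lost = ""
        # downward: -step, -2*step, ... floor at -100%
        k = 1
        while True:
            frac = -k * step_frac
            if frac < -1.0:
                break
            trial = model.copy()
            ref.set(trial, base * (1.0 + frac))
            lost = _failed_ids(trial, cfg, criteria, ids)
            if lost:
                lower_frac, lower_lost = frac, lost[0]
                break
            if frac <= -1.0 + 1e-12:
                break
            k += 1
        # upward: +step, ... capped
        k = 1
        while True:
            frac = k * step_frac
            if frac > cap_frac + 1e-12:
                break
            trial = model.copy()
            ref.set(trial, base * (1.0 + frac))
            lost = _failed_ids(trial, cfg, criteria, ids)
            if lost:
                upper_frac, upper_lost = frac, lost[0]
                break
            k += 1
        report.parameters.append(
            ParameterReport(ref.name, base, lower_frac, upper_frac, lower_lost, upper_lost)
        )
        if progress is not None:
            progress(ref.name)
    return report


def prune_removable(report: SensitivityReport) -> list[str]:
    """Parameters whose value can be set to zero without losing anything."""
    return [p.parameter for p in report.parameters if p.removable]
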
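"""The in-silico experiment battery.

Each entry of the registry reproduces one published finding on cued
fear conditioning, extinction or reinstatement — behavioral courses,
synaptic-plasticity signatures measured by PSP probes, and the effects
of lesions, pharmacological inactivation, optogenetic-style clamps and
endocannabinoid blockades — and scores it against the operational
criteria: a unit counts as *active* above 20% of its maximum rate, the
fear response as *expressed* when CeM exceeds 70% of its maximum, and
LTP/LTD as *having happened* when the evoked PSP changes by at least
20%.

The registry groups the findings into 25 entries keyed to figure
panels; each entry carries one or more named sub-checks and passes only
if all of them do.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import cached_property
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .circuit import CircuitModel, Connection, UnitSpec, build_default_circuit
from .dynamics import SimConfig, unmap_potential, U_MAX
from .engine import CompiledNetwork
from .perturb import Perturbation, block, clamp_connection, clamp_max, lesion, zero_region
from .protocols import (
    Protocol,
    SessionTrace,
    Simulation,
    StimulusEpoch,
    make_conditioning,
    make_extinction,
    make_reinstatement,
)

__all__ = [
    "CriteriaConfig",
    "Check",
    "ExperimentResult",
    "ExperimentSpec",
    "ExperimentContext",
    "REGISTRY",
    "psp_probe",
    "classify_units",
    "evaluate_experiment",
    "run_registry",
    "PLASTIC_IDS",
]


@dataclass(frozen=True)
class CriteriaConfig:
    """Operational pass thresholds shared by every experiment."""

    unit_active_frac: float = 0.20  # a unit is "active" above this fraction of phi
    cem_fear_frac: float = 0.70  # CeM expresses fear above this fraction of phi
    psp_change_frac: float = 0.20  # LTP/LTD "happened" beyond this PSP change

    def __post_init__(self) -> None:
        for name in ("unit_active_frac", "cem_fear_frac", "psp_change_frac"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")


#: The eight plastic connections of the default model.
PLASTIC_IDS = [
    "CS->LAp1",
    "LAp2->CeL-ON",
    "PLp->BAp4",
    "BAp2->ILp",
    "BAp3->ITC",
    "BAcck->BAp2",
    "BAp4->CeM",
    "BAp5->CeM",
]


# ---------------------------------------------------------------------------
# PSP probe (acute-slice style measurement)


def _isolated_pair(model: CircuitModel, conn: Connection) -> CircuitModel:
    """Slice preparation: the probed connection with its two elements only."""
    units: list[UnitSpec] = []
    if conn.pre not in ("CS", "US"):
        units.append(model.unit(conn.pre))
    post = model.unit(conn.post)
    if post not in units:
        units.append(post)
    iso = CircuitModel.__new__(CircuitModel)  # skip validation of externals
    iso.units = units
    iso.connections = [Connection(conn.pre, conn.post, conn.weight)]
    iso.external_inputs = {"CS": 0.0, "US": 0.0}
    iso.dsi_theta = model.dsi_theta
    iso.description = f"isolated {conn.id}"
    return iso


def _probe_peak_mv(model: CircuitModel, conn_id: str, drive: float, duration_ms: float, cfg: SimConfig) -> float:
    """Peak postsynaptic deflection (mV) evoked by a presynaptic pulse.

    Inhibitory connections are probed from a depolarized holding level
    (mid-range potential), the slice-recording convention that makes a
    hyperpolarizing response measurable above the resting floor.
    """
    conn = model.connection(conn_id)
    iso = _isolated_pair(model, conn)
    net = CompiledNetwork(iso, cfg)
    net.frozen = True
    inhibitory = conn.pre not in ("CS", "US") and model.unit(conn.pre).polarity.sign < 0
    post_i = net.unit_index[conn.post]
    hold = np.zeros(net.n_units)
    if inhibitory:
        # steady holding drive placing the post unit at U = pi/2
        pre_i = net.unit_index[conn.pre]
        net.settle(1.0)
        a_pre0 = net.a[pre_i]
        hold[post_i] = 0.5 * U_MAX - net.tonic[post_i] + conn.weight * a_pre0
    for _ in range(int(round(1000.0 / cfg.dt))):
        net.step(0.0, 0.0, hold)
    u0 = net.u[post_i]
    n_stim = max(1, int(round(duration_ms / cfg.dt)))
    n_tail = int(round(300.0 / cfg.dt))
    peak = 0.0
    for k in range(n_stim + n_tail):
        cs = us = 0.0
        ext = hold.copy()
        if k < n_stim:
            if conn.pre == "CS":
                cs = drive
            elif conn.pre == "US":
                us = drive
            else:
                ext[net.unit_index[conn.pre]] += drive
        net.step(cs, us, ext)
        peak = max(peak, abs(net.u[post_i] - u0))
    # linear map [0, pi] <-> 100 mV, so a deflection converts directly
    return float(peak / U_MAX * (unmap_potential(U_MAX) - unmap_potential(0.0)))


def psp_probe(
    model: CircuitModel,
    conn_id: str,
    duration_ms: float = 30.0,
    ceiling_mv: float = 10.0,
    drive: Optional[float] = None,
    cfg: Optional[SimConfig] = None,
) -> tuple[float, float]:
    """Evoked-PSP measurement on one connection, in mV.

    With ``drive=None`` the presynaptic pulse amplitude is calibrated by
    bisection so that the evoked deflection sits just below
    ``ceiling_mv`` (the reference condition); pass the returned drive
    back in to re-measure the identical stimulation after learning.
    Runs on an isolated pair (no network feedback) with plasticity
    frozen; returns ``(drive, psp_mv)``.
    """
    cfg = cfg or SimConfig()
    model.connection(conn_id)  # raises for unknown connection
    if drive is not None:
        return drive, _probe_peak_mv(model, conn_id, drive, duration_ms, cfg)

    target = 0.95 * ceiling_mv
    lo, hi = 0.0, 1.0
    for _ in range(60):
        if _probe_peak_mv(model, conn_id, hi, duration_ms, cfg) >= target:
            break
        hi *= 2.0
    else:
        raise RuntimeError(f"{conn_id}: probe cannot reach {target} mV (weight zero?)")
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if _probe_peak_mv(model, conn_id, mid, duration_ms, cfg) < target:
            lo = mid
        else:
            hi = mid
    return hi, _probe_peak_mv(model, conn_id, hi, duration_ms, cfg)


def psp_change_pct(pre_mv: float, post_mv: float) -> float:
    """Percent PSP change; a vanished baseline reports +/-inf."""
    if pre_mv <= 1e-9:
        return float("inf") if post_mv > 1e-9 else 0.0
    return (post_mv - pre_mv) / pre_mv * 100.0


# ---------------------------------------------------------------------------
# unit taxonomy


def classify_units(
    post_cond: Mapping[str, float],
    post_ext: Mapping[str, float],
    model: CircuitModel,
    criteria: CriteriaConfig = CriteriaConfig(),
) -> dict[str, str]:
    """Fear / extinction / persistent taxonomy from two probe-CS responses.

    ``post_cond`` and ``post_ext`` map unit name to peak rate at a
    plasticity-frozen probe CS after conditioning and after extinction.
    Fear units respond only after conditioning, extinction units only
    after extinction, persistent units after both; activity is judged
    against ``unit_active_frac`` of each unit's maximum rate.
    """
    out = {}
    for u in model.units:
        thr = criteria.unit_active_frac * u.phi
        cond_on = post_cond[u.name] >= thr
        ext_on = post_ext[u.name] >= thr
        out[u.name] = (
            "persistent" if cond_on and ext_on else "fear" if cond_on else "extinction" if ext_on else "none"
        )
    return out


# ---------------------------------------------------------------------------
# experiment framework


@dataclass
class Check:
    name: str
    passed: bool
    value: float
    detail: str = ""


@dataclass
class ExperimentResult:
    id: str
    figure: str
    description: str
    checks: list[Check] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def check(self, name: str, passed, value, detail: str = "") -> None:
        self.checks.append(Check(name, bool(passed), float(value), detail))


@dataclass(frozen=True)
class ExperimentSpec:
    id: str
    figure: str
    description: str
    runner: Callable[["ExperimentContext"], ExperimentResult]

    def new_result(self) -> ExperimentResult:
        return ExperimentResult(self.id, self.figure, self.description)


class ExperimentContext:
    """Shared control pipeline: the unperturbed four-session paradigm.

    Computed lazily and cached, so the registry pays for the control
    run, its probes and its PSP measurements exactly once.
    """

    def __init__(
        self,
        model: Optional[CircuitModel] = None,
        cfg: Optional[SimConfig] = None,
        criteria: CriteriaConfig = CriteriaConfig(),
    ):
        self.model = model or build_default_circuit()
        self.cfg = cfg or SimConfig()
        self.criteria = criteria

    # -- helpers ----------------------------------------------------------
    def fresh(self) -> Simulation:
        return Simulation(self.model, replace(self.cfg))

    def phi(self, unit: str) -> float:
        return self.model.unit(unit).phi

    def frac(self, peaks: Mapping[str, float], unit: str) -> float:
        return peaks[unit] / self.phi(unit)

    def crossing_trial(self, trace: SessionTrace, unit: str = "CeM") -> int:
        """1-based index of the first CS whose response drops below the
        fear criterion; one past the end if it never does."""
        thr = self.criteria.cem_fear_frac * self.phi(unit)
        peaks = trace.cs_peaks(unit)
        below = np.nonzero(peaks < thr)[0]
        return int(below[0]) + 1 if len(below) else trace.n_cs + 1

    def psp_all(self, weights: Mapping[str, float]) -> dict[str, float]:
        """PSP (mV) of every plastic connection at the given weights,
        using the drives calibrated on the naive model."""
        model = self.model.copy()
        for cid, w in weights.items():
            model.connection(cid).weight = w
        out = {}
        for cid in PLASTIC_IDS:
            drive = self.probe_drives[cid]
            _, mv = psp_probe(model, cid, drive=drive, cfg=self.cfg)
            out[cid] = mv
        return out

    def psp_pct(self, stage_pre: Mapping[str, float], stage_post: Mapping[str, float], cid: str) -> float:
        return psp_change_pct(stage_pre[cid], stage_post[cid])

    # -- cached control pipeline ------------------------------------------
    @cached_property
    def probe_drives(self) -> dict[str, float]:
        out = {}
        for cid in PLASTIC_IDS:
            drive, _ = psp_probe(self.model, cid, cfg=self.cfg)
            out[cid] = drive
        return out

    @cached_property
    def naive_psp(self) -> dict[str, float]:
        return self.psp_all({c.id: c.weight for c in self.model.connections if c.id in PLASTIC_IDS})

    @cached_property
    def baseline(self) -> dict[str, float]:
        sim = self.fresh()
        return {n: float(sim.net.a[i]) for i, n in enumerate(sim.net.unit_names)}

    @cached_property
    def naive_probe(self) -> dict[str, float]:
        return self.fresh().probe_cs()

    # the control paradigm is computed in lazy stages, so evaluating a
    # subset of experiments (e.g. during a sensitivity scan) only pays
    # for the sessions and probes it actually touches

    @cached_property
    def _stage_cond(self) -> dict:
        sim = self.fresh()
        out = {"cond_trace": sim.run(make_conditioning())}
        sim.reset_transient()
        out["post_cond_w"] = sim.weights()
        out["cond_sim"] = sim
        return out

    @cached_property
    def _stage_ext(self) -> dict:
        sim = self._stage_cond["cond_sim"].clone()
        out = {"ext1_trace": sim.run(make_extinction())}
        out["end_ext1_w"] = sim.weights()  # before the between-session reset
        sim.reset_transient()
        out["ext2_trace"] = sim.run(make_extinction())
        # classification probe in the session-end state: the transient
        # DSI/DSE depression is still engaged, as when extinction units
        # are scored at the end of training
        out["post_ext_probe"] = sim.probe_cs(reset_transient=False)
        sim.reset_transient()
        out["post_ext_w"] = sim.weights()
        out["ext_sim"] = sim
        return out

    @cached_property
    def _stage_reinst(self) -> dict:
        sim = self._stage_ext["ext_sim"].clone()
        out = {"reinst_trace": sim.run(make_reinstatement())}
        sim.reset_transient()
        out["post_reinst_w"] = sim.weights()
        return out

    @property
    def _pipeline(self) -> dict:
        return {**self._stage_cond, **self._stage_ext, **self._stage_reinst}

    def conditioned_sim(self) -> Simulation:
        """A fresh simulation already taken through clean conditioning."""
        return self._stage_cond["cond_sim"].clone()

    def extinguished_sim(self) -> Simulation:
        """A fresh simulation after conditioning plus both extinction sessions."""
        return self._stage_ext["ext_sim"].clone()

    @cached_property
    def cond_trace(self) -> SessionTrace:
        return self._stage_cond["cond_trace"]

    @cached_property
    def ext1_trace(self) -> SessionTrace:
        return self._stage_ext["ext1_trace"]

    @cached_property
    def ext2_trace(self) -> SessionTrace:
        return self._stage_ext["ext2_trace"]

    @cached_property
    def reinst_trace(self) -> SessionTrace:
        return self._stage_reinst["reinst_trace"]

    @cached_property
    def post_cond_probe(self) -> dict[str, float]:
        return self.conditioned_sim().probe_cs()

    @cached_property
    def post_ext_probe(self) -> dict[str, float]:
        return self._stage_ext["post_ext_probe"]

    @cached_property
    def post_cond_psp(self) -> dict[str, float]:
        return self.psp_all(self._stage_cond["post_cond_w"])

    @cached_property
    def post_ext_psp(self) -> dict[str, float]:
        return self.psp_all(self._stage_ext["post_ext_w"])

    @cached_property
    def post_reinst_psp(self) -> dict[str, float]:
        return self.psp_all(self._stage_reinst["post_reinst_w"])

    @cached_property
    def taxonomy(self) -> dict[str, str]:
        return classify_units(self.post_cond_probe, self.post_ext_probe, self.model, self.criteria)

    @cached_property
    def crossing_s1(self) -> int:
        return self.crossing_trial(self.ext1_trace)

    @cached_property
    def crossing_s2(self) -> int:
        return self.crossing_trial(self.ext2_trace)


# ---------------------------------------------------------------------------
# registry runners

_REGISTRY: dict[str, ExperimentSpec] = {}


def _experiment(id: str, figure: str, description: str):
    def deco(fn):
        _REGISTRY[id] = ExperimentSpec(id, figure, description, fn)
        return fn

    return deco


def _pct(x: float) -> float:
    return round(x * 100.0, 1)


# -- Fig 3: the behavioral course ------------------------------------------


@_experiment("fig3_conditioning", "Fig 3", "Three CS-US pairings establish a CS-evoked CeM (fear) response")
def _fig3_conditioning(ctx: ExperimentContext) -> ExperimentResult:
    r = _REGISTRY["fig3_conditioning"].new_result()
    phi = ctx.phi("CeM")
    peaks = ctx.cond_trace.cs_peaks("CeM") / phi
    r.check("cem_cs3_fear", peaks[2] >= ctx.criteria.cem_fear_frac, _pct(peaks[2]), "CeM at 3rd CS, % of max")
    r.check("acquisition_rises", peaks[0] < peaks[2], _pct(peaks[2] - peaks[0]), "CS3 - CS1 response")
    r.check("naive_cs_silent", ctx.frac(ctx.naive_probe, "CeM") < ctx.criteria.unit_active_frac,
            _pct(ctx.frac(ctx.naive_probe, "CeM")), "CeM at naive probe CS")
    return r


@_experiment("fig3_within_session_extinction", "Fig 3", "The fear response declines within one 20-CS extinction session")
def _fig3_within(ctx: ExperimentContext) -> ExperimentResult:
    r = _REGISTRY["fig3_within_session_extinction"].new_result()
    peaks = ctx.ext1_trace.cs_peaks("CeM") / ctx.phi("CeM")
    r.check("starts_fearful", peaks[0] >= ctx.criteria.cem_fear_frac, _pct(peaks[0]))
    r.check("ends_below_criterion", peaks[-1] < ctx.criteria.cem_fear_frac, _pct(peaks[-1]))
    r.check("declines", peaks[-1] < peaks[0], _pct(peaks[0] - peaks[-1]))
    return r


@_experiment("fig3_between_session_extinction", "Fig 3", "Extinction is retained across the session break")
def _fig3_between(ctx: ExperimentContext) -> ExperimentResult:
    r = _REGISTRY["fig3_between_session_extinction"].new_result()
    s1 = ctx.ext1_trace.cs_peaks("CeM") / ctx.phi("CeM")
    s2 = ctx.ext2_trace.cs_peaks("CeM") / ctx.phi("CeM")
    r.check("s2_starts_below_criterion", s2[0] < ctx.criteria.cem_fear_frac, _pct(s2[0]))
    r.check("s2_start_below_s1_start", s2[0] < s1[0], _pct(s1[0] - s2[0]))
    return r


@_experiment("fig3_residual_freezing", "Fig 3", "A residual CeM response persists into session 2 and fades within it")
def _fig3_residual(ctx: ExperimentContext) -> ExperimentResult:
    r = _REGISTRY["fig3_residual_freezing"].new_result()
    s2 = ctx.ext2_trace.cs_peaks("CeM") / ctx.phi("CeM")
    reinst = ctx.reinst_trace.cs_peaks("CeM") / ctx.phi("CeM")
    r.check("residual_present", s2[0] >= ctx.criteria.unit_active_frac, _pct(s2[0]), "first CS of session 2")
    r.check("fades_within_session", s2[-1] < 0.5 * s2[0], _pct(s2[-1]), "last CS of session 2")
    r.check("reappears_after_break", reinst[0] >= ctx.criteria.unit_active_frac, _pct(reinst[0]),
            "first reinstatement CS (transient weights forgotten)")
    return r


@_experiment("fig3_reinstatement", "Fig 3", "A single unpaired US restores the extinguished fear response")
def _fig3_reinstatement(ctx: ExperimentContext) -> ExperimentResult:
    r = _REGISTRY["fig3_reinstatement"].new_result()
    peaks = ctx.reinst_trace.cs_peaks("CeM") / ctx.phi("CeM")
    r.check("pre_us_cs_extinguished", peaks[0] < ctx.criteria.cem_fear_frac, _pct(peaks[0]))
    r.check("post_us_cs_fear", peaks[1] >= ctx.criteria.cem_fear_frac, _pct(peaks[1]))
    bap4 = ctx.reinst_trace.cs_peak("BAp4", 2) / ctx.phi("BAp4")
    r.check("fear_unit_reappears", bap4 >= ctx.criteria.unit_active_frac, _pct(bap4), "BAp4 at final CS")
    ilp = ctx.reinst_trace.cs_peak("ILp", 2) / ctx.phi("ILp")
    r.check("extinction_unit_shut_down", ilp < ctx.criteria.unit_active_frac, _pct(ilp), "ILp at final CS")
    return r


@_experiment("fig3_unit_taxonomy", "Fig 3", "Probe CSs after conditioning/extinction sort units into fear, extinction and persistent classes")
def _fig3_taxonomy(ctx: ExperimentContext) -> ExperimentResult:
    r = _REGISTRY["fig3_unit_taxonomy"].new_result()
    tax = ctx.taxonomy
    fear = {u for u, k in tax.items() if k == "fear"}
    r.check("fear_units", fear == {"BAp4", "CeM"}, len(fear), f"fear class = {sorted(fear)}")
    for u in ("BAp3", "ILp", "ITC"):
        r.check(f"extinction_{u}", tax[u] == "extinction", 1.0 if tax[u] == "extinction" else 0.0, tax[u])
    for u in ("LAp1", "BAp1", "BAp5", "BAcck", "BApv", "CeL-ON", "PLp"):
        r.check(f"persistent_{u}", tax[u] == "persistent", 1.0 if tax[u] == "persistent" else 0.0, tax[u])
    return r


# -- Figs 4-6: plasticity signatures ---------------------------------------


@_experiment("fig4_conditioning_ltp", "Fig 4", "Conditioning potentiates the CS pathway, the LA->CeL-ON gate and the PL->BA fear synapse")
def _fig4_ltp(ctx: ExperimentContext) -> ExperimentResult:
    r = _REGISTRY["fig4_conditioning_ltp"].new_result()
    thr = ctx.criteria.psp_change_frac * 100.0
    for cid in ("CS->LAp1", "LAp2->CeL-ON", "PLp->BAp4"):
        pct = ctx.psp_pct(ctx.naive_psp, ctx.post_cond_psp, cid)
        r.check(f"ltp_{cid}", pct >= thr, round(pct, 1), "% PSP change over conditioning")
    return r


@_experiment("fig4_conditioning_stability", "Fig 4", "The remaining plastic synapses are unchanged by conditioning")
def _fig4_stability(ctx: ExperimentContext) -> ExperimentResult:
    r = _REGISTRY["fig4_conditioning_stability"].new_result()
    thr = ctx.criteria.psp_change_frac * 100.0
    for cid in ("BAp3->ITC", "BAp2->ILp"):
        pct = ctx.psp_pct(ctx.naive_psp, ctx.post_cond_psp, cid)
        r.check(f"stable_{cid}", abs(pct) < thr, round(pct, 1), "% PSP change over conditioning")
    # transient endocannabinoid weights recover at the session boundary
    for cid in ("BAcck->BAp2", "BAp4->CeM", "BAp5->CeM"):
        w0 = ctx.model.connection(cid).weight
        w1 = ctx._stage_cond["post_cond_w"][cid]
        r.check(f"recovered_{cid}", abs(w1 - w0) < 1e-9 * max(w0, 1.0), w1, "weight after session boundary")
    return r


@_experiment("fig5_extinction_plasticity", "Fig 5", "Extinction depresses PL->BA, potentiates BA->IL and BA->ITC, and spares the CS pathway")
def _fig5_plasticity(ctx: ExperimentContext) -> ExperimentResult:
    r = _REGISTRY["fig5_extinction_plasticity"].new_result()
    thr = ctx.criteria.psp_change_frac * 100.0
    ltd = ctx.psp_pct(ctx.post_cond_psp, ctx.post_ext_psp, "PLp->BAp4")
    r.check("ltd_PLp->BAp4", ltd <= -thr, round(ltd, 1), "% PSP change over extinction")
    for cid in ("BAp2->ILp", "BAp3->ITC"):
        pct = ctx.psp_pct(ctx.post_cond_psp, ctx.post_ext_psp, cid)
        r.check(f"ltp_{cid}", pct >= thr, min(round(pct, 1), 9999.0), "% PSP change over extinction")
    for cid in ("CS->LAp1", "LAp2->CeL-ON"):
        pct = ctx.psp_pct(ctx.post_cond_psp, ctx.post_ext_psp, cid)
        r.check(f"stable_{cid}", abs(pct) < thr, round(pct, 1), "no depotentiation of the conditioning LTP")
    return r


@_experiment("fig5_transient_dsi_dse", "Fig 5", "DSI/DSE transiently weaken their synapses by the end of an extinction session")
def _fig5_transient(ctx: ExperimentContext) -> ExperimentResult:
    r = _REGISTRY["fig5_transient_dsi_dse"].new_result()
    thr = ctx.criteria.psp_change_frac
    end_w = ctx._stage_ext["end_ext1_w"]
    for cid in ("BAcck->BAp2", "BAp4->CeM", "BAp5->CeM"):
        w0 = ctx.model.connection(cid).weight
        drop = 1.0 - end_w[cid] / w0
        r.check(f"weakened_{cid}", drop >= thr, _pct(drop), "% weight drop at session end (before forgetting)")
    return r


@_experiment("fig6_reinstatement_plasticity", "Fig 6", "Reinstatement re-potentiates PL->BA and depotentiates BA->IL")
def _fig6_plasticity(ctx: ExperimentContext) -> ExperimentResult:
    r = _REGISTRY["fig6_reinstatement_plasticity"].new_result()
    thr = ctx.criteria.psp_change_frac * 100.0
    up = ctx.psp_pct(ctx.post_ext_psp, ctx.post_reinst_psp, "PLp->BAp4")
    r.check("repotentiation_PLp->BAp4", up >= thr, round(up, 1), "% PSP change over reinstatement")
    down = ctx.psp_pct(ctx.post_ext_psp, ctx.post_reinst_psp, "BAp2->ILp")
    r.check("depotentiation_BAp2->ILp", down <= -thr, round(down, 1), "% PSP change over reinstatement")
    return r


# -- Fig 7: conditioning manipulations -------------------------------------


@_experiment("fig7a_pl_ttx", "Fig 7A", "PL inactivation blunts fear expression during conditioning but not the learning itself")
def _fig7a(ctx: ExperimentContext) -> ExperimentResult:
    r = _REGISTRY["fig7a_pl_ttx"].new_result()
    sim = ctx.fresh()
    tr = sim.run(make_conditioning(), perturbations=[zero_region("PL")])
    cs3 = tr.cs_peak("CeM", 3) / ctx.phi("CeM")
    ctrl = ctx.cond_trace.cs_peak("CeM", 3) / ctx.phi("CeM")
    r.check("expression_reduced", cs3 < ctrl - 0.10, _pct(cs3), "CeM at 3rd CS under PL inactivation")
    sim.reset_transient()
    test = ctx.frac(sim.probe_cs(), "CeM")
    r.check("learning_intact", test >= ctx.criteria.cem_fear_frac, _pct(test), "probe CS after PL restoration")
    return r


@_experiment("fig7b_optogenetic_toggle", "Fig 7B", "CS-pathway LTP is necessary but not sufficient; fear toggles with de/re-potentiation")
def _fig7b(ctx: ExperimentContext) -> ExperimentResult:
    r = _REGISTRY["fig7b_optogenetic_toggle"].new_result()
    fear = ctx.criteria.cem_fear_frac
    conn = ctx.model.connection("CS->LAp1")
    tripled = 3.0 * conn.initial_weight

    naive = ctx.fresh()
    naive.set_weight("CS->LAp1", tripled)
    ltp_only = ctx.frac(naive.probe_cs(), "CeM")
    r.check("ltp_alone_insufficient", ltp_only < fear, _pct(ltp_only), "probe CS, naive circuit + artificial LTP")

    sim = ctx.conditioned_sim()
    cond = ctx.frac(sim.probe_cs(), "CeM")
    r.check("conditioned", cond >= fear, _pct(cond))
    sim.set_weight("CS->LAp1", 0.0)
    ltd = ctx.frac(sim.probe_cs(), "CeM")
    r.check("depotentiation_abolishes", ltd < fear, _pct(ltd))
    sim.set_weight("CS->LAp1", tripled)
    reltp = ctx.frac(sim.probe_cs(), "CeM")
    r.check("repotentiation_restores", reltp >= fear, _pct(reltp))
    return r


@_experiment("fig7c_la_cel_inactivation", "Fig 7C", "Inactivating LA or CeL during conditioning prevents fear learning")
def _fig7c(ctx: ExperimentContext) -> ExperimentResult:
    r = _REGISTRY["fig7c_la_cel_inactivation"].new_result()
    for label, lesions in (
        ("la", [lesion("LAp1"), lesion("LAp2")]),
        ("cel", [lesion("CeL-ON"), lesion("CeL-OFF")]),
    ):
        sim = ctx.fresh()
        sim.run(make_conditioning(), perturbations=lesions, record=False)
        sim.reset_transient()
        test = ctx.frac(sim.probe_cs(), "CeM")
        r.check(f"{label}_conditioning_lost", test < ctx.criteria.cem_fear_frac, _pct(test),
                f"probe CS after {label.upper()}-inactivated training")
    return r


# -- Fig 8: the CeL gate and US substitution -------------------------------


@_experiment("fig8ab_cel_reversal", "Fig 8A,B", "Conditioning recruits CeL-ON and shuts down the tonic CeL-OFF brake")
def _fig8ab(ctx: ExperimentContext) -> ExperimentResult:
    r = _REGISTRY["fig8ab_cel_reversal"].new_result()
    act = ctx.criteria.unit_active_frac
    on_naive = ctx.frac(ctx.naive_probe, "CeL-ON")
    on_cond = ctx.frac(ctx.post_cond_probe, "CeL-ON")
    r.check("cel_on_naive_silent", on_naive < act, _pct(on_naive), "CeL-ON at naive probe CS")
    r.check("cel_on_recruited", on_cond >= act, _pct(on_cond), "CeL-ON at post-conditioning probe CS")
    off_base = ctx.baseline["CeL-OFF"] / ctx.phi("CeL-OFF")
    off_cond = ctx.frac(ctx.post_cond_probe, "CeL-OFF")
    r.check("cel_off_tonically_active", off_base >= act, _pct(off_base), "CeL-OFF at rest")
    r.check("cel_off_shut_down", off_cond < act, _pct(off_cond), "CeL-OFF during post-conditioning CS")
    return r


def _substitution_protocol() -> tuple[Protocol, list[tuple[float, float]]]:
    """Conditioning with the US epochs silenced; returns their windows."""
    p = make_conditioning()
    windows = [(e.t_start, e.t_end) for e in p.epochs_of("US")]
    epochs = [
        e if e.channel == "CS" else StimulusEpoch(e.t_start, e.duration, "US", 0.0) for e in p.epochs
    ]
    return Protocol(name="us_substitution", epochs=epochs, tail_s=p.tail_s), windows


def _run_substitution(ctx: ExperimentContext, extra: Sequence[Perturbation] = (), unpaired: bool = False) -> Simulation:
    proto, windows = _substitution_protocol()
    if unpaired:  # deliver the LA depolarization in the inter-trial interval
        windows = [(t0 + 3.0, t1 + 3.0) for (t0, t1) in windows]
    perts = []
    for w in windows:
        perts += [clamp_max("LAp1", w), clamp_max("LAp2", w)]
        for p in extra:
            perts.append(Perturbation(p.kind, p.target, w, p.value))
    sim = ctx.fresh()
    sim.run(proto, perturbations=perts, record=False)
    sim.reset_transient()
    return sim


@_experiment("fig8c_us_substitution", "Fig 8C", "Pairing the CS with LA depolarization conditions, but more weakly than a real US")
def _fig8c(ctx: ExperimentContext) -> ExperimentResult:
    r = _REGISTRY["fig8c_us_substitution"].new_result()
    sub = ctx.frac(_run_substitution(ctx).probe_cs(), "CeM")
    ctrl = ctx.frac(ctx.post_cond_probe, "CeM")
    r.check("conditioning_present", sub >= ctx.criteria.unit_active_frac, _pct(sub), "probe CS after paired LA depolarization")
    r.check("weaker_than_us", sub <= ctrl - 0.10, _pct(ctrl - sub), "deficit vs real-US conditioning, % of max")
    unp = ctx.frac(_run_substitution(ctx, unpaired=True).probe_cs(), "CeM")
    r.check("unpaired_control_fails", unp < ctx.criteria.unit_active_frac, _pct(unp), "probe CS after unpaired control")
    return r


@_experiment("fig9_bap2_rescue", "Fig 9", "LA-depolarization conditioning engages the extinction circuit; silencing BAp2 rescues full learning")
def _fig9(ctx: ExperimentContext) -> ExperimentResult:
    r = _REGISTRY["fig9_bap2_rescue"].new_result()
    thr = ctx.criteria.psp_change_frac * 100.0
    sub_sim = _run_substitution(ctx)
    sub_psp = ctx.psp_all(sub_sim.weights())
    for cid in ("CS->LAp1", "LAp2->CeL-ON"):
        pct = ctx.psp_pct(ctx.naive_psp, sub_psp, cid)
        r.check(f"ltp_{cid}", pct >= thr, round(pct, 1), "% PSP change, substitution conditioning")
    pct = ctx.psp_pct(ctx.naive_psp, sub_psp, "PLp->BAp4")
    r.check("fear_synapse_unpotentiated", pct < thr, round(pct, 1), "% PSP change, substitution conditioning")
    resc = ctx.frac(_run_substitution(ctx, extra=[lesion("BAp2")]).probe_cs(), "CeM")
    ctrl = ctx.frac(ctx.post_cond_probe, "CeM")
    r.check("rescue_full_conditioning", resc >= ctrl - 0.10, _pct(resc), "probe CS with BAp2 silenced during depolarization")
    return r


# -- Figs 10-11: endocannabinoid blockades ---------------------------------


def _blockade_course(ctx: ExperimentContext, s1_blocks: Sequence[Perturbation], s2_blocks: Sequence[Perturbation] = ()) -> tuple[SessionTrace, SessionTrace]:
    sim = ctx.conditioned_sim()
    t1 = sim.run(make_extinction(), perturbations=list(s1_blocks))
    sim.reset_transient()
    t2 = sim.run(make_extinction(), perturbations=list(s2_blocks))
    sim.reset_transient()
    return t1, t2


@_experiment("fig10a_ecb_global_blockade", "Fig 10A", "Blocking DSI/DSE everywhere abolishes both within- and between-session extinction")
def _fig10a(ctx: ExperimentContext) -> ExperimentResult:
    r = _REGISTRY["fig10a_ecb_global_blockade"].new_result()
    blocks = [block("DSI", "all"), block("DSE", "all")]
    t1, t2 = _blockade_course(ctx, blocks, blocks)
    fear = ctx.criteria.cem_fear_frac
    s1_last = t1.cs_peak("CeM", t1.n_cs) / ctx.phi("CeM")
    s2_last = t2.cs_peak("CeM", t2.n_cs) / ctx.phi("CeM")
    r.check("no_within_session_extinction", s1_last >= fear, _pct(s1_last), "CeM at last CS of session 1")
    r.check("no_between_session_extinction", s2_last >= fear, _pct(s2_last), "CeM at last CS of session 2")
    return r


@_experiment("fig10b_dse_cem_blockade", "Fig 10B", "Blocking DSI/DSE in CeM impairs within-session extinction only")
def _fig10b(ctx: ExperimentContext) -> ExperimentResult:
    r = _REGISTRY["fig10b_dse_cem_blockade"].new_result()
    t1, t2 = _blockade_course(ctx, [block("all", "CeM")])
    c1 = ctx.crossing_trial(t1)
    r.check("s1_extinction_delayed", c1 >= ctx.crossing_s1 + 3, c1,
            f"first sub-criterion CS in session 1 (control: {ctx.crossing_s1})")
    s2_last = t2.cs_peak("CeM", t2.n_cs) / ctx.phi("CeM")
    r.check("s2_extinction_spared", s2_last < ctx.criteria.cem_fear_frac, _pct(s2_last), "CeM at last CS of session 2")
    c2 = ctx.crossing_trial(t2)
    r.check("s2_course_like_control", abs(c2 - ctx.crossing_s2) <= 3, c2,
            f"first sub-criterion CS in session 2 (control: {ctx.crossing_s2})")
    return r


@_experiment("fig10c_dsi_ba_blockade", "Fig 10C", "Blocking DSI/DSE in BA spares within-session but abolishes between-session extinction")
def _fig10c(ctx: ExperimentContext) -> ExperimentResult:
    r = _REGISTRY["fig10c_dsi_ba_blockade"].new_result()
    t1, t2 = _blockade_course(ctx, [block("all", "BA")])
    s1_last = t1.cs_peak("CeM", t1.n_cs) / ctx.phi("CeM")
    r.check("s1_extinction_spared", s1_last < ctx.criteria.cem_fear_frac, _pct(s1_last),
            "CeM at last CS of session 1 (within-session extinction intact)")
    s2_first = t2.cs_peak("CeM", 1) / ctx.phi("CeM")
    r.check("between_session_deficit", s2_first >= ctx.criteria.cem_fear_frac, _pct(s2_first),
            "CeM at first CS of session 2 (control stays below criterion)")
    return r


@_experiment("fig11_ba_blockade_plasticity", "Fig 11", "Blocking DSI in BA during extinction prevents the extinction-circuit plasticity")
def _fig11(ctx: ExperimentContext) -> ExperimentResult:
    r = _REGISTRY["fig11_ba_blockade_plasticity"].new_result()
    sim = ctx.conditioned_sim()
    post_cond_w = sim.weights()
    blocks = [block("all", "BA")]
    sim.run(make_extinction(), perturbations=blocks, record=False)
    end_w = sim.weights()
    sim.reset_transient()
    sim.run(make_extinction(), perturbations=blocks, record=False)
    sim.reset_transient()
    w = sim.weights()
    ctrl_w = ctx._stage_ext["post_ext_w"]
    r.check("no_dsi_BAcck->BAp2", end_w["BAcck->BAp2"] >= 0.99 * ctx.model.connection("BAcck->BAp2").weight,
            end_w["BAcck->BAp2"], "weight at end of blocked session 1")
    r.check("ltp_BAp2->ILp_impaired", w["BAp2->ILp"] < 0.2 * max(ctrl_w["BAp2->ILp"], 1e-9),
            w["BAp2->ILp"], f"vs control extinction ({ctrl_w['BAp2->ILp']:.2f})")
    r.check("ltp_BAp3->ITC_impaired", w["BAp3->ITC"] < post_cond_w["BAp3->ITC"] * (1 + ctx.criteria.psp_change_frac),
            w["BAp3->ITC"], "no extinction LTP of BA->ITC")
    r.check("no_ltd_PLp->BAp4", w["PLp->BAp4"] >= post_cond_w["PLp->BAp4"] * (1 - ctx.criteria.psp_change_frac),
            w["PLp->BAp4"], "fear synapse not depotentiated")
    return r


# -- Fig 12: IL and PL->IL manipulations -----------------------------------


_IL_LESION = (lesion("ILp"), lesion("ILpv"), Perturbation("set_connection", "US->ILpv", value=0.0))


@_experiment("fig12a_il_lesion", "Fig 12A", "IL lesion spares conditioning and within-session extinction, abolishes between-session extinction")
def _fig12a(ctx: ExperimentContext) -> ExperimentResult:
    r = _REGISTRY["fig12a_il_lesion"].new_result()
    sim = ctx.fresh()
    sim.run(make_conditioning(), perturbations=list(_IL_LESION), record=False)
    sim.reset_transient()
    cond = ctx.frac(sim.probe_cs(perturbations=_IL_LESION[:2]), "CeM")
    r.check("conditioning_intact", cond >= ctx.criteria.cem_fear_frac, _pct(cond), "probe CS after lesioned conditioning")
    t1 = sim.run(make_extinction(), perturbations=list(_IL_LESION))
    sim.reset_transient()
    s1_last = t1.cs_peak("CeM", t1.n_cs) / ctx.phi("CeM")
    r.check("within_session_spared", s1_last < ctx.criteria.cem_fear_frac, _pct(s1_last),
            "CeM at last CS of session 1 (within-session extinction intact)")
    t2 = sim.run(make_extinction(), perturbations=list(_IL_LESION))
    s2_first = t2.cs_peak("CeM", 1) / ctx.phi("CeM")
    r.check("between_session_deficit", s2_first >= ctx.criteria.cem_fear_frac, _pct(s2_first),
            "CeM at first CS of session 2")
    return r


@_experiment("fig12b_il_stimulation", "Fig 12B", "Stimulating ILp at each CS speeds extinction")
def _fig12b(ctx: ExperimentContext) -> ExperimentResult:
    r = _REGISTRY["fig12b_il_stimulation"].new_result()
    sim = ctx.conditioned_sim()
    t1 = sim.run(make_extinction(), perturbations=[clamp_max("ILp", window="cs")])
    c1 = ctx.crossing_trial(t1)
    r.check("extinction_faster", c1 <= ctx.crossing_s1 - 2, c1,
            f"first sub-criterion CS (control: {ctx.crossing_s1})")
    return r


@_experiment("fig12c_pl_il_stimulation", "Fig 12C", "Driving the PL->IL projection at each CS speeds extinction")
def _fig12c(ctx: ExperimentContext) -> ExperimentResult:
    r = _REGISTRY["fig12c_pl_il_stimulation"].new_result()
    sim = ctx.conditioned_sim()
    t1 = sim.run(make_extinction(), perturbations=[clamp_connection("PLp->ILp", None, window="cs")])
    c1 = ctx.crossing_trial(t1)
    r.check("extinction_faster", c1 <= ctx.crossing_s1 - 2, c1,
            f"first sub-criterion CS (control: {ctx.crossing_s1})")
    return r


@_experiment("fig12d_pl_il_inactivation", "Fig 12D", "Silencing the PL->IL projection slows early but not late extinction")
def _fig12d(ctx: ExperimentContext) -> ExperimentResult:
    r = _REGISTRY["fig12d_pl_il_inactivation"].new_result()
    sim = ctx.conditioned_sim()
    t1 = sim.run(make_extinction(), perturbations=[clamp_connection("PLp->ILp", 0.0, window="cs")])
    c1 = ctx.crossing_trial(t1)
    r.check("early_extinction_slowed", c1 >= ctx.crossing_s1 + 2, c1,
            f"first sub-criterion CS (control: {ctx.crossing_s1})")
    last = t1.cs_peak("CeM", t1.n_cs) / ctx.phi("CeM")
    r.check("late_extinction_intact", last < ctx.criteria.cem_fear_frac, _pct(last), "CeM at last CS of the session")
    return r


# ---------------------------------------------------------------------------

REGISTRY: dict[str, ExperimentSpec] = dict(_REGISTRY)


def evaluate_experiment(spec: ExperimentSpec, ctx: ExperimentContext) -> ExperimentResult:
    """Run one registered experiment against a (cached) control context."""
    return spec.runner(ctx)


def run_registry(
    model: Optional[CircuitModel] = None,
    cfg: Optional[SimConfig] = None,
    criteria: CriteriaConfig = CriteriaConfig(),
    ids: Optional[Sequence[str]] = None,
    ctx: Optional[ExperimentContext] = None,
) -> tuple[list[ExperimentResult], pd.DataFrame]:
    """Evaluate the experiment battery; returns results and a summary table."""
    ctx = ctx or ExperimentContext(model, cfg, criteria)
    chosen = list(REGISTRY) if ids is None else list(ids)
    unknown = set(chosen) - set(REGISTRY)
    if unknown:
        raise KeyError(f"unknown experiment ids: {sorted(unknown)}")
    results = [evaluate_experiment(REGISTRY[i], ctx) for i in chosen]
    rows = []
    for res in results:
        failed = [c.name for c in res.checks if not c.passed]
        rows.append(
            {
                "id": res.id,
                "figure": res.figure,
                "verdict": "pass" if res.passed else "FAIL",
                "n_checks": len(res.checks),
                "failed_checks": ";".join(failed),
                "description": res.description,
            }
        )
    return results, pd.DataFrame(rows)
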
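"""Write the calibrated default circuit configuration.

The main text of the underlying experimental literature pins down only
a handful of constants (the 0.7 basket-cell weights, the 7.0/5.0/3.0
LA->BA fan-out, stimulus drive 100, the 3x-initial weight ceiling, the
10-s endocannabinoid trigger, dt = 10 ms, membrane time constants
between 7.7 and 35.6 ms, and tonic drives proportional to basal rates
of 0.3/1.3/5.3 Hz).  Every other unit parameter, weight and learning
rate below is a calibration by this package, found by incremental
manual search against the experiment registry (run
``fearcircuit experiments`` to audit) followed by the coordinate
refinement in ``scripts/refine.py``.

Usage:  python scripts/calibrate.py [--out PATH]
"""

from __future__ import annotations

import argparse
from pathlib import Path

import yaml

# --- unit electrophysiology -------------------------------------------------
# tau in ms; tonic/psi in remapped-potential units; phi in rate units of
# 100 Hz.  Tonic drives are basal-rate-proportional (constant 0.15 per
# 1 Hz): pyramidal 0.3 Hz -> 0.045, interneurons 1.3 Hz -> 0.195,
# parvalbumin (and cck basket, which shares pv kinetics) 5.3 Hz -> 0.795.
# CeL-OFF carries its own strong tonic drive: it is the tonically firing
# brake on CeM.

PYR = dict(tau=24.4, tonic=0.045, phi=0.40, polarity="excitatory", **{"class": "pyramidal"})
PV = dict(tau=7.7, tonic=0.795, phi=1.20, psi=0.31, polarity="inhibitory", **{"class": "parvalbumin"})
SST = dict(tau=16.0, tonic=0.195, phi=0.60, psi=0.40, polarity="inhibitory", **{"class": "somatostatin"})

UNITS = [
    # lateral amygdala: sensory entry
    dict(name="LAp1", psi=0.63, **PYR),
    dict(name="LAp2", psi=0.63, **PYR),
    dict(name="LApv", **PV),
    dict(name="LAvip", tau=14.0, tonic=0.195, phi=0.60, psi=0.40, polarity="inhibitory", **{"class": "vip"}),
    # basal amygdala: hub between LA, cortex and output
    dict(name="BAp1", psi=0.63, **PYR),
    dict(name="BAp2", psi=0.63, **PYR),
    dict(name="BAp3", psi=0.50, **PYR),
    dict(name="BAp4", psi=0.50, **PYR),
    dict(name="BAp5", psi=0.45, **PYR),
    dict(name="BAcck", tau=9.0, tonic=0.795, phi=1.20, psi=0.31, polarity="inhibitory", **{"class": "cck"}),
    dict(name="BApv", **PV),
    # central amygdala: CeL gate and CeM output
    dict(name="CeL-ON", tau=15.0, tonic=0.195, phi=0.60, psi=0.40, polarity="inhibitory", **{"class": "other"}),
    dict(name="CeL-OFF", tau=15.0, tonic=1.20, phi=0.60, psi=0.40, polarity="inhibitory", **{"class": "other"}),
    dict(name="CeM", tau=20.0, tonic=0.195, phi=0.40, psi=0.40, polarity="inhibitory", **{"class": "other"}),
    dict(name="ITC", tau=13.0, tonic=0.195, phi=0.60, psi=0.40, polarity="inhibitory", **{"class": "other"}),
    # prelimbic cortex: fear expression
    dict(name="PLp", tau=28.0, tonic=0.045, phi=0.40, psi=0.63, polarity="excitatory", **{"class": "pyramidal"}),
    dict(name="PLpv", **PV),
    dict(name="PLs", **SST),
    # infralimbic cortex: extinction
    dict(name="ILp", tau=28.0, tonic=0.045, phi=0.40, psi=0.50, polarity="excitatory", **{"class": "pyramidal"}),
    dict(name="ILpv", **PV),
    dict(name="ILs", **SST),
]

# --- connections ------------------------------------------------------------

def C(pre, post, weight, plasticity=None):
    d = dict(pre=pre, post=post, weight=weight)
    if plasticity:
        d["plasticity"] = plasticity
    return d


CONNECTIONS = [
    # sensory input to LA; the CS pathway onto LAp1 is the conditioning synapse
    C("CS", "LAp1", 0.0054, dict(rule="LTP", eta=0.0008, sigma=0.25)),
    C("CS", "LAp2", 0.0163),
    C("US", "LAp1", 0.020),
    C("US", "LAvip", 0.010),
    # hypothesis: the US silences IL pyramids via their pv interneurons
    C("US", "ILpv", 0.030),
    C("LAvip", "LApv", 1.5),
    C("LApv", "LAp1", 0.5),
    C("LApv", "LAp2", 0.5),
    # LA fan-out into BA (7.0 / 5.0 / 3.0) and feedforward cck inhibition
    C("LAp1", "BAp1", 7.0),
    C("LAp1", "BAp2", 5.0),
    C("LAp1", "BAp5", 3.0),
    C("LAp1", "BAcck", 0.5),
    # CS-only LA neurons gate the CeL brake
    C("LAp2", "CeL-ON", 1.2, dict(rule="LTP", eta=0.02, sigma=0.05)),
    C("CeL-ON", "CeL-OFF", 6.0),
    C("CeL-OFF", "CeM", 6.0),
    C("BAcck", "BAp1", 0.7),
    C("BAcck", "BAp2", 0.7, dict(rule="DSI", eta=0.00003, trigger_s=10.0)),
    # BA -> PL -> BA fear loop
    C("BAp1", "PLs", 4.0),
    C("BAp1", "PLp", 5.0),
    C("PLs", "PLpv", 4.0),
    C("PLpv", "PLp", 0.5),
    C("PLp", "BAp4", 5.0, dict(rule="LTP_LTD", eta=0.0025, eta_ltd=0.0013, sigma=0.30, sigma_ltd=0.125)),
    C("PLp", "BApv", 0.5),
    C("BApv", "BAp4", 0.3),
    # BA -> IL -> BA extinction loop
    C("PLp", "ILp", 3.0),
    C("BAp2", "ILp", 1.5, dict(rule="LTP_LTD", eta=0.7, eta_ltd=25.0, sigma=0.05, sigma_ltd=0.05, M=12.0, ltd_hold_s=0.25)),
    C("BAp2", "ILs", 6.0),
    C("ILs", "ILpv", 1.4),
    C("ILpv", "ILp", 3.2),
    C("ILp", "BAp3", 5.0),
    C("ILp", "ITC", 3.0),
    C("BAp3", "ITC", 3.0, dict(rule="LTP", eta=0.01, sigma=0.10)),
    C("ITC", "BAp4", 6.8),
    # output stage; both BA->CeM projections are DSE-sensitive
    C("BAp4", "CeM", 2.0, dict(rule="DSE", eta=0.00035, trigger_s=10.0)),
    C("BAp5", "CeM", 7.1, dict(rule="DSE", eta=0.00035, trigger_s=10.0)),
]

DESCRIPTION = (
    "Calibrated default amygdala-prefrontal fear circuit: 9 excitatory and "
    "12 inhibitory leaky units, CS/US step inputs of drive 100."
)


def circuit_document() -> dict:
    return {
        "version": 1,
        "description": DESCRIPTION,
        "external_inputs": {"CS": 100.0, "US": 100.0},
        "dsi_theta": 0.15,
        "units": UNITS,
        "connections": CONNECTIONS,
    }


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    default_out = Path(__file__).resolve().parents[1] / "src" / "fearcircuit" / "data" / "default_circuit.yaml"
    ap.add_argument("--out", type=Path, default=default_out)
    args = ap.parse_args()
    args.out.parent.mkdir(parents=True, exist_ok=True)
    with open(args.out, "w") as fh:
        fh.write("# Generated by scripts/calibrate.py -- do not edit by hand.\n")
        yaml.safe_dump(circuit_document(), fh, sort_keys=False)
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
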
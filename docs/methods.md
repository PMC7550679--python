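# Methods

## The model

`fearcircuit` simulates the amygdala–prefrontal circuit of cued fear
conditioning with firing-rate leaky units. Each unit stands for a
population of neurons of one type in one region (e.g. "the LA pyramidal
cells that respond to the CS only") and carries four constants: a
membrane time constant τ, a tonic drive T, a firing threshold ψ and a
maximum rate φ. The membrane potential is remapped from the biological
(−70, +30) mV range onto U ∈ [0, π], linearly, so that the leak pulls
every unit toward a resting value of zero:

    τ · dU/dt = −U + T + I,      I = Σᵢ sᵢ wᵢ Aᵢ,      A = φ·[tanh(U − ψ)]⁺

with `sᵢ = ±1` for excitatory/inhibitory presynaptic units, integrated
by the forward Euler method at dt = 10 ms. dt exceeds the fastest τ
(7.7 ms); the Euler factor stays below one in magnitude, so the scheme
is stable (leaky units are low-pass filters), and the test suite checks
that the unit taxonomy is unchanged at dt = 1 ms. Updates are
synchronous and strictly ordered within a step — inputs from the
previous activations, potential update, transfer, output clamps,
plasticity — so every run is deterministic and bit-reproducible.

The CS (tone) and US (shock) are step inputs of drive 100 entering the
lateral amygdala; the model's output is the activation of CeM, read as
freezing. Twenty-one units (9 excitatory pyramidal populations, 12
inhibitory) implement three routes from input to output: a *persistent*
route (LA→BA→CeM directly via BAp5, and the LA→CeL gate in which
tonically firing CeL-OFF cells brake CeM until CeL-ON silences them), a
*fear* route (LA→BA→PL→BA→CeM via BAp4), and an *extinction* route
(BA→IL→BA→ITC, whose intercalated cells shut the fear route down).

### Unit-count bookkeeping

The source literature names 22 populations while counting "9 excitatory
and 12 inhibitory". This package resolves the arithmetic by counting
CeM — whose projection neurons are GABAergic — as the twelfth
inhibitory unit, and by implementing the US→IL relay ("ILu") as a
direct external connection `US->ILpv` rather than as a 22nd unit. The
IL-lesion experiment zeroes that connection together with the ILp/ILpv
outputs, and the sensitivity scan exposes its weight as an ordinary
parameter.

## Plasticity

Three rule families act once per integration step; rate constants in
the config are defined at the 10-ms reference step and scaled linearly
with dt.

**Hebbian LTP/LTD** on the five glutamatergic learning synapses:

    ΔW = [ η·(M − W)·(Post − σ·φ)⁺  −  η_LTD·W·(σ_LTD·φ − Post)⁺ ] · Pre

Potentiation saturates at the ceiling M (three times the initial weight
unless a config overrides it) exactly as in the classical gated rule;
the depression branch is weight-proportional — the same multiplicative
form as the endocannabinoid rule below — rather than ceiling-gated.
This is a deliberate design choice: a (M − W)-scaled depression can
never depotentiate a saturated synapse (ΔW → 0 as W → M) and otherwise
produces runaway exponential growth of (M − W) that cannot land at a
mid-range weight over a fixed protocol, whereas multiplicative decay is
self-decelerating. With η_LTD = η and σ_LTD = σ the rule's LTP side is
the classical form unchanged. Connections the literature reports as
potentiation-only (the CS pathway onto LAp1, LAp2→CeL-ON, BAp3→ITC)
clip negative deltas.

One connection, BAp2→ILp, additionally carries an *LTD hold* of 0.25 s:
its depression engages only after the (presynaptically active,
postsynaptically silenced) pattern has persisted continuously for the
hold time. The hold mirrors the sustained-depolarization logic of the
endocannabinoid trigger and is needed because the ~100-ms feedforward
onset transient at every CS edge produces the same instantaneous
pattern ~40 times per extinction session; without the hold no rate
constant can reconcile session-long stability with the depotentiation
that a single 0.5-s unpaired US must produce at reinstatement.

**Endocannabinoid DSI/DSE** on BAcck→BAp2 (inhibitory target) and
BAp4→CeM, BAp5→CeM (excitatory targets):

    ΔW = −η·W·Pre        once the postsynaptic unit has been
                         depolarized continuously for 10 s

The depolarization threshold θ is 15% of the postsynaptic maximum rate
(the source never defines "depolarized"; θ is exposed in the config as
`dsi_theta`), accumulation is continuous with reset on sub-threshold
dips, and one timer per postsynaptic unit is shared by all its
endocannabinoid-sensitive afferents (the ligand is released by the
postsynaptic cell). DSI/DSE changes are transient: at every session
boundary the affected weights return to their pre-session values.

## Protocols and measurements

The standard paradigm is four sessions: conditioning (three 20-s CS,
each with a 0.5-s US in its final half second), two extinction sessions
(twenty 20-s CS each), and reinstatement (CS, unpaired US, CS).
Inter-trial intervals are not stated in the literature; the default is
5 s, far beyond the slowest τ (35.6 ms), so every unit returns to its
tonic fixed point between trials. The network settles for 1 s before
each run and all units start at their tonic fixed points.

A unit's *CS response* is its peak rate during a CS, excluding any
concurrent US and the first 2 s of the cue: the onset transient of the
feedforward sweep is an artifact of the synchronous update order, and
freezing is scored over the bulk of the cue. Probe CSs are delivered
with plasticity frozen on a clone of the simulation, so measurement
never alters learning. The post-conditioning probe models a test on a
later day (transient DSI/DSE changes forgotten); the post-extinction
probe is taken in the session-end state (transients still engaged),
which is the state in which fear/extinction/persistent cells are scored
experimentally — at a next-day probe the BAp5 residual would sit above
the 20% activity criterion and misclassify CeM.

Synaptic changes are reported two ways: raw weights, and an evoked-PSP
measurement that mimics the acute-slice protocol — a 30-ms presynaptic
pulse whose amplitude is calibrated by bisection on the naive circuit
to evoke just under 10 mV, then re-applied identically after learning.
The probe runs on an isolated pre/post pair so network feedback cannot
contaminate the synaptic measure, and inhibitory synapses are probed
from a depolarized holding potential (mid-range U), as real IPSPs are.

## Operational criteria

Three global thresholds decide every verdict: a unit is *active* above
20% of its φ; CeM *expresses fear* above 70% of its φ; LTP/LTD *has
happened* when the evoked PSP changes by at least 20%. Extinction
*speed* (the IL-stimulation and PL→IL experiments) is the index of the
first extinction CS whose CeM response falls below the fear criterion.
"Weaker conditioning" in the US-substitution experiment means a probe
response at least 10 percentage points of φ below the real-US control
while still above the activity criterion; "full rescue" means within 10
points of the control. The within-session-sparing checks of the IL
lesion and BA endocannabinoid blockade ask that CeM is below the fear
criterion by the last CS of session 1 (extinction *achieved*), since
those findings concern extinction occurring despite the manipulation,
with the deficit appearing between sessions.

## Calibration

Only a handful of constants are fixed by the main text of the
literature: the 0.7 basket-cell weights, the 7.0/5.0/3.0 LA→BA
fan-out, stimulus drive 100, the 3×-initial ceiling, the 10-s trigger,
dt = 10 ms, τ ∈ [7.7, 35.6] ms, and tonic drives proportional to basal
rates of 0.3/1.3/5.3 Hz (pyramidal/interneuron/parvalbumin, with the
cholecystokinin basket cells given parvalbumin-like properties and the
tonically firing CeL-OFF brake given its own strong drive). Everything
else — thresholds, maximum rates, the remaining weights and learning
rates — is this package's calibration, produced by the incremental
manual search recorded in `scripts/calibrate.py` and audited by
`scripts/refine.py`, with the experiment registry as the objective.

One scale choice deserves note: with potentials confined to [0, π] and
synaptic weights as large as 7.0, unit activations must be of order
0.1, so φ is stored in model rate units of 100 Hz (a 40-Hz pyramidal
population has φ = 0.40). All criteria are fractions of φ, so the
choice cancels everywhere except in the absolute weight scale, which
the printed weights pin down.

On the shipped calibration, 23 of the 25 registered experiments pass.
The two exceptions are structural consequences of the published rule
set rather than calibration failures, and both are visible in the
verdict table:

* *BAp2→ILp stability across conditioning.* The reinstatement
  hypothesis requires the unpaired US to depotentiate BAp2→ILp via the
  (BAp2 active, ILp US-silenced) pattern; the three conditioning USs
  produce the identical pattern with three times the exposure, so
  stability across conditioning and depotentiation at reinstatement are
  jointly unsatisfiable for any rate constants. The calibration lets
  the conditioning USs strip the connection — which is also what gives
  the US-substitution experiment its "weaker conditioning" contrast and
  its rescue — and the conditioning-stability sub-check for this one
  connection fails.
* *Early-extinction slowing under PL→IL silencing.* Early session-1
  extinction is carried by CeM DSE (which is what lets the CeM-blockade
  experiment delay it and the IL manipulations spare it); with BAp4's
  single excitatory afferent and the saturating transfer function, the
  late-arriving ITC inhibition cannot shave the early extinction curve,
  so removing the PL→IL drive leaves early extinction unchanged.

## Sensitivity analysis

`oat_scan` perturbs one parameter at a time in ±5% steps, holding the
rest at reference, and records the first value at which any registered
experiment is lost, with the upward sweep capped at +1000% and
parameters surviving to −100% flagged as removable. The full scan over
all weights and learning rates re-evaluates the battery at every step
and runs for hours; the `--fast` mode (25% steps, the three-experiment
behavioral subset) is the variant exercised in CI-scale runs.

## What the simulations do and do not show

All inputs are generated internally as noiseless step stimuli and the
units are deterministic population rates, so the model reproduces
qualitative circuit phenomena — acquisition curves, within- vs
between-session extinction, residual freezing, reinstatement, and the
lesion/blockade dissociations — not trial-to-trial variability, animal
heterogeneity, or quantitative freezing percentages. Contextual
conditioning, renewal, spontaneous recovery, reconsolidation and
neuromodulation are outside the model's scope. Passing the registry
means the architecture and calibration jointly account for the targeted
findings under these idealized conditions; it does not certify
parameter values against unpublished recordings.
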
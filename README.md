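# fearcircuit

A firing-rate model of the amygdala–prefrontal circuit underlying cued
fear conditioning, extinction, and reinstatement — for computational
neuroscientists who want a compact, fully deterministic circuit model
that reproduces the classic behavioral and synaptic findings of the
fear-learning literature and supports in-silico lesion, inactivation,
optogenetic-style and endocannabinoid-blockade experiments.

## The model

Twenty-one leaky firing-rate units (9 excitatory pyramidal populations,
12 inhibitory) represent the lateral (LA) and basal (BA) amygdala, the
lateral and medial central amygdala (CeL, CeM), the intercalated cells
(ITC), and the prelimbic (PL) and infralimbic (IL) medial prefrontal
cortex. Each unit integrates

    τ·dU/dt = −U + T + Σᵢ sᵢ·wᵢ·Aᵢ,     A = φ·[tanh(U − ψ)]⁺

by forward Euler at dt = 10 ms, with the membrane potential U remapped
from (−70, +30) mV onto [0, π]. The CS (tone) and US (shock) are step
inputs of drive 100 into LA; freezing is read out as the activation of
CeM. Three plasticity rules act on eight synapses at every step: a
Hebbian LTP/LTD rule ΔW = η·(M−W)·(Post−σφ)·Pre with a weight ceiling
M = 3× the initial weight (the depression branch is
weight-proportional, −η_LTD·W·(σ_LTD·φ−Post)⁺·Pre, so saturated
synapses stay depotentiable), and transient endocannabinoid DSI/DSE,
ΔW = −η·W·Pre, engaged after 10 s of sustained postsynaptic
depolarization and forgotten at every session boundary.

Fear expression requires two gates to open at once: the CS pathway onto
LA must be potentiated (LTP of CS→LAp1) *and* the tonic CeL-OFF brake
on CeM must be released (LTP of LAp2→CeL-ON). Extinction is two
processes: DSE at the BA→CeM synapses carries the within-session
decline, while DSI in BA disinhibits the IL-projecting BA cells, whose
LTP onto IL recruits the ITC and shuts the fear pathway down between
sessions. A single unpaired US silences IL (via its parvalbumin cells),
depotentiates BA→IL and re-potentiates PL→BA: reinstatement.

Details, calibration choices and known limitations are in
[docs/methods.md](docs/methods.md).

## A worked example

```python
import fearcircuit as fc

model = fc.build_default_circuit()
sim = fc.Simulation(model)

trace = sim.run(fc.make_conditioning())      # 3 x (20 s CS + 0.5 s US)
phi = model.unit("CeM").phi
print("CeM per conditioning CS (% of max):",
      [round(float(100 * p / phi), 1) for p in trace.cs_peaks("CeM")])

sim.reset_transient()                        # next day: DSI/DSE forgotten
ext = sim.run(fc.make_extinction())          # 20 CS, no US
print("CeM across extinction:",
      [round(float(100 * p / phi), 1) for p in ext.cs_peaks("CeM")][::4])
```

prints

```
CeM per conditioning CS (% of max): [0.0, 85.3, 86.8]
CeM across extinction: [90.9, 79.3, 62.7, 33.7, 24.7]
```

— no fear response at the first CS, acquisition by the second pairing,
and a within-session decline of the conditioned response across the
extinction session (every fifth trial shown). The fear criterion is 70%
of CeM's maximum rate; a unit counts as active above 20% of its own
maximum.

The same machinery runs from the shell:

```
fearcircuit simulate --out runs/standard          # 4-session paradigm, trace + manifest
fearcircuit experiments --out runs/registry       # the 25-experiment battery
fearcircuit classify                              # fear/extinction/persistent taxonomy
fearcircuit psp-probe --connection CS->LAp1       # slice-style evoked PSP, before vs after
fearcircuit sensitivity --fast --out runs/oat     # one-factor-at-a-time scan
```

`fearcircuit experiments` replays, among others: PL inactivation during
conditioning (expression blunted, learning intact), optogenetic
de-/re-potentiation of the CS pathway toggling fear off and on, LA and
CeL inactivation abolishing learning, US-substitution by LA
depolarization (weaker conditioning, rescued by silencing the
IL-projecting BA cells), global/CeM/BA endocannabinoid blockades
dissociating within- from between-session extinction, and IL lesion or
stimulation slowing or speeding extinction.

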
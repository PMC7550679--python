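# Generated by scripts/calibrate.py -- do not edit by hand.
version: 1
description: 'Calibrated default amygdala-prefrontal fear circuit: 9 excitatory and
  12 inhibitory leaky units, CS/US step inputs of drive 100.'
external_inputs:
  CS: 100.0
  US: 100.0
dsi_theta: 0.15
units:
- name: LAp1
  psi: 0.63
  tau: 24.4
  tonic: 0.045
  phi: 0.4
  polarity: excitatory
  class: pyramidal
- name: LAp2
  psi: 0.63
  tau: 24.4
  tonic: 0.045
  phi: 0.4
  polarity: excitatory
  class: pyramidal
- name: LApv
  tau: 7.7
  tonic: 0.795
  phi: 1.2
  psi: 0.31
  polarity: inhibitory
  class: parvalbumin
- name: LAvip
  tau: 14.0
  tonic: 0.195
  phi: 0.6
  psi: 0.4
  polarity: inhibitory
  class: vip
- name: BAp1
  psi: 0.63
  tau: 24.4
  tonic: 0.045
  phi: 0.4
  polarity: excitatory
  class: pyramidal
- name: BAp2
  psi: 0.63
  tau: 24.4
  tonic: 0.045
  phi: 0.4
  polarity: excitatory
  class: pyramidal
- name: BAp3
  psi: 0.5
  tau: 24.4
  tonic: 0.045
  phi: 0.4
  polarity: excitatory
  class: pyramidal
- name: BAp4
  psi: 0.5
  tau: 24.4
  tonic: 0.045
  phi: 0.4
  polarity: excitatory
  class: pyramidal
- name: BAp5
  psi: 0.45
  tau: 24.4
  tonic: 0.045
  phi: 0.4
  polarity: excitatory
  class: pyramidal
- name: BAcck
  tau: 9.0
  tonic: 0.795
  phi: 1.2
  psi: 0.31
  polarity: inhibitory
  class: cck
- name: BApv
  tau: 7.7
  tonic: 0.795
  phi: 1.2
  psi: 0.31
  polarity: inhibitory
  class: parvalbumin
- name: CeL-ON
  tau: 15.0
  tonic: 0.195
  phi: 0.6
  psi: 0.4
  polarity: inhibitory
  class: other
- name: CeL-OFF
  tau: 15.0
  tonic: 1.2
  phi: 0.6
  psi: 0.4
  polarity: inhibitory
  class: other
- name: CeM
  tau: 20.0
  tonic: 0.195
  phi: 0.4
  psi: 0.4
  polarity: inhibitory
  class: other
- name: ITC
  tau: 13.0
  tonic: 0.195
  phi: 0.6
  psi: 0.4
  polarity: inhibitory
  class: other
- name: PLp
  tau: 28.0
  tonic: 0.045
  phi: 0.4
  psi: 0.63
  polarity: excitatory
  class: pyramidal
- name: PLpv
  tau: 7.7
  tonic: 0.795
  phi: 1.2
  psi: 0.31
  polarity: inhibitory
  class: parvalbumin
- name: PLs
  tau: 16.0
  tonic: 0.195
  phi: 0.6
  psi: 0.4
  polarity: inhibitory
  class: somatostatin
- name: ILp
  tau: 28.0
  tonic: 0.045
  phi: 0.4
  psi: 0.5
  polarity: excitatory
  class: pyramidal
- name: ILpv
  tau: 7.7
  tonic: 0.795
  phi: 1.2
  psi: 0.31
  polarity: inhibitory
  class: parvalbumin
- name: ILs
  tau: 16.0
  tonic: 0.195
  phi: 0.6
  psi: 0.4
  polarity: inhibitory
  class: somatostatin
connections:
- pre: CS
  post: LAp1
  weight: 0.0054
  plasticity:
    rule: LTP
    eta: 0.0008
    sigma: 0.25
- pre: CS
  post: LAp2
  weight: 0.0163
- pre: US
  post: LAp1
  weight: 0.02
- pre: US
  post: LAvip
  weight: 0.01
- pre: US
  post: ILpv
  weight: 0.03
- pre: LAvip
  post: LApv
  weight: 1.5
- pre: LApv
  post: LAp1
  weight: 0.5
- pre: LApv
  post: LAp2
  weight: 0.5
- pre: LAp1
  post: BAp1
  weight: 7.0
- pre: LAp1
  post: BAp2
  weight: 5.0
- pre: LAp1
  post: BAp5
  weight: 3.0
- pre: LAp1
  post: BAcck
  weight: 0.5
- pre: LAp2
  post: CeL-ON
  weight: 1.2
  plasticity:
    rule: LTP
    eta: 0.02
    sigma: 0.05
- pre: CeL-ON
  post: CeL-OFF
  weight: 6.0
- pre: CeL-OFF
  post: CeM
  weight: 6.0
- pre: BAcck
  post: BAp1
  weight: 0.7
- pre: BAcck
  post: BAp2
  weight: 0.7
  plasticity:
    rule: DSI
    eta: 3.0e-05
    trigger_s: 10.0
- pre: BAp1
  post: PLs
  weight: 4.0
- pre: BAp1
  post: PLp
  weight: 5.0
- pre: PLs
  post: PLpv
  weight: 4.0
- pre: PLpv
  post: PLp
  weight: 0.5
- pre: PLp
  post: BAp4
  weight: 5.0
  plasticity:
    rule: LTP_LTD
    eta: 0.0025
    eta_ltd: 0.0013
    sigma: 0.3
    sigma_ltd: 0.125
- pre: PLp
  post: BApv
  weight: 0.5
- pre: BApv
  post: BAp4
  weight: 0.3
- pre: PLp
  post: ILp
  weight: 3.0
- pre: BAp2
  post: ILp
  weight: 1.5
  plasticity:
    rule: LTP_LTD
    eta: 0.7
    eta_ltd: 25.0
    sigma: 0.05
    sigma_ltd: 0.05
    M: 12.0
    ltd_hold_s: 0.25
- pre: BAp2
  post: ILs
  weight: 6.0
- pre: ILs
  post: ILpv
  weight: 1.4
- pre: ILpv
  post: ILp
  weight: 3.2
- pre: ILp
  post: BAp3
  weight: 5.0
- pre: ILp
  post: ITC
  weight: 3.0
- pre: BAp3
  post: ITC
  weight: 3.0
  plasticity:
    rule: LTP
    eta: 0.01
    sigma: 0.1
- pre: ITC
  post: BAp4
  weight: 6.8
- pre: BAp4
  post: CeM
  weight: 2.0
  plasticity:
    rule: DSE
    eta: 0.00035
    trigger_s: 10.0
- pre: BAp5
  post: CeM
  weight: 7.1
  plasticity:
    rule: DSE
    eta: 0.00035
    trigger_s: 10.0
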
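# Amine-terminated SAM archetype: strong electrostatic initial attachment
# (largest initial drop) followed by partial detachment; dissipative
# inertial loading.
category: inertial_dissipative
surface_label: NH2
bond_freq_hz: 1.2e+8
gamma: 0.2
kinetics:
  initial_amp_hz: -22.0
  initial_tau_h: 0.025
  accum_amp_hz: -4.0
  accum_tau_h: 1.0
  overshoot_recovery: 0.35
  recovery_tau_h: 4.0
  rinse_recovery: 0.03
  rinse_tau_h: 0.1
  dd_fast_ppm: 2.0
  dd_fast_tau_h: 0.025
  dd_slow_ppm: 6.5
  dd_slow_tau_h: 0.5
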
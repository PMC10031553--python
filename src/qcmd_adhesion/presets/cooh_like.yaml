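# Carboxy-terminated SAM archetype: overshoot-recovery kinetics (f shift
# relaxes toward positive after the initial maximum while D stays flat),
# the most dissipative of the inertial surfaces.
category: inertial_dissipative
surface_label: COOH
bond_freq_hz: 1.2e+8
gamma: 0.4
kinetics:
  initial_amp_hz: -18.0
  initial_tau_h: 0.025
  accum_amp_hz: -6.0
  accum_tau_h: 0.7
  overshoot_recovery: 0.55
  recovery_tau_h: 5.0
  rinse_recovery: 0.03
  rinse_tau_h: 0.1
  dd_fast_ppm: 2.0
  dd_fast_tau_h: 0.025
  dd_slow_ppm: 8.0
  dd_slow_tau_h: 0.5
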
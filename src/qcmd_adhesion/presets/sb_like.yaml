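# Sulfobetaine-terminated SAM archetype: sparse but dissipative attachment,
# fully elastic loading -- the bond resonance sits below the lowest measured
# overtone frequency, so every overtone registers a positive shift.
category: elastic_full
surface_label: SB
bond_freq_hz: 1.0e+7
gamma: 0.15
kinetics:
  initial_amp_hz: 2.4
  initial_tau_h: 0.03
  accum_amp_hz: 0.8
  accum_tau_h: 2.0
  rinse_recovery: 0.02
  rinse_tau_h: 0.1
  dd_fast_ppm: 1.5
  dd_fast_tau_h: 0.025
  dd_slow_ppm: 6.5
  dd_slow_tau_h: 0.5
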
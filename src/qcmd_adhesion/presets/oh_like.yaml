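# Hydroxy-terminated SAM archetype: mixed loading with the bond resonance
# between the n = 11 and n = 13 overtone frequencies of a 5 MHz sensor,
# so shifts are negative through n = 11 and positive at n = 13.
category: elastic_mixed
surface_label: OH
bond_freq_hz: 6.0e+7
gamma: 0.4
kinetics:
  initial_amp_hz: -10.0
  initial_tau_h: 0.03
  accum_amp_hz: -5.0
  accum_tau_h: 2.0
  rinse_recovery: 0.02
  rinse_tau_h: 0.1
  dd_fast_ppm: 1.0
  dd_fast_tau_h: 0.025
  dd_slow_ppm: 6.0
  dd_slow_tau_h: 0.5
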
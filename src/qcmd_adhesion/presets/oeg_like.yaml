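# Oligo(ethylene glycol)-terminated SAM archetype: cells cling through
# appendages across the interfacial water barrier.  Bond resonance between
# the n = 3 and n = 5 overtone frequencies: negative shift at n = 3,
# positive at n = 5 and above (zero crossing in the (3, 5) bracket).
category: elastic_mixed
surface_label: OEG
bond_freq_hz: 2.0e+7
gamma: 0.1
kinetics:
  initial_amp_hz: -4.0
  initial_tau_h: 0.03
  accum_amp_hz: -1.5
  accum_tau_h: 2.0
  rinse_recovery: 0.02
  rinse_tau_h: 0.1
  dd_fast_ppm: 1.0
  dd_fast_tau_h: 0.025
  dd_slow_ppm: 5.0
  dd_slow_tau_h: 0.5
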
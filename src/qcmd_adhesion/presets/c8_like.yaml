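# Hydrophobic methyl-terminated SAM archetype: dense rigid adlayer.
# Rapid initial drop, slow accumulation to a deep plateau, late "hook"
# detachment; bond resonance far above every measured overtone (pure
# inertial loading, all shifts negative) with a small loss tangent.
category: inertial_rigid
surface_label: C8
bond_freq_hz: 1.5e+8
gamma: 0.05
kinetics:
  initial_amp_hz: -12.0
  initial_tau_h: 0.025
  accum_amp_hz: -23.0
  accum_tau_h: 3.75
  overshoot_recovery: 0.0
  hook_onset_h: 45.0
  hook_amp_hz: 8.0
  hook_tau_h: 0.5
  rinse_recovery: 0.02
  rinse_tau_h: 0.1
  dd_fast_ppm: 2.0
  dd_fast_tau_h: 0.025
  dd_slow_ppm: 10.0
  dd_slow_tau_h: 0.5
  dd_hook_ppm: 1.5
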
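# Demo run configuration for the entrainment pipeline.
# Angles are radians in [-pi, pi); times in seconds; SOAs in milliseconds.
experiment:
  entrainment_frequency: 9.6   # Hz (IAF-like; 5.0 and 15.0 are the other studied rates)
  trial_duration: 6.25
  edge_margin: 0.8
  min_gap: 0.8
  n_phase_bins: 8
  n_surrogates: 2000           # demo profile; the full analysis uses 50000
  fdr_q: 0.05
  rng_seed: 7

observer:
  threshold: 100.0             # luminance (0-255) at 50% detection
  slope: 8.0                   # logistic steepness per log-luminance unit
  lapse_rate: 0.02
  depths: [0.50, 0.45, 0.42, 0.40, 0.38]   # peak-to-trough fraction m per position
  global_phase: -2.356         # -3pi/4, shared by positions away from the disc
  local_phase: -0.785          # -pi/4, position nearest the disc

run:
  n_subjects: 3
  targets_per_cell: 33
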
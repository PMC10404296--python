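# Demo run: 100×100-cell synthetic landscape (1 km² cells at 100 m),
# 300 plots under the reference measurement-error model.
scenario:
  grid_shape: [100, 100]
  n_plots: 300
  sampling_design: uniform
learners:
  fast: true
  tune: false
cv:
  k: 5
aggregation:
  mode: independent
  eq4_mode: corrected
seed: 0
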
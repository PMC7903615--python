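simulate:
  seed: 42
  n_genes: 60
  n_replicates: 3
  noise_log2_sd: 0.0
  peak_fold: 10.0
  timepoints_h: [0, 6, 12, 24, 72, 120, 168, 240]
  fibrosis_timepoints_h: [0, 72, 168, 240]
  class_proportions: {TRANSIENT: 0.1, SUSTAINED: 0.1, FLAT: 0.8}
  aliases: {G000001: Areg}
  overlap: {Areg: SUSTAINED}
screen:
  induction_fold: 2.0
  induction_timepoints_h: [12, 24]
  return_timepoint_h: 72
  return_band: 0.2
  sustained_fold: 2.0
  alpha: 0.01
  require_significance: true
  test_method: welch_t
  fibrosis_baseline: matched_control
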
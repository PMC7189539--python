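# Default configuration for the synthetic seated-pressure simulator and
# the downstream pipeline.  All effect sizes for the compensation classes
# are assumptions of the synthetic model, not measurements.

sample_rate: 50.0

population:
  # Blob geometry in grid units; row 0 = anterior (front) edge,
  # column 0 = sitter's left.  Left-side values are drawn from these
  # ranges; right-side partners mirror about column 15.5 with a small
  # asymmetry jitter.
  ischial_row: [19.0, 21.5]
  ischial_col_left: [9.5, 12.0]
  thigh_row: [8.0, 11.0]
  thigh_col_left: [8.5, 11.5]
  row_jitter: 0.5          # per-blob row asymmetry, grid units
  mirror_jitter: 0.5       # per-blob column asymmetry, grid units
  asymmetry_jitter: 0.05   # left/right amplitude & width asymmetry fraction
  ischial_amplitude: [48.0, 58.0]
  thigh_amplitude: [24.0, 30.0]
  ischial_width: [2.5, 2.9]
  thigh_width: [2.9, 3.3]
  weight_scale: [640.0, 660.0]

effects:
  ap_shift_max_rows: 6.0   # lean-forward: anterior blob translation at magnitude 1
  ml_shift_max_cols: 5.0   # trunk rotation: lateral blob translation at magnitude 1
  tlf_load_shift: 0.5      # ischial -> thigh load transfer fraction at magnitude 1
  tr_load_shift: 0.5       # ipsi -> contra pair load transfer fraction at magnitude 1
  se_unload: 0.4           # ipsilateral thigh amplitude reduction at magnitude 1
  se_jitter_sd: 0.2        # ipsilateral amplitude jitter SD at magnitude 1

reach_cycle:
  period_s: 4.0
  ap_amplitude_rows: 0.8
  ml_amplitude_cols: 0.8
  mixed_amplitude: 0.4

anisotropy_row: 1.3        # blob row sigma = width * this factor
load_tolerance: 0.02       # per-frame total load in weight_scale * (1 +/- tol)

noise:
  multiplicative_sd: 0.05
  additive_sd: 0.03        # sensor units; ~1% of a typical peak cell value
  dropout_prob: 0.005

trial:
  duration_s: 4.0
  magnitude_range: [0.4, 1.0]
  posture_sd_rows: 0.5     # per-trial whole-body offset SD, grid units
  posture_sd_cols: 0.5
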
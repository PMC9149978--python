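# Demo configuration for `pseudomr run-all`: a small phantom study.
seed: 7
phantom:
  shape: [96, 96]
  texture_correlation: 2.0
  ct_noise_sd: 10.0      # HU, per repeat
  ct_repeats: 9
  mr_noise_fraction: 0.01  # MR noise sd as a fraction of peak signal
segmentation:
  n_clusters: 3
  m: 2.0
  rule: brightest
  largest_component: true
fit:
  t2_saturation_correction: true
  t2_weighted: true
features:
  window_size: 5
  min_count: 6
mapping:
  mode: piecewise_linear
  fallback: nearest
synthesize:
  - {te: 10, tr: 500}     # T1-weighted
  - {te: 130, tr: 2000}   # T2-weighted
  - {te: 10, tr: 4000}    # proton-density-weighted
evaluate:
  normalization: none
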
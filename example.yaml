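seed: 7
generator:
  duration_s: 150
  n_rows: 4
  n_cols: 8
  truth:
    informative_channels: [1, 4, 8, 11, 15, 18, 22, 25, 29, 32]
    band_weights: {gamma2: 1.0, gamma3: 1.0, gamma4: 1.0}
    snr: 25.0
decode:
  train_s: 100
  test_s: 45
selection:
  sizes: [3, 6, 9, 12, 16, 32]
  incremental_sizes: [1, 2, 3, 4, 6, 8, 10, 12, 16, 32]
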
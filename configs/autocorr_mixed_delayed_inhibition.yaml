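# Response autocorrelation to a seeded synthetic naturalistic movie with
# mixed delayed-inhibition feedback.
grid:
  n_spatial: 64
  extent: 12.566370614359172
  n_time: 512
  duration: 2000.0
circuit:
  feedback:
    - {weight: 0.3, a: 0.1, delta: 5.0, tau: 5.0}
    - {weight: -0.6, a: 0.9, delta: 30.0, tau: 5.0}
autocorr:
  window: 40
  max_lag: 50
  spatial_exponent: 2.0
  temporal_correlation: 0.9
seed: 1234
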
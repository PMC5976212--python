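# Temporal frequency tuning at |k| = 1 rad/deg for mixed feedback with
# short-delay excitation (5 ms) and long-delay inhibition (30 ms).
grid:
  n_spatial: 64
  extent: 12.566370614359172
  n_time: 256
  duration: 1000.0
circuit:
  feedback:
    - {weight: 0.3, a: 0.1, delta: 5.0, tau: 5.0}
    - {weight: -0.6, a: 0.9, delta: 30.0, tau: 5.0}
tuning:
  kind: temporal
  k: 1.0
  frequencies: [0.0, 0.019, 0.038, 0.057, 0.075, 0.094, 0.113, 0.132, 0.151,
                0.17, 0.189, 0.208, 0.226, 0.245, 0.264, 0.283, 0.302, 0.321,
                0.34, 0.358, 0.377]
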
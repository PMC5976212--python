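# Patch-grating area-response curve and suppression index without cortical
# feedback, wavenumber 1 rad/deg (grid extent 8*pi puts it exactly on the
# DFT frequencies).
grid:
  n_spatial: 512
  extent: 25.132741228718345
  n_time: 8
  duration: 100.0
circuit:
  feedback: []
area_response:
  kind: patch_grating
  k: 1.0
  diameters: [0.25, 0.5, 0.75, 1.0, 1.25, 1.5, 1.75, 2.0, 2.5, 3.0, 3.5,
              4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0, 11.0, 12.0]
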
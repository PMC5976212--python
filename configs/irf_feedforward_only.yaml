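# Impulse-response measures (biphasic index, peak latency) for the circuit
# with feedforward excitation from retinal ganglion cells only.
grid:
  n_spatial: 128
  extent: 6.4
  n_time: 1024
  duration: 500.0
circuit:
  ff_inhibition: null
  feedback: []
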
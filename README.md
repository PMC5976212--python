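# edog — Fourier-domain firing-rate model of the dLGN circuit

`edog` simulates visual responses of relay cells in the dorsal lateral
geniculate nucleus (dLGN), the thalamic stage between retina and visual
cortex.  It implements the extended difference-of-Gaussians (eDOG) model: a
linear firing-rate description of the circuit comprising retinal ganglion
cell input, indirect feedforward inhibition via intrageniculate
interneurons, and the thalamo-cortico-thalamic feedback loop in its
excitatory, inhibitory and mixed phase-reversed arrangements.  It is aimed
at computational and systems neuroscientists who want fast, closed-form
exploration of how corticothalamic feedback shapes spatial and temporal
relay-cell response properties.

## The model

The relay-cell impulse-response function is evaluated in Fourier space as a
single closed-form transfer function

```
             w_RG f̃_RG(k) h̃_RG(ω) + w_RIG f̃_RIG(k) h̃_RIG(ω)
W̃_R(k, ω) = ───────────────────────────────────────────────── · F̃(k) H̃(ω)
             1 − Σ_j w_j f̃_j(k) h̃_j(ω)
```

where every coupling is a separable kernel `K(r, t) = w f(r) h(t)` with a
normalized Gaussian spatial part `f(r; a)` and a delayed exponential
temporal part `h(t; Δ, τ)`; the retinal input has a difference-of-Gaussians
spatial part `F(r; A, a, B, b)` and a biphasic temporal part `H(t; τ, B)`.
The sum in the denominator runs over the net cortical feedback loop kernels
(one term for pure excitatory or inhibitory feedback, two for mixed
feedback).  Although the cortical populations are half-wave rectifying, the
phase-reversed ON/OFF arrangement cancels the rectification exactly, so the
relay-cell response stays linear and the response to *any* stimulus is

```
R(r, t) = F⁻¹{ W̃_R(k, ω) S̃(k, ω) }
```

— one 3-D FFT for movies, one 2-D FFT for static stimuli.  Stimuli include
full-field drifting gratings (analytic transform), circular patch gratings
and spots, flashing spots, arbitrary raster movies, and a seeded synthetic
naturalistic movie (1/f²-type spatial spectrum, AR(1) frame correlation).

On top of the response engine, `edog.measures` provides the standard
characterization toolbox: receptive-field size / center excitation /
surround inhibition, area-response curves with suppression index
`α_s = (R_max − R_plateau)/R_max` and optimal size, spatial and temporal
frequency tuning, center/surround response-reduction percentage, biphasic
index `I_BP` and peak latency `t_peak` of the temporal impulse response,
and response autocorrelation for naturalistic movies.

## Worked example

```python
import numpy as np
from edog import (SpaceTimeGrid, no_feedback_circuit, mixed_feedback_circuit,
                  feedforward_only_circuit, spatiotemporal_irf)
from edog.measures import (area_response_curve, suppression_index,
                           optimal_size, temporal_irf_measures)

# patch-grating area-response curve at |k| = 1 rad/deg (static fast-loop path)
grid = SpaceTimeGrid(n_spatial=512, extent=8 * np.pi, n_time=8, duration=100.0)
diameters = np.linspace(0.25, 12.0, 48)
curve = area_response_curve(no_feedback_circuit(), grid, diameters,
                            kind="patch_grating", k_pg=1.0)
print(f"suppression index: {suppression_index(curve):.3f}")
print(f"optimal size:      {optimal_size(curve):.2f} deg")

fed = area_response_curve(mixed_feedback_circuit(1.0), grid, diameters,
                          kind="patch_grating", k_pg=1.0)
print(f"with mixed feedback: alpha_s = {suppression_index(fed):.3f}, "
      f"optimal size = {optimal_size(fed):.2f} deg")

# temporal impulse response, feedforward excitation only
tgrid = SpaceTimeGrid(n_spatial=128, extent=6.4, n_time=1024, duration=500.0)
field = spatiotemporal_irf(feedforward_only_circuit(), tgrid)
m = temporal_irf_measures(field[tgrid.center_index, tgrid.center_index, :], tgrid.dt)
print(f"i_bp = {m.i_bp:.3f}, t_peak = {m.t_peak:.1f} ms")
```

prints

```
suppression index: 0.376
optimal size:      1.72 deg
with mixed feedback: alpha_s = 0.517, optimal size = 1.57 deg
i_bp = 0.378, t_peak = 26.0 ms
```

Without feedback the relay cell shows moderate surround suppression
(α_s ≈ 0.38) with an optimal patch diameter of ≈ 1.7 deg.  Turning on the
mixed feedback configuration — narrow fast excitation plus broad delayed
inhibition — strengthens the suppression (α_s ≈ 0.52) and shrinks the
receptive-field center, while the feedforward-only temporal impulse
response is biphasic (I_BP ≈ 0.38) peaking ≈ 26 ms after the flash.

## Command line

The same analyses are available as subcommands over YAML configs (see
`configs/` for ready-made ones):

```
edog irf           --config configs/irf_feedforward_only.yaml --out out/irf
edog area-response --config configs/area_response_patch_no_feedback.yaml --out out/area
edog tuning        --config configs/tuning_temporal_mixed_delayed_inhibition.yaml --out out/tuning
edog autocorr      --config configs/autocorr_mixed_delayed_inhibition.yaml --out out/acf
```

Curves are written as CSV, fields as HDF5 with axis metadata, scalar
measures as JSON, and every run leaves a log with the config hash.

## docs

`docs/methods.md` describes the model assumptions, parameter defaults,
numerical conventions (Fourier signs, grids, interpolation and plateau
rules), the synthetic-movie generator, and known limitations.
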
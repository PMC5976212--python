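# Methods

## Model

The package evaluates the linear firing-rate response of dLGN relay cells
through a closed-form Fourier-space transfer function.  The circuit
comprises:

* **Retinal input `W_G`** — a descriptive impulse-response function,
  difference-of-Gaussians (DOG) in space and biphasic in time.  Its weight
  is fixed at 1 (it sets the response scale).
* **Feedforward excitation `K_RG`** — direct retinogeniculate coupling,
  narrow Gaussian in space, delayed exponential in time, weight > 0.
* **Feedforward inhibition `K_RIG`** — the indirect
  ganglion → interneuron → relay pathway, broader Gaussian, small delay,
  weight < 0.  Optional.
* **Cortical feedback** — the net thalamo-cortico-thalamic loop
  (relay → cortex → relay).  The per-orientation cortical populations sum
  to an essentially circularly symmetric net loop kernel, so each feedback
  arrangement is represented by one (excitatory or inhibitory) or two
  (mixed) circularly symmetric separable kernels appearing in the
  denominator `1 − Σ w f̃ h̃` of the transfer function.

The cortical cells are half-wave rectifiers, but because the OFF pathway
mirrors the ON pathway with a phase-reversed (cross-symmetry) feedback
arrangement, the identity `H[x] − H[−x] = x` removes the rectification
from the relay-cell equation; no nonlinearity appears at runtime.  Relay
responses are linear firing-rate *deviations* and may be negative; no
geniculate rectification is applied.  Response units are arbitrary — every
shipped measure is a ratio or an argmax position and is unit-free.

### Assumptions

* linearity of all couplings (tonic-mode responses);
* ON/OFF symmetry (only the ON pathway is simulated);
* space-time separable kernels, circularly symmetric spatial parts;
* spatially homogeneous layers (retinotopy → convolution structure);
* periodic boundary conditions inherited from the FFT.

## Default parameters

| Kernel | weight | spatial | temporal |
| --- | --- | --- | --- |
| `W_G` | 1 | DOG: A=1, a=0.62°, B=0.85, b=1.26° | biphasic: τ=42.5 ms, B=0.38 |
| `K_RG` | 1.0 | Gaussian a=0.1° | exp: Δ=0 ms, τ=5 ms |
| `K_RIG` | −0.5 | Gaussian a=0.3° | exp: Δ=3 ms, τ=5 ms |
| feedback (excitatory) | 0.5 | Gaussian a=0.83° | exp: Δ=5–30 ms, τ=5 ms |
| feedback (inhibitory) | −0.5 | Gaussian a=0.83° | exp: Δ=5–30 ms, τ=5 ms |
| feedback (mixed, ex + in) | 0.3 / −0.6 | Gaussian a=0.1° / 0.9° | exp: Δ=5–30 ms, τ=5 ms |

Width parameters are in degrees of visual angle, temporal parameters in
ms.  The coupling time constant is kept at 5 ms throughout; the feedback
delays Δ are the interesting degrees of freedom (the mixed-feedback
factory defaults to the delayed-inhibition arrangement Δ_ex = 5 ms,
Δ_in = 30 ms, the configuration of principal scientific interest).  The
`mixed_feedback_circuit(weight_factor)` scales both feedback weights
jointly for weight sweeps.

A note on internal consistency of this parameter set: with `W_G` and
`K_RG` as listed, the temporal impulse response of the
feedforward-excitation-only circuit has, analytically, a peak latency of
26.0 ms and a biphasic index of 0.378 (the convolution of the biphasic
retinal filter with a 5-ms exponential barely attenuates the second
phase).  These are the values the package computes and tests against its
own continuous-time quadrature oracle.

## Fourier conventions

Library-wide: `W̃(k, ω) = ∬ W(r, t) e^{−i(k·r − ωt)} d²r dt` — note the
*opposite* temporal sign.  With this choice a drifting plane wave
`cos(k_g·r − ω_g t)` probes the transfer function exactly at
`(k_g, ω_g)`, and the center-neuron response amplitude to a unit-contrast
aligned grating is `|W̃_R(k_g, ω_g)|`.  Closed forms under this
convention:

* Gaussian: `f̃(k) = e^{−a²k²/4}`;
* DOG: `F̃(k) = A e^{−a²k²/4} − B e^{−b²k²/4}` (zero-frequency value A − B);
* delayed exponential: `h̃(ω) = e^{iωΔ}/(1 − iωτ)` (exactly 1 at ω = 0);
* biphasic: `H̃(ω) = (π/τ)(1 + e^{iωτ})(1 − B e^{iωτ})/((π/τ)² − ω²)`,
  with the removable singularities at ω = ±π/τ replaced by their analytic
  limits `±iτ(1 + B)/2` inside a 1e-8-relative neighborhood.

All closed forms are verified against independent dense-DFT oracles in the
test suite (1e-4 absolute or better; the delayed exponential's jump is
sampled at its Fourier midpoint value in the oracle).

## Grids and numerics

`SpaceTimeGrid(n_spatial, extent, n_time, duration)` owns all sampling.
The constructor default (128 points over 10°, 512 samples over 1000 ms)
resolves the default kernels; for the narrow 0.1° kernels the resolution
rule dx ≤ a_min/2 asks for dx ≤ 0.05°, and a warning is emitted whenever
a grid under-resolves a circuit.  Analyses in the examples, tests and the
acceptance script pick grids per task:

* temporal impulse-response measures: 128 points over 6.4° (dx = 0.05°)
  and 1024 samples over 500 ms (dt ≈ 0.49 ms);
* static patch-grating analyses: 512 points over 8π ≈ 25.1° (dx ≈ 0.049°),
  chosen so that the measurement wavenumbers 0.25 and 1.0 rad/deg are
  exact DFT frequencies;
* movie decorrelation analyses: 64 points over 4π° with 256–512 frames.

Further numerical policies:

* **Stability.** The loop-gain denominator `1 − Σ w f̃ h̃` is monitored at
  every evaluation; |den| < 1e-6 raises `CircuitInstabilityError` naming
  the offending (k, ω), and 1e-6–0.05 warns.  (The no-feedback denominator
  is identically 1; a unit-weight narrow excitatory feedback with zero
  delay is the canonical divergent case, at k = ω = 0.)
* **Causality / wrap-around.** The inverse FFT lives on t ∈ [0, duration);
  the grid duration should exceed twice the kernel temporal support, and
  late-time leakage above 1e-6 of the peak triggers a warning.  Residual
  leakage stems from spectral aliasing of the kernels' non-smooth points
  and decreases quadratically with dt.
* **Static path.** Static stimuli (and slowly drifting patch gratings, in
  the fast-loop approximation) use `W̃_R(k, 0)` with all coupling
  `h̃(0) = 1`; the retinal constant `H̃(0) = (2τ/π)(1 − B)` is kept
  explicitly so static and dynamic paths agree exactly at ω = 0.  The
  drifting-patch response scalar is the static-path value at cosine phase
  zero (patch concentric with the analyzed neuron, cosine maximal at its
  center); the alternative — the modulation amplitude — differs only by a
  k-independent factor for the sizes probed here.
* **Disc masks.** A pixel belongs to a spot iff its center lies within
  d/2 of the patch center; no anti-aliasing, matching the sharp-edged
  stimulus definition.
* **Interpolation.** Zero crossings: linear between bracketing radial
  samples along +x.  All argmax refinements: 3-point quadratic, ties
  toward the smaller argument, falling back to the raw sample at domain
  boundaries or for non-concave triples.
* **Plateau rule.** `R_plateau` is the mean response over the largest 10%
  of probed diameters; if those responses still vary by more than 1% a
  "plateau not reached" warning is emitted.
* **Rebound phase.** For multiphasic traces the rebound is the *global*
  minimum after the first positive peak (not the first local minimum).
  The first positive peak is the first local maximum above 1e-8 of the
  trace maximum, which suppresses floating-point ripple.
* **Flashing spots.** The area-response scalar for flashing spots defaults
  to the peak absolute center response over time (`flash_summary="peak"`;
  `"mean"` and `"sustained"` are available), since flashed responses mix a
  transient and a sustained component and no canonical scalar exists.
* **Response maps.** Natural-image response maps are normalized by the
  peak absolute response of the *same image* through the no-feedback
  variant of the circuit, so feedback effects read directly as values
  above/below 1.

## Synthetic naturalistic movie

`generate_synthetic_movie(seed, grid, ...)` emulates the statistics of
head-camera footage of natural scenes: zero-mean grayscale frames with an
isotropic power-law spatial power spectrum `∝ |k|^−2` (the classic
natural-scene exponent; configurable) and stationary AR(1) frame-to-frame
correlation with lag-1 coefficient 0.9 (strong short-range temporal
correlation at the frame rates used here).  Defaults were fixed once from
these two well-established natural-statistics facts.  The generator is
fully seeded and reproducible.

What it does *not* reproduce: non-Gaussian luminance statistics, occlusion
structure, global motion flow/panning, and phase alignment across scales
(real scenes have edges; a power-law Gaussian field does not).
Consequently, decorrelation results obtained with it demonstrate the
*filtering* properties of the circuit on correlated input — the ordering
of feedback configurations — not quantitative autocorrelation values for
any particular movie.

## Design choices

* The feedback loop is represented directly by its net circularly
  symmetric kernels rather than explicit per-orientation cortical
  populations with elliptical couplings; the orientation sum makes the net
  loop kernel essentially circularly symmetric, and only the net kernel
  enters the relay-cell transfer function.
* Off-grid grating frequencies are snapped to the nearest DFT frequency
  (ties toward lower magnitude) rather than evaluated approximately, so
  grating responses are exactly sinusoidal on the grid.
* The OFF pathway is not duplicated: it mirrors the ON pathway by
  construction.
* The `cli` module is a thin layer over the library: YAML configs
  validated by a strict schema (unknown keys rejected, weight signs
  checked), subcommands mapping one-to-one onto library operations, and
  deterministic outputs (byte-identical CSV on reruns).

## Known limitations

* No spiking, bursting, adaptation, lagged cells or X/Y nonlinearity —
  the model is linear and tonic-mode by construction.
* Periodic boundaries: stimuli and kernels must decay well inside the
  domain; a warning fires when kernel support exceeds a quarter of the
  extent.
* Anisotropic (elliptical) spatial kernels and space-time-coupled kernels
  are not supported.
* The loop-gain divergence policy (error below 1e-6, warning below 0.05)
  is a practical guard; the underlying rate model itself says nothing
  about behavior at unit loop gain.
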
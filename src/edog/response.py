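"""Relay-cell responses: R = F^-1 { W_R(k, omega) S(k, omega) }.

The response to any stimulus is the inverse Fourier transform of the
pointwise product of the circuit transfer function with the stimulus
transform.  Static stimuli route through the spatial (omega = 0) transfer
function, multiplied by the retinal temporal constant H(0) so that the
static and dynamic paths agree numerically at zero frequency.

Periodic boundary conditions are inherited from the FFT: stimuli and kernel
supports must decay well inside the domain.  Response units are arbitrary
(firing-rate deviation); all downstream measures are ratios or argmax
positions and therefore unit-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circuit import Circuit, transfer_function_field
from .grid import SpaceTimeGrid
from .stimuli import PatchGrating, RasterStimulus, Stimulus, stimulus_ft

__all__ = [
    "ResponseField",
    "compute_response",
    "static_response",
    "fullfield_amplitude",
    "center_trace",
]


@dataclass(frozen=True)
class ResponseField:
    """Firing-rate deviation field on the grid, with provenance.

    ``values`` is (x, y, t) for dynamic stimuli or (x, y) for static
    analyses; the analyzed neuron is at ``grid.center_index`` on each
    spatial axis.
    """

    values: np.ndarray
    grid: SpaceTimeGrid
    stimulus: str = ""
    circuit_repr: str = ""

    @property
    def is_static(self) -> bool:
        return self.values.ndim == 2

    def center_value(self) -> float:
        c = self.grid.center_index
        if self.is_static:
            return float(self.values[c, c])
        raise ValueError("center_value is for static fields; use center_trace")


def _is_static(stimulus: Stimulus) -> bool:
    if isinstance(stimulus, PatchGrating):
        return stimulus.is_static
    if isinstance(stimulus, RasterStimulus):
        return stimulus.is_static
    return False


def compute_response(circuit: Circuit, stimulus: Stimulus,
                     grid: SpaceTimeGrid) -> ResponseField:
    """Response of the relay-cell layer to an arbitrary stimulus.

    Static stimuli (spots, static images) are evaluated with a single 2-D
    inverse transform of ``W_R(k, 0) S(k)``; everything else with the full
    3-D product.
    """
    if _is_static(stimulus):
        return static_response(circuit, stimulus, grid)
    s_ft = stimulus_ft(stimulus, grid)
    tf = transfer_function_field(circuit, grid, static=False)
    values = np.real(grid.ift(tf.values * s_ft))
    return ResponseField(values, grid, stimulus=repr(stimulus),
                         circuit_repr=repr(circuit))


def static_response(circuit: Circuit, stimulus: Stimulus,
                    grid: SpaceTimeGrid) -> ResponseField:
    """Static-path (fast-loop) response: 2-D inverse transform of W_R(k,0) S(k).

    Also applicable to slowly drifting patch gratings, whose response is
    evaluated at cosine phase zero; the retinal temporal constant H(0) is
    kept explicitly.
    """
    if isinstance(stimulus, PatchGrating):
        s_spatial = stimulus.sample_spatial(grid)
    elif isinstance(stimulus, RasterStimulus) and stimulus.is_static:
        s_spatial = stimulus.sample(grid)
    elif isinstance(stimulus, np.ndarray) and stimulus.ndim == 2:
        s_spatial = stimulus
    else:
        raise TypeError(f"no static path for stimulus {type(stimulus).__name__}")
    s_ft = grid.spatial_ft(s_spatial)
    w_static = circuit.static_transfer(grid.k_mag) * circuit.retinal_h0
    values = np.real(grid.spatial_ift(w_static * s_ft))
    return ResponseField(values, grid, stimulus=repr(stimulus),
                         circuit_repr=repr(circuit))


def fullfield_amplitude(circuit: Circuit, k_vec, omega: float,
                        contrast: float = 1.0) -> float:
    """Amplitude of the center-neuron sinusoid for an aligned full-field grating.

    Equals ``contrast * |W_R(k_g, omega_g)|``, consistent with the trace
    amplitude obtained from :func:`compute_response` on an aligned grating.
    """
    k_vec = np.asarray(k_vec, dtype=float)
    k_mag = np.hypot(k_vec[0], k_vec[1]) if k_vec.shape == (2,) else float(np.abs(k_vec))
    return float(contrast * np.abs(circuit.transfer_function(k_mag, omega)))


def center_trace(field: ResponseField) -> np.ndarray:
    """Time series of the neuron at the grid center (index n // 2 per axis)."""
    if field.is_static:
        raise ValueError("center_trace requires a 3-D response field")
    c = field.grid.center_index
    return field.values[c, c, :]
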
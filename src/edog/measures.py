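"""Quantitative response measures.

Everything derived from relay-cell responses lives here: receptive-field
geometry (size, center excitation, surround inhibition), area-response
curves with suppression index and optimal size, spatial and temporal
frequency tuning, the center/surround response-reduction percentage,
temporal impulse-response measures (biphasic index, peak latency),
response autocorrelation for movies, and normalized response maps for
natural images.

Numerical conventions used throughout:

* zero crossings are linearly interpolated between bracketing radial
  samples along the +x axis from the center;
* argmax refinements use 3-point quadratic interpolation, ties breaking
  toward the smaller argument;
* the area-curve plateau is the mean response over the largest 10% of the
  probed diameters (warning if it still varies by more than 1%);
* the rebound phase of a (possibly multiphasic) temporal trace is the
  global minimum after the first positive peak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .circuit import Circuit
from .grid import SpaceTimeGrid
from .response import ResponseField, center_trace, compute_response, static_response
from .stimuli import FlashingSpot, PatchGrating, RasterStimulus, align_wavevector

__all__ = [
    "RFCharacteristics",
    "AreaResponseCurve",
    "TemporalIRFMeasures",
    "TuningCurve",
    "rf_characteristics",
    "area_response_curve",
    "suppression_index",
    "optimal_size",
    "spatial_frequency_tuning",
    "temporal_frequency_tuning",
    "response_reduction",
    "temporal_irf_measures",
    "temporal_autocorrelation",
    "response_map",
]


# -- helpers -----------------------------------------------------------------

def _quadratic_refine(x: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """Vertex of the parabola through points (i-1, i, i+1); falls back to the
    sample itself at the boundary or for a degenerate (flat) triple."""
    if i == 0 or i == len(y) - 1:
        return float(x[i]), float(y[i])
    x0, x1, x2 = x[i - 1], x[i], x[i + 1]
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
    if a >= 0:  # not a maximum; keep the grid sample
        return float(x1), float(y1)
    xv = -b / (2 * a)
    c_ = y1 - a * x1**2 - b * x1
    return float(xv), float(a * xv**2 + b * xv + c_)


def _first_positive_peak(trace: np.ndarray) -> int:
    floor = 1e-8 * float(np.max(trace))
    peaks, _ = find_peaks(trace, height=floor)
    if peaks.size:
        return int(peaks[0])
    return int(np.argmax(trace))


# -- receptive-field geometry ------------------------------------------------

@dataclass(frozen=True)
class RFCharacteristics:
    """Geometry of a center-surround spatial impulse-response field.

    ``rf_size`` is the radius of the first zero crossing of the radial
    profile (deg), ``None`` when the field never changes sign (the
    ``size_defined`` flag is then False).
    """

    rf_size: float | None
    center_excitation: float
    surround_inhibition: float

    @property
    def size_defined(self) -> bool:
        return self.rf_size is not None


def rf_characteristics(spatial_field: np.ndarray, grid: SpaceTimeGrid) -> RFCharacteristics:
    """Measure a centered 2-D spatial impulse-response field."""
    c = grid.center_index
    if spatial_field[c, c] <= 0:
        raise ValueError("field must have a positive center")
    profile = spatial_field[c:, c]
    radii = grid.x[c:]
    sign_change = np.nonzero(np.diff(np.signbit(profile)))[0]
    if sign_change.size:
        i = int(sign_change[0])
        y0, y1 = profile[i], profile[i + 1]
        r0, r1 = radii[i], radii[i + 1]
        rf_size = float(r0 + (r1 - r0) * y0 / (y0 - y1))
    else:
        rf_size = None
    return RFCharacteristics(
        rf_size=rf_size,
        center_excitation=float(spatial_field.max()),
        surround_inhibition=float(spatial_field.min()),
    )


# -- area-response curves ----------------------------------------------------

@dataclass(frozen=True)
class AreaResponseCurve:
    """Center-neuron response versus stimulus diameter."""

    diameters: np.ndarray
    responses: np.ndarray
    kind: str = "static_spot"

    def __post_init__(self) -> None:
        d = np.asarray(self.diameters, dtype=float)
        r = np.asarray(self.responses, dtype=float)
        if d.ndim != 1 or d.shape != r.shape:
            raise ValueError("diameters and responses must be matching 1-D arrays")
        if not np.all(np.diff(d) > 0):
            raise ValueError("diameters must be strictly increasing")
        object.__setattr__(self, "diameters", d)
        object.__setattr__(self, "responses", r)

    @property
    def r_max(self) -> float:
        return float(self.responses.max())

    @property
    def r_plateau(self) -> float:
        n_tail = max(1, int(np.ceil(0.1 * len(self.diameters))))
        tail = self.responses[-n_tail:]
        spread = np.ptp(tail)
        scale = max(abs(tail.mean()), 1e-300)
        if spread > 0.01 * scale:
            warnings.warn(
                f"plateau not reached: tail responses vary by {spread / scale:.1%}",
                RuntimeWarning,
                stacklevel=2,
            )
        return float(tail.mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"diameter_deg": self.diameters, "response": self.responses,
             "kind": self.kind}
        )


def area_response_curve(
    circuit: Circuit,
    grid: SpaceTimeGrid,
    diameters: Sequence[float],
    kind: str = "static_spot",
    k_pg: float = 0.0,
    omega_pg: float = 0.0,
    flash_summary: str = "peak",
) -> AreaResponseCurve:
    """Center-neuron response versus diameter of a concentric spot/patch.

    ``kind`` is ``"static_spot"``, ``"patch_grating"`` (wavenumber ``k_pg``
    along x, evaluated via the static fast-loop path at cosine phase zero)
    or ``"flashing_spot"`` (full dynamic response summarized by
    ``flash_summary``: peak absolute center response by default, or
    ``"mean"``/``"sustained"``).
    """
    diameters = np.asarray(diameters, dtype=float)
    if np.any(diameters > grid.extent / 2):
        raise ValueError("diameters must not exceed half the grid extent")
    if kind == "static_spot":
        k_pg = 0.0
    if kind in ("static_spot", "patch_grating"):
        if k_pg:
            k_vec, _, _ = align_wavevector((k_pg, 0.0), 0.0, grid)
        else:
            k_vec = np.zeros(2)
        responses = []
        for d in diameters:
            stim = PatchGrating(k_pg=(k_vec[0], k_vec[1]), omega_pg=0.0, d_pg=d)
            responses.append(static_response(circuit, stim, grid).center_value())
    elif kind == "flashing_spot":
        responses = []
        for d in diameters:
            stim = FlashingSpot(diameter=d, onset=0.0,
                                on_duration=grid.duration / 4)
            trace = center_trace(compute_response(circuit, stim, grid))
            if flash_summary == "peak":
                responses.append(float(np.max(np.abs(trace))))
            elif flash_summary == "mean":
                responses.append(float(np.mean(trace)))
            elif flash_summary == "sustained":
                on = (grid.t >= grid.duration / 8) & (grid.t < grid.duration / 4)
                responses.append(float(np.mean(trace[on])))
            else:
                raise ValueError(f"unknown flash_summary {flash_summary!r}")
    else:
        raise ValueError(f"unknown curve kind {kind!r}")
    return AreaResponseCurve(diameters, np.asarray(responses), kind=kind)


def suppression_index(curve: AreaResponseCurve) -> float:
    """Surround-suppression index (R_max - R_plateau) / R_max, in [0, 1]."""
    r_max = curve.r_max
    if r_max <= 0:
        raise ValueError("suppression index undefined for non-positive R_max")
    return (r_max - curve.r_plateau) / r_max


def optimal_size(curve: AreaResponseCurve) -> float:
    """Diameter of the maximum response, quadratically refined."""
    i = int(np.argmax(curve.responses))  # argmax returns the first (smallest) tie
    d, _ = _quadratic_refine(curve.diameters, curve.responses, i)
    return d


# -- frequency tuning --------------------------------------------------------

@dataclass(frozen=True)
class TuningCurve:
    """Response magnitude versus frequency (spatial or temporal)."""

    frequencies: np.ndarray
    responses: np.ndarray
    label: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({self.label or "frequency": self.frequencies,
                             "response": self.responses})


def spatial_frequency_tuning(
    circuit: Circuit,
    grid: SpaceTimeGrid,
    d_pg: float,
    k_list: Sequence[float],
) -> TuningCurve:
    """Static-path center response versus patch-grating wavenumber (rad/deg)."""
    k_list = np.asarray(k_list, dtype=float)
    if np.any(np.abs(k_list) > grid.k_nyquist):
        raise ValueError("wavenumbers must stay below the grid Nyquist frequency")
    responses = []
    for k in k_list:
        stim = PatchGrating(k_pg=(k, 0.0), omega_pg=0.0, d_pg=d_pg)
        responses.append(static_response(circuit, stim, grid).center_value())
    return TuningCurve(k_list, np.asarray(responses), label="k_rad_per_deg")


def temporal_frequency_tuning(
    circuit: Circuit,
    k_mag: float,
    omega_list: Sequence[float],
) -> TuningCurve:
    """|W_R(k_g, omega)| versus temporal angular frequency at fixed |k_g|."""
    omega_list = np.asarray(omega_list, dtype=float)
    values = np.abs(circuit.transfer_function(k_mag, omega_list))
    return TuningCurve(omega_list, values, label="omega_rad_per_ms")


def response_reduction(
    circuit: Circuit,
    grid: SpaceTimeGrid,
    k_pg: float = 0.25,
    d_center: float = 1.5,
    d_full: float = 10.0,
) -> float:
    """Percentage response reduction from center-only to center-plus-surround
    stimulation: 100 (R(d_center) - R(d_full)) / R(d_center) at wavenumber
    ``k_pg``."""
    if d_center > d_full:
        raise ValueError("d_center must not exceed d_full")
    if d_center == d_full:
        return 0.0
    k_vec, _, _ = align_wavevector((k_pg, 0.0), 0.0, grid)
    responses = {}
    for d in (d_center, d_full):
        stim = PatchGrating(k_pg=(k_vec[0], k_vec[1]), omega_pg=0.0, d_pg=d)
        responses[d] = static_response(circuit, stim, grid).center_value()
    if responses[d_center] <= 0:
        raise ValueError("center-only response must be positive")
    return 100.0 * (responses[d_center] - responses[d_full]) / responses[d_center]


# -- temporal impulse-response measures --------------------------------------

@dataclass(frozen=True)
class TemporalIRFMeasures:
    """Biphasic index and peak latency of a temporal impulse-response trace."""

    i_bp: float
    t_peak: float


def temporal_irf_measures(trace: np.ndarray, dt: float) -> TemporalIRFMeasures:
    """Biphasic index and (interpolated) peak latency of a temporal trace.

    The first positive local maximum defines the primary phase; the rebound
    is the global minimum at later times.  ``i_bp`` is the rebound/peak
    magnitude ratio (0 for monophasic traces); ``t_peak`` the refined time
    of the primary peak in ms.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.max() <= 0:
        raise ValueError("trace has no positive phase")
    t = np.arange(len(trace)) * dt
    i = _first_positive_peak(trace)
    t_peak, peak_val = _quadratic_refine(t, trace, i)
    rebound = float(trace[i:].min())
    i_bp = abs(rebound) / peak_val if rebound < 0 else 0.0
    return TemporalIRFMeasures(i_bp=float(i_bp), t_peak=float(t_peak))


# -- autocorrelation ---------------------------------------------------------

def temporal_autocorrelation(
    field: ResponseField | np.ndarray,
    window: int = 40,
    max_lag: int = 50,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean +- sd temporal autocorrelation over a central block of neurons.

    Each neuron's trace is mean-subtracted and normalized by its lag-0
    autocovariance; zero-variance neurons are excluded with a warning.
    Returns ``(lags, mean_acf, sd_acf)`` with ``lags`` in samples.
    """
    values = field.values if isinstance(field, ResponseField) else np.asarray(field)
    if values.ndim != 3:
        raise ValueError("temporal autocorrelation requires a 3-D (x, y, t) field")
    nx, ny, nt = values.shape
    if window > min(nx, ny):
        raise ValueError("window exceeds the spatial grid")
    if max_lag >= nt:
        raise ValueError("max_lag must be below the number of time samples")
    x0 = (nx - window) // 2
    y0 = (ny - window) // 2
    block = values[x0:x0 + window, y0:y0 + window, :].reshape(-1, nt)
    block = block - block.mean(axis=1, keepdims=True)
    var = np.sum(block**2, axis=1)
    keep = var > 0
    if not np.all(keep):
        warnings.warn(
            f"excluded {np.count_nonzero(~keep)} zero-variance neurons",
            RuntimeWarning,
            stacklevel=2,
        )
    block = block[keep]
    var = var[keep]
    if block.shape[0] == 0:
        raise ValueError("all neurons in the window have zero variance")
    lags = np.arange(max_lag + 1)
    acfs = np.empty((block.shape[0], max_lag + 1))
    for lag in lags:
        if lag == 0:
            acfs[:, 0] = 1.0
        else:
            acfs[:, lag] = np.sum(block[:, lag:] * block[:, :-lag], axis=1) / var
    return lags, acfs.mean(axis=0), acfs.std(axis=0)


# -- natural-image response maps ---------------------------------------------

def response_map(circuit: Circuit, image: RasterStimulus,
                 grid: SpaceTimeGrid) -> np.ndarray:
    """Static response to an image, normalized by the peak absolute response
    of the same image through the no-feedback variant of the circuit."""
    if not image.is_static:
        raise ValueError("response_map requires a static image")
    baseline = static_response(circuit.without_feedback(), image, grid).values
    peak = float(np.max(np.abs(baseline)))
    if peak == 0:
        raise ValueError("no-feedback response is identically zero")
    fed = static_response(circuit, image, grid).values
    return fed / peak
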
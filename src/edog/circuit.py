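"""The dLGN circuit and its closed-form relay-cell transfer function.

A relay cell receives direct feedforward excitation from retinal ganglion
cells (kernel K_RG), indirect feedforward inhibition via intrageniculate
interneurons (K_RIG), and corticothalamic feedback closing the
relay -> cortex -> relay loop.  Because the cortical populations are
half-wave rectifying and the OFF pathway mirrors the ON pathway with a
phase-reversed feedback arrangement, the rectifications cancel and the
relay-cell impulse-response function has the closed Fourier-space form

    W_R(k, w) = [ sum_ff  w f(k) h(w) ] / [ 1 - sum_fb w f(k) h(w) ] * F(k) H(w)

where the feedforward sum runs over K_RG and (optionally) K_RIG, the
feedback sum over the net thalamo-cortico-thalamic loop kernels, and
F, H are the spatial (DOG) and temporal (biphasic) parts of the retinal
input.  Every response computation in the library evaluates this single
expression on a frequency grid.

Relay responses are linear and may be negative: no rectification is applied
at the geniculate level.  All derived measures are ratios or argmax
positions and therefore unit-free.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .grid import SpaceTimeGrid
from .kernels import (
    BiphasicTemporal,
    DelayedExponential,
    DOGSpatial,
    GaussianSpatial,
    SeparableKernel,
)

__all__ = [
    "Circuit",
    "CircuitInstabilityError",
    "StabilityReport",
    "TransferFunctionField",
    "retinal_irf",
    "ff_excitation_kernel",
    "ff_inhibition_kernel",
    "feedback_kernel",
    "feedforward_only_circuit",
    "no_feedback_circuit",
    "excitatory_feedback_circuit",
    "inhibitory_feedback_circuit",
    "mixed_feedback_circuit",
    "transfer_function",
    "static_transfer",
    "spatial_irf",
    "spatiotemporal_irf",
    "stability_check",
]

#: below this denominator magnitude the loop gain is treated as divergent
INSTABILITY_TOL = 1e-6
#: between INSTABILITY_TOL and this value a warning is emitted
INSTABILITY_WARN = 0.05


class CircuitInstabilityError(RuntimeError):
    """Raised when the feedback-loop denominator (nearly) vanishes."""


@dataclass(frozen=True)
class Circuit:
    """Kernel collection defining one relay-cell transfer function.

    Parameters
    ----------
    retinal_irf:
        Impulse response of the retinal ganglion input (weight fixed at 1;
        DOG spatial part, biphasic temporal part).
    ff_excitation:
        Feedforward excitation K_RG (weight > 0).
    ff_inhibition:
        Optional feedforward inhibition K_RIG via interneurons (weight < 0).
    feedback_terms:
        Net cortico-thalamic loop kernels; excitatory terms have positive,
        inhibitory terms negative weight.  Mixed feedback is two terms.
    """

    retinal_irf: SeparableKernel
    ff_excitation: SeparableKernel
    ff_inhibition: SeparableKernel | None = None
    feedback_terms: tuple[SeparableKernel, ...] = ()

    def __post_init__(self) -> None:
        if self.retinal_irf.weight != 1:
            raise ValueError("retinal input weight is fixed at 1")
        if not self.ff_excitation.weight > 0:
            raise ValueError("feedforward excitation weight must be positive")
        if self.ff_inhibition is not None and not self.ff_inhibition.weight < 0:
            raise ValueError("feedforward inhibition weight must be negative")
        object.__setattr__(self, "feedback_terms", tuple(self.feedback_terms))

    # -- variants ---------------------------------------------------------
    def without_feedback(self) -> "Circuit":
        """Identical circuit with all feedback terms removed."""
        return replace(self, feedback_terms=())

    @property
    def feedforward_terms(self) -> tuple[SeparableKernel, ...]:
        terms = (self.ff_excitation,)
        if self.ff_inhibition is not None:
            terms += (self.ff_inhibition,)
        return terms

    @property
    def min_spatial_width(self) -> float:
        widths = [self.retinal_irf.spatial.a]
        for k in (*self.feedforward_terms, *self.feedback_terms):
            widths.append(k.spatial.a)
        return min(widths)

    @property
    def max_spatial_width(self) -> float:
        widths = [self.retinal_irf.spatial.b]
        for k in (*self.feedforward_terms, *self.feedback_terms):
            widths.append(k.spatial.a)
        return max(widths)

    def temporal_support(self) -> float:
        """Rough upper bound on the kernel chain's temporal support (ms)."""
        total = 2 * self.retinal_irf.temporal.tau_phase
        for k in (*self.feedforward_terms, *self.feedback_terms):
            total += k.temporal.delta + 8 * k.temporal.tau
        return total

    # -- transfer function ------------------------------------------------
    def denominator(self, k_mag, omega) -> np.ndarray:
        den = np.ones(np.broadcast(np.asarray(k_mag), np.asarray(omega)).shape, dtype=complex)
        for term in self.feedback_terms:
            den = den - term.ft(k_mag, omega)
        return den

    def transfer_function(self, k_mag, omega) -> np.ndarray:
        """Relay-cell gain W_R at spatial frequency |k| (rad/deg), omega (rad/ms)."""
        num = sum(term.ft(k_mag, omega) for term in self.feedforward_terms)
        den = self.denominator(k_mag, omega)
        _check_denominator(den, k_mag, omega)
        retina = self.retinal_irf.spatial.ft(k_mag) * self.retinal_irf.temporal.ft(omega)
        return num / den * retina

    def static_transfer(self, k_mag) -> np.ndarray:
        """Spatial transfer function W_R(k, 0) with the constant H(0) factored out.

        All temporal transforms of the coupling kernels equal 1 at omega = 0,
        so only spatial profiles and weights enter.  Multiplying by
        ``retinal_h0`` recovers ``transfer_function(k, 0)`` exactly.
        """
        num = sum(t.weight * t.spatial.ft(k_mag) for t in self.feedforward_terms)
        den = 1.0 - sum(t.weight * t.spatial.ft(k_mag) for t in self.feedback_terms)
        _check_denominator(den, k_mag, 0.0)
        return num / den * self.retinal_irf.spatial.ft(k_mag)

    @property
    def retinal_h0(self) -> float:
        """H(0), the zero-frequency value of the retinal temporal filter."""
        return float(np.real(self.retinal_irf.temporal.ft(0.0)))


def _check_denominator(den, k_mag, omega) -> None:
    mag = np.abs(den)
    idx = np.argmin(mag)
    mmin = float(np.ravel(mag)[idx])
    if mmin < INSTABILITY_TOL:
        k_bad = float(np.ravel(np.broadcast_to(k_mag, np.shape(mag)))[idx])
        w_bad = float(np.ravel(np.broadcast_to(omega, np.shape(mag)))[idx])
        raise CircuitInstabilityError(
            f"feedback loop gain diverges: |1 - sum(K_loop)| = {mmin:.3g} "
            f"at |k| = {k_bad:.4g} rad/deg, omega = {w_bad:.4g} rad/ms"
        )
    if mmin < INSTABILITY_WARN:
        warnings.warn(
            f"feedback loop close to instability: min |denominator| = {mmin:.3g}",
            RuntimeWarning,
            stacklevel=3,
        )


# -- Default parameterization ------------------------------------------------
# Standard cat parameters: retinal DOG fitted to flashing-spot responses,
# biphasic retinal time course, narrow feedforward excitation, broader and
# slightly delayed feedforward inhibition, and the three canonical feedback
# configurations (excitatory / inhibitory / mixed).  Coupling time constants
# are 5 ms throughout; feedback delays are the varied parameters.


def retinal_irf() -> SeparableKernel:
    return SeparableKernel(
        weight=1.0,
        spatial=DOGSpatial(A=1.0, a=0.62, B=0.85, b=1.26),
        temporal=BiphasicTemporal(tau_phase=42.5, B_second=0.38),
    )


def ff_excitation_kernel(weight: float = 1.0, a: float = 0.1,
                         delta: float = 0.0, tau: float = 5.0) -> SeparableKernel:
    return SeparableKernel(weight, GaussianSpatial(a), DelayedExponential(delta, tau))


def ff_inhibition_kernel(weight: float = -0.5, a: float = 0.3,
                         delta: float = 3.0, tau: float = 5.0) -> SeparableKernel:
    return SeparableKernel(weight, GaussianSpatial(a), DelayedExponential(delta, tau))


def feedback_kernel(weight: float, a: float, delta: float = 5.0,
                    tau: float = 5.0) -> SeparableKernel:
    return SeparableKernel(weight, GaussianSpatial(a), DelayedExponential(delta, tau))


def feedforward_only_circuit() -> Circuit:
    """Retinal input plus feedforward excitation only."""
    return Circuit(retinal_irf(), ff_excitation_kernel())


def no_feedback_circuit() -> Circuit:
    """Feedforward excitation and inhibition, no cortical feedback."""
    return Circuit(retinal_irf(), ff_excitation_kernel(), ff_inhibition_kernel())


def excitatory_feedback_circuit(weight: float = 0.5, a: float = 0.83,
                                delta: float = 5.0) -> Circuit:
    return Circuit(
        retinal_irf(), ff_excitation_kernel(), ff_inhibition_kernel(),
        feedback_terms=(feedback_kernel(weight, a, delta),),
    )


def inhibitory_feedback_circuit(weight: float = -0.5, a: float = 0.83,
                                delta: float = 5.0) -> Circuit:
    return Circuit(
        retinal_irf(), ff_excitation_kernel(), ff_inhibition_kernel(),
        feedback_terms=(feedback_kernel(weight, a, delta),),
    )


def mixed_feedback_circuit(weight_factor: float = 1.0, delta_ex: float = 5.0,
                           delta_in: float = 30.0) -> Circuit:
    """Narrow excitatory plus broad inhibitory feedback (default weights 0.3/-0.6).

    ``weight_factor`` scales both feedback weights jointly, as in weight
    sweeps; the default delays realize the delayed-inhibition arrangement.
    """
    return Circuit(
        retinal_irf(), ff_excitation_kernel(), ff_inhibition_kernel(),
        feedback_terms=(
            feedback_kernel(0.3 * weight_factor, 0.1, delta_ex),
            feedback_kernel(-0.6 * weight_factor, 0.9, delta_in),
        ),
    )


# -- module-level functional API ---------------------------------------------

def transfer_function(circuit: Circuit, k_vec, omega) -> np.ndarray:
    """W_R at wave vector(s) ``k_vec`` (rad/deg; scalar magnitude or 2-vector)."""
    return circuit.transfer_function(_k_magnitude(k_vec), omega)


def static_transfer(circuit: Circuit, k_vec) -> np.ndarray:
    return circuit.static_transfer(_k_magnitude(k_vec))


def _k_magnitude(k_vec) -> np.ndarray:
    arr = np.asarray(k_vec, dtype=float)
    if arr.ndim == 1 and arr.shape == (2,):
        return np.hypot(arr[0], arr[1])
    return np.abs(arr)


@dataclass(frozen=True)
class TransferFunctionField:
    """Transfer function sampled on a grid's conjugate frequencies."""

    values: np.ndarray
    grid: SpaceTimeGrid
    static: bool

    def __post_init__(self) -> None:
        expected = (
            (self.grid.n_spatial, self.grid.n_spatial)
            if self.static
            else (self.grid.n_spatial, self.grid.n_spatial, self.grid.n_time)
        )
        if self.values.shape != expected:
            raise ValueError(f"expected shape {expected}, got {self.values.shape}")


def transfer_function_field(circuit: Circuit, grid: SpaceTimeGrid,
                            static: bool = False) -> TransferFunctionField:
    """Sample the (static or full) transfer function on the grid frequencies."""
    if static:
        values = circuit.static_transfer(grid.k_mag)
    else:
        k = grid.k_mag[:, :, None]
        w = grid.omega[None, None, :]
        values = circuit.transfer_function(k, w)
    return TransferFunctionField(np.asarray(values), grid, static)


def _require_resolution(circuit: Circuit, grid: SpaceTimeGrid) -> None:
    if grid.dx > circuit.min_spatial_width / 2:
        warnings.warn(
            f"grid spacing dx = {grid.dx:.3g} deg does not resolve the narrowest "
            f"kernel width {circuit.min_spatial_width:.3g} deg; increase n_spatial",
            RuntimeWarning,
            stacklevel=3,
        )
    if circuit.max_spatial_width > grid.extent / 4:
        warnings.warn(
            "widest kernel support exceeds a quarter of the periodic domain; "
            "boundary wrap-around may contaminate the response",
            RuntimeWarning,
            stacklevel=3,
        )


def spatial_irf(circuit: Circuit, grid: SpaceTimeGrid) -> np.ndarray:
    """Real-space spatial impulse-response field (static transfer, 2-D).

    Returns a real, circularly symmetric field centered at
    ``grid.center_index`` with the familiar center-surround structure.
    """
    _require_resolution(circuit, grid)
    tf = transfer_function_field(circuit, grid, static=True)
    out = grid.spatial_ift(tf.values)
    return np.real(out)


def spatiotemporal_irf(circuit: Circuit, grid: SpaceTimeGrid) -> np.ndarray:
    """Real-space impulse-response field W_R(x, y, t) via a 3-D inverse FFT.

    The field is causal; the inverse FFT wraps negative times onto the top
    of the time axis, so the grid duration must comfortably exceed the
    kernel chain's temporal support (a warning is emitted otherwise).
    """
    _require_resolution(circuit, grid)
    if grid.duration < 2 * circuit.temporal_support():
        warnings.warn(
            "grid duration is less than twice the kernel temporal support; "
            "temporal wrap-around may contaminate the impulse response",
            RuntimeWarning,
            stacklevel=2,
        )
    tf = transfer_function_field(circuit, grid, static=False)
    out = np.real(grid.ift(tf.values))
    peak = np.max(np.abs(out))
    tail = np.max(np.abs(out[:, :, -out.shape[2] // 8:]))
    if peak > 0 and tail > 1e-6 * peak:
        warnings.warn(
            f"late-time leakage {tail / peak:.2e} of peak; enlarge grid duration",
            RuntimeWarning,
            stacklevel=2,
        )
    return out


@dataclass(frozen=True)
class StabilityReport:
    min_denominator: float
    k_mag: float
    omega: float

    @property
    def stable(self) -> bool:
        return self.min_denominator >= INSTABILITY_TOL


def stability_check(circuit: Circuit, grid: SpaceTimeGrid) -> StabilityReport:
    """Scan the discrete (k, omega) grid for the minimum loop-gain denominator."""
    k = grid.k_mag[:, :, None]
    w = grid.omega[None, None, :]
    den = np.abs(circuit.denominator(k, w))
    idx = np.unravel_index(np.argmin(den), den.shape)
    return StabilityReport(
        min_denominator=float(den[idx]),
        k_mag=float(grid.k_mag[idx[:2]]),
        omega=float(grid.omega[idx[2]]),
    )
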
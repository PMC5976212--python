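"""Spatial and temporal profile functions and separable coupling kernels.

Every connection in the circuit is described by a separable kernel

    K(r, t) = w f(r) h(t),

where ``w`` is a signed coupling weight (positive for excitation, negative
for inhibition), ``f`` a normalized circularly-symmetric spatial profile and
``h`` a normalized temporal profile.  The retinal input uses a
difference-of-Gaussians (DOG) spatial profile and a biphasic temporal
profile; all couplings inside the circuit use a Gaussian spatial profile and
a delayed decaying exponential in time.

Fourier convention (library-wide)
---------------------------------
    K~(k, w) = int int K(r, t) exp(-i(k.r - w t)) d2r dt

i.e. the spatial transform carries ``exp(-i k.r)`` and the temporal one
``exp(+i w t)``.  With this choice a drifting plane wave
``cos(k_g.r - w_g t)`` probes the transfer function exactly at
``(k_g, w_g)``.  All closed forms below are derived under this convention
and checked against dense FFT oracles in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

__all__ = [
    "GaussianSpatial",
    "DOGSpatial",
    "BiphasicTemporal",
    "DelayedExponential",
    "SeparableKernel",
    "SpatialProfile",
    "TemporalProfile",
]


def _as_finite_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite, got {x!r}")
    return arr


@dataclass(frozen=True)
class GaussianSpatial:
    """Normalized 2-D Gaussian, f(r; a) = exp(-r^2/a^2) / (pi a^2).

    Parameters
    ----------
    a:
        Width parameter in degrees of visual angle.  The profile integrates
        to one over the plane for any ``a > 0``.
    """

    a: float

    def __post_init__(self) -> None:
        if not (self.a > 0):
            raise ValueError(f"width parameter a must be > 0, got {self.a}")

    def evaluate(self, r) -> np.ndarray:
        """Profile value at radius ``r`` (deg); units deg^-2."""
        r = _as_finite_array(r, "r")
        return np.exp(-(r / self.a) ** 2) / (np.pi * self.a**2)

    def ft(self, k_mag) -> np.ndarray:
        """2-D Fourier transform at radial wavenumber ``k_mag`` (rad/deg).

        Closed form exp(-a^2 k^2 / 4); equals 1 at k = 0 (normalization) and
        decays monotonically.
        """
        k_mag = _as_finite_array(k_mag, "k_mag")
        return np.exp(-((self.a * k_mag) ** 2) / 4.0)


@dataclass(frozen=True)
class DOGSpatial:
    """Difference-of-Gaussians center-surround profile.

    F(r) = A exp(-r^2/a^2)/(pi a^2) - B exp(-r^2/b^2)/(pi b^2)

    ``A``/``a`` are the center strength/width, ``B``/``b`` the surround
    strength/width (all positive; widths in degrees).  The plane integral is
    ``A - B``.
    """

    A: float
    a: float
    B: float
    b: float

    def __post_init__(self) -> None:
        for name in ("A", "a", "B", "b"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")

    @property
    def center(self) -> GaussianSpatial:
        return GaussianSpatial(self.a)

    @property
    def surround(self) -> GaussianSpatial:
        return GaussianSpatial(self.b)

    def evaluate(self, r) -> np.ndarray:
        return self.A * self.center.evaluate(r) - self.B * self.surround.evaluate(r)

    def ft(self, k_mag) -> np.ndarray:
        """A exp(-a^2 k^2/4) - B exp(-b^2 k^2/4); equals A - B at k = 0."""
        return self.A * self.center.ft(k_mag) - self.B * self.surround.ft(k_mag)


@dataclass(frozen=True)
class BiphasicTemporal:
    """Biphasic temporal profile of the retinal impulse response.

    H(t) = sin(pi t / tau_phase)            for 0 <= t <= tau_phase
         = B_second sin(pi t / tau_phase)   for tau_phase < t <= 2 tau_phase
         = 0                                otherwise

    ``tau_phase`` is the duration of each phase in ms; ``B_second`` weights
    the (negative) second phase.  The time integral is
    ``(2 tau_phase / pi) (1 - B_second)``; this profile is deliberately not
    unit-normalized, matching its role as a descriptive retinal filter.
    """

    tau_phase: float
    B_second: float

    def __post_init__(self) -> None:
        if not (self.tau_phase > 0):
            raise ValueError(f"tau_phase must be > 0, got {self.tau_phase}")

    def evaluate(self, t) -> np.ndarray:
        t = _as_finite_array(t, "t")
        tau = self.tau_phase
        phase = np.sin(np.pi * t / tau)
        first = (t >= 0) & (t <= tau)
        second = (t > tau) & (t <= 2 * tau)
        return np.where(first, phase, 0.0) + np.where(second, self.B_second * phase, 0.0)

    def ft(self, omega) -> np.ndarray:
        """Closed-form transform  pi/tau (1+e^{i w tau})(1-B e^{i w tau}) / ((pi/tau)^2 - w^2).

        The apparent poles at w = +-pi/tau are removable (the numerator
        vanishes there); the analytic limit +-i tau (1 + B)/2 is substituted
        within a small neighborhood.
        """
        omega = _as_finite_array(omega, "omega")
        scalar = omega.ndim == 0
        tau = self.tau_phase
        a = np.pi / tau
        omega = np.atleast_1d(omega)
        near_pole = np.isclose(np.abs(omega), a, rtol=0.0, atol=1e-8 * a)
        # avoid 0/0 at the poles; masked points are overwritten below
        safe = np.where(near_pole, omega + a, omega)
        phase = np.exp(1j * safe * tau)
        out = a * (1.0 + phase) * (1.0 - self.B_second * phase) / (a**2 - safe**2)
        limit = 1j * tau * (1.0 + self.B_second) / 2.0 * np.sign(omega)
        out = np.where(near_pole, limit, out)
        return complex(out[0]) if scalar else out


@dataclass(frozen=True)
class DelayedExponential:
    """Delayed decaying exponential, h(t) = exp(-(t - delta)/tau)/tau for t >= delta.

    ``delta`` (ms, >= 0) is the combined axonal and synaptic delay and
    ``tau`` (ms, > 0) the decay time constant.  Integrates to one, so the
    transform is exactly 1 at omega = 0 and |h~| <= 1 everywhere.
    """

    delta: float
    tau: float

    def __post_init__(self) -> None:
        if not (self.tau > 0):
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if self.delta < 0:
            raise ValueError(f"delta must be >= 0, got {self.delta}")

    def evaluate(self, t) -> np.ndarray:
        t = _as_finite_array(t, "t")
        shifted = t - self.delta
        with np.errstate(over="ignore"):
            val = np.exp(-np.clip(shifted, 0.0, None) / self.tau) / self.tau
        return np.where(shifted >= 0, val, 0.0)

    def ft(self, omega) -> np.ndarray:
        """Closed form exp(i w delta) / (1 - i w tau)."""
        omega = _as_finite_array(omega, "omega")
        return np.exp(1j * omega * self.delta) / (1.0 - 1j * omega * self.tau)


SpatialProfile = Union[GaussianSpatial, DOGSpatial]
TemporalProfile = Union[BiphasicTemporal, DelayedExponential]


@dataclass(frozen=True)
class SeparableKernel:
    """Weighted separable coupling kernel K(r, t) = w f(r) h(t).

    The sign of ``weight`` encodes excitation (+) or inhibition (-).
    """

    weight: float
    spatial: SpatialProfile
    temporal: TemporalProfile

    def evaluate(self, r, t) -> np.ndarray:
        return self.weight * self.spatial.evaluate(r) * self.temporal.evaluate(t)

    def ft(self, k_mag, omega) -> np.ndarray:
        return self.weight * self.spatial.ft(k_mag) * self.temporal.ft(omega)
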
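"""Discrete space-time sampling grid and its FFT conventions.

The grid owns every discretization convention in the library:

* real space is sampled on an ``n_spatial x n_spatial`` square of side
  ``extent`` degrees, centered so that the analyzed neuron sits at index
  ``n_spatial // 2`` on each axis (coordinate r = 0);
* time is sampled on ``[0, duration)`` ms with ``n_time`` points;
* conjugate frequencies follow standard DFT ordering,
  ``k = 2 pi fftfreq(n, d)``;
* forward/inverse transforms approximate the continuous pair

      F~(k, w) = int F(r, t) exp(-i k.r) exp(+i w t) d2r dt
      F(r, t)  = (2 pi)^-3 int F~ exp(+i k.r) exp(-i w t) d2k dw

  so that ``inverse(forward(x)) == x`` to machine precision.

Note the opposite temporal sign: a drifting grating cos(k_g.r - w_g t)
lands on the (+k_g, +w_g) and (-k_g, -w_g) bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

__all__ = ["SpaceTimeGrid"]


@dataclass(frozen=True)
class SpaceTimeGrid:
    """Sampling grid for (x, y, t) fields and their (kx, ky, omega) conjugates.

    Parameters
    ----------
    n_spatial:
        Points per spatial axis (a power of two keeps the FFTs fast).
    extent:
        Spatial side length in degrees.
    n_time:
        Temporal points.
    duration:
        Total simulated time in ms.
    """

    n_spatial: int = 128
    extent: float = 10.0
    n_time: int = 512
    duration: float = 1000.0

    def __post_init__(self) -> None:
        if self.n_spatial < 2 or self.n_time < 2:
            raise ValueError("grid needs at least 2 points per axis")
        if not (self.extent > 0 and self.duration > 0):
            raise ValueError("extent and duration must be positive")

    # -- sampling ---------------------------------------------------------
    @property
    def dx(self) -> float:
        return self.extent / self.n_spatial

    @property
    def dt(self) -> float:
        return self.duration / self.n_time

    @cached_property
    def x(self) -> np.ndarray:
        """Centered spatial coordinates; x[n_spatial // 2] == 0."""
        return (np.arange(self.n_spatial) - self.n_spatial // 2) * self.dx

    @cached_property
    def t(self) -> np.ndarray:
        return np.arange(self.n_time) * self.dt

    @property
    def center_index(self) -> int:
        return self.n_spatial // 2

    # -- conjugate frequencies -------------------------------------------
    @cached_property
    def k(self) -> np.ndarray:
        """Spatial angular frequencies along one axis (rad/deg), DFT order."""
        return 2 * np.pi * np.fft.fftfreq(self.n_spatial, self.dx)

    @cached_property
    def omega(self) -> np.ndarray:
        """Temporal angular frequencies (rad/ms), DFT order."""
        return 2 * np.pi * np.fft.fftfreq(self.n_time, self.dt)

    @cached_property
    def k_mag(self) -> np.ndarray:
        """|k| on the 2-D (kx, ky) grid, DFT order."""
        kx, ky = np.meshgrid(self.k, self.k, indexing="ij")
        return np.hypot(kx, ky)

    @property
    def k_nyquist(self) -> float:
        return np.pi / self.dx

    @property
    def omega_nyquist(self) -> float:
        return np.pi / self.dt

    def spatial_meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.x, self.x, indexing="ij")

    # -- transforms -------------------------------------------------------
    # Spatial axes are (0, 1); time, when present, is axis 2.
    def spatial_ft(self, field: np.ndarray) -> np.ndarray:
        """2-D transform of a centered real-space field, continuous scaling."""
        shifted = np.fft.ifftshift(field, axes=(0, 1))
        return np.fft.fft2(shifted, axes=(0, 1)) * self.dx**2

    def spatial_ift(self, field_ft: np.ndarray) -> np.ndarray:
        out = np.fft.ifft2(field_ft, axes=(0, 1)) / self.dx**2
        return np.fft.fftshift(out, axes=(0, 1))

    def temporal_ft(self, field: np.ndarray, axis: int = -1) -> np.ndarray:
        """1-D transform with the exp(+i w t) sign; continuous scaling."""
        n = field.shape[axis]
        return np.fft.ifft(field, axis=axis) * n * self.dt

    def temporal_ift(self, field_ft: np.ndarray, axis: int = -1) -> np.ndarray:
        n = field_ft.shape[axis]
        return np.fft.fft(field_ft, axis=axis) / (n * self.dt)

    def ft(self, field: np.ndarray) -> np.ndarray:
        """Full 3-D transform of a field sampled on (x, y, t)."""
        return self.temporal_ft(self.spatial_ft(field), axis=2)

    def ift(self, field_ft: np.ndarray) -> np.ndarray:
        return self.spatial_ift(self.temporal_ift(field_ft, axis=2))

    # -- diagnostics ------------------------------------------------------
    def resolves(self, min_spatial_width: float, min_temporal_scale: float) -> bool:
        """Whether dx <= a_min/2 and dt <= tau_min (kernel resolution rule)."""
        return self.dx <= min_spatial_width / 2 and self.dt <= min_temporal_scale
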
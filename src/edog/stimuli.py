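"""Visual stimuli and their Fourier transforms on a space-time grid.

Four stimulus families are supported: full-field drifting gratings
(analytic transform: a conjugate pair of delta bins), circular patches of
drifting grating (sharp-edged disc mask, numeric FFT), flashing spots
(disc mask times a rectangular time window), and raster movies (arbitrary
grayscale frames, numeric FFT).  A seeded generator produces synthetic
naturalistic movies with a power-law spatial spectrum and AR(1) temporal
correlation, emulating head-camera footage of natural scenes.

Stimulus values are luminance *deviations* from the background (zero mean
for gratings); contrast C scales the amplitude and defaults to 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .grid import SpaceTimeGrid

__all__ = [
    "FullFieldGrating",
    "PatchGrating",
    "FlashingSpot",
    "RasterStimulus",
    "align_wavevector",
    "stimulus_ft",
    "generate_synthetic_movie",
    "disc_mask",
]


def _snap_axis(value: float, step: float, nyquist: float, name: str) -> float:
    """Nearest on-grid frequency; ties break toward the lower magnitude."""
    if abs(value) > nyquist + 1e-12:
        raise ValueError(f"{name} = {value:.4g} beyond Nyquist {nyquist:.4g}")
    lo = np.floor(value / step) * step
    hi = lo + step
    # pick the nearer of the two bracketing grid frequencies
    if abs(value - lo) < abs(hi - value):
        snapped = lo
    elif abs(hi - value) < abs(value - lo):
        snapped = hi
    else:
        snapped = lo if abs(lo) <= abs(hi) else hi
    if abs(snapped) > nyquist:  # clamp exactly-at-Nyquist overshoot
        snapped -= np.sign(snapped) * step
    return float(snapped)


def align_wavevector(k_vec, omega: float, grid: SpaceTimeGrid):
    """Snap (k_vec, omega) to exact DFT grid frequencies.

    Returns ``(k_snapped, omega_snapped, relative_error)`` where the error
    is the Euclidean snap distance relative to the frequency step sizes.
    """
    k_vec = np.asarray(k_vec, dtype=float)
    if k_vec.shape != (2,):
        raise ValueError("k_vec must be a 2-vector (kx, ky)")
    dk = 2 * np.pi / grid.extent
    dw = 2 * np.pi / grid.duration
    kx = _snap_axis(k_vec[0], dk, grid.k_nyquist, "kx")
    ky = _snap_axis(k_vec[1], dk, grid.k_nyquist, "ky")
    w = _snap_axis(omega, dw, grid.omega_nyquist, "omega")
    err = np.sqrt(
        ((kx - k_vec[0]) / dk) ** 2
        + ((ky - k_vec[1]) / dk) ** 2
        + ((w - omega) / dw) ** 2
    )
    return np.array([kx, ky]), w, float(err)


@dataclass(frozen=True)
class FullFieldGrating:
    """Drifting full-field grating C cos(k_g . r - omega_g t)."""

    k_g: tuple[float, float]
    omega_g: float
    contrast: float = 1.0

    def aligned(self, grid: SpaceTimeGrid) -> "FullFieldGrating":
        k, w, _ = align_wavevector(self.k_g, self.omega_g, grid)
        return FullFieldGrating((k[0], k[1]), w, self.contrast)

    def sample(self, grid: SpaceTimeGrid) -> np.ndarray:
        X, Y = grid.spatial_meshgrid()
        phase = (
            self.k_g[0] * X[:, :, None]
            + self.k_g[1] * Y[:, :, None]
            - self.omega_g * grid.t[None, None, :]
        )
        return self.contrast * np.cos(phase)

    def ft(self, grid: SpaceTimeGrid) -> np.ndarray:
        """Analytic transform: C/2 times the grid volume on the two conjugate bins."""
        k, w, err = align_wavevector(self.k_g, self.omega_g, grid)
        if err > 1e-9:
            raise ValueError(
                "grating frequencies are off-grid; call .aligned(grid) first "
                f"(snap error {err:.3g} grid steps)"
            )
        out = np.zeros((grid.n_spatial, grid.n_spatial, grid.n_time), dtype=complex)
        dk = 2 * np.pi / grid.extent
        dw = 2 * np.pi / grid.duration
        ix = int(round(k[0] / dk)) % grid.n_spatial
        iy = int(round(k[1] / dk)) % grid.n_spatial
        it = int(round(w / dw)) % grid.n_time
        volume = grid.extent**2 * grid.duration
        out[ix, iy, it] += self.contrast / 2 * volume
        out[-ix % grid.n_spatial, -iy % grid.n_spatial, -it % grid.n_time] += (
            self.contrast / 2 * volume
        )
        return out


def disc_mask(grid: SpaceTimeGrid, diameter: float) -> np.ndarray:
    """Sharp-edged circular mask: a pixel belongs to the spot iff its center
    lies within diameter/2 of the grid center (no anti-aliasing)."""
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    X, Y = grid.spatial_meshgrid()
    return (X**2 + Y**2 <= (diameter / 2) ** 2).astype(float)


@dataclass(frozen=True)
class PatchGrating:
    """Circular patch of drifting grating, concentric with the analyzed neuron.

    S(r, t) = C cos(k_pg . r - omega_pg t) for |r| <= d_pg / 2, else 0.

    The cosine has its maximum at the patch center (phase 0 at r = 0).  A
    static spot is the special case k_pg = omega_pg = 0.
    """

    k_pg: tuple[float, float] = (0.0, 0.0)
    omega_pg: float = 0.0
    d_pg: float = 1.0
    contrast: float = 1.0

    def __post_init__(self) -> None:
        if not self.d_pg > 0:
            raise ValueError("patch diameter must be positive")

    @property
    def is_static(self) -> bool:
        return self.omega_pg == 0.0

    def sample_spatial(self, grid: SpaceTimeGrid) -> np.ndarray:
        """Spatial frame at t = 0 (the cosine at phase 0)."""
        X, Y = grid.spatial_meshgrid()
        wave = np.cos(self.k_pg[0] * X + self.k_pg[1] * Y)
        return self.contrast * wave * disc_mask(grid, self.d_pg)

    def sample(self, grid: SpaceTimeGrid) -> np.ndarray:
        X, Y = grid.spatial_meshgrid()
        phase = (
            self.k_pg[0] * X[:, :, None]
            + self.k_pg[1] * Y[:, :, None]
            - self.omega_pg * grid.t[None, None, :]
        )
        mask = disc_mask(grid, self.d_pg)
        return self.contrast * np.cos(phase) * mask[:, :, None]

    def ft(self, grid: SpaceTimeGrid) -> np.ndarray:
        return grid.ft(self.sample(grid))


@dataclass(frozen=True)
class FlashingSpot:
    """Bright disc flashed on at ``onset`` for ``on_duration`` ms."""

    diameter: float
    onset: float = 0.0
    on_duration: float = 100.0
    contrast: float = 1.0

    def __post_init__(self) -> None:
        if not self.diameter > 0:
            raise ValueError("diameter must be positive")
        if self.on_duration <= 0:
            raise ValueError("on_duration must be positive")

    def sample(self, grid: SpaceTimeGrid) -> np.ndarray:
        window = (grid.t >= self.onset) & (grid.t < self.onset + self.on_duration)
        mask = disc_mask(grid, self.diameter)
        return self.contrast * mask[:, :, None] * window[None, None, :].astype(float)

    def ft(self, grid: SpaceTimeGrid) -> np.ndarray:
        return grid.ft(self.sample(grid))


@dataclass(frozen=True)
class RasterStimulus:
    """Grayscale movie given as a raw (x, y, t) array of luminance deviations.

    ``pixel_size`` is in degrees and ``frame_interval`` in ms; they must
    match the grid the stimulus is evaluated on.  A 2-D array is treated as
    a static image.
    """

    frames: np.ndarray
    pixel_size: float
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        if frames.ndim not in (2, 3):
            raise ValueError("frames must be a 2-D image or a 3-D (x, y, t) array")
        object.__setattr__(self, "frames", frames)

    @property
    def is_static(self) -> bool:
        return self.frames.ndim == 2

    def _check_grid(self, grid: SpaceTimeGrid) -> None:
        shape = self.frames.shape
        if shape[0] != grid.n_spatial or shape[1] != grid.n_spatial:
            raise ValueError(
                f"raster shape {shape[:2]} does not match grid "
                f"({grid.n_spatial}, {grid.n_spatial})"
            )
        if not np.isclose(self.pixel_size, grid.dx, rtol=1e-6):
            raise ValueError(
                f"pixel size {self.pixel_size} deg does not match grid dx {grid.dx} deg"
            )
        if not self.is_static:
            if shape[2] != grid.n_time:
                raise ValueError(
                    f"{shape[2]} frames do not match grid n_time {grid.n_time}"
                )
            if not np.isclose(self.frame_interval, grid.dt, rtol=1e-6):
                raise ValueError(
                    f"frame interval {self.frame_interval} ms does not match "
                    f"grid dt {grid.dt} ms"
                )

    def sample(self, grid: SpaceTimeGrid) -> np.ndarray:
        self._check_grid(grid)
        return self.frames

    def ft(self, grid: SpaceTimeGrid) -> np.ndarray:
        self._check_grid(grid)
        if self.is_static:
            return grid.spatial_ft(self.frames)
        return grid.ft(self.frames)


Stimulus = FullFieldGrating | PatchGrating | FlashingSpot | RasterStimulus


def stimulus_ft(stimulus: Stimulus, grid: SpaceTimeGrid) -> np.ndarray:
    """Fourier transform of any stimulus on the grid (3-D, or 2-D if static)."""
    return stimulus.ft(grid)


def _powerlaw_field(rng: np.random.Generator, grid: SpaceTimeGrid,
                    exponent: float) -> np.ndarray:
    """One zero-mean spatial field with amplitude spectrum ~ |k|^(-exponent/2),
    i.e. power spectrum ~ |k|^(-exponent)."""
    white = rng.standard_normal((grid.n_spatial, grid.n_spatial))
    spec = np.fft.fft2(white)
    k = grid.k_mag.copy()
    k[0, 0] = 1.0
    spec *= k ** (-exponent / 2.0)
    spec[0, 0] = 0.0  # zero mean
    field = np.real(np.fft.ifft2(spec))
    return field / field.std()


def generate_synthetic_movie(
    seed: int,
    grid: SpaceTimeGrid,
    n_frames: int | None = None,
    spatial_exponent: float = 2.0,
    temporal_correlation: float = 0.9,
) -> RasterStimulus:
    """Seeded synthetic naturalistic movie.

    Frames are zero-mean grayscale fields with a radially averaged power
    spectrum ~ |k|^(-spatial_exponent) (natural scenes are close to
    exponent 2) evolving as a stationary AR(1) process with lag-1
    autocorrelation ``temporal_correlation`` per frame, mimicking the
    strong frame-to-frame correlation of head-camera footage.
    """
    if n_frames is None:
        n_frames = grid.n_time
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if not abs(temporal_correlation) < 1:
        raise ValueError("|temporal_correlation| must be < 1")
    if spatial_exponent < 0:
        raise ValueError("spatial_exponent must be >= 0")
    rng = np.random.default_rng(seed)
    rho = temporal_correlation
    frames = np.empty((grid.n_spatial, grid.n_spatial, n_frames))
    frames[:, :, 0] = _powerlaw_field(rng, grid, spatial_exponent)
    innovation_scale = np.sqrt(1.0 - rho**2)
    for i in range(1, n_frames):
        frames[:, :, i] = rho * frames[:, :, i - 1] + innovation_scale * _powerlaw_field(
            rng, grid, spatial_exponent
        )
    return RasterStimulus(frames, pixel_size=grid.dx, frame_interval=grid.dt)


def raster_from_images(paths: Sequence[str], pixel_size: float,
                       frame_interval: float = 1.0,
                       subtract_mean: bool = True) -> RasterStimulus:
    """Load a grayscale image sequence (PNG/TIFF) as a raster stimulus."""
    import imageio.v3 as iio

    frames = []
    for p in paths:
        img = np.asarray(iio.imread(p), dtype=float)
        if img.ndim == 3:  # collapse color channels
            img = img.mean(axis=2)
        frames.append(img)
    stack = np.stack(frames, axis=-1)
    if stack.shape[-1] == 1:
        stack = stack[:, :, 0]
    if subtract_mean:
        stack = stack - stack.mean()
    return RasterStimulus(stack, pixel_size, frame_interval)
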
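"""YAML run-configuration schema (pydantic-validated).

A configuration file fully specifies a reproducible run: the space-time
grid, every circuit kernel (defaults are the standard cat parameters),
an optional stimulus block, and per-command measure settings.  Unknown
keys are rejected; weight signs are validated against each connection's
excitatory/inhibitory role.
"""

from __future__ import annotations

from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import circuit as _circuit
from .grid import SpaceTimeGrid
from .kernels import (
    BiphasicTemporal,
    DelayedExponential,
    DOGSpatial,
    GaussianSpatial,
    SeparableKernel,
)

__all__ = ["RunConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GridConfig(_Strict):
    n_spatial: int = 128
    extent: float = 10.0
    n_time: int = 512
    duration: float = 1000.0

    def build(self) -> SpaceTimeGrid:
        return SpaceTimeGrid(self.n_spatial, self.extent, self.n_time, self.duration)


class RetinalConfig(_Strict):
    """DOG spatial part and biphasic temporal part of the retinal input."""

    A: float = 1.0
    a: float = 0.62
    B: float = 0.85
    b: float = 1.26
    tau_phase: float = 42.5
    B_second: float = 0.38

    def build(self) -> SeparableKernel:
        return SeparableKernel(
            1.0,
            DOGSpatial(self.A, self.a, self.B, self.b),
            BiphasicTemporal(self.tau_phase, self.B_second),
        )


class CouplingConfig(_Strict):
    """Gaussian x delayed-exponential coupling kernel."""

    weight: float
    a: float
    delta: float = 0.0
    tau: float = 5.0

    def build(self) -> SeparableKernel:
        return SeparableKernel(
            self.weight, GaussianSpatial(self.a), DelayedExponential(self.delta, self.tau)
        )


class CircuitConfig(_Strict):
    retinal: RetinalConfig = RetinalConfig()
    ff_excitation: CouplingConfig = CouplingConfig(weight=1.0, a=0.1, delta=0.0)
    ff_inhibition: Optional[CouplingConfig] = CouplingConfig(weight=-0.5, a=0.3, delta=3.0)
    feedback: list[CouplingConfig] = Field(default_factory=list)

    @field_validator("ff_excitation")
    @classmethod
    def _excitatory(cls, v: CouplingConfig) -> CouplingConfig:
        if v.weight <= 0:
            raise ValueError("ff_excitation.weight must be positive (excitatory)")
        return v

    @field_validator("ff_inhibition")
    @classmethod
    def _inhibitory(cls, v: Optional[CouplingConfig]) -> Optional[CouplingConfig]:
        if v is not None and v.weight >= 0:
            raise ValueError("ff_inhibition.weight must be negative (inhibitory)")
        return v

    def build(self) -> _circuit.Circuit:
        return _circuit.Circuit(
            retinal_irf=self.retinal.build(),
            ff_excitation=self.ff_excitation.build(),
            ff_inhibition=None if self.ff_inhibition is None else self.ff_inhibition.build(),
            feedback_terms=tuple(term.build() for term in self.feedback),
        )


class StimulusConfig(_Strict):
    type: Literal["full_field_grating", "patch_grating", "flashing_spot"] = "patch_grating"
    k: float = 0.0
    omega: float = 0.0
    diameter: float = 2.0
    contrast: float = 1.0
    onset: float = 0.0
    on_duration: float = 100.0

    def build(self, grid: SpaceTimeGrid):
        from . import stimuli

        if self.type == "full_field_grating":
            return stimuli.FullFieldGrating(
                (self.k, 0.0), self.omega, self.contrast
            ).aligned(grid)
        if self.type == "patch_grating":
            return stimuli.PatchGrating(
                (self.k, 0.0), self.omega, self.diameter, self.contrast
            )
        return stimuli.FlashingSpot(
            self.diameter, self.onset, self.on_duration, self.contrast
        )


class AreaResponseConfig(_Strict):
    kind: Literal["static_spot", "patch_grating", "flashing_spot"] = "static_spot"
    k: float = 0.0
    diameters: list[float] = Field(
        default_factory=lambda: [round(0.2 * i, 2) for i in range(1, 25)]
    )


class TuningConfig(_Strict):
    kind: Literal["spatial", "temporal"] = "spatial"
    diameter: float = 10.0
    k: float = 1.0
    frequencies: list[float] = Field(
        default_factory=lambda: [round(0.05 * i, 3) for i in range(41)]
    )


class AutocorrConfig(_Strict):
    window: int = 40
    max_lag: int = 50
    n_frames: Optional[int] = None
    spatial_exponent: float = 2.0
    temporal_correlation: float = 0.9


class RunConfig(_Strict):
    grid: GridConfig = GridConfig()
    circuit: CircuitConfig = CircuitConfig()
    stimulus: StimulusConfig = StimulusConfig()
    area_response: AreaResponseConfig = AreaResponseConfig()
    tuning: TuningConfig = TuningConfig()
    autocorr: AutocorrConfig = AutocorrConfig()
    seed: int = 0


def load_config(path) -> RunConfig:
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    return RunConfig.model_validate(raw)
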
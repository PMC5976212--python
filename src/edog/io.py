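"""Result export: HDF5 fields with axis metadata, CSV curves, JSON scalars."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .grid import SpaceTimeGrid

__all__ = ["save_field_h5", "load_field_h5", "save_scalars_json"]


def save_field_h5(path, values: np.ndarray, grid: SpaceTimeGrid,
                  name: str = "field", attrs: dict | None = None) -> None:
    """Write a real-space field with (deg, deg[, ms]) axis annotations."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        dset = f.create_dataset(name, data=values)
        dset.attrs["axis0"] = "x [deg]"
        dset.attrs["axis1"] = "y [deg]"
        f.create_dataset("x_deg", data=grid.x)
        if values.ndim == 3:
            dset.attrs["axis2"] = "t [ms]"
            f.create_dataset("t_ms", data=grid.t)
        for key, val in (attrs or {}).items():
            dset.attrs[key] = val


def load_field_h5(path, name: str = "field") -> np.ndarray:
    with h5py.File(path, "r") as f:
        return f[name][()]


def save_scalars_json(path, scalars: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _coerce(v):
        if isinstance(v, (np.floating, np.integer)):
            return v.item()
        return v

    path.write_text(json.dumps({k: _coerce(v) for k, v in scalars.items()},
                               indent=2, sort_keys=True) + "\n")
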
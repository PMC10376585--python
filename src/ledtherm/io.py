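"""Hierarchical field snapshots and delimited metric tables.

Temperature fields are stored in HDF5 together with the grid geometry and
the run provenance, so a snapshot is self-describing; summary/probe series
go to plain CSV via pandas.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .grid import SimulationGrid
from .solver import TemperatureField


def save_field(path, field: TemperatureField, provenance: dict | None = None) -> None:
    """Write a temperature field (K) plus grid metadata to an HDF5 file."""
    grid = field.grid
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("temperature_K", data=field.values)
        ds.attrs["time_s"] = field.time
        g = fh.create_group("grid")
        g.attrs["nx"], g.attrs["ny"] = grid.nx, grid.ny
        g.attrs["dx_m"], g.attrs["dy_m"] = grid.dx, grid.dy
        g.create_dataset("z_edges_m", data=grid.z_edges)
        if provenance is not None:
            fh.attrs["provenance_json"] = json.dumps(provenance, default=str)


def load_field(path) -> tuple[TemperatureField, dict | None]:
    """Read a field snapshot; returns (field, provenance or None)."""
    with h5py.File(path, "r") as fh:
        values = np.asarray(fh["temperature_K"])
        time = float(fh["temperature_K"].attrs["time_s"])
        g = fh["grid"]
        grid = SimulationGrid(
            int(g.attrs["nx"]), int(g.attrs["ny"]),
            float(g.attrs["dx_m"]), float(g.attrs["dy_m"]),
            np.asarray(g["z_edges_m"]),
        )
        prov = fh.attrs.get("provenance_json")
    return TemperatureField(values, time, grid), (json.loads(prov) if prov else None)
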
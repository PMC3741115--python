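"""Run artifacts: HDF5 field snapshots, CSV traces and the JSON manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .engine import Trajectory
from .params import SimulationParams

__all__ = ["params_to_dict", "params_hash", "write_snapshots",
           "write_trace", "write_manifest", "read_snapshot"]


def params_to_dict(params: SimulationParams) -> dict:
    d = dataclasses.asdict(params)
    d["grid"]["shape"] = list(d["grid"]["shape"])
    return d


def params_hash(params: SimulationParams) -> str:
    blob = json.dumps(params_to_dict(params), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_snapshots(path, trajectory: Trajectory, params: SimulationParams,
                    seed) -> None:
    """One HDF5 dataset per stored field, with time/seed/params-hash attrs."""
    with h5py.File(path, "w") as fh:
        fh.attrs["params_hash"] = params_hash(params)
        fh.attrs["seed"] = str(seed)
        fh.attrs["units"] = "nM (extracellular water)"
        for t, snap in zip(trajectory.snapshot_times, trajectory.snapshots):
            ds = fh.create_dataset(f"concentration/t={t:.4f}", data=snap.values)
            ds.attrs["time_s"] = float(t)
            ds.attrs["spacing_um"] = params.grid.spacing


def read_snapshot(path, time: float) -> np.ndarray:
    with h5py.File(path, "r") as fh:
        return fh[f"concentration/t={time:.4f}"][()]


def write_trace(path, trajectory: Trajectory) -> None:
    pd.DataFrame({
        "time_s": trajectory.trace_time,
        "volume_mean_nM": trajectory.trace_mean,
        "injected_mol": trajectory.trace_injected_mol,
        "uptaken_mol": trajectory.trace_uptaken_mol,
    }).to_csv(path, index=False)


def write_manifest(path, params: SimulationParams, protocol, seed) -> None:
    manifest = {
        "package": "dopadiff",
        "version": __version__,
        "seed": seed,
        "params": params_to_dict(params),
        "params_hash": params_hash(params),
        "protocol": dataclasses.asdict(protocol) if protocol is not None else None,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))
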
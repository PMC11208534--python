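"""File formats: spikes, tracking, profiles, barcodes, coordinates.

Conventions: time in seconds, positions in cm, angles in radians, intervals
half-open.  Spikes: CSV with columns (neuron_id, t) or HDF5 with one
dataset per neuron under /spikes/<id>.  Tracking: CSV (t, x, y, hd).
Barcodes are JSON; decoded coordinates CSV (t, theta1, theta2[, theta3]).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import h5py
import numpy as np
import pandas as pd
import yaml

from .coordinatize import ToroidalCoordinates
from .preprocess import ParameterProfile, SpikeTrainSet
from .sim import SimOutput, TrajectorySample
from .topology import Barcode, PersistenceBar

__all__ = [
    "read_spikes",
    "write_spikes",
    "read_tracking",
    "write_tracking",
    "read_profile",
    "write_profile",
    "write_barcode",
    "read_barcode",
    "write_coords",
    "read_coords",
    "write_sim_output",
]


def read_spikes(path: Union[str, Path]) -> SpikeTrainSet:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            if "spikes" not in f:
                raise ValueError(f"{path}: missing /spikes group")
            ids = sorted(f["spikes"].keys(), key=lambda s: (len(s), s))
            trains = [np.asarray(f["spikes"][k][...], dtype=float) for k in ids]
        tmax = max((t[-1] for t in trains if t.size), default=0.0)
        return SpikeTrainSet(trains, span=(0.0, tmax), neuron_ids=ids)
    df = pd.read_csv(path)
    for col in ("neuron_id", "t"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    bad = df[~np.isfinite(df["t"])]
    if len(bad):
        raise ValueError(f"{path}: non-finite time at row {bad.index[0]}")
    ids = sorted(df["neuron_id"].unique().tolist())
    trains = [np.sort(df.loc[df["neuron_id"] == i, "t"].to_numpy()) for i in ids]
    tmax = max((t[-1] for t in trains if t.size), default=0.0)
    return SpikeTrainSet(trains, span=(0.0, float(tmax)), neuron_ids=ids)


def write_spikes(spikes: SpikeTrainSet, path: Union[str, Path]):
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            g = f.create_group("spikes")
            for i, t in zip(spikes.neuron_ids, spikes.spikes):
                g.create_dataset(str(i), data=t)
        return
    rows = [
        {"neuron_id": i, "t": tt}
        for i, t in zip(spikes.neuron_ids, spikes.spikes)
        for tt in t
    ]
    pd.DataFrame(rows, columns=["neuron_id", "t"]).to_csv(path, index=False)


def read_tracking(path: Union[str, Path]) -> TrajectorySample:
    df = pd.read_csv(path)
    for col in ("t", "x", "y"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    traj = TrajectorySample.from_positions(
        df["t"].to_numpy(), df["x"].to_numpy(), df["y"].to_numpy()
    )
    if "hd" in df.columns:
        traj.heading = df["hd"].to_numpy(dtype=float)
    return traj


def write_tracking(traj: TrajectorySample, path: Union[str, Path]):
    pd.DataFrame(
        {"t": traj.t, "x": traj.x, "y": traj.y, "hd": traj.heading}
    ).to_csv(path, index=False)


def read_profile(path: Union[str, Path]) -> ParameterProfile:
    with open(path) as f:
        data = yaml.safe_load(f) or {}
    known = set(ParameterProfile.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"{path}: unknown profile fields {sorted(unknown)}")
    return ParameterProfile(**data)


def write_profile(profile: ParameterProfile, path: Union[str, Path]):
    with open(path, "w") as f:
        yaml.safe_dump(vars(profile), f)


def write_barcode(barcode: Barcode, path: Union[str, Path]):
    Path(path).write_text(barcode.to_json())


def read_barcode(path: Union[str, Path]) -> Barcode:
    data = json.loads(Path(path).read_text())
    bars = [
        PersistenceBar(
            dim=b["dim"],
            birth=b["birth"],
            death=np.inf if b["death"] is None else b["death"],
        )
        for b in data["bars"]
    ]
    return Barcode(
        bars=bars,
        metric=data["metric"],
        prime=data["prime"],
        thresholds={int(k): v for k, v in data.get("thresholds", {}).items()},
    )


def write_coords(coords: ToroidalCoordinates, path: Union[str, Path]):
    cols = {"t": coords.times if coords.times is not None else np.arange(len(coords.angles))}
    for d in range(coords.n_dims):
        cols[f"theta{d + 1}"] = coords.angles[:, d]
    cols["valid"] = coords.valid.astype(int)
    pd.DataFrame(cols).to_csv(path, index=False)


def read_coords(path: Union[str, Path]) -> ToroidalCoordinates:
    df = pd.read_csv(path)
    dims = [c for c in df.columns if c.startswith("theta")]
    if not dims:
        raise ValueError(f"{path}: no theta columns found")
    return ToroidalCoordinates(
        angles=df[dims].to_numpy(),
        valid=df["valid"].to_numpy(dtype=bool) if "valid" in df else None,
        times=df["t"].to_numpy() if "t" in df else None,
    )


def write_sim_output(out: SimOutput, prefix: Union[str, Path]):
    """Save simulated rates (HDF5) and tracking (CSV) as pipeline inputs."""
    prefix = Path(prefix)
    with h5py.File(prefix.with_suffix(".h5"), "w") as f:
        f.create_dataset("rates", data=out.rates.values)
        f.create_dataset("times", data=out.rates.times)
        f.create_dataset("unit_phases", data=out.unit_phases)
        if out.bump_phases is not None:
            f.create_dataset("bump_phases", data=out.bump_phases)
        f.attrs["dt"] = out.rates.dt
    write_tracking(out.trajectory, prefix.with_suffix(".csv"))
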
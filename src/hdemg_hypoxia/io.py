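"""File interfaces: HDF5 / delimited EMG containers, ground-truth sidecars,
spike-train and response tables, YAML configs."""

from __future__ import annotations

import os
from typing import Union

import numpy as np
import pandas as pd
import yaml

from .core import DischargeTrain, EMGRecording, GridGeometry

__all__ = [
    "save_recording_h5",
    "load_recording_h5",
    "save_recording_csv",
    "load_recording_csv",
    "save_ground_truth",
    "load_ground_truth",
    "save_spike_table",
    "load_spike_table",
    "load_config",
    "save_config",
]

_PathLike = Union[str, os.PathLike]


def save_recording_h5(path: _PathLike, recordings: dict[str, EMGRecording]) -> None:
    """Write recordings as one HDF5 dataset per contraction.

    Attributes per dataset: fs (Hz), ied (mm), rows, cols, units, t0 (s).
    """
    import h5py

    with h5py.File(path, "w") as f:
        for name, rec in recordings.items():
            ds = f.create_dataset(name, data=rec.signal)
            g = rec.geometry
            ds.attrs.update(
                fs=g.fs, ied=g.ied, rows=g.n_rows, cols=g.n_cols, units="uV", t0=rec.t0
            )


def load_recording_h5(path: _PathLike) -> dict[str, EMGRecording]:
    import h5py

    out = {}
    with h5py.File(path, "r") as f:
        for name, ds in f.items():
            a = ds.attrs
            geom = GridGeometry(
                n_rows=int(a["rows"]), n_cols=int(a["cols"]), ied=float(a["ied"]), fs=float(a["fs"])
            )
            out[name] = EMGRecording(
                signal=np.asarray(ds), geometry=geom, t0=float(a.get("t0", 0.0))
            )
    return out


def save_recording_csv(path: _PathLike, rec: EMGRecording) -> None:
    """One column per channel, header row of r{row}c{col} labels."""
    df = pd.DataFrame(rec.signal.T, columns=rec.labels())
    df.to_csv(path, index=False)


def load_recording_csv(path: _PathLike, geometry: GridGeometry, t0: float = 0.0) -> EMGRecording:
    df = pd.read_csv(path)
    expected = geometry.channel_labels()
    if list(df.columns) != expected:
        raise ValueError("channel labels do not match the declared geometry")
    return EMGRecording(signal=df.to_numpy().T, geometry=geometry, t0=t0)


def save_ground_truth(path: _PathLike, specs, trains_per_contraction) -> None:
    """Ground-truth sidecar: one row per MU per contraction with its spec
    and discharge times (seconds, ';'-joined)."""
    rows = []
    for ci, trains in enumerate(trains_per_contraction):
        for spec, tr in zip(specs, trains):
            rows.append(
                {
                    "contraction": ci + 1,
                    "mu_id": spec.mu_id,
                    "mean_dr": spec.mean_dr,
                    "isi_cv": spec.isi_cv,
                    "cv_true": spec.cv_true,
                    "iz_row": spec.iz_row,
                    "amp": spec.amp,
                    "discharge_times_s": ";".join(f"{t:.6f}" for t in tr.times_s),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def load_ground_truth(path: _PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["discharge_times_s"] = df["discharge_times_s"].map(
        lambda s: np.array([float(v) for v in str(s).split(";")]) if s else np.array([])
    )
    return df


def save_spike_table(path: _PathLike, trains: list[DischargeTrain]) -> None:
    """Per-session delimited spike-train table: mu_id, time_s, pnr_db."""
    rows = []
    for tr in trains:
        for t in tr.times_s:
            rows.append({"mu_id": tr.mu_id, "time_s": t, "pnr_db": tr.pnr})
    pd.DataFrame(rows).to_csv(path, index=False)


def load_spike_table(path: _PathLike, fs: float) -> list[DischargeTrain]:
    df = pd.read_csv(path)
    trains = []
    for mu_id, sub in df.groupby("mu_id"):
        times = sub["time_s"].to_numpy() * fs
        pnr = sub["pnr_db"].iloc[0]
        trains.append(
            DischargeTrain(
                times=np.sort(times),
                fs=fs,
                pnr=None if pd.isna(pnr) else float(pnr),
                mu_id=str(mu_id),
            )
        )
    return trains


def load_config(path: _PathLike) -> dict:
    with open(path) as f:
        return yaml.safe_load(f)


def save_config(path: _PathLike, config: dict) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(config, f, sort_keys=False)
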
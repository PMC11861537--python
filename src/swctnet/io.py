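"""Reading and writing the package's on-disk formats.

Two interchangeable containers for a :class:`~swctnet.preprocess.RawRecording`:

* delimited text — CSV with a header row of channel names and the
  timestamp (seconds) as the first column;
* columnar binary — HDF5 with datasets ``/data`` (channels x samples)
  and ``/timestamps`` and root attributes ``fs`` and ``modality``.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .preprocess import RawRecording

__all__ = [
    "save_recording_csv", "load_recording_csv",
    "save_recording_hdf5", "load_recording_hdf5",
    "save_feature_table", "load_feature_table",
    "write_json", "read_json",
]


def save_recording_csv(rec: RawRecording, path: str | Path) -> None:
    df = pd.DataFrame(rec.data.T, columns=rec.channel_names)
    df.insert(0, "timestamp", rec.timestamps)
    df.to_csv(path, index=False)


def load_recording_csv(path: str | Path, fs: float, modality: str) -> RawRecording:
    df = pd.read_csv(path)
    if df.columns[0] != "timestamp":
        raise ValueError("first CSV column must be 'timestamp'")
    return RawRecording(
        data=df.iloc[:, 1:].to_numpy().T,
        fs=fs,
        timestamps=df["timestamp"].to_numpy(),
        channel_names=list(df.columns[1:]),
        modality=modality,
    )


def save_recording_hdf5(rec: RawRecording, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        # track_times=False keeps files byte-identical across reruns
        f.create_dataset("data", data=rec.data, track_times=False)
        f.create_dataset("timestamps", data=rec.timestamps, track_times=False)
        f.attrs["fs"] = rec.fs
        f.attrs["modality"] = rec.modality
        f.attrs["channel_names"] = [str(c) for c in rec.channel_names]


def load_recording_hdf5(path: str | Path) -> RawRecording:
    with h5py.File(path, "r") as f:
        return RawRecording(
            data=f["data"][...],
            fs=float(f.attrs["fs"]),
            timestamps=f["timestamps"][...],
            channel_names=[str(c) for c in f.attrs["channel_names"]],
            modality=str(f.attrs["modality"]),
        )


def save_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def load_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_coerce))


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _coerce(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
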
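"""Containers and on-disk formats.

Arrays live in HDF5 files (one dataset per array, scalar attributes for
metadata), tables in RFC-4180 CSV with a header row, and run manifests in
JSON.  Nothing here touches the network.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

TRIAL_COLUMNS = ["subject", "condition", "block", "onset_sample", "S", "Y"]


@dataclasses.dataclass
class ParcelTimeSeries:
    """Parcel-level recording: ``data`` is channels x samples at ``fs`` Hz."""

    data: np.ndarray
    fs: float
    subject: str = "s00"
    condition: str = "none"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (parcels x samples)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_parcels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            dset = f.create_dataset("data", data=self.data)
            dset.attrs["fs"] = self.fs
            dset.attrs["subject"] = self.subject
            dset.attrs["condition"] = self.condition

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "ParcelTimeSeries":
        with h5py.File(path, "r") as f:
            dset = f["data"]
            return cls(
                data=dset[()],
                fs=float(dset.attrs["fs"]),
                subject=str(dset.attrs.get("subject", "s00")),
                condition=str(dset.attrs.get("condition", "none")),
            )


def write_trial_table(trials: pd.DataFrame, path: str | Path) -> None:
    """Write a trial table as CSV with the canonical column order."""
    cols = [c for c in TRIAL_COLUMNS if c in trials.columns]
    cols += [c for c in trials.columns if c not in cols]
    trials.to_csv(path, index=False, columns=cols, lineterminator="\r\n")


def read_trial_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trial table not found: {path}")
    return pd.read_csv(path)


def write_arrays(path: str | Path, attrs: dict | None = None, **arrays) -> None:
    """Write named arrays to one HDF5 file, with optional root attributes."""
    with h5py.File(path, "w") as f:
        for name, arr in arrays.items():
            f.create_dataset(name, data=np.asarray(arr))
        for key, val in (attrs or {}).items():
            f.attrs[key] = val


def read_arrays(path: str | Path) -> dict:
    out: dict = {}
    with h5py.File(path, "r") as f:
        for name in f:
            out[name] = f[name][()]
        out["__attrs__"] = dict(f.attrs)
    return out


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
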
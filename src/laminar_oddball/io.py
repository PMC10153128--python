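"""HDF5 container I/O for recordings and event tables.

Layout::

    /lfp        float32 dataset, contacts x samples (uV)
    /events     compound table: onset_sample, orientation_deg, context, run,
                duration_samples
    attrs       fs_hz, subject_id, pitch_um, n_contacts

The container holds the raw (pre-filtering) voltage; "lfp" names the dataset
for compatibility with the field's habit of calling wideband laminar voltage
LFP.  Events are also exportable as CSV with identical column names.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import EVENT_COLUMNS, EventTable, ProbeGeometry, Recording
from .errors import FormatError

_EVENT_DTYPE = np.dtype(
    [
        ("onset_sample", "<i8"),
        ("orientation_deg", "<i8"),
        ("context", "S16"),
        ("run", "S16"),
        ("duration_samples", "<i8"),
    ]
)


def write_recording(rec: Recording, events: EventTable, path: str | Path) -> None:
    """Validate then write a recording + events to the HDF5 container."""
    rec.validate()
    events.validate()
    path = Path(path)
    arr = np.zeros(len(events.df), dtype=_EVENT_DTYPE)
    for col in EVENT_COLUMNS:
        vals = events.df[col].to_numpy()
        if _EVENT_DTYPE[col].kind == "S":
            vals = np.array([str(v).encode() for v in vals])
        arr[col] = vals
    with h5py.File(path, "w") as f:
        f.create_dataset("lfp", data=rec.signal.astype(np.float32))
        f.create_dataset("events", data=arr)
        f.attrs["fs_hz"] = float(rec.fs)
        f.attrs["subject_id"] = rec.subject_id
        f.attrs["pitch_um"] = float(rec.geometry.pitch_um)
        f.attrs["n_contacts"] = int(rec.geometry.n_contacts)


def read_recording(path: str | Path) -> tuple[Recording, EventTable]:
    """Read a recording + events; round-trips exactly with write_recording."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        missing = [name for name in ("lfp", "events") if name not in f]
        if missing:
            raise FormatError(f"{path.name}: missing dataset(s) {missing}")
        missing_attrs = [
            a for a in ("fs_hz", "subject_id", "pitch_um", "n_contacts")
            if a not in f.attrs
        ]
        if missing_attrs:
            raise FormatError(f"{path.name}: missing attribute(s) {missing_attrs}")
        fs = float(f.attrs["fs_hz"])
        if fs <= 0:
            raise FormatError(f"{path.name}: fs_hz must be > 0, got {fs}")
        signal = f["lfp"][()]
        raw = f["events"][()]
        geometry = ProbeGeometry(
            n_contacts=int(f.attrs["n_contacts"]), pitch_um=float(f.attrs["pitch_um"])
        )
        subject_id = str(f.attrs["subject_id"])
    df = pd.DataFrame(
        {
            "onset_sample": raw["onset_sample"],
            "orientation_deg": raw["orientation_deg"],
            "context": [b.decode() for b in raw["context"]],
            "run": [b.decode() for b in raw["run"]],
            "duration_samples": raw["duration_samples"],
        }
    )
    rec = Recording(signal=signal, fs=fs, geometry=geometry, subject_id=subject_id)
    return rec.validate(), EventTable(df)
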
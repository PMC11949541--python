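"""Readers and writers: EDF (via MNE), HDF5 containers, delimited text.

HDF5 is the native results format: a ``data`` (or ``values``) dataset plus
attributes carrying the sampling rate, labels and stage parameters.
Delimited text stores the bare channels x samples matrix, so the sampling
rate must be supplied on load.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .recording import Recording

__all__ = ["load_recording", "save_recording", "save_matrix", "load_matrix"]

_DELIMITED = {".csv": ",", ".tsv": "\t", ".txt": None}


def _detect_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".edf":
        return "edf"
    if suffix in (".h5", ".hdf5"):
        return "hdf5"
    if suffix in _DELIMITED:
        return "delimited"
    raise ValueError(f"cannot infer format from extension {suffix!r}")


def load_recording(
    path: str | Path,
    fmt: str | None = None,
    fs: float | None = None,
    condition: str | None = None,
) -> Recording:
    """Load a channels x samples recording from EDF, HDF5 or delimited text.

    The format is auto-detected from the extension unless ``fmt`` is given.
    Delimited files carry no sampling-rate metadata, so ``fs`` is required
    for them (pass ``--fs`` on the command line).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or _detect_format(path)

    if fmt == "edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        return Recording(
            data=raw.get_data(),
            fs=float(raw.info["sfreq"]),
            channel_labels=list(raw.ch_names),
            condition=condition,
        )
    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            data = np.asarray(f["data"])
            file_fs = f.attrs.get("fs")
            labels = f.attrs.get("channel_labels")
            cond = f.attrs.get("condition")
        if fs is None:
            if file_fs is None:
                raise ValueError(f"{path} has no 'fs' attribute; pass fs explicitly")
            fs = float(file_fs)
        return Recording(
            data=data,
            fs=fs,
            channel_labels=None if labels is None else [str(c) for c in labels],
            condition=condition if condition is not None else (None if cond is None else str(cond)),
        )
    if fmt == "delimited":
        if fs is None:
            raise ValueError(
                "delimited files carry no sampling-rate metadata; --fs is required"
            )
        data = np.loadtxt(path, delimiter=_DELIMITED.get(path.suffix.lower()))
        return Recording(data=np.atleast_2d(data), fs=fs, condition=condition)
    raise ValueError(f"unknown format {fmt!r}")


def save_recording(recording: Recording, path: str | Path) -> Path:
    """Write a recording to HDF5 (preferred) or delimited text."""
    path = Path(path)
    fmt = _detect_format(path)
    if fmt == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=recording.data)
            f.attrs["fs"] = recording.fs
            f.attrs["channel_labels"] = recording.channel_labels
            if recording.condition is not None:
                f.attrs["condition"] = recording.condition
            if recording.artifact_mask is not None:
                f.create_dataset("artifact_mask", data=recording.artifact_mask)
    elif fmt == "delimited":
        np.savetxt(path, recording.data, delimiter=_DELIMITED.get(path.suffix.lower()) or " ")
    else:
        raise ValueError(f"cannot write format {fmt!r} (EDF export not supported)")
    return path


def save_matrix(values: np.ndarray, path: str | Path, **attrs) -> Path:
    """Write a dense matrix (MDF, dFC, ISC, ...) with metadata attributes."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=np.asarray(values))
        for key, val in attrs.items():
            if val is not None:
                f.attrs[key] = val
    return path


def load_matrix(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read back a matrix written by :func:`save_matrix`."""
    with h5py.File(path, "r") as f:
        values = np.asarray(f["values"])
        attrs = {k: f.attrs[k] for k in f.attrs}
    return values, attrs
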
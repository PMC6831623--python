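"""Session I/O: EDF + sidecar event TSV, montage TSV, HDF5 session container."""
from __future__ import annotations

import json
import logging
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from ..core import EVENT_COLUMNS, ElectrodeMontage, Recording
from .edf import read_edf, write_edf

log = logging.getLogger("eegdays.io")

SIDECAR_COLUMNS = ("trial", "rest_onset_s", "stim_onset_s", "stim_end_s", "valence", "arousal")


def write_montage_tsv(montage: ElectrodeMontage, path: str | Path) -> None:
    montage.to_frame().to_csv(path, sep="\t", index=False)


def read_montage_tsv(path: str | Path) -> ElectrodeMontage:
    return ElectrodeMontage.from_frame(pd.read_csv(path, sep="\t"))


def _events_to_sidecar(events: pd.DataFrame, fs: float) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "trial": events["trial"],
            "rest_onset_s": events["rest_onset"] / fs,
            "stim_onset_s": events["stim_onset"] / fs,
            "stim_end_s": events["stim_end"] / fs,
            "valence": events["valence"],
            "arousal": events["arousal"],
        }
    )


def _sidecar_to_events(sidecar: pd.DataFrame, fs: float) -> pd.DataFrame:
    missing = [c for c in SIDECAR_COLUMNS if c not in sidecar.columns]
    if missing:
        raise ValueError(f"sidecar event table missing columns {missing}")
    return pd.DataFrame(
        {
            "trial": sidecar["trial"].astype(int),
            "rest_onset": np.round(sidecar["rest_onset_s"] * fs).astype(int),
            "stim_onset": np.round(sidecar["stim_onset_s"] * fs).astype(int),
            "stim_end": np.round(sidecar["stim_end_s"] * fs).astype(int),
            "valence": sidecar["valence"].astype(int),
            "arousal": sidecar["arousal"].astype(int),
        },
        columns=list(EVENT_COLUMNS),
    )


def write_session(recording: Recording, edf_path: str | Path) -> Path:
    """EDF + sidecar TSV (``<stem>_events.tsv``); returns the sidecar path."""
    edf_path = Path(edf_path)
    write_edf(
        edf_path,
        recording.data,
        recording.fs,
        list(recording.montage.labels),
        recording=f"{recording.subject_id} {recording.session_id}",
    )
    sidecar = edf_path.with_name(edf_path.stem + "_events.tsv")
    _events_to_sidecar(recording.events, recording.fs).to_csv(sidecar, sep="\t", index=False)
    return sidecar


def read_session(
    edf_path: str | Path,
    montage: ElectrodeMontage,
    subject_id: str = "S00",
    session_id: str = "D0",
) -> Recording:
    """Read EDF + sidecar; channels matched to the montage case-insensitively."""
    edf_path = Path(edf_path)
    sidecar = edf_path.with_name(edf_path.stem + "_events.tsv")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar event table {sidecar}")
    data, fs, labels = read_edf(edf_path)
    lower_to_row = {lab.lower(): i for i, lab in enumerate(labels)}
    rows, unmatched = [], []
    for lab in montage.labels:
        row = lower_to_row.get(lab.lower())
        if row is None:
            unmatched.append(lab)
        else:
            rows.append(row)
            if labels[row] != lab:
                log.info("channel label %r matched case-insensitively to montage %r", labels[row], lab)
    if unmatched:
        raise ValueError(f"montage channels not found in EDF: {unmatched}")
    events = _sidecar_to_events(pd.read_csv(sidecar, sep="\t"), fs)
    return Recording(
        data=data[rows],
        fs=fs,
        montage=montage,
        events=events,
        subject_id=subject_id,
        session_id=session_id,
    )


def save_recording_h5(recording: Recording, path: str | Path) -> None:
    """Internal single-file session container (lossless, float64)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=recording.data, compression="gzip", compression_opts=1)
        f.attrs["fs"] = recording.fs
        f.attrs["subject_id"] = recording.subject_id
        f.attrs["session_id"] = recording.session_id
        f.create_dataset("montage/positions", data=recording.montage.positions)
        f.create_dataset(
            "montage/labels",
            data=np.array([l.encode() for l in recording.montage.labels]),
        )
        ev = recording.events
        for col in EVENT_COLUMNS:
            f.create_dataset(f"events/{col}", data=ev[col].to_numpy())


def load_recording_h5(path: str | Path) -> Recording:
    with h5py.File(path, "r") as f:
        montage = ElectrodeMontage(
            labels=tuple(l.decode() for l in f["montage/labels"][()]),
            positions=f["montage/positions"][()],
        )
        events = pd.DataFrame({col: f[f"events/{col}"][()] for col in EVENT_COLUMNS})
        return Recording(
            data=f["data"][()],
            fs=float(f.attrs["fs"]),
            montage=montage,
            events=events,
            subject_id=str(f.attrs["subject_id"]),
            session_id=str(f.attrs["session_id"]),
        )


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True, default=_jsonable))


def _jsonable(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, (set, frozenset)):
        return sorted(x)
    raise TypeError(f"not JSON serializable: {type(x)}")
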
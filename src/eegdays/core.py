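"""Shared domain types: electrode montage, head model, recordings.

Coordinates are head-frame millimetres: +x right, +y anterior (nasion),
+z superior (vertex). Signals are microvolts, channels x samples.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

EVENT_COLUMNS = ("trial", "rest_onset", "stim_onset", "stim_end", "valence", "arousal")


@dataclass(frozen=True)
class ElectrodeMontage:
    """Labelled scalp electrode positions on the scalp sphere."""

    labels: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 3) mm

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "labels", tuple(self.labels))
        if len(self.labels) < 4:
            raise ValueError("montage needs at least 4 electrodes")
        if pos.shape != (len(self.labels), 3):
            raise ValueError("positions must be (n_channels, 3)")
        if len(set(l.lower() for l in self.labels)) != len(self.labels):
            raise ValueError("duplicate electrode labels")
        radii = np.linalg.norm(pos, axis=1)
        if not np.allclose(radii, radii[0], rtol=1e-6):
            raise ValueError("electrodes must lie on a common scalp sphere")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def scalp_radius(self) -> float:
        return float(np.linalg.norm(self.positions[0]))

    def index(self, label: str) -> int:
        """Case-insensitive channel lookup."""
        low = [l.lower() for l in self.labels]
        try:
            return low.index(label.lower())
        except ValueError:
            raise KeyError(f"channel {label!r} not in montage") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": list(self.labels),
                "x_mm": self.positions[:, 0],
                "y_mm": self.positions[:, 1],
                "z_mm": self.positions[:, 2],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ElectrodeMontage":
        return cls(
            labels=tuple(df["label"].astype(str)),
            positions=df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float),
        )


@dataclass(frozen=True)
class HeadModel:
    """Three concentric spheres (brain, skull, scalp)."""

    radii: tuple[float, float, float] = (80.0, 85.0, 92.0)  # mm
    conductivities: tuple[float, float, float] = (0.33, 0.0042, 0.33)  # S/m
    series_terms: int = 60

    def __post_init__(self) -> None:
        r = tuple(float(x) for x in self.radii)
        c = tuple(float(x) for x in self.conductivities)
        object.__setattr__(self, "radii", r)
        object.__setattr__(self, "conductivities", c)
        if not (0 < r[0] < r[1] < r[2]):
            raise ValueError("radii must be strictly increasing and positive")
        if any(x <= 0 for x in c):
            raise ValueError("conductivities must be positive")
        if self.series_terms < 20:
            raise ValueError("series_terms must be >= 20")

    @property
    def brain_radius(self) -> float:
        return self.radii[0]

    @property
    def scalp_radius(self) -> float:
        return self.radii[2]


def validate_events(events: pd.DataFrame, n_samples: int) -> pd.DataFrame:
    ev = events.reset_index(drop=True)
    missing = [c for c in EVENT_COLUMNS if c not in ev.columns]
    if missing:
        raise ValueError(f"event table missing columns {missing}")
    if len(ev) == 0:
        return ev
    on = ev["rest_onset"].to_numpy()
    stim = ev["stim_onset"].to_numpy()
    end = ev["stim_end"].to_numpy()
    if not (np.all(on < stim) & np.all(stim < end)):
        raise ValueError("events must satisfy rest_onset < stim_onset < stim_end")
    if np.any(on[1:] < end[:-1]):
        raise ValueError("events overlap or are unsorted")
    if on[0] < 0 or end[-1] > n_samples:
        raise ValueError("events extend beyond the recording")
    for col in ("valence", "arousal"):
        r = ev[col].to_numpy()
        if not np.all(np.isin(r, [1, 2, 3, 4, 5])):
            raise ValueError(f"{col} ratings must be in 1..5")
    return ev


@dataclass
class Recording:
    """One session of multichannel EEG with its trial/rating events."""

    data: np.ndarray  # (n_channels, n_samples) microvolts
    fs: float
    montage: ElectrodeMontage
    events: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=list(EVENT_COLUMNS)))
    subject_id: str = "S00"
    session_id: str = "D0"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.data.shape[0] != len(self.montage):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but montage has {len(self.montage)} channels"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        self.events = validate_events(self.events, self.data.shape[1])

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, data: np.ndarray) -> "Recording":
        return Recording(
            data=data,
            fs=self.fs,
            montage=self.montage,
            events=self.events.copy(),
            subject_id=self.subject_id,
            session_id=self.session_id,
        )
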
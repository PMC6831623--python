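"""Minimal EDF (European Data Format) writer/reader.

Implements the fixed-layout ASCII header plus 16-bit little-endian sample
records — enough for lossless-within-quantization exchange of our sessions.
The whole session is stored as a single data record; physical bounds are
symmetric integers so the 8-character header fields stay exact.
"""
from __future__ import annotations

import math
from pathlib import Path

import numpy as np

_HDR_FIXED = 256
_HDR_PER_SIGNAL = 256


def _field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def write_edf(
    path: str | Path,
    data: np.ndarray,
    fs: float,
    labels: list[str],
    *,
    patient: str = "X",
    recording: str = "eegdays session",
) -> None:
    """Write channels x samples microvolt data as a single-record EDF."""
    data = np.asarray(data, dtype=float)
    ns, n_samples = data.shape
    if len(labels) != ns:
        raise ValueError("one label per channel required")
    duration = n_samples / fs
    dur_str = f"{duration:.6g}"
    if len(dur_str) > 8:
        dur_str = f"{duration:.4g}"

    phys_max = np.ceil(np.maximum(np.abs(data).max(axis=1), 1.0)).astype(int)
    dig_max, dig_min = 32767, -32768
    scale = 2.0 * phys_max / (dig_max - dig_min)
    offset = phys_max - scale * dig_max
    digital = np.clip(
        np.round((data - offset[:, None]) / scale[:, None]), dig_min, dig_max
    ).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(_field("0", 8))
        fh.write(_field(patient, 80))
        fh.write(_field(recording, 80))
        fh.write(_field("01.01.00", 8))
        fh.write(_field("00.00.00", 8))
        fh.write(_field(str(_HDR_FIXED + _HDR_PER_SIGNAL * ns), 8))
        fh.write(_field("", 44))
        fh.write(_field("1", 8))
        fh.write(_field(dur_str, 8))
        fh.write(_field(str(ns), 4))
        for lab in labels:
            fh.write(_field(lab, 16))
        for _ in labels:
            fh.write(_field("AgAgCl electrode", 80))
        for _ in labels:
            fh.write(_field("uV", 8))
        for pm in phys_max:
            fh.write(_field(str(-pm), 8))
        for pm in phys_max:
            fh.write(_field(str(pm), 8))
        for _ in labels:
            fh.write(_field(str(dig_min), 8))
        for _ in labels:
            fh.write(_field(str(dig_max), 8))
        for _ in labels:
            fh.write(_field("BP 1-50Hz", 80))
        for _ in labels:
            fh.write(_field(str(n_samples), 8))
        for _ in labels:
            fh.write(_field("", 32))
        fh.write(digital.tobytes())


def read_edf(path: str | Path) -> tuple[np.ndarray, float, list[str]]:
    """Read an EDF file written by :func:`write_edf` (or compatible)."""
    raw = Path(path).read_bytes()

    def txt(off: int, width: int) -> str:
        return raw[off : off + width].decode("ascii", errors="replace").strip()

    n_records = int(txt(236, 8))
    duration = float(txt(244, 8))
    ns = int(txt(252, 4))
    off = _HDR_FIXED
    labels = [txt(off + 16 * i, 16) for i in range(ns)]
    off += 16 * ns + 80 * ns + 8 * ns
    phys_min = np.array([float(txt(off + 8 * i, 8)) for i in range(ns)])
    off += 8 * ns
    phys_max = np.array([float(txt(off + 8 * i, 8)) for i in range(ns)])
    off += 8 * ns
    dig_min = np.array([float(txt(off + 8 * i, 8)) for i in range(ns)])
    off += 8 * ns
    dig_max = np.array([float(txt(off + 8 * i, 8)) for i in range(ns)])
    off += 8 * ns + 80 * ns
    spr = np.array([int(txt(off + 8 * i, 8)) for i in range(ns)])
    header_bytes = _HDR_FIXED + _HDR_PER_SIGNAL * ns

    body = np.frombuffer(raw, dtype="<i2", offset=header_bytes)
    per_record = int(spr.sum())
    if body.size < n_records * per_record:
        raise ValueError("EDF body shorter than header promises")
    chans = []
    for rec in range(n_records):
        base = rec * per_record
        pos = 0
        rec_chunks = []
        for i in range(ns):
            rec_chunks.append(body[base + pos : base + pos + spr[i]])
            pos += spr[i]
        chans.append(rec_chunks)
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    offset = phys_max - scale * dig_max
    data = np.stack(
        [np.concatenate([chans[rec][i] for rec in range(n_records)]).astype(float) for i in range(ns)]
    )
    data = data * scale[:, None] + offset[:, None]
    n_samples = data.shape[1]
    fs = spr[0] / duration if duration > 0 else math.nan
    return data, float(fs), labels
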
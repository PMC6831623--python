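"""Band-pass filtering and artifact subspace reconstruction (ASR).

ASR here is the desk-scale variant of the subspace-threshold-reconstruct
contract: calibrate principal axes and per-axis RMS thresholds on the
cleanest portion of the data, then slide half-second windows over the
recording and project any window whose per-axis RMS exceeds threshold onto
the retained axes, recombining with raised-cosine overlap-add.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .core import Recording


class CalibrationError(ValueError):
    """Not enough usable calibration data."""


def bandpass(recording: Recording, lo_hz: float = 1.0, hi_hz: float = 50.0, order: int = 6) -> Recording:
    """Zero-phase Butterworth band-pass; length-preserving."""
    nyq = recording.fs / 2.0
    if not (0 < lo_hz < hi_hz):
        raise ValueError("need 0 < lo_hz < hi_hz")
    if hi_hz >= nyq:
        raise ValueError(f"hi_hz {hi_hz} must be below Nyquist {nyq}")
    sos = sps.butter(order, [lo_hz, hi_hz], btype="bandpass", fs=recording.fs, output="sos")
    out = sps.sosfiltfilt(sos, recording.data, axis=1)
    return recording.copy_with(out)


def bandpass_attenuation_db(fs: float, freq_hz: float, lo_hz: float = 1.0, hi_hz: float = 50.0, order: int = 6) -> float:
    """Two-pass (zero-phase) attenuation of the designed filter at freq_hz, in dB."""
    sos = sps.butter(order, [lo_hz, hi_hz], btype="bandpass", fs=fs, output="sos")
    _, h = sps.sosfreqz(sos, worN=[freq_hz], fs=fs)
    mag = np.abs(h[0]) ** 2  # forward-backward doubles the attenuation
    return float(-20.0 * np.log10(max(mag, 1e-300)))


@dataclass
class ASRState:
    """Calibration axes and per-axis rejection thresholds."""

    axes: np.ndarray  # (n_channels, n_channels) orthonormal principal axes (columns)
    thresholds: np.ndarray  # per-axis RMS rejection threshold
    window_s: float
    cutoff_sd: float
    n_channels: int

    def __post_init__(self) -> None:
        if np.any(self.thresholds <= 0):
            raise ValueError("thresholds must be strictly positive")
        if self.cutoff_sd <= 0:
            raise ValueError("cutoff_sd must be positive")
        gram = self.axes.T @ self.axes
        if not np.allclose(gram, np.eye(gram.shape[0]), atol=1e-8):
            raise ValueError("axes must be orthonormal")


@dataclass
class CleaningReport:
    """Bookkeeping of how much data reconstruction altered."""

    fraction_modified: float
    window_flags: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_modified <= 1.0:
            raise ValueError("fraction_modified must be in [0, 1]")

    def to_jsonable(self) -> dict:
        return {
            "fraction_modified": self.fraction_modified,
            "n_windows": int(self.window_flags.size),
            "n_flagged": int(self.window_flags.sum()),
        }


def _window_rms(proj: np.ndarray, win: int, hop: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-axis RMS over sliding windows. proj is axes x samples."""
    n = proj.shape[1]
    starts = np.arange(0, n - win + 1, hop)
    sq = proj**2
    csum = np.concatenate([np.zeros((proj.shape[0], 1)), np.cumsum(sq, axis=1)], axis=1)
    rms = np.sqrt((csum[:, starts + win] - csum[:, starts]) / win)  # (axes, n_windows)
    return starts, rms


def asr_calibrate(recording: Recording, cutoff_sd: float = 5.0, window_s: float = 0.5) -> ASRState:
    """Estimate principal axes and mean + cutoff_sd * SD RMS thresholds.

    Calibration uses the lowest-RMS 60% of one-second windows, a stand-in
    for clean resting data.
    """
    data = recording.data
    fs = recording.fs
    if recording.duration_s < 30.0:
        raise CalibrationError(
            f"need >= 30 s of data for calibration, got {recording.duration_s:.1f} s"
        )
    cal_win = int(round(fs))
    n_windows = data.shape[1] // cal_win
    segs = data[:, : n_windows * cal_win].reshape(data.shape[0], n_windows, cal_win)
    seg_rms = np.sqrt((segs**2).mean(axis=(0, 2)))
    keep = np.argsort(seg_rms)[: max(1, int(np.ceil(0.6 * n_windows)))]
    clean = segs[:, np.sort(keep), :].reshape(data.shape[0], -1)

    cov = np.cov(clean)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    axes = evecs[:, order]

    win = int(round(window_s * fs))
    hop = max(1, win // 2)
    proj = axes.T @ clean
    _, rms = _window_rms(proj, win, hop)
    mean = rms.mean(axis=1)
    sd = rms.std(axis=1)
    thresholds = mean + cutoff_sd * sd
    thresholds = np.maximum(thresholds, np.finfo(float).tiny)
    return ASRState(
        axes=axes,
        thresholds=thresholds,
        window_s=window_s,
        cutoff_sd=cutoff_sd,
        n_channels=data.shape[0],
    )


def asr_reconstruct(recording: Recording, state: ASRState) -> tuple[Recording, CleaningReport]:
    """Reconstruct above-threshold subspaces window by window.

    Flagged windows have their offending axes projected out (reconstruction
    from retained axes); raised-cosine overlap-add leaves unflagged regions
    untouched up to float rounding.
    """
    if recording.n_channels != state.n_channels:
        raise ValueError(
            f"recording has {recording.n_channels} channels, state calibrated on {state.n_channels}"
        )
    data = recording.data
    fs = recording.fs
    win = int(round(state.window_s * fs))
    hop = max(1, win // 2)
    n = data.shape[1]
    if n < win:
        return recording.copy_with(data.copy()), CleaningReport(0.0, np.zeros(0, dtype=bool))

    proj = state.axes.T @ data
    starts, rms = _window_rms(proj, win, hop)
    flags_axes = rms > state.thresholds[:, None]  # (axes, n_windows)
    flagged = flags_axes.any(axis=0)

    if not flagged.any():
        return recording.copy_with(data.copy()), CleaningReport(0.0, flagged)

    # raised-cosine (Hann) overlap-add; window weights sum to 1 at 50% overlap
    taper = np.sin(np.pi * (np.arange(win) + 0.5) / win) ** 2
    out = np.zeros_like(data)
    weight = np.zeros(n)
    modified = np.zeros(n, dtype=bool)
    for k, s0 in enumerate(starts):
        seg = proj[:, s0 : s0 + win]
        if flagged[k]:
            seg = seg.copy()
            # shrink offending axes back to their calibration-plausible RMS;
            # a 50x burst is suppressed by ~threshold/rms, a borderline
            # excursion is barely touched (keeps clean data intact)
            f = flags_axes[:, k]
            seg[f, :] *= (state.thresholds[f] / rms[f, k])[:, None]
            modified[s0 : s0 + win] = True
        out[:, s0 : s0 + win] += (state.axes @ seg) * taper
        weight[s0 : s0 + win] += taper
    tail = starts[-1] + win
    if tail < n:  # samples no window covered
        out[:, tail:] = data[:, tail:]
        weight[tail:] = 1.0
    nz = weight > 1e-12
    out[:, nz] /= weight[nz]
    out[:, ~nz] = data[:, ~nz]

    frac = float(modified.mean())
    return recording.copy_with(out), CleaningReport(frac, flagged)


def clean(
    recording: Recording,
    lo_hz: float = 1.0,
    hi_hz: float = 50.0,
    cutoff_sd: float = 5.0,
    window_s: float = 0.5,
) -> tuple[Recording, CleaningReport]:
    """Band-pass then ASR; the standard per-session preprocessing chain."""
    filtered = bandpass(recording, lo_hz, hi_hz)
    state = asr_calibrate(filtered, cutoff_sd=cutoff_sd, window_s=window_s)
    return asr_reconstruct(filtered, state)
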
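"""Spectro-temporal decomposition of component activations.

STFT with a 50%-overlapped 2-s Hamming window, log power in dB, grouping
into the five canonical bands, and per-trial z-normalization against the
trial's own preceding rest phase.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import get_window

from .bands import BANDS, BAND_ORDER

_TINY = np.finfo(float).tiny


class DegenerateBaselineError(ValueError):
    """Rest-phase SD too small to normalize against."""


def stft_logpower(
    activation: np.ndarray,
    fs: float,
    window_s: float = 2.0,
    overlap: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hamming-window STFT log-power.

    Returns (freqs, frame_times, S) with S of shape (n_freqs, n_frames) in
    dB (10*log10 of one-sided PSD). Frames are fully inside the signal;
    hop = window * (1 - overlap); frequency resolution 1/window_s Hz.
    """
    x = np.asarray(activation, dtype=float)
    if x.ndim != 1:
        raise ValueError("activation must be 1-D")
    win = int(round(window_s * fs))
    if x.size < win:
        raise ValueError(f"signal ({x.size} samples) shorter than one {win}-sample window")
    hop = int(round(win * (1.0 - overlap)))
    if hop < 1:
        raise ValueError("overlap too large")
    n_frames = (x.size - win) // hop + 1
    w = get_window("hamming", win, fftbins=True)
    idx = np.arange(win)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = x[idx] * w
    spec = np.fft.rfft(frames, axis=1)
    # one-sided PSD scaling (matches scipy.signal.welch density convention)
    psd = (np.abs(spec) ** 2) / (fs * np.sum(w**2))
    psd[:, 1:] *= 2.0
    if win % 2 == 0:
        psd[:, -1] /= 2.0
    freqs = np.fft.rfftfreq(win, d=1.0 / fs)
    times = (np.arange(n_frames) * hop + win / 2.0) / fs
    return freqs, times, 10.0 * np.log10(np.maximum(psd.T, _TINY))


def band_series(
    freqs: np.ndarray,
    logpower: np.ndarray,
    bands: dict[str, tuple[float, float]] | None = None,
) -> dict[str, np.ndarray]:
    """Per-frame mean of log-power bins whose centre lies in [lo, hi] inclusive."""
    bands = bands or BANDS
    freqs = np.asarray(freqs, dtype=float)
    out: dict[str, np.ndarray] = {}
    tol = 1e-9
    for name, (lo, hi) in bands.items():
        if hi > freqs[-1] + tol or lo < freqs[0] - tol:
            raise ValueError(f"band {name} ({lo}-{hi} Hz) outside frequency axis")
        mask = (freqs >= lo - tol) & (freqs <= hi + tol)
        if not mask.any():
            raise ValueError(f"band {name} covers no frequency bins")
        out[name] = logpower[mask].mean(axis=0)
    return out


@dataclass
class BandPowerTrial:
    """Baseline-normalized band power for one trial of one component."""

    component: tuple  # (subject_id, session_id, component index) or similar
    trial: int
    band: str
    series: np.ndarray  # z per stimulus STFT frame
    trial_mean: float
    mu_rest: float
    sigma_rest: float

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        if self.band not in BANDS:
            raise ValueError(f"unknown band {self.band!r}")
        if self.sigma_rest <= 0:
            raise ValueError("sigma_rest must be positive")
        if abs(self.trial_mean - self.series.mean()) > 1e-12 * max(1.0, abs(self.trial_mean)):
            raise ValueError("trial_mean inconsistent with series")


def baseline_normalize(
    trial_series: np.ndarray,
    rest_series: np.ndarray,
    *,
    component: tuple = ("", "", -1),
    trial: int = 0,
    band: str = "alpha",
    eps: float = 1e-6,
) -> BandPowerTrial:
    """z(t) = (x(t) - mu_rest) / sigma_rest over the trial's own rest frames."""
    rest = np.asarray(rest_series, dtype=float)
    stim = np.asarray(trial_series, dtype=float)
    if rest.size < 2:
        raise ValueError("rest series needs at least 2 frames")
    mu = float(rest.mean())
    sigma = float(rest.std())
    if sigma <= eps:
        raise DegenerateBaselineError(
            f"rest-phase SD {sigma:.3g} dB <= {eps:.3g} for {component} trial {trial} {band}"
        )
    z = (stim - mu) / sigma
    return BandPowerTrial(
        component=component,
        trial=trial,
        band=band,
        series=z,
        trial_mean=float(z.mean()),
        mu_rest=mu,
        sigma_rest=sigma,
    )


def trial_band_powers(
    activation: np.ndarray,
    fs: float,
    events: pd.DataFrame,
    *,
    component: tuple = ("", "", -1),
    window_s: float = 2.0,
    overlap: float = 0.5,
) -> tuple[list[BandPowerTrial], list[int]]:
    """Normalized band power of every trial; returns (trials, flagged_trial_ids).

    Flagged trials had a degenerate rest baseline in some band and are
    excluded from statistics.
    """
    x = np.asarray(activation, dtype=float)
    results: list[BandPowerTrial] = []
    flagged: list[int] = []
    for row in events.itertuples(index=False):
        rest = x[int(row.rest_onset) : int(row.stim_onset)]
        stim = x[int(row.stim_onset) : int(row.stim_end)]
        try:
            fr, _, s_rest = stft_logpower(rest, fs, window_s, overlap)
            _, _, s_stim = stft_logpower(stim, fs, window_s, overlap)
            rest_bands = band_series(fr, s_rest)
            stim_bands = band_series(fr, s_stim)
            for band in BAND_ORDER:
                results.append(
                    baseline_normalize(
                        stim_bands[band],
                        rest_bands[band],
                        component=component,
                        trial=int(row.trial),
                        band=band,
                    )
                )
        except (DegenerateBaselineError, ValueError):
            flagged.append(int(row.trial))
            results = [r for r in results if r.trial != int(row.trial)]
    return results, flagged


def band_power_frame(trials: list[BandPowerTrial]) -> pd.DataFrame:
    """Long-format table of trial means (one row per trial x band)."""
    return pd.DataFrame(
        {
            "component": [t.component for t in trials],
            "trial": [t.trial for t in trials],
            "band": [t.band for t in trials],
            "trial_mean": [t.trial_mean for t in trials],
            "mu_rest": [t.mu_rest for t in trials],
            "sigma_rest": [t.sigma_rest for t in trials],
        }
    )
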
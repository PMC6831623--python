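"""Multiday synthetic EEG generator with known ground truth.

Each session is a pure function of (scenario seed, subject index, session
index). Sources are dipolar: a pink-noise background plus band-limited
oscillatory peaks, projected through the three-shell spherical forward
model. Planted emotion effects multiply the peak waveform during stimulus
windows by a gain calibrated (by one-off bisection) so the realized
standardized difference of trial-mean log band power matches the requested
effect size d.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from ..bands import BANDS
from ..bandpower import band_series, stft_logpower
from ..core import EVENT_COLUMNS, Recording
from .head import lead_field
from .scenario import QUADRANTS, ScenarioSpec, SourceSpec


class DegenerateScenarioError(ValueError):
    """No active sources and no sensor noise: nothing to simulate."""


@dataclass
class GroundTruth:
    """What the generator planted in one session."""

    active: tuple[int, ...]  # indices into ScenarioSpec.sources
    mixing: dict[int, np.ndarray]  # source index -> average-referenced scalp column
    activations: dict[int, np.ndarray]  # source index -> activation time series
    power_multipliers: np.ndarray  # (n_trials, n_sources) band-power gain per trial
    quadrants: tuple[str, ...]

    def to_jsonable(self) -> dict:
        return {
            "active": list(self.active),
            "mixing": {str(k): v.tolist() for k, v in self.mixing.items()},
            "power_multipliers": self.power_multipliers.tolist(),
            "quadrants": list(self.quadrants),
        }


def _pink_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = np.zeros_like(f)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * scale, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _band_noise(n: int, fs: float, lo: float, hi: float, rng: np.random.Generator) -> np.ndarray:
    hi = min(hi, 0.99 * fs / 2)
    if hi <= lo:  # band unrepresentable at this sampling rate
        rng.standard_normal(n)  # keep the stream position deterministic
        return np.zeros(n)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _peak_edges(peak) -> tuple[float, float]:
    lo, hi = BANDS[peak.band]
    w = 2.0  # Hz half-width around the centre, clipped to the band
    return max(lo, peak.centre_hz - w), min(hi, peak.centre_hz + w)


def _positive_condition(quadrant: str, dimension: str) -> bool:
    return quadrant.startswith("pv") if dimension == "valence" else quadrant.endswith("ha")


def _trial_logpower(x: np.ndarray, fs: float, band: str) -> float:
    freqs, _, s = stft_logpower(x, fs)
    return float(band_series(freqs, s, {band: BANDS[band]})[band].mean())


_GAIN_CACHE: dict = {}


def effect_gain(scenario: ScenarioSpec, src_index: int) -> float:
    """Amplitude gain realizing the planted |d| for one source (cached bisection)."""
    src = scenario.sources[src_index]
    if src.effect is None:
        return 1.0
    key = (scenario.seed, src_index, scenario.fs, scenario.stim_s, src)
    if key in _GAIN_CACHE:
        return _GAIN_CACHE[key]
    d_target = abs(src.effect.d)
    if d_target == 0:
        _GAIN_CACHE[key] = 1.0
        return 1.0
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 0xCA11B, src_index]))
    n_cal = 32
    n = int(round(scenario.stim_s * scenario.fs))
    bg = [
        _pink_noise(n, src.background_exponent, rng) for _ in range(n_cal)
    ]
    peak_waves = []  # per trial: list of (in_effect_band, amplitude, wave)
    for _ in range(n_cal):
        waves = []
        for pk in src.peaks:
            lo, hi = _peak_edges(pk)
            waves.append((pk.band == src.effect.band, pk.amplitude, _band_noise(n, scenario.fs, lo, hi, rng)))
        peak_waves.append(waves)
    pos = np.arange(n_cal) % 2 == 0

    def realized(gain: float) -> float:
        means = np.empty(n_cal)
        for t in range(n_cal):
            g = gain if pos[t] else 1.0 / gain
            x = bg[t].copy()
            for in_band, amp, wave in peak_waves[t]:
                x += amp * (g if in_band else 1.0) * wave
            means[t] = _trial_logpower(x, scenario.fs, src.effect.band)
        a, b = means[pos], means[~pos]
        sd = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
        return (a.mean() - b.mean()) / sd if sd > 0 else 0.0

    lo_g, hi_g = 1.0, 2.0
    while realized(hi_g) < d_target:
        hi_g *= 2.0
        if hi_g > 1e4:
            break
    for _ in range(40):
        mid = np.sqrt(lo_g * hi_g)
        if realized(mid) < d_target:
            lo_g = mid
        else:
            hi_g = mid
        if hi_g / lo_g < 1.001:
            break
    g = float(np.sqrt(lo_g * hi_g))
    if src.effect.d < 0:
        g = 1.0 / g
    _GAIN_CACHE[key] = g
    return g


def _blink_column(positions: np.ndarray) -> np.ndarray:
    r = np.linalg.norm(positions[0])
    w = np.clip(positions[:, 1] / r, 0.0, None) ** 2
    col = w / w.max()
    return col - col.mean()


def _blink_template(fs: float) -> np.ndarray:
    t = np.arange(0.0, 0.4, 1.0 / fs)
    tpl = np.sin(2 * np.pi * t / 0.4) * np.exp(-2.0 * t / 0.4)
    return tpl / np.abs(tpl).max()


def _add_blinks(data: np.ndarray, scenario: ScenarioSpec, positions: np.ndarray, rng: np.random.Generator) -> None:
    duration_min = data.shape[1] / scenario.fs / 60.0
    n_blinks = rng.poisson(scenario.blink_rate_per_min * duration_min)
    if n_blinks == 0:
        return
    col = _blink_column(positions)
    tpl = _blink_template(scenario.fs)
    starts = rng.integers(0, max(1, data.shape[1] - tpl.size), size=n_blinks)
    amps = rng.normal(120.0, 20.0, size=n_blinks)
    for s0, a in zip(starts, amps):
        seg = tpl[: data.shape[1] - s0]
        data[:, s0 : s0 + seg.size] += np.outer(col, a * seg)


def _add_emg(data: np.ndarray, scenario: ScenarioSpec, positions: np.ndarray, rng: np.random.Generator) -> None:
    duration_min = data.shape[1] / scenario.fs / 60.0
    n_bursts = rng.poisson(scenario.emg_rate_per_min * duration_min)
    if n_bursts == 0:
        return
    r = np.linalg.norm(positions[0])
    lateral = np.where(np.abs(positions[:, 0]) > 0.45 * r)[0]
    if lateral.size == 0:
        lateral = np.arange(data.shape[0])
    for _ in range(n_bursts):
        ch = int(rng.choice(lateral))
        dur = rng.uniform(0.5, 2.0)
        n = int(round(dur * scenario.fs))
        s0 = int(rng.integers(0, max(1, data.shape[1] - n)))
        burst = _band_noise(n, scenario.fs, 20.0, 50.0, rng) * sps.windows.hann(n) * 15.0
        d = np.linalg.norm(positions - positions[ch], axis=1)
        spread = np.exp(-(d**2) / (2 * 25.0**2))
        seg = burst[: data.shape[1] - s0]
        data[:, s0 : s0 + seg.size] += np.outer(spread, seg)


def _add_sustained_artifacts(
    data: np.ndarray, scenario: ScenarioSpec, positions: np.ndarray, rng: np.random.Generator
) -> None:
    """Continuous muscle tone (20-50 Hz, lateral, focal) and slow ocular
    activity (1-3.5 Hz, frontal column) with amplitude-modulated envelopes
    so the processes are non-Gaussian enough for ICA to isolate."""
    n = data.shape[1]
    fs = scenario.fs
    r = np.linalg.norm(positions[0])
    if scenario.emg_tone_channels > 0 and scenario.emg_tone_uv > 0:
        lateral = np.where(np.abs(positions[:, 0]) > 0.45 * r)[0]
        chans = rng.choice(lateral, size=min(scenario.emg_tone_channels, lateral.size), replace=False)
        for ch in chans:
            carrier = _band_noise(n, fs, 20.0, 50.0, rng)
            env = 1.0 + 1.5 * np.abs(_band_noise(n, fs, 0.05, 0.3, rng))
            tone = carrier * env
            tone *= scenario.emg_tone_uv / tone.std()
            d = np.linalg.norm(positions - positions[ch], axis=1)
            spread = np.exp(-(d**2) / (2 * 18.0**2))
            data += np.outer(spread, tone)
    if scenario.ocular_slow_uv > 0:
        col = _blink_column(positions)
        slow = _band_noise(n, fs, 1.0, 3.5, rng)
        env = 1.0 + 1.5 * np.abs(_band_noise(n, fs, 0.05, 0.3, rng))
        wave = slow * env
        wave *= scenario.ocular_slow_uv / wave.std()
        data += np.outer(col, wave)


def simulate_session(
    scenario: ScenarioSpec, subject: int, session: int
) -> tuple[Recording, GroundTruth]:
    """One deterministic session: sources + artifacts + noise, with events."""
    ss = np.random.SeedSequence([scenario.seed, subject, session])
    rng_events, rng_sources, rng_artifacts, rng_noise, rng_diffuse = (
        np.random.default_rng(child) for child in ss.spawn(5)
    )
    montage = scenario.get_montage()
    n_ch = len(montage)
    n_samples = scenario.n_samples
    trial_len = scenario.trial_samples
    rest_len = int(round(scenario.rest_s * scenario.fs))

    # 1) trial structure: quadrants in shuffled four-trial blocks
    quadrants: list[str] = []
    for _ in range(scenario.n_trials // 4):
        quadrants.extend(np.array(QUADRANTS)[rng_events.permutation(4)])
    # 2) ratings from the quadrant's categorical model
    valence = np.empty(scenario.n_trials, dtype=int)
    arousal = np.empty(scenario.n_trials, dtype=int)
    for t, quad in enumerate(quadrants):
        valence[t] = rng_events.choice(5, p=np.asarray(scenario.rating_model[quad]["valence"])) + 1
        arousal[t] = rng_events.choice(5, p=np.asarray(scenario.rating_model[quad]["arousal"])) + 1
    # 3) day-to-day source presence
    presence_draws = rng_events.uniform(size=len(scenario.sources))
    active = tuple(
        i for i, src in enumerate(scenario.sources) if presence_draws[i] < src.presence_prob
    )
    if not active and scenario.sensor_noise_sd == 0:
        raise DegenerateScenarioError("no active sources and zero sensor noise")

    rest_on = np.arange(scenario.n_trials) * trial_len
    stim_on = rest_on + rest_len
    stim_end = rest_on + trial_len
    events = pd.DataFrame(
        {
            "trial": np.arange(scenario.n_trials),
            "rest_onset": rest_on,
            "stim_onset": stim_on,
            "stim_end": stim_end,
            "valence": valence,
            "arousal": arousal,
        },
        columns=list(EVENT_COLUMNS),
    )

    data = np.zeros((n_ch, n_samples))
    mixing: dict[int, np.ndarray] = {}
    activations: dict[int, np.ndarray] = {}
    power_mult = np.ones((scenario.n_trials, len(scenario.sources)))

    for i in active:
        src: SourceSpec = scenario.sources[i]
        col = lead_field(np.asarray(src.location), np.asarray(src.orientation), montage, scenario.head_model)
        col = col / np.abs(col).max()
        bg = _pink_noise(n_samples, src.background_exponent, rng_sources)
        wave = bg.copy()
        gain = effect_gain(scenario, i)
        for pk in src.peaks:
            lo, hi = _peak_edges(pk)
            pw = pk.amplitude * _band_noise(n_samples, scenario.fs, lo, hi, rng_sources)
            if src.effect is not None and pk.band == src.effect.band and gain != 1.0:
                for t, quad in enumerate(quadrants):
                    g = gain if _positive_condition(quad, src.effect.dimension) else 1.0 / gain
                    pw[stim_on[t] : stim_end[t]] *= g
                    power_mult[t, i] = g**2
            wave += pw
        sd = wave.std()
        if sd > 0:
            wave = wave / sd * src.amplitude_uv
        data += np.outer(col, wave)
        mixing[i] = col
        activations[i] = wave

    if scenario.n_diffuse_sources > 0 and scenario.diffuse_amplitude_uv > 0:
        brain_r = scenario.head_model.brain_radius
        for _ in range(scenario.n_diffuse_sources):
            while True:
                loc = rng_diffuse.uniform(-0.9 * brain_r, 0.9 * brain_r, size=3)
                if np.linalg.norm(loc) < 0.9 * brain_r:
                    break
            ori = rng_diffuse.standard_normal(3)
            col = lead_field(loc, ori / np.linalg.norm(ori), montage, scenario.head_model)
            peak = np.abs(col).max()
            if peak > 0:
                col = col / peak
            wave = _pink_noise(n_samples, 1.0, rng_diffuse) * scenario.diffuse_amplitude_uv
            data += np.outer(col, wave)

    _add_blinks(data, scenario, montage.positions, rng_artifacts)
    _add_emg(data, scenario, montage.positions, rng_artifacts)
    _add_sustained_artifacts(data, scenario, montage.positions, rng_artifacts)
    if scenario.sensor_noise_sd > 0:
        data += rng_noise.normal(0.0, scenario.sensor_noise_sd, size=data.shape)

    rec = Recording(
        data=data,
        fs=scenario.fs,
        montage=montage,
        events=events,
        subject_id=f"S{subject:02d}",
        session_id=f"D{session}",
    )
    gt = GroundTruth(
        active=active,
        mixing=mixing,
        activations=activations,
        power_multipliers=power_mult,
        quadrants=tuple(quadrants),
    )
    return rec, gt


def simulate_study(scenario: ScenarioSpec) -> list[tuple[Recording, GroundTruth]]:
    """All subjects x sessions, row-major by subject."""
    return [
        simulate_session(scenario, s, d)
        for s in range(scenario.n_subjects)
        for d in range(scenario.n_sessions)
    ]
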
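"""Scenario specifications for the multiday synthetic EEG generator."""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ..bands import BANDS
from ..core import ElectrodeMontage, HeadModel
from .montage import standard_montage_30

QUADRANTS = ("pv_ha", "nv_ha", "nv_la", "pv_la")


@dataclass(frozen=True)
class Peak:
    """A band-limited oscillatory component of a source."""

    band: str
    centre_hz: float
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.band not in BANDS:
            raise ValueError(f"unknown band {self.band!r}")
        lo, hi = BANDS[self.band]
        if not (lo <= self.centre_hz <= hi):
            raise ValueError(f"peak centre {self.centre_hz} outside {self.band} band")
        if self.amplitude < 0:
            raise ValueError("peak amplitude must be >= 0")


@dataclass(frozen=True)
class Effect:
    """Planted emotion modulation: signed standardized effect size d on one band."""

    dimension: str  # "valence" | "arousal"
    band: str
    d: float

    def __post_init__(self) -> None:
        if self.dimension not in ("valence", "arousal"):
            raise ValueError("effect dimension must be 'valence' or 'arousal'")
        if self.band not in BANDS:
            raise ValueError(f"unknown band {self.band!r}")


@dataclass(frozen=True)
class SourceSpec:
    """A dipolar cortical source with 1/f background and band peaks."""

    location: tuple[float, float, float]
    orientation: tuple[float, float, float]
    background_exponent: float = 1.0
    peaks: tuple[Peak, ...] = ()
    effect: Effect | None = None
    presence_prob: float = 1.0
    amplitude_uv: float = 10.0  # channel-level RMS scale of the projected source

    def __post_init__(self) -> None:
        loc = tuple(float(x) for x in self.location)
        ori = np.asarray(self.orientation, dtype=float)
        n = np.linalg.norm(ori)
        if n == 0 or not np.all(np.isfinite(ori)):
            raise ValueError("orientation must be a finite non-zero 3-vector")
        object.__setattr__(self, "location", loc)
        object.__setattr__(self, "orientation", tuple(ori / n))
        object.__setattr__(self, "peaks", tuple(self.peaks))
        if not 0.0 <= self.presence_prob <= 1.0:
            raise ValueError("presence_prob must be in [0, 1]")


def _default_rating_model(p_match: float = 0.8) -> dict[str, dict[str, tuple[float, ...]]]:
    hi = (0.02, 0.05, 0.13, 0.35, 0.45)  # peaked on {4, 5}
    lo = tuple(reversed(hi))
    model: dict[str, dict[str, tuple[float, ...]]] = {}
    for quad in QUADRANTS:
        pos_v = quad.startswith("pv")
        high_a = quad.endswith("ha")
        model[quad] = {
            "valence": hi if pos_v else lo,
            "arousal": hi if high_a else lo,
        }
    # p_match defines the mass on the matching side {4,5} (or {1,2})
    if abs(sum(hi[3:]) - p_match) > 1e-9:
        scale_hi = p_match / sum(hi[3:])
        scale_lo = (1 - p_match - hi[2]) / sum(hi[:2])
        hi2 = tuple(np.r_[np.array(hi[:2]) * scale_lo, hi[2], np.array(hi[3:]) * scale_hi])
        lo2 = tuple(reversed(hi2))
        for quad in QUADRANTS:
            model[quad] = {
                "valence": hi2 if quad.startswith("pv") else lo2,
                "arousal": hi2 if quad.endswith("ha") else lo2,
            }
    return model


@dataclass(frozen=True)
class ScenarioSpec:
    """Full description of a simulated multiday study (pure function of seed)."""

    n_subjects: int = 2
    n_sessions: int = 3
    n_trials: int = 8
    fs: float = 250.0
    rest_s: float = 30.0
    stim_s: float = 60.0
    sources: tuple[SourceSpec, ...] = ()
    blink_rate_per_min: float = 4.0
    emg_rate_per_min: float = 2.0
    sensor_noise_sd: float = 2.0
    # diffuse cortical background: weak random dipoles (spatially correlated
    # noise floor, keeps residual ICs from looking like clean sources)
    n_diffuse_sources: int = 10
    diffuse_amplitude_uv: float = 2.0
    # sustained artifact processes (screenable by spectral profile):
    # continuous temporal-muscle tone on lateral channels and slow ocular
    # activity on a frontal projection
    emg_tone_channels: int = 6
    emg_tone_uv: float = 6.0
    ocular_slow_uv: float = 8.0
    rating_model: dict = field(default_factory=_default_rating_model)
    seed: int = 0
    head_model: HeadModel = field(default_factory=HeadModel)
    montage: ElectrodeMontage | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sources", tuple(self.sources))
        if self.n_trials % 4 != 0:
            raise ValueError("n_trials must be divisible by 4 (four emotion quadrants)")
        if self.rest_s <= 0 or self.stim_s <= 0:
            raise ValueError("rest_s and stim_s must be positive")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        brain = self.head_model.brain_radius
        for i, src in enumerate(self.sources):
            if np.linalg.norm(src.location) >= brain:
                raise ValueError(f"source {i} location outside the brain sphere")
            for pk in src.peaks:
                if not (0 < pk.centre_hz < self.fs / 2):
                    raise ValueError(f"source {i} peak centre outside (0, fs/2)")
        for quad, dists in self.rating_model.items():
            for dim, p in dists.items():
                p = np.asarray(p, dtype=float)
                if p.shape != (5,) or abs(p.sum() - 1.0) > 1e-9 or np.any(p < 0):
                    raise ValueError(f"rating distribution {quad}/{dim} must be a length-5 simplex")

    def get_montage(self) -> ElectrodeMontage:
        return self.montage if self.montage is not None else standard_montage_30(self.head_model)

    @property
    def trial_samples(self) -> int:
        return int(round((self.rest_s + self.stim_s) * self.fs))

    @property
    def n_samples(self) -> int:
        return self.n_trials * self.trial_samples

    def with_(self, **kwargs) -> "ScenarioSpec":
        return replace(self, **kwargs)


def default_sources(head: HeadModel | None = None) -> tuple[SourceSpec, ...]:
    """Eight plausible cortical sources: frontal/midline theta, posterior alpha."""
    return (
        SourceSpec((-35.0, 45.0, 30.0), (0.0, 0.7, 0.7), peaks=(Peak("theta", 6.0, 1.2),)),
        SourceSpec((0.0, 55.0, 35.0), (0.0, 0.8, 0.6), peaks=(Peak("theta", 5.5, 1.2),)),
        SourceSpec((35.0, 45.0, 30.0), (0.0, 0.7, 0.7), peaks=(Peak("alpha", 10.0, 1.0),)),
        SourceSpec((-45.0, -15.0, 45.0), (-0.6, 0.0, 0.8), peaks=(Peak("alpha", 10.5, 1.3), Peak("beta", 20.0, 0.5))),
        SourceSpec((0.0, -5.0, 60.0), (0.0, 0.0, 1.0), peaks=(Peak("theta", 6.5, 1.0), Peak("beta", 18.0, 0.6))),
        SourceSpec((45.0, -15.0, 45.0), (0.6, 0.0, 0.8), peaks=(Peak("alpha", 10.5, 1.3), Peak("beta", 20.0, 0.5))),
        SourceSpec((-30.0, -60.0, 20.0), (0.0, -0.7, 0.7), peaks=(Peak("alpha", 10.0, 1.6),)),
        SourceSpec((30.0, -60.0, 20.0), (0.0, -0.7, 0.7), peaks=(Peak("alpha", 10.0, 1.6),)),
    )


def protocol_scenario(seed: int = 0) -> ScenarioSpec:
    """The study protocol: 10 subjects, 8 sessions, 24 trials, 500 Hz, 30 s + 60 s."""
    return ScenarioSpec(
        n_subjects=10,
        n_sessions=8,
        n_trials=24,
        fs=500.0,
        rest_s=30.0,
        stim_s=60.0,
        sources=default_sources(),
        seed=seed,
    )


def fast_scenario(seed: int = 0, **overrides) -> ScenarioSpec:
    """Desk-scale default: same structure, reduced rate/duration for tests."""
    spec = ScenarioSpec(
        n_subjects=2,
        n_sessions=3,
        n_trials=8,
        fs=250.0,
        rest_s=6.0,
        stim_s=12.0,
        sources=default_sources(),
        seed=seed,
    )
    return spec.with_(**overrides) if overrides else spec
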
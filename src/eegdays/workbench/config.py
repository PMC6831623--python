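"""Run configuration with protocol defaults, TOML round-trip, seed derivation."""
from __future__ import annotations

import hashlib
import tomllib
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path


@dataclass
class RunConfig:
    """All stage parameters; defaults follow the source protocol constants."""

    # scenario (synthetic input)
    n_subjects: int = 2
    n_sessions: int = 3
    n_trials: int = 8
    fs: float = 250.0
    rest_s: float = 6.0
    stim_s: float = 12.0
    sensor_noise_sd: float = 2.0
    # preprocessing
    lo_hz: float = 1.0
    hi_hz: float = 50.0
    asr_cutoff_sd: float = 5.0
    asr_window_s: float = 0.5
    # decomposition
    ica_max_iter: int = 512
    ica_tol: float = 1e-6
    dipolarity_min: float = 85.0
    # tracking
    k_clusters: int = 0  # 0 -> silhouette scan over k_range
    k_range: list[int] = field(default_factory=lambda: [5, 15])
    feature_weights: list[float] = field(default_factory=lambda: [1.0, 1.0, 2.0])
    relocate_sd: float = 3.0
    dip_tol_mm: float = 25.0
    map_corr_min: float = 0.8
    min_days: int = 6
    # statistics
    n_perm: int = 20000
    alpha: float = 0.05
    rating_threshold: int = 3
    # run
    seed: int = 0
    out_dir: str = "runs/out"
    log_level: str = "INFO"

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed: sha256 of '<seed>:<stage>' mod 2^32."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "little")

    def config_hash(self) -> str:
        return hashlib.sha256(to_toml(self).encode()).hexdigest()[:16]

    def with_(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot emit {type(v)} to TOML")


def to_toml(config: RunConfig) -> str:
    lines = ["[run]"]
    for f in fields(config):
        lines.append(f"{f.name} = {_toml_value(getattr(config, f.name))}")
    return "\n".join(lines) + "\n"


def from_toml(text: str) -> RunConfig:
    doc = tomllib.loads(text)
    table = doc.get("run", doc)
    known = {f.name for f in fields(RunConfig)}
    unknown = set(table) - known
    if unknown:
        raise ValueError(f"unknown config keys {sorted(unknown)}")
    return RunConfig(**table)


def load_config(path: str | Path) -> RunConfig:
    return from_toml(Path(path).read_text())


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(to_toml(config))


def config_dict(config: RunConfig) -> dict:
    return asdict(config)
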
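"""Pipeline orchestration: per-session stages, per-subject clustering,
cross-subject commonality, statistics, manifest and caching."""
from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .. import __version__
from ..bandpower import band_power_frame, trial_band_powers
from ..core import Recording
from ..decompose import extended_infomax, screen_components
from ..dipoles import fit_decomposition
from ..preprocess import asr_calibrate, asr_reconstruct, bandpass
from ..stats import StatReport, cluster_band_tests, tendency_commonality
from ..synth import simulate_session
from ..synth.scenario import ScenarioSpec, default_sources
from ..tracking import (
    annotate_clusters,
    cluster_subject,
    commonality,
    component_psd,
    ic_features,
    match_clusters_across_subjects,
    relocate_outliers,
)
from .config import RunConfig, to_toml
from .io import write_json
from .schemas import validate_report

log = logging.getLogger("eegdays.pipeline")


class PipelineError(RuntimeError):
    """A stage failed; names the stage and the offending session."""


@dataclass
class RunManifest:
    config_hash: str
    package_version: str = __version__
    stages: list = field(default_factory=list)
    seeds: dict = field(default_factory=dict)

    def record(self, stage: str, subject: str, session: str, payload: np.ndarray | bytes, seconds: float) -> None:
        if isinstance(payload, np.ndarray):
            payload = np.ascontiguousarray(payload).tobytes()
        self.stages.append(
            {
                "stage": stage,
                "subject": subject,
                "session": session,
                "checksum": hashlib.sha256(payload).hexdigest()[:16],
                "seconds": round(seconds, 3),
            }
        )

    def to_jsonable(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "package_version": self.package_version,
            "stages": self.stages,
            "seeds": self.seeds,
        }


def scenario_from_config(config: RunConfig) -> ScenarioSpec:
    return ScenarioSpec(
        n_subjects=config.n_subjects,
        n_sessions=config.n_sessions,
        n_trials=config.n_trials,
        fs=config.fs,
        rest_s=config.rest_s,
        stim_s=config.stim_s,
        sources=default_sources(),
        sensor_noise_sd=config.sensor_noise_sd,
        seed=config.stage_seed("simulate"),
    )


def process_session(recording: Recording, config: RunConfig) -> dict:
    """preprocess -> decompose -> dipoles -> screen -> features + band power."""
    subject, session = recording.subject_id, recording.session_id

    def _stage(name, fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kwargs)
        except Exception as e:  # noqa: BLE001 - annotate and re-raise
            raise PipelineError(f"stage {name} failed for {subject}/{session}: {e}") from e
        log.debug("%s %s/%s: %.2fs", name, subject, session, time.perf_counter() - t0)
        return out

    filtered = _stage("preprocess.bandpass", bandpass, recording, config.lo_hz, config.hi_hz)
    state = _stage("preprocess.asr_calibrate", asr_calibrate, filtered, config.asr_cutoff_sd, config.asr_window_s)
    cleaned, report = _stage("preprocess.asr_reconstruct", asr_reconstruct, filtered, state)
    ica_seed = config.stage_seed(f"ica:{subject}:{session}")
    dec = _stage(
        "decompose.extended_infomax",
        extended_infomax,
        cleaned.data,
        seed=ica_seed,
        max_iter=config.ica_max_iter,
        tol=config.ica_tol,
    )
    fits = _stage("dipoles.fit", fit_decomposition, dec, recording.montage)
    screened = _stage(
        "decompose.screen",
        screen_components,
        dec,
        fits,
        recording.fs,
        recording.montage,
        config.dipolarity_min,
    )
    components = []
    power_rows = []
    for k in screened.kept:
        psd = component_psd(dec.activations[k], recording.fs)
        components.append(
            {
                "session_id": session,
                "component": k,
                "psd": psd,
                "map": dec.scalp_map(k),
                "dip": fits[k].location,
                "dipolarity": fits[k].dipolarity,
            }
        )
        trials, flagged = trial_band_powers(
            dec.activations[k], recording.fs, recording.events, component=(subject, session, k)
        )
        df = band_power_frame(trials)
        if len(df):
            df["session_id"] = session
            df["component"] = k
            ev = recording.events.set_index("trial")
            df["valence"] = df["trial"].map(ev["valence"])
            df["arousal"] = df["trial"].map(ev["arousal"])
            power_rows.append(df.drop(columns=["mu_rest", "sigma_rest"]))
    return {
        "subject": subject,
        "session": session,
        "cleaning": report,
        "decomposition": dec,
        "fits": fits,
        "screened": screened,
        "components": components,
        "power": pd.concat(power_rows, ignore_index=True) if power_rows else pd.DataFrame(),
        "ica_seed": ica_seed,
    }


def track_subject(session_results: list[dict], config: RunConfig):
    """Cluster one subject's screened components across sessions."""
    components = [c for r in session_results for c in r["components"]]
    if len(components) < 2:
        raise PipelineError(
            f"stage source_tracking failed for {session_results[0]['subject']}: "
            f"only {len(components)} screened components"
        )
    feats, matrix = ic_features(components, tuple(config.feature_weights))
    k = config.k_clusters or None
    if k is not None and k > len(feats):
        raise PipelineError(
            f"stage source_tracking failed for {session_results[0]['subject']}: "
            f"K={k} exceeds {len(feats)} components"
        )
    clusters = cluster_subject(
        feats,
        matrix,
        k=k,
        seed=config.stage_seed("kmeans"),
        k_range=tuple(config.k_range),
    )
    matrix_of = {(f.session_id, f.component): matrix[i] for i, f in enumerate(feats)}
    clusters, outliers = relocate_outliers(clusters, matrix_of, config.relocate_sd)
    clusters = annotate_clusters(clusters, n_sessions=config.n_sessions)
    return clusters, outliers


def subject_trial_table(session_results: list[dict], clusters) -> pd.DataFrame:
    """Cluster-level trial means: average over a cluster's components per session."""
    memb = {}
    for ci, c in enumerate(clusters):
        for m in c.members:
            memb[(m.session_id, m.component)] = f"c{ci:02d}:{c.label}"
    frames = []
    for r in session_results:
        df = r["power"]
        if not len(df):
            continue
        df = df.copy()
        df["cluster"] = [
            memb.get((s, k)) for s, k in zip(df["session_id"], df["component"])
        ]
        frames.append(df[df["cluster"].notna()])
    if not frames:
        return pd.DataFrame()
    allp = pd.concat(frames, ignore_index=True)
    return (
        allp.groupby(["cluster", "session_id", "trial", "band"], as_index=False)
        .agg(trial_mean=("trial_mean", "mean"), valence=("valence", "first"), arousal=("arousal", "first"))
    )


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> RunManifest:
    """Full synthetic-study run; writes reports and returns the manifest."""
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.toml").write_text(to_toml(config))
    manifest = RunManifest(config_hash=config.config_hash())
    manifest.seeds["global"] = config.seed

    scenario = scenario_from_config(config)
    per_subject_sessions: dict[str, list[dict]] = {}
    for s in range(config.n_subjects):
        for d in range(config.n_sessions):
            t0 = time.perf_counter()
            rec, _gt = simulate_session(scenario, s, d)
            manifest.record("simulate", rec.subject_id, rec.session_id, rec.data, time.perf_counter() - t0)
            t0 = time.perf_counter()
            result = process_session(rec, config)
            manifest.record(
                "session", rec.subject_id, rec.session_id, result["decomposition"].unmixing,
                time.perf_counter() - t0,
            )
            manifest.seeds[f"ica:{rec.subject_id}:{rec.session_id}"] = result["ica_seed"]
            per_subject_sessions.setdefault(rec.subject_id, []).append(result)

    reports: dict[str, StatReport] = {}
    per_subject_clusters = {}
    for subject, sessions in per_subject_sessions.items():
        clusters, outliers = track_subject(sessions, config)
        per_subject_clusters[subject] = clusters
        cluster_json = [c.to_jsonable() for c in clusters]
        for cj in cluster_json:
            validate_report("cluster_report", cj)
        write_json(
            {"clusters": cluster_json, "n_outliers": len(outliers)},
            out / f"clusters_{subject}.json",
        )
        table = subject_trial_table(sessions, clusters)
        if len(table):
            table.to_csv(out / f"trial_band_power_{subject}.tsv", sep="\t", index=False)
            rep = cluster_band_tests(
                table,
                subject,
                n_perm=config.n_perm,
                seed=config.stage_seed(f"perm:{subject}"),
            )
            reports[subject] = rep
            rj = rep.to_jsonable()
            validate_report("stat_report", rj)
            write_json(rj, out / f"stats_{subject}.json")

    if len(per_subject_clusters) >= 2:
        groups = match_clusters_across_subjects(
            per_subject_clusters, config.dip_tol_mm, config.map_corr_min
        )
        min_days = min(config.min_days, config.n_sessions)
        comm = commonality(groups, config.n_subjects, min_days, config.n_sessions)
        cj = comm.to_jsonable()
        validate_report("commonality_report", cj)
        write_json(cj, out / "commonality.json")
        pd.DataFrame(comm.rows).to_csv(out / "commonality.tsv", sep="\t", index=False)

        group_members = {
            f"g{gi:02d}:{g.label}": {
                subj: f"c{per_subject_clusters[subj].index(c):02d}:{c.label}"
                for subj, c in g.clusters.items()
            }
            for gi, g in enumerate(groups)
        }
        tend = tendency_commonality(reports, group_members, n_subjects=config.n_subjects)
        tend.to_csv(out / "tendency.tsv", sep="\t", index=False)

    mj = manifest.to_jsonable()
    validate_report("manifest", mj)
    write_json(mj, out / "manifest.json")
    return manifest
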
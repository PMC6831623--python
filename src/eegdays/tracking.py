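"""Cross-session clustering of screened ICs and stationarity statistics.

Feature vectors concatenate z-scored blocks (Welch log-PSD in 1-Hz bins,
unit-norm polarity-aligned scalp map, dipole location); k-means groups a
subject's components across sessions; the 3-SD rule relocates stragglers;
reproducibility counts distinct sessions; greedy centroid matching across
subjects yields commonality.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import welch
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

PSD_LO, PSD_HI = 1.0, 50.0

# canonical anatomical labels (informational): name -> head-frame mm
CANONICAL_REGIONS = {
    "left frontal": (-35.0, 45.0, 30.0),
    "frontal central": (0.0, 55.0, 35.0),
    "right frontal": (35.0, 45.0, 30.0),
    "left sensorimotor": (-45.0, -15.0, 45.0),
    "central midline": (0.0, -5.0, 60.0),
    "right sensorimotor": (45.0, -15.0, 45.0),
    "left occipital": (-30.0, -60.0, 20.0),
    "superior parietal": (0.0, -40.0, 55.0),
    "right occipital": (30.0, -60.0, 20.0),
}


@dataclass
class ICFeature:
    """Standardizable description of one screened component."""

    session_id: str
    component: int
    psd: np.ndarray  # log power, 1-Hz bins over 1-50 Hz
    map: np.ndarray  # unit-norm polarity-aligned scalp map
    dip: np.ndarray  # dipole location mm
    dipolarity: float = np.nan

    def __post_init__(self) -> None:
        self.psd = np.asarray(self.psd, dtype=float)
        self.map = np.asarray(self.map, dtype=float)
        self.dip = np.asarray(self.dip, dtype=float)
        if abs(np.linalg.norm(self.map) - 1.0) > 1e-9:
            raise ValueError("scalp map must be unit norm")
        if not (np.all(np.isfinite(self.psd)) and np.all(np.isfinite(self.dip))):
            raise ValueError("non-finite feature block")


@dataclass
class ICCluster:
    """A cross-session group of components."""

    members: list[ICFeature]
    centroid: np.ndarray
    sessions_present: frozenset[str]
    reproducibility: float = np.nan  # percent
    mean_dipolarity: float = np.nan  # percent
    label: str = ""

    def to_jsonable(self) -> dict:
        return {
            "members": [(m.session_id, m.component) for m in self.members],
            "sessions_present": sorted(self.sessions_present),
            "reproducibility": self.reproducibility,
            "mean_dipolarity": self.mean_dipolarity,
            "label": self.label,
        }


def component_psd(activation: np.ndarray, fs: float) -> np.ndarray:
    """Welch log-PSD in 1-Hz bins over 1-50 Hz."""
    nperseg = int(round(fs))  # 1-s segments -> 1-Hz resolution
    f, pxx = welch(activation, fs=fs, nperseg=min(nperseg, activation.size))
    mask = (f >= PSD_LO - 1e-9) & (f <= PSD_HI + 1e-9)
    return 10.0 * np.log10(np.maximum(pxx[mask], np.finfo(float).tiny))


def ic_features(
    components: list[dict],
    weights: tuple[float, float, float] = (1.0, 1.0, 2.0),
) -> tuple[list[ICFeature], np.ndarray]:
    """Build standardized feature matrix from screened components.

    Each entry of ``components`` must carry psd, map, dip (and session_id,
    component, dipolarity). Blocks are z-scored per dimension across the
    subject's components, then scaled by w_b / sqrt(dim_b) so a block's
    total variance contribution is w_b^2 regardless of its dimensionality.
    Returns (features, matrix).
    """
    if any(w <= 0 for w in weights):
        raise ValueError("block weights must be positive")
    feats: list[ICFeature] = []
    for i, c in enumerate(components):
        for attr in ("psd", "map", "dip"):
            if attr not in c or c[attr] is None:
                raise ValueError(f"component {i} ({c.get('session_id')}) missing {attr}")
        m = np.asarray(c["map"], dtype=float)
        n = np.linalg.norm(m)
        if n == 0:
            raise ValueError(f"component {i} has zero scalp map")
        m = m / n
        k = int(np.abs(m).argmax())
        if m[k] < 0:
            m = -m
        feats.append(
            ICFeature(
                session_id=str(c["session_id"]),
                component=int(c["component"]),
                psd=np.asarray(c["psd"], dtype=float),
                map=m,
                dip=np.asarray(c["dip"], dtype=float),
                dipolarity=float(c.get("dipolarity", np.nan)),
            )
        )
    blocks = [
        np.stack([f.psd for f in feats]),
        np.stack([f.map for f in feats]),
        np.stack([f.dip for f in feats]),
    ]
    cols = []
    for w, b in zip(weights, blocks):
        mu = b.mean(axis=0)
        sd = b.std(axis=0)
        z = (b - mu) / np.where(sd > 0, sd, 1.0)
        cols.append(z * (w / np.sqrt(b.shape[1])))
    return feats, np.hstack(cols)


def standardized_blocks(components: list[dict]) -> np.ndarray:
    """Z-scored, unweighted concatenation (diagnostic; mean 0 / SD 1 per dim)."""
    feats, _ = ic_features(components)
    blocks = [
        np.stack([f.psd for f in feats]),
        np.stack([f.map for f in feats]),
        np.stack([f.dip for f in feats]),
    ]
    cols = []
    for b in blocks:
        sd = b.std(axis=0)
        cols.append((b - b.mean(axis=0)) / np.where(sd > 0, sd, 1.0))
    return np.hstack(cols)


def _mean_dipolarity(members: list[ICFeature]) -> float:
    vals = [m.dipolarity for m in members if np.isfinite(m.dipolarity)]
    return float(np.mean(vals)) if vals else float("nan")


def _make_clusters(feats: list[ICFeature], matrix: np.ndarray, labels: np.ndarray) -> list[ICCluster]:
    clusters = []
    for k in sorted(set(int(l) for l in labels)):
        idx = np.where(labels == k)[0]
        if idx.size == 0:
            continue
        members = [feats[i] for i in idx]
        clusters.append(
            ICCluster(
                members=members,
                centroid=matrix[idx].mean(axis=0),
                sessions_present=frozenset(m.session_id for m in members),
                mean_dipolarity=_mean_dipolarity(members),
            )
        )
    return clusters


def cluster_subject(
    feats: list[ICFeature],
    matrix: np.ndarray,
    k: int | None = None,
    seed: int = 0,
    restarts: int = 50,
    k_range: tuple[int, int] = (5, 15),
) -> list[ICCluster]:
    """Best-of-restarts k-means++ clustering; silhouette scan when k is None."""
    n = matrix.shape[0]
    if k is not None:
        if not 2 <= k <= n:
            raise ValueError(f"K={k} invalid for {n} features")
        km = KMeans(n_clusters=k, n_init=restarts, random_state=seed).fit(matrix)
        return _make_clusters(feats, matrix, km.labels_)
    best_k, best_score, best_labels = None, -np.inf, None
    lo = max(2, k_range[0])
    hi = min(k_range[1], n - 1)
    for kk in range(lo, hi + 1):
        km = KMeans(n_clusters=kk, n_init=restarts, random_state=seed).fit(matrix)
        if len(set(km.labels_)) < 2:
            continue
        score = silhouette_score(matrix, km.labels_)
        if score > best_score:
            best_k, best_score, best_labels = kk, score, km.labels_
    if best_labels is None:
        raise ValueError(f"could not cluster {n} features in K range {k_range}")
    return _make_clusters(feats, matrix, best_labels)


def relocate_outliers(
    clusters: list[ICCluster],
    matrix_of: dict | None = None,
    sd_limit: float = 3.0,
) -> tuple[list[ICCluster], list[ICFeature]]:
    """One-pass 3-SD relocation rule, then centroid recomputation.

    A member farther than mean + sd_limit*SD of its cluster's member-centroid
    distances moves to the nearest other centroid if it falls within that
    cluster's own threshold, else becomes an outlier.
    """

    def vec(f: ICFeature) -> np.ndarray:
        if matrix_of is not None:
            return matrix_of[(f.session_id, f.component)]
        return np.concatenate([f.psd, f.map, f.dip])

    cents = [c.centroid for c in clusters]
    dists = [
        np.array([np.linalg.norm(vec(m) - c.centroid) for m in c.members]) for c in clusters
    ]
    stats = [(d.mean(), d.std()) for d in dists]
    new_members: list[list[ICFeature]] = [[] for _ in clusters]
    outliers: list[ICFeature] = []
    for ci, c in enumerate(clusters):
        d_all = dists[ci]
        for mi, m in enumerate(c.members):
            d_own = d_all[mi]
            # leave-one-out statistics: a lone extreme member must not be
            # able to inflate its own rejection threshold
            others = np.delete(d_all, mi)
            if others.size:
                mu, sd = others.mean(), others.std()
            else:
                mu, sd = d_own, 0.0
            if d_own <= mu + sd_limit * sd:
                new_members[ci].append(m)
                continue
            # candidate: nearest other centroid
            others = [(np.linalg.norm(vec(m) - cents[cj]), cj) for cj in range(len(clusters)) if cj != ci]
            if not others:
                outliers.append(m)
                continue
            d_new, cj = min(others)
            mu_j, sd_j = stats[cj]
            if d_new <= mu_j + sd_limit * sd_j:
                new_members[cj].append(m)
            else:
                outliers.append(m)
    out: list[ICCluster] = []
    for ci, members in enumerate(new_members):
        if not members:
            continue
        mat = np.stack([vec(m) for m in members])
        out.append(
            ICCluster(
                members=members,
                centroid=mat.mean(axis=0),
                sessions_present=frozenset(m.session_id for m in members),
                mean_dipolarity=_mean_dipolarity(members),
            )
        )
    return out, outliers


def reproducibility(cluster: ICCluster, n_sessions: int) -> float:
    """Percent of sessions contributing at least one member (a session counts once)."""
    if n_sessions < 1:
        raise ValueError("n_sessions must be >= 1")
    if not cluster.members:
        raise ValueError("empty cluster")
    return 100.0 * len(set(m.session_id for m in cluster.members)) / n_sessions


def annotate_clusters(clusters: list[ICCluster], n_sessions: int) -> list[ICCluster]:
    """Fill reproducibility and nearest canonical-region label."""
    names = list(CANONICAL_REGIONS)
    locs = np.array([CANONICAL_REGIONS[n] for n in names])
    for c in clusters:
        c.reproducibility = reproducibility(c, n_sessions)
        dip = np.mean([m.dip for m in c.members], axis=0)
        c.label = names[int(np.argmin(np.linalg.norm(locs - dip, axis=1)))]
    return clusters


@dataclass
class CanonicalGroup:
    """Cross-subject agglomeration of matching subject-level clusters."""

    clusters: dict[str, ICCluster]  # subject id -> cluster
    dip_centroid: np.ndarray = field(default_factory=lambda: np.zeros(3))
    map_centroid: np.ndarray = field(default_factory=lambda: np.zeros(0))
    label: str = ""


def _cluster_map(c: ICCluster) -> np.ndarray:
    m = np.mean([f.map for f in c.members], axis=0)
    n = np.linalg.norm(m)
    return m / n if n > 0 else m


def _cluster_dip(c: ICCluster) -> np.ndarray:
    return np.mean([f.dip for f in c.members], axis=0)


def match_clusters_across_subjects(
    per_subject: dict[str, list[ICCluster]],
    dip_tol_mm: float = 25.0,
    map_corr_min: float = 0.8,
) -> list[CanonicalGroup]:
    """Greedy agglomeration: dipole centroids within tolerance AND |map corr| high."""
    if len(per_subject) < 2:
        raise ValueError("need clusters from at least 2 subjects")
    groups: list[CanonicalGroup] = []
    for subject in sorted(per_subject):
        for c in per_subject[subject]:
            dip = _cluster_dip(c)
            cmap = _cluster_map(c)
            placed = False
            order = np.argsort([np.linalg.norm(g.dip_centroid - dip) for g in groups]) if groups else []
            for gi in order:
                g = groups[gi]
                if subject in g.clusters:
                    continue
                if np.linalg.norm(g.dip_centroid - dip) > dip_tol_mm:
                    continue
                corr = float(np.corrcoef(g.map_centroid, cmap)[0, 1])
                if abs(corr) < map_corr_min:
                    continue
                g.clusters[subject] = c
                dips = np.stack([_cluster_dip(x) for x in g.clusters.values()])
                maps = np.stack([_cluster_map(x) for x in g.clusters.values()])
                # polarity-align maps to the group's first map before averaging
                ref = maps[0]
                maps = maps * np.sign(maps @ ref)[:, None]
                g.dip_centroid = dips.mean(axis=0)
                mc = maps.mean(axis=0)
                g.map_centroid = mc / np.linalg.norm(mc)
                placed = True
                break
            if not placed:
                groups.append(CanonicalGroup(clusters={subject: c}, dip_centroid=dip, map_centroid=cmap))
    names = list(CANONICAL_REGIONS)
    locs = np.array([CANONICAL_REGIONS[n] for n in names])
    for g in groups:
        g.label = names[int(np.argmin(np.linalg.norm(locs - g.dip_centroid, axis=1)))]
    return groups


@dataclass
class CommonalityReport:
    """Per canonical group: subjects matched with enough reproducible days."""

    rows: list[dict]  # label, n_matched, commonality (%), min_days

    def to_jsonable(self) -> dict:
        return {"rows": self.rows}


def commonality(
    groups: list[CanonicalGroup],
    n_subjects: int,
    min_days: int = 6,
    n_sessions: int = 8,
) -> CommonalityReport:
    """Percent of subjects whose matched cluster appears in >= min_days sessions."""
    if min_days > n_sessions:
        raise ValueError("min_days cannot exceed n_sessions")
    rows = []
    for g in groups:
        n_ok = sum(1 for c in g.clusters.values() if len(c.sessions_present) >= min_days)
        rows.append(
            {
                "label": g.label,
                "n_matched": len(g.clusters),
                "n_reproducible": n_ok,
                "min_days": min_days,
                "commonality": 100.0 * n_ok / n_subjects,
            }
        )
    return CommonalityReport(rows=rows)
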
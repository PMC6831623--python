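"""Dichotomized valence/arousal statistics on cluster band power.

Cross-day tests pool trial means over all sessions (unpaired t); within-day
tests use one session's trials with a label-permutation null (add-one p
estimator). Ratings equal to the scale midpoint are excluded by the strict
dichotomization inequalities.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

DIMENSIONS = ("valence", "arousal")


@dataclass
class EmotionLabels:
    """Per-trial ratings and their dichotomization."""

    ratings: np.ndarray  # (n_trials,) in 1..5
    binary: np.ndarray  # +1 positive/high, -1 negative/low, 0 excluded
    n_excluded: int

    @property
    def positive(self) -> np.ndarray:
        return self.binary > 0

    @property
    def negative(self) -> np.ndarray:
        return self.binary < 0


def dichotomize(ratings: np.ndarray, threshold: int = 3) -> EmotionLabels:
    """>threshold -> positive/high, <threshold -> negative/low, ==threshold -> excluded."""
    r = np.asarray(ratings)
    if not np.all(np.isin(r, [1, 2, 3, 4, 5])):
        bad = r[~np.isin(r, [1, 2, 3, 4, 5])]
        raise ValueError(f"ratings outside 1..5: {np.unique(bad)}")
    binary = np.zeros(r.shape, dtype=int)
    binary[r > threshold] = 1
    binary[r < threshold] = -1
    return EmotionLabels(ratings=r, binary=binary, n_excluded=int((binary == 0).sum()))


def exclude_imbalanced_subjects(minority_counts: dict[str, int]) -> set[str]:
    """Subjects whose minority-class trial count is below mean - SD (sample SD)."""
    if len(minority_counts) < 3:
        raise ValueError("need at least 3 subjects")
    subjects = sorted(minority_counts)
    counts = np.array([minority_counts[s] for s in subjects], dtype=float)
    threshold = counts.mean() - counts.std(ddof=1)
    kept = {s for s, c in zip(subjects, counts) if not c < threshold}
    if not kept:
        raise ValueError("exclusion rule removed every subject")
    return kept


def ttest_unpaired(
    group_a: np.ndarray, group_b: np.ndarray, welch: bool = False
) -> tuple[float, float]:
    """Two-sided pooled-variance Student's t (Welch via flag)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise FloatingPointError("zero variance with unequal means: t undefined")
    t, p = sstats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def _t_stat_batch(values: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """Pooled-variance t for many boolean group-A masks at once."""
    n = values.size
    na = masks.sum(axis=1)
    nb = n - na
    sum_all = values.sum()
    sumsq_all = (values**2).sum()
    sa = masks @ values
    ssa = masks @ (values**2)
    sb = sum_all - sa
    ssb = sumsq_all - ssa
    ma, mb = sa / na, sb / nb
    va = (ssa - na * ma**2) / (na - 1)
    vb = (ssb - nb * mb**2) / (nb - 1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(sp2 * (1 / na + 1 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / denom
    return np.where(np.isfinite(t), t, 0.0)


def permutation_test(
    values: np.ndarray,
    labels: np.ndarray,
    n_perm: int = 20000,
    seed: int = 0,
) -> float:
    """Label-shuffle p for the unpaired t statistic, add-one estimator.

    ``labels`` is boolean (True = group A). Shuffles preserve class counts.
    """
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels, dtype=bool)
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    # canonicalize the labeling: |t| and p are invariant under class
    # relabeling in law; fixing the reference class makes it exact
    n_true = int(lab.sum())
    if n_true > lab.size - n_true or (2 * n_true == lab.size and not lab[0]):
        lab = ~lab
    n_a = int(lab.sum())
    if n_a < 2 or (v.size - n_a) < 2:
        raise ValueError("both classes need >= 2 trials")
    t_obs = _t_stat_batch(v, lab[None, :])[0]
    rng = np.random.default_rng(seed)
    masks = np.zeros((n_perm, v.size), dtype=bool)
    base = np.zeros(v.size, dtype=bool)
    base[:n_a] = True
    for i in range(n_perm):
        masks[i] = base[rng.permutation(v.size)]
    t_perm = _t_stat_batch(v, masks)
    count = int(np.sum(np.abs(t_perm) >= np.abs(t_obs) - 1e-12))
    return (count + 1) / (n_perm + 1)


def rating_regression(
    ratings: np.ndarray, trial_means: np.ndarray
) -> tuple[float, float, float, float]:
    """Pearson r (two-sided p) and least-squares line of power on ratings."""
    r_arr = np.asarray(ratings, dtype=float)
    y = np.asarray(trial_means, dtype=float)
    if r_arr.size < 3:
        raise ValueError("need >= 3 trials")
    if r_arr.var() == 0:
        raise ValueError("zero rating variance")
    res = sstats.linregress(r_arr, y)
    return float(res.rvalue), float(res.pvalue), float(res.slope), float(res.intercept)


def bh_qvalues(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg q-values (extension; clearly labelled in reports)."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(q, 1.0)
    return out


@dataclass
class StatResult:
    """One cluster x band x dimension test."""

    cluster: str
    band: str
    dimension: str
    mean_pos: float
    mean_neg: float
    t: float
    p_param: float
    p_perm: float
    n_pos: int
    n_neg: int
    direction: str  # which binary state shows suppression (lower power)
    sig_05: bool = False
    sig_01: bool = False

    def __post_init__(self) -> None:
        self.sig_05 = self.p_perm < 0.05 if np.isfinite(self.p_perm) else self.p_param < 0.05
        self.sig_01 = self.p_perm < 0.01 if np.isfinite(self.p_perm) else self.p_param < 0.01


@dataclass
class StatReport:
    """All tests for one subject (cross-day) or one session (within-day)."""

    subject_id: str
    scope: str  # "cross_day" | f"within_day:{session}"
    results: list[StatResult] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([vars(r) for r in self.results])
        if len(df):
            df["q_bh"] = bh_qvalues(df["p_param"].to_numpy())  # extension, not in the source design
        return df

    def to_jsonable(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "scope": self.scope,
            "results": [vars(r) | {"t": float(r.t)} for r in self.results],
        }


def cluster_band_tests(
    trial_table: pd.DataFrame,
    subject_id: str,
    *,
    scope: str = "cross_day",
    n_perm: int = 20000,
    seed: int = 0,
    run_permutation: bool = True,
) -> StatReport:
    """Tests per cluster x band x dimension on a trial-mean table.

    ``trial_table`` columns: cluster, band, trial_mean, valence, arousal
    (ratings 1-5), and any trial identifier. Midpoint ratings are excluded.
    """
    report = StatReport(subject_id=subject_id, scope=scope)
    for (cluster, band), sub in trial_table.groupby(["cluster", "band"], sort=True):
        for dim in DIMENSIONS:
            labels = dichotomize(sub[dim].to_numpy())
            vals = sub["trial_mean"].to_numpy(dtype=float)
            pos, neg = vals[labels.positive], vals[labels.negative]
            if pos.size < 2 or neg.size < 2:
                continue
            try:
                t, p = ttest_unpaired(pos, neg)
            except FloatingPointError:
                continue
            p_perm = np.nan
            if run_permutation:
                both = np.concatenate([pos, neg])
                mask = np.zeros(both.size, dtype=bool)
                mask[: pos.size] = True
                p_perm = permutation_test(both, mask, n_perm=n_perm, seed=seed)
            if dim == "valence":
                direction = "negative" if pos.mean() > neg.mean() else "positive"
            else:
                direction = "low" if pos.mean() > neg.mean() else "high"
            report.results.append(
                StatResult(
                    cluster=str(cluster),
                    band=str(band),
                    dimension=dim,
                    mean_pos=float(pos.mean()),
                    mean_neg=float(neg.mean()),
                    t=t,
                    p_param=p,
                    p_perm=p_perm,
                    n_pos=int(pos.size),
                    n_neg=int(neg.size),
                    direction=direction,
                )
            )
    return report


def tendency_commonality(
    reports: dict[str, StatReport],
    group_members: dict[str, dict[str, str]],
    n_subjects: int | None = None,
    alpha: float = 0.05,
    floor_percent: float = 20.0,
    use_permutation: bool = True,
) -> pd.DataFrame:
    """Percent of subjects significant / significant-with-majority-direction.

    ``group_members`` maps canonical-group label -> {subject -> subject's
    cluster name}. Rows whose significant-percentage falls below
    ``floor_percent`` are suppressed.
    """
    n_subjects = n_subjects or len(reports)
    rows = []
    for glabel, members in group_members.items():
        per_band: dict[tuple[str, str], list[StatResult]] = {}
        for subject, cluster_name in members.items():
            rep = reports.get(subject)
            if rep is None:
                continue
            for res in rep.results:
                if res.cluster != cluster_name:
                    continue
                p = res.p_perm if use_permutation and np.isfinite(res.p_perm) else res.p_param
                if p < alpha:
                    per_band.setdefault((res.band, res.dimension), []).append(res)
        for (band, dim), results in per_band.items():
            pct_sig = 100.0 * len(results) / n_subjects
            if pct_sig < floor_percent:
                continue
            directions = [r.direction for r in results]
            uniq, cnt = np.unique(directions, return_counts=True)
            majority = uniq[int(np.argmax(cnt))]
            n_same = int(cnt.max())
            rows.append(
                {
                    "group": glabel,
                    "band": band,
                    "dimension": dim,
                    "pct_significant": pct_sig,
                    "label": majority,
                    "pct_same_tendency": 100.0 * n_same / n_subjects,
                    "n_significant": len(results),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "group", "band", "dimension", "pct_significant",
            "label", "pct_same_tendency", "n_significant",
        ],
    )
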
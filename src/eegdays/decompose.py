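"""Extended-infomax ICA and automated brain-component screening.

The decomposition is square (components = channels), computed on whitened
data with the natural-gradient extended-infomax rule; the sub/super-Gaussian
switch is a per-component kurtosis-sign estimate refreshed periodically.
Screening keeps components whose equivalent dipole explains enough scalp-map
variance, lies within the brain sphere, and whose activation spectrum does
not match the blink/EMG artifact proxies.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class RankError(ValueError):
    """Rank-deficient input covariance."""


class ConvergenceError(RuntimeError):
    """ICA diverged repeatedly."""


def whiten(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (whitened data, sphere matrix) with identity covariance.

    sphere = C^{-1/2} from the eigendecomposition of the data covariance.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("data must be channels x samples with >= 2 channels")
    if x.shape[1] <= x.shape[0]:
        raise ValueError("need more samples than channels")
    xc = x - x.mean(axis=1, keepdims=True)
    cov = (xc @ xc.T) / (x.shape[1] - 1)
    evals, evecs = np.linalg.eigh(cov)
    tol = evals[-1] * x.shape[0] * np.finfo(float).eps
    deficient = np.where(evals <= tol)[0]
    if deficient.size:
        raise RankError(
            f"covariance is rank deficient in {deficient.size} dimension(s) "
            f"(smallest eigenvalue {evals[0]:.3e})"
        )
    sphere = (evecs / np.sqrt(evals)) @ evecs.T
    return sphere @ xc, sphere


@dataclass
class Decomposition:
    """Square ICA decomposition of one cleaned session."""

    sphere: np.ndarray  # whitening matrix (channels x channels)
    unmixing: np.ndarray  # components x channels (acts on raw data)
    mixing: np.ndarray  # channels x components; columns are scalp maps
    activations: np.ndarray  # components x samples
    variance_share: np.ndarray  # per-component projected-variance fraction
    n_iterations: int = 0
    final_delta: float = np.nan
    signs: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def n_components(self) -> int:
        return self.unmixing.shape[0]

    def scalp_map(self, k: int) -> np.ndarray:
        return self.mixing[:, k]


def _kurtosis_signs(u: np.ndarray) -> np.ndarray:
    m2 = (u**2).mean(axis=1)
    m4 = (u**4).mean(axis=1)
    k = m4 - 3.0 * m2**2
    return np.where(k >= 0, 1.0, -1.0)


def extended_infomax(
    data: np.ndarray,
    seed: int = 0,
    max_iter: int = 512,
    tol: float = 1e-6,
    l_rate: float | None = None,
    block: int | None = None,
    ext_blocks: int = 1,
    anneal: float = 0.9,
    random_start: bool = False,
) -> Decomposition:
    """Extended-infomax ICA of channels x samples data.

    Deterministic given ``seed`` (the RNG drives sample shuffling, the
    kurtosis subsample, and the optional random start). Components are
    ordered by descending projected variance and polarity-aligned so each
    scalp map's largest-magnitude entry is positive.
    """
    x = np.asarray(data, dtype=float)
    n_ch, n_samp = x.shape
    xw, sphere = whiten(x)
    rng = np.random.default_rng(seed)

    if block is None:
        block = int(min(512, max(8, n_samp // 8)))
    if l_rate is None:
        l_rate = 0.00065 / np.log(n_ch)

    if random_start:
        a = rng.standard_normal((n_ch, n_ch))
        q, _ = np.linalg.qr(a)
        w = q
    else:
        w = np.eye(n_ch)

    eye = np.eye(n_ch)
    signs = np.ones(n_ch)
    n_sub_samp = min(n_samp, 6000)

    restarts = 0
    lrate = l_rate
    iteration = 0
    delta = np.inf
    w_prev = w.copy()
    old_change = None
    while iteration < max_iter:
        perm = rng.permutation(n_samp)
        diverged = False
        for start in range(0, n_samp - block + 1, block):
            u = w @ xw[:, perm[start : start + block]]
            y = np.tanh(u)
            grad = eye * block - (signs[:, None] * y) @ u.T - u @ u.T
            w = w + lrate * grad @ w
            if not np.all(np.isfinite(w)) or np.abs(w).max() > 1e8:
                diverged = True
                break
        if diverged:
            restarts += 1
            if restarts > 3:
                raise ConvergenceError("extended infomax diverged after 3 restarts")
            lrate *= 0.5
            w = np.eye(n_ch) if not random_start else w_prev * 0 + np.eye(n_ch)
            w_prev = w.copy()
            signs = np.ones(n_ch)
            iteration = 0
            old_change = None
            continue

        iteration += 1
        if ext_blocks > 0 and iteration % ext_blocks == 0:
            sub = rng.choice(n_samp, size=n_sub_samp, replace=False)
            signs = _kurtosis_signs(w @ xw[:, sub])

        change = w - w_prev
        delta = float(np.linalg.norm(change) / max(1.0, np.linalg.norm(w_prev)))
        if old_change is not None:
            denom = np.linalg.norm(change) * np.linalg.norm(old_change)
            if denom > 0:
                cosang = float(np.sum(change * old_change) / denom)
                if cosang < 0.5:  # oscillation (> 60 deg turn): anneal the learning rate
                    lrate *= anneal
        old_change = change
        w_prev = w.copy()
        if delta < tol:
            break

    unmixing = w @ sphere
    mixing = np.linalg.pinv(unmixing)
    xc = x - x.mean(axis=1, keepdims=True)
    acts = unmixing @ xc

    # order by projected variance: var of mixing_col * activation
    proj_var = (np.linalg.norm(mixing, axis=0) ** 2) * acts.var(axis=1)
    share = proj_var / proj_var.sum()
    order = np.argsort(share)[::-1]
    unmixing = unmixing[order]
    mixing = mixing[:, order]
    acts = acts[order]
    share = share[order]
    signs = signs[order]

    # polarity: largest-magnitude scalp-map entry positive
    flip = np.sign(mixing[np.abs(mixing).argmax(axis=0), np.arange(n_ch)])
    flip[flip == 0] = 1.0
    mixing = mixing * flip
    unmixing = unmixing * flip[:, None]
    acts = acts * flip[:, None]

    return Decomposition(
        sphere=sphere,
        unmixing=unmixing,
        mixing=mixing,
        activations=acts,
        variance_share=share,
        n_iterations=iteration,
        final_delta=delta,
        signs=signs,
    )


@dataclass
class ScreenedComponents:
    """Outcome of automated brain-component screening."""

    kept: tuple[int, ...]
    reasons: dict[int, str]  # component -> low_dipolarity | out_of_brain | artifact_profile | kept

    def __post_init__(self) -> None:
        allowed = {"low_dipolarity", "out_of_brain", "artifact_profile", "kept"}
        bad = set(self.reasons.values()) - allowed
        if bad:
            raise ValueError(f"unknown rejection reasons {bad}")


def _artifact_profile(
    activation: np.ndarray,
    scalp_map: np.ndarray,
    fs: float,
    frontal_weight: np.ndarray,
    blink_low_hz: float = 4.0,
    blink_power_frac: float = 0.6,
    emg_high_hz: float = 30.0,
    emg_power_frac: float = 0.5,
    frontal_frac: float = 0.5,
    band_lo_hz: float = 1.0,
    band_hi_hz: float = 50.0,
) -> bool:
    """Blink rule: frontal-dominant map with >60% power below 4 Hz.
    EMG rule: >50% power above 30 Hz.

    Power fractions are taken within the 1-50 Hz analysis band the pipeline
    filters to, so the rules are sampling-rate independent.
    """
    if activation.size >= 4096:
        seg = activation[: 4096 * (activation.size // 4096)]
        segs = seg.reshape(-1, 4096)
        pxx = (np.abs(np.fft.rfft(segs, axis=1)) ** 2).mean(axis=0)
        freqs = np.fft.rfftfreq(4096, d=1.0 / fs)
    else:
        pxx = np.abs(np.fft.rfft(activation)) ** 2
        freqs = np.fft.rfftfreq(activation.size, d=1.0 / fs)
    in_band = (freqs >= band_lo_hz) & (freqs <= band_hi_hz)
    total = pxx[in_band].sum()
    if total <= 0:
        return False
    low = pxx[in_band & (freqs < blink_low_hz)].sum() / total
    high = pxx[in_band & (freqs > emg_high_hz)].sum() / total
    m = np.abs(scalp_map)
    frontal = float((m * frontal_weight).sum() / m.sum()) if m.sum() > 0 else 0.0
    if frontal > frontal_frac and low > blink_power_frac:
        return True
    if high > emg_power_frac:
        return True
    return False


def screen_components(
    decomposition: Decomposition,
    dipole_fits: list,
    fs: float,
    montage,
    dipolarity_min: float = 85.0,
) -> ScreenedComponents:
    """Keep components that are dipolar, within-brain, and non-artifactual."""
    n = decomposition.n_components
    if len(dipole_fits) != n:
        raise ValueError(f"need one dipole fit per component ({len(dipole_fits)} != {n})")
    r = np.linalg.norm(montage.positions[0])
    frontal_weight = np.clip(montage.positions[:, 1] / r, 0.0, None)
    kept: list[int] = []
    reasons: dict[int, str] = {}
    for k in range(n):
        fit = dipole_fits[k]
        if not fit.dipolarity > dipolarity_min:
            reasons[k] = "low_dipolarity"
            continue
        if not fit.within_brain:
            reasons[k] = "out_of_brain"
            continue
        if _artifact_profile(
            decomposition.activations[k], decomposition.scalp_map(k), fs, frontal_weight
        ):
            reasons[k] = "artifact_profile"
            continue
        reasons[k] = "kept"
        kept.append(k)
    return ScreenedComponents(kept=tuple(kept), reasons=reasons)
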
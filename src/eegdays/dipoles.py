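"""Single equivalent-current-dipole fitting of IC scalp maps.

The moment is linear least squares at each candidate location, so the search
is over location only: a coarse 10-mm grid inside the brain sphere seeds a
derivative-free simplex refinement. Residual variance (RV) is the fraction
of average-referenced map variance a single dipole cannot explain;
dipolarity = 100 * (1 - RV).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import minimize

from .core import ElectrodeMontage, HeadModel
from .synth.head import dipole_gain, gain_single


@dataclass
class DipoleFit:
    """One fitted equivalent dipole."""

    location: np.ndarray  # mm
    moment: np.ndarray  # arbitrary units
    residual_variance: float
    dipolarity: float  # percent
    within_brain: bool
    n_evaluations: int = 0

    def __post_init__(self) -> None:
        self.location = np.asarray(self.location, dtype=float)
        self.moment = np.asarray(self.moment, dtype=float)
        if not 0.0 <= self.dipolarity <= 100.0:
            raise ValueError("dipolarity must be in [0, 100]")
        if abs(self.dipolarity - 100.0 * (1.0 - self.residual_variance)) > 1e-9:
            raise ValueError("dipolarity inconsistent with residual variance")

    def to_jsonable(self) -> dict:
        return {
            "location_mm": self.location.tolist(),
            "moment": self.moment.tolist(),
            "residual_variance": self.residual_variance,
            "dipolarity": self.dipolarity,
            "within_brain": self.within_brain,
        }


def dipolarity(fit: DipoleFit) -> float:
    """Percent of scalp-map variance explained by the fitted dipole."""
    return 100.0 * (1.0 - fit.residual_variance)


def is_within_brain(location: np.ndarray, head_model: HeadModel) -> bool:
    """Inclusive brain-sphere membership."""
    loc = np.asarray(location, dtype=float)
    if not np.all(np.isfinite(loc)):
        raise ValueError("non-finite location")
    return bool(np.linalg.norm(loc) <= head_model.brain_radius)


@lru_cache(maxsize=8)
def _coarse_grid(radii: tuple, spacing: float, margin: float) -> np.ndarray:
    """Cartesian grid strictly inside the brain sphere (shared across fits)."""
    r = radii[0] - margin
    ax = np.arange(-r, r + spacing / 2, spacing)
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    return pts[np.linalg.norm(pts, axis=1) < r]


class _GainCache:
    """Precomputed orthonormal gain bases at the coarse-grid points."""

    def __init__(self, montage: ElectrodeMontage, head: HeadModel, spacing: float, margin: float):
        self.grid = _coarse_grid(head.radii, spacing, margin)
        g = dipole_gain(self.grid, montage, head)  # (n_grid, n_ch, 3)
        self.q, _ = np.linalg.qr(g)  # batched: (n_grid, n_ch, 3)


_CACHE: dict = {}


def _grid_basis(montage: ElectrodeMontage, head: HeadModel, spacing: float, margin: float) -> _GainCache:
    key = (id(montage), head.radii, head.conductivities, head.series_terms, spacing, margin)
    if key not in _CACHE:
        _CACHE[key] = _GainCache(montage, head, spacing, margin)
    return _CACHE[key]


def _rv_at(location: np.ndarray, m: np.ndarray, montage: ElectrodeMontage, head: HeadModel) -> tuple[float, np.ndarray]:
    g = gain_single(location, montage, head)
    moment, resid, *_ = np.linalg.lstsq(g, m, rcond=None)
    if resid.size:
        rv = float(resid[0]) / float(m @ m)
    else:
        r = m - g @ moment
        rv = float(r @ r) / float(m @ m)
    return max(rv, 0.0), moment


def grid_search_rv(
    scalp_map: np.ndarray,
    montage: ElectrodeMontage,
    head_model: HeadModel | None = None,
    spacing: float = 10.0,
    margin: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """RV at every grid point (brute-force oracle). Returns (grid, rv)."""
    head = head_model or HeadModel()
    m = np.asarray(scalp_map, dtype=float)
    m = m - m.mean()
    cache = _grid_basis(montage, head, spacing, margin)
    proj = np.einsum("gcd,c->gd", cache.q, m)
    rv = 1.0 - (proj**2).sum(axis=1) / float(m @ m)
    return cache.grid, np.maximum(rv, 0.0)


def fit_single_dipole(
    scalp_map: np.ndarray,
    montage: ElectrodeMontage,
    head_model: HeadModel | None = None,
    *,
    grid_spacing: float = 10.0,
    n_seeds: int = 3,
    xatol: float = 0.05,
    fatol: float = 1e-9,
) -> DipoleFit:
    """Deterministic multi-start single-dipole fit of one scalp map."""
    head = head_model or HeadModel()
    m = np.asarray(scalp_map, dtype=float)
    if m.shape != (len(montage),):
        raise ValueError(f"scalp map length {m.shape} does not match montage ({len(montage)})")
    if not np.linalg.norm(m) > 0:
        raise ValueError("zero-norm scalp map")
    m = m - m.mean()
    norm2 = float(m @ m)
    if norm2 == 0:
        raise ValueError("scalp map is constant (zero after average reference)")

    grid, rv_grid = grid_search_rv(m, montage, head, spacing=grid_spacing)
    seeds = grid[np.argsort(rv_grid)[:n_seeds]]

    brain_r = head.brain_radius
    evals = 0

    def objective(loc: np.ndarray) -> float:
        nonlocal evals
        evals += 1
        r = np.linalg.norm(loc)
        limit = brain_r - 1.0
        if r >= limit:  # fold back inside; penalize the excursion
            loc = loc * (limit / r) * 0.999
            penalty = (r - limit) * 1e-3
        else:
            penalty = 0.0
        rv, _ = _rv_at(loc, m, montage, head)
        return rv + penalty

    best_loc, best_rv = None, np.inf
    for seed_pt in seeds:
        res = minimize(
            objective,
            seed_pt,
            method="Nelder-Mead",
            options={"xatol": xatol, "fatol": fatol, "maxiter": 250},
        )
        loc = res.x
        r = np.linalg.norm(loc)
        if r >= brain_r - 1.0:
            loc = loc * (brain_r - 1.0) * 0.999 / r
        rv, _ = _rv_at(loc, m, montage, head)
        if rv < best_rv:
            best_rv, best_loc = rv, loc

    rv, moment = _rv_at(best_loc, m, montage, head)
    return DipoleFit(
        location=best_loc,
        moment=moment,
        residual_variance=rv,
        dipolarity=100.0 * (1.0 - rv),
        within_brain=is_within_brain(best_loc, head),
        n_evaluations=evals,
    )


def fit_decomposition(decomposition, montage: ElectrodeMontage, head_model: HeadModel | None = None) -> list[DipoleFit]:
    """Fit every component scalp map of a decomposition."""
    return [
        fit_single_dipole(decomposition.scalp_map(k), montage, head_model)
        for k in range(decomposition.n_components)
    ]
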
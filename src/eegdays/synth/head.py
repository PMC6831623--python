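"""Analytic three-shell spherical forward model.

The scalp potential of a current dipole inside the innermost sphere is a
Legendre series; the shell structure enters through per-order radial
transfer coefficients obtained from the boundary conditions (potential and
radial current continuous at the inner interfaces, zero radial current at
the scalp). All lengths are internally scaled by the scalp radius, so the
series is numerically tame up to high orders.
"""
from __future__ import annotations

from functools import lru_cache

import numpy as np

from ..core import ElectrodeMontage, HeadModel


@lru_cache(maxsize=8)
def _transfer_coeffs(radii: tuple, conductivities: tuple, n_terms: int) -> np.ndarray:
    """Surface-value transfer coefficient t_n for unit source coefficient.

    For each order n, solve for the homogeneous expansion coefficients
    (a1, a2, b2, a3, b3) given the particular (dipole) term r^-(n+1) in the
    innermost shell, and return the scalp-surface radial factor a3 + b3.
    """
    s1, s2, s3 = conductivities
    r3 = radii[2]
    p1, p2 = radii[0] / r3, radii[1] / r3
    t = np.zeros(n_terms + 1)
    for n in range(1, n_terms + 1):
        m = n + 1
        A = np.array(
            [
                # V continuous at p1
                [p1**n, -(p1**n), -(p1 ** -m), 0.0, 0.0],
                # sigma dV/dr continuous at p1
                [s1 * n * p1 ** (n - 1), -s2 * n * p1 ** (n - 1), s2 * m * p1 ** (-n - 2), 0.0, 0.0],
                # V continuous at p2
                [0.0, p2**n, p2 ** -m, -(p2**n), -(p2 ** -m)],
                # sigma dV/dr continuous at p2
                [0.0, s2 * n * p2 ** (n - 1), -s2 * m * p2 ** (-n - 2), -s3 * n * p2 ** (n - 1), s3 * m * p2 ** (-n - 2)],
                # no radial current at the scalp surface (rho = 1)
                [0.0, 0.0, 0.0, float(n), -float(m)],
            ]
        )
        rhs = np.array([-(p1 ** -m), s1 * m * p1 ** (-n - 2), 0.0, 0.0, 0.0])
        a1, a2, b2, a3, b3 = np.linalg.solve(A, rhs)
        t[n] = a3 + b3
    return t


def dipole_gain(
    locations: np.ndarray,
    montage: ElectrodeMontage,
    head_model: HeadModel | None = None,
    *,
    average_reference: bool = True,
    chunk: int = 16384,
) -> np.ndarray:
    """Gain tensor (n_locations, n_channels, 3): potential per unit moment.

    Locations strictly inside the brain sphere, mm. Output rows are
    average-referenced over channels by default.
    """
    head = head_model or HeadModel()
    locs = np.atleast_2d(np.asarray(locations, dtype=float))
    if not np.all(np.isfinite(locs)):
        raise ValueError("non-finite dipole location")
    r3 = head.scalp_radius
    b = np.linalg.norm(locs, axis=1) / r3
    if np.any(b * r3 >= head.brain_radius):
        raise ValueError("dipole location outside the brain sphere")
    t = _transfer_coeffs(head.radii, head.conductivities, head.series_terms)
    e_hat = montage.positions / np.linalg.norm(montage.positions, axis=1, keepdims=True)
    out = np.empty((locs.shape[0], len(montage), 3))
    for start in range(0, locs.shape[0], chunk):
        sl = slice(start, start + chunk)
        out[sl] = _gain_block(locs[sl] / r3, b[sl], e_hat, t, head)
    if average_reference:
        out -= out.mean(axis=1, keepdims=True)
    return out


def _gain_block(locs: np.ndarray, b: np.ndarray, e_hat: np.ndarray, t: np.ndarray, head: HeadModel) -> np.ndarray:
    n_loc, n_ch = locs.shape[0], e_hat.shape[0]
    r0_hat = np.zeros_like(locs)
    nz = b > 0
    r0_hat[nz] = locs[nz] / b[nz, None]
    r0_hat[~nz] = np.array([0.0, 0.0, 1.0])  # arbitrary; order-1 term is isotropic

    c = r0_hat @ e_hat.T  # (n_loc, n_ch) cos(angle dipole->electrode)
    c = np.clip(c, -1.0, 1.0)
    # tangential vector term P'_n(c) * (e_hat - c r0_hat): no sin(gamma) division
    tang = e_hat[None, :, :] - c[:, :, None] * r0_hat[:, None, :]

    # Legendre P_n and P'_n by stable recurrences
    p_prev = np.ones_like(c)  # P_0
    p_cur = c.copy()  # P_1
    dp_prev = np.zeros_like(c)  # P'_0
    dp_cur = np.ones_like(c)  # P'_1

    g = np.zeros((n_loc, n_ch, 3))
    b_pow = np.ones(n_loc)  # b^(n-1), starts at n=1
    n_terms = len(t) - 1
    for n in range(1, n_terms + 1):
        coef = t[n] * b_pow  # (n_loc,)
        radial = (n * coef)[:, None] * p_cur  # (n_loc, n_ch)
        g += radial[:, :, None] * r0_hat[:, None, :]
        g += (coef[:, None] * dp_cur)[:, :, None] * tang
        if n < n_terms:
            p_next = ((2 * n + 1) * c * p_cur - n * p_prev) / (n + 1)
            dp_next = dp_prev + (2 * n + 1) * p_cur
            p_prev, p_cur = p_cur, p_next
            dp_prev, dp_cur = dp_cur, dp_next
            b_pow = b_pow * b
    g /= 4.0 * np.pi * head.conductivities[0]
    return g


def gain_single(
    location: np.ndarray,
    montage: ElectrodeMontage,
    head_model: HeadModel | None = None,
) -> np.ndarray:
    """Fast path: average-referenced gain matrix (n_channels, 3) at one location."""
    head = head_model or HeadModel()
    r3 = head.scalp_radius
    loc = np.asarray(location, dtype=float) / r3
    b = float(np.linalg.norm(loc))
    if b * r3 >= head.brain_radius:
        raise ValueError("dipole location outside the brain sphere")
    t = _transfer_coeffs(head.radii, head.conductivities, head.series_terms)
    e_hat = montage.positions / np.linalg.norm(montage.positions, axis=1, keepdims=True)
    r0_hat = loc / b if b > 0 else np.array([0.0, 0.0, 1.0])
    c = np.clip(e_hat @ r0_hat, -1.0, 1.0)  # (n_ch,)
    tang = e_hat - c[:, None] * r0_hat  # (n_ch, 3)

    p_prev = np.ones_like(c)
    p_cur = c.copy()
    dp_prev = np.zeros_like(c)
    dp_cur = np.ones_like(c)
    rad_acc = np.zeros_like(c)
    tan_acc = np.zeros_like(c)
    b_pow = 1.0
    n_terms = len(t) - 1
    for n in range(1, n_terms + 1):
        coef = t[n] * b_pow
        rad_acc += (n * coef) * p_cur
        tan_acc += coef * dp_cur
        if n < n_terms:
            p_next = ((2 * n + 1) * c * p_cur - n * p_prev) / (n + 1)
            dp_next = dp_prev + (2 * n + 1) * p_cur
            p_prev, p_cur = p_cur, p_next
            dp_prev, dp_cur = dp_cur, dp_next
            b_pow *= b
    g = rad_acc[:, None] * r0_hat[None, :] + tan_acc[:, None] * tang
    g /= 4.0 * np.pi * head.conductivities[0]
    return g - g.mean(axis=0, keepdims=True)


def lead_field(
    location: np.ndarray,
    orientation: np.ndarray,
    montage: ElectrodeMontage,
    head_model: HeadModel | None = None,
) -> np.ndarray:
    """Average-referenced scalp potentials of a single dipole (linear in moment)."""
    loc = np.asarray(location, dtype=float)
    q = np.asarray(orientation, dtype=float)
    if loc.shape != (3,) or q.shape != (3,):
        raise ValueError("location and orientation must be 3-vectors")
    if not np.all(np.isfinite(q)):
        raise ValueError("non-finite dipole orientation")
    g = dipole_gain(loc[None, :], montage, head_model)
    return g[0] @ q
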
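"""Vectorized standard bivariate normal rectangle probabilities.

The polychoric likelihood needs Phi2(h, k; rho) for whole grids of cut-points at
every trial value of rho, so the routine must be array-valued.  We use the
classical identity expressing the bivariate normal CDF through Owen's T function

    Phi2(h, k; rho) = (Phi(h) + Phi(k)) / 2 - T(h, a_h) - T(k, a_k) - delta,

with a_h = (k - rho h) / (h sqrt(1 - rho^2)), a_k symmetric, and delta = 1/2 when
h k < 0 (or h k = 0 with h + k < 0), 0 otherwise.  ``scipy.special.owens_t`` is a
true ufunc, which makes the whole computation vectorized.  Infinite cut-points
(empty extreme categories) reduce to the univariate CDF; arguments exactly at
zero are nudged by 1e-13, well below every tolerance used downstream.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr, owens_t

__all__ = ["bvn_cdf", "bvn_pdf", "rectangle_probs"]

_EPS_RHO = 1e-12
_EPS_H = 1e-13


def bvn_cdf(h, k, rho: float):
    """P(X <= h, Y <= k) for a standard bivariate normal with correlation rho.

    ``h`` and ``k`` broadcast; +-inf allowed.  ``rho`` is a scalar in [-1, 1].
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    h, k = np.broadcast_arrays(h, k)
    scalar = h.ndim == 0
    h = np.atleast_1d(h).copy()
    k = np.atleast_1d(k).copy()

    if abs(rho) >= 1.0 - _EPS_RHO:
        # Degenerate: Y = sign(rho) X almost surely.
        if rho > 0:
            out = ndtr(np.minimum(h, k))
        else:
            out = np.clip(ndtr(h) - ndtr(-k), 0.0, 1.0)
        return float(out[0]) if scalar else out

    out = np.empty(h.shape, dtype=float)
    ninf = (h == -np.inf) | (k == -np.inf)
    inf_h = (h == np.inf) & ~ninf
    inf_k = (k == np.inf) & ~ninf & ~inf_h
    out[ninf] = 0.0
    out[inf_h] = ndtr(k[inf_h])
    out[inf_k] = ndtr(h[inf_k])

    m = ~(ninf | inf_h | inf_k)
    if np.any(m):
        hh = h[m]
        kk = k[m]
        # push (sub)normal near-zeros off zero so the Owen arguments stay finite
        hh = np.where(np.abs(hh) < _EPS_H, np.where(hh < 0, -_EPS_H, _EPS_H), hh)
        kk = np.where(np.abs(kk) < _EPS_H, np.where(kk < 0, -_EPS_H, _EPS_H), kk)
        s = np.sqrt(1.0 - rho * rho)
        ah = (kk - rho * hh) / (hh * s)
        ak = (hh - rho * kk) / (kk * s)
        val = 0.5 * (ndtr(hh) + ndtr(kk)) - owens_t(hh, ah) - owens_t(kk, ak)
        val -= 0.5 * (hh * kk < 0.0)
        out[m] = np.clip(val, 0.0, 1.0)
    return float(out[0]) if scalar else out


def bvn_pdf(h, k, rho: float):
    """Standard bivariate normal density; zero at infinite arguments."""
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    h, k = np.broadcast_arrays(h, k)
    s2 = 1.0 - rho * rho
    with np.errstate(invalid="ignore", over="ignore"):
        z = (h * h - 2.0 * rho * h * k + k * k) / s2
        val = np.exp(-0.5 * z) / (2.0 * np.pi * np.sqrt(s2))
    val = np.where(np.isfinite(h) & np.isfinite(k), val, 0.0)
    return val if val.shape else float(val)


def rectangle_probs(cuts_row: np.ndarray, cuts_col: np.ndarray, rho: float) -> np.ndarray:
    """Cell probabilities of a discretized standard bivariate normal.

    ``cuts_row``/``cuts_col`` are full cut vectors including -inf and +inf
    (length C+1).  Returns the (C_row x C_col) matrix of rectangle probabilities
    P(tau_{j-1} < X <= tau_j, tau_{k-1} < Y <= tau_k).
    """
    cr = np.asarray(cuts_row, dtype=float)
    cc = np.asarray(cuts_col, dtype=float)
    grid = bvn_cdf(cr[:, None], cc[None, :], rho)
    p = grid[1:, 1:] - grid[:-1, 1:] - grid[1:, :-1] + grid[:-1, :-1]
    return np.clip(p, 0.0, 1.0)
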
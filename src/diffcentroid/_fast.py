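"""Numba-compiled inner loops for shooting, adjoint and attachment terms.

These duplicate, loop-for-loop, the vectorized numpy formulas in
:mod:`.geodesics` and :mod:`._adjoint`; the test suite asserts both paths
agree to machine precision.  Import of this module may fail (no numba);
callers fall back to the numpy path.

Kernel family codes: 0 = cauchy h(r) = 1/(1+r), 1 = gaussian h(r) = exp(-r).
"""

from __future__ import annotations

import numpy as np
from numba import njit

FAMILY_CODES = {"cauchy": 0, "gaussian": 1}


@njit(cache=True)
def _h012(r: float, fam: int) -> tuple[float, float, float]:
    if fam == 0:
        u = 1.0 / (1.0 + r)
        return u, -u * u, 2.0 * u * u * u
    e = np.exp(-r)
    return e, -e, e


@njit(cache=True)
def rhs_core(x: np.ndarray, a: np.ndarray, s2: float, fam: int):
    # symmetric pair loop: the (p,q) kernel evaluation serves both rows
    n = x.shape[0]
    dx = np.zeros((n, 3))
    da = np.zeros((n, 3))
    c2 = 2.0 / s2
    for p in range(n):
        dx[p, 0] += a[p, 0]  # h(0) = 1 diagonal term
        dx[p, 1] += a[p, 1]
        dx[p, 2] += a[p, 2]
        for q in range(p + 1, n):
            d0 = x[p, 0] - x[q, 0]
            d1 = x[p, 1] - x[q, 1]
            d2 = x[p, 2] - x[q, 2]
            r = (d0 * d0 + d1 * d1 + d2 * d2) / s2
            h, h1, _ = _h012(r, fam)
            for i in range(3):
                dx[p, i] += h * a[q, i]
                dx[q, i] += h * a[p, i]
            w = c2 * h1 * (a[p, 0] * a[q, 0] + a[p, 1] * a[q, 1] + a[p, 2] * a[q, 2])
            da[p, 0] -= w * d0
            da[p, 1] -= w * d1
            da[p, 2] -= w * d2
            da[q, 0] += w * d0
            da[q, 1] += w * d1
            da[q, 2] += w * d2
    return dx, da


@njit(cache=True)
def rhs_vjp_core(
    x: np.ndarray, a: np.ndarray, px: np.ndarray, pa: np.ndarray, s2: float, fam: int
):
    # every pairwise quantity (usym, bsym, c, h-derivatives) is symmetric in
    # (p, q), so one evaluation feeds both rows; the diagonal contributes
    # only h(0) px[p] to ga.
    n = x.shape[0]
    gx = np.zeros((n, 3))
    ga = np.zeros((n, 3))
    c2 = 2.0 / s2
    c4 = 4.0 / (s2 * s2)
    for p in range(n):
        ga[p, 0] += px[p, 0]
        ga[p, 1] += px[p, 1]
        ga[p, 2] += px[p, 2]
        for q in range(p + 1, n):
            d0 = x[p, 0] - x[q, 0]
            d1 = x[p, 1] - x[q, 1]
            d2 = x[p, 2] - x[q, 2]
            r = (d0 * d0 + d1 * d1 + d2 * d2) / s2
            h, h1, h2 = _h012(r, fam)
            e0 = pa[p, 0] - pa[q, 0]
            e1 = pa[p, 1] - pa[q, 1]
            e2 = pa[p, 2] - pa[q, 2]
            usym = e0 * d0 + e1 * d1 + e2 * d2
            w = c2 * h1 * usym
            for i in range(3):
                ga[p, i] += h * px[q, i] - w * a[q, i]
                ga[q, i] += h * px[p, i] - w * a[p, i]
            bsym = (
                px[p, 0] * a[q, 0]
                + px[p, 1] * a[q, 1]
                + px[p, 2] * a[q, 2]
                + px[q, 0] * a[p, 0]
                + px[q, 1] * a[p, 1]
                + px[q, 2] * a[p, 2]
            )
            c = a[p, 0] * a[q, 0] + a[p, 1] * a[q, 1] + a[p, 2] * a[q, 2]
            wx = c2 * h1 * bsym - c4 * h2 * usym * c
            wp = c2 * h1 * c
            gx[p, 0] += wx * d0 - wp * e0
            gx[p, 1] += wx * d1 - wp * e1
            gx[p, 2] += wx * d2 - wp * e2
            gx[q, 0] += -wx * d0 + wp * e0
            gx[q, 1] += -wx * d1 + wp * e1
            gx[q, 2] += -wx * d2 + wp * e2
    return gx, ga


@njit(cache=True)
def attachment_core(
    centers: np.ndarray,
    eta: np.ndarray,
    tc: np.ndarray,
    te: np.ndarray,
    s2: float,
    fam: int,
):
    """<S,S> - 2<S,T> plus gradients with respect to centers and eta."""
    m = centers.shape[0]
    mt = tc.shape[0]
    gC = np.zeros((m, 3))
    gE = np.zeros((m, 3))
    val = 0.0
    for f in range(m):
        val += eta[f, 0] ** 2 + eta[f, 1] ** 2 + eta[f, 2] ** 2
        gE[f, 0] += 2.0 * eta[f, 0]
        gE[f, 1] += 2.0 * eta[f, 1]
        gE[f, 2] += 2.0 * eta[f, 2]
        for g in range(f + 1, m):
            d0 = centers[f, 0] - centers[g, 0]
            d1 = centers[f, 1] - centers[g, 1]
            d2 = centers[f, 2] - centers[g, 2]
            r = (d0 * d0 + d1 * d1 + d2 * d2) / s2
            h, h1, _ = _h012(r, fam)
            q = eta[f, 0] * eta[g, 0] + eta[f, 1] * eta[g, 1] + eta[f, 2] * eta[g, 2]
            val += 2.0 * h * q
            w = (4.0 / s2) * h1 * q
            gC[f, 0] += w * d0
            gC[f, 1] += w * d1
            gC[f, 2] += w * d2
            gC[g, 0] -= w * d0
            gC[g, 1] -= w * d1
            gC[g, 2] -= w * d2
            for i in range(3):
                gE[f, i] += 2.0 * h * eta[g, i]
                gE[g, i] += 2.0 * h * eta[f, i]
        for g in range(mt):
            d0 = centers[f, 0] - tc[g, 0]
            d1 = centers[f, 1] - tc[g, 1]
            d2 = centers[f, 2] - tc[g, 2]
            r = (d0 * d0 + d1 * d1 + d2 * d2) / s2
            h, h1, _ = _h012(r, fam)
            q = eta[f, 0] * te[g, 0] + eta[f, 1] * te[g, 1] + eta[f, 2] * te[g, 2]
            val -= 2.0 * h * q
            w = -2.0 * (2.0 / s2) * h1 * q
            gC[f, 0] += w * d0
            gC[f, 1] += w * d1
            gC[f, 2] += w * d2
            gE[f, 0] -= 2.0 * h * te[g, 0]
            gE[f, 1] -= 2.0 * h * te[g, 1]
            gE[f, 2] -= 2.0 * h * te[g, 2]
    return val, gC, gE
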
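"""Hand-coded reverse-mode derivatives for the matching functional.

The matching objective J(alpha0) = gamma * E + ||[phi(S)] - [T]||^2_{W*}
depends on the initial momenta through the Heun-integrated geodesic system.
This module provides the vector-Jacobian products needed to backpropagate
through it: the VJP of the geodesic right-hand side, the backward sweep
over Heun steps, and the gradient of the currents attachment term with
respect to the endpoint vertices.  All formulas are analytic (first and
second derivatives of the scalar kernel profile) and are validated against
finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

from .kernels import KernelConfig, _sq_dists
from .currents import CurrentRep
from .geodesics import Flow, geodesic_rhs

try:
    from . import _fast
except ImportError:  # pragma: no cover
    _fast = None

__all__ = ["rhs_vjp", "backward_sweep", "attachment_and_grad"]


def rhs_vjp(
    cfg: KernelConfig,
    x: np.ndarray,
    a: np.ndarray,
    px: np.ndarray,
    pa: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """VJP of the geodesic right-hand side F(x, a) = (K(x) a, -1/2 grad_x[a^T K a]).

    Given cotangents (px, pa) on the outputs, returns gradients (gx, ga) of
    <px, F_x> + <pa, F_a> with respect to (x, a).
    """
    if _fast is not None and cfg.family in _fast.FAMILY_CODES:
        return _fast.rhs_vjp_core(
            np.ascontiguousarray(x), np.ascontiguousarray(a),
            np.ascontiguousarray(px), np.ascontiguousarray(pa),
            cfg.sigma**2, _fast.FAMILY_CODES[cfg.family],
        )
    s2 = cfg.sigma**2
    r = _sq_dists(x, x) / s2
    H, Hp, Hpp = cfg.h(r), cfg.h1(r), cfg.h2(r)
    C = a @ a.T                                   # <a_p, a_q>
    # U_pq = <pa_p, x_p - x_q>; Usym_pq = <pa_p - pa_q, x_p - x_q>
    pa_dot_x = np.einsum("pi,pi->p", pa, x)
    U = pa_dot_x[:, None] - pa @ x.T
    Usym = U + U.T
    # Bsym_pq = <px_p, a_q> + <px_q, a_p>
    PXA = px @ a.T
    Bsym = PXA + PXA.T

    ga = H @ px - (2.0 / s2) * (Hp * Usym) @ a

    def d_sum(n: np.ndarray, v: np.ndarray) -> np.ndarray:
        # sum_q n_pq (v_p - v_q)
        return n.sum(axis=1)[:, None] * v - n @ v

    M1 = Hp * Bsym
    N2 = Hpp * Usym * C
    E2 = Hp * C
    gx = (
        (2.0 / s2) * d_sum(M1, x)
        - (4.0 / s2**2) * d_sum(N2, x)
        - (2.0 / s2) * (E2.sum(axis=1)[:, None] * pa - E2 @ pa)
    )
    return gx, ga


def backward_sweep(
    flow: Flow, px_end: np.ndarray, pa_end: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Backpropagate cotangents from t=1 to t=0 through the stored Heun steps.

    Returns the cotangent (px0, pa0) at the initial state; pa0 is the
    gradient of the terminal quantity with respect to alpha(0).
    """
    cfg = flow.kernel_V
    dt = 1.0 / flow.n_steps
    px, pa = px_end.copy(), pa_end.copy()
    for k in range(flow.n_steps - 1, -1, -1):
        xk, ak = flow.traj_x[k], flow.traj_alpha[k]
        dx1, da1 = geodesic_rhs(cfg, xk, ak)
        wx, wa = xk + dt * dx1, ak + dt * da1          # predictor state
        gwx, gwa = rhs_vjp(cfg, wx, wa, 0.5 * dt * px, 0.5 * dt * pa)
        gzx, gza = rhs_vjp(cfg, xk, ak, 0.5 * dt * px + dt * gwx, 0.5 * dt * pa + dt * gwa)
        px = px + gwx + gzx
        pa = pa + gwa + gza
    return px, pa


def face_currents(
    verts: np.ndarray, faces: np.ndarray, face_weights: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Barycenters and (weighted) area-scaled normals of each triangle."""
    tri = verts[faces]
    centers = tri.mean(axis=1)
    eta = 0.5 * np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    if face_weights is not None:
        eta = face_weights[:, None] * eta
    return centers, eta


def attachment_and_grad(
    verts: np.ndarray,
    faces: np.ndarray,
    target: CurrentRep,
    kW: KernelConfig,
    target_norm_sq: float | None = None,
    face_weights: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """||[S(verts)] - [T]||^2_{W*} and its gradient with respect to verts.

    ``target_norm_sq`` caches <T, T>_{W*} (constant across optimizer
    iterations); when None it is computed here.
    """
    s2 = kW.sigma**2
    centers, eta = face_currents(verts, faces, face_weights)
    tc, te = target.centers, target.eta
    if target_norm_sq is None:
        rtt = _sq_dists(tc, tc) / s2
        target_norm_sq = float(np.einsum("fi,fg,gi->", te, kW.h(rtt), te))

    if _fast is not None and kW.family in _fast.FAMILY_CODES:
        val, gC, gE = _fast.attachment_core(
            np.ascontiguousarray(centers), np.ascontiguousarray(eta),
            np.ascontiguousarray(tc), np.ascontiguousarray(te),
            s2, _fast.FAMILY_CODES[kW.family],
        )
        value = val + target_norm_sq
    else:
        r_ss = _sq_dists(centers, centers) / s2
        H_ss, Hp_ss = kW.h(r_ss), kW.h1(r_ss)
        Q = eta @ eta.T
        r_st = _sq_dists(centers, tc) / s2
        H_st, Hp_st = kW.h(r_st), kW.h1(r_st)
        Qx = eta @ te.T

        ss = float(np.sum(H_ss * Q))
        st = float(np.sum(H_st * Qx))
        value = ss - 2.0 * st + target_norm_sq

        # gradient with respect to Dirac centers
        W_ss = Hp_ss * Q
        gC = (4.0 / s2) * (W_ss.sum(axis=1)[:, None] * centers - W_ss @ centers)
        W_st = Hp_st * Qx
        gC -= 2.0 * (2.0 / s2) * (W_st.sum(axis=1)[:, None] * centers - W_st @ tc)
        # gradient with respect to eta
        gE = 2.0 * (H_ss @ eta) - 2.0 * (H_st @ te)
    if face_weights is not None:
        gE = face_weights[:, None] * gE

    # chain through centers (mean of 3 vertices) and eta (half cross product)
    grad = np.zeros_like(verts)
    i, j, k = faces[:, 0], faces[:, 1], faces[:, 2]
    e1 = verts[j] - verts[i]
    e2 = verts[k] - verts[i]
    gj = 0.5 * np.cross(e2, gE)
    gk = 0.5 * np.cross(gE, e1)
    np.add.at(grad, i, gC / 3.0 - gj - gk)
    np.add.at(grad, j, gC / 3.0 + gj)
    np.add.at(grad, k, gC / 3.0 + gk)
    return value, grad
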
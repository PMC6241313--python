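"""Hamiltonian geodesics of the LDDMM point system.

A deformation is parametrized by control points x(0) and momentum vectors
alpha(0); the geodesic equations

    dx/dt     =  K_V(x) alpha
    dalpha/dt = -1/2 grad_x [alpha^T K_V(x) alpha]

are integrated with the explicit trapezoidal (Heun) rule on a uniform grid
over [0, 1].  The Hamiltonian alpha^T K_V(x) alpha is conserved along exact
geodesics and equals the squared diffeomorphic distance D(id, phi)^2; its
numerical drift is the integrator diagnostic.  Arbitrary points are carried
by the flow by evaluating the velocity field v(y, t) = sum_p K_V(y, x_p(t))
alpha_p(t) at them, forward or in reverse time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kernels import KernelConfig, _sq_dists, convolve, quadratic_form

try:  # numba-compiled inner loops; numpy fallback below is the reference
    from . import _fast
except ImportError:  # pragma: no cover
    _fast = None
from .mesh_io import TriangleMesh

__all__ = [
    "MomentaField",
    "Flow",
    "ShootingDivergence",
    "shoot",
    "hamiltonian",
    "flow_at_time",
    "transport_points",
    "deform_mesh",
]


class ShootingDivergence(RuntimeError):
    """Integration produced non-finite states (momenta too large for sigma_V)."""


@dataclass
class MomentaField:
    """Control points plus initial momenta: the tangent-space coordinate of a subject."""

    points: np.ndarray
    alpha: np.ndarray
    kernel_V: KernelConfig

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.alpha = np.atleast_2d(np.asarray(self.alpha, dtype=float))
        if self.points.shape != self.alpha.shape:
            raise ValueError(
                f"points {self.points.shape} and alpha {self.alpha.shape} must match"
            )

    @property
    def n_points(self) -> int:
        return len(self.points)

    def norm_sq(self) -> float:
        """alpha^T K_V(x) alpha = squared diffeomorphic distance of the shot path."""
        return quadratic_form(self.kernel_V, self.points, self.alpha, self.alpha)

    def norm(self) -> float:
        return float(np.sqrt(max(self.norm_sq(), 0.0)))


@dataclass
class Flow:
    """Time-discretized geodesic: states at T+1 uniform grid times on [0, 1]."""

    times: np.ndarray          # (T+1,)
    traj_x: np.ndarray         # (T+1, n, 3)
    traj_alpha: np.ndarray     # (T+1, n, 3)
    kernel_V: KernelConfig

    @property
    def n_steps(self) -> int:
        return len(self.times) - 1

    def state_at(self, t: float) -> tuple[np.ndarray, np.ndarray]:
        """States at time t; linear interpolation between adjacent grid states."""
        if t < -1e-12 or t > 1 + 1e-12:
            raise ValueError(f"t={t} outside [0, 1]")
        s = np.clip(t, 0.0, 1.0) * self.n_steps
        i = int(np.floor(s))
        if i >= self.n_steps:
            return self.traj_x[-1], self.traj_alpha[-1]
        w = s - i
        if w == 0.0:
            return self.traj_x[i], self.traj_alpha[i]
        return (
            (1 - w) * self.traj_x[i] + w * self.traj_x[i + 1],
            (1 - w) * self.traj_alpha[i] + w * self.traj_alpha[i + 1],
        )


def geodesic_rhs(cfg: KernelConfig, x: np.ndarray, a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Right-hand side of the geodesic system at state (x, alpha).

    Shares one pairwise-distance computation between the two equations;
    da/dt = -1/2 grad_x[a^T K a] expanded with the kernel profile derivative.
    """
    if _fast is not None and cfg.family in _fast.FAMILY_CODES:
        return _fast.rhs_core(
            np.ascontiguousarray(x), np.ascontiguousarray(a),
            cfg.sigma**2, _fast.FAMILY_CODES[cfg.family],
        )
    r = _sq_dists(x, x) / cfg.sigma**2
    dx = cfg.h(r) @ a
    w = cfg.h1(r) * (a @ a.T)
    da = -(2.0 / cfg.sigma**2) * (w.sum(axis=1)[:, None] * x - w @ x)
    return dx, da


def shoot(m: MomentaField, n_steps: int = 10) -> Flow:
    """Integrate the geodesic equations with the trapezoidal (Heun) rule."""
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    cfg = m.kernel_V
    dt = 1.0 / n_steps
    x = m.points.copy()
    a = m.alpha.copy()
    traj_x = [x.copy()]
    traj_a = [a.copy()]
    for k in range(n_steps):
        dx1, da1 = geodesic_rhs(cfg, x, a)
        xp = x + dt * dx1
        ap = a + dt * da1
        dx2, da2 = geodesic_rhs(cfg, xp, ap)
        x = x + 0.5 * dt * (dx1 + dx2)
        a = a + 0.5 * dt * (da1 + da2)
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(a))):
            raise ShootingDivergence(
                f"non-finite state at step {k + 1}/{n_steps}; "
                "momenta are likely too large relative to sigma_V"
            )
        traj_x.append(x.copy())
        traj_a.append(a.copy())
    return Flow(
        times=np.linspace(0.0, 1.0, n_steps + 1),
        traj_x=np.array(traj_x),
        traj_alpha=np.array(traj_a),
        kernel_V=cfg,
    )


def hamiltonian(flow: Flow, t_index: int) -> float:
    """alpha(t)^T K_V(x(t)) alpha(t) at grid index t_index."""
    x = flow.traj_x[t_index]
    a = flow.traj_alpha[t_index]
    return quadratic_form(flow.kernel_V, x, a, a)


def flow_at_time(flow: Flow, t: float) -> tuple[np.ndarray, np.ndarray]:
    """(points, momenta) at time t in [0, 1]."""
    return flow.state_at(t)


def transport_points(
    flow: Flow, query: np.ndarray, t_start: float, t_end: float
) -> np.ndarray:
    """Carry query points by the flow's velocity field from t_start to t_end.

    Uses the same Heun rule on dy/dt = v(y, t), with the stored trajectory
    (interpolated off-grid) supplying v.  Reverse time (t_start > t_end)
    re-integrates the ODE backwards; it does not invert a map numerically.
    """
    for t in (t_start, t_end):
        if t < -1e-12 or t > 1 + 1e-12:
            raise ValueError(f"time {t} outside [0, 1]")
    y = np.atleast_2d(np.asarray(query, dtype=float)).copy()
    if t_start == t_end:
        return y
    cfg = flow.kernel_V
    dt_g = 1.0 / flow.n_steps

    def vel(pts: np.ndarray, t: float) -> np.ndarray:
        xs, als = flow.state_at(t)
        return convolve(cfg, pts, xs, als)

    # Breakpoints: t_start -> t_end hitting every grid node in between, so
    # grid-aligned forward steps can reuse the shooting predictor states and
    # carry the control points bit-consistently with the stored trajectory.
    forward = t_end > t_start
    eps = 1e-12
    nodes = flow.times[(flow.times > min(t_start, t_end) + eps) & (flow.times < max(t_start, t_end) - eps)]
    inner = nodes if forward else nodes[::-1]
    breaks = np.concatenate(([t_start], inner, [t_end]))

    for ta, tb in zip(breaks[:-1], breaks[1:]):
        dt = tb - ta
        k = int(round(ta * flow.n_steps))
        if forward and abs(ta - k * dt_g) < eps and abs(tb - (k + 1) * dt_g) < eps:
            # exact shooting step: corrector velocity from the predictor state
            xk, ak = flow.traj_x[k], flow.traj_alpha[k]
            dx1, da1 = geodesic_rhs(cfg, xk, ak)
            xp, ap = xk + dt * dx1, ak + dt * da1
            v1 = convolve(cfg, y, xk, ak)
            v2 = convolve(cfg, y + dt * v1, xp, ap)
        else:
            v1 = vel(y, ta)
            v2 = vel(y + dt * v1, tb)
        y = y + 0.5 * dt * (v1 + v2)
        if not np.all(np.isfinite(y)):
            raise ShootingDivergence("non-finite transported points")
    return y


def deform_mesh(
    flow: Flow, mesh: TriangleMesh, t_start: float = 0.0, t_end: float = 1.0
) -> TriangleMesh:
    """Transport the mesh vertices along the flow; connectivity is untouched."""
    return mesh.with_vertices(transport_points(flow, mesh.vertices, t_start, t_end))
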
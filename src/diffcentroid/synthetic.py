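"""Synthetic shape populations with a known exact centre.

A population of N shapes is generated by geodesic shooting of one base
shape S0 along momenta alpha^i = k1 b1 + k2 b2 + k3 b3, where b1, b2 are
random orthogonal momentum fields spanning a 2D subspace, b3 adds weak
noise off that plane, and k_j ~ N(0, sigma_j) with sigma1 > sigma2 >>
sigma3.  Subjects come in antipodal pairs (alpha^{i+N/2} = -alpha^i), so
the momenta sum to zero exactly and S0 is the exact centre of the
population — which makes these populations the ground truth for judging
how well-centred an estimated centroid is.

Default scales: sigma_V = 15 mm (about half the base-shape length, a
hippocampus-sized bent ellipsoid), sigma1 = 0.30 sigma_V, sigma2 =
0.21 sigma_V, sigma3 = sigma2 / 20.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh as _trimesh

from .geodesics import MomentaField, shoot, transport_points
from .kernels import KernelConfig, quadratic_form
from .mesh_io import TriangleMesh

__all__ = ["SyntheticConfig", "SyntheticPopulation", "make_base_shape", "generate_population"]

DEFAULT_SIGMA_V = 15.0


def make_base_shape(
    n_vertices_target: int = 162,
    kind: str = "bent_ellipsoid",
    seed: int = 0,
) -> TriangleMesh:
    """Closed, consistently oriented base shape.

    ``icosphere``: unit-radius icosphere scaled to 10 mm radius at the
    subdivision level whose vertex count (10 * 4^L + 2) first reaches the
    target.  ``bent_ellipsoid``: the same sphere anisotropically scaled to
    semi-axes (15, 6, 5) mm and bent into a banana-like arc, mimicking
    hippocampal geometry.  Deterministic for a given seed.
    """
    if n_vertices_target < 12:
        raise ValueError("n_vertices_target must be >= 12")
    level = 0
    while 10 * 4**level + 2 < n_vertices_target:
        level += 1
    ico = _trimesh.creation.icosphere(subdivisions=level, radius=1.0)
    v = np.asarray(ico.vertices, dtype=float)
    f = np.asarray(ico.faces, dtype=np.int64)
    if kind == "icosphere":
        return TriangleMesh(10.0 * v, f, name=f"icosphere_L{level}")
    if kind != "bent_ellipsoid":
        raise ValueError(f"unknown base-shape kind {kind!r}")
    v = v * np.array([15.0, 6.0, 5.0])
    # gentle arc: displace y quadratically along the long axis
    v[:, 1] += 0.015 * v[:, 0] ** 2
    return TriangleMesh(v, f, name=f"bent_ellipsoid_L{level}")


@dataclass(frozen=True)
class SyntheticConfig:
    """Generation parameters for one synthetic population."""

    n_subjects: int = 50
    base_shape: TriangleMesh | None = None      # default: 162-vertex bent ellipsoid
    sigma1: float = 0.30 * DEFAULT_SIGMA_V
    sigma2: float = 0.21 * DEFAULT_SIGMA_V
    sigma3: float = 0.21 * DEFAULT_SIGMA_V / 20.0
    kernel_V: KernelConfig = field(default_factory=lambda: KernelConfig("cauchy", DEFAULT_SIGMA_V))
    n_steps: int = 10
    orthogonalize: str = "euclidean"            # or "kernel"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects % 2 != 0:
            raise ValueError("n_subjects must be even (antipodal pairing)")
        if not (self.sigma1 > self.sigma2 > self.sigma3 >= 0):
            raise ValueError("need sigma1 > sigma2 > sigma3 >= 0")


@dataclass
class SyntheticPopulation:
    shapes: list[TriangleMesh]
    momenta: list[MomentaField]        # the generating momenta, at S0's vertices
    basis: tuple[np.ndarray, np.ndarray, np.ndarray]
    base_shape: TriangleMesh
    config: SyntheticConfig


def _unit_k_norm(field_: np.ndarray, pts: np.ndarray, kV: KernelConfig) -> np.ndarray:
    nrm = np.sqrt(quadratic_form(kV, pts, field_, field_))
    if nrm == 0:
        raise ValueError("cannot normalize a zero momentum field")
    return field_ / nrm


def generate_population(cfg: SyntheticConfig) -> SyntheticPopulation:
    """Draw one population; the sum of generating momenta is exactly zero."""
    rng = np.random.default_rng(cfg.seed)
    base = cfg.base_shape if cfg.base_shape is not None else make_base_shape()
    pts = base.vertices
    kV = cfg.kernel_V
    n = base.n_vertices

    b1 = rng.standard_normal((n, 3))
    b2 = rng.standard_normal((n, 3))
    b3 = rng.standard_normal((n, 3))
    if cfg.orthogonalize == "kernel":
        def inner(u, v):
            return quadratic_form(kV, pts, u, v)
    else:
        def inner(u, v):
            return float(np.sum(u * v))
    b2 = b2 - inner(b2, b1) / inner(b1, b1) * b1
    b1 = _unit_k_norm(b1, pts, kV)
    b2 = _unit_k_norm(b2, pts, kV)
    b3 = _unit_k_norm(b3, pts, kV)

    half = cfg.n_subjects // 2
    ks = np.column_stack(
        [
            rng.normal(0.0, cfg.sigma1, size=half),
            rng.normal(0.0, cfg.sigma2, size=half),
            rng.normal(0.0, cfg.sigma3, size=half),
        ]
    )
    alphas = [k[0] * b1 + k[1] * b2 + k[2] * b3 for k in ks]
    alphas += [-a for a in alphas]              # exact zero-sum by pairing

    shapes: list[TriangleMesh] = []
    momenta: list[MomentaField] = []
    for i, a in enumerate(alphas):
        m = MomentaField(pts, a, kV)
        try:
            flow = shoot(m, cfg.n_steps)
        except Exception as exc:
            raise RuntimeError(
                "geodesic shooting diverged while generating the population; "
                "reduce sigma1 relative to sigma_V"
            ) from exc
        shapes.append(
            base.with_vertices(transport_points(flow, pts, 0.0, 1.0))
        )
        shapes[-1].name = f"subject_{i:03d}"
        momenta.append(m)
    return SyntheticPopulation(
        shapes=shapes, momenta=momenta, basis=(b1, b2, b3), base_shape=base, config=cfg
    )
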
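"""Surfaces as currents: vectorial-Dirac representation and W* metric.

An oriented surface S acts on a test vector field w by integrating the
normal component of w over S.  Discretely, each triangle contributes one
vectorial Dirac placed at its barycenter and weighted by the area-scaled
face normal, so a mesh becomes a finite sum of Diracs in the dual space W*.
Inner products between currents are closed-form double sums through the
kernel of W, which is what makes this representation usable as a
correspondence-free data-attachment metric: weighted unions of surfaces
(the IC2 centroid, the variational template) live in the same space and
enter matching through the same inner products.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .kernels import KernelConfig, kernel_matrix
from .mesh_io import TriangleMesh

__all__ = ["CurrentRep", "to_current", "current_inner", "current_sqdist", "combine_currents"]


@dataclass
class CurrentRep:
    """Finite sum of vectorial Diracs representing a (union of) surface(s).

    centers : (m, 3) Dirac locations (triangle barycenters, mm).
    eta : (m, 3) weights: per-face area-scaled normals (mm^2), already
        multiplied by the scalar weight of the shape they come from.
    source_weights : scalar weight of each contributing shape (unitless).
    """

    centers: np.ndarray
    eta: np.ndarray
    source_weights: np.ndarray = field(default_factory=lambda: np.ones(1))

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.eta = np.atleast_2d(np.asarray(self.eta, dtype=float))
        self.source_weights = np.atleast_1d(np.asarray(self.source_weights, dtype=float))
        if self.centers.shape != self.eta.shape:
            raise ValueError(
                f"centers {self.centers.shape} and eta {self.eta.shape} must match"
            )
        if np.any(self.source_weights <= 0):
            raise ValueError("source weights must be > 0")

    @property
    def n_diracs(self) -> int:
        return len(self.centers)


def to_current(mesh: TriangleMesh, weight: float = 1.0) -> CurrentRep:
    """One Dirac per face at the barycenter, eta = weight * (e1 x e2) / 2."""
    if weight <= 0:
        raise ValueError("weight must be > 0")
    v, f = mesh.vertices, mesh.faces
    centers = v[f].mean(axis=1)
    eta = 0.5 * weight * np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    return CurrentRep(centers, eta, np.array([weight]))


def current_inner(a: CurrentRep, b: CurrentRep, kW: KernelConfig) -> float:
    """<[A], [B]>_{W*} = sum_{f,g} h(||c_f - c_g||^2/sigma_W^2) <eta_f, eta_g>."""
    K = kernel_matrix(kW, a.centers, b.centers)
    return float(np.einsum("fi,fg,gi->", a.eta, K, b.eta))


def current_sqdist(a: CurrentRep, b: CurrentRep, kW: KernelConfig) -> float:
    """||[A] - [B]||^2_{W*}; clamped at 0 against floating-point cancellation."""
    aa = current_inner(a, a, kW)
    bb = current_inner(b, b, kW)
    ab = current_inner(a, b, kW)
    d = aa + bb - 2.0 * ab
    if d < 0:
        if d < -1e-8 * max(aa, 1e-300):
            warnings.warn(
                f"currents squared distance {d} below the cancellation floor; clamping to 0",
                stacklevel=2,
            )
        d = 0.0
    return d


def combine_currents(parts: list[tuple[CurrentRep, float]]) -> CurrentRep:
    """Weighted union: concatenate Diracs, scale eta by the weights.

    Linear in each part: inner(combine([(a, w)]), b) == w * inner(a, b).
    """
    if not parts:
        raise ValueError("combine_currents needs at least one part")
    centers, etas, weights = [], [], []
    for rep, w in parts:
        if w <= 0:
            raise ValueError("combination weights must be > 0")
        centers.append(rep.centers)
        etas.append(w * rep.eta)
        weights.append(w * rep.source_weights)
    return CurrentRep(
        np.vstack(centers), np.vstack(etas), np.concatenate(weights)
    )
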
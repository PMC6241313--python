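"""Test doubles: exact Euclidean translator and identity-kernel helpers.

The Euclidean matcher replaces LDDMM pairwise matching by exact straight
lines between shape barycenters (a flat shape space).  Under it, every
centroid estimator must return the arithmetic mean of the inputs exactly,
which pins down the recursion weights independently of matching accuracy.
"""

from __future__ import annotations

import numpy as np

from .kernels import KernelConfig
from .mesh_io import TriangleMesh

__all__ = ["EuclideanMatcher", "identity_kernel"]


def identity_kernel() -> KernelConfig:
    """Kernel whose Gram matrix is the identity on distinct points.

    Turns kernel PCA and K-norms into their plain Euclidean counterparts,
    enabling cross-checks against standard covariance eigendecompositions.
    """
    return KernelConfig("identity", 1.0)


class _TranslationStep:
    """Constant-velocity flow y(t) = y + t * v."""

    def __init__(self, v: np.ndarray):
        self.v = v

    def carry(self, points: np.ndarray, t_start: float, t_end: float) -> np.ndarray:
        return np.asarray(points, dtype=float) + (t_end - t_start) * self.v


class EuclideanMatcher:
    """Exact matcher in a flat space: geodesics are straight translations.

    The estimated "deformation" carries every point by the difference of
    barycenters (weighted, for collections), so single-point shapes follow
    exact Euclidean geodesics.
    """

    def __init__(self):
        self.n_calls = 0

    @staticmethod
    def _barycenter(obj) -> np.ndarray:
        if isinstance(obj, TriangleMesh):
            return obj.vertices.mean(axis=0)
        # weighted collection [(mesh, w)]
        num = np.zeros(3)
        den = 0.0
        for mesh, w in obj:
            num += w * mesh.vertices.mean(axis=0)
            den += w
        return num / den

    def __call__(self, source, target) -> _TranslationStep:
        self.n_calls += 1
        return _TranslationStep(self._barycenter(target) - self._barycenter(source))
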
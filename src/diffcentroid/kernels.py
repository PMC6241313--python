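"""Scalar-invariant kernels for the deformation space V and the currents space W.

Both spaces are reproducing kernel Hilbert spaces with a kernel of the form
``K(x, y) = h(||x - y||^2 / sigma^2) * I_3``, where ``h`` is a scalar profile.
The default profile is the Cauchy kernel ``h(r) = 1/(1+r)``; a Gaussian
profile ``h(r) = exp(-r)`` is available as an option.  Because the kernel is
a scalar times the 3x3 identity, all operations work on the scalar kernel
matrix and never materialize 3x3 blocks.

Everything here is dense O(n^2) numpy; populations in this package stay at
the scale of a few hundred control points per shape, where dense evaluation
is both the fastest and the most transparent choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "KernelConfig",
    "kernel_value",
    "kernel_matrix",
    "convolve",
    "quadratic_form",
    "grad_quadratic_form",
]

_FAMILIES = ("cauchy", "gaussian", "identity")


@dataclass(frozen=True)
class KernelConfig:
    """Kernel family and length scale (mm).

    ``identity`` is a testing family: h(r) = 1 iff r == 0, i.e. the kernel
    Gram matrix is the identity for distinct points.  It turns kernel
    operations into plain Euclidean ones and exists so statistical layers
    can be cross-checked against standard (non-kernel) oracles.
    """

    family: str = "cauchy"
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown kernel family {self.family!r}; choose from {_FAMILIES}")
        if not (self.sigma > 0):
            raise ValueError(f"kernel sigma must be > 0, got {self.sigma}")

    # scalar profile h and its derivatives, vectorized over r >= 0
    def h(self, r: np.ndarray) -> np.ndarray:
        if self.family == "cauchy":
            return 1.0 / (1.0 + r)
        if self.family == "gaussian":
            return np.exp(-r)
        return (r == 0).astype(float)

    def h1(self, r: np.ndarray) -> np.ndarray:
        """First derivative h'(r)."""
        if self.family == "cauchy":
            return -1.0 / (1.0 + r) ** 2
        if self.family == "gaussian":
            return -np.exp(-r)
        raise ValueError("identity kernel is not differentiable")

    def h2(self, r: np.ndarray) -> np.ndarray:
        """Second derivative h''(r)."""
        if self.family == "cauchy":
            return 2.0 / (1.0 + r) ** 3
        if self.family == "gaussian":
            return np.exp(-r)
        raise ValueError("identity kernel is not differentiable")


def _as_points(x) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim == 1:
        a = a[None, :]
    if a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"expected (n, 3) points, got shape {a.shape}")
    return a


def _sq_dists(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    # ||x||^2 + ||y||^2 - 2 x.y via gemm; clip tiny negative cancellations
    xx = np.einsum("ij,ij->i", x, x)
    yy = xx if y is x else np.einsum("ij,ij->i", y, y)
    d = xx[:, None] + yy[None, :] - 2.0 * (x @ y.T)
    np.maximum(d, 0.0, out=d)
    if y is x:
        np.fill_diagonal(d, 0.0)
    return d


def kernel_matrix(cfg: KernelConfig, x, y=None) -> np.ndarray:
    """Scalar kernel matrix ``h(||x_i - y_j||^2 / sigma^2)``, shape (n, m)."""
    x = _as_points(x)
    y = x if y is None else _as_points(y)
    return cfg.h(_sq_dists(x, y) / cfg.sigma**2)


def kernel_value(cfg: KernelConfig, x, y) -> float:
    """Scalar kernel value between two single points.

    The full 3x3 kernel is this scalar times the identity.
    """
    x = np.asarray(x, dtype=float).reshape(3)
    y = np.asarray(y, dtype=float).reshape(3)
    r = float(np.dot(x - y, x - y)) / cfg.sigma**2
    return float(cfg.h(np.asarray(r)))


def convolve(cfg: KernelConfig, targets, sources, vectors) -> np.ndarray:
    """Kernel convolution: out[q] = sum_p h(||t_q - s_p||^2/sigma^2) v_p.

    This evaluates the RKHS vector field with momenta ``vectors`` attached at
    ``sources``, at the ``targets``; it is linear in ``vectors``.
    """
    sources = _as_points(sources)
    vectors = np.asarray(vectors, dtype=float)
    if vectors.ndim == 1:
        vectors = vectors[None, :]
    if vectors.shape != sources.shape:
        raise ValueError(
            f"sources {sources.shape} and vectors {vectors.shape} must have equal shapes"
        )
    return kernel_matrix(cfg, targets, sources) @ vectors


def quadratic_form(cfg: KernelConfig, points, a, b) -> float:
    """a^T K(points) b = sum_{p,q} h(||x_p - x_q||^2/sigma^2) <a_p, b_q>."""
    points = _as_points(points)
    a = np.asarray(a, dtype=float).reshape(points.shape)
    b = np.asarray(b, dtype=float).reshape(points.shape)
    K = kernel_matrix(cfg, points)
    return float(np.einsum("pi,pq,qi->", a, K, b))


def grad_quadratic_form(cfg: KernelConfig, points, a) -> np.ndarray:
    """Analytic gradient of ``a^T K(x) a`` with respect to each point x_p.

    grad_p = (4/sigma^2) sum_q h'(r_pq) (x_p - x_q) <a_p, a_q>.
    """
    x = _as_points(points)
    a = np.asarray(a, dtype=float).reshape(x.shape)
    r = _sq_dists(x, x) / cfg.sigma**2
    w = cfg.h1(r) * (a @ a.T)  # h'(r_pq) <a_p, a_q>
    # sum_q w_pq (x_p - x_q) = rowsum(w) x_p - (w @ x)_p
    return (4.0 / cfg.sigma**2) * (w.sum(axis=1)[:, None] * x - w @ x)
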
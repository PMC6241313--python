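"""Tangent-space statistics at an estimated centre.

Initial momentum vectors from the centre to each subject are coordinates in
one linear space (the tangent space at the centre, with the K_V inner
product).  This module extracts them, runs kernel PCA on them, measures how
well-centred the centre is (ratio R), and builds pairwise-distance matrices
either directly (O(N^2) matchings) or by the first-order tangent-space
approximation (N matchings).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .centroids import CentroidResult
from .geodesics import MomentaField, shoot
from .kernels import KernelConfig, kernel_matrix, quadratic_form
from .matching import MatchConfig, match
from .mesh_io import TriangleMesh
from .template import TemplateResult

logger = logging.getLogger(__name__)

__all__ = [
    "PCAResult",
    "DistanceMatrix",
    "DegenerateMomentaError",
    "extract_momenta",
    "kernel_pca",
    "subject_coordinates",
    "shoot_mode",
    "centring_ratio",
    "approx_distance_matrix",
    "direct_distance_matrix",
    "matrix_error",
]


class DegenerateMomentaError(ValueError):
    """All momenta vanish; the requested statistic is undefined."""


@dataclass
class PCAResult:
    """Kernel PCA of initial momenta.

    eigenvalues: lambda_1 >= ... >= lambda_N (variance units); eigenvectors
    holds nu^k as rows; modes holds the momentum fields m^k = mean + sum_j
    nu^k_j (alpha_j - mean); cev is the cumulative explained variance curve
    (None when all eigenvalues vanish).
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray          # (N, N), row k = nu^k over subjects
    mean_momenta: np.ndarray          # (n, 3)
    modes: np.ndarray                 # (N, n, 3)
    cev: np.ndarray | None
    points: np.ndarray                # shared control points (n, 3)
    kernel_V: KernelConfig

    @property
    def degenerate(self) -> bool:
        return self.cev is None


@dataclass
class DistanceMatrix:
    """Symmetric, zero-diagonal, non-negative pairwise dissimilarities."""

    values: np.ndarray
    kind: str  # "approximated" | "direct"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        self.values = v


def _shared_points(momenta: list[MomentaField]) -> np.ndarray:
    pts = momenta[0].points
    for m in momenta[1:]:
        if m.points.shape != pts.shape or not np.allclose(m.points, pts, atol=1e-9):
            raise ValueError("momenta do not share one control-point set")
    return pts


def extract_momenta(
    centre: CentroidResult | TemplateResult | TriangleMesh,
    shapes: list[TriangleMesh],
    cfg: MatchConfig,
) -> list[MomentaField]:
    """Initial momenta from the centre to each subject, on one shared point set.

    Mesh centres (IC1, PW, or a raw mesh such as the exact centre of a
    synthetic population) are matched centre -> subject directly, so all
    momenta live on the centre's vertices.  Collection centres (IC2,
    variational template) are too expensive to shoot from; instead each
    subject is matched to the centre-current and the momenta are reversed,
    -alpha(1) at the transported subject vertices, then kernel-interpolated
    onto one shared point set (the first subject's transported points).
    """
    if isinstance(centre, TriangleMesh):
        mesh, collection = centre, None
    elif isinstance(centre, TemplateResult):
        if centre.per_subject_momenta:
            return _reconcile_points(centre.per_subject_momenta, cfg.kernel_V)
        mesh, collection = None, centre.as_collection()
    elif centre.is_collection:
        mesh, collection = None, centre.as_collection()
    else:
        mesh, collection = centre.centre, None

    out: list[MomentaField] = []
    if mesh is not None:
        for i, s in enumerate(shapes):
            try:
                res = match(mesh, s, cfg)
            except Exception as exc:
                raise RuntimeError(f"momenta extraction failed for subject {i}") from exc
            out.append(res.momenta)
        return out

    for i, s in enumerate(shapes):
        try:
            res = match(s, collection, cfg)
        except Exception as exc:
            raise RuntimeError(f"momenta extraction failed for subject {i}") from exc
        rev = res.final_momenta()
        out.append(MomentaField(rev.points, -rev.alpha, cfg.kernel_V))
    return _reconcile_points(out, cfg.kernel_V)


def _reconcile_points(momenta: list[MomentaField], kV: KernelConfig) -> list[MomentaField]:
    """Re-express reversal momenta on one shared point set.

    The reversed momenta of different subjects sit at different transported
    vertex sets.  Each momentum field defines a velocity field v_i =
    sum_p K_V(., y_p) alpha_p; we solve for momenta on the first subject's
    points that reproduce v_i there (kernel interpolation, per coordinate,
    with a tiny ridge for conditioning).
    """
    shared = momenta[0].points
    same = all(
        m.points.shape == shared.shape and np.allclose(m.points, shared, atol=1e-9)
        for m in momenta
    )
    if same:
        return momenta
    logger.warning(
        "collection-centre momenta live on per-subject point sets; "
        "kernel-interpolating all fields onto the first subject's %d points",
        len(shared),
    )
    K_shared = kernel_matrix(kV, shared)
    K_reg = K_shared + 1e-10 * np.trace(K_shared) / len(shared) * np.eye(len(shared))
    out = []
    for m in momenta:
        v_at_shared = kernel_matrix(kV, shared, m.points) @ m.alpha
        out.append(MomentaField(shared, np.linalg.solve(K_reg, v_at_shared), kV))
    return out


def kernel_pca(momenta: list[MomentaField], kernel: KernelConfig | None = None) -> PCAResult:
    """PCA of initial momenta under the K_V inner product.

    The N x N covariance C(i, j) = (a_i - abar)^T K_V(x) (a_j - abar)/(N-1)
    is symmetrized and eigendecomposed; eigenvalues are the per-mode
    variances of the corresponding initial velocity fields.
    """
    pts = _shared_points(momenta)
    kV = kernel or momenta[0].kernel_V
    N = len(momenta)
    A = np.stack([m.alpha for m in momenta])          # (N, n, 3)
    mean = A.mean(axis=0)
    Ac = A - mean
    K = kernel_matrix(kV, pts)
    KA = np.einsum("pq,jqi->jpi", K, Ac)
    C = np.einsum("ipk,jpk->ij", Ac, KA) / max(N - 1, 1)
    C = 0.5 * (C + C.T)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order].T                          # rows = nu^k
    modes = mean[None] + np.einsum("kj,jpi->kpi", evecs, Ac)
    total = evals.sum()
    if total <= 1e-14 * max(1.0, abs(evals).max() if len(evals) else 1.0):
        cev = None
    else:
        cev = np.cumsum(evals) / total
    return PCAResult(
        eigenvalues=evals,
        eigenvectors=evecs,
        mean_momenta=mean,
        modes=modes,
        cev=cev,
        points=pts,
        kernel_V=kV,
    )


def shoot_mode(
    pca: PCAResult,
    centre: TriangleMesh,
    k: int,
    c: float,
    n_steps: int = 10,
) -> TriangleMesh:
    """Deform the centre along principal mode k by geodesic shooting.

    The mode deviation sum_j nu^k_j (alpha_j - mean) is normalized to unit
    K-norm so that |c| is a geodesic distance; c in [-2 sqrt(lambda_k),
    +2 sqrt(lambda_k)] spans two standard deviations.  c = 0 returns the
    centre unchanged.
    """
    if pca.degenerate or pca.eigenvalues[k] <= 1e-12 * max(1.0, float(pca.eigenvalues[0])):
        raise DegenerateMomentaError(f"mode {k} has no variance")
    if c == 0:
        return centre.copy()
    dev = pca.modes[k] - pca.mean_momenta
    nrm = np.sqrt(quadratic_form(pca.kernel_V, pca.points, dev, dev))
    alpha = (c / nrm) * dev
    flow = shoot(MomentaField(pca.points, alpha, pca.kernel_V), n_steps)
    from .geodesics import transport_points

    return centre.with_vertices(transport_points(flow, centre.vertices, 0.0, 1.0))


def subject_coordinates(pca: PCAResult) -> np.ndarray:
    """Per-subject scores on the principal modes, shape (N, N).

    The score of subject j on mode k is the K_V projection of its centred
    momenta onto the unit-norm mode, which reduces to
    sqrt((N-1) lambda_k) nu^k_j; column k spans mode k.
    """
    lam = np.maximum(pca.eigenvalues, 0.0)
    scale = np.sqrt((len(lam) - 1) * lam)
    return pca.eigenvectors.T * scale[None, :]


def centring_ratio(momenta: list[MomentaField]) -> float:
    """R = ||sum_i v_i(., 0)||_V / sum_i ||v_i(., 0)||_V, in [0, 1].

    Zero exactly at a critical point of the Frechet functional; the triangle
    inequality bounds it by 1.  Undefined (raises) when all momenta vanish.
    """
    pts = _shared_points(momenta)
    kV = momenta[0].kernel_V
    norms = [np.sqrt(max(quadratic_form(kV, pts, m.alpha, m.alpha), 0.0)) for m in momenta]
    denom = float(np.sum(norms))
    if denom == 0.0:
        raise DegenerateMomentaError("all momenta are zero; centring ratio undefined")
    total = np.sum([m.alpha for m in momenta], axis=0)
    num = np.sqrt(max(quadratic_form(kV, pts, total, total), 0.0))
    return float(num / denom)


def approx_distance_matrix(momenta: list[MomentaField]) -> DistanceMatrix:
    """First-order pairwise distances: K-norm of momentum differences."""
    pts = _shared_points(momenta)
    kV = momenta[0].kernel_V
    N = len(momenta)
    A = np.stack([m.alpha for m in momenta])
    K = kernel_matrix(kV, pts)
    KA = np.einsum("pq,jqi->jpi", K, A)
    G = np.einsum("ipk,jpk->ij", A, KA)               # Gram of momenta
    sq = np.maximum(np.diag(G)[:, None] + np.diag(G)[None, :] - 2 * G, 0.0)
    np.fill_diagonal(sq, 0.0)
    return DistanceMatrix(np.sqrt(sq), kind="approximated")


def direct_distance_matrix(shapes: list[TriangleMesh], cfg: MatchConfig) -> DistanceMatrix:
    """Pairwise diffeomorphic distances by explicit matchings.

    Matching is not exactly symmetric; entries are computed for i < j
    (source = lower index) and mirrored, halving the O(N^2) cost.
    """
    N = len(shapes)
    if N < 2:
        raise ValueError("need at least two shapes")
    vals = np.zeros((N, N))
    for i in range(N):
        for j in range(i + 1, N):
            try:
                res = match(shapes[i], shapes[j], cfg)
            except Exception as exc:
                raise RuntimeError(f"direct distance matching failed for pair ({i}, {j})") from exc
            d = float(np.sqrt(max(res.energy, 0.0)))
            vals[i, j] = vals[j, i] = d
    return DistanceMatrix(vals, kind="direct")


def matrix_error(m1: DistanceMatrix | np.ndarray, m2: DistanceMatrix | np.ndarray) -> float:
    """e = (1/N^2) sum_{i,j} |M1 - M2| / max(M1, M2), with 0/0 terms = 0."""
    a = m1.values if isinstance(m1, DistanceMatrix) else np.asarray(m1, dtype=float)
    b = m2.values if isinstance(m2, DistanceMatrix) else np.asarray(m2, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    mx = np.maximum(a, b)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(mx > 0, np.abs(a - b) / np.where(mx > 0, mx, 1.0), 0.0)
    return float(terms.sum() / a.size)
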
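"""Iterative centroid estimators over a shape population.

All three estimators decompose the Euclidean running-mean recursion
b_{k+1} = (k b_k + x_{k+1}) / (k+1) into pairwise geodesic convex
combinations, performing exactly N-1 matchings:

* IC1 carries a single mesh: match the current centroid to the next shape
  and step 1/(k+1) of the way along the geodesic.
* IC2 carries a weighted union of surfaces in current space: the existing
  members flow forward to t = 1/(k+1), the new shape flows backward along
  the same matching to the meeting time, and all members end with equal
  weight.
* PW recursively splits the population in two, averages each half, and
  combines the halves at the time dictated by their sizes.

The result depends on the subject ordering; orderings are always recorded.
A ``matcher`` hook allows substituting the LDDMM pairwise matcher (e.g. by
an exact Euclidean translator in tests of the mean-recovery property).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .geodesics import transport_points
from .matching import MatchConfig, MatchResult, match
from .mesh_io import TriangleMesh

__all__ = ["CentroidResult", "LDDMMPairMatcher", "ic1_centroid", "ic2_centroid", "pw_centroid"]


class CentroidError(RuntimeError):
    """A pairwise matching failed during centroid estimation."""


@dataclass
class CentroidResult:
    """Estimated population centre with provenance.

    ``centre`` is a single mesh (IC1, PW) or None; ``collection`` holds the
    weighted surfaces of a current-space centre (IC2).  ``step_log`` keeps a
    per-matching summary; ``ordering`` the subject permutation used.
    """

    centre: TriangleMesh | None
    collection: list[tuple[TriangleMesh, float]] | None
    ordering: list[int]
    step_log: list[dict]
    n_matchings: int
    method: str

    @property
    def is_collection(self) -> bool:
        return self.collection is not None

    def as_collection(self) -> list[tuple[TriangleMesh, float]]:
        if self.collection is not None:
            return self.collection
        return [(self.centre, 1.0)]


class _LDDMMStep:
    """One estimated pairwise geodesic, able to carry points along itself."""

    def __init__(self, result: MatchResult):
        self.result = result

    def carry(self, points: np.ndarray, t_start: float, t_end: float) -> np.ndarray:
        return transport_points(self.result.flow, points, t_start, t_end)

    def summary(self) -> dict:
        r = self.result
        return {
            "energy": r.energy,
            "data_term": r.data_term,
            "functional": r.functional,
            "n_iter": r.n_iter,
            "converged": r.converged,
        }


class LDDMMPairMatcher:
    """Default pairwise matcher: full multiscale LDDMM at every step."""

    def __init__(self, cfg: MatchConfig):
        self.cfg = cfg

    def __call__(self, source, target) -> _LDDMMStep:
        return _LDDMMStep(match(source, target, self.cfg))


def _resolve_ordering(n: int, ordering) -> list[int]:
    if ordering is None:
        return list(range(n))
    if isinstance(ordering, (int, np.integer)):
        rng = np.random.default_rng(int(ordering))
        return list(rng.permutation(n))
    perm = [int(i) for i in ordering]
    if sorted(perm) != list(range(n)):
        raise ValueError(f"ordering must be a permutation of range({n})")
    return perm


def ic1_centroid(
    shapes: Sequence[TriangleMesh],
    cfg: MatchConfig,
    ordering=None,
    matcher: Callable | None = None,
) -> CentroidResult:
    """Direct iterative centroid: the centre is a deformation of the first shape."""
    if len(shapes) == 0:
        raise ValueError("need at least one shape")
    order = _resolve_ordering(len(shapes), ordering)
    matcher = matcher or LDDMMPairMatcher(cfg)
    centre = shapes[order[0]].copy()
    log: list[dict] = []
    for k in range(1, len(shapes)):
        target = shapes[order[k]]
        try:
            step = matcher(centre, target)
        except Exception as exc:
            raise CentroidError(f"IC1 matching failed at step {k} (subject {order[k]})") from exc
        centre = centre.with_vertices(step.carry(centre.vertices, 0.0, 1.0 / (k + 1)))
        entry = {"step": k, "t": 1.0 / (k + 1), "subject": order[k]}
        if hasattr(step, "summary"):
            entry.update(step.summary())
        log.append(entry)
    centre.name = "ic1_centroid"
    return CentroidResult(
        centre=centre,
        collection=None,
        ordering=order,
        step_log=log,
        n_matchings=len(log),
        method="ic1",
    )


def ic2_centroid(
    shapes: Sequence[TriangleMesh],
    cfg: MatchConfig,
    ordering=None,
    matcher: Callable | None = None,
) -> CentroidResult:
    """Iterative centroid with averaging in current space.

    The centroid after k subjects is a union of k surfaces with weight 1/k
    each; matching shoots from the union's full vertex set, which is what
    makes IC2 the costlier estimator.
    """
    if len(shapes) == 0:
        raise ValueError("need at least one shape")
    order = _resolve_ordering(len(shapes), ordering)
    matcher = matcher or LDDMMPairMatcher(cfg)
    members: list[TriangleMesh] = [shapes[order[0]].copy()]
    log: list[dict] = []
    for k in range(1, len(shapes)):
        target = shapes[order[k]]
        source = [(m, 1.0 / k) for m in members]
        try:
            step = matcher(source, target)
        except Exception as exc:
            raise CentroidError(f"IC2 matching failed at step {k} (subject {order[k]})") from exc
        t_meet = 1.0 / (k + 1)
        # the matching flow is parametrized over the union's vertices: carry
        # members forward and the new shape backward along the same flow
        members = [m.with_vertices(step.carry(m.vertices, 0.0, t_meet)) for m in members]
        members.append(target.with_vertices(step.carry(target.vertices, 1.0, t_meet)))
        entry = {"step": k, "t": t_meet, "subject": order[k]}
        if hasattr(step, "summary"):
            entry.update(step.summary())
        log.append(entry)
    w = 1.0 / len(members)
    return CentroidResult(
        centre=None,
        collection=[(m, w) for m in members],
        ordering=order,
        step_log=log,
        n_matchings=len(log),
        method="ic2",
    )


def pw_centroid(
    shapes: Sequence[TriangleMesh],
    cfg: MatchConfig,
    matcher: Callable | None = None,
) -> CentroidResult:
    """Pairwise (dyadic) centroid: recursive splitting, size-weighted merges.

    Combining subtree centroids of sizes n_a and n_b matches B_a onto B_b
    and takes the flow at t = n_b / (n_a + n_b); odd splits put the extra
    subject in the left subtree.
    """
    if len(shapes) == 0:
        raise ValueError("need at least one shape")
    matcher = matcher or LDDMMPairMatcher(cfg)
    log: list[dict] = []

    def recurse(idx: list[int]) -> tuple[TriangleMesh, int]:
        if len(idx) == 1:
            return shapes[idx[0]].copy(), 1
        half = (len(idx) + 1) // 2
        left, n_a = recurse(idx[:half])
        right, n_b = recurse(idx[half:])
        try:
            step = matcher(left, right)
        except Exception as exc:
            raise CentroidError(f"PW matching failed combining groups {idx[:half]} | {idx[half:]}") from exc
        t = n_b / (n_a + n_b)
        merged = left.with_vertices(step.carry(left.vertices, 0.0, t))
        entry = {"t": t, "group_sizes": (n_a, n_b)}
        if hasattr(step, "summary"):
            entry.update(step.summary())
        log.append(entry)
        return merged, n_a + n_b

    centre, total = recurse(list(range(len(shapes))))
    centre.name = "pw_centroid"
    return CentroidResult(
        centre=centre,
        collection=None,
        ordering=list(range(len(shapes))),
        step_log=log,
        n_matchings=len(log),
        method="pw",
    )
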
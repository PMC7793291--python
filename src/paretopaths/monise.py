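"""Supported non-dominated least-cost paths via multiobjective non-inferior
set estimation (MONISE).

The search runs in weight space.  Three anchor solves (near-unit weight on
one objective, small ``delta`` on the others) seed the frontier; the Utopia
plane through three known frontier points supplies, via its normal, the next
candidate weight vector.  Each weighted solve either rediscovers a known
frontier point or cuts strictly below the generating plane, in which case the
new point is swapped into the plane in place of each vertex in turn, giving
three child planes and three new candidate weights.  The loop ends when the
weight queue empties; every supported efficient solution reachable as a
weighted-sum optimum of an extreme point of the lower convex envelope is then
in hand.  (Unsupported efficient points are invisible to every weighted-sum
scalarization by definition; the labeling module finds those.)
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Deque, List, Optional, Tuple

import numpy as np

from .model import LandscapeNetwork, ObjectiveVector, ParetoSet, Path
from .pareto import dominates_tol
from .scalar import WeightVector, solve_weighted, solve_anchor

__all__ = ["UtopiaPlane", "plane_normal", "monise"]

_WEIGHT_TOL = 1e-9  # duplicate-weight infinity-norm tolerance
_VEC_TOL = 1e-9  # duplicate-frontier-vector relative tolerance
_CUT_TOL = 1e-9  # plane-improvement (facet confirmation) relative tolerance
_NORMAL_FLOOR = 1e-12  # reject plane normals with any component below this


@dataclass(frozen=True)
class UtopiaPlane:
    """Plane through three frontier points, oriented toward the origin.

    ``level`` is the common weighted value ``n . y`` at the vertices under
    the normalized normal ``n``; a weighted solve below this level certifies
    a new supported frontier point.
    """

    vertices: Tuple[Tuple[float, float, float], ...]
    normal: Tuple[float, float, float]
    level: float


def plane_normal(
    vertices: Tuple[Tuple[float, float, float], ...]
) -> Optional[WeightVector]:
    """Normal of the plane through three objective vectors, as a weight.

    The cross product of the two edge vectors is sign-oriented so its
    components are nonnegative and scaled to sum one.  Returns ``None``
    (reject) for affinely dependent vertices or normals with a component at
    or below zero: such weights either define no plane or would rediscover
    boundary solutions the anchors already cover.
    """
    a, b, c = (np.asarray(v, dtype=float) for v in vertices)
    n = np.cross(b - a, c - a)
    scale = np.abs(n).max()
    if scale <= 0 or not np.isfinite(scale):
        return None
    if np.all(n <= 0):
        n = -n
    if np.any(n < _NORMAL_FLOOR * scale) or n.min() < _NORMAL_FLOOR:
        return None
    s = n.sum()
    return WeightVector(n[0] / s, n[1] / s, n[2] / s, provenance="plane-normal")


def _vec_close(a: Tuple[float, ...], b: Tuple[float, ...], tol: float = _VEC_TOL) -> bool:
    return all(abs(x - y) <= tol * max(1.0, abs(x), abs(y)) for x, y in zip(a, b))


def monise(
    network: LandscapeNetwork,
    o: str,
    d: str,
    delta: float = 1e-4,
) -> ParetoSet:
    """All supported efficient solutions for one origin-destination pair.

    Returns a :class:`ParetoSet` whose paths are all flagged supported, one
    path per distinct frontier vector, each tagged with the weight vector
    that produced it.  Deterministic: anchors, FIFO weight queue, and the
    scalar solver's tie-break are all fixed.
    """
    frontier: List[Tuple[float, float, float]] = []
    sep: List[Path] = []

    def record(path: Path) -> bool:
        v = path.objectives.as_tuple()
        for known in frontier:
            if _vec_close(v, known):
                return False
        frontier.append(v)
        path.supported = True
        sep.append(path)
        return True

    # Stage B: anchor solves seed the frontier
    for l in (1, 2, 3):
        record(solve_anchor(network, o, d, l, delta))

    queue: Deque[Tuple[WeightVector, UtopiaPlane]] = deque()
    seen_weights: List[Tuple[float, float, float]] = []

    def push(plane_vertices: Tuple[Tuple[float, float, float], ...]) -> None:
        w = plane_normal(plane_vertices)
        if w is None:
            return
        wt = w.as_tuple()
        for s in seen_weights:
            if max(abs(x - y) for x, y in zip(wt, s)) <= _WEIGHT_TOL:
                return
        seen_weights.append(wt)
        level = sum(wi * yi for wi, yi in zip(wt, plane_vertices[0]))
        queue.append((w, UtopiaPlane(tuple(plane_vertices), wt, level)))

    # Stage C: initial Utopia plane from the (deduplicated) anchor vectors
    if len(frontier) == 3:
        push(tuple(frontier))

    def drain() -> None:
        # Stage D: iterate weights until the queue empties
        while queue:
            w, plane = queue.popleft()
            path = solve_weighted(network, o, d, w)
            y = path.objectives.as_tuple()
            value = sum(wi * yi for wi, yi in zip(w.as_tuple(), y))
            cut = plane.level - value > _CUT_TOL * max(1.0, abs(plane.level))
            if record(path) and cut:
                # swap the new point into the generating plane, one vertex at a time
                for k in range(3):
                    verts = list(plane.vertices)
                    verts[k] = y
                    push(tuple(verts))

    drain()

    # Confirmation sweep: probe the lower-envelope facet normals of the found
    # frontier until no solve yields a new point.  The plane-swap recursion
    # cannot start when anchors are affinely dependent (e.g. one path minimizes
    # two objectives at once) even though further supported extreme points may
    # exist; probing hull facets closes that gap while staying entirely within
    # weighted-sum scalarization.
    while len(frontier) >= 2:
        grew = False
        for w in _envelope_normals(frontier):
            wt = w.as_tuple()
            if any(
                max(abs(x - y) for x, y in zip(wt, s)) <= _WEIGHT_TOL
                for s in seen_weights
            ):
                continue
            seen_weights.append(wt)
            if record(solve_weighted(network, o, d, w)):
                grew = True
        if not grew:
            break

    # re-drain in case the sweep is ever combined with queued planes
    drain()

    # prune points kept alive only by floating-point summation noise: an
    # anchor can undercut a true frontier point by a few ulp (elevation
    # costs telescope, so distinct routes tie mathematically) and would
    # otherwise masquerade as an extra supported solution
    kept = [
        p
        for p in sep
        if not any(
            dominates_tol(q.objectives.as_tuple(), p.objectives.as_tuple())
            for q in sep
            if q is not p
        )
    ]
    return ParetoSet(origin=o, destination=d, paths=kept)


def _envelope_normals(
    frontier: List[Tuple[float, float, float]], delta: float = 1e-6
) -> List[WeightVector]:
    """Candidate weights: inner normals of lower-envelope facets of the
    frontier's free-disposal hull ``conv(Y) + R^3_+``.

    The cone is approximated by padding every point far along each axis;
    facets whose outward normal points weakly down on every axis belong to
    the lower envelope.  Zero normal components are nudged into the strict
    interior by ``delta`` (relative) so the probing weight stays strictly
    positive.
    """
    from scipy.spatial import ConvexHull, QhullError

    y = np.asarray(frontier, dtype=float)
    span = float(np.ptp(y, axis=0).max())
    big = 10.0 * (span if span > 0 else 1.0) + 1.0
    pads = [y + big * np.eye(3)[k] for k in range(3)]
    pts = np.vstack([y] + pads)
    try:
        hull = ConvexHull(pts)
    except QhullError:
        try:
            hull = ConvexHull(pts, qhull_options="QJ")
        except QhullError:
            return []
    out: List[WeightVector] = []
    seen: List[Tuple[float, float, float]] = []
    for eq in hull.equations:
        n = -eq[:3]  # inner normal
        scale = np.abs(n).max()
        if scale <= 0 or np.any(n < -1e-9 * scale):
            continue
        n = np.clip(n, delta * scale, None)
        n = n / n.sum()
        wt = (float(n[0]), float(n[1]), float(n[2]))
        if np.min(n) <= 0 or any(
            max(abs(a - b) for a, b in zip(wt, s)) <= _WEIGHT_TOL for s in seen
        ):
            continue
        seen.append(wt)
        out.append(WeightVector(*wt, provenance="plane-normal"))
    return out
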
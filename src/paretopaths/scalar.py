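"""Weighted single-objective least-cost path solver.

The weighting method combines the three objectives into one scalar cost
``w1*f1 + w2*f2 + w3*f3`` (risk in additive log form) and solves an ordinary
least-cost path problem.  The binary-integer path LP is integral, so a
nonnegative-cost shortest-path search is an exact solver for it; no LP/MIP
machinery is needed.

Determinism: among equal-scalar-cost paths the solver prefers the
lexicographically smallest objective triple ``(f1, f2, f3)``, then the
lexicographically smallest node sequence.  All three objective components are
nonnegative and additive, so Dijkstra over the composite key is exact, and
anchor solves are reproducible.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass
from typing import Optional, Tuple

from .model import LandscapeNetwork, NetworkStructureError, ObjectiveVector, Path

__all__ = ["WeightVector", "solve_weighted", "solve_anchor", "NoPathError"]


class NoPathError(NetworkStructureError):
    """Destination unreachable from origin."""


@dataclass(frozen=True)
class WeightVector:
    """Nonnegative objective weights summing to one.

    ``provenance`` records how the weight arose: an ``"anchor"`` weight puts
    nearly all mass on one objective; a ``"plane-normal"`` weight is the
    normal of a Utopia plane through three frontier points.
    """

    w1: float
    w2: float
    w3: float
    provenance: str = "manual"

    def __post_init__(self) -> None:
        if min(self.w1, self.w2, self.w3) < 0:
            raise ValueError(f"negative weight in {self.as_tuple()}")
        if abs(self.w1 + self.w2 + self.w3 - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1 +- 1e-9, got {self.as_tuple()}")

    def as_tuple(self) -> Tuple[float, float, float]:
        return (self.w1, self.w2, self.w3)

    @classmethod
    def normalized(cls, w1: float, w2: float, w3: float, provenance: str = "manual") -> "WeightVector":
        s = w1 + w2 + w3
        if s <= 0:
            raise ValueError(f"cannot normalize nonpositive weight sum {s}")
        return cls(w1 / s, w2 / s, w3 / s, provenance)

    def scalarize(self, v: ObjectiveVector) -> float:
        return self.w1 * v.f1 + self.w2 * v.f2 + self.w3 * v.f3


def solve_weighted(
    network: LandscapeNetwork,
    o: str,
    d: str,
    w: WeightVector,
    tie_order: Tuple[int, int, int] = (1, 2, 3),
) -> Path:
    """Least-cost o->d path under the scalarized cost ``w . (f1, f2, f3)``.

    Exact label-setting (Dijkstra) search over the composite label
    ``(scalar cost, objectives in tie_order, node sequence)`` compared
    lexicographically; ``tie_order`` (a permutation of 1..3) controls which
    objective breaks scalar-cost ties first.  Zero-cost cycles
    (wetland-internal arcs) are harmless because a node is never expanded
    after it is finalized.

    Raises :class:`NoPathError` if ``d`` is unreachable.
    """
    if sorted(tie_order) != [1, 2, 3]:
        raise ValueError(f"tie_order must permute (1, 2, 3), got {tie_order}")
    if o == d:
        return Path(origin=o, destination=d, arcs=[],
                    objectives=ObjectiveVector(0.0, 0.0, 0.0), weight=w.as_tuple())
    if o not in network.nodes or d not in network.nodes:
        raise NetworkStructureError(f"unknown origin/destination {o!r}/{d!r}")

    # label: (scalar, objectives permuted by tie_order, node_seq);
    # node_seq breaks exact ties deterministically
    start = (0.0, 0.0, 0.0, 0.0, (o,))
    best = {o: start}
    heap = [(start, o)]
    done = set()
    pred: dict = {o: None}
    perm = tuple(k - 1 for k in tie_order)

    while heap:
        label, u = heapq.heappop(heap)
        if u in done or best.get(u) != label:
            continue
        done.add(u)
        if u == d:
            break
        for arc in network.out_arcs(u):
            v = arc.to_id
            if v in done:
                continue
            f = arc.objectives.as_tuple()
            cand = (
                label[0] + w.scalarize(arc.objectives),
                label[1] + f[perm[0]],
                label[2] + f[perm[1]],
                label[3] + f[perm[2]],
                label[4] + (v,),
            )
            if v not in best or cand < best[v]:
                best[v] = cand
                pred[v] = (u, arc.key)
                heapq.heappush(heap, (cand, v))

    if d not in done:
        raise NoPathError(f"no path from {o!r} to {d!r}")

    arcs = []
    node = d
    while pred[node] is not None:
        u, key = pred[node]
        arcs.append(key)
        node = u
    arcs.reverse()
    lab = best[d]
    f = [0.0, 0.0, 0.0]
    for pos, idx in enumerate(perm):
        f[idx] = lab[1 + pos]
    return Path(
        origin=o,
        destination=d,
        arcs=arcs,
        objectives=ObjectiveVector(*f),
        weight=w.as_tuple(),
    )


def solve_anchor(
    network: LandscapeNetwork,
    o: str,
    d: str,
    objective_index: int,
    delta: float = 1e-4,
) -> Path:
    """Anchor solve: the efficient path minimal in one chosen objective.

    ``objective_index`` is 1-based.  Conceptually the anchor weight puts
    nearly all mass on the chosen objective and a small ``delta`` on the
    others (e.g. ``(0.9998, 0.0001, 0.0001)``) so the anchor is efficient
    rather than merely weakly efficient.  Any fixed ``delta`` fails when the
    objectives differ in magnitude by orders (a ``delta`` share of a
    distance in the thousands swamps log-risk differences of ~0.01), so the
    solve is performed in the scale-free ``delta -> 0`` limit: unit weight
    on the chosen objective with the lexicographic tie-break ordered to put
    that objective first.  ``delta`` is accepted for interface compatibility
    and validated, but does not enter the arithmetic.
    """
    if objective_index not in (1, 2, 3):
        raise ValueError(f"objective index must be 1, 2 or 3, got {objective_index}")
    if not (0.0 < delta < 1.0 / 3.0):
        raise ValueError(f"delta must lie in (0, 1/3), got {delta}")
    ws = [0.0, 0.0, 0.0]
    ws[objective_index - 1] = 1.0
    order = (objective_index,) + tuple(k for k in (1, 2, 3) if k != objective_index)
    return solve_weighted(
        network,
        o,
        d,
        WeightVector(ws[0], ws[1], ws[2], provenance="anchor"),
        tie_order=order,  # type: ignore[arg-type]
    )
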
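"""Dominance filtering, supported/unsupported classification, and a
brute-force enumeration oracle.

A feasible path *dominates* another when it is no worse on every objective
and strictly better on at least one.  The mutually non-dominated paths form
the Pareto frontier.  A frontier point is *supported* when some strictly
positive weight vector makes it a minimizer of the weighted objective sum
over the frontier — equivalently, when it lies on the lower convex envelope.
Points on the interior of an envelope facet ("weakly supported") are
classified as supported: a facet's weight attains them, so weighted-sum
scalarization can reach them.
"""

from __future__ import annotations

import itertools
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linprog

from .model import LandscapeNetwork, ObjectiveVector, ParetoSet, Path, evaluate_path

__all__ = [
    "dominates",
    "dominates_tol",
    "pareto_filter",
    "classify_supported",
    "is_supported",
    "brute_force_pareto",
    "PathCountExceeded",
]


def dominates(a: Sequence[float], b: Sequence[float]) -> bool:
    """True iff ``a <= b`` componentwise with strict inequality somewhere."""
    if len(a) != len(b):
        raise ValueError("dominance needs equal dimensionality")
    return all(x <= y for x, y in zip(a, b)) and any(x < y for x, y in zip(a, b))


def dominates_tol(a: Sequence[float], b: Sequence[float], rel_tol: float = 1e-9) -> bool:
    """Dominance with a relative tolerance band per component.

    ``a`` tolerance-dominates ``b`` when every component of ``a`` is at most
    the corresponding component of ``b`` plus the band, and at least one is
    below it by more than the band.  Used to prune frontier points that
    survive exact comparison only through floating-point summation noise
    (e.g. uphill elevation costs telescope, so distinct routes can tie to
    within a few ulp).
    """
    if len(a) != len(b):
        raise ValueError("dominance needs equal dimensionality")
    bands = [rel_tol * max(1.0, abs(x), abs(y)) for x, y in zip(a, b)]
    return all(x <= y + t for x, y, t in zip(a, b, bands)) and any(
        x < y - t for x, y, t in zip(a, b, bands)
    )


def pareto_filter(vectors: Sequence[Sequence[float]]) -> List[Tuple[float, ...]]:
    """Return the non-dominated subset, duplicates collapsed, input order kept."""
    tuples = [tuple(v) for v in vectors]
    out: List[Tuple[float, ...]] = []
    for i, v in enumerate(tuples):
        if v in out:
            continue
        if any(dominates(w, v) for j, w in enumerate(tuples) if j != i):
            continue
        out.append(v)
    return out


def is_supported(
    point: Sequence[float],
    frontier: Sequence[Sequence[float]],
    w_floor: float = 1e-6,
) -> bool:
    """LP test for membership of the lower convex envelope.

    ``point`` is supported iff some strictly positive weight vector ``w``
    (``sum(w) = 1``) satisfies ``w . point <= w . y`` for every frontier
    point ``y``.  Strict positivity is certified by maximizing the smallest
    weight component subject to those constraints and requiring the optimum
    to exceed ``w_floor`` (a floor below the LP solver's feasibility
    tolerance would let zero weights slip through).
    """
    y = np.asarray(point, dtype=float)
    others = [np.asarray(v, dtype=float) for v in frontier if not np.array_equal(np.asarray(v, float), y)]
    k = y.size
    if not others:
        return True
    # variables: w (k of them) and t = min weight; maximize t subject to
    # (y - y') . w <= 0, w_l >= t, sum(w) = 1
    a_ub = np.vstack(
        [
            np.column_stack([np.array([y - o for o in others]), np.zeros(len(others))]),
            np.column_stack([-np.eye(k), np.ones(k)]),  # t - w_l <= 0
        ]
    )
    b_ub = np.zeros(len(others) + k)
    res = linprog(
        c=np.concatenate([np.zeros(k), [-1.0]]),
        A_ub=a_ub,
        b_ub=b_ub,
        A_eq=np.concatenate([np.ones(k), [0.0]]).reshape(1, -1),
        b_eq=np.array([1.0]),
        bounds=[(0.0, 1.0)] * k + [(0.0, 1.0)],
        method="highs",
    )
    return bool(res.status == 0 and res.x is not None and res.x[-1] > w_floor)


def classify_supported(pareto_set: ParetoSet) -> ParetoSet:
    """Flag each path of a mutually non-dominated set as supported or not.

    Paths sharing one objective vector get the same flag.  Mutates and
    returns the input set.
    """
    vectors = [p.objectives.as_tuple() for p in pareto_set.paths]
    unique = sorted(set(vectors))
    flags = {v: is_supported(v, unique) for v in unique}
    for p in pareto_set.paths:
        p.supported = flags[p.objectives.as_tuple()]
    return pareto_set


class PathCountExceeded(RuntimeError):
    """Raised when brute-force enumeration would exceed its path guard."""


def _simple_paths(
    network: LandscapeNetwork, o: str, d: str, max_paths: int
) -> List[List[Tuple[str, str]]]:
    """Depth-first enumeration of all simple o->d paths (arc-key lists)."""
    paths: List[List[Tuple[str, str]]] = []
    stack: List[Tuple[str, str]] = []
    visited = {o}

    def rec(u: str) -> None:
        if len(paths) > max_paths:
            raise PathCountExceeded(
                f"more than {max_paths} simple paths between {o!r} and {d!r}"
            )
        if u == d:
            paths.append(list(stack))
            return
        for arc in network.out_arcs(u):
            v = arc.to_id
            if v in visited:
                continue
            visited.add(v)
            stack.append(arc.key)
            rec(v)
            stack.pop()
            visited.remove(v)

    rec(o)
    return paths


def brute_force_pareto(
    network: LandscapeNetwork,
    o: str,
    d: str,
    max_paths: int = 100_000,
    keep_equal_vectors: bool = True,
) -> ParetoSet:
    """Exhaustive-enumeration ground truth for the efficient path set.

    Enumerates every simple path (non-simple walks can only repeat zero-cost
    arcs and never improve any objective, so simple paths realize every
    non-dominated vector), evaluates the objective triple of each, and keeps
    the non-dominated ones.  With ``keep_equal_vectors`` every path attaining
    a non-dominated vector is retained; otherwise one representative per
    vector (first in deterministic enumeration order).
    """
    arc_lists = _simple_paths(network, o, d, max_paths)
    evaluated: List[Path] = []
    for arcs in arc_lists:
        p = Path(origin=o, destination=d, arcs=arcs)
        p.objectives = evaluate_path(p, network)
        evaluated.append(p)
    frontier = set(pareto_filter([p.objectives.as_tuple() for p in evaluated]))
    seen: set = set()
    kept: List[Path] = []
    for p in sorted(evaluated, key=lambda q: (q.objectives.as_tuple(), q.arcs)):
        v = p.objectives.as_tuple()
        if v not in frontier:
            continue
        if not keep_equal_vectors:
            if v in seen:
                continue
            seen.add(v)
        kept.append(p)
    return ParetoSet(origin=o, destination=d, paths=kept)
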
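"""Biobjective non-inferior set estimation (NISE).

For a chosen pair of the three objectives, NISE finds every supported
efficient solution by dichotomy in objective space: solve the two anchors,
then for each adjacent pair of frontier points solve with the weight
proportional to the segment's normal; if the optimum falls strictly below
the segment, a new supported point has been found and both sub-segments are
examined in turn.  The third, uninvolved objective receives zero weight in
the scalarization; the scalar solver's lexicographic tie-break still returns
an efficient representative among alternative optima.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

from .model import LandscapeNetwork, ParetoSet, Path
from .pareto import dominates_tol
from .scalar import WeightVector, solve_weighted

__all__ = ["nise_biobjective"]

_EPS_REL = 1e-9  # facet-confirmation tolerance, relative to segment level
_DELTA = 1e-4  # perturbation for degenerate (axis-parallel) segment normals


def _pair_weight(u: float, v: float, pair: Tuple[int, int]) -> WeightVector:
    """Embed 2D weights (u, v) for the chosen objective pair into 3D."""
    w = [0.0, 0.0, 0.0]
    w[pair[0] - 1] = u
    w[pair[1] - 1] = v
    s = u + v
    return WeightVector(w[0] / s, w[1] / s, w[2] / s, provenance="plane-normal")


def nise_biobjective(
    network: LandscapeNetwork,
    o: str,
    d: str,
    objective_pair: Tuple[int, int] = (1, 2),
) -> ParetoSet:
    """All supported efficient solutions for two of the three objectives.

    ``objective_pair`` selects 1-based objective indices (risk, moisture-
    weighted distance, elevation cost).  Returns a :class:`ParetoSet` of
    paths flagged supported, ordered by the first objective of the pair;
    each path's stored 3-vector is complete but dominance and support refer
    to the chosen pair only.
    """
    p, q = objective_pair
    if p == q or p not in (1, 2, 3) or q not in (1, 2, 3):
        raise ValueError(f"objective pair must be two distinct indices in 1..3, got {objective_pair}")

    def proj(path: Path) -> Tuple[float, float]:
        t = path.objectives.as_tuple()
        return (t[p - 1], t[q - 1])

    third = next(k for k in (1, 2, 3) if k not in (p, q))
    order_pq = (p, q, third)
    order_qp = (q, p, third)

    # anchors of the pair: minimize one objective, tie-break by the other
    # (the scale-free limit of near-unit/near-zero anchor weights)
    found: Dict[Tuple[float, float], Path] = {}
    a = solve_weighted(network, o, d, _pair_weight(1.0, 0.0, objective_pair), tie_order=order_pq)
    b = solve_weighted(network, o, d, _pair_weight(0.0, 1.0, objective_pair), tie_order=order_qp)
    found[proj(a)] = a
    ya, yb = proj(a), proj(b)
    if ya == yb:
        a.supported = True
        return ParetoSet(origin=o, destination=d, paths=[a])
    found[yb] = b

    stack: List[Tuple[Tuple[float, float], Tuple[float, float]]] = [(ya, yb)]
    while stack:
        left, right = stack.pop()
        # segment normal: weights proportional to the coordinate differences
        du = abs(left[1] - right[1])
        dv = abs(right[0] - left[0])
        scale = max(du, dv)
        if scale <= 0:
            continue
        du = max(du, _DELTA * scale)  # nudge axis-parallel normals inward
        dv = max(dv, _DELTA * scale)
        w = _pair_weight(du, dv, objective_pair)
        path = solve_weighted(network, o, d, w, tie_order=order_pq)
        y = proj(path)
        level = du * left[0] + dv * left[1]
        value = du * y[0] + dv * y[1]
        if y in found or level - value <= _EPS_REL * max(1.0, abs(level)):
            continue
        found[y] = path
        stack.append((left, y))
        stack.append((y, right))

    # prune projections kept alive only by floating-point summation noise
    keys = sorted(found)
    keys = [
        k for k in keys
        if not any(dominates_tol(k2, k) for k2 in keys if k2 != k)
    ]
    paths = [found[k] for k in keys]
    for path in paths:
        path.supported = True
    return ParetoSet(origin=o, destination=d, paths=paths)
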
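"""Seeded synthetic landscape networks for testing and demonstration.

:func:`make_landscape` fabricates, at reduced scale, the kind of network the
method targets in the field: a planar grid of landscape nodes over a smooth
random elevation field, categorical land cover with per-class base traversal
risk, wetland habitat patches sitting at local elevation minima with
zero-cost internal arcs, and a topographic-wetness moisture surface.  All
randomness flows from one integer seed, so every generated network is
reproducible.

:func:`hand_fixtures` returns three tiny hand-built networks with known
structure: ``F1`` for arc-attribute arithmetic, ``F2`` for frontier
enumeration with both supported and unsupported solutions plus a zero-cost
habitat cycle, and ``F3`` for the biobjective supported/unsupported
classification with the frontier {(1,3), (3,1), (2.5,2.5)} by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .costs import DEFAULT_BASE_RISK, CostConfig, derive_all
from .model import Arc, LandscapeNetwork, Node

__all__ = ["FixtureSpec", "make_landscape", "hand_fixtures"]

_CLASSES = list(DEFAULT_BASE_RISK)


@dataclass
class FixtureSpec:
    """Parameters of the synthetic landscape generator.

    Defaults fabricate a small but structurally faithful landscape: grid
    spacing 50 m (the real network's mean arc length is of that order),
    elevation relief of ~13 m (matching the study system's maximum per-arc
    elevation cost), TWI in a typical [-0.7, 22] range, and the standard
    seven-land-cover base-risk table spanning [0.060, 0.095].
    """

    seed: int = 0
    grid_n: int = 5
    n_wetlands: int = 2
    spacing: float = 50.0
    elevation_relief: float = 13.0
    elevation_smoothness: float = 1.5
    twi_range: Tuple[float, float] = (-0.66, 21.77)
    land_cover_classes: List[str] = field(default_factory=lambda: list(_CLASSES))
    wetland_size: int = 2
    derive: bool = True

    def __post_init__(self) -> None:
        if self.n_wetlands < 2:
            raise ValueError("need at least 2 wetlands for any OD analysis")
        if self.grid_n < 2:
            raise ValueError("grid must be at least 2x2")
        if self.n_wetlands * self.wetland_size > self.grid_n * self.grid_n:
            raise ValueError("wetlands do not fit on the grid")


def _smooth_field(rng: np.random.Generator, n: int, smoothness: float) -> np.ndarray:
    """Smooth random surface on an n x n grid via low-frequency cosines."""
    xs = np.linspace(0.0, 1.0, n)
    gx, gy = np.meshgrid(xs, xs, indexing="ij")
    z = np.zeros((n, n))
    for _ in range(6):
        fx, fy = rng.uniform(0.5, 2.5, size=2) * smoothness
        px, py = rng.uniform(0, 2 * math.pi, size=2)
        amp = rng.uniform(0.3, 1.0)
        z += amp * np.cos(2 * math.pi * fx * gx + px) * np.cos(2 * math.pi * fy * gy + py)
    z -= z.min()
    peak = z.max()
    return z / peak if peak > 0 else z


def make_landscape(spec: FixtureSpec) -> LandscapeNetwork:
    """Generate a connected, fully attributed landscape network.

    Grid nodes are joined to their 4-neighbors by directed arc pairs.
    Wetlands occupy ``wetland_size``-node blocks anchored at the lowest
    available elevations; their member nodes are all entrance/exit nodes and
    their internal arcs carry zero cost.  With ``spec.derive`` the three
    objective attributes are derived immediately.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.grid_n

    elev = _smooth_field(rng, n, spec.elevation_smoothness) * spec.elevation_relief
    moist_raw = _smooth_field(rng, n, spec.elevation_smoothness * 2)
    lo, hi = spec.twi_range
    # wetter where lower: anticorrelate TWI with elevation, plus noise
    moist = lo + (hi - lo) * np.clip(
        0.65 * (1.0 - elev / max(elev.max(), 1e-9)) + 0.35 * moist_raw, 0, 1
    )
    cover_field = _smooth_field(rng, n, spec.elevation_smoothness)
    classes = spec.land_cover_classes
    cover_idx = np.minimum(
        (cover_field * len(classes)).astype(int), len(classes) - 1
    )

    # wetlands: blocks of adjacent nodes anchored at the lowest elevations
    order = np.argsort(elev, axis=None)
    taken: set = set()
    wetland_of: Dict[Tuple[int, int], str] = {}
    wid = 0
    for flat in order:
        if wid >= spec.n_wetlands:
            break
        i, j = divmod(int(flat), n)
        if (i, j) in taken:
            continue
        block = [(i, j)]
        for di, dj in ((0, 1), (1, 0), (0, -1), (-1, 0)):
            if len(block) >= spec.wetland_size:
                break
            ii, jj = i + di, j + dj
            if 0 <= ii < n and 0 <= jj < n and (ii, jj) not in taken:
                block.append((ii, jj))
        if len(block) < spec.wetland_size:
            continue
        wid += 1
        for cell in block:
            taken.add(cell)
            wetland_of[cell] = f"W{wid}"
    if wid < spec.n_wetlands:
        raise RuntimeError(
            f"could not place {spec.n_wetlands} wetlands on a {n}x{n} grid (seed {spec.seed})"
        )

    net = LandscapeNetwork()
    for i in range(n):
        for j in range(n):
            w = wetland_of.get((i, j))
            net.add_node(
                Node(
                    id=f"n{i}_{j}",
                    x=j * spec.spacing,
                    y=i * spec.spacing,
                    elevation=float(elev[i, j]),
                    land_cover="woody_wetland" if w else classes[cover_idx[i, j]],
                    wetland_id=w,
                    is_entrance=w is not None,
                    moisture=float(moist[i, j]),
                )
            )
    for i in range(n):
        for j in range(n):
            for di, dj in ((0, 1), (1, 0)):
                ii, jj = i + di, j + dj
                if ii >= n or jj >= n:
                    continue
                u, v = f"n{i}_{j}", f"n{ii}_{jj}"
                cls = classes[cover_idx[i, j]]
                length = spec.spacing
                net.add_arc(Arc(from_id=u, to_id=v, length=length, land_cover=cls))
                net.add_arc(Arc(from_id=v, to_id=u, length=length, land_cover=cls))

    if spec.derive:
        derive_all(net, CostConfig(twi_max=hi, twi_min=lo))
    return net


def _chain(
    net: LandscapeNetwork,
    nodes: List[str],
    triples: List[Tuple[float, float, float]],
) -> None:
    """Add a directed chain with prescribed objective triples per arc."""
    for (u, v), (f1, f2, f3) in zip(zip(nodes, nodes[1:]), triples):
        net.add_arc(
            Arc(
                from_id=u,
                to_id=v,
                length=1.0,
                log_risk=f1,
                moisture_weighted_distance=f2,
                elevation_cost=f3,
                risk=-math.expm1(-f1),
            )
        )


def hand_fixtures() -> Dict[str, LandscapeNetwork]:
    """Three hand-built reference networks: ``F1``, ``F2``, ``F3``."""
    # F1: a 4-node line with raw attributes for cost-derivation arithmetic
    f1 = LandscapeNetwork()
    elevs = [100.0, 102.0, 101.0, 104.0]
    moists = [4.0, 6.0, 2.0, 8.0]
    for k, (e, m) in enumerate(zip(elevs, moists)):
        f1.add_node(Node(id=f"a{k}", x=30.0 * k, y=0.0, elevation=e, moisture=m))
    covers = ["grassland", "cropland", "deciduous_forest"]
    lengths = [30.0, 50.0, 40.0]
    for k in range(3):
        u, v = f"a{k}", f"a{k+1}"
        f1.add_arc(Arc(from_id=u, to_id=v, length=lengths[k], land_cover=covers[k]))
        f1.add_arc(Arc(from_id=v, to_id=u, length=lengths[k], land_cover=covers[k]))

    # F2: 9 nodes; four parallel 2-arc routes o->d with frontier
    # {(1,6,1), (6,1,1), (4,4,4), (2,2,9)} of which (4,4,4) is unsupported,
    # one dominated route, and zero-cost wetland cycles at both endpoints.
    f2 = LandscapeNetwork()
    for nid in ("o", "o2", "d", "d2", "m1", "m2", "m3", "m4", "m5"):
        wet = {"o": "W1", "o2": "W1", "d": "W2", "d2": "W2"}.get(nid)
        f2.add_node(Node(id=nid, elevation=0.0, wetland_id=wet, is_entrance=wet is not None))
    routes = {
        "m1": (1.0, 6.0, 1.0),
        "m2": (6.0, 1.0, 1.0),
        "m3": (4.0, 4.0, 4.0),  # efficient but off the convex envelope
        "m4": (2.0, 2.0, 9.0),
        "m5": (7.0, 7.0, 7.0),  # dominated by m3's route
    }
    for mid, (f1v, f2v, f3v) in routes.items():
        _chain(f2, ["o", mid, "d"], [(f1v / 2, f2v / 2, f3v / 2)] * 2)
    for u, v in (("o", "o2"), ("o2", "o"), ("d", "d2"), ("d2", "d")):
        f2.add_arc(
            Arc(from_id=u, to_id=v, length=0.0, risk=0.0, log_risk=0.0,
                moisture_weighted_distance=0.0, elevation_cost=0.0,
                wetland_internal=True)
        )

    # F3: biobjective fixture, frontier {(1,3), (3,1), (2.5,2.5)} in
    # (risk, moisture-weighted distance); elevation cost identically zero.
    f3 = LandscapeNetwork()
    for nid in ("o", "d", "p", "q", "r", "s"):
        wet = {"o": "W1", "d": "W2"}.get(nid)
        f3.add_node(Node(id=nid, elevation=0.0, wetland_id=wet, is_entrance=wet is not None))
    f3_routes = {
        "p": (1.0, 3.0),
        "q": (3.0, 1.0),
        "r": (2.5, 2.5),
        "s": (4.0, 4.0),  # dominated
    }
    for mid, (f1v, f2v) in f3_routes.items():
        _chain(f3, ["o", mid, "d"], [(f1v / 2, f2v / 2, 0.0)] * 2)

    return {"F1": f1, "F2": f2, "F3": f3}
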
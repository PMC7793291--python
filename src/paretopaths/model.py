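"""Core data types for attributed landscape networks and multiobjective paths.

A landscape is modeled as a directed graph ``G(N, A)``: habitat patches
(wetlands) and intervening land-cover areas are nodes, adjacencies between
neighboring areas are arcs.  Every arc carries three nonnegative objective
attributes, one per movement criterion:

* ``log_risk`` — ln(1/(1 - pi_ij)), the additive form of the per-arc traversal
  failure probability ``pi_ij``.  Summing log-risks along a path and applying
  :func:`failure_probability` recovers the path's multiplicative failure
  probability ``1 - prod(1 - pi_ij)``.
* ``moisture_weighted_distance`` — arc length weighted by the deviation of
  surface moisture from an ideal level.
* ``elevation_cost`` — direction-dependent penalty on elevation change
  (uphill weighted more heavily than downhill).

The risk objective is stored and compared in additive log form throughout:
additivity and monotonicity are what make label-correcting search and
weighted-sum scalarization valid.  The multiplicative probability is a
reporting view only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

__all__ = [
    "Node",
    "Arc",
    "LandscapeNetwork",
    "ObjectiveVector",
    "Path",
    "ParetoSet",
    "evaluate_path",
    "failure_probability",
    "NetworkStructureError",
]


class NetworkStructureError(ValueError):
    """Raised when a path or network violates a structural invariant."""


@dataclass(frozen=True)
class ObjectiveVector:
    """The additive objective triple accumulated along a path.

    ``f1`` cumulative log-risk (dimensionless), ``f2`` cumulative
    moisture-weighted distance, ``f3`` cumulative elevation cost (meters).
    All components are finite and >= 0.
    """

    f1: float
    f2: float
    f3: float

    def __post_init__(self) -> None:
        for v in (self.f1, self.f2, self.f3):
            if not math.isfinite(v):
                raise ValueError(f"objective component not finite: {self}")

    def as_tuple(self) -> Tuple[float, float, float]:
        return (self.f1, self.f2, self.f3)

    def __add__(self, other: "ObjectiveVector") -> "ObjectiveVector":
        return ObjectiveVector(self.f1 + other.f1, self.f2 + other.f2, self.f3 + other.f3)

    @property
    def failure_probability(self) -> float:
        """The risk objective on the probability scale, ``1 - exp(-f1)``."""
        return failure_probability(self.f1)


def failure_probability(f1: float) -> float:
    """Convert cumulative log-risk to path traversal-failure probability.

    ``1 - exp(-f1) = 1 - prod(1 - pi_ij)`` over the path's arcs.  Strictly
    increasing in ``f1``, so path orderings by log-risk and by failure
    probability coincide.
    """
    if f1 < 0:
        raise ValueError(f"log-risk must be >= 0, got {f1}")
    return -math.expm1(-f1)


@dataclass
class Node:
    id: str
    x: float = 0.0
    y: float = 0.0
    elevation: float = 0.0
    land_cover: Optional[str] = None
    wetland_id: Optional[str] = None
    is_entrance: bool = False
    moisture: Optional[float] = None  # node TWI, if supplied/derived

    def __post_init__(self) -> None:
        if not math.isfinite(self.elevation):
            raise ValueError(f"node {self.id}: elevation not finite")


@dataclass
class Arc:
    """A directed arc with raw landscape attributes and derived objective costs.

    Raw attributes (``length``, ``land_cover``, ``moisture``) come from the
    landscape; the derived costs (``risk``, ``log_risk``,
    ``moisture_weighted_distance``, ``elevation_cost``) are populated by
    :mod:`paretopaths.costs`.  Arcs internal to a wetland have all three
    objective attributes equal to zero (habitat interiors are homogeneous).
    """

    from_id: str
    to_id: str
    length: float = 0.0
    land_cover: Optional[str] = None
    moisture: Optional[float] = None
    base_risk: Optional[float] = None
    risk: Optional[float] = None
    elevation_cost: Optional[float] = None
    moisture_weighted_distance: Optional[float] = None
    log_risk: Optional[float] = None
    wetland_internal: bool = False

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValueError(f"arc {self.key}: negative length {self.length}")
        if self.risk is not None:
            if not (0.0 <= self.risk < 1.0):
                raise ValueError(f"arc {self.key}: risk {self.risk} outside [0, 1)")
            if self.log_risk is None:
                self.log_risk = -math.log1p(-self.risk)  # ln(1/(1-pi))

    @property
    def key(self) -> Tuple[str, str]:
        return (self.from_id, self.to_id)

    @property
    def objectives(self) -> ObjectiveVector:
        """The arc's objective attribute triple; requires derived costs."""
        if self.log_risk is None or self.moisture_weighted_distance is None or self.elevation_cost is None:
            raise NetworkStructureError(
                f"arc {self.key} has underived objective attributes; run derive_all() first"
            )
        return ObjectiveVector(self.log_risk, self.moisture_weighted_distance, self.elevation_cost)

    @property
    def has_derived_costs(self) -> bool:
        return (
            self.log_risk is not None
            and self.moisture_weighted_distance is not None
            and self.elevation_cost is not None
        )


class LandscapeNetwork:
    """Directed landscape graph with node/arc lookup and wetland bookkeeping.

    At most one arc per ordered node pair.  Undirected landscape adjacency is
    materialized as two directed arcs because elevation cost is
    direction-dependent; symmetric attributes are copied to both directions.
    """

    def __init__(self, nodes: Iterable[Node] = (), arcs: Iterable[Arc] = ()) -> None:
        self.nodes: Dict[str, Node] = {}
        self.arcs: Dict[Tuple[str, str], Arc] = {}
        self._out: Dict[str, List[Arc]] = {}
        for n in nodes:
            self.add_node(n)
        for a in arcs:
            self.add_arc(a)

    def add_node(self, node: Node) -> None:
        if node.id in self.nodes:
            raise NetworkStructureError(f"duplicate node id {node.id!r}")
        self.nodes[node.id] = node
        self._out[node.id] = []

    def add_arc(self, arc: Arc) -> None:
        if arc.from_id not in self.nodes:
            raise NetworkStructureError(f"arc {arc.key} references missing node {arc.from_id!r}")
        if arc.to_id not in self.nodes:
            raise NetworkStructureError(f"arc {arc.key} references missing node {arc.to_id!r}")
        if arc.key in self.arcs:
            raise NetworkStructureError(f"duplicate arc {arc.key}")
        self.arcs[arc.key] = arc
        self._out[arc.from_id].append(arc)

    def out_arcs(self, node_id: str) -> List[Arc]:
        return self._out[node_id]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_arcs(self) -> int:
        return len(self.arcs)

    @property
    def wetlands(self) -> Dict[str, List[str]]:
        """Map wetland id -> sorted list of member node ids."""
        out: Dict[str, List[str]] = {}
        for n in self.nodes.values():
            if n.wetland_id is not None:
                out.setdefault(n.wetland_id, []).append(n.id)
        return {w: sorted(ids) for w, ids in sorted(out.items())}

    def wetland_entrances(self, wetland_id: str) -> List[str]:
        members = self.wetlands.get(wetland_id, [])
        ent = [i for i in members if self.nodes[i].is_entrance]
        return ent or members

    def to_networkx(self, weight_attr: Optional[str] = None):
        """Export as a :class:`networkx.DiGraph` (arc objects on edges)."""
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for arc in self.arcs.values():
            data = {"arc": arc}
            if weight_attr is not None:
                data["weight"] = getattr(arc, weight_attr)
            g.add_edge(arc.from_id, arc.to_id, **data)
        return g

    def validate(self) -> None:
        """Check structural invariants; raises :class:`NetworkStructureError`."""
        for arc in self.arcs.values():
            if (arc.to_id, arc.from_id) not in self.arcs:
                raise NetworkStructureError(
                    f"adjacency {arc.key} has no reverse arc; elevation cost is "
                    "direction-dependent so both directions must be present"
                )


@dataclass
class Path:
    """An origin-destination walk as an ordered arc list with its objectives."""

    origin: str
    destination: str
    arcs: List[Tuple[str, str]] = field(default_factory=list)
    objectives: Optional[ObjectiveVector] = None
    supported: Optional[bool] = None
    weight: Optional[Tuple[float, float, float]] = None  # generating weight, if any

    @property
    def node_sequence(self) -> List[str]:
        seq = [self.origin]
        seq.extend(to for _, to in self.arcs)
        return seq

    def __len__(self) -> int:
        return len(self.arcs)


def evaluate_path(path: Path, network: LandscapeNetwork) -> ObjectiveVector:
    """Componentwise sum of arc objective attributes along ``path``.

    Validates that the arc sequence is a connected origin-to-destination walk
    (conservation of flow) before summing.
    """
    prev = path.origin
    total = ObjectiveVector(0.0, 0.0, 0.0)
    for key in path.arcs:
        if key not in network.arcs:
            raise NetworkStructureError(f"path uses arc {key} absent from network")
        if key[0] != prev:
            raise NetworkStructureError(
                f"path breaks at node {prev!r}: next arc {key} does not start there"
            )
        total = total + network.arcs[key].objectives
        prev = key[1]
    if prev != path.destination:
        raise NetworkStructureError(
            f"path ends at {prev!r}, expected destination {path.destination!r}"
        )
    return total


@dataclass
class ParetoSet:
    """Mutually non-dominated paths for one origin-destination pair."""

    origin: str
    destination: str
    paths: List[Path] = field(default_factory=list)

    @property
    def vectors(self) -> List[ObjectiveVector]:
        return [p.objectives for p in self.paths]

    @property
    def n_supported(self) -> int:
        return sum(1 for p in self.paths if p.supported)

    @property
    def n_unsupported(self) -> int:
        return sum(1 for p in self.paths if p.supported is False)

    def __len__(self) -> int:
        return len(self.paths)

    def __iter__(self):
        return iter(self.paths)
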
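"""Network readers/writers, the deposited-dataset adapter, and reporting.

The native schema is a pair of long-form CSV tables:

* nodes: ``id,x,y,elevation[,land_cover][,wetland_id][,is_entrance][,moisture]``
* arcs:  ``from,to,length[,land_cover][,moisture][,base_risk][,pi][,z][,mwd]``

One row per *directed* arc.  Tables that store one undirected record per
adjacency are normalized on read: the missing reverse arcs are materialized
with symmetric attributes copied over (direction-dependent elevation cost is
recomputed by the cost-derivation step, never copied).  Column synonyms used
by deposited network tables are sniffed and mapped; unknown columns are
ignored.  Path exports use GeoJSON LineStrings with the objective triple in
the feature properties.
"""

from __future__ import annotations

import json
import math
from pathlib import Path as FilePath
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .model import Arc, LandscapeNetwork, Node, ParetoSet, Path

__all__ = [
    "read_network",
    "write_network",
    "paths_to_geojson",
    "report_frontiers",
    "report_arc_usage",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when input tables violate the schema or referential integrity."""


_NODE_SYNONYMS = {
    "id": ["id", "node", "node_id", "nodeid", "name"],
    "x": ["x", "lon", "easting", "x_coord"],
    "y": ["y", "lat", "northing", "y_coord"],
    "elevation": ["elevation", "elev", "e", "z", "dem"],
    "land_cover": ["land_cover", "landcover", "lulc", "cover", "class"],
    "wetland_id": ["wetland_id", "wetland", "habitat", "habitat_id", "patch"],
    "is_entrance": ["is_entrance", "entrance", "entry"],
    "moisture": ["moisture", "twi", "m", "wetness"],
}

_ARC_SYNONYMS = {
    "from": ["from", "from_id", "source", "u", "i", "tail", "start"],
    "to": ["to", "to_id", "target", "v", "j", "head", "end"],
    "length": ["length", "len", "c", "cij", "distance", "dist"],
    "land_cover": ["land_cover", "landcover", "lulc", "cover", "class"],
    "moisture": ["moisture", "twi", "m", "mij", "wetness"],
    "base_risk": ["base_risk", "pib", "pi_b", "baserisk"],
    "risk": ["risk", "pi", "pij", "pi_ij", "probability"],
    "elevation_cost": ["elevation_cost", "z", "zij", "z_ij", "elev_cost"],
    "moisture_weighted_distance": [
        "moisture_weighted_distance", "mwd", "weighted_distance", "wdist",
    ],
    "log_risk": ["log_risk", "lnrisk", "logrisk"],
}


def _map_columns(df: pd.DataFrame, synonyms: Mapping[str, List[str]], required: Sequence[str], what: str) -> Dict[str, str]:
    lower = {c.lower().strip(): c for c in df.columns}
    mapping: Dict[str, str] = {}
    for canon, names in synonyms.items():
        for name in names:
            if name in lower:
                mapping[canon] = lower[name]
                break
    missing = [c for c in required if c not in mapping]
    if missing:
        raise ValidationError(
            f"{what} table lacks required column(s) {missing}; found {list(df.columns)}"
        )
    return mapping


def _opt(row, col: Optional[str]):
    if col is None:
        return None
    v = row[col]
    if v is None or (isinstance(v, float) and math.isnan(v)) or (isinstance(v, str) and not v.strip()):
        return None
    return v


def read_network(
    node_table: FilePath | str | pd.DataFrame,
    arc_table: FilePath | str | pd.DataFrame,
) -> LandscapeNetwork:
    """Build a validated :class:`LandscapeNetwork` from node and arc tables.

    Accepts CSV paths or DataFrames.  Missing reverse arcs are materialized
    (symmetric raw attributes copied; derived direction-dependent costs left
    for :func:`paretopaths.costs.derive_all`).  Referential breakage, negative
    lengths and risks outside [0, 1) raise :class:`ValidationError` listing
    the offending rows.
    """
    nodes_df = node_table if isinstance(node_table, pd.DataFrame) else pd.read_csv(node_table)
    arcs_df = arc_table if isinstance(arc_table, pd.DataFrame) else pd.read_csv(arc_table)

    ncols = _map_columns(nodes_df, _NODE_SYNONYMS, ["id"], "node")
    acols = _map_columns(arcs_df, _ARC_SYNONYMS, ["from", "to", "length"], "arc")

    net = LandscapeNetwork()
    for _, row in nodes_df.iterrows():
        wet = _opt(row, ncols.get("wetland_id"))
        ent = _opt(row, ncols.get("is_entrance"))
        moist = _opt(row, ncols.get("moisture"))
        net.add_node(
            Node(
                id=str(row[ncols["id"]]),
                x=float(_opt(row, ncols.get("x")) or 0.0),
                y=float(_opt(row, ncols.get("y")) or 0.0),
                elevation=float(_opt(row, ncols.get("elevation")) or 0.0),
                land_cover=(str(_opt(row, ncols.get("land_cover"))) if _opt(row, ncols.get("land_cover")) is not None else None),
                wetland_id=(str(wet) if wet is not None else None),
                is_entrance=bool(ent) if ent is not None else wet is not None,
                moisture=float(moist) if moist is not None else None,
            )
        )

    bad_rows: List[str] = []
    for idx, row in arcs_df.iterrows():
        u, v = str(row[acols["from"]]), str(row[acols["to"]])
        length = float(row[acols["length"]])
        if u not in net.nodes or v not in net.nodes:
            bad_rows.append(f"row {idx}: arc ({u},{v}) references a missing node")
            continue
        if length < 0:
            bad_rows.append(f"row {idx}: arc ({u},{v}) has negative length {length}")
            continue
        risk = _opt(row, acols.get("risk"))
        if risk is not None and not (0.0 <= float(risk) < 1.0):
            bad_rows.append(f"row {idx}: arc ({u},{v}) has risk {risk} outside [0, 1)")
            continue
        mwd = _opt(row, acols.get("moisture_weighted_distance"))
        z = _opt(row, acols.get("elevation_cost"))
        base = _opt(row, acols.get("base_risk"))
        moist = _opt(row, acols.get("moisture"))
        cover = _opt(row, acols.get("land_cover"))
        net.add_arc(
            Arc(
                from_id=u,
                to_id=v,
                length=length,
                land_cover=str(cover) if cover is not None else None,
                moisture=float(moist) if moist is not None else None,
                base_risk=float(base) if base is not None else None,
                risk=float(risk) if risk is not None else None,
                elevation_cost=float(z) if z is not None else None,
                moisture_weighted_distance=float(mwd) if mwd is not None else None,
            )
        )
    if bad_rows:
        raise ValidationError("invalid arc rows:\n  " + "\n  ".join(bad_rows))

    # normalize undirected storage: materialize missing reverse arcs
    for key, arc in list(net.arcs.items()):
        if (arc.to_id, arc.from_id) not in net.arcs:
            net.add_arc(
                Arc(
                    from_id=arc.to_id,
                    to_id=arc.from_id,
                    length=arc.length,
                    land_cover=arc.land_cover,
                    moisture=arc.moisture,
                    base_risk=arc.base_risk,
                    risk=arc.risk,
                    moisture_weighted_distance=arc.moisture_weighted_distance,
                    wetland_internal=arc.wetland_internal,
                )
            )
    # wetland-internal flag from endpoint membership
    for arc in net.arcs.values():
        u, v = net.nodes[arc.from_id], net.nodes[arc.to_id]
        if u.wetland_id is not None and u.wetland_id == v.wetland_id:
            arc.wetland_internal = True
    return net


def write_network(
    network: LandscapeNetwork, node_path: FilePath | str, arc_path: FilePath | str
) -> None:
    """Write the native two-CSV representation (one row per directed arc)."""
    nodes = pd.DataFrame(
        [
            {
                "id": n.id,
                "x": n.x,
                "y": n.y,
                "elevation": n.elevation,
                "land_cover": n.land_cover,
                "wetland_id": n.wetland_id,
                "is_entrance": n.is_entrance,
                "moisture": n.moisture,
            }
            for n in network.nodes.values()
        ]
    )
    arcs = pd.DataFrame(
        [
            {
                "from": a.from_id,
                "to": a.to_id,
                "length": a.length,
                "land_cover": a.land_cover,
                "moisture": a.moisture,
                "base_risk": a.base_risk,
                "pi": a.risk,
                "z": a.elevation_cost,
                "mwd": a.moisture_weighted_distance,
            }
            for a in network.arcs.values()
        ]
    )
    nodes.to_csv(node_path, index=False)
    arcs.to_csv(arc_path, index=False)


def paths_to_geojson(paths: Iterable[Path], network: LandscapeNetwork) -> dict:
    """GeoJSON FeatureCollection: one LineString per path with objectives."""
    features = []
    for p in paths:
        coords = [
            [network.nodes[nid].x, network.nodes[nid].y] for nid in p.node_sequence
        ]
        obj = p.objectives
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "LineString", "coordinates": coords},
                "properties": {
                    "origin": p.origin,
                    "destination": p.destination,
                    "failure_probability": obj.failure_probability if obj else None,
                    "log_risk": obj.f1 if obj else None,
                    "moisture_weighted_distance": obj.f2 if obj else None,
                    "elevation_cost": obj.f3 if obj else None,
                    "supported": p.supported,
                },
            }
        )
    return {"type": "FeatureCollection", "features": features}


def _wetland_of(network: LandscapeNetwork, node_id: str) -> Optional[str]:
    return network.nodes[node_id].wetland_id


def report_frontiers(
    results: Iterable[ParetoSet], network: LandscapeNetwork
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-wetland path counts and per-class objective summary statistics.

    Returns ``(counts, summary)``.  ``counts`` has one row per wetland with
    incoming/outgoing supported, unsupported, and total non-dominated path
    counts plus a ``Sum`` row.  ``summary`` reports mean/SD/min/max of each
    objective split by supported vs unsupported paths, with the risk
    objective on the failure-probability scale.
    """
    wetlands = sorted(network.wetlands)
    rows = {
        w: {"supported_in": 0, "supported_out": 0, "unsupported_in": 0,
            "unsupported_out": 0, "all_in": 0, "all_out": 0}
        for w in wetlands
    }
    records = []
    for ps in results:
        w_o = _wetland_of(network, ps.origin)
        w_d = _wetland_of(network, ps.destination)
        for p in ps.paths:
            kind = "supported" if p.supported else "unsupported"
            if w_d in rows:
                rows[w_d][f"{kind}_in"] += 1
                rows[w_d]["all_in"] += 1
            if w_o in rows:
                rows[w_o][f"{kind}_out"] += 1
                rows[w_o]["all_out"] += 1
            records.append(
                {
                    "supported": bool(p.supported),
                    "failure_probability": p.objectives.failure_probability,
                    "moisture_weighted_distance": p.objectives.f2,
                    "elevation_cost": p.objectives.f3,
                }
            )
    counts = pd.DataFrame.from_dict(rows, orient="index")
    counts.index.name = "wetland"
    if len(counts):
        counts.loc["Sum"] = counts.sum()

    if records:
        df = pd.DataFrame.from_records(records)
        summary = (
            df.groupby("supported")
            .agg(["mean", "std", "min", "max"])
            .rename(index={True: "supported", False: "unsupported"})
        )
    else:
        summary = pd.DataFrame()
    return counts, summary


def report_arc_usage(
    paths: Iterable[Path], network: LandscapeNetwork
) -> pd.DataFrame:
    """Traversal count per directed arc, with undirected adjacency totals.

    The returned frame has one row per directed arc with ``count`` (paths
    traversing the arc) and ``undirected_count`` (paths traversing either
    direction of the adjacency); the fraction of arcs used at least once is
    available as ``df.attrs['fraction_used']`` and the never-used fraction
    as ``df.attrs['fraction_unused']``.
    """
    counts: Dict[Tuple[str, str], int] = {k: 0 for k in network.arcs}
    for p in paths:
        for key in p.arcs:
            counts[key] += 1
    rows = []
    for (u, v), c in counts.items():
        und = c + counts.get((v, u), 0)
        rows.append({"from": u, "to": v, "count": c, "undirected_count": und})
    df = pd.DataFrame(rows)
    if len(df):
        used = (df["count"] > 0).mean()
        df.attrs["fraction_used"] = float(used)
        df.attrs["fraction_unused"] = float(1.0 - used)
    return df
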
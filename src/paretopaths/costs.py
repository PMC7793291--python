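"""Derivation of per-arc objective attributes from raw landscape inputs.

Three attributes are derived for every arc of a landscape network:

* elevation cost ``z_ij``: uphill changes weighted ``w_p`` (default 2), downhill
  ``w_n`` (default 1) — uphill movement is assumed twice as costly;
* moisture-weighted distance ``(M - m_ij + 1) * c_ij``: arc length ``c_ij``
  scaled by the deviation of arc moisture ``m_ij`` (topographic wetness index,
  TWI) from an ideal moisture level ``M``;
* traversal risk ``pi_ij = pi_b * (1 + c_ij / (2 * c_max))``: a per-land-cover
  base failure probability ``pi_b`` inflated by up to 50% with arc length
  relative to the longest arc ``c_max``, then log-transformed to the additive
  form ``ln(1/(1 - pi_ij))``.

Arcs internal to a wetland are hard-set to zero on all three attributes:
habitat interiors are treated as homogeneous, so movement within them is free.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional

from .model import LandscapeNetwork

__all__ = [
    "CostConfig",
    "DEFAULT_BASE_RISK",
    "elevation_cost",
    "twi",
    "moisture_weighted_distance",
    "adjusted_risk",
    "derive_all",
    "CostConfigError",
]

#: Relative traversal-failure risk per land use / land cover class.
DEFAULT_BASE_RISK: Dict[str, float] = {
    "woody_wetland": 0.060,
    "deciduous_forest": 0.065,
    "deciduous_woody": 0.070,
    "grassland": 0.075,
    "open_water": 0.085,
    "cropland": 0.090,
    "impervious": 0.095,
}


class CostConfigError(ValueError):
    """Raised for invalid cost-derivation configuration or inputs."""


@dataclass
class CostConfig:
    """Parameters of the arc-cost derivation.

    ``w_p``/``w_n`` are the uphill/downhill elevation weights (only their
    ratio matters for the Pareto set; the default 2:1 penalizes uphill twice).
    ``ideal_moisture`` is the target TWI level ``M``; when ``None`` it defaults
    to the maximum observed arc moisture, which keeps every deviation >= 0.
    ``twi_max``/``twi_min`` substitute for degenerate TWI cells (zero slope
    with/without drainage); when ``None`` they default to the observed
    max/min finite TWI of the network being derived.
    """

    w_p: float = 2.0
    w_n: float = 1.0
    ideal_moisture: Optional[float] = None
    moisture_offset: float = 1.0
    base_risk: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BASE_RISK))
    risk_length_factor: float = 0.5
    twi_max: Optional[float] = None
    twi_min: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.w_p >= self.w_n > 0):
            raise CostConfigError(f"need w_p >= w_n > 0, got w_p={self.w_p}, w_n={self.w_n}")
        for cls, pb in self.base_risk.items():
            if not (0.0 < pb < 1.0):
                raise CostConfigError(f"base risk for {cls!r} must lie in (0, 1), got {pb}")


def elevation_cost(e_i: float, e_j: float, config: CostConfig = CostConfig()) -> float:
    """Directed elevation-change cost ``z_ij`` in meters (always >= 0)."""
    if e_j >= e_i:
        return config.w_p * (e_j - e_i)
    return config.w_n * (e_i - e_j)


def twi(drainage_area: float, slope_tan: float, config: CostConfig) -> float:
    """Topographic wetness index ``ln(alpha / tan(beta))``.

    Degenerate cells follow the substitution rule: zero slope with nonzero
    drainage gets the maximum meaningful TWI; zero slope and zero drainage
    gets the minimum meaningful TWI.  Both bounds must be set on the config
    (site-specific values; fixtures derive them from the generated field).
    """
    if drainage_area < 0:
        raise CostConfigError(f"drainage area must be >= 0, got {drainage_area}")
    if slope_tan < 0:
        raise CostConfigError(f"slope tangent must be >= 0, got {slope_tan}")
    if slope_tan == 0.0:
        if drainage_area > 0:
            if config.twi_max is None:
                raise CostConfigError("twi_max unset but needed for a zero-slope cell")
            return config.twi_max
        if config.twi_min is None:
            raise CostConfigError("twi_min unset but needed for a zero-slope, zero-drainage cell")
        return config.twi_min
    if drainage_area == 0.0:
        if config.twi_min is None:
            raise CostConfigError("twi_min unset but needed for a zero-drainage cell")
        return config.twi_min
    return math.log(drainage_area / slope_tan)


def moisture_weighted_distance(m_ij: float, c_ij: float, config: CostConfig) -> float:
    """Moisture-deviation-weighted arc length ``(M - m_ij + offset) * c_ij``."""
    if c_ij < 0:
        raise CostConfigError(f"arc length must be >= 0, got {c_ij}")
    if c_ij == 0.0:
        return 0.0
    if config.ideal_moisture is None:
        raise CostConfigError("ideal_moisture (M) unset; set it or use derive_all()")
    value = (config.ideal_moisture - m_ij + config.moisture_offset) * c_ij
    if value < 0:
        raise CostConfigError(
            f"negative moisture-weighted distance ({value:.6g}) for m={m_ij}, "
            f"c={c_ij}: raise ideal_moisture above {m_ij - config.moisture_offset:.6g}"
        )
    return value


def adjusted_risk(
    pi_b: float, c_ij: float, c_max: float, risk_length_factor: float = 0.5
) -> float:
    """Length-adjusted traversal risk ``pi_b * (1 + f * c_ij / c_max)``.

    With the default factor ``f = 1/2`` the base risk is inflated by up to
    50% for the longest arc in the network.  Monotone nondecreasing in
    ``c_ij`` and bounded by ``(1 + f) * pi_b``.
    """
    if c_max <= 0:
        raise CostConfigError(f"c_max must be > 0, got {c_max}")
    if not (0.0 <= c_ij <= c_max):
        raise CostConfigError(f"need 0 <= c_ij <= c_max, got c_ij={c_ij}, c_max={c_max}")
    pi = pi_b + c_ij * pi_b * risk_length_factor / c_max
    if pi >= 1.0:
        raise CostConfigError(f"adjusted risk {pi} >= 1; base risk {pi_b} too large")
    return pi


def derive_all(network: LandscapeNetwork, config: Optional[CostConfig] = None) -> LandscapeNetwork:
    """Populate derived objective attributes for every arc, in place.

    Wetland-internal arcs (both endpoints in the same wetland) get all three
    attributes set to zero and are excluded from the ``c_max`` computation.
    Arc moisture, when absent, is the mean of the endpoint node TWI values.
    Returns the same network for chaining.
    """
    config = config or CostConfig()

    internal = {}
    for key, arc in network.arcs.items():
        u, v = network.nodes[arc.from_id], network.nodes[arc.to_id]
        internal[key] = (
            arc.wetland_internal
            or (u.wetland_id is not None and u.wetland_id == v.wetland_id)
        )

    lengths = [a.length for k, a in network.arcs.items() if not internal[k] and a.length > 0]
    if not lengths:
        c_max = 1.0  # all arcs wetland-internal or zero-length; risk term unused
    else:
        c_max = max(lengths)

    # fill arc moisture from endpoint node TWI where missing
    for key, arc in network.arcs.items():
        if arc.moisture is None and not internal[key]:
            mu = network.nodes[arc.from_id].moisture
            mv = network.nodes[arc.to_id].moisture
            if mu is None or mv is None:
                raise CostConfigError(
                    f"arc {key}: no moisture on arc or both endpoint nodes"
                )
            arc.moisture = 0.5 * (mu + mv)

    m_ideal = config.ideal_moisture
    if m_ideal is None:
        observed = [a.moisture for k, a in network.arcs.items() if not internal[k]]
        m_ideal = max(observed) if observed else 0.0
    local = CostConfig(
        w_p=config.w_p,
        w_n=config.w_n,
        ideal_moisture=m_ideal,
        moisture_offset=config.moisture_offset,
        base_risk=config.base_risk,
        risk_length_factor=config.risk_length_factor,
        twi_max=config.twi_max,
        twi_min=config.twi_min,
    )

    for key, arc in network.arcs.items():
        if internal[key]:
            arc.wetland_internal = True
            arc.risk = 0.0
            arc.log_risk = 0.0
            arc.moisture_weighted_distance = 0.0
            arc.elevation_cost = 0.0
            continue
        u, v = network.nodes[arc.from_id], network.nodes[arc.to_id]
        arc.elevation_cost = elevation_cost(u.elevation, v.elevation, local)
        arc.moisture_weighted_distance = moisture_weighted_distance(
            arc.moisture, arc.length, local
        )
        if arc.base_risk is None:
            if arc.land_cover is None:
                raise CostConfigError(f"arc {key}: no land cover and no base risk")
            try:
                arc.base_risk = local.base_risk[arc.land_cover]
            except KeyError:
                raise CostConfigError(
                    f"arc {key}: unknown land-cover class {arc.land_cover!r}; "
                    f"known classes: {sorted(local.base_risk)}"
                ) from None
        arc.risk = adjusted_risk(arc.base_risk, arc.length, c_max, local.risk_length_factor)
        arc.log_risk = -math.log1p(-arc.risk)
    return network
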
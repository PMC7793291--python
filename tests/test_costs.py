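import math

import pytest

from paretopaths import (
    Arc,
    CostConfig,
    LandscapeNetwork,
    Node,
    adjusted_risk,
    derive_all,
    elevation_cost,
    moisture_weighted_distance,
    twi,
)
from paretopaths.costs import CostConfigError
from conftest import small_grid


class TestElevationCost:
    @pytest.mark.parametrize(
        "e_i, e_j, expected",
        [(100.0, 100.0, 0.0), (100.0, 102.0, 4.0), (102.0, 100.0, 2.0)],
    )
    def test_uphill_weighted_twice_downhill(self, e_i, e_j, expected):
        assert elevation_cost(e_i, e_j, CostConfig(w_p=2.0, w_n=1.0)) == expected

    def test_antisymmetric_decomposition(self):
        """z(i->j) + z(j->i) = (w_p + w_n) * |e_j - e_i| for any adjacency."""
        cfg = CostConfig(w_p=2.0, w_n=1.0)
        for e_i, e_j in [(10.0, 13.5), (13.5, 10.0), (7.0, 7.0), (0.0, 1.25)]:
            total = elevation_cost(e_i, e_j, cfg) + elevation_cost(e_j, e_i, cfg)
            assert total == pytest.approx(3.0 * abs(e_j - e_i), abs=1e-12)

    def test_weight_ordering_enforced(self):
        with pytest.raises(CostConfigError):
            CostConfig(w_p=1.0, w_n=2.0)


class TestTwi:
    def test_log_ratio(self):
        cfg = CostConfig(twi_max=21.77, twi_min=-0.66)
        assert twi(math.e, 1.0, cfg) == pytest.approx(1.0, abs=1e-12)

    def test_zero_slope_nonzero_drainage_gets_max(self):
        cfg = CostConfig(twi_max=21.77, twi_min=-0.66)
        assert twi(5.0, 0.0, cfg) == 21.77

    def test_zero_slope_zero_drainage_gets_min(self):
        cfg = CostConfig(twi_max=21.77, twi_min=-0.66)
        assert twi(0.0, 0.0, cfg) == -0.66

    def test_negative_inputs_rejected(self):
        cfg = CostConfig(twi_max=21.77, twi_min=-0.66)
        with pytest.raises(CostConfigError):
            twi(1.0, -0.1, cfg)


class TestMoistureWeightedDistance:
    def test_at_ideal_moisture_cost_is_length(self):
        cfg = CostConfig(ideal_moisture=8.0)
        assert moisture_weighted_distance(8.0, 10.0, cfg) == 10.0

    def test_deviation_scales_length(self):
        cfg = CostConfig(ideal_moisture=8.0)
        assert moisture_weighted_distance(4.0, 10.0, cfg) == 50.0

    def test_zero_length_arc_costs_nothing(self):
        cfg = CostConfig(ideal_moisture=8.0)
        assert moisture_weighted_distance(30.0, 0.0, cfg) == 0.0

    def test_moisture_above_ideal_band_raises_with_guidance(self):
        cfg = CostConfig(ideal_moisture=8.0)
        with pytest.raises(CostConfigError, match="raise ideal_moisture"):
            moisture_weighted_distance(10.0, 10.0, cfg)


class TestAdjustedRisk:
    def test_longest_arc_gets_fifty_percent_uplift(self):
        # woody-dominated wetland base risk
        assert adjusted_risk(0.060, 100.0, 100.0) == pytest.approx(0.090, abs=1e-12)

    def test_zero_length_no_uplift(self):
        # impervious surface base risk
        assert adjusted_risk(0.095, 0.0, 100.0) == pytest.approx(0.095, abs=1e-12)

    def test_half_cmax_quarter_uplift(self):
        # cropland base risk
        assert adjusted_risk(0.090, 50.0, 100.0) == pytest.approx(0.1125, abs=1e-12)

    def test_monotone_and_bounded(self):
        vals = [adjusted_risk(0.075, c, 100.0) for c in (0.0, 25.0, 50.0, 75.0, 100.0)]
        assert vals == sorted(vals)
        assert vals[-1] <= 1.5 * 0.075 + 1e-15

    def test_length_beyond_cmax_rejected(self):
        with pytest.raises(CostConfigError):
            adjusted_risk(0.06, 101.0, 100.0)


class TestDeriveAll:
    def test_f1_matches_row_by_row_recomputation(self, hand):
        """Spreadsheet-style oracle over the hand fixture's raw attributes."""
        net = hand["F1"]
        derive_all(net, CostConfig())
        elev = {"a0": 100.0, "a1": 102.0, "a2": 101.0, "a3": 104.0}
        moist = {"a0": 4.0, "a1": 6.0, "a2": 2.0, "a3": 8.0}
        base = {("a0", "a1"): 0.075, ("a1", "a2"): 0.090, ("a2", "a3"): 0.065}
        lengths = {("a0", "a1"): 30.0, ("a1", "a2"): 50.0, ("a2", "a3"): 40.0}
        c_max = 50.0
        arc_m = {k: 0.5 * (moist[k[0]] + moist[k[1]]) for k in lengths}
        m_ideal = max(arc_m.values())  # default M: max observed arc moisture
        for (u, v), c in lengths.items():
            for key in [(u, v), (v, u)]:
                arc = net.arcs[key]
                du = elev[key[1]] - elev[key[0]]
                z = 2.0 * du if du >= 0 else -du
                pi = base[(u, v)] * (1.0 + c / (2.0 * c_max))
                assert arc.elevation_cost == pytest.approx(z, abs=1e-12)
                assert arc.moisture_weighted_distance == pytest.approx(
                    (m_ideal - arc_m[(u, v)] + 1.0) * c, abs=1e-12
                )
                assert arc.risk == pytest.approx(pi, abs=1e-12)
                assert arc.log_risk == pytest.approx(math.log(1 / (1 - pi)), abs=1e-12)

    def test_all_wetland_network_gets_zero_costs(self):
        net = LandscapeNetwork()
        for nid in ("a", "b"):
            net.add_node(Node(id=nid, wetland_id="W1"))
        net.add_arc(Arc(from_id="a", to_id="b", length=5.0))
        net.add_arc(Arc(from_id="b", to_id="a", length=5.0))
        derive_all(net, CostConfig())
        for arc in net.arcs.values():
            assert arc.objectives.as_tuple() == (0.0, 0.0, 0.0)

    def test_unknown_land_cover_names_the_class(self):
        net = LandscapeNetwork()
        net.add_node(Node(id="a", moisture=1.0))
        net.add_node(Node(id="b", moisture=1.0))
        net.add_arc(Arc(from_id="a", to_id="b", length=5.0, land_cover="lava_field"))
        with pytest.raises(CostConfigError, match="lava_field"):
            derive_all(net, CostConfig())

    def test_generated_network_costs_nonnegative_and_antisymmetric(self):
        net = small_grid(seed=3, grid_n=4)
        cfg = CostConfig()
        for arc in net.arcs.values():
            assert arc.log_risk >= 0.0
            assert arc.moisture_weighted_distance >= 0.0
            assert arc.elevation_cost >= 0.0
        for (u, v), arc in net.arcs.items():
            rev = net.arcs[(v, u)]
            if arc.wetland_internal:
                continue
            e_u, e_v = net.nodes[u].elevation, net.nodes[v].elevation
            assert arc.elevation_cost + rev.elevation_cost == pytest.approx(
                (cfg.w_p + cfg.w_n) * abs(e_v - e_u), abs=1e-9
            )
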
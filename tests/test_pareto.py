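import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from paretopaths import (
    brute_force_pareto,
    classify_supported,
    dominates,
    is_supported,
    pareto_filter,
)
from paretopaths.pareto import PathCountExceeded


class TestDominates:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((1, 2, 3), (1, 2, 4), True),
            ((1, 2, 3), (1, 2, 3), False),  # equal vectors do not dominate
            ((1, 5, 3), (2, 2, 3), False),  # incomparable
            ((2, 2, 4), (1, 2, 3), False),
        ],
    )
    def test_cases(self, a, b, expected):
        assert dominates(a, b) is expected

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            dominates((1, 2), (1, 2, 3))


class TestParetoFilter:
    def test_dominated_point_dropped(self):
        assert pareto_filter([(1, 1), (2, 2)]) == [(1, 1)]

    def test_mutually_incomparable_all_kept(self):
        out = pareto_filter([(1, 3), (3, 1), (2, 2)])
        assert sorted(out) == [(1, 3), (2, 2), (3, 1)]

    def test_duplicates_collapsed(self):
        assert pareto_filter([(1, 2), (1, 2)]) == [(1, 2)]

    @given(
        st.lists(
            st.tuples(*[st.integers(min_value=0, max_value=9)] * 3),
            min_size=0,
            max_size=40,
        )
    )
    @settings(max_examples=150, deadline=None)
    def test_equals_quadratic_pairwise_oracle(self, vectors):
        got = set(pareto_filter(vectors))
        expected = {
            tuple(v)
            for v in vectors
            if not any(dominates(w, v) for w in vectors)
        }
        assert got == expected

    def test_random_three_vectors_match_oracle(self):
        rng = np.random.default_rng(42)
        vectors = [tuple(v) for v in rng.uniform(0, 1, size=(200, 3))]
        got = set(pareto_filter(vectors))
        expected = {
            v for v in vectors if not any(dominates(w, v) for w in vectors)
        }
        assert got == expected


class TestClassifySupported:
    def test_interior_point_above_segment_unsupported(self):
        frontier = [(1.0, 3.0), (3.0, 1.0), (2.5, 2.5)]
        assert is_supported((1.0, 3.0), frontier)
        assert is_supported((3.0, 1.0), frontier)
        assert not is_supported((2.5, 2.5), frontier)

    def test_on_facet_point_counts_as_supported(self):
        frontier = [(1.0, 3.0), (3.0, 1.0), (2.0, 2.0)]
        assert all(is_supported(v, frontier) for v in frontier)

    def test_singleton_frontier_supported(self):
        assert is_supported((5.0, 5.0, 5.0), [(5.0, 5.0, 5.0)])

    def test_coordinate_minima_always_supported(self):
        rng = np.random.default_rng(7)
        pts = [tuple(v) for v in rng.uniform(0, 1, size=(30, 3))]
        frontier = pareto_filter(pts)
        if len(frontier) >= 2:
            for l in range(3):
                v_min = min(frontier, key=lambda v: v[l])
                assert is_supported(v_min, frontier)

    def test_classification_matches_direct_weight_search(self):
        """Dense weight-grid certification: any point that some strictly
        positive weight certifies must be flagged supported."""
        rng = np.random.default_rng(3)
        pts = [tuple(v) for v in rng.uniform(0, 1, size=(40, 3))]
        frontier = pareto_filter(pts)
        flags = {v: is_supported(v, frontier) for v in frontier}
        grid = np.linspace(0.05, 0.9, 12)
        for w1 in grid:
            for w2 in grid:
                w3 = 1.0 - w1 - w2
                if w3 < 0.05:
                    continue
                w = np.array([w1, w2, w3])
                vals = {v: float(w @ np.array(v)) for v in frontier}
                best = min(vals.values())
                for v, val in vals.items():
                    if val <= best + 1e-12:
                        assert flags[v], (v, w)


class TestBruteForce:
    def test_single_arc_network(self):
        from paretopaths import Arc, LandscapeNetwork, Node

        net = LandscapeNetwork()
        net.add_node(Node(id="o"))
        net.add_node(Node(id="d"))
        net.add_arc(
            Arc(from_id="o", to_id="d", length=1.0, log_risk=1.0, risk=0.5,
                moisture_weighted_distance=2.0, elevation_cost=3.0)
        )
        ps = brute_force_pareto(net, "o", "d")
        assert len(ps) == 1
        assert ps.paths[0].objectives.as_tuple() == (1.0, 2.0, 3.0)

    def test_diamond_network_keeps_incomparable_routes(self):
        from paretopaths import Arc, LandscapeNetwork, Node

        net = LandscapeNetwork()
        for nid in ("o", "a", "b", "d"):
            net.add_node(Node(id=nid))
        for mid, (x, y, z) in (("a", (1.0, 3.0, 1.0)), ("b", (3.0, 1.0, 1.0))):
            for u, v in (("o", mid), (mid, "d")):
                net.add_arc(
                    Arc(from_id=u, to_id=v, length=1.0, log_risk=x / 2, risk=0.1,
                        moisture_weighted_distance=y / 2, elevation_cost=z / 2)
                )
        ps = brute_force_pareto(net, "o", "d")
        assert sorted(v.as_tuple() for v in ps.vectors) == [
            (1.0, 3.0, 1.0),
            (3.0, 1.0, 1.0),
        ]

    def test_guard_refuses_explosive_enumeration(self, f2):
        with pytest.raises(PathCountExceeded, match="more than 1"):
            brute_force_pareto(f2, "o", "d", max_paths=1)

    def test_f2_classification(self, f2):
        ps = classify_supported(brute_force_pareto(f2, "o", "d"))
        by_vec = {p.objectives.as_tuple(): p.supported for p in ps}
        assert by_vec == {
            (1.0, 6.0, 1.0): True,
            (6.0, 1.0, 1.0): True,
            (2.0, 2.0, 9.0): True,
            (4.0, 4.0, 4.0): False,
        }
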
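import pytest
from hypothesis import given, settings, strategies as st

from paretopaths import (
    Arc,
    LandscapeNetwork,
    Node,
    brute_force_pareto,
    dominates,
    label_all,
    merge_labels,
    monise,
)
from paretopaths.labeling import Label
from conftest import small_grid, wetland_od_pairs


def _mk_labels(vectors):
    return [Label(tuple(map(float, g)), None, None, k) for k, g in enumerate(vectors)]


class TestMergeLabels:
    def test_insert_into_empty(self):
        survivors, accept = merge_labels([], (1.0, 1.0, 1.0))
        assert survivors == [] and accept

    def test_dominated_candidate_rejected(self):
        existing = _mk_labels([(1, 1, 1)])
        survivors, accept = merge_labels(existing, (2.0, 2.0, 2.0))
        assert not accept and survivors == existing

    def test_equal_vector_deduplicated_by_default(self):
        existing = _mk_labels([(1, 1, 1)])
        _, accept = merge_labels(existing, (1.0, 1.0, 1.0))
        assert not accept
        _, accept = merge_labels(existing, (1.0, 1.0, 1.0), keep_equal_vectors=True)
        assert accept

    def test_candidate_evicts_dominated_labels(self):
        existing = _mk_labels([(2, 2, 2), (1, 1, 5)])
        survivors, accept = merge_labels(existing, (1.0, 3.0, 1.0))
        assert accept
        # brute-force pairwise dominance oracle over the union
        got = {s.g for s in survivors} | {(1.0, 3.0, 1.0)}
        union = [(2.0, 2.0, 2.0), (1.0, 1.0, 5.0), (1.0, 3.0, 1.0)]
        expected = {
            v for v in union if not any(dominates(w, v) for w in union)
        }
        assert got == expected

    @given(
        existing=st.lists(
            st.tuples(*[st.integers(0, 5)] * 3), min_size=0, max_size=8
        ),
        cand=st.tuples(*[st.integers(0, 5)] * 3),
    )
    @settings(max_examples=150, deadline=None)
    def test_merge_agrees_with_pairwise_oracle(self, existing, cand):
        base = [tuple(map(float, v)) for v in existing]
        base = [v for v in base if not any(dominates(w, v) for w in base)]
        base = list(dict.fromkeys(base))  # mutually non-dominated, unique
        cand = tuple(map(float, cand))
        survivors, accept = merge_labels(_mk_labels(base), cand)
        if accept:
            final = {s.g for s in survivors} | {cand}
        else:
            final = {s.g for s in survivors}
        union = base + [cand]
        expected = {v for v in union if not any(dominates(w, v) for w in union)}
        assert final == expected


class TestLabelAll:
    def test_single_arc_network(self):
        net = LandscapeNetwork()
        net.add_node(Node(id="o"))
        net.add_node(Node(id="d"))
        net.add_arc(
            Arc(from_id="o", to_id="d", length=1.0, log_risk=0.2, risk=0.18,
                moisture_weighted_distance=5.0, elevation_cost=1.0)
        )
        res = label_all(net, "o")
        assert [v.as_tuple() for v in res["d"].vectors] == [(0.2, 5.0, 1.0)]
        assert res["d"].paths[0].arcs == [("o", "d")]

    def test_unreachable_destination_empty_set(self):
        net = LandscapeNetwork()
        net.add_node(Node(id="o"))
        net.add_node(Node(id="x"))
        res = label_all(net, "o")
        assert len(res["x"]) == 0

    def test_f2_equals_exhaustive_oracle(self, f2):
        res = label_all(f2, "o", ["d"])["d"]
        oracle = brute_force_pareto(f2, "o", "d", keep_equal_vectors=True)
        assert sorted(v.as_tuple() for v in res.vectors) == sorted(
            {p.objectives.as_tuple() for p in oracle}
        )
        oracle_arcseqs = {tuple(p.arcs) for p in oracle.paths}
        for p in res.paths:
            assert tuple(p.arcs) in oracle_arcseqs

    def test_terminates_with_zero_cost_wetland_cycles(self, f2):
        # F2 has zero-cost cycles o<->o2 and d<->d2; finite label sets prove halt
        res = label_all(f2, "o")
        assert all(len(ps) < 50 for ps in res.values())

    def test_keep_equal_vectors_returns_distinct_arc_sequences(self):
        # two routes engineered to share one objective vector
        net = LandscapeNetwork()
        for nid in ("o", "a", "b", "d"):
            net.add_node(Node(id=nid))
        for mid in ("a", "b"):
            for u, v in (("o", mid), (mid, "d")):
                net.add_arc(
                    Arc(from_id=u, to_id=v, length=1.0, log_risk=1.0, risk=0.5,
                        moisture_weighted_distance=1.0, elevation_cost=1.0)
                )
        dedup = label_all(net, "o", ["d"])["d"]
        keep = label_all(net, "o", ["d"], keep_equal_vectors=True)["d"]
        assert len(dedup) == 1
        assert len(keep) == 2
        assert {tuple(p.arcs) for p in keep.paths} == {
            (("o", "a"), ("a", "d")),
            (("o", "b"), ("b", "d")),
        }

    def test_subpath_efficiency_of_returned_paths(self):
        """Bellman property: every prefix of a returned path is itself
        non-dominated to its intermediate node."""
        net = small_grid(seed=13)
        (o, d), *_ = wetland_od_pairs(net)
        res = label_all(net, o, [d])[d]
        for p in res.paths[:6]:
            for cut in range(1, len(p.arcs)):
                mid = p.arcs[cut - 1][1]
                prefix_vec = [0.0, 0.0, 0.0]
                for key in p.arcs[:cut]:
                    t = net.arcs[key].objectives.as_tuple()
                    prefix_vec = [a + b for a, b in zip(prefix_vec, t)]
                frontier = {
                    q.objectives.as_tuple()
                    for q in brute_force_pareto(net, o, mid, max_paths=5000)
                }
                assert not any(
                    dominates(v, tuple(prefix_vec)) for v in frontier
                )

    @pytest.mark.parametrize("seed", [21, 22, 23])
    def test_contains_every_monise_vector(self, seed):
        net = small_grid(seed=seed)
        for o, d in wetland_od_pairs(net):
            lab_vecs = {
                v.as_tuple() for v in label_all(net, o, [d])[d].vectors
            }
            for v in monise(net, o, d).vectors:
                assert v.as_tuple() in lab_vecs
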
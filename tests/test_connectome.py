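import math

import numpy as np
import pytest

from geneconnectome import (
    InteractionRecord,
    UnknownGeneError,
    build_connectome,
    build_network,
    route_between,
    shortest_paths,
)
from conftest import D_AB, D_AC, D_AD, net_from_distances
from oracles import enumerate_distance, random_edges


class TestShortestPaths:
    def test_indirect_route_beats_direct_edge(self, g1_net):
        dist, routes = shortest_paths(g1_net, "A")
        assert dist["C"] == pytest.approx(D_AC, abs=1e-12)
        assert routes["C"] == ["A", "B", "C"]
        # cross-check against exhaustive simple-path enumeration
        edges = {
            ("A", "B"): 1 / 0.9, ("B", "C"): 1 / 0.5,
            ("A", "C"): 1 / 0.25, ("C", "D"): 1 / 0.8,
        }
        assert dist["C"] == pytest.approx(enumerate_distance(edges, "A", "C"), abs=1e-12)
        assert dist["D"] == pytest.approx(enumerate_distance(edges, "A", "D"), abs=1e-12)

    def test_unreachable_node_gets_infinite_distance(self, g1_net):
        dist, routes = shortest_paths(g1_net, "A")
        assert math.isinf(dist["E"])
        assert routes["E"] == []

    def test_unknown_core_raises_with_symbol(self, g1_net):
        with pytest.raises(UnknownGeneError, match="NOPE"):
            shortest_paths(g1_net, "NOPE")


class TestBuildConnectome:
    def test_g1_full_hand_derived_table(self, g1_net):
        conn = build_connectome(g1_net, "A")
        by = {r.target: r for r in conn.records}
        assert conn.n_genes == 4

        b = by["B"]
        assert b.distance == pytest.approx(D_AB, abs=1e-12)
        assert (b.rank, b.p_value, b.degrees, b.sphere) == (1, 0.25, 1, 3)
        finite = sorted([D_AB, D_AC, D_AD])
        assert b.ratio_median == pytest.approx(D_AB / finite[1], abs=1e-12)
        assert b.ratio_mean == pytest.approx(D_AB / (sum(finite) / 3), abs=1e-12)

        assert by["C"].rank == 2 and by["C"].p_value == 0.5
        assert by["D"].route == ("A", "B", "C", "D") and by["D"].degrees == 3

        e = by["E"]
        assert math.isinf(e.distance)
        assert (e.rank, e.p_value, e.route, e.degrees) == (4, 1.0, (), None)
        assert e.ratio_median is None and e.ratio_mean is None
        assert e.brp == 1.0

    def test_core_queried_against_own_connectome(self, g1_net):
        rec = build_connectome(g1_net, "A").record("A")
        assert (rec.distance, rec.rank, rec.degrees) == (0.0, 0, 0)
        assert rec.route == ("A",)
        assert rec.p_value == pytest.approx(0.25)

    def test_equal_distances_tie_break_alphabetically(self):
        records = [InteractionRecord("X", t, 0.5) for t in ("C", "B", "D")]
        conn = build_connectome(build_network(records), "X")
        assert [r.target for r in conn.records] == ["B", "C", "D"]
        assert [r.rank for r in conn.records] == [1, 2, 3]

    def test_full_names_come_from_alias_map(self, g1_net):
        from geneconnectome import AliasEntry, AliasMap

        amap = AliasMap([AliasEntry("B", "B", "gene bee")])
        conn = build_connectome(g1_net, "A", alias_map=amap)
        assert conn.record("B").full_name == "gene bee"
        assert conn.record("C").full_name == ""

    @pytest.mark.parametrize("seed", range(5))
    def test_rank_and_route_invariants_on_random_networks(self, seed):
        rng = np.random.default_rng(seed)
        nodes, edges = random_edges(rng, n=25, p=0.12)
        if not edges:
            pytest.skip("empty draw")
        net = net_from_distances(nodes, edges)
        core = nodes[0]
        conn = build_connectome(net, core, with_brp=False)
        # distance nondecreasing with rank; unreachable strictly last
        dists = [r.distance for r in conn.records]
        assert all(a <= b or math.isinf(a) == math.isinf(b) for a, b in zip(dists, dists[1:]))
        assert dists == sorted(dists)
        assert [r.rank for r in conn.records] == list(range(1, len(nodes)))
        # route consistency: edge sums reproduce the distance; degrees = hops
        for r in conn.records:
            if not r.reachable:
                continue
            total = sum(
                net.distance(a, b) for a, b in zip(r.route, r.route[1:])
            )
            assert total == pytest.approx(r.distance, abs=1e-9)
            assert r.degrees == len(r.route) - 1


class TestRouteBetween:
    def test_minimal_route_g1(self, g1_net):
        assert route_between(g1_net, "A", "D") == ["A", "B", "C", "D"]

    def test_self_route(self, g1_net):
        assert route_between(g1_net, "A", "A") == ["A"]

    def test_disconnected_pair_returns_empty(self, g1_net):
        assert route_between(g1_net, "A", "E") == []

    def test_route_is_symmetric_in_content(self, g1_net):
        assert route_between(g1_net, "D", "A") == list(reversed(route_between(g1_net, "A", "D")))
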
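"""Network search, enrichment, RWR and the rewiring null model."""

import math
from itertools import combinations

import numpy as np
import pytest

from coupnet import Link, Network, OrthologMap
from coupnet.nettools import (
    align_orthologs,
    ease_enrichment,
    group_search,
    independent_search,
    maxlink_rank,
    neighbor_gain,
    performance_gain,
    rewire_preserve_degree,
    rwr,
)


def _net(edges, ppv=0.9):
    if isinstance(edges, dict):
        return Network(Link(a=a, b=b, ppv=p) for (a, b), p in edges.items())
    return Network(Link(a=a, b=b, ppv=ppv) for a, b in edges)


# a 6-node toy graph: hub links to all of q1-q3; leaf links only to q1
TOY = _net(
    {
        ("hub", "q1"): 0.90,
        ("hub", "q2"): 0.90,
        ("hub", "q3"): 0.90,
        ("leaf", "q1"): 0.99,
        ("q1", "q2"): 0.95,
    }
)


class TestGroupSearch:
    def test_common_neighbor_prioritization_ranks_hub_first(self):
        res = group_search(
            TOY, {"q1", "q2", "q3"}, n_add=2, prioritize_common=True, cutoff=0.85
        )
        assert [e.node for e in res.added_nodes] == ["hub", "leaf"]
        assert res.added_nodes[0].links_to_query == 3

    def test_without_prioritization_summed_ppv_rules(self):
        res = group_search(TOY, {"q1", "q2", "q3"}, n_add=2, cutoff=0.85)
        assert res.added_nodes[0].node == "hub"  # 2.7 > 0.99

    def test_zero_expansion_returns_induced_subgraph(self):
        res = group_search(TOY, {"q1", "q2"}, n_add=0, cutoff=0.85)
        assert res.added_nodes == []
        assert res.subnetwork.pairs() == {("q1", "q2")}

    def test_duplicate_query_genes_deduplicated(self):
        res = group_search(TOY, ["q1", "q1", "q2"], n_add=1, cutoff=0.85)
        assert all(e.node not in {"q1", "q2"} for e in res.added_nodes)

    def test_unmapped_query_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            res = group_search(TOY, {"zzz"}, n_add=3)
        assert len(res.subnetwork) == 0


class TestIndependentSearch:
    def test_disconnected_queries_each_expand(self):
        net = _net({("a", "x"): 0.9, ("b", "y"): 0.9})
        res = independent_search(net, {"a", "b"}, n_add_per_gene=1, cutoff=0.85)
        assert {e.node for e in res.added_nodes} == {"x", "y"}

    def test_shared_neighbors_deduplicated(self):
        res = independent_search(TOY, {"q2", "q3"}, n_add_per_gene=2, cutoff=0.85)
        nodes = [e.node for e in res.added_nodes]
        assert len(nodes) == len(set(nodes))

    def test_at_least_as_large_as_group_search(self):
        query = {"q1", "q2", "q3"}
        ind = independent_search(TOY, query, n_add_per_gene=1, cutoff=0.85)
        grp = group_search(TOY, query, n_add=1, cutoff=0.85)
        assert len(ind.added_nodes) >= len(grp.added_nodes)


def _maxlink_brute_force_p(n_pop, q, d, x):
    """Exact hypergeometric upper tail by enumeration."""
    total = math.comb(n_pop, d)
    acc = 0
    for k in range(x, min(d, q) + 1):
        acc += math.comb(q, k) * math.comb(n_pop - q, d - k)
    return acc / total


class TestMaxLink:
    def test_hand_checked_p_value(self):
        # N=10, q=3, candidate degree 4 with all 3 query links
        query = {"q1", "q2", "q3"}
        edges = {("cand", q) for q in query} | {("cand", "n1")}
        others = {("n2", "n3"), ("n4", "n5"), ("q1", "n6")}
        net = _net(edges | others)
        assert len(net.nodes()) == 10
        ranked = maxlink_rank(net, query, cutoff=0.85)
        cand = next(e for e in ranked if e.node == "cand")
        assert cand.p_value == pytest.approx(6 / 126, rel=1e-9)

    def test_zero_links_gives_p_one(self):
        net = _net({("a", "b"), ("c", "d")})
        ranked = maxlink_rank(net, {"a"}, cutoff=0.85)
        c = next(e for e in ranked if e.node == "c")
        assert c.links_to_query == 0 and c.p_value == 1.0

    def test_more_query_links_rank_higher(self):
        query = {"q1", "q2", "q3"}
        edges = (
            {("full", q) for q in query}
            | {("partial", "q1"), ("partial", "n1"), ("partial", "n2")}
        )
        net = _net(edges)
        ranked = maxlink_rank(net, query, cutoff=0.85)
        assert ranked[0].node == "full"

    def test_matches_enumeration_on_random_networks(self):
        rng = np.random.default_rng(8)
        for trial in range(100):
            n = int(rng.integers(5, 13))
            nodes = [f"n{i}" for i in range(n)]
            possible = list(combinations(nodes, 2))
            k = int(rng.integers(n - 1, len(possible) + 1))
            idx = rng.choice(len(possible), size=k, replace=False)
            net = _net({possible[i] for i in idx})
            present = sorted(net.nodes())
            q_size = int(rng.integers(1, max(2, len(present) // 2)))
            query = set(present[:q_size])
            adj = net.neighbors()
            for entry in maxlink_rank(net, query, cutoff=0.0):
                d = len(adj[entry.node])
                expected = _maxlink_brute_force_p(
                    len(present) - 1, len(query & set(adj)), d,
                    entry.links_to_query,
                )
                assert entry.p_value == pytest.approx(expected, rel=1e-9)


class TestEase:
    def test_hand_checked_value(self):
        query = {f"g{i}" for i in range(5)}
        pathway = {"g0", "g1", "g2", "p3", "p4", "p5"}
        # overlap 3, EASE tests P(X >= 2) with universe 20
        expected = 1.0
        for k in (0, 1):
            expected -= (
                math.comb(6, k) * math.comb(14, 5 - k) / math.comb(20, 5)
            )
        assert ease_enrichment(query, pathway, 20) == pytest.approx(
            expected, rel=1e-9
        )
        assert expected == pytest.approx(0.4835, abs=5e-4)

    def test_single_overlap_gives_one(self):
        assert ease_enrichment({"a", "b"}, {"a", "z"}, 10) == 1.0

    def test_pathway_equal_to_universe(self):
        query = {"a", "b"}
        pathway = {f"g{i}" for i in range(8)} | query
        assert ease_enrichment(query, pathway, 10) == pytest.approx(1.0)

    def test_zero_overlap_gives_one(self):
        assert ease_enrichment({"a"}, {"b"}, 10) == 1.0

    def test_matches_enumeration_on_random_instances(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            universe = int(rng.integers(5, 31))
            genes = [f"g{i}" for i in range(universe)]
            q = set(rng.choice(genes, size=int(rng.integers(1, universe)), replace=False))
            p = set(rng.choice(genes, size=int(rng.integers(1, universe)), replace=False))
            k = len(q & p)
            if k == 0:
                expected = 1.0
            else:
                total = math.comb(universe, len(q))
                acc = 0
                for j in range(k - 1, min(len(q), len(p)) + 1):
                    acc += math.comb(len(p), j) * math.comb(
                        universe - len(p), len(q) - j
                    )
                expected = acc / total
            assert ease_enrichment(q, p, universe) == pytest.approx(
                expected, rel=1e-9
            )


class TestAlignOrthologs:
    def test_single_rectangle(self):
        net_a = _net({("PSEN1", "CRK")})
        net_b = _net({("sel-12", "ced-2")})
        omap = OrthologMap(
            species_pair=("hs", "ce"),
            pairs={("PSEN1", "sel-12"), ("CRK", "ced-2")},
        )
        rects = align_orthologs(net_a, net_b, omap)
        assert len(rects) == 1
        r = rects[0]
        assert {r.a1, r.b1} == {"PSEN1", "CRK"}
        assert {r.a2, r.b2} == {"ced-2", "sel-12"}

    def test_no_ortholog_links_empty(self):
        net_a = _net({("a", "b")})
        net_b = _net({("x", "y")})
        omap = OrthologMap(species_pair=("hs", "ce"), pairs=set())
        assert align_orthologs(net_a, net_b, omap) == []

    def test_symmetric_under_species_swap(self):
        net_a = _net({("a1", "b1"), ("a1", "c1")})
        net_b = _net({("a2", "b2")})
        omap = OrthologMap(
            species_pair=("s1", "s2"),
            pairs={("a1", "a2"), ("b1", "b2"), ("c1", "b2")},
        )
        forward = align_orthologs(net_a, net_b, omap)
        backward = align_orthologs(net_b, net_a, omap.reversed())
        fw = {(r.a2, r.b2, r.a1, r.b1) for r in forward}
        bw = {(r.a1, r.b1, r.a2, r.b2) for r in backward}
        assert {tuple(sorted(t[:2]) + sorted(t[2:])) for t in fw} == {
            tuple(sorted(t[:2]) + sorted(t[2:])) for t in bw
        }


class TestRWR:
    def test_two_node_fixed_point(self):
        net = _net({("a", "b")})
        p = rwr(net, {"a"}, restart=0.75)
        assert p["a"] == pytest.approx(0.8, abs=1e-9)
        assert p["b"] == pytest.approx(0.2, abs=1e-9)

    def test_full_restart_returns_seed_vector(self):
        net = _net({("a", "b"), ("b", "c")})
        p = rwr(net, {"a", "c"}, restart=1.0)
        assert p == pytest.approx({"a": 0.5, "b": 0.0, "c": 0.5})

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(10)
        nodes = [f"n{i}" for i in range(30)]
        edges = set()
        for i, a in enumerate(nodes[:-1]):
            edges.add((a, nodes[i + 1]))  # path keeps everything connected
        extra = list(combinations(nodes, 2))
        idx = rng.choice(len(extra), size=40, replace=False)
        edges |= {extra[i] for i in idx}
        net = _net({(a, b) for a, b in edges if a != b})
        p = rwr(net, {"n0", "n7"}, restart=0.75)
        assert sum(p.values()) == pytest.approx(1.0, abs=1e-9)

    def test_matches_direct_linear_solve(self):
        rng = np.random.default_rng(11)
        for _ in range(20)[:20]:
            n = int(rng.integers(4, 12))
            nodes = [f"n{i}" for i in range(n)]
            edges = {(nodes[i], nodes[i + 1]) for i in range(n - 1)}
            extra = list(combinations(nodes, 2))
            idx = rng.choice(len(extra), size=min(6, len(extra)), replace=False)
            edges |= {extra[i] for i in idx}
            net = _net(edges)
            seeds = {nodes[0]}
            got = rwr(net, seeds, restart=0.75, tol=1e-14)
            ordered = sorted(net.nodes())
            w = np.zeros((len(ordered), len(ordered)))
            for a, b in net.pairs():
                i, j = ordered.index(a), ordered.index(b)
                w[i, j] = w[j, i] = 1.0
            w = w / w.sum(axis=0)
            e = np.array([1.0 if x in seeds else 0.0 for x in ordered])
            p = 0.75 * np.linalg.solve(np.eye(len(ordered)) - 0.25 * w, e)
            for i, x in enumerate(ordered):
                assert got[x] == pytest.approx(p[i], abs=1e-9)

    def test_unmapped_seeds_rejected(self):
        with pytest.raises(ValueError):
            rwr(_net({("a", "b")}), {"zzz"})


class TestRewiring:
    @staticmethod
    def _degrees(net):
        deg = {}
        for a, b in net.pairs():
            deg[a] = deg.get(a, 0) + 1
            deg[b] = deg.get(b, 0) + 1
        return deg

    def test_degree_sequence_preserved(self):
        rng = np.random.default_rng(12)
        nodes = [f"n{i}" for i in range(20)]
        possible = list(combinations(nodes, 2))
        idx = rng.choice(len(possible), size=50, replace=False)
        net = _net({possible[i] for i in idx})
        rewired = rewire_preserve_degree(net, seed=3)
        assert self._degrees(rewired) == self._degrees(net)
        assert len(rewired) == len(net)
        assert all(a != b for a, b in rewired.pairs())
        assert rewired.pairs() != net.pairs()  # enough links that some move

    def test_triangle_cannot_be_rewired(self):
        net = _net({("a", "b"), ("b", "c"), ("a", "c")})
        rewired = rewire_preserve_degree(net, seed=1)
        assert rewired.pairs() == net.pairs()

    def test_seeded_determinism(self):
        rng = np.random.default_rng(13)
        nodes = [f"n{i}" for i in range(15)]
        possible = list(combinations(nodes, 2))
        idx = rng.choice(len(possible), size=30, replace=False)
        net = _net({possible[i] for i in idx})
        r1 = rewire_preserve_degree(net, seed=9)
        r2 = rewire_preserve_degree(net, seed=9)
        assert r1.pairs() == r2.pairs()


class TestPerformanceGain:
    @staticmethod
    def _planted_module_network(seed=14):
        # dense 12-node module inside a 60-node sparse background
        rng = np.random.default_rng(seed)
        module = [f"m{i}" for i in range(12)]
        background = [f"b{i}" for i in range(48)]
        edges = set()
        mod_pairs = list(combinations(module, 2))
        idx = rng.choice(len(mod_pairs), size=40, replace=False)
        edges |= {mod_pairs[i] for i in idx}
        allnodes = module + background
        for i, node in enumerate(background):
            edges.add((node, allnodes[rng.integers(0, i + 12)]))
        edges = {e for e in edges if e[0] != e[1]}
        return _net(edges), module

    def test_planted_module_has_positive_gain(self):
        net, module = self._planted_module_network()
        result = performance_gain(
            module, net, n_splits=10, n_randomizations=5, seed=0
        )
        assert result is not None
        assert result.median_real > result.median_null
        assert result.pg > 0
        # PG is consistent with the stored medians
        assert result.pg == pytest.approx(
            (result.median_real - result.median_null) / result.median_null
        )

    def test_unmappable_geneset_skipped_with_warning(self):
        net = _net({("a", "b")})
        with pytest.warns(UserWarning):
            assert performance_gain({"x"}, net, n_splits=2) is None


class TestNeighborGain:
    NET = _net(
        {("q1", "x1"), ("q1", "x2"), ("q2", "x3"), ("q2", "x4"), ("q1", "q2")}
    )

    def test_hand_checked_ratio(self):
        assert neighbor_gain(self.NET, {"q1", "q2"}) == pytest.approx(2.0)

    def test_query_neighbors_excluded_from_numerator(self):
        net = _net({("q1", "q2"), ("q2", "q3")})
        assert neighbor_gain(net, {"q1", "q2", "q3"}) == 0.0

    def test_unmapped_query_rejected(self):
        with pytest.raises(ValueError):
            neighbor_gain(self.NET, {"zzz"})
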
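"""Shortest-path engines, distance profiles, enrichment, linker extraction."""
import networkx as nx
import numpy as np
import pytest

from conftest import random_simple_graph
from repurposenet.network import (
    all_pairs_distances,
    degree_contrast,
    distance_to_set,
    enrichment_permutation_null,
    extract_linker_subnetwork,
    neighbor_enrichment,
    neighborhood_of_order,
)


class TestAllPairsDistances:
    def test_path_graph(self):
        g = nx.path_graph(["a", "b", "c"])
        for engine in ("bfs", "floyd-warshall"):
            d = all_pairs_distances(g, engine=engine)
            assert d.loc["a", "c"] == 2
            assert d.loc["a", "a"] == 0

    def test_disconnected_components_unreachable(self):
        g = nx.Graph([("a", "b"), ("c", "d")])
        d = all_pairs_distances(g)
        assert np.isinf(d.loc["a", "c"])

    def test_engines_agree_on_random_graphs(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            g = random_simple_graph(rng, 30)
            bfs = all_pairs_distances(g, engine="bfs")
            fw = all_pairs_distances(g, engine="floyd-warshall")
            assert bfs.equals(fw)

    def test_unknown_engine_rejected(self):
        with pytest.raises(ValueError):
            all_pairs_distances(nx.path_graph(3), engine="dijkstra")


class TestDistanceToSet:
    def test_member_of_reference_has_distance_zero(self):
        g = nx.path_graph(["a", "b", "c"])
        prof = distance_to_set(g, {"a"}, {"a", "c"})
        assert prof.distances["a"] == 0

    def test_star_leaves_all_at_distance_one(self):
        g = nx.star_graph(5)
        prof = distance_to_set(g, set(range(1, 6)), {0})
        assert (prof.distances == 1).all()

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            distance_to_set(nx.path_graph(3), {0}, set())

    def test_unreachable_kept_out_of_mean(self):
        g = nx.Graph([("a", "b"), ("c", "d")])
        prof = distance_to_set(g, {"a", "c"}, {"b"})
        assert prof.unreachable == ["c"]
        assert prof.mean_distance == 1.0
        assert prof.histogram["unreachable"] == 1

    def test_union_decomposes_as_minimum(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            g = random_simple_graph(rng, 25)
            nodes = list(g.nodes)
            if len(nodes) < 4:
                continue
            s1 = set(rng.choice(nodes, 2, replace=False).tolist())
            s2 = set(rng.choice(nodes, 2, replace=False).tolist())
            q = set(nodes)
            du = distance_to_set(g, q, s1 | s2).distances
            d1 = distance_to_set(g, q, s1).distances
            d2 = distance_to_set(g, q, s2).distances
            combined = d1.reindex(du.index).combine(
                d2.reindex(du.index), lambda x, y: np.nanmin([x, y])
            )
            assert du.equals(combined.astype(float))


class TestNeighborEnrichment:
    def toy(self):
        # seeds s1,s2; their only neighbors x,y are class members; 8 nodes total
        g = nx.Graph([("s1", "x"), ("s2", "y"), ("a", "b"), ("c", "d")])
        return g

    def test_hand_computed_fold(self):
        res = neighbor_enrichment(self.toy(), {"s1", "s2"}, {"x", "y"}, order=1)
        assert res.neighborhood_fraction == 1.0
        assert res.background_fraction == pytest.approx(0.25)
        assert res.fold_enrichment == pytest.approx(4.0)

    def test_class_disjoint_from_neighborhood_gives_zero(self):
        res = neighbor_enrichment(self.toy(), {"s1", "s2"}, {"a", "b"}, order=1)
        assert res.fold_enrichment == 0.0

    def test_seeds_excluded_from_own_neighborhood(self):
        g = nx.Graph([("s1", "s2"), ("s1", "x")])
        hood = neighborhood_of_order(g, {"s1", "s2"}, 1)
        assert hood == {"x"}

    def test_order1_and_order2_disjoint(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            g = random_simple_graph(rng, 30)
            nodes = list(g.nodes)
            seeds = set(rng.choice(nodes, min(3, len(nodes)), replace=False).tolist())
            n1 = neighborhood_of_order(g, seeds, 1)
            n2 = neighborhood_of_order(g, seeds, 2)
            assert n1 & n2 == set()
            assert seeds & (n1 | n2) == set()

    def test_empty_neighborhood_flagged_undefined(self):
        g = nx.Graph()
        g.add_edge("a", "b")
        g.add_node("s")  # isolated seed
        res = neighbor_enrichment(g, {"s"}, {"a"}, order=1)
        assert res.undefined

    def test_permutation_null_mean_fold_near_one(self):
        from repurposenet.synthetic import gen_network

        g, _ = gen_network(200, seed=5)
        seeds = set(sorted(g.nodes)[:10])
        folds = enrichment_permutation_null(g, seeds, class_size=50, order=1,
                                            n_permutations=400, seed=9)
        assert abs(folds.mean() - 1.0) < 0.1


class TestDegreeContrast:
    def test_regular_graph_no_difference(self):
        g = nx.cycle_graph(12)
        res = degree_contrast(g, set(range(4)))
        assert res.test.pvalue == 1.0

    def test_star_hubs_dominate(self):
        g = nx.Graph()
        for h in range(3):
            for leaf in range(5):
                g.add_edge(f"h{h}", f"h{h}_l{leaf}")
        res = degree_contrast(g, {"h0", "h1", "h2"})
        assert res.class_degrees.min() > res.all_degrees.median()
        assert res.test.pvalue < 0.01

    def test_degree_weighted_class_has_higher_degree(self):
        from repurposenet.synthetic import gen_network

        wins = 0
        for s in range(10):
            g, _ = gen_network(300, seed=s)
            degrees = dict(g.degree)
            nodes = sorted(g.nodes)
            w = np.array([degrees[v] for v in nodes], dtype=float)
            rng = np.random.default_rng(100 + s)
            cls = set(rng.choice(nodes, size=50, replace=False, p=w / w.sum()))
            res = degree_contrast(g, cls)
            if res.class_degrees.mean() > res.all_degrees.mean():
                wins += 1
        assert wins >= 9


class TestLinkerSubnetwork:
    def test_single_intermediate_kept(self):
        g = nx.path_graph(["a", "x", "b"])
        sub = extract_linker_subnetwork(g, {"a"}, {"b"}, max_intermediates=1)
        assert set(sub.nodes) == {"a", "x", "b"}
        assert sub.nodes["x"]["klass"] == "linker"
        assert sub.number_of_edges() == 2

    def test_two_intermediates_excluded_at_limit_one(self):
        g = nx.path_graph(["a", "x", "y", "b"])
        sub = extract_linker_subnetwork(g, {"a"}, {"b"}, max_intermediates=1)
        assert set(sub.nodes) == {"a", "b"}
        assert sub.number_of_edges() == 0

    def test_matches_neighbor_intersection_oracle(self):
        # for one allowed intermediate, a linker is exactly a node adjacent
        # to two or more distinct kept genes
        rng = np.random.default_rng(23)
        for _ in range(20):
            g = random_simple_graph(rng, 20)
            nodes = list(g.nodes)
            if len(nodes) < 6:
                continue
            a = set(rng.choice(nodes, 2, replace=False).tolist())
            b = set(rng.choice(nodes, 2, replace=False).tolist())
            kept = a | b
            expected = {
                v for v in g.nodes
                if v not in kept and len(set(g[v]) & kept) >= 2
            }
            sub = extract_linker_subnetwork(g, a, b, max_intermediates=1)
            got = {v for v in sub.nodes if sub.nodes[v]["klass"] == "linker"}
            assert got == expected
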
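import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from rbpnet import network as net
from rbpnet.containers import EdgeList, IDMap

from conftest import make_sample_table


def edge_list(*triples) -> EdgeList:
    return EdgeList.from_records(triples)


class TestBuildGraph:
    def test_score_threshold_is_inclusive(self):
        edges = edge_list(("P1", "P2", 499), ("P2", "P3", 500), ("P3", "P4", 800))
        g = net.build_graph(edges, 500)
        assert not g.has_edge("P1", "P2")
        assert g.has_edge("P2", "P3")
        assert "P1" not in g  # only sub-threshold edges -> absent

    def test_high_scores_keep_everything(self):
        edges = edge_list(("P1", "P2", 1000), ("P2", "P3", 1000))
        g = net.build_graph(edges, 500)
        assert g.number_of_nodes() == 3 and g.number_of_edges() == 2

    def test_empty_after_filter_is_an_error(self):
        edges = edge_list(("P1", "P2", 499))
        with pytest.raises(ValueError, match="no edges"):
            net.build_graph(edges, 500)


class TestAnnotateGraph:
    @staticmethod
    def _de(records):
        return pd.DataFrame(records, columns=["gene", "log2fc", "padj"])

    def test_gene_stamps_all_its_proteins(self):
        g = net.build_graph(edge_list(("P1", "P2", 600), ("P2", "P3", 700)), 500)
        idmap = IDMap(pd.DataFrame({"gene": ["G1", "G1", "G2"],
                                    "protein": ["P1", "P2", "P3"]}))
        de = self._de([("G1", 2.0, 0.01), ("G2", 0.5, 0.5)])
        net.annotate_graph(g, idmap, de)
        assert g.nodes["P1"]["padj"] == 0.01
        assert g.nodes["P2"]["padj"] == 0.01
        assert g.nodes["P3"]["padj"] == 0.5

    def test_unmapped_protein_never_significant(self):
        g = net.build_graph(edge_list(("P1", "P9", 600)), 500)
        idmap = IDMap(pd.DataFrame({"gene": ["G1"], "protein": ["P1"]}))
        net.annotate_graph(g, idmap, self._de([("G1", 1.0, 0.01)]))
        assert np.isnan(g.nodes["P9"]["padj"])

    def test_conflicting_genes_resolved_by_smaller_padj(self):
        g = net.build_graph(edge_list(("P1", "P2", 600)), 500)
        idmap = IDMap(pd.DataFrame({"gene": ["G1", "G2", "G3"],
                                    "protein": ["P1", "P1", "P2"]}))
        de = self._de([("G1", 1.0, 0.04), ("G2", -2.0, 0.002), ("G3", 0.1, 0.9)])
        net.annotate_graph(g, idmap, de)
        assert g.nodes["P1"]["gene"] == "G2"
        assert g.nodes["P1"]["padj"] == 0.002


class TestShortestPaths:
    def test_five_node_worked_example(self, five_node_graph):
        paths = net.all_shortest_paths(five_node_graph, ["A", "E"])
        assert sorted(paths.paths) == [("A", "B", "C", "E"), ("A", "D", "C", "E")]
        retained = net.filter_paths(paths, five_node_graph, alpha=0.05)
        assert retained.paths == [("A", "D", "C", "E")]
        g = net.union_network(retained)
        assert set(g.edges) >= {("A", "D"), ("D", "C"), ("C", "E")} or \
            set(map(frozenset, g.edges)) == {frozenset(e) for e in
                                             [("A", "D"), ("D", "C"), ("C", "E")]}
        degrees = dict(g.degree())
        assert degrees == {"A": 1, "D": 2, "C": 2, "E": 1}

    def test_adjacent_endpoints_single_hop(self, five_node_graph):
        paths = net.all_shortest_paths(five_node_graph, ["A", "B"])
        assert paths.paths == [("A", "B")]

    def test_disconnected_endpoints_yield_nothing(self, five_node_graph):
        five_node_graph.add_node("Z")
        paths = net.all_shortest_paths(five_node_graph, ["A", "Z"])
        assert paths.paths == []

    def test_per_pair_cap_truncates_and_logs(self):
        # complete bipartite K(1,1) through 6 parallel intermediates:
        # 6 shortest paths S-x-T
        g = nx.Graph()
        for i in range(6):
            g.add_edge("S", f"m{i}")
            g.add_edge(f"m{i}", "T")
        capped = net.all_shortest_paths(g, ["S", "T"], max_paths_per_pair=4)
        assert len(capped.paths) == 4
        assert capped.truncated_pairs == 1
        full = net.all_shortest_paths(g, ["S", "T"], max_paths_per_pair=None)
        assert len(full.paths) == 6
        assert full.truncated_pairs == 0

    def test_alpha_monotonicity_grows_retained_set(self, five_node_graph):
        paths = net.all_shortest_paths(five_node_graph, ["A", "E"])
        small = net.filter_paths(paths, five_node_graph, alpha=0.02)
        mid = net.filter_paths(paths, five_node_graph, alpha=0.05)
        big = net.filter_paths(paths, five_node_graph, alpha=0.5)
        assert set(small.paths) <= set(mid.paths) <= set(big.paths)

    def test_alpha_zero_retains_nothing(self, five_node_graph):
        paths = net.all_shortest_paths(five_node_graph, ["A", "E"])
        assert net.filter_paths(paths, five_node_graph, alpha=0.0).paths == []


class TestUnionNetwork:
    def test_shared_edges_stored_once_and_handshake(self):
        paths = net.PathSet([("A", "B", "C"), ("D", "B", "C")])
        g = net.union_network(paths)
        assert g.number_of_edges() == 3
        assert sum(dict(g.degree()).values()) == 2 * g.number_of_edges()

    def test_empty_pathset_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            g = net.union_network(net.PathSet([]))
        assert g.number_of_nodes() == 0


class TestCallHubs:
    def test_nearest_rank_with_ties_included(self):
        g = nx.Graph()
        # build a graph with degree sequence (5,5,4,3,2,1,1,1,1,1)
        degrees = {"h1": 5, "h2": 5, "a": 4, "b": 3, "c": 2}
        g.add_edges_from(
            [("h1", "h2"), ("h1", "a"), ("h1", "b"), ("h1", "c"), ("h1", "l1"),
             ("h2", "a"), ("h2", "b"), ("h2", "l2"), ("h2", "l3"),
             ("a", "c"), ("a", "l4"), ("b", "l5")]
        )
        seq = sorted(dict(g.degree()).values(), reverse=True)
        assert seq == [5, 5, 4, 3, 2, 1, 1, 1, 1, 1]
        hubs = net.call_hubs(g, 90)
        called = set(hubs.loc[hubs["is_hub"], "node"])
        assert called == {"h1", "h2"}

    def test_hand_ranked_degree_multiset(self):
        # nearest-rank: ceil(0.9*10)=9th smallest of
        # (1,1,1,1,1,2,3,4,5,5) is 5 -> both degree-5 nodes are hubs
        class Fake:
            def __init__(self, degs):
                self._d = degs
            def degree(self):
                return list(self._d.items())
            def number_of_nodes(self):
                return len(self._d)
        degs = {f"n{i}": d for i, d in
                enumerate([5, 5, 4, 3, 2, 1, 1, 1, 1, 1])}
        hubs = net.call_hubs(Fake(degs), 90)
        assert list(hubs.loc[hubs["is_hub"], "degree"]) == [5, 5]

    def test_all_equal_degrees_everyone_is_a_hub(self):
        g = nx.cycle_graph(6)
        hubs = net.call_hubs(g, 90)
        assert hubs["is_hub"].all()

    def test_single_node_is_the_hub(self):
        g = nx.Graph()
        g.add_node("only")
        hubs = net.call_hubs(g, 90)
        assert hubs["is_hub"].tolist() == [True]


class TestHubComposition:
    def test_percentages_over_rbp_hubs(self, five_node_graph):
        hubs = pd.DataFrame(
            {"node": ["A", "E", "C"], "degree": [3, 3, 2],
             "is_hub": [True, True, True]}
        )
        comp = net.hub_composition(hubs, five_node_graph)
        m = comp.set_index("rbp_class")
        assert m.loc["mRBP", "count"] == 2
        assert m.loc["mRBP", "pct_of_rbp_hubs"] == pytest.approx(100.0)
        assert m.loc["non-RBP", "count"] == 1
        assert comp["count"].sum() == 3

    def test_no_rbp_hubs_warns(self, five_node_graph):
        hubs = pd.DataFrame({"node": ["C"], "degree": [2], "is_hub": [True]})
        with pytest.warns(UserWarning, match="no RBP hubs"):
            comp = net.hub_composition(hubs, five_node_graph)
        assert comp["count"].sum() == 1


class TestSplitHubsByExpression:
    @staticmethod
    def _expr(means, n_a=4, n_b=4, delta=0.0, noise=0.01):
        samples = make_sample_table({"A": n_a, "B": n_b})
        rows = []
        rng = np.random.default_rng(0)
        for m in means:
            a = m + rng.normal(0, noise, n_a) if noise else np.full(n_a, float(m))
            b = m + delta + (rng.normal(0, noise, n_b) if noise else 0.0)
            rows.append(np.concatenate([a, np.atleast_1d(b) * np.ones(n_b)]))
        genes = [f"g{i}" for i in range(len(means))]
        expr = pd.DataFrame(rows, index=genes, columns=samples["sample"])
        return expr, samples, genes

    def test_interquartile_split_on_linear_means(self):
        expr, samples, genes = self._expr([1, 2, 3, 4, 5, 6, 7, 8])
        out = net.split_hubs_by_expression(genes, expr, samples, ("A", "B"))
        grp = out.set_index("gene")["expression_group"]
        assert set(grp[grp == "low"].index) == {"g0", "g1"}
        assert set(grp[grp == "high"].index) == {"g6", "g7"}

    def test_equal_means_no_split(self):
        expr, samples, genes = self._expr([5, 5, 5, 5], noise=0.0)
        with pytest.warns(UserWarning, match="no low/high"):
            out = net.split_hubs_by_expression(genes, expr, samples, ("A", "B"))
        assert (out["expression_group"] == "none").all()

    def test_flagged_genes_satisfy_p_below_005(self):
        expr, samples, genes = self._expr([1, 2, 3, 4, 5, 6, 7, 8], delta=1.0)
        out = net.split_hubs_by_expression(genes, expr, samples, ("A", "B"))
        flagged = out[out["significant"]]
        assert len(flagged) > 0
        assert (flagged["pvalue"] < 0.05).all()


def exhaustive_oracle(graph, endpoints, alpha):
    """Enumerate-all-simple-paths oracle for the SP -> filter -> union chain.

    Keeps, per endpoint pair, the simple paths of minimum length (the
    pair's shortest-path distance in the full graph) whose nodes are all
    significant, and unions them into a network.
    """
    sig = {n for n, d in graph.nodes(data=True)
           if not np.isnan(d.get("padj", np.nan)) and d["padj"] <= alpha}
    g = nx.Graph()
    for u, v in itertools.combinations(sorted(endpoints), 2):
        if not nx.has_path(graph, u, v):
            continue
        d = nx.shortest_path_length(graph, u, v)
        for p in nx.all_simple_paths(graph, u, v, cutoff=d):
            if len(p) - 1 == d and all(n in sig for n in p):
                g.add_nodes_from(p)
                g.add_edges_from(zip(p, p[1:]))
    return g


class TestOracleEquivalence:
    def test_matches_exhaustive_simple_path_oracle(self, rng):
        """On random small graphs the BFS chain equals the brute-force
        enumeration: same nodes, edges and degrees."""
        mismatches = 0
        for trial in range(200):
            n = int(rng.integers(4, 13))
            g = nx.gnp_random_graph(n, 0.35, seed=int(rng.integers(2**31)))
            g = nx.relabel_nodes(g, {i: f"P{i}" for i in g.nodes})
            for node in g.nodes:
                g.nodes[node]["padj"] = (
                    float(rng.uniform(0, 0.05)) if rng.random() < 0.6
                    else float(rng.uniform(0.06, 1))
                )
            k = int(rng.integers(2, max(3, n // 2)))
            endpoints = list(rng.choice(sorted(g.nodes), size=k, replace=False))
            paths = net.all_shortest_paths(g, endpoints, max_paths_per_pair=None)
            retained = net.filter_paths(paths, g, 0.05)
            with np.errstate(all="ignore"):
                import warnings as _w
                with _w.catch_warnings():
                    _w.simplefilter("ignore")
                    mine = net.union_network(retained)
            ref = exhaustive_oracle(g, endpoints, 0.05)
            same = (
                set(mine.nodes) == set(ref.nodes)
                and {frozenset(e) for e in mine.edges}
                == {frozenset(e) for e in ref.edges}
                and dict(mine.degree()) == dict(ref.degree())
            )
            mismatches += not same
        assert mismatches == 0

    def test_union_is_subgraph_of_filtered_ppi(self, rng):
        for trial in range(20):
            n = 15
            g = nx.gnp_random_graph(n, 0.3, seed=trial)
            g = nx.relabel_nodes(g, {i: f"P{i}" for i in g.nodes})
            for node in g.nodes:
                g.nodes[node]["padj"] = float(rng.uniform(0, 0.2))
            endpoints = sorted(g.nodes)[:5]
            paths = net.all_shortest_paths(g, endpoints, None)
            retained = net.filter_paths(paths, g, 0.05)
            import warnings as _w
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                union = net.union_network(retained)
            assert set(union.nodes) <= set(g.nodes)
            assert all(g.has_edge(*e) for e in union.edges)


class TestModelSurface:
    def test_end_to_end_on_simulated_ppi(self):
        from rbpnet.dge import NBDifferentialExpression
        from rbpnet.simulate import (
            PlantedEffect,
            SimConfig,
            gene_names,
            simulate_counts,
            simulate_ppi,
        )

        genes = gene_names(400)
        de_set = tuple(genes[:80])
        cfg = SimConfig(
            n_genes=400, n_rbp=120, groups=(("HSC", 4), ("LSC", 4)),
            planted_de=(PlantedEffect(de_set, "HSC", "LSC", 3.0),),
            ppi_n_nodes=200, n_hubs=2, hub_min_degree=12, seed=21,
        )
        cm, samples, anno, truth = simulate_counts(cfg)
        edges, idmap, truth = simulate_ppi(cfg, list(de_set), truth)
        de = NBDifferentialExpression(cm, samples).fit(("HSC", "LSC"))
        spn = net.ShortestPathNetwork(edges, idmap, de.table, anno)
        res = spn.fit()
        # union network is a subgraph of the filtered PPI
        assert set(res.network.nodes) <= set(spn.graph.nodes)
        assert all(spn.graph.has_edge(*e) for e in res.network.edges)
        # raising alpha can only grow the retained path set
        res_loose = spn.fit(alpha=0.5)
        assert set(res.retained.paths) <= set(res_loose.retained.paths)
        # raising min_score can only shrink the graph
        strict = net.ShortestPathNetwork(edges, idmap, de.table, anno,
                                         min_score=800)
        assert strict.graph.number_of_edges() <= spn.graph.number_of_edges()
        assert "hubs" in res.summary()
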
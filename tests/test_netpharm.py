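"""ADME filtering, layered networks, centralities and the R-score ranking."""

import itertools

import networkx as nx
import numpy as np
import pytest

from vkmet import simdata
from vkmet.netpharm import (
    AdmeCompound,
    CentralityRow,
    LayeredNetwork,
    adme_filter,
    compound_target_network,
    expand_ppi,
    gene_metabolite_network,
    merge_tripartite,
    node_centralities,
    r_score,
    rank_targets,
)

# the 13 ids retained on literature evidence despite failing the ADME rule
LITERATURE_WHITELIST = {
    "GE05", "GE06", "GE07", "GE08", "GE12", "GE14", "GE15",
    "GE17", "GE18", "GE24", "GE25", "GE26", "GE27",
}


def centrality_oracle(g: nx.Graph):
    """Shortest-path counting oracle built from scratch (no networkx calls).

    Distances come from a hand-rolled BFS; the number of shortest s-t paths
    is counted recursively by descending the BFS distance field; a pair's
    betweenness contribution to an interior node v is
    count(s,v) * count(v,t) / count(s,t) whenever v lies on a shortest
    path, normalised by the component's (n-1)(n-2)/2 pair count.
    """
    adj = {n: set(g.neighbors(n)) for n in g}

    def bfs(s):
        dist = {s: 0}
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        return dist

    dist = {n: bfs(n) for n in g}

    from functools import lru_cache

    @lru_cache(maxsize=None)
    def n_shortest(s, t):
        if s == t:
            return 1
        return sum(n_shortest(u, t) for u in adj[s]
                   if t in dist[u] and dist[u][t] == dist[s][t] - 1)

    comps, seen = [], set()
    for n in g:
        if n not in seen:
            comp = set(dist[n])
            seen |= comp
            comps.append(comp)

    aspl, btw = {}, {n: 0.0 for n in g}
    for comp in comps:
        if len(comp) < 2:
            continue
        nodes = sorted(comp)
        for s, t in itertools.combinations(nodes, 2):
            total = n_shortest(s, t)
            for v in comp:
                if v in (s, t):
                    continue
                if dist[s].get(v, 99) + dist[v].get(t, 99) == dist[s][t]:
                    btw[v] += n_shortest(s, v) * n_shortest(v, t) / total
        for v in nodes:
            aspl[v] = float(np.mean([dist[v][u] for u in nodes if u != v]))
        if len(comp) > 2:
            norm = (len(comp) - 1) * (len(comp) - 2) / 2
            for v in nodes:
                btw[v] /= norm
    return aspl, btw


class TestAdmeFilter:
    def test_bundled_table_yields_eight_rule_passers(self):
        selected, report = adme_filter(simdata.table2_compounds())
        assert selected == {"GE10", "GE11", "GE13", "GE16", "GE20", "GE21",
                            "GE22", "GE26"}
        assert report["whitelist_only"] == []

    def test_union_with_literature_whitelist_is_twenty(self):
        selected, report = adme_filter(simdata.table2_compounds(),
                                       whitelist=LITERATURE_WHITELIST)
        assert len(selected) == 20
        assert report["overlap"] == ["GE26"]  # passes the rule AND whitelisted
        assert report["n_selected"] == 20

    def test_zero_thresholds_keep_all_compounds(self):
        selected, _ = adme_filter(simdata.table2_compounds(), ob_min=0, dl_min=0)
        assert len(selected) == 31

    def test_unknown_whitelist_id_named_in_error(self):
        with pytest.raises(ValueError, match="GE99"):
            adme_filter(simdata.table2_compounds(), whitelist={"GE99"})

    def test_negative_scores_rejected(self):
        with pytest.raises(ValueError):
            AdmeCompound("X", "x", -1.0, 0.5)


class TestLayeredNetworks:
    def test_two_metabolites_sharing_one_gene(self):
        net = gene_metabolite_network(["C1", "C2"], [("C1", "g1"), ("C2", "g1")])
        assert net.graph.number_of_nodes() == 3
        assert net.graph.number_of_edges() == 2

    def test_empty_associations_leave_metabolites_isolated(self):
        with pytest.warns(UserWarning):
            net = gene_metabolite_network(["C1", "C2"], [])
        assert net.graph.number_of_edges() == 0
        assert net.nodes_in_layer("metabolite") == {"C1", "C2"}

    def test_duplicate_association_rows_collapse_to_one_edge(self):
        net = gene_metabolite_network(["C1"], [("C1", "g1"), ("C1", "g1")])
        assert net.graph.number_of_edges() == 1

    def test_ppi_star_from_leaf_returns_leaf_hub_edge(self):
        star = [("HUB", f"L{i}") for i in range(5)]
        net = expand_ppi({"L0"}, star)
        assert set(net.graph.nodes) == {"L0", "HUB"}
        assert net.graph.number_of_edges() == 1

    def test_ppi_all_seeds_recover_whole_interactome(self):
        inter = simdata.generate_interactome(20, seed=1)
        net = expand_ppi(set(inter.nodes), inter.edges)
        assert net.graph.number_of_edges() == len(inter.edges)

    def test_ppi_neighbour_count_matches_adjacency_scan(self):
        inter = simdata.generate_interactome(40, seed=2)
        seeds = set(list(inter.seed_compound_targets)[:5])
        net = expand_ppi(seeds, inter.edges)
        expected = set(seeds)
        for a, b in inter.edges:
            if a in seeds:
                expected.add(b)
            if b in seeds:
                expected.add(a)
        assert set(net.graph.nodes) == {s.upper() for s in expected}

    def test_compound_target_union(self):
        net = compound_target_network(
            {"c1", "c2"}, [("c1", "A"), ("c1", "B"), ("c2", "B"), ("c2", "C")])
        assert net.nodes_in_layer("target") == {"A", "B", "C"}

    def test_compound_target_empty_compound_set(self):
        net = compound_target_network(set(), [("c1", "A")])
        assert net.graph.number_of_nodes() == 0

    def test_merge_intersection_and_edge_preservation(self):
        ct = compound_target_network({"c1"}, [("c1", "A"), ("c1", "B"), ("c1", "C")])
        ppi = expand_ppi({"B", "C", "D"}, [("B", "C"), ("C", "D"), ("D", "E")])
        with pytest.warns(UserWarning):
            gm = gene_metabolite_network(["M1"], [])
        merged, inter = merge_tripartite(ct, ppi, gm)
        assert inter == {"B", "C"}
        for net in (ct, ppi, gm):
            for e in net.graph.edges:
                assert merged.graph.has_edge(*e)

    def test_merge_disjoint_layers_has_empty_intersection(self):
        ct = compound_target_network({"c1"}, [("c1", "A")])
        ppi = expand_ppi({"X"}, [("X", "Y")])
        gm = gene_metabolite_network(["M1"], [("M1", "Z")])
        _, inter = merge_tripartite(ct, ppi, gm)
        assert inter == set()

    def test_conflicting_layer_tags_rejected(self):
        net = LayeredNetwork()
        net.add_node("A", "compound")
        with pytest.raises(ValueError, match="A"):
            net.add_node("A", "metabolite")


class TestCentralities:
    def test_path_graph_values(self):
        g = nx.path_graph(["A", "B", "C"])
        rows = {r.node_id: r for r in node_centralities(g)}
        assert rows["B"].aspl == pytest.approx(1.0)
        assert rows["A"].aspl == pytest.approx(1.5)
        assert rows["B"].betweenness == pytest.approx(1.0)
        assert rows["A"].betweenness == 0.0

    def test_complete_graph_values(self):
        rows = node_centralities(nx.complete_graph(4))
        for r in rows:
            assert r.aspl == pytest.approx(1.0)
            assert r.betweenness == 0.0

    def test_matches_exhaustive_oracle_on_random_graphs(self):
        rng = np.random.default_rng(42)
        for trial in range(50):
            n = int(rng.integers(4, 13))
            p = float(rng.uniform(0.25, 0.7))
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31)))
            g.remove_nodes_from([v for v in list(g) if g.degree(v) == 0])
            if g.number_of_nodes() < 3:
                continue
            rows = {r.node_id: r for r in node_centralities(g)}
            aspl, btw = centrality_oracle(g)
            for v in g:
                assert rows[str(v)].aspl == pytest.approx(aspl[v], abs=1e-9)
                assert rows[str(v)].betweenness == pytest.approx(btw[v], abs=1e-9)

    def test_isolated_node_excluded_with_warning(self):
        g = nx.path_graph(3)
        g.add_node(99)
        with pytest.warns(UserWarning):
            rows = node_centralities(g)
        assert "99" not in {r.node_id for r in rows}

    def test_tiny_graph_rejected(self):
        with pytest.raises(ValueError):
            node_centralities(nx.path_graph(2))


class TestRScore:
    def test_bundled_candidates_min_is_hsp90aa1_at_zero(self):
        scores = r_score(simdata.table3_rows())
        best = min(scores, key=lambda s: s.r)
        assert best.node_id == "HSP90AA1"
        assert best.r == pytest.approx(0.0, abs=1e-12)

    def test_bundled_candidates_sorted_scores_match_printed_column(self):
        printed = sorted(float(r) for r in simdata.load_fixture("table3")["r_printed"])
        recomputed = sorted(s.r for s in r_score(simdata.table3_rows()))
        np.testing.assert_allclose(recomputed, printed, atol=0.005)

    def test_extremes_of_the_unit_interval(self):
        rows = [CentralityRow("worst", 5.0, 0.01), CentralityRow("best", 1.0, 0.9),
                CentralityRow("mid", 3.0, 0.1)]
        scores = {s.node_id: s.r for s in r_score(rows)}
        assert scores["best"] == 0.0
        assert scores["worst"] == pytest.approx(1.0)
        assert 0.0 < scores["mid"] < 1.0

    def test_affine_and_scale_invariance(self):
        rows = simdata.table3_rows()
        base = [s.r for s in r_score(rows)]
        transformed = [CentralityRow(r.node_id, 3.0 * r.aspl + 2.0, 0.5 * r.betweenness)
                       for r in rows]
        np.testing.assert_allclose([s.r for s in r_score(transformed)], base, atol=1e-12)

    def test_zero_betweenness_candidates_excluded(self):
        rows = [CentralityRow("a", 1.0, 0.5), CentralityRow("b", 2.0, 0.1),
                CentralityRow("c", 3.0, 0.0)]
        with pytest.warns(UserWarning, match="c"):
            scores = r_score(rows)
        assert {s.node_id for s in scores} == {"a", "b"}

    def test_equal_aspl_zeroes_first_term(self):
        rows = [CentralityRow("a", 2.0, 0.5), CentralityRow("b", 2.0, 0.1)]
        scores = {s.node_id: s.r for s in r_score(rows)}
        assert scores["a"] == 0.0
        assert scores["b"] == pytest.approx(0.5)

    def test_scores_stay_in_unit_interval(self):
        rng = np.random.default_rng(5)
        rows = [CentralityRow(f"n{i}", float(rng.uniform(1, 5)),
                              float(rng.uniform(0.001, 0.5))) for i in range(30)]
        for s in r_score(rows):
            assert 0.0 <= s.r <= 1.0


class TestRankTargets:
    def test_bundled_candidates_rank_one_is_hsp90aa1(self):
        ranked = rank_targets(r_score(simdata.table3_rows()), top_k=6)
        assert ranked[0].node_id == "HSP90AA1"
        assert len(ranked) == 6

    def test_ties_break_lexicographically(self):
        scores = r_score([CentralityRow("b", 2.0, 0.5), CentralityRow("a", 2.0, 0.5),
                          CentralityRow("z", 4.0, 0.1)])
        ranked = rank_targets(scores)
        assert [s.node_id for s in ranked[:2]] == ["a", "b"]

    def test_top_k_beyond_candidates_warns_and_returns_all(self):
        scores = r_score(simdata.table3_rows())
        with pytest.warns(UserWarning):
            ranked = rank_targets(scores, top_k=99)
        assert len(ranked) == 12

    def test_planted_bridge_ranks_in_top_three(self):
        hits = 0
        for seed in range(20):
            inter = simdata.generate_interactome(60, 4.0, seed=seed)
            g = nx.Graph()
            g.add_edges_from(inter.edges)
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ranked = rank_targets(r_score(node_centralities(g)), top_k=3)
            hits += inter.planted_bridge in {s.node_id for s in ranked}
        assert hits >= 16  # >= 80% of instances
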
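import io
import itertools
import math

import pytest

from membranome.network import (
    build_graph,
    edge_node_ratio,
    extract_subnetwork,
    isolated_and_missing,
    merge,
    network_score,
    overlay_quant,
    read_edge_tsv,
    write_edge_tsv,
)
from membranome.quant import ProteinQuantRecord
from membranome.reporting import round1


class TestBuildGraph:
    def test_triangle(self):
        g = build_graph([("a", "b"), ("b", "c"), ("c", "a")])
        assert g.n_nodes == 3 and g.n_edges == 3
        assert edge_node_ratio(g) == 1.0

    def test_duplicate_edges_collapse(self):
        g = build_graph([("a", "b"), ("b", "a"), ("a", "b")])
        assert g.n_edges == 1

    def test_self_loop_dropped(self, caplog):
        with caplog.at_level("WARNING"):
            g = build_graph([("a", "a"), ("a", "b")])
        assert g.n_edges == 1
        assert "self-loop" in caplog.text

    def test_node_attributes_joined(self):
        g = build_graph(
            [("a", "b")],
            node_attributes={"a": {"molecule_class": "kinase"},
                             "c": {"molecule_class": "receptor"}},
        )
        assert g.graph.nodes["a"]["molecule_class"] == "kinase"
        assert "c" in g.graph  # attribute-only node becomes isolated
        assert g.degree("c") == 0

    def test_roundtrip_through_edge_tsv(self):
        g = build_graph([("a", "b", True, "net1"), ("b", "c", False, "net1")])
        buf = io.StringIO()
        write_edge_tsv(g, buf)
        reparsed = build_graph(read_edge_tsv(buf.getvalue()))
        assert reparsed.edges() == g.edges()
        assert reparsed.graph.edges["a", "b"]["directed"] is True


class TestMerge:
    def test_disjoint_graphs_sum(self):
        g1 = build_graph([("a", "b")])
        g2 = build_graph([("c", "d"), ("d", "e")])
        m = merge([g1, g2])
        assert m.n_nodes == 5 and m.n_edges == 3

    def test_idempotence(self):
        g = build_graph([("a", "b"), ("b", "c")])
        m = merge([g, g])
        assert m.nodes() == g.nodes()
        assert m.edges() == g.edges()

    def test_merged_edges_bounded_by_component_sum(self):
        import random

        rng = random.Random(3)
        graphs = []
        for _ in range(4):
            edges = {
                tuple(sorted(rng.sample(range(12), 2))) for _ in range(15)
            }
            graphs.append(build_graph([(f"n{u}", f"n{v}") for u, v in edges]))
        merged = merge(graphs)
        assert merged.n_edges <= sum(g.n_edges for g in graphs)

    def test_attribute_conflict_keeps_first(self, caplog):
        g1 = build_graph([("a", "b")], node_attributes={"a": {"molecule_class": "x"}})
        g2 = build_graph([("a", "c")], node_attributes={"a": {"molecule_class": "y"}})
        with caplog.at_level("WARNING"):
            m = merge([g1, g2])
        assert m.graph.nodes["a"]["molecule_class"] == "x"
        assert "conflict" in caplog.text

    def test_empty_list_is_error(self):
        with pytest.raises(ValueError):
            merge([])


class TestEdgeNodeRatio:
    def _graph_with(self, n_nodes: int, n_edges: int):
        import networkx as nx

        g = nx.gnm_random_graph(n_nodes, n_edges, seed=1)
        built = build_graph([(f"n{u}", f"n{v}") for u, v in g.edges()])
        # gnm may leave isolated nodes out of build_graph; add them back
        for i in range(n_nodes):
            if f"n{i}" not in built.graph:
                built.graph.add_node(f"n{i}")
        assert built.n_nodes == n_nodes and built.n_edges == n_edges
        return built

    def test_adhesion_network_counts_round_to_3_2(self):
        assert round1(edge_node_ratio(self._graph_with(121, 390))) == 3.2

    def test_global_interactome_counts_exceed_4(self):
        assert edge_node_ratio(self._graph_with(491, 2292)) > 4

    def test_tree_ratio_below_one(self):
        k = 9
        g = build_graph([(f"n{i}", f"n{i+1}") for i in range(k - 1)])
        assert edge_node_ratio(g) == (k - 1) / k < 1

    def test_empty_graph_is_error(self):
        from membranome.network import InteractionGraph

        with pytest.raises(ValueError):
            edge_node_ratio(InteractionGraph())


class TestIsolatedAndMissing:
    def test_fully_connected_inputs(self):
        g = build_graph([("a", "b"), ("b", "c"), ("a", "c")])
        res = isolated_and_missing(g, {"a", "b", "c"})
        assert res["isolated_count"] == 0 and res["missing_count"] == 0

    def test_missing_input(self):
        g = build_graph([("a", "b")])
        res = isolated_and_missing(g, {"a", "zzz"})
        assert res["missing_count"] == 1 and res["missing"] == ["zzz"]

    def test_planted_isolated_inputs(self):
        g = build_graph([("a", "b")])
        for lone in ("x1", "x2", "x3"):
            g.graph.add_node(lone)
        res = isolated_and_missing(g, {"a", "x1", "x2", "x3"})
        assert res["isolated_count"] == 3

    def test_empty_input_set_is_error(self):
        g = build_graph([("a", "b")])
        with pytest.raises(ValueError):
            isolated_and_missing(g, set())


class TestNetworkScore:
    def test_zero_focus_gives_zero_score(self):
        score = network_score(0, 30, 100, 1000)
        assert score.p_right == 1.0
        assert score.score == 0.0

    def test_monotone_in_focus_count(self):
        scores = [network_score(k, 30, 100, 1000).score for k in range(0, 31)]
        assert all(a <= b for a, b in zip(scores, scores[1:]))

    def test_small_universe_matches_bruteforce_fisher_tail(self):
        from test_enrichment import tail_oracle

        for focus, size, eligible, universe in [
            (3, 5, 10, 30), (0, 4, 6, 20), (5, 5, 5, 25), (2, 8, 4, 16),
        ]:
            score = network_score(focus, size, eligible, universe)
            assert score.p_right == pytest.approx(
                tail_oracle(focus, universe, eligible, size, "right"), rel=1e-12
            )

    def test_score_is_minus_log10_p(self):
        score = network_score(8, 10, 20, 200)
        assert score.score == pytest.approx(-math.log10(score.p_right))

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            network_score(10, 5, 20, 100)  # focus > network size


class TestOverlayQuant:
    def _records(self):
        return [
            ProteinQuantRecord(protein_id="enriched", ratio_PH=3.92),
            ProteinQuantRecord(protein_id="depleted", ratio_PH=0.5),
            ProteinQuantRecord(protein_id="membrane_only", ratio_PH=math.inf),
        ]

    def test_classes_and_intensity(self):
        g = build_graph([("enriched", "depleted"), ("depleted", "membrane_only"),
                         ("enriched", "unquantified")])
        overlay_quant(g, self._records())
        nodes = g.graph.nodes
        assert nodes["enriched"]["ratio_class"] == "enriched_red"
        assert nodes["enriched"]["intensity"] == pytest.approx(math.log2(3.92))
        assert nodes["depleted"]["ratio_class"] == "depleted_green"
        assert nodes["membrane_only"]["ratio_class"] == "enriched_red"
        assert nodes["membrane_only"]["intensity"] == math.inf
        assert nodes["unquantified"]["ratio_class"] == "absent_white"

    def test_doubling_ratios_flips_only_across_unity(self):
        records = [
            ProteinQuantRecord(protein_id="p_low", ratio_PH=0.3),
            ProteinQuantRecord(protein_id="p_mid", ratio_PH=0.8),
        ]
        g = build_graph([("p_low", "p_mid")])
        overlay_quant(g, records)
        before = {n: g.graph.nodes[n]["ratio_class"] for n in g.graph.nodes}
        doubled = [
            ProteinQuantRecord(protein_id=r.protein_id, ratio_PH=r.ratio_PH * 2)
            for r in records
        ]
        overlay_quant(g, doubled)
        after = {n: g.graph.nodes[n]["ratio_class"] for n in g.graph.nodes}
        assert before["p_low"] == after["p_low"] == "depleted_green"  # 0.6 still < 1
        assert before["p_mid"] == "depleted_green"
        assert after["p_mid"] == "enriched_red"  # 1.6 crossed unity


class TestExtractSubnetwork:
    def _labeled_graph(self):
        edges = [("a", "b"), ("b", "c"), ("c", "d"), ("d", "e"), ("a", "e"),
                 ("f", "g"), ("g", "h"), ("h", "i"), ("i", "j"), ("b", "f")]
        labels = {n: {"function_labels": ("adhesion",)} for n in "abcde"}
        labels |= {n: {"function_labels": ("transport",)} for n in "fghij"}
        return build_graph(edges, node_attributes=labels)

    def test_induced_subgraph_on_label(self):
        g = self._labeled_graph()
        sub = extract_subnetwork(g, function_label="adhesion")
        assert sub.nodes() == ["a", "b", "c", "d", "e"]
        # only direct interactions between retained nodes survive
        assert ("b", "f") not in sub.edges()

    def test_induced_edges_match_bruteforce_filter(self):
        g = self._labeled_graph()
        keep = {"a", "b", "c", "f"}
        sub = extract_subnetwork(g, node_list=keep)
        brute = sorted(
            tuple(sorted(e)) for e in g.edges() if e[0] in keep and e[1] in keep
        )
        assert sub.edges() == brute

    def test_augmentation_node_appears_isolated(self):
        g = self._labeled_graph()
        sub = extract_subnetwork(g, function_label="adhesion", augment=["ANX_EXTRA"])
        assert "ANX_EXTRA" in sub.graph
        assert sub.degree("ANX_EXTRA") == 0

    def test_no_match_is_error(self):
        g = self._labeled_graph()
        with pytest.raises(ValueError, match="no nodes match"):
            extract_subnetwork(g, function_label="nonexistent")


class TestComponentOracle:
    def test_connected_components_match_union_find(self):
        import random

        import networkx as nx

        rng = random.Random(11)
        edges = {tuple(sorted(rng.sample(range(20), 2))) for _ in range(18)}
        g = build_graph([(f"n{u}", f"n{v}") for u, v in edges])

        # brute-force union-find
        parent = {n: n for n in g.nodes()}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for u, v in g.edges():
            parent[find(u)] = find(v)
        brute = len({find(n) for n in g.nodes()})
        assert nx.number_connected_components(g.graph) == brute
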
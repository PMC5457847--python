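"""Risk genes, triples, network assembly and topology metrics."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import riskmir as rm
from riskmir import network


def triples_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["mirna", "gene", "pathway", "mirna_direction", "gene_direction", "concordance"],
    )


class TestRiskGenes:
    def test_exact_intersection(self):
        table = network.identify_risk_genes({"a", "b", "c"}, {"b": 1, "c": -1, "d": 1})
        assert list(table["gene"]) == ["b", "c"]
        assert list(table["direction"]) == ["up", "down"]

    def test_disjoint_inputs_give_empty_set(self):
        assert len(network.identify_risk_genes({"a"}, {"b": 1})) == 0

    def test_member_pathways_annotated(self):
        table = network.identify_risk_genes(
            {"a"}, {"a": 1}, {"P1": frozenset({"a", "x"}), "P2": frozenset({"y"})}
        )
        assert table["pathways"].iloc[0] == "P1"


class TestTriples:
    def _inputs(self):
        targets = rm.TargetMap(frozenset([("m1", "g1"), ("m1", "g2"), ("m2", "g1")]))
        pathways = rm.GeneSetCollection(
            {"A": frozenset({"g1", "g3"}), "B": frozenset({"g2"}), "C": frozenset({"g9"})}
        )
        risk_genes = network.identify_risk_genes({"g1", "g2"}, {"g1": -1, "g2": 1})
        return targets, pathways, risk_genes

    def test_concordance_labels(self):
        targets, pathways, risk_genes = self._inputs()
        triples = network.build_triples({"m1": 1}, risk_genes, ["A", "B"], targets, pathways)
        got = {(r.gene, r.concordance) for r in triples.itertuples()}
        assert got == {("g1", "opposite"), ("g2", "same")}

    def test_gene_outside_risk_pathways_excluded(self):
        targets, pathways, risk_genes = self._inputs()
        triples = network.build_triples({"m1": 1}, risk_genes, ["A"], targets, pathways)
        assert set(triples["gene"]) == {"g1"}

    def test_non_target_pairs_excluded(self):
        targets, pathways, risk_genes = self._inputs()
        triples = network.build_triples({"m2": 1}, risk_genes, ["A", "B"], targets, pathways)
        assert set(triples["gene"]) == {"g1"}


class TestNetworkBuild:
    def test_ppi_restricted_to_risk_genes_in_triples(self):
        triples = triples_frame([("m1", "g1", "A", "up", "down", "opposite")])
        ppi = rm.PpiNetwork(frozenset([("g1", "h1")]))
        net = network.build_network(triples, ppi)
        assert net.number_of_nodes() == 3 and net.number_of_edges() == 2
        assert all(d["edge_type"] in ("targets", "member_of") for _, _, d in net.edges(data=True))

    def test_empty_triples_give_empty_network(self):
        net = network.build_network(triples_frame([]), rm.PpiNetwork(frozenset([("a", "b")])))
        assert net.number_of_nodes() == 0

    def test_ppi_edge_between_two_triple_genes_included(self):
        triples = triples_frame(
            [
                ("m1", "g1", "A", "up", "down", "opposite"),
                ("m1", "g2", "A", "up", "up", "same"),
            ]
        )
        net = network.build_network(triples, rm.PpiNetwork(frozenset([("g1", "g2")])))
        assert net.edges["g1", "g2"]["edge_type"] == "ppi"

    def test_degree_sum_is_twice_edge_count(self):
        rng = np.random.default_rng(0)
        rows = [
            (f"m{rng.integers(3)}", f"g{rng.integers(6)}", f"P{rng.integers(2)}", "up", "down", "opposite")
            for _ in range(20)
        ]
        net = network.build_network(triples_frame(rows).drop_duplicates(), None)
        assert sum(d for _, d in net.degree) == 2 * net.number_of_edges()


class TestTopology:
    def test_triangle_hand_values(self):
        g = nx.complete_graph(3)
        table = network.node_topology(g).set_index("node")
        assert np.allclose(table["clustering"], 1.0)
        assert np.allclose(table["topological_coefficient"], 1.0)
        assert np.allclose(table["betweenness"], 0.0)
        assert np.allclose(table["avg_shortest_path"], 1.0)

    def test_path_graph_hand_values(self):
        g = nx.path_graph(["A", "B", "C"])
        table = network.node_topology(g).set_index("node")
        assert table.loc["B", "betweenness"] == pytest.approx(1.0)
        assert table.loc["B", "closeness"] == pytest.approx(1.0)
        assert table.loc["A", "closeness"] == pytest.approx(2 / 3)
        assert table.loc["B", "topological_coefficient"] == 0.0

    def test_empty_graph_gives_empty_table(self):
        assert len(network.node_topology(nx.Graph())) == 0

    def test_isolated_component_metrics_are_componentwise(self):
        g = nx.Graph([("a", "b")])
        g.add_node("solo")
        table = network.node_topology(g).set_index("node")
        assert table.loc["solo", "closeness"] == 0.0
        assert table.loc["a", "closeness"] == pytest.approx(1.0)
        assert table.loc["solo", "avg_shortest_path"] == 0.0


class TestHubsAndConcordance:
    def test_hub_ties_broken_by_betweenness_then_id(self):
        table = pd.DataFrame(
            {
                "node": ["a", "b", "c", "d"],
                "degree": [3, 3, 3, 1],
                "betweenness": [1.0, 2.0, 1.0, 9.0],
            }
        )
        assert network.hub_nodes(table, k=3) == ["b", "a", "c"]

    def test_concordance_counts_unique_pairs(self):
        rows = [
            ("m", "g", "A", "up", "down", "opposite"),
            ("m", "g", "B", "up", "down", "opposite"),  # same pair, second pathway
            ("m", "h", "A", "up", "up", "same"),
        ]
        assert network.classify_concordance(triples_frame(rows)) == (1, 1)

    def test_empty_triples_count_zero(self):
        assert network.classify_concordance(triples_frame([])) == (0, 0)
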
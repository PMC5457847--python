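"""Risk genes, miRNA-gene-pathway triples, the tripartite regulatory
network with PPI overlay, and node-topology metrics.

Risk genes are the intersection of the GSEA core (leading-edge) genes of
the risk pathways with the differentially expressed genes.  A *triple*
(miRNA, gene, pathway) requires the miRNA to be differentially expressed
and a validated regulator of the gene, the gene to be a risk gene and a
member of the pathway, and the pathway to be a risk pathway; the pair is
*opposite* when miRNA and gene change in opposite directions (the
canonically repressive pattern) and *same* otherwise.

Topology metrics follow the Cytoscape NetworkAnalyzer conventions the
field's network tables report: unnormalized betweenness (each unordered
pair counted once), component-wise closeness (n_reachable - 1) / sum(d),
local clustering, per-node average shortest path length over reachable
nodes, and the topological coefficient

    TC_v = mean over partners u of (shared_neighbors(v, u) + [u ~ v]) / deg(v)

where partners are the nodes (u != v) sharing at least one neighbor with v;
TC is 0 for degree < 2.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .io import GeneSetCollection, PpiNetwork, TargetMap

logger = logging.getLogger(__name__)

_DIR_NAME = {1: "up", -1: "down"}


def identify_risk_genes(
    core: Iterable[str],
    deg_directions: Mapping[str, int],
    risk_pathway_sets: Mapping[str, frozenset[str]] | None = None,
) -> pd.DataFrame:
    """Risk genes = core (leading-edge) genes of risk pathways ∩ DEGs.

    Returns a table with the gene's direction and (when the risk pathway
    sets are supplied) the risk pathways it belongs to.
    """
    core = frozenset(core)
    risk = sorted(core & set(deg_directions))
    if not risk:
        logger.warning("risk-gene set is empty (core genes and DEGs are disjoint)")
    rows = []
    for g in risk:
        pathways = sorted(
            name for name, members in (risk_pathway_sets or {}).items() if g in members
        )
        rows.append(
            {
                "gene": g,
                "direction": _DIR_NAME[int(np.sign(deg_directions[g]))],
                "is_core": True,
                "is_de": True,
                "pathways": ";".join(pathways),
            }
        )
    return pd.DataFrame(rows, columns=["gene", "direction", "is_core", "is_de", "pathways"])


def build_triples(
    demir_directions: Mapping[str, int],
    risk_genes: pd.DataFrame,
    risk_pathways: Iterable[str],
    targets: TargetMap,
    pathways: GeneSetCollection,
) -> pd.DataFrame:
    """All (DEmiR, risk gene, risk pathway) relationships, with concordance."""
    risk_dir = {row.gene: row.direction for row in risk_genes.itertuples()}
    risk_names = sorted(set(risk_pathways))
    by_mirna = targets.by_mirna()
    rows = []
    for mirna in sorted(demir_directions):
        m_dir = _DIR_NAME[int(np.sign(demir_directions[mirna]))]
        hit_genes = by_mirna.get(mirna, frozenset()) & set(risk_dir)
        for gene in sorted(hit_genes):
            for name in risk_names:
                if gene in pathways[name]:
                    rows.append(
                        {
                            "mirna": mirna,
                            "gene": gene,
                            "pathway": name,
                            "mirna_direction": m_dir,
                            "gene_direction": risk_dir[gene],
                            "concordance": "opposite" if m_dir != risk_dir[gene] else "same",
                        }
                    )
    return pd.DataFrame(
        rows,
        columns=["mirna", "gene", "pathway", "mirna_direction", "gene_direction", "concordance"],
    )


def build_network(triples: pd.DataFrame, ppi: PpiNetwork | None = None) -> nx.Graph:
    """Tripartite miRNA/gene/pathway network with a PPI overlay.

    Node attributes: ``node_type`` (miRNA | gene | pathway) and
    ``direction``; edge attribute ``edge_type`` (targets | member_of | ppi).
    PPI edges are added only where both endpoints are risk genes appearing
    in at least one triple.
    """
    g = nx.Graph()
    for row in triples.itertuples():
        g.add_node(row.mirna, node_type="miRNA", direction=row.mirna_direction)
        g.add_node(row.gene, node_type="gene", direction=row.gene_direction)
        g.add_node(row.pathway, node_type="pathway", direction="")
        g.add_edge(row.mirna, row.gene, edge_type="targets")
        g.add_edge(row.gene, row.pathway, edge_type="member_of")
    if ppi is not None and len(triples):
        genes_in_triples = set(triples["gene"])
        for a, b in ppi.subgraph_edges(genes_in_triples):
            if not g.has_edge(a, b):
                g.add_edge(a, b, edge_type="ppi")
    return g


def topological_coefficient(g: nx.Graph, node) -> float:
    """Neighborhood-sharing coefficient; 0 for nodes of degree < 2."""
    nbrs = set(g[node])
    k = len(nbrs)
    if k < 2:
        return 0.0
    partners: set = set()
    for w in nbrs:
        partners |= set(g[w])
    partners.discard(node)
    if not partners:
        return 0.0
    total = 0.0
    for u in partners:
        shared = len(nbrs & set(g[u]))
        total += (shared + (1 if u in nbrs else 0)) / k
    return total / len(partners)


def node_topology(net: nx.Graph | PpiNetwork, nodes: Iterable | None = None) -> pd.DataFrame:
    """Six per-node metrics, ranked by degree (ties by node id).

    The graph is treated as one undirected simple graph; heterogeneous node
    types are ignored for the metric computation.
    """
    g = net.to_networkx() if isinstance(net, PpiNetwork) else net
    if g.number_of_nodes() == 0:
        return pd.DataFrame(
            columns=["node", "node_type", "degree", "betweenness", "closeness",
                     "clustering", "avg_shortest_path", "topological_coefficient"]
        )
    betweenness = nx.betweenness_centrality(g, normalized=False)
    closeness = nx.closeness_centrality(g, wf_improved=False)
    clustering = nx.clustering(g)

    wanted = set(g.nodes) if nodes is None else set(nodes) & set(g.nodes)
    rows = []
    for v in wanted:
        lengths = nx.single_source_shortest_path_length(g, v)
        dists = [d for u, d in lengths.items() if u != v]
        rows.append(
            {
                "node": v,
                "node_type": g.nodes[v].get("node_type", ""),
                "degree": g.degree(v),
                "betweenness": betweenness[v],
                "closeness": closeness[v],
                "clustering": clustering[v],
                "avg_shortest_path": float(np.mean(dists)) if dists else 0.0,
                "topological_coefficient": topological_coefficient(g, v),
            }
        )
    table = pd.DataFrame(rows)
    table = table.sort_values(["degree", "node"], ascending=[False, True], kind="stable")
    return table.reset_index(drop=True)


def hub_nodes(topology: pd.DataFrame, k: int = 3) -> list[str]:
    """Top-k nodes by degree; ties broken by betweenness, then node id."""
    if len(topology) == 0:
        return []
    ranked = topology.sort_values(
        ["degree", "betweenness", "node"], ascending=[False, False, True], kind="stable"
    )
    return list(ranked["node"].head(k))


def classify_concordance(triples: pd.DataFrame) -> tuple[int, int]:
    """(n_opposite, n_same) over unique (miRNA, gene) pairs."""
    if len(triples) == 0:
        return 0, 0
    pairs = triples.drop_duplicates(subset=["mirna", "gene"])
    n_opposite = int((pairs["concordance"] == "opposite").sum())
    n_same = int((pairs["concordance"] == "same").sum())
    return n_opposite, n_same
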
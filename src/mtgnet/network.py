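"""Typed miRNA-TF-gene network and confidence-filtered PPI assembly.

The M-T-G network is a directed graph over miRNA/TF/gene nodes with four
edge classes (miRNA-gene, miRNA-TF, TF-gene, TF-miRNA); a node appearing
both as TF and as gene target is typed TF (TF > gene precedence). The PPI
network is an undirected confidence-weighted graph thresholded at 0.7
(edges scoring under the threshold removed, boundary kept).
"""
from __future__ import annotations

import networkx as nx
import pandas as pd

from .pairs import PAIR_CLASSES, RegulatoryPair

__all__ = ["build_mtg", "build_ppi", "network_summary", "node_kinds", "mtg_to_simple"]

_KIND_PRECEDENCE = {"TF": 2, "gene": 1}


def build_mtg(pairs: list[RegulatoryPair]) -> nx.MultiDiGraph:
    """Assemble the typed directed M-T-G network from regulatory pairs.

    Nodes carry a ``kind`` attribute in {miRNA, TF, gene}; parallel edges
    between the same endpoints are allowed only when their ``edge_class``
    differs (edge key = class). Duplicate pairs merge, accumulating
    provenance.
    """
    g = nx.MultiDiGraph()
    kinds: dict[str, str] = {}

    def assign(node: str, kind: str) -> None:
        prev = kinds.get(node)
        if prev is None or prev == kind:
            kinds[node] = kind
            return
        if {prev, kind} == {"TF", "gene"}:
            kinds[node] = "TF"  # a DETF is simultaneously a DEG; type it TF
            return
        raise ValueError(f"conflicting kinds for node {node!r}: {prev} vs {kind}")

    for p in pairs:
        assign(p.regulator_id, p.regulator_kind)
        assign(p.target_id, p.target_kind)

    for p in pairs:
        u, v, cls = p.regulator_id, p.target_id, p.pair_class
        if g.has_edge(u, v, key=cls):
            prov = g.edges[u, v, cls]["provenance"] | p.provenance
            g.edges[u, v, cls]["provenance"] = prov
        else:
            g.add_edge(u, v, key=cls, edge_class=cls, provenance=frozenset(p.provenance))

    nx.set_node_attributes(g, kinds, "kind")
    return g


def mtg_to_simple(g: nx.MultiDiGraph) -> nx.DiGraph:
    """Collapse parallel class edges to a simple digraph (for metrics and
    motif tests that care only about who regulates whom)."""
    simple = nx.DiGraph()
    simple.add_nodes_from(g.nodes(data=True))
    for u, v in g.edges():
        simple.add_edge(u, v)
    return simple


def node_kinds(g: nx.Graph) -> dict[str, str]:
    return dict(g.nodes(data="kind"))


def build_ppi(edge_table: pd.DataFrame, confidence_min: float = 0.7) -> nx.Graph:
    """Undirected PPI network keeping edges with confidence >= threshold.

    Edges scored under ``confidence_min`` are removed (the boundary is
    kept); nodes left without any surviving edge are dropped.
    """
    required = {"gene_a", "gene_b", "confidence"}
    missing = required - set(edge_table.columns)
    if missing:
        raise ValueError(f"PPI table missing columns: {sorted(missing)}")
    conf = edge_table["confidence"].astype(float)
    if ((conf < 0) | (conf > 1)).any():
        bad = edge_table.loc[(conf < 0) | (conf > 1)].iloc[0]
        raise ValueError(
            f"confidence outside [0, 1]: {bad['gene_a']}-{bad['gene_b']} = {bad['confidence']}"
        )
    g = nx.Graph()
    for a, b, c in edge_table[["gene_a", "gene_b", "confidence"]].itertuples(index=False):
        if a == b:
            raise ValueError(f"self-interaction not allowed: {a}")
        c = float(c)
        if c < confidence_min:
            continue
        if g.has_edge(a, b):
            g.edges[a, b]["confidence"] = max(g.edges[a, b]["confidence"], c)
        else:
            g.add_edge(a, b, confidence=c)
    return g


def network_summary(network: nx.Graph) -> dict:
    """Node counts by kind and edge counts by class (PPI: plain totals)."""
    if network.is_directed():
        kind_counts: dict[str, int] = {}
        for _, kind in network.nodes(data="kind"):
            kind_counts[kind] = kind_counts.get(kind, 0) + 1
        class_counts = {cls: 0 for cls in PAIR_CLASSES}
        for _, _, cls in network.edges(data="edge_class"):
            class_counts[cls] = class_counts.get(cls, 0) + 1
        return {
            "n_nodes": network.number_of_nodes(),
            "n_edges": network.number_of_edges(),
            "nodes_by_kind": kind_counts,
            "edges_by_class": class_counts,
        }
    return {
        "n_nodes": network.number_of_nodes(),
        "n_edges": network.number_of_edges(),
    }
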
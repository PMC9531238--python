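"""Topological node metrics, composite Z-scores, and key-node selection.

Directed metrics follow hub-screening conventions: betweenness counts
shortest directed paths through a node (Brandes, unnormalized), closeness
is harmonic (well-defined on disconnected graphs), neighborhood
connectivity is the mean total degree of a node's in/out neighbors. On the
undirected PPI, MCC (maximal clique centrality, sum over maximal cliques
containing the node of (|clique|-1)!) and MNC (size of the largest
connected component of the open neighborhood) are computed exactly via
Bron-Kerbosch clique enumeration.

Composite Z-scores standardize each metric within node kind using the
population SD, orient average shortest path length so that smaller is more
central, and average the available per-metric z values.
"""
from __future__ import annotations

import logging
import math

import networkx as nx
import numpy as np
import pandas as pd

from .network import mtg_to_simple

__all__ = [
    "node_metrics",
    "clique_metrics",
    "composite_zscore",
    "select_key_nodes",
    "select_key_genes",
    "DIRECTED_METRICS",
    "PPI_METRICS",
    "DEFAULT_ORIENTATION",
]

logger = logging.getLogger(__name__)

DIRECTED_METRICS = (
    "degree",
    "outdegree",
    "closeness",
    "betweenness",
    "average_shortest_path_length",
    "neighborhood_connectivity",
)
PPI_METRICS = ("MCC", "MNC", "degree", "betweenness", "closeness")

# larger is more central for every metric except path length
DEFAULT_ORIENTATION = {"average_shortest_path_length": -1.0}

_MCC_NODE_LIMIT = 5000


def node_metrics(network: nx.DiGraph) -> pd.DataFrame:
    """Directed topological metrics per node of the M-T-G network.

    Returns a DataFrame indexed by node id with a ``kind`` column and one
    column per metric. ``average_shortest_path_length`` is NaN for nodes
    that reach no other node.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("network is empty")
    g = mtg_to_simple(network) if network.is_multigraph() else network
    betweenness = nx.betweenness_centrality(g, normalized=False)
    rows = {}
    degrees = dict(g.degree())
    for v in g.nodes():
        dists = nx.single_source_shortest_path_length(g, v)
        del dists[v]
        closeness = sum(1.0 / d for d in dists.values())
        aspl = float(np.mean(list(dists.values()))) if dists else np.nan
        neigh = set(g.predecessors(v)) | set(g.successors(v))
        nc = float(np.mean([degrees[u] for u in neigh])) if neigh else 0.0
        rows[v] = {
            "kind": g.nodes[v].get("kind"),
            "degree": g.in_degree(v) + g.out_degree(v),
            "outdegree": g.out_degree(v),
            "closeness": closeness,
            "betweenness": betweenness[v],
            "average_shortest_path_length": aspl,
            "neighborhood_connectivity": nc,
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "node_id"
    return df.sort_index()


def clique_metrics(ppi: nx.Graph) -> pd.DataFrame:
    """MCC and MNC per node of an undirected simple graph.

    MCC(v) = sum over maximal cliques C containing v (|C| >= 2) of
    (|C|-1)!; an isolated node scores 0, and a node whose neighborhood has
    no internal edges scores its degree. MNC(v) is the size of the largest
    connected component of the subgraph induced on N(v), v excluded.
    """
    n = ppi.number_of_nodes()
    if n > _MCC_NODE_LIMIT:
        raise ValueError(f"exact MCC enumeration is limited to {_MCC_NODE_LIMIT} nodes (got {n})")
    mcc = {v: 0 for v in ppi.nodes()}
    for clique in nx.find_cliques(ppi):
        if len(clique) < 2:
            continue
        w = math.factorial(len(clique) - 1)
        for v in clique:
            mcc[v] += w
    mnc = {}
    for v in ppi.nodes():
        neigh = list(ppi.neighbors(v))
        if not neigh:
            mnc[v] = 0
            continue
        sub = ppi.subgraph(neigh)
        mnc[v] = max(len(c) for c in nx.connected_components(sub))
    df = pd.DataFrame({"MCC": pd.Series(mcc), "MNC": pd.Series(mnc)})
    df.index.name = "node_id"
    return df.sort_index()


def ppi_metrics(ppi: nx.Graph) -> pd.DataFrame:
    """The five hub-screening metrics on the PPI: MCC, MNC, degree,
    unnormalized betweenness, harmonic closeness."""
    df = clique_metrics(ppi)
    betweenness = nx.betweenness_centrality(ppi, normalized=False)
    degree = dict(ppi.degree())
    closeness = {}
    for v in ppi.nodes():
        dists = nx.single_source_shortest_path_length(ppi, v)
        del dists[v]
        closeness[v] = sum(1.0 / d for d in dists.values())
    df["degree"] = pd.Series(degree)
    df["betweenness"] = pd.Series(betweenness)
    df["closeness"] = pd.Series(closeness)
    return df


def composite_zscore(
    metrics: pd.DataFrame,
    orientation: dict[str, float] | None = None,
    metric_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Standardize metrics within node kind and average into a composite Z.

    Each metric column x is oriented (multiplied by the orientation sign,
    default +1; average shortest path length defaults to -1 because smaller
    is more central) then standardized as (x - mean) / SD with the
    population SD over the nodes of the same kind carrying a value; SD = 0
    gives z = 0. The composite is the mean of the per-metric z values
    present for the node. Requires >= 2 nodes per scored kind.
    """
    orient = dict(DEFAULT_ORIENTATION)
    if orientation:
        orient.update(orientation)
    if metric_columns is None:
        metric_columns = [c for c in metrics.columns if c != "kind"]
    kinds = metrics["kind"] if "kind" in metrics.columns else pd.Series("all", index=metrics.index)
    for kind, idx in metrics.groupby(kinds).groups.items():
        if len(idx) < 2:
            raise ValueError(f"composite z-score needs >= 2 nodes of kind {kind!r}")
    out = pd.DataFrame(index=metrics.index)
    out["kind"] = kinds
    zcols = []
    for col in metric_columns:
        z = pd.Series(np.nan, index=metrics.index, dtype=float)
        for kind, idx in metrics.groupby(kinds).groups.items():
            vals = metrics.loc[idx, col].astype(float) * orient.get(col, 1.0)
            present = vals.dropna()
            if len(present) < 2:
                continue  # metric absent for this kind; contributes nothing
            sd = float(present.std(ddof=0))
            if sd == 0.0:
                z.loc[present.index] = 0.0
            else:
                z.loc[present.index] = (present - present.mean()) / sd
        out[f"z_{col}"] = z
        zcols.append(f"z_{col}")
    out["composite_z"] = out[zcols].mean(axis=1)
    return out


def _top_k(scores: pd.DataFrame, k: int, by: str, ascending: bool) -> list[str]:
    ordered = scores.sort_values(
        by=[by, "node_id"], ascending=[ascending, True]
    )
    return list(ordered["node_id"].head(k))


def select_key_nodes(
    scores: pd.DataFrame, k_tf: int = 10, k_mirna: int = 5
) -> tuple[list[str], list[str]]:
    """Top-k TFs and miRNAs by composite Z (ties broken by node id)."""
    df = scores.reset_index().rename(columns={scores.index.name or "index": "node_id"})
    out = []
    for kind, k in (("TF", k_tf), ("miRNA", k_mirna)):
        pool = df[df["kind"] == kind]
        if k > len(pool):
            logger.warning("requested top-%d %s nodes but only %d available", k, kind, len(pool))
        out.append(_top_k(pool, k, by="composite_z", ascending=False))
    return out[0], out[1]


def select_key_genes(ppi_metrics_table: pd.DataFrame, k: int = 7) -> list[str]:
    """Top-k PPI hub genes by mean rank over MCC, MNC, degree, betweenness
    and closeness (rank 1 = best; ties averaged within a metric, then
    broken by gene id)."""
    missing = set(PPI_METRICS) - set(ppi_metrics_table.columns)
    if missing:
        raise ValueError(f"PPI metric table missing columns: {sorted(missing)}")
    ranks = pd.DataFrame(index=ppi_metrics_table.index)
    for col in PPI_METRICS:
        ranks[col] = ppi_metrics_table[col].rank(ascending=False, method="average")
    mean_rank = ranks.mean(axis=1)
    df = pd.DataFrame({"node_id": ppi_metrics_table.index, "mean_rank": mean_rank.values})
    if k > len(df):
        logger.warning("requested top-%d genes but only %d available", k, len(df))
    return _top_k(df, k, by="mean_rank", ascending=True)
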
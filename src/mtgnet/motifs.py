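"""Three-node feed-forward-loop and composite-loop enumeration.

Motifs over typed (miRNA m, TF t, gene g) triples of the M-T-G network:

- miRNA-FFL (miRNA-dominated): m->t, m->g, t->g
- TF-FFL (TF-dominated):       t->m, m->g, t->g
- composite:                   m<->t plus m->g and t->g

A triple meeting the composite condition is reported as composite only
(composite takes precedence over both FFL readings). Edge direction is
what matters; edge class and repression/activation sign are ignored.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import networkx as nx

from .network import mtg_to_simple

__all__ = ["MotifInstance", "enumerate_motifs", "node_occurrences", "extract_key_subgraph"]

_KIND_ORDER = {"miRNA-FFL": 0, "TF-FFL": 1, "composite": 2}


@dataclass(frozen=True)
class MotifInstance:
    kind: str
    mirna_id: str
    tf_id: str
    gene_id: str

    @property
    def nodes(self) -> tuple[str, str, str]:
        return (self.mirna_id, self.tf_id, self.gene_id)


def enumerate_motifs(
    network: nx.DiGraph, composite_requires_both_gene_edges: bool = True
) -> list[MotifInstance]:
    """Exhaustively enumerate motif instances over kind-consistent triples.

    With ``composite_requires_both_gene_edges=False`` the composite
    condition relaxes to the bare mutual m<->t pair plus at least one of
    the two gene-directed edges.

    Output order is deterministic: by kind (miRNA-FFL, TF-FFL, composite)
    then by (miRNA, TF, gene) ids.
    """
    g = mtg_to_simple(network) if network.is_multigraph() else network
    kinds = dict(g.nodes(data="kind"))
    mirnas = sorted(v for v, k in kinds.items() if k == "miRNA")
    tfs = sorted(v for v, k in kinds.items() if k == "TF")
    genes = sorted(v for v, k in kinds.items() if k == "gene")

    out: list[MotifInstance] = []
    for m in mirnas:
        m_succ = set(g.successors(m))
        for t in tfs:
            m_to_t = t in m_succ
            t_to_m = g.has_edge(t, m)
            if not (m_to_t or t_to_m):
                continue
            t_succ = set(g.successors(t))
            for gene in genes:
                m_to_g = gene in m_succ
                t_to_g = gene in t_succ
                if composite_requires_both_gene_edges:
                    is_composite = m_to_t and t_to_m and m_to_g and t_to_g
                else:
                    is_composite = m_to_t and t_to_m and (m_to_g or t_to_g)
                if is_composite:
                    out.append(MotifInstance("composite", m, t, gene))
                elif m_to_t and m_to_g and t_to_g:
                    out.append(MotifInstance("miRNA-FFL", m, t, gene))
                elif t_to_m and m_to_g and t_to_g:
                    out.append(MotifInstance("TF-FFL", m, t, gene))
    out.sort(key=lambda i: (_KIND_ORDER[i.kind], i.mirna_id, i.tf_id, i.gene_id))
    return out


def node_occurrences(motifs: list[MotifInstance]) -> Counter:
    """Number of motif instances each node participates in.

    The counts satisfy sum_v occurrence(v) == 3 * len(motifs).
    """
    counts: Counter = Counter()
    for inst in motifs:
        counts.update(inst.nodes)
    return counts


def extract_key_subgraph(
    network: nx.MultiDiGraph,
    key_mirnas: list[str],
    key_tfs: list[str],
    key_genes: list[str],
) -> nx.MultiDiGraph:
    """Induced subgraph on the union of the key node sets, all edge
    classes preserved. Unknown ids raise, listing every offender."""
    keys = set(key_mirnas) | set(key_tfs) | set(key_genes)
    unknown = sorted(keys - set(network.nodes()))
    if unknown:
        raise ValueError(f"key nodes not in network: {unknown}")
    return network.subgraph(keys).copy()
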
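from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mtgnet import CountMatrix, SimulationConfig, generate_truth


@pytest.fixture
def small_config():
    return SimulationConfig(n_genes=50, n_tfs=10, n_mirnas=8, seed=1)


@pytest.fixture
def noiseless_config():
    return SimulationConfig(
        n_genes=50, n_tfs=10, n_mirnas=8,
        frac_de=1.0, prediction_sensitivity=1.0, prediction_fpr=0.0,
        n_databases=1, seed=7,
    )


@pytest.fixture
def tiny_counts():
    counts = pd.DataFrame(
        {"s1": [10, 10], "s2": [20, 5], "s3": [7, 3], "s4": [9, 12]},
        index=["gA", "gB"],
    )
    groups = pd.Series(
        ["control", "control", "treated", "treated"], index=["s1", "s2", "s3", "s4"]
    )
    lengths = pd.Series([1000, 2000], index=["gA", "gB"])
    return CountMatrix(counts=counts, feature_kind="gene", groups=groups, lengths=lengths)


def recover_pairs_and_network(truth, config):
    """Evidence -> consensus/filter -> pairs -> network with DE sets taken
    from the planted truth (all-DE oracle conditions)."""
    from mtgnet import recover_planted

    return recover_planted(truth, config)


@pytest.fixture
def noiseless_recovery(noiseless_config):
    truth = generate_truth(noiseless_config)
    pair_lists, mtg = recover_pairs_and_network(truth, noiseless_config)
    return truth, pair_lists, mtg


def random_typed_digraph(rng: np.random.Generator, n_mirna, n_tf, n_gene, p=0.3):
    """Random kind-consistent typed digraph as (kinds, edge set)."""
    kinds = {}
    for i in range(n_mirna):
        kinds[f"m{i}"] = "miRNA"
    for i in range(n_tf):
        kinds[f"t{i}"] = "TF"
    for i in range(n_gene):
        kinds[f"g{i}"] = "gene"
    mirnas = [v for v, k in kinds.items() if k == "miRNA"]
    tfs = [v for v, k in kinds.items() if k == "TF"]
    genes = [v for v, k in kinds.items() if k == "gene"]
    edges = set()
    for m in mirnas:
        for tgt in tfs + genes:
            if rng.random() < p:
                edges.add((m, tgt))
    for t in tfs:
        for tgt in mirnas + genes + [x for x in tfs if x != t]:
            if rng.random() < p:
                edges.add((t, tgt))
    return kinds, edges


def typed_graph_to_nx(kinds: dict, edges: set):
    import networkx as nx

    g = nx.DiGraph()
    for v, k in kinds.items():
        g.add_node(v, kind=k)
    g.add_edges_from(edges)
    return g
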
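"""Centrality metrics vs brute-force oracles; z-scoring; key-node selection."""
from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from _oracles import directed_metrics_oracle, betweenness_oracle, mcc_oracle, mnc_oracle
from conftest import random_typed_digraph, typed_graph_to_nx
from mtgnet import (
    clique_metrics,
    composite_zscore,
    load_fixture,
    node_metrics,
    ppi_metrics,
    select_key_genes,
    select_key_nodes,
)


def _digraph(edges, nodes=None):
    g = nx.DiGraph()
    g.add_nodes_from(nodes or sorted({x for e in edges for x in e}))
    g.add_edges_from(edges)
    return g


def _assert_matches_oracle(g: nx.DiGraph):
    nodes = list(g.nodes())
    edges = set(g.edges())
    got = node_metrics(g)
    expect = directed_metrics_oracle(nodes, edges)
    bc = betweenness_oracle(nodes, edges)
    for v in nodes:
        row = got.loc[v]
        assert row["degree"] == expect[v]["degree"]
        assert row["outdegree"] == expect[v]["outdegree"]
        assert row["closeness"] == pytest.approx(expect[v]["closeness"])
        assert row["betweenness"] == pytest.approx(bc[v])
        aspl = expect[v]["average_shortest_path_length"]
        if aspl is None:
            assert np.isnan(row["average_shortest_path_length"])
        else:
            assert row["average_shortest_path_length"] == pytest.approx(aspl)
        assert row["neighborhood_connectivity"] == pytest.approx(
            expect[v]["neighborhood_connectivity"]
        )


class TestNodeMetrics:
    def test_directed_path_betweenness(self):
        got = node_metrics(_digraph([("a", "b"), ("b", "c")]))
        assert got.loc["b", "betweenness"] == 1
        assert got.loc["a", "betweenness"] == 0
        assert got.loc["c", "betweenness"] == 0

    def test_out_star_center(self):
        g = _digraph([("hub", f"leaf{i}") for i in range(3)])
        got = node_metrics(g)
        assert got.loc["hub", "outdegree"] == 3
        assert got.loc["hub", "closeness"] == pytest.approx(3.0)
        assert got.loc["hub", "neighborhood_connectivity"] == pytest.approx(1.0)
        # leaves reach nobody: path length undefined
        assert np.isnan(got.loc["leaf0", "average_shortest_path_length"])

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            node_metrics(nx.DiGraph())

    def test_exhaustive_three_node_digraphs_match_oracle(self):
        nodes = ["a", "b", "c"]
        arcs = [(u, v) for u in nodes for v in nodes if u != v]
        for mask in range(2 ** len(arcs)):
            edges = [arcs[i] for i in range(len(arcs)) if mask >> i & 1]
            _assert_matches_oracle(_digraph(edges, nodes=nodes))

    def test_random_eight_node_digraphs_match_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            kinds, edges = random_typed_digraph(rng, 2, 3, 3, p=0.25)
            _assert_matches_oracle(typed_graph_to_nx(kinds, edges))


class TestCliqueMetrics:
    def test_triangle(self):
        got = clique_metrics(nx.complete_graph(3))
        assert (got["MCC"] == 2).all()  # (3-1)! for the single K3
        assert (got["MNC"] == 2).all()

    def test_star_center(self):
        g = nx.star_graph(4)  # center 0, four leaves
        got = clique_metrics(g)
        assert got.loc[0, "MCC"] == 4  # four maximal K2 cliques
        assert got.loc[0, "MNC"] == 1  # neighbors are pairwise disconnected

    def test_isolated_node_scores_zero(self):
        g = nx.Graph()
        g.add_node("alone")
        g.add_edge("a", "b")
        got = clique_metrics(g)
        assert got.loc["alone", "MCC"] == 0
        assert got.loc["alone", "MNC"] == 0

    def test_edgeless_neighborhood_mcc_equals_degree(self):
        g = nx.star_graph(5)
        assert clique_metrics(g).loc[0, "MCC"] == g.degree(0)

    def test_random_graphs_match_subset_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(15):
            g = nx.gnp_random_graph(10, 0.35, seed=int(rng.integers(2**31)))
            got = clique_metrics(g)
            uedges = {frozenset(e) for e in g.edges()}
            exp_mcc = mcc_oracle(list(g.nodes()), uedges)
            exp_mnc = mnc_oracle(list(g.nodes()), uedges)
            for v in g.nodes():
                assert got.loc[v, "MCC"] == exp_mcc[v]
                assert got.loc[v, "MNC"] == exp_mnc[v]


class TestCompositeZscore:
    def _metrics(self, values, kind="TF"):
        return pd.DataFrame({"kind": kind, "m1": values},
                            index=[f"n{i}" for i in range(len(values))])

    def test_identical_nodes_score_zero(self):
        out = composite_zscore(self._metrics([5.0, 5.0, 5.0]))
        assert (out["composite_z"] == 0).all()

    def test_two_nodes_single_metric_population_sd(self):
        out = composite_zscore(self._metrics([0.0, 1.0]))
        np.testing.assert_allclose(out["composite_z"], [-1.0, 1.0])

    def test_path_length_oriented_smaller_is_central(self):
        df = pd.DataFrame(
            {"kind": "TF", "average_shortest_path_length": [1.0, 3.0]}, index=["a", "b"]
        )
        out = composite_zscore(df)
        assert out.loc["a", "composite_z"] > 0 > out.loc["b", "composite_z"]

    def test_single_node_kind_rejected(self):
        with pytest.raises(ValueError, match=">= 2 nodes"):
            composite_zscore(self._metrics([1.0]))

    def test_affine_rescaling_leaves_scores_unchanged(self):
        rng = np.random.default_rng(3)
        base = pd.DataFrame(
            {"kind": "TF", "m1": rng.normal(size=6), "m2": rng.uniform(size=6)},
            index=[f"n{i}" for i in range(6)],
        )
        scaled = base.copy()
        scaled["m1"] = base["m1"] * 7.0 + 3.0
        np.testing.assert_allclose(
            composite_zscore(base)["composite_z"],
            composite_zscore(scaled)["composite_z"],
        )

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(
            {"kind": ["TF"] * 4 + ["miRNA"] * 3, "m1": rng.normal(size=7)},
            index=[f"n{i}" for i in range(7)],
        )
        out = composite_zscore(df)
        shuffled = composite_zscore(df.sample(frac=1, random_state=1))
        pd.testing.assert_series_equal(
            out["composite_z"].sort_index(), shuffled["composite_z"].sort_index()
        )

    def test_missing_metric_values_are_skipped_not_fatal(self):
        df = pd.DataFrame(
            {"kind": "TF", "m1": [1.0, 2.0, 3.0], "m2": [np.nan, np.nan, np.nan]},
            index=["a", "b", "c"],
        )
        out = composite_zscore(df)
        assert out["composite_z"].notna().all()


class TestSelection:
    def test_published_key_node_table_reselected(self):
        tab = load_fixture("table4_key_nodes")
        scores = pd.DataFrame(
            {
                "kind": tab["type"].map({"transcription factor": "TF", "miRNA": "miRNA"}).values,
                "composite_z": tab["z_score"].values,
            },
            index=tab["name"].values,
        )
        tfs, mirnas = select_key_nodes(scores, k_tf=10, k_mirna=5)
        assert set(tfs) == set(tab[tab["type"] == "transcription factor"]["name"])
        assert set(mirnas) == set(tab[tab["type"] == "miRNA"]["name"])
        assert tfs[0] == "Mxi1"
        assert mirnas[0] == "miR-5132-5p"

    def test_k_exceeding_population_returns_all(self):
        scores = pd.DataFrame(
            {"kind": ["TF", "miRNA"], "composite_z": [1.0, 2.0]}, index=["t1", "m1"]
        )
        tfs, mirnas = select_key_nodes(scores, k_tf=10, k_mirna=5)
        assert tfs == ["t1"] and mirnas == ["m1"]

    def test_selection_matches_sorting_oracle(self):
        rng = np.random.default_rng(11)
        names = [f"tf{i:02d}" for i in range(20)]
        z = rng.normal(size=20)
        scores = pd.DataFrame({"kind": "TF", "composite_z": z}, index=names)
        tfs, _ = select_key_nodes(scores, k_tf=5, k_mirna=0)
        expected = [n for _, n in sorted(zip(-z, names))][:5]
        assert tfs == expected

    def test_dominant_hub_ranks_first_for_key_genes(self):
        g = nx.star_graph(6)
        g.add_edge(1, 2)  # give the graph some non-hub structure
        table = ppi_metrics(nx.relabel_nodes(g, {i: f"g{i}" for i in g.nodes()}))
        assert select_key_genes(table, k=1) == ["g0"]

    def test_key_gene_selection_matches_rank_aggregation_oracle(self):
        rng = np.random.default_rng(12)
        g = nx.gnp_random_graph(12, 0.4, seed=5)
        g = nx.relabel_nodes(g, {i: f"g{i:02d}" for i in g.nodes()})
        table = ppi_metrics(g)
        got = select_key_genes(table, k=4)
        ranks = pd.DataFrame(index=table.index)
        for col in ("MCC", "MNC", "degree", "betweenness", "closeness"):
            ranks[col] = table[col].rank(ascending=False, method="average")
        mean_rank = ranks.mean(axis=1)
        expected = list(mean_rank.sort_values(kind="stable").index[:4])
        expected = [n for _, n in sorted(zip(mean_rank, table.index))][:4]
        assert got == expected

    def test_planted_hub_recovered_at_k_one(self):
        # hub-and-spoke M-T-G network: the hub TF regulates everything
        import mtgnet

        pairs = [
            mtgnet.RegulatoryPair("hub", "TF", f"g{i}", "gene", "TF-gene")
            for i in range(6)
        ] + [
            mtgnet.RegulatoryPair("other", "TF", "g0", "gene", "TF-gene"),
            mtgnet.RegulatoryPair("m1", "miRNA", "g1", "gene", "miRNA-gene"),
            mtgnet.RegulatoryPair("m2", "miRNA", "g2", "gene", "miRNA-gene"),
        ]
        net = mtgnet.build_mtg(pairs)
        metrics = node_metrics(net)
        regulators = metrics[metrics["kind"].isin(["TF", "miRNA"])]
        scores = composite_zscore(regulators)
        tfs, _ = select_key_nodes(scores, k_tf=1, k_mirna=1)
        assert tfs == ["hub"]
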
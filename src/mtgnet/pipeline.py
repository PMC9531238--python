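"""End-to-end pipeline: DE -> pairs -> networks -> metrics -> motifs -> ORA.

Stages mirror the workflow of a miRNA/TF co-regulatory network study:

1. normalize counts (RPM for miRNA, TPM for mRNA) and drop low-expressed
   features (mean RPM < 0.05 / TPM < 1);
2. negative-binomial Wald differential expression, called at
   |log2FC| > 1 and P < 0.05; DETFs = DEGs found in the TF catalog;
3. the four regulatory-pair classes by set logic (multi-database miRNA
   target consensus; TF targets at score >= 4.0; TF->miRNA via promoter
   windows);
4. typed M-T-G network and confidence >= 0.7 PPI over the jointly
   regulated genes;
5. centrality metrics, motif enumeration and occurrence counts,
   composite Z key-node selection (top 10 TFs, top 5 miRNAs) and
   mean-rank key-gene selection (top 7);
6. optional hypergeometric ORA of the jointly regulated genes.

Every intermediate table is written to the output directory along with a
manifest (seed, thresholds, stage row counts, output checksums) that makes
each reported count traceable; a rerun with the same config reproduces
identical outputs.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import centrality, enrichment, io, motifs as motifs_mod, network as network_mod, pairs as pairs_mod
from .expression import CountMatrix, call_status, low_expression_filter, nb_de_test, normalize

__all__ = ["PipelineConfig", "run_pipeline", "recover_planted"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Input paths and thresholds for a full pipeline run.

    Threshold defaults are the study's quoted values: RPM 0.05 / TPM 1
    low-expression cutoffs, |log2FC| > 1 and P < 0.05 DE calls, TF-target
    score >= 4.0, PPI confidence >= 0.7, ORA raw P < 0.01, top 10 TFs /
    5 miRNAs / 7 genes.
    """

    mirna_counts: str | Path
    mrna_counts: str | Path
    groups: str | Path
    lengths: str | Path
    tf_catalog: str | Path
    predictions: str | Path
    promoter_hits: str | Path
    tss: str | Path
    ppi: str | Path
    out_dir: str | Path
    gene_sets: str | Path | None = None
    truth_json: str | Path | None = None
    rpm_min: float = 0.05
    tpm_min: float = 1.0
    lfc_min: float = 1.0
    p_max: float = 0.05
    tf_score_min: float = 4.0
    ppi_confidence_min: float = 0.7
    ora_p_max: float = 0.01
    k_tf: int = 10
    k_mirna: int = 5
    k_gene: int = 7
    min_db_support: int = 1
    seed: int = 0
    de_from_truth: bool = False
    """Oracle mode: take DE status from the planted-truth JSON instead of
    the estimated test, isolating pair/network/motif recovery from DE
    power (requires ``truth_json``)."""


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_counts(cfg: PipelineConfig) -> tuple[CountMatrix, CountMatrix]:
    groups_df = io.read_table(cfg.groups, "groups")
    groups = pd.Series(groups_df["group"].values, index=groups_df["sample_id"].values)
    lengths_df = io.read_table(cfg.lengths, "lengths")
    lengths = pd.Series(lengths_df["length_bp"].values, index=lengths_df["gene_id"].values)
    mirna = CountMatrix(
        counts=io.read_table(cfg.mirna_counts, "counts"), feature_kind="miRNA", groups=groups.copy()
    )
    mrna = CountMatrix(
        counts=io.read_table(cfg.mrna_counts, "counts"),
        feature_kind="gene",
        groups=groups.copy(),
        lengths=lengths,
    )
    return mirna, mrna


def _de_stage(matrix: CountMatrix, unit: str, cfg: PipelineConfig) -> pd.DataFrame:
    norm = normalize(matrix, unit)
    retained = low_expression_filter(norm, rpm_min=cfg.rpm_min, tpm_min=cfg.tpm_min)
    low = set(matrix.feature_ids) - set(retained)
    res = nb_de_test(matrix, retained=retained)
    res = res.reindex(matrix.feature_ids)
    res = call_status(res, lfc_min=cfg.lfc_min, p_max=cfg.p_max, low_expression=low)
    return res


def _pairs_to_frame(pair_lists: dict[str, list[pairs_mod.RegulatoryPair]]) -> pd.DataFrame:
    rows = []
    for cls, plist in pair_lists.items():
        for p in plist:
            rows.append(
                (
                    p.regulator_id,
                    p.regulator_kind,
                    p.target_id,
                    p.target_kind,
                    cls,
                    ";".join(sorted(p.provenance)) or "NA",
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "regulator_id",
            "regulator_kind",
            "target_id",
            "target_kind",
            "pair_class",
            "provenance",
        ],
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the run manifest.

    The manifest records the seed, thresholds, per-stage set sizes (the
    audit trail: DEM/DEG/DETF counts, pair counts per class, network
    sizes, motif counts, key-node lists), output file checksums, and --
    when a planted-truth JSON is supplied -- precision/recall of the
    recovered regulatory edges and motifs against the planted truth.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load_inputs"
    try:
        mirna_mat, mrna_mat = _load_counts(config)
        tf_catalog = set(io.read_table(config.tf_catalog, "tf_catalog")["tf_id"])
        predictions = io.read_table(config.predictions, "predictions")
        promoter_hits = io.read_table(config.promoter_hits, "promoter_hits")
        tss = io.read_table(config.tss, "tss")
        ppi_table = io.read_table(config.ppi, "ppi")

        stage = "differential_expression"
        de_mirna = _de_stage(mirna_mat, "RPM", config)
        de_mrna = _de_stage(mrna_mat, "TPM", config)
        dems = set(de_mirna.index[de_mirna["status"].isin(["up", "down"])])
        degs = set(de_mrna.index[de_mrna["status"].isin(["up", "down"])])
        if config.de_from_truth:
            if config.truth_json is None:
                raise ValueError("de_from_truth requires truth_json")
            truth_de = {
                f for f, lfc in json.loads(Path(config.truth_json).read_text())["true_lfc"].items()
                if lfc != 0.0
            }
            dems = truth_de & set(de_mirna.index)
            degs = truth_de & set(de_mrna.index)
        detfs = pairs_mod.identify_detfs(degs, tf_catalog)

        stage = "regulatory_pairs"
        mirna_pred = predictions[predictions["regulator_kind"] == "miRNA"]
        tf_pred = predictions[predictions["regulator_kind"] == "TF"]
        mirna_candidates = pairs_mod.mirna_target_consensus(
            mirna_pred, min_db_support=config.min_db_support
        )
        tf_filtered = pairs_mod.tf_target_score_filter(tf_pred, score_min=config.tf_score_min)
        tf_candidates: dict[tuple[str, str], set[str]] = {}
        for db, reg, tgt in tf_filtered[["database", "regulator_id", "target_id"]].itertuples(
            index=False
        ):
            tf_candidates.setdefault((reg, tgt), set()).add(db)
        windows = pairs_mod.promoter_windows(tss)
        promo_candidates = {
            pair: {"promoter_scan"}
            for pair in pairs_mod.filter_promoter_hits(promoter_hits, windows)
        }
        pair_lists = {
            "miRNA-gene": pairs_mod.derive_pairs(mirna_candidates, degs, detfs, dems, "miRNA-gene"),
            "miRNA-TF": pairs_mod.derive_pairs(mirna_candidates, degs, detfs, dems, "miRNA-TF"),
            "TF-gene": pairs_mod.derive_pairs(tf_candidates, degs, detfs, dems, "TF-gene"),
            "TF-miRNA": pairs_mod.derive_pairs(promo_candidates, degs, detfs, dems, "TF-miRNA"),
        }
        dem_targets = {t for (r, t) in mirna_candidates if r in dems}
        detf_targets = {t for (r, t) in tf_candidates if r in detfs}
        joint_genes = pairs_mod.associated_genes(dem_targets, detf_targets, degs)

        stage = "network_build"
        all_pairs = [p for plist in pair_lists.values() for p in plist]
        mtg = network_mod.build_mtg(all_pairs)
        mtg_summary = network_mod.network_summary(mtg)
        ppi_joint = ppi_table[
            ppi_table["gene_a"].isin(joint_genes) & ppi_table["gene_b"].isin(joint_genes)
        ]
        ppi = network_mod.build_ppi(ppi_joint, confidence_min=config.ppi_confidence_min)
        ppi_summary = network_mod.network_summary(ppi)

        stage = "metrics_and_motifs"
        metrics = centrality.node_metrics(mtg) if mtg.number_of_nodes() else pd.DataFrame()
        motif_list = motifs_mod.enumerate_motifs(mtg)
        occurrences = motifs_mod.node_occurrences(motif_list)
        if len(metrics):
            metrics["motif_occurrence"] = [occurrences.get(v, 0) for v in metrics.index]

        stage = "key_nodes"
        regulators = metrics[metrics["kind"].isin(["TF", "miRNA"])] if len(metrics) else metrics
        key_tfs: list[str] = []
        key_mirnas: list[str] = []
        scores = pd.DataFrame()
        if len(regulators):
            # a kind needs >= 2 nodes for within-kind standardization
            counts_by_kind = regulators["kind"].value_counts()
            scorable = regulators[
                regulators["kind"].map(counts_by_kind).ge(2)
            ]
            if len(scorable):
                scores = centrality.composite_zscore(scorable)
                key_tfs, key_mirnas = centrality.select_key_nodes(
                    scores, k_tf=config.k_tf, k_mirna=config.k_mirna
                )
        key_genes: list[str] = []
        ppi_metric_table = pd.DataFrame()
        if ppi.number_of_nodes():
            ppi_metric_table = centrality.ppi_metrics(ppi)
            key_genes = centrality.select_key_genes(ppi_metric_table, k=config.k_gene)
        sub_motifs: list[motifs_mod.MotifInstance] = []
        if key_tfs or key_mirnas or key_genes:
            present = [g for g in key_genes if g in mtg]
            subgraph = motifs_mod.extract_key_subgraph(mtg, key_mirnas, key_tfs, present)
            sub_motifs = motifs_mod.enumerate_motifs(subgraph)

        stage = "enrichment"
        ora_results = pd.DataFrame()
        if config.gene_sets is not None:
            gene_sets = io.read_gmt(config.gene_sets)
            if joint_genes:
                ora_results = enrichment.ora(joint_genes, gene_sets, p_max=config.ora_p_max)

        stage = "write_outputs"
        io.write_table(de_mirna.reset_index(), out / "de_mirna.tsv")
        io.write_table(de_mrna.reset_index(), out / "de_mrna.tsv")
        pairs_frame = _pairs_to_frame(pair_lists)
        io.write_table(pairs_frame, out / "pairs.tsv")
        io.write_sif(mtg, out / "mtg_network.sif")
        io.write_table(
            pd.DataFrame(
                [(u, v, c["confidence"]) for u, v, c in ppi.edges(data=True)],
                columns=["gene_a", "gene_b", "confidence"],
            ),
            out / "ppi_network.tsv",
        )
        if len(metrics):
            io.write_table(metrics.reset_index(), out / "node_metrics.tsv")
        if len(scores):
            io.write_table(scores.reset_index(), out / "key_node_scores.tsv")
        if len(ppi_metric_table):
            io.write_table(ppi_metric_table.reset_index(), out / "ppi_metrics.tsv")
        io.write_table(
            pd.DataFrame(
                [(m.kind, m.mirna_id, m.tf_id, m.gene_id) for m in motif_list],
                columns=["kind", "mirna_id", "tf_id", "gene_id"],
            ),
            out / "motifs.tsv",
        )
        io.write_table(
            pd.DataFrame(
                sorted(occurrences.items()), columns=["node_id", "occurrence"]
            ),
            out / "occurrences.tsv",
        )
        if len(ora_results):
            io.write_table(ora_results, out / "ora_results.tsv")

        stage = "manifest"
        manifest = {
            "seed": config.seed,
            "thresholds": {
                k: getattr(config, k)
                for k in (
                    "rpm_min",
                    "tpm_min",
                    "lfc_min",
                    "p_max",
                    "tf_score_min",
                    "ppi_confidence_min",
                    "ora_p_max",
                    "k_tf",
                    "k_mirna",
                    "k_gene",
                    "min_db_support",
                )
            },
            "counts": {
                "n_dems": len(dems),
                "n_degs": len(degs),
                "n_detfs": len(detfs),
                "n_joint_target_genes": len(joint_genes),
                "pairs_by_class": {cls: len(pl) for cls, pl in pair_lists.items()},
                "mtg": mtg_summary,
                "ppi": ppi_summary,
                "n_motifs": len(motif_list),
                "n_key_subgraph_motifs": len(sub_motifs),
            },
            "key_nodes": {"tfs": key_tfs, "mirnas": key_mirnas, "genes": key_genes},
        }
        if config.truth_json is not None:
            truth = json.loads(Path(config.truth_json).read_text())
            manifest["recovery"] = _recovery(truth, pair_lists, motif_list)
        manifest["outputs"] = {
            p.name: _sha256(p) for p in sorted(out.glob("*")) if p.name != "manifest.json"
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        return manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def recover_planted(truth, config, min_db_support: int = 1):
    """Drive evidence -> consensus/filters -> pairs -> network with the DE
    sets taken from the planted truth (every planted node treated as DE).

    This isolates the pair-derivation, network and motif stages from
    differential-expression power, the configuration under which noiseless
    evidence must reproduce the planted edges and motifs exactly. Returns
    ``(pair_lists by class, M-T-G network)``.
    """
    from .synthetic import simulate_evidence

    ev = simulate_evidence(truth, config)
    de = truth.de_features
    dems = de & set(truth.mirna_ids)
    degs = de & set(truth.gene_ids)
    detfs = degs & set(truth.tf_ids)

    mirna_pred = ev.predictions[ev.predictions["regulator_kind"] == "miRNA"]
    tf_pred = ev.predictions[ev.predictions["regulator_kind"] == "TF"]
    mirna_cand = pairs_mod.mirna_target_consensus(mirna_pred, min_db_support=min_db_support)
    tf_filtered = pairs_mod.tf_target_score_filter(tf_pred)
    tf_cand: dict[tuple[str, str], set[str]] = {}
    for db, reg, tgt in tf_filtered[["database", "regulator_id", "target_id"]].itertuples(
        index=False
    ):
        tf_cand.setdefault((reg, tgt), set()).add(db)
    promo_cand = pairs_mod.filter_promoter_hits(
        ev.promoter_hits, pairs_mod.promoter_windows(truth.tss_table)
    )
    pair_lists = {
        "miRNA-gene": pairs_mod.derive_pairs(mirna_cand, degs, detfs, dems, "miRNA-gene"),
        "miRNA-TF": pairs_mod.derive_pairs(mirna_cand, degs, detfs, dems, "miRNA-TF"),
        "TF-gene": pairs_mod.derive_pairs(tf_cand, degs, detfs, dems, "TF-gene"),
        "TF-miRNA": pairs_mod.derive_pairs(promo_cand, degs, detfs, dems, "TF-miRNA"),
    }
    all_pairs = [p for pl in pair_lists.values() for p in pl]
    return pair_lists, network_mod.build_mtg(all_pairs)


def _recovery(truth: dict, pair_lists: dict, motif_list: list) -> dict:
    """Precision/recall of recovered edges and motifs vs planted truth."""
    true_edges = {(r, t) for r, _, t, _ in truth["true_edges"]}
    found_edges = {
        (p.regulator_id, p.target_id) for plist in pair_lists.values() for p in plist
    }
    true_motifs = {tuple(m) for m in truth["planted_motifs"]}
    found_motifs = {(m.mirna_id, m.tf_id, m.gene_id, m.kind) for m in motif_list}

    def pr(found: set, true: set) -> dict:
        tp = len(found & true)
        return {
            "precision_pct": 100.0 * tp / len(found) if found else 0.0,
            "recall_pct": 100.0 * tp / len(true) if true else 100.0,
        }

    return {"edges": pr(found_edges, true_edges), "motifs": pr(found_motifs, true_motifs)}
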
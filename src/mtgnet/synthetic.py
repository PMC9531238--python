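"""Synthetic two-group count data and regulatory-evidence generator.

Emulates the inputs of a small-animal two-group (treated vs control,
n = 3 per group) transcriptome study: negative-binomial miRNA and mRNA
counts with planted log2 fold changes, a TF subset of the genes, noisy
multi-database regulator->target prediction tables, scored TF-target
evidence, promoter-region TF binding hits for miRNAs, and
confidence-scored PPI edges — all with a known planted truth (DE
features, regulatory edges, three-node motifs) so every downstream
stage of the pipeline can be tested against ground truth.

All randomness flows from one integer seed through a documented
splitting scheme: each stage draws from
``numpy.random.default_rng(SeedSequence([seed, stage_code]))``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import CountMatrix

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "EvidenceTables",
    "generate_truth",
    "simulate_counts",
    "simulate_evidence",
    "write_inputs",
]

# stage codes for the seed-splitting scheme
_STAGE_TRUTH = 11
_STAGE_COUNTS = 23
_STAGE_EVIDENCE = 37

MOTIF_KINDS = ("miRNA-FFL", "TF-FFL", "composite")


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stage)]))


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for the synthetic generator.

    Defaults are the emulated study design: two groups of 3 samples,
    baseline expression 500 counts, NB dispersion phi = 0.1 (variance
    mu + phi*mu^2), planted |log2FC| = 2 on 30% of features, and
    three prediction databases at 90% sensitivity / 1% false-positive
    rate per database.
    """

    n_genes: int = 50
    n_tfs: int = 10
    n_mirnas: int = 8
    n_per_group: int = 3
    baseline_mean: float = 500.0
    dispersion: float = 0.1
    frac_de: float = 0.3
    lfc_magnitude: float = 2.0
    prediction_sensitivity: float = 0.9
    prediction_fpr: float = 0.01
    n_databases: int = 3
    ppi_confidence_range: tuple[float, float] = (0.3, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be nonnegative")
        for name in ("frac_de", "prediction_sensitivity", "prediction_fpr"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.lfc_magnitude <= 0:
            raise ValueError("lfc_magnitude must be positive")
        if self.n_databases < 1:
            raise ValueError("n_databases must be >= 1")
        lo, hi = self.ppi_confidence_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("ppi_confidence_range must be an interval within [0, 1]")


@dataclass
class SyntheticTruth:
    """Planted ground truth behind one synthetic dataset."""

    gene_ids: list[str]
    tf_ids: list[str]
    mirna_ids: list[str]
    gene_lengths: pd.Series
    tss_table: pd.DataFrame  # mirna_id, chrom, tss, strand
    true_lfc: dict[str, float]
    true_edges: set[tuple[str, str, str, str]]  # (reg_id, reg_kind, tgt_id, tgt_kind)
    planted_motifs: list[tuple[str, str, str, str]]  # (mirna, tf, gene, kind)
    seed: int

    def validate(self) -> None:
        if not set(self.tf_ids) <= set(self.gene_ids):
            raise ValueError("tf_ids must be a subset of gene_ids")
        if set(self.mirna_ids) & set(self.gene_ids):
            raise ValueError("mirna and gene id spaces must be disjoint")
        if (self.gene_lengths <= 0).any():
            raise ValueError("gene lengths must be positive")
        edge_pairs = {(r, t) for r, _, t, _ in self.true_edges}
        for m, t, g, kind in self.planted_motifs:
            if kind == "miRNA-FFL":
                need = [(m, t), (m, g), (t, g)]
            elif kind == "TF-FFL":
                need = [(t, m), (m, g), (t, g)]
            elif kind == "composite":
                need = [(m, t), (t, m), (m, g), (t, g)]
            else:
                raise ValueError(f"unknown motif kind {kind!r}")
            for pair in need:
                if pair not in edge_pairs:
                    raise ValueError(f"motif {(m, t, g, kind)} edge {pair} missing from true_edges")

    @property
    def de_features(self) -> set[str]:
        return {f for f, lfc in self.true_lfc.items() if lfc != 0.0}


@dataclass
class EvidenceTables:
    """Noisy regulatory evidence emulating external prediction databases."""

    predictions: pd.DataFrame  # database, regulator_id, regulator_kind, target_id, score
    promoter_hits: pd.DataFrame  # tf_id, mirna_id, chrom, position
    ppi: pd.DataFrame  # gene_a, gene_b, confidence


def generate_truth(config: SimulationConfig) -> SyntheticTruth:
    """Draw a planted regulatory network, DE assignment and annotation.

    Plants at least one motif of each kind (miRNA-FFL, TF-FFL,
    composite) when the node pools permit, on disjoint
    (miRNA, TF, non-TF gene) triples. Background true edges only run
    from a single regulator kind into genes unused by any motif, and no
    background miRNA<->TF edges are drawn, so the motif set of the
    true-edge graph is exactly the planted list.
    """
    rng = _stage_rng(config.seed, _STAGE_TRUTH)
    n_nontf = config.n_genes - config.n_tfs
    if config.n_mirnas < 1 or config.n_tfs < 1 or n_nontf < 1:
        raise ValueError(
            "need at least 1 miRNA, 1 TF and 1 non-TF gene to plant a motif "
            f"(got {config.n_mirnas} miRNAs, {config.n_tfs} TFs, {n_nontf} non-TF genes)"
        )
    gene_ids = [f"g{i:04d}" for i in range(config.n_genes)]
    tf_ids = sorted(rng.choice(gene_ids, size=config.n_tfs, replace=False).tolist())
    mirna_ids = [f"mir{i:03d}" for i in range(config.n_mirnas)]
    nontf = [g for g in gene_ids if g not in set(tf_ids)]

    gene_lengths = pd.Series(
        rng.integers(500, 5001, size=config.n_genes), index=gene_ids, name="length_bp"
    )
    strands = rng.choice(["+", "-"], size=config.n_mirnas)
    tss_table = pd.DataFrame(
        {
            "mirna_id": mirna_ids,
            "chrom": [f"chr{c}" for c in rng.integers(1, 21, size=config.n_mirnas)],
            "tss": rng.integers(50_000, 1_000_000, size=config.n_mirnas),
            "strand": strands,
        }
    )

    # DE assignment: frac_de of all features at +/- lfc_magnitude, sign random
    features = mirna_ids + gene_ids
    n_de = int(round(config.frac_de * len(features)))
    de_feats = rng.choice(features, size=n_de, replace=False) if n_de else np.array([], dtype=object)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    true_lfc = {f: 0.0 for f in features}
    for f, s in zip(de_feats, signs):
        true_lfc[f] = float(s * config.lfc_magnitude)

    # plant motifs on disjoint triples, cycling through the three kinds
    n_motifs = min(config.n_mirnas, config.n_tfs, n_nontf)
    n_motifs = min(n_motifs, 6)
    motif_mirnas = rng.choice(mirna_ids, size=n_motifs, replace=False)
    motif_tfs = rng.choice(tf_ids, size=n_motifs, replace=False)
    motif_genes = rng.choice(nontf, size=n_motifs, replace=False)
    planted_motifs: list[tuple[str, str, str, str]] = []
    true_edges: set[tuple[str, str, str, str]] = set()
    for i in range(n_motifs):
        m, t, g = str(motif_mirnas[i]), str(motif_tfs[i]), str(motif_genes[i])
        kind = MOTIF_KINDS[i % 3]
        planted_motifs.append((m, t, g, kind))
        true_edges.add((m, "miRNA", g, "gene"))
        true_edges.add((t, "TF", g, "gene"))
        if kind == "miRNA-FFL":
            true_edges.add((m, "miRNA", t, "TF"))
        elif kind == "TF-FFL":
            true_edges.add((t, "TF", m, "miRNA"))
        else:
            true_edges.add((m, "miRNA", t, "TF"))
            true_edges.add((t, "TF", m, "miRNA"))

    # background edges into genes untouched by motifs; one regulator kind per gene
    used_genes = {g for _, _, g, _ in planted_motifs} | set(motif_tfs.tolist())
    background = [g for g in gene_ids if g not in used_genes]
    for g in background:
        if rng.random() < 0.5:
            continue
        if rng.random() < 0.5:
            reg = str(rng.choice(mirna_ids))
            true_edges.add((reg, "miRNA", g, "TF" if g in set(tf_ids) else "gene"))
        else:
            reg = str(rng.choice(tf_ids))
            if reg != g:
                true_edges.add((reg, "TF", g, "TF" if g in set(tf_ids) else "gene"))

    truth = SyntheticTruth(
        gene_ids=gene_ids,
        tf_ids=tf_ids,
        mirna_ids=mirna_ids,
        gene_lengths=gene_lengths,
        tss_table=tss_table,
        true_lfc=true_lfc,
        true_edges=true_edges,
        planted_motifs=planted_motifs,
        seed=config.seed,
    )
    truth.validate()
    return truth


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    """NB(mu, variance mu + phi*mu^2); phi == 0 degenerates to Poisson."""
    if phi == 0.0:
        return rng.poisson(mu)
    r = 1.0 / phi
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def simulate_counts(
    truth: SyntheticTruth, config: SimulationConfig
) -> tuple[CountMatrix, CountMatrix]:
    """Draw the miRNA and mRNA count matrices.

    Count for feature g in sample s ~ NB with mean
    ``baseline_mean * 2**(true_lfc_g * [s in treated group])`` and
    variance mu + phi*mu^2.
    """
    rng = _stage_rng(config.seed, _STAGE_COUNTS)
    n = config.n_per_group
    samples = [f"control_{i+1}" for i in range(n)] + [f"treated_{i+1}" for i in range(n)]
    groups = pd.Series(["control"] * n + ["treated"] * n, index=samples, name="group")
    treated_mask = np.array([0.0] * n + [1.0] * n)

    def matrix(feature_ids: list[str]) -> pd.DataFrame:
        lfc = np.array([truth.true_lfc[f] for f in feature_ids])
        mu = config.baseline_mean * 2.0 ** (lfc[:, None] * treated_mask[None, :])
        return pd.DataFrame(_nb_draw(rng, mu, config.dispersion), index=feature_ids, columns=samples)

    mirna = CountMatrix(counts=matrix(truth.mirna_ids), feature_kind="miRNA", groups=groups.copy())
    mrna = CountMatrix(
        counts=matrix(truth.gene_ids),
        feature_kind="gene",
        groups=groups.copy(),
        lengths=truth.gene_lengths.copy(),
    )
    return mirna, mrna


def _promoter_window(tss: int, strand: str, upstream: int = 5000, downstream: int = 1000) -> tuple[int, int]:
    if strand == "+":
        lo, hi = tss - upstream, tss + downstream
    else:
        lo, hi = tss - downstream, tss + upstream
    return max(lo, 1), hi


def simulate_evidence(truth: SyntheticTruth, config: SimulationConfig) -> EvidenceTables:
    """Emit noisy multi-database prediction tables, promoter hits and PPI.

    Each of the ``n_databases`` databases reports each true
    miRNA->gene/miRNA->TF/TF->gene edge independently with probability
    ``prediction_sensitivity``, and each candidate false pair (uniform
    over the non-edge set, capped at 10x the true-edge count) with
    probability ``prediction_fpr``. TF->gene rows carry a score >= 4.0
    when true and uniform on [0, 8] when false; miRNA rows carry no
    score. True TF->miRNA edges appear as promoter binding hits placed
    inside the miRNA's promoter window (5 kb upstream to 1 kb
    downstream of the TSS, strand-aware); false hits are scattered
    within +/- 20 kb of the TSS. PPI edges among the planted motif
    genes carry confidence >= 0.7; background gene pairs draw from
    ``ppi_confidence_range``.
    """
    rng = _stage_rng(config.seed, _STAGE_EVIDENCE)
    tf_set = set(truth.tf_ids)
    db_names = [f"db{i+1}" for i in range(config.n_databases)]

    tabular_true = sorted(e for e in truth.true_edges if not (e[1] == "TF" and e[3] == "miRNA"))
    promo_true = sorted(e for e in truth.true_edges if e[1] == "TF" and e[3] == "miRNA")

    # candidate false pool: uniform over non-edges, capped at 10x true count
    true_pairs = {(r, t) for r, _, t, _ in truth.true_edges}
    candidates: list[tuple[str, str, str, str]] = []
    for m in truth.mirna_ids:
        for g in truth.gene_ids:
            if (m, g) not in true_pairs:
                candidates.append((m, "miRNA", g, "TF" if g in tf_set else "gene"))
    for t in truth.tf_ids:
        for g in truth.gene_ids:
            if g != t and (t, g) not in true_pairs:
                candidates.append((t, "TF", g, "TF" if g in tf_set else "gene"))
    cap = 10 * max(len(tabular_true), 1)
    if len(candidates) > cap:
        idx = rng.choice(len(candidates), size=cap, replace=False)
        candidates = [candidates[i] for i in sorted(idx)]

    rows = []
    for db in db_names:
        for reg, rkind, tgt, tkind in tabular_true:
            if rng.random() < config.prediction_sensitivity:
                score = float(rng.uniform(4.0, 8.0)) if rkind == "TF" else np.nan
                rows.append((db, reg, rkind, tgt, score))
        for reg, rkind, tgt, tkind in candidates:
            if rng.random() < config.prediction_fpr:
                score = float(rng.uniform(0.0, 8.0)) if rkind == "TF" else np.nan
                rows.append((db, reg, rkind, tgt, score))
    predictions = pd.DataFrame(
        rows, columns=["database", "regulator_id", "regulator_kind", "target_id", "score"]
    )

    # promoter binding hits for TF->miRNA evidence
    tss_lookup = truth.tss_table.set_index("mirna_id")
    hit_rows = []
    for tf, _, m, _ in promo_true:
        if rng.random() < config.prediction_sensitivity:
            row = tss_lookup.loc[m]
            lo, hi = _promoter_window(int(row["tss"]), str(row["strand"]))
            hit_rows.append((tf, m, str(row["chrom"]), int(rng.integers(lo, hi + 1))))
    n_false_hits = rng.binomial(len(truth.tf_ids) * len(truth.mirna_ids), config.prediction_fpr)
    for _ in range(n_false_hits):
        tf = str(rng.choice(truth.tf_ids))
        m = str(rng.choice(truth.mirna_ids))
        if (tf, m) in true_pairs:
            continue
        row = tss_lookup.loc[m]
        pos = int(row["tss"]) + int(rng.integers(-20_000, 20_001))
        hit_rows.append((tf, m, str(row["chrom"]), max(pos, 1)))
    promoter_hits = pd.DataFrame(hit_rows, columns=["tf_id", "mirna_id", "chrom", "position"])

    # PPI: planted-module genes form a high-confidence clique
    module_genes = sorted({g for _, _, g, _ in truth.planted_motifs})
    ppi_rows = []
    seen = set()
    for i, a in enumerate(module_genes):
        for b in module_genes[i + 1 :]:
            ppi_rows.append((a, b, float(rng.uniform(0.7, 1.0))))
            seen.add((a, b))
    lo, hi = config.ppi_confidence_range
    n_bg = 2 * len(truth.gene_ids)
    for _ in range(n_bg):
        a, b = rng.choice(truth.gene_ids, size=2, replace=False)
        a, b = sorted((str(a), str(b)))
        if (a, b) in seen:
            continue
        seen.add((a, b))
        ppi_rows.append((a, b, float(rng.uniform(lo, hi))))
    ppi = pd.DataFrame(ppi_rows, columns=["gene_a", "gene_b", "confidence"])

    return EvidenceTables(predictions=predictions, promoter_hits=promoter_hits, ppi=ppi)


def write_inputs(truth: SyntheticTruth, config: SimulationConfig, out_dir) -> dict:
    """Simulate counts and evidence and write every pipeline input to TSV.

    Writes miRNA/mRNA count matrices, group labels, gene lengths, the TF
    catalog, the TSS table, prediction and promoter-hit tables, the PPI
    edge list, a small gene-set GMT (random 8-30-gene terms over the gene
    universe, for the enrichment stage), and the planted truth as JSON.
    Returns a dict mapping logical names to file paths.
    """
    import json
    from pathlib import Path

    from . import io as io_mod

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mirna, mrna = simulate_counts(truth, config)
    evidence = simulate_evidence(truth, config)

    paths = {name: out / fname for name, fname in [
        ("mirna_counts", "mirna_counts.tsv"),
        ("mrna_counts", "mrna_counts.tsv"),
        ("groups", "groups.tsv"),
        ("lengths", "lengths.tsv"),
        ("tf_catalog", "tf_catalog.tsv"),
        ("tss", "tss.tsv"),
        ("predictions", "predictions.tsv"),
        ("promoter_hits", "promoter_hits.tsv"),
        ("ppi", "ppi.tsv"),
        ("gene_sets", "gene_sets.gmt"),
        ("truth_json", "truth.json"),
    ]}
    mirna.counts.rename_axis("feature_id").to_csv(paths["mirna_counts"], sep="\t")
    mrna.counts.rename_axis("feature_id").to_csv(paths["mrna_counts"], sep="\t")
    io_mod.write_table(
        pd.DataFrame({"sample_id": mirna.groups.index, "group": mirna.groups.values}),
        paths["groups"],
    )
    io_mod.write_table(
        pd.DataFrame({"gene_id": truth.gene_lengths.index, "length_bp": truth.gene_lengths.values}),
        paths["lengths"],
    )
    io_mod.write_table(pd.DataFrame({"tf_id": truth.tf_ids}), paths["tf_catalog"])
    io_mod.write_table(truth.tss_table, paths["tss"])
    io_mod.write_table(evidence.predictions, paths["predictions"])
    io_mod.write_table(evidence.promoter_hits, paths["promoter_hits"])
    io_mod.write_table(evidence.ppi, paths["ppi"])

    rng = _stage_rng(config.seed, 53)
    gene_sets = {}
    for i in range(8):
        size = int(rng.integers(8, min(31, len(truth.gene_ids) + 1)))
        members = rng.choice(truth.gene_ids, size=size, replace=False)
        gene_sets[f"term{i+1:02d}"] = set(str(g) for g in members)
    io_mod.write_gmt(gene_sets, paths["gene_sets"])

    paths["truth_json"].write_text(
        json.dumps(
            {
                "gene_ids": truth.gene_ids,
                "tf_ids": truth.tf_ids,
                "mirna_ids": truth.mirna_ids,
                "true_lfc": truth.true_lfc,
                "true_edges": sorted(truth.true_edges),
                "planted_motifs": truth.planted_motifs,
                "seed": truth.seed,
            },
            indent=2,
        )
        + "\n"
    )
    return {k: str(v) for k, v in paths.items()}
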
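"""Derivation of the four regulatory-pair classes by set logic.

Pair classes: miRNA-gene, miRNA-TF, TF-gene, TF-miRNA. Regulators must be
differentially expressed (DEM or DETF) and targets must fall in the
class-appropriate differential set. TF-target predictions are filtered at
score >= 4.0; TF->miRNA evidence is filtered by promoter windows (5 kb
upstream to 1 kb downstream of the miRNA TSS, strand-aware, 1-based
inclusive coordinates).
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "RegulatoryPair",
    "PromoterWindow",
    "identify_detfs",
    "mirna_target_consensus",
    "tf_target_score_filter",
    "promoter_windows",
    "filter_promoter_hits",
    "derive_pairs",
    "associated_genes",
    "PAIR_CLASSES",
]

PAIR_CLASSES = ("miRNA-gene", "miRNA-TF", "TF-gene", "TF-miRNA")

_CLASS_KINDS = {
    "miRNA-gene": ("miRNA", "gene"),
    "miRNA-TF": ("miRNA", "TF"),
    "TF-gene": ("TF", "gene"),
    "TF-miRNA": ("TF", "miRNA"),
}


@dataclass(frozen=True)
class RegulatoryPair:
    """Typed directed regulatory edge with provenance."""

    regulator_id: str
    regulator_kind: str
    target_id: str
    target_kind: str
    pair_class: str
    provenance: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.pair_class not in _CLASS_KINDS:
            raise ValueError(f"unknown pair_class {self.pair_class!r}")
        rkind, tkind = _CLASS_KINDS[self.pair_class]
        if self.regulator_kind != rkind or self.target_kind != tkind:
            raise ValueError(
                f"pair_class {self.pair_class} inconsistent with kinds "
                f"({self.regulator_kind} -> {self.target_kind})"
            )
        if self.regulator_id == self.target_id:
            raise ValueError(f"self-pair not allowed: {self.regulator_id}")


@dataclass(frozen=True)
class PromoterWindow:
    """1-based inclusive promoter interval around a miRNA TSS."""

    mirna_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("window start must be <= end")

    def contains(self, chrom: str, position: int) -> bool:
        return chrom == self.chrom and self.start <= position <= self.end


def identify_detfs(deg_ids: set[str], tf_catalog: set[str]) -> set[str]:
    """Differentially expressed TFs: DEGs that appear in the TF catalog."""
    return set(deg_ids) & set(tf_catalog)


def mirna_target_consensus(
    predictions: pd.DataFrame, min_db_support: int = 1
) -> dict[tuple[str, str], frozenset]:
    """Collapse multi-database miRNA-target predictions by database support.

    Returns a map (mirna, target) -> frozenset of supporting database names
    for pairs predicted by at least ``min_db_support`` distinct databases.
    """
    required = {"database", "regulator_id", "target_id"}
    missing = required - set(predictions.columns)
    if missing:
        raise ValueError(f"prediction table missing columns: {sorted(missing)}")
    n_dbs = predictions["database"].nunique()
    if min_db_support > max(n_dbs, 1):
        raise ValueError(
            f"min_db_support={min_db_support} exceeds the {n_dbs} databases present"
        )
    support: dict[tuple[str, str], set[str]] = {}
    for db, reg, tgt in predictions[["database", "regulator_id", "target_id"]].itertuples(
        index=False
    ):
        support.setdefault((reg, tgt), set()).add(db)
    return {
        pair: frozenset(dbs) for pair, dbs in support.items() if len(dbs) >= min_db_support
    }


def tf_target_score_filter(tf_predictions: pd.DataFrame, score_min: float = 4.0) -> pd.DataFrame:
    """Drop TF-target prediction rows scoring below ``score_min``.

    Rows with score >= 4.0 are retained (the boundary is kept); rows
    lacking a numeric score are rejected.
    """
    if "score" not in tf_predictions.columns:
        raise ValueError("TF prediction table has no 'score' column")
    scores = pd.to_numeric(tf_predictions["score"], errors="coerce")
    return tf_predictions.loc[scores >= score_min].copy()


def promoter_windows(
    tss_table: pd.DataFrame, upstream: int = 5000, downstream: int = 1000
) -> list[PromoterWindow]:
    """Strand-aware promoter windows around each miRNA TSS.

    + strand: [tss - upstream, tss + downstream];
    - strand: [tss - downstream, tss + upstream]; clipped at position 1.
    """
    windows = []
    for row in tss_table.itertuples(index=False):
        tss = int(row.tss)
        if tss < 1:
            raise ValueError(f"TSS must be >= 1 for {row.mirna_id}")
        if row.strand == "+":
            start, end = tss - upstream, tss + downstream
        elif row.strand == "-":
            start, end = tss - downstream, tss + upstream
        else:
            raise ValueError(f"bad strand {row.strand!r} for {row.mirna_id}")
        windows.append(
            PromoterWindow(
                mirna_id=str(row.mirna_id),
                chrom=str(row.chrom),
                start=max(start, 1),
                end=end,
                strand=str(row.strand),
            )
        )
    return windows


def filter_promoter_hits(
    hits: pd.DataFrame, windows: list[PromoterWindow]
) -> set[tuple[str, str]]:
    """TF->miRNA candidate pairs whose binding hit falls inside the
    miRNA's promoter window (matching chromosome, 1-based inclusive)."""
    by_mirna = {w.mirna_id: w for w in windows}
    kept: set[tuple[str, str]] = set()
    for row in hits.itertuples(index=False):
        w = by_mirna.get(str(row.mirna_id))
        if w is not None and w.contains(str(row.chrom), int(row.position)):
            kept.add((str(row.tf_id), str(row.mirna_id)))
    return kept


_CLASS_FILTER = {
    "miRNA-gene": "deg",
    "miRNA-TF": "detf",
    "TF-gene": "deg",
    "TF-miRNA": "dem",
}


def derive_pairs(
    candidate_pairs,
    deg_ids: set[str],
    detf_ids: set[str],
    dem_ids: set[str],
    pair_class: str,
) -> list[RegulatoryPair]:
    """Filter candidate (regulator, target) pairs into one pair class.

    The regulator must be differentially expressed (DEM for miRNA
    classes, DETF for TF classes) and the target must lie in the
    class filter set: DEGs for miRNA-gene and TF-gene, DETFs for
    miRNA-TF, DEMs for TF-miRNA. ``candidate_pairs`` is an iterable of
    (regulator, target) tuples or a mapping of those tuples to
    provenance sets. Duplicates collapse with provenance accumulated.
    """
    if pair_class not in _CLASS_KINDS:
        raise ValueError(f"unknown pair_class {pair_class!r}")
    rkind, tkind = _CLASS_KINDS[pair_class]
    regulator_set = dem_ids if rkind == "miRNA" else detf_ids
    target_set = {"deg": deg_ids, "detf": detf_ids, "dem": dem_ids}[_CLASS_FILTER[pair_class]]

    if isinstance(candidate_pairs, dict):
        items = candidate_pairs.items()
    else:
        items = [(pair, frozenset()) for pair in candidate_pairs]

    merged: dict[tuple[str, str], set[str]] = {}
    for (reg, tgt), prov in items:
        if reg == tgt:
            continue
        if reg in regulator_set and tgt in target_set:
            merged.setdefault((reg, tgt), set()).update(prov)
    return [
        RegulatoryPair(
            regulator_id=reg,
            regulator_kind=rkind,
            target_id=tgt,
            target_kind=tkind,
            pair_class=pair_class,
            provenance=frozenset(prov),
        )
        for (reg, tgt), prov in sorted(merged.items())
    ]


def associated_genes(
    dem_target_set: set[str], detf_target_set: set[str], deg_ids: set[str]
) -> set[str]:
    """Genes jointly regulated: the triple intersection of miRNA targets,
    TF targets, and DEGs."""
    return set(dem_target_set) & set(detf_target_set) & set(deg_ids)
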
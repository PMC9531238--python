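"""Schema-validated TSV I/O, GMT/SIF writers, and packaged table fixtures.

All tables are UTF-8 TSV with a header row; missing values are "NA".
Schemas name the required columns and their types; validation errors name
the first offending cell. Fixtures transcribe the published summary tables
of differentially expressed miRNAs (with mature sequences and cross-species
homology), key genes, and key TF/miRNA nodes.
"""
from __future__ import annotations

from importlib import resources
from pathlib import Path

import networkx as nx
import pandas as pd

__all__ = [
    "read_table",
    "write_table",
    "read_gmt",
    "write_gmt",
    "write_sif",
    "load_fixture",
    "FIXTURE_NAMES",
    "SCHEMAS",
]

FIXTURE_NAMES = ("table2_dems", "table3_key_genes", "table4_key_nodes")

# schema: column -> dtype kind ("str", "int", "float", "num_or_na")
SCHEMAS: dict[str, dict] = {
    "counts": {"index": "feature_id", "columns": None},  # wide: validated specially
    "groups": {"columns": {"sample_id": "str", "group": "str"}, "key": "sample_id"},
    "lengths": {"columns": {"gene_id": "str", "length_bp": "int"}, "key": "gene_id"},
    "tss": {
        "columns": {"mirna_id": "str", "chrom": "str", "tss": "int", "strand": "str"},
        "key": "mirna_id",
    },
    "predictions": {
        "columns": {
            "database": "str",
            "regulator_id": "str",
            "regulator_kind": "str",
            "target_id": "str",
            "score": "num_or_na",
        },
        "key": None,
    },
    "promoter_hits": {
        "columns": {"tf_id": "str", "mirna_id": "str", "chrom": "str", "position": "int"},
        "key": None,
    },
    "ppi": {
        "columns": {"gene_a": "str", "gene_b": "str", "confidence": "float"},
        "key": None,
    },
    "de_results": {
        "columns": {
            "feature_id": "str",
            "base_mean": "float",
            "log2fc": "float",
            "p_value": "float",
            "status": "str",
        },
        "key": "feature_id",
    },
    "pairs": {
        "columns": {
            "regulator_id": "str",
            "regulator_kind": "str",
            "target_id": "str",
            "target_kind": "str",
            "pair_class": "str",
            "provenance": "str",
        },
        "key": None,
    },
    "tf_catalog": {"columns": {"tf_id": "str"}, "key": "tf_id"},
    "motifs": {
        "columns": {"kind": "str", "mirna_id": "str", "tf_id": "str", "gene_id": "str"},
        "key": None,
    },
    "occurrence": {"columns": {"node_id": "str", "occurrence": "int"}, "key": "node_id"},
}


class SchemaError(ValueError):
    """A table failed schema validation."""


def _check_numeric(df: pd.DataFrame, col: str, kind: str, path) -> pd.Series:
    raw = df[col]
    coerced = pd.to_numeric(raw, errors="coerce")
    if kind == "num_or_na":
        bad = coerced.isna() & raw.notna() & (raw.astype(str) != "NA")
    else:
        bad = coerced.isna()
    if bad.any():
        row = int(bad.idxmax())
        raise SchemaError(
            f"{path}: non-numeric value {raw.loc[row]!r} in column {col!r}, row {row + 2}"
        )
    if kind == "int":
        frac = coerced.dropna() % 1
        if (frac != 0).any():
            row = int(frac.index[(frac != 0)][0])
            raise SchemaError(
                f"{path}: non-integer value {raw.loc[row]!r} in column {col!r}, row {row + 2}"
            )
        return coerced.astype("int64")
    return coerced.astype(float)


def read_table(path, schema_name: str) -> pd.DataFrame:
    """Read a TSV and validate it against a named schema.

    Row order is preserved. Raises :class:`SchemaError` naming the first
    offending cell on missing columns, non-numeric numeric fields, negative
    counts, or duplicate keys.
    """
    if schema_name not in SCHEMAS:
        raise ValueError(f"unknown schema {schema_name!r}")
    path = Path(path)
    if schema_name == "counts":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.index.name != "feature_id":
            raise SchemaError(f"{path}: first column must be 'feature_id', got {df.index.name!r}")
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise SchemaError(f"{path}: duplicate feature_id {dup!r}")
        for col in df.columns:
            vals = _check_numeric(df.reset_index(), col, "int", path)
            if (vals < 0).any():
                row = int(vals.index[vals < 0][0])
                raise SchemaError(f"{path}: negative count in column {col!r}, row {row + 2}")
        return df.astype("int64")
    spec = SCHEMAS[schema_name]
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA"], keep_default_na=False)
    missing = set(spec["columns"]) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    for col, kind in spec["columns"].items():
        if kind in ("int", "float", "num_or_na"):
            df[col] = _check_numeric(df, col, kind, path)
    key = spec.get("key")
    if key and df[key].duplicated().any():
        dup = df[key][df[key].duplicated()].iloc[0]
        raise SchemaError(f"{path}: duplicate key {dup!r} in column {key!r}")
    return df


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    """Write a table as UTF-8 TSV with 'NA' for missing values."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, na_rep="NA")


def read_gmt(path) -> dict[str, set[str]]:
    """Read gene sets in GMT format (term, description, members...)."""
    sets: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise SchemaError(f"{path}: GMT line {lineno} has fewer than 3 fields")
        sets[fields[0]] = set(f for f in fields[2:] if f)
    return sets


def write_gmt(gene_sets: dict[str, set[str]], path, descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    lines = []
    for term in sorted(gene_sets):
        members = "\t".join(sorted(gene_sets[term]))
        lines.append(f"{term}\t{descriptions.get(term, 'NA')}\t{members}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text("\n".join(lines) + "\n")


def write_sif(network: nx.MultiDiGraph, path) -> None:
    """Write a typed directed network as SIF (source, edge class, target)."""
    lines = []
    for u, v, cls in sorted(network.edges(keys=True)):
        lines.append(f"{u}\t{cls}\t{v}")
    for v in sorted(network.nodes()):
        if network.degree(v) == 0:
            lines.append(str(v))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text("\n".join(lines) + "\n")


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged table fixture.

    Names: ``table2_dems`` (differentially expressed miRNAs: id, mature
    sequence, log2fc, p_value, homology), ``table3_key_genes`` (key PPI hub
    genes: id, log2fc, p_value, z_score), ``table4_key_nodes`` (key TFs and
    miRNAs: id, type, occurrences, z_score).
    """
    if name not in FIXTURE_NAMES:
        raise ValueError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
    ref = resources.files("mtgnet") / "fixtures" / f"{name}.tsv"
    with resources.as_file(ref) as p:
        return pd.read_csv(p, sep="\t")
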
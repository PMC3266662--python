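"""Readers and writers for the pipeline's tab-separated interchange files.

TSV is the primary format; annotation is also accepted/emitted as GFF3
(gene features with gc/taxonomy/categories/domains carried as attributes,
1-based inclusive coordinates preserved exactly). Cluster tables are
written BED-like: 0-based half-open coordinates on disk, converted back to
1-based inclusive on read.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import pandas as pd

from .physiology import CultivationRecord

ANNOTATION_COLUMNS = [
    "gene_id",
    "scaffold_id",
    "start",
    "end",
    "strand",
    "length",
    "gc",
    "dist_to_end",
    "scaffold_length",
    "taxonomy",
    "categories",
    "domains",
]

CULTIVATION_COLUMNS = [
    "sample_id",
    "condition",
    "dilution_rate",
    "biomass",
    "protein",
    "substrate_feed",
    "substrate_residual",
]


class SchemaError(ValueError):
    """File does not match the expected schema."""


def _require_columns(df: pd.DataFrame, columns: Sequence[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def read_expression(path) -> pd.DataFrame:
    """Expression TSV: first column gene_id, remaining columns sample ids."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "gene_id":
        raise SchemaError(f"{path}: first column must be 'gene_id'")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise SchemaError(f"{path}: duplicate gene id {dup!r}")
    return df.set_index("gene_id")


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.rename_axis("gene_id").to_csv(path, sep="\t")


def read_annotation(path) -> pd.DataFrame:
    """Gene annotation from flat TSV or GFF3 (by extension)."""
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        return read_annotation_gff3(path)
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ANNOTATION_COLUMNS, path)
    if df["gene_id"].duplicated().any():
        raise SchemaError(f"{path}: duplicate gene ids")
    if (df["start"] > df["end"]).any():
        raise SchemaError(f"{path}: start > end")
    if not df["strand"].isin(["+", "-"]).all():
        raise SchemaError(f"{path}: strand must be '+' or '-'")
    df["categories"] = df["categories"].fillna("")
    df["domains"] = df["domains"].fillna("")
    return df[ANNOTATION_COLUMNS]


def write_annotation(annotation: pd.DataFrame, path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        write_annotation_gff3(annotation, path)
    else:
        annotation.to_csv(path, sep="\t", index=False)


def write_annotation_gff3(annotation: pd.DataFrame, path) -> None:
    """GFF3 gene features; gc/taxonomy/categories/domains in column 9."""
    lines = ["##gff-version 3"]
    for sc, sub in annotation.groupby("scaffold_id", sort=True):
        lines.append(f"##sequence-region {sc} 1 {int(sub['scaffold_length'].iloc[0])}")
    for row in annotation.itertuples(index=False):
        attrs = (
            f"ID={row.gene_id};gc={row.gc:.4f};taxonomy={row.taxonomy};"
            f"categories={row.categories.replace(';', ',')};"
            f"domains={row.domains.replace(';', ',')}"
        )
        lines.append(
            "\t".join(
                [
                    row.scaffold_id,
                    "sppr_omics",
                    "gene",
                    str(int(row.start)),
                    str(int(row.end)),
                    ".",
                    row.strand,
                    ".",
                    attrs,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_annotation_gff3(path) -> pd.DataFrame:
    """Read gene features back from GFF3 (coordinates stay 1-based)."""
    scaffold_len: dict[str, int] = {}
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if line.startswith("##sequence-region"):
            _, sc, _, end = line.split()
            scaffold_len[sc] = int(end)
            continue
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise SchemaError(f"{path}: malformed GFF3 row at line {lineno}")
        sc, _, ftype, start, end, _, strand, _, attrs = fields
        if ftype != "gene":
            continue
        attr = dict(
            kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
        )
        start_i, end_i = int(start), int(end)
        sc_len = scaffold_len.get(sc, end_i)
        rows.append(
            {
                "gene_id": attr["ID"],
                "scaffold_id": sc,
                "start": start_i,
                "end": end_i,
                "strand": strand,
                "length": end_i - start_i + 1,
                "gc": float(attr.get("gc", "nan")),
                "dist_to_end": min(start_i - 1, sc_len - end_i),
                "scaffold_length": sc_len,
                "taxonomy": attr.get("taxonomy", ""),
                "categories": attr.get("categories", "").replace(",", ";"),
                "domains": attr.get("domains", "").replace(",", ";"),
            }
        )
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def read_network(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["gene_id", "metabolite_id"], path)
    return df


def write_network(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def read_similarity(path) -> pd.DataFrame:
    """Blast-tabular-like similarity scores: query, subject, bitscore."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["query", "subject", "bitscore"], path)
    return df


def write_similarity(similarity: pd.DataFrame, path) -> None:
    similarity.to_csv(path, sep="\t", index=False)


def read_cultivations(path) -> list[CultivationRecord]:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, CULTIVATION_COLUMNS, path)
    return [
        CultivationRecord(**{k: row[k] for k in CULTIVATION_COLUMNS})
        for _, row in df.iterrows()
    ]


def write_cultivations(records: Sequence[CultivationRecord], path) -> None:
    pd.DataFrame([asdict(r) for r in records]).to_csv(path, sep="\t", index=False)


def read_pairs(path) -> pd.DataFrame:
    """Transcript-protein fold-change pairs."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(
        df,
        ["protein_id", "gene_id", "comparison", "protein_log2fc", "transcript_log2fc"],
        path,
    )
    return df


def write_pairs(pairs: pd.DataFrame, path) -> None:
    pairs.to_csv(path, sep="\t", index=False)


def read_trac(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["gene_id", "sample_id", "trac_signal", "array_signal"], path)
    return df


def write_trac(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_gene_orders(path) -> pd.DataFrame:
    """Per-species gene orders for the conservation analysis."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(
        df, ["species_id", "scaffold_id", "rank", "gene_id", "domains"], path
    )
    df["domains"] = df["domains"].fillna("")
    return df


def write_clusters_bed(table: pd.DataFrame, path) -> None:
    """Write cluster summaries BED-like (0-based half-open coordinates)."""
    out = table.copy()
    out["start"] = out["start"] - 1  # 1-based inclusive -> 0-based half-open
    out.to_csv(path, sep="\t", index=False)


def read_clusters_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["start"] = df["start"] + 1
    return df
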
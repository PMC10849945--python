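"""Readers and writers for the external formats the pipeline touches.

GFF3 is read/written with the format's 1-based inclusive coordinates and
converted to the internal 0-based half-open convention at the boundary.
FASTA goes through Biopython; tab-separated tables through pandas.
All tables are UTF-8, tab-delimited, with a header row; writers can prepend
``#``-prefixed provenance comment lines which readers skip.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO

from .model import RANKS, AlignmentMatrix, GeneRecord, TaxonomyTable


class GFFParseError(ValueError):
    pass


def _parse_attributes(field: str) -> dict[str, str]:
    out = {}
    for item in field.strip().split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff(path, genome_id: Optional[str] = None) -> list[GeneRecord]:
    """Read CDS features from a GFF3 file into :class:`GeneRecord` objects.

    Coordinates are converted from 1-based inclusive to 0-based half-open.
    ``rank_on_contig`` is assigned per contig by start position (stable on
    ties). Records with ``end <= start`` (after conversion) are rejected
    with a warning; malformed lines raise :class:`GFFParseError` naming the
    line number.

    Recognised attributes: ``ID``/``gene_id`` (required), ``genome_id``,
    ``partial`` / ``is_complete``.
    """
    records: list[GeneRecord] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GFFParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attrs_s = fields
            if ftype != "CDS":
                continue
            try:
                start1 = int(start_s)
                end1 = int(end_s)
            except ValueError:
                raise GFFParseError(
                    f"{path}: line {lineno}: non-integer coordinates "
                    f"({start_s!r}, {end_s!r})"
                ) from None
            if strand not in ("+", "-"):
                raise GFFParseError(
                    f"{path}: line {lineno}: invalid strand {strand!r}"
                )
            attrs = _parse_attributes(attrs_s)
            gid = attrs.get("ID") or attrs.get("gene_id")
            if not gid:
                raise GFFParseError(
                    f"{path}: line {lineno}: CDS feature lacks ID/gene_id attribute"
                )
            start = start1 - 1  # 0-based half-open
            end = end1
            if end <= start:
                warnings.warn(
                    f"{path}: line {lineno}: rejected gene {gid} with "
                    f"end <= start ({start1}..{end1})"
                )
                continue
            complete = attrs.get("is_complete")
            if complete is not None:
                is_complete = complete.lower() in ("1", "true", "yes")
            else:
                # PROKKA/prodigal-style partial=10/01/11 means truncated ends
                is_complete = attrs.get("partial", "00") == "00"
            records.append(
                GeneRecord(
                    gene_id=gid,
                    genome_id=attrs.get("genome_id", genome_id or ""),
                    contig_id=seqid,
                    start=start,
                    end=end,
                    strand=strand,
                    is_complete=is_complete,
                )
            )
    assign_contig_ranks(records)
    return records


def assign_contig_ranks(records: Sequence[GeneRecord]) -> None:
    """Assign ``rank_on_contig`` per (genome, contig) by start position, in place."""
    by_contig: dict[tuple[str, str], list[GeneRecord]] = {}
    for rec in records:
        by_contig.setdefault((rec.genome_id, rec.contig_id), []).append(rec)
    for recs in by_contig.values():
        for i, rec in enumerate(sorted(recs, key=lambda r: r.start)):
            rec.rank_on_contig = i


def write_gff(records: Iterable[GeneRecord], path, header_comments: Sequence[str] = ()) -> None:
    """Write gene records as GFF3 CDS features (1-based inclusive coordinates)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for comment in header_comments:
            fh.write(f"# {comment}\n")
        for rec in records:
            attrs = (
                f"ID={rec.gene_id};genome_id={rec.genome_id};"
                f"is_complete={'true' if rec.is_complete else 'false'}"
            )
            fh.write(
                "\t".join(
                    [
                        rec.contig_id,
                        "magfams",
                        "CDS",
                        str(rec.start + 1),
                        str(rec.end),
                        ".",
                        rec.strand,
                        "0",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_cluster_tsv(path) -> dict[str, list[str]]:
    """Read a two-column (family_id, gene_id) TSV into an ordered membership map.

    Duplicate (family, gene) rows are deduplicated; a gene listed in two
    different families is a hard error (clusters must form a partition).
    """
    families: dict[str, list[str]] = {}
    seen: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected 2 tab-separated columns"
                )
            fam, gene = parts[0], parts[1]
            if fam == "family_id":  # header row
                continue
            if gene in seen:
                if seen[gene] != fam:
                    raise ValueError(
                        f"{path}: gene {gene} assigned to both family "
                        f"{seen[gene]} and {fam}; clusters must be a partition"
                    )
                continue
            seen[gene] = fam
            families.setdefault(fam, []).append(gene)
    return families


def write_cluster_tsv(families: Mapping[str, Sequence[str]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("family_id\tgene_id\n")
        for fam, genes in families.items():
            for gene in genes:
                fh.write(f"{fam}\t{gene}\n")


def read_fasta(path) -> dict[str, str]:
    """Plain (unaligned) FASTA -> id -> sequence."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sid, seq in seqs.items():
            fh.write(f">{sid}\n{seq}\n")


def read_alignment_fasta(path, alphabet: str = "aa") -> AlignmentMatrix:
    """Aligned FASTA -> :class:`AlignmentMatrix`; ragged input raises."""
    ids: list[str] = []
    rows: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq))
    return AlignmentMatrix(ids=ids, rows=rows, alphabet=alphabet)


def parse_lineage(lineage: str, genome_id: str = "?") -> tuple[str, ...]:
    """Split a ';'-separated GTDB lineage string into a 7-rank tuple."""
    parts = tuple(p.strip() for p in lineage.split(";"))
    if len(parts) != len(RANKS) or any(not p for p in parts):
        raise ValueError(
            f"genome {genome_id}: lineage must have {len(RANKS)} ranks, "
            f"got {len(parts)}: {lineage!r}"
        )
    return parts


def read_taxonomy_tsv(path) -> TaxonomyTable:
    """Two-column (genome_id, lineage) TSV; lineage split on ';' into 7 ranks."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if not {"genome_id", "lineage"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns genome_id, lineage")
    return TaxonomyTable(
        {
            row.genome_id: parse_lineage(row.lineage, row.genome_id)
            for row in df.itertuples()
        }
    )


def write_taxonomy_tsv(taxonomy: TaxonomyTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("genome_id\tlineage\n")
        for g in taxonomy.genome_ids:
            fh.write(f"{g}\t{';'.join(taxonomy.lineage(g))}\n")


def read_annotation_tsv(path) -> pd.DataFrame:
    """Per-gene functional annotations.

    Columns: gene_id, pathways (comma-separated KEGG pathway ids, '-' for
    none), optional ko, optional is_resistance (0/1). Returns a DataFrame
    indexed by gene_id with a ``pathways`` column holding frozensets.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("-")
    if "gene_id" not in df.columns or "pathways" not in df.columns:
        raise ValueError(f"{path}: expected columns gene_id, pathways")
    df["pathways"] = df["pathways"].map(
        lambda s: frozenset() if s in ("-", "") else frozenset(s.split(","))
    )
    if "is_resistance" in df.columns:
        df["is_resistance"] = df["is_resistance"].map(
            lambda s: str(s).lower() in ("1", "true", "yes")
        )
    else:
        df["is_resistance"] = False
    if "ko" not in df.columns:
        df["ko"] = "-"
    return df.set_index("gene_id")


def apply_annotations(genes: Iterable[GeneRecord], annotations: pd.DataFrame) -> None:
    """Attach pathway/KO/resistance annotations to gene records in place."""
    for gene in genes:
        if gene.gene_id in annotations.index:
            row = annotations.loc[gene.gene_id]
            gene.pathways = set(row["pathways"])
            gene.ko = None if row["ko"] in ("-", "") else row["ko"]
            gene.is_resistance = bool(row["is_resistance"])


def read_contig_flags_tsv(path) -> dict[str, dict[str, bool]]:
    """Per-contig mobility flags: contig_id -> {'plasmid': bool, 'viral': bool}."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    need = {"contig_id", "is_plasmid", "is_viral"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(need)}")
    out = {}
    for row in df.itertuples():
        out[row.contig_id] = {
            "plasmid": str(row.is_plasmid).lower() in ("1", "true", "yes"),
            "viral": str(row.is_viral).lower() in ("1", "true", "yes"),
        }
    return out


def read_hit_table_tsv(path) -> pd.DataFrame:
    """External homology-search hits: family_id, database, evalue, coverage."""
    df = pd.read_csv(path, sep="\t", comment="#")
    need = {"family_id", "database", "evalue", "coverage"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(need)}")
    return df


def write_results_tsv(df: pd.DataFrame, path, header_comments: Sequence[str] = ()) -> None:
    """Write a results table with ``#``-prefixed provenance comment lines."""
    with open(path, "w", encoding="utf-8") as fh:
        for comment in header_comments:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_results_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
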
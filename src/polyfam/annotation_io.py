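"""Readers and writers for the standard formats the pipeline touches.

GFF3 parsing is delegated to :mod:`gffutils`; tabular formats go through
pandas; protein FASTA through Biopython. Gene models come back with a
per-chromosome rank index (1-based ordinal by ascending start) computed over
*all* genes in the annotation, which the tandem-duplication rule depends on.
"""
from __future__ import annotations

import io
import warnings
from typing import Iterable, TextIO

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO

from .models import (
    DomainHit,
    ExpressionMatrix,
    GeneModel,
    ProteinRecord,
    SyntenyPair,
    ValidationError,
)


class ParseError(ValueError):
    """A stream could not be parsed; the message names the offending line."""


def _as_text(stream: TextIO | str) -> str:
    if hasattr(stream, "read"):
        return stream.read()
    return str(stream)


def _as_handle(stream: TextIO | str) -> tuple[TextIO, bool]:
    """(handle, owned): open paths ourselves and close them after use."""
    if hasattr(stream, "read"):
        return stream, False
    return open(stream), True


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_GENE_TYPES = {"gene"}
_EXON_TYPES = {"exon"}
_CDS_TYPES = {"CDS"}


def _merge_intervals(intervals: list[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    """Union of possibly-overlapping segments (e.g. exons of several mRNAs)."""
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


def assign_ranks(genes: Iterable[GeneModel]) -> list[GeneModel]:
    """Return genes with per-chromosome ranks, sorted by (chrom, start).

    Rank order is ascending start, ties broken by end then gene_id, so the
    ordering (and thus the tandem rule downstream) is deterministic.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    out: list[GeneModel] = []
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda g: (g.start, g.end, g.gene_id))
        for i, g in enumerate(ordered, start=1):
            out.append(GeneModel(g.gene_id, g.chrom, g.start, g.end, g.strand, g.exons, rank=i))
    return out


def parse_gff3(stream: TextIO | str) -> list[GeneModel]:
    """Parse gene models from GFF3 text, a path-like string, or a handle.

    One :class:`GeneModel` per ``gene`` feature; exon structure is the merged
    union of ``exon`` children, falling back to ``CDS`` segments for genes
    annotated without exon features. Output is sorted by (chrom, start) with
    ranks assigned per chromosome over all parsed genes. Records whose end
    precedes their start are rejected with a warning; structurally malformed
    lines raise :class:`ParseError` naming the line number.
    """
    text = _as_text(stream)
    if "\t" not in text and "\n" not in text and not text.startswith("#"):
        # probably a filesystem path
        try:
            with open(text) as fh:
                text = fh.read()
        except OSError:
            pass

    kept_lines: list[str] = []
    rejected_ids: set[str] = set()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ParseError(f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}")
        try:
            start, end = int(fields[3]), int(fields[4])
        except ValueError:
            raise ParseError(f"line {lineno}: non-integer coordinates {fields[3]!r}/{fields[4]!r}")
        if end < start:
            warnings.warn(f"line {lineno}: end < start, record rejected", stacklevel=2)
            rejected_ids.add(line)
            continue
        kept_lines.append(line)

    if not kept_lines:
        return []

    db = gffutils.create_db(
        "\n".join(kept_lines),
        dbfn=":memory:",
        from_string=True,
        merge_strategy="create_unique",
        keep_order=True,
    )

    genes: list[GeneModel] = []
    for feat in db.features_of_type(tuple(_GENE_TYPES)):
        exon_ivals = [(c.start, c.end) for c in db.children(feat, featuretype=tuple(_EXON_TYPES))]
        if not exon_ivals:
            exon_ivals = [(c.start, c.end) for c in db.children(feat, featuretype=tuple(_CDS_TYPES))]
        if not exon_ivals:
            exon_ivals = [(feat.start, feat.end)]
        genes.append(
            GeneModel(
                gene_id=feat.id,
                chrom=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand if feat.strand in ("+", "-") else "+",
                exons=_merge_intervals(exon_ivals),
            )
        )
    return assign_ranks(genes)


def write_gff3(genes: Iterable[GeneModel], handle: TextIO) -> None:
    """Write gene models (gene + exon features) as GFF3."""
    handle.write("##gff-version 3\n")
    for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
        handle.write(
            f"{g.chrom}\tpolyfam\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
        )
        for i, (s, e) in enumerate(g.exons, start=1):
            handle.write(
                f"{g.chrom}\tpolyfam\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
            )


def count_introns(gene: GeneModel) -> int:
    """Number of introns = number of exons - 1."""
    if not gene.exons:
        raise ValidationError(f"{gene.gene_id}: gene has no exons")
    return len(gene.exons) - 1


# ---------------------------------------------------------------------------
# Protein FASTA
# ---------------------------------------------------------------------------

def read_fasta_proteins(stream: TextIO | str) -> list[ProteinRecord]:
    """Read protein records; id is the first header token.

    A ``gene=`` key in the description overrides the gene id, which otherwise
    defaults to the protein id.
    """
    handle, owned = _as_handle(stream)
    try:
        records = []
        for rec in SeqIO.parse(handle, "fasta"):
            gene_id = rec.id
            for token in rec.description.split():
                if token.startswith("gene="):
                    gene_id = token[len("gene="):]
            seq = str(rec.seq).upper().rstrip("*")
            records.append(ProteinRecord(protein_id=rec.id, gene_id=gene_id, sequence=seq))
        return records
    finally:
        if owned:
            handle.close()


def write_fasta_proteins(records: Iterable[ProteinRecord], handle: TextIO) -> None:
    for rec in records:
        header = rec.protein_id
        if rec.gene_id != rec.protein_id:
            header += f" gene={rec.gene_id}"
        handle.write(f">{header}\n{rec.sequence}\n")


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def read_expression_matrix(stream: TextIO | str) -> ExpressionMatrix:
    """Read a genes x conditions FPKM table (TSV, header row, first col ids)."""
    handle, owned = _as_handle(stream)
    try:
        df = pd.read_csv(handle, sep="\t", index_col=0)
    finally:
        if owned:
            handle.close()
    df.index = df.index.astype(str)
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index
            raise ValidationError(
                f"non-numeric value at gene {bad[0]!r}, condition {col!r}"
            )
    return ExpressionMatrix(df.astype(float))


def write_expression_matrix(matrix: ExpressionMatrix, handle: TextIO) -> None:
    matrix.df.to_csv(handle, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# Synteny tables
# ---------------------------------------------------------------------------

_SYNTENY_COLS = ["gene_a", "gene_b", "block_id", "ks"]


def read_synteny_table(stream: TextIO | str) -> list[SyntenyPair]:
    """Read syntenic paralog pairs (TSV: gene_a, gene_b, block_id, ks).

    Rows with negative, non-numeric or NaN Ks, and self-pairs, are dropped
    with a warning. Pair order is canonicalized (smaller id first).
    """
    handle, owned = _as_handle(stream)
    try:
        df = pd.read_csv(handle, sep="\t", dtype=str)
    finally:
        if owned:
            handle.close()
    missing = [c for c in _SYNTENY_COLS if c not in df.columns]
    if missing:
        raise ParseError(f"synteny table missing columns: {missing}")
    pairs: list[SyntenyPair] = []
    for row in df.itertuples(index=False):
        try:
            ks = float(row.ks)
        except (TypeError, ValueError):
            ks = float("nan")
        a, b = str(row.gene_a), str(row.gene_b)
        if not np.isfinite(ks) or ks < 0:
            warnings.warn(f"row {a}/{b}: invalid ks {row.ks!r}, dropped", stacklevel=2)
            continue
        if a == b:
            warnings.warn(f"self-pair {a} dropped", stacklevel=2)
            continue
        pairs.append(SyntenyPair(gene_a=a, gene_b=b, block_id=str(row.block_id), ks=float(ks)))
    return pairs


def write_synteny_table(pairs: Iterable[SyntenyPair], handle: TextIO, with_event: bool = False) -> None:
    cols = _SYNTENY_COLS + (["event"] if with_event else [])
    handle.write("\t".join(cols) + "\n")
    for p in pairs:
        row = [p.gene_a, p.gene_b, p.block_id, repr(p.ks)]
        if with_event:
            row.append(p.event)
        handle.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Domain tables (HMMER3 domtblout dialect)
# ---------------------------------------------------------------------------

def parse_domtbl(stream: TextIO | str) -> list[DomainHit]:
    """Parse per-domain rows from a domain table in the HMMER3 dialect.

    Whitespace-delimited, 22+ columns; ``#`` lines are comments. Uses the
    envelope coordinates (columns 20-21) and the per-domain bit score
    (column 14). A truncated row raises :class:`ParseError` with its line
    number. Hits carry no aligned string (the table does not record one).
    """
    text = _as_text(stream)
    hits: list[DomainHit] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 22:
            raise ParseError(f"line {lineno}: truncated domain-table row ({len(fields)} columns)")
        try:
            score = float(fields[13])
            env_from, env_to = int(fields[19]), int(fields[20])
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}")
        hits.append(
            DomainHit(
                protein_id=fields[0],
                domain=fields[3],
                start=env_from,
                end=env_to,
                score=score,
            )
        )
    return hits
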
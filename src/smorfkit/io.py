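"""Readers and writers for the plain-text formats the pipeline consumes.

FASTA goes through Biopython; transcriptional-unit tables, count matrices and
catalogues are TSV via pandas; GFF3 CDS annotation uses a minimal reader and
writer (only CDS features with ``locus_tag``/``gene``/``product`` attributes
are needed; GFF3 is 1-based inclusive like the internal model).
"""

from __future__ import annotations

import urllib.parse
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .coords import (
    CdsRecord,
    GenomeRecord,
    GenomicInterval,
    TranscriptionalUnit,
)


class ParseError(ValueError):
    """Malformed input table; the message names the offending line."""


# ---------------------------------------------------------------- FASTA

def read_genome_fasta(path) -> list[GenomeRecord]:
    return [
        GenomeRecord(replicon_id=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_genome_fasta(genomes: Iterable[GenomeRecord], path) -> None:
    records = [
        SeqRecord(Seq(g.sequence), id=g.replicon_id, description="")
        for g in genomes
    ]
    SeqIO.write(records, str(path), "fasta")


def read_protein_fasta(path, source_set: str = ""):
    """Protein FASTA as a list of :class:`~smorfkit.orthology.ProteinRecord`."""
    from .orthology import ProteinRecord

    return [
        ProteinRecord(id=rec.id, sequence=str(rec.seq), source_set=source_set)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_protein_fasta(proteins, path) -> None:
    records = [SeqRecord(Seq(p.sequence), id=p.id, description="") for p in proteins]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------- GFF3

_GFF_COLS = 9


def read_gff3_cds(path) -> list[CdsRecord]:
    """CDS features from a GFF3 file.

    The GFF3 convention for a CDS is to include the stop codon in the span;
    records are created with ``includes_stop=True``.
    """
    out: list[CdsRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != _GFF_COLS:
                raise ParseError(f"{path}:{lineno}: expected 9 columns, got {len(fields)}")
            seqid, _source, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype != "CDS":
                continue
            try:
                interval = GenomicInterval(seqid, int(start), int(end), strand)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            attr = {}
            for item in attrs.split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    attr[k.strip()] = urllib.parse.unquote(v.strip())
            locus = attr.get("locus_tag") or attr.get("ID") or f"cds_{lineno}"
            out.append(
                CdsRecord(
                    interval=interval,
                    includes_stop=True,
                    locus_tag=locus,
                    gene_name=attr.get("gene"),
                    product=attr.get("product"),
                )
            )
    return out


def write_gff3_cds(records: Iterable[CdsRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in records:
            attrs = [f"ID={rec.locus_tag}", f"locus_tag={rec.locus_tag}"]
            if rec.gene_name:
                attrs.append(f"gene={rec.gene_name}")
            if rec.product:
                attrs.append("product=" + urllib.parse.quote(rec.product, safe=" "))
            iv = rec.interval
            fh.write(
                "\t".join(
                    [
                        iv.replicon_id,
                        "smorfkit",
                        "CDS",
                        str(iv.start),
                        str(iv.end),
                        ".",
                        iv.strand,
                        "0",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------- TU tables

TU_COLUMNS = ["tu_id", "replicon", "start", "end", "strand", "tss", "category"]


def read_tu_table(path) -> list[TranscriptionalUnit]:
    """TSV with columns tu_id, replicon, start, end, strand, tss, category.

    Reverse-strand rows may list end < start; the span is normalized.  A
    malformed row raises :class:`ParseError` naming the line number.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        return []
    missing = [c for c in TU_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    tus = []
    for idx, row in df.iterrows():
        lineno = idx + 2  # header is line 1
        try:
            interval = GenomicInterval(
                str(row["replicon"]), int(row["start"]), int(row["end"]), str(row["strand"])
            )
            tus.append(
                TranscriptionalUnit(
                    tu_id=str(row["tu_id"]),
                    interval=interval,
                    tss_position=int(row["tss"]),
                    category=str(row["category"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return tus


def write_tu_table(tus: Sequence[TranscriptionalUnit], path) -> None:
    rows = [
        {
            "tu_id": tu.tu_id,
            "replicon": tu.replicon_id,
            "start": tu.interval.start,
            "end": tu.interval.end,
            "strand": tu.strand,
            "tss": tu.tss_position,
            "category": tu.category,
        }
        for tu in tus
    ]
    pd.DataFrame(rows, columns=TU_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- counts

def read_counts(path) -> pd.DataFrame:
    """Condition x TU count matrix: rows indexed by tu_id, one column per condition."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise ParseError(f"{path}: negative counts")
    return df


def write_counts(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------- alignments

def read_alignment(path, frame_offset: int = 0):
    """An aligned FASTA or Clustal file as a :class:`~smorfkit.coding.CodonAlignment`.

    The first row is taken as the reference (candidate) sequence.  Format is
    chosen by extension: .aln/.clustal/.clw read as Clustal, else FASTA.
    """
    from Bio import AlignIO

    from .coding import CodonAlignment

    fmt = "clustal" if str(path).endswith((".aln", ".clustal", ".clw")) else "fasta"
    msa = AlignIO.read(str(path), fmt)
    return CodonAlignment(
        rows=tuple(str(rec.seq) for rec in msa),
        frame_offset=frame_offset,
        ids=tuple(rec.id for rec in msa),
    )


# ---------------------------------------------------------------- catalogue

CATALOGUE_COLUMNS = [
    "candidate_id",
    "replicon",
    "start",
    "end",
    "strand",
    "length_aa",
    "locus_tag",
    "gene",
    "product",
    "parent_tu",
]


def write_catalogue(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_catalogue(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
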
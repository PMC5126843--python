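"""Genomic coordinate model shared by every pipeline stage.

Coordinates are 1-based and inclusive on both ends, matching GenBank
conventions.  Reverse-strand features may be supplied with ``end < start``
(as published catalogues sometimes list them); intervals normalize to
``start <= end`` internally and carry the strand separately, so the span
``|end - start| + 1`` is orientation-free.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

from Bio.Seq import Seq

STRANDS = ("+", "-")


class CoordinateError(ValueError):
    """Invalid genomic coordinates (bounds, strand or orientation)."""


class FrameError(ValueError):
    """A CDS span that is not a whole number of codons."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A strand-aware interval on one replicon (1-based, inclusive)."""

    replicon_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise CoordinateError(f"strand must be one of {STRANDS}, got {self.strand!r}")
        lo, hi = sorted((int(self.start), int(self.end)))
        if lo < 1:
            raise CoordinateError(f"positions are 1-based, got start={self.start}, end={self.end}")
        object.__setattr__(self, "start", lo)
        object.__setattr__(self, "end", hi)

    @property
    def span_nt(self) -> int:
        return self.end - self.start + 1

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.replicon_id == other.replicon_id
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlap_nt(self, other: "GenomicInterval") -> int:
        """Number of shared bases; 0 for disjoint intervals or different replicons."""
        if self.replicon_id != other.replicon_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.overlap_nt(other) > 0

    @property
    def five_prime(self) -> int:
        """Genomic position of the 5' end on this interval's strand."""
        return self.start if self.strand == "+" else self.end

    @property
    def three_prime(self) -> int:
        return self.end if self.strand == "+" else self.start


@dataclass(frozen=True)
class CdsRecord:
    """An annotated (or candidate) protein-coding span.

    ``includes_stop`` is mandatory and never inferred: published coordinate
    tables mix both conventions, and the protein length depends on it.
    """

    interval: GenomicInterval
    includes_stop: bool
    locus_tag: str
    gene_name: Optional[str] = None
    product: Optional[str] = None

    def __post_init__(self) -> None:
        if self.interval.span_nt % 3 != 0:
            raise FrameError(
                f"{self.locus_tag}: span {self.interval.span_nt} nt is not a whole number of codons"
            )

    @property
    def protein_length_aa(self) -> int:
        return cds_protein_length(self)


def cds_protein_length(cds: CdsRecord) -> int:
    """Protein length in amino acids implied by a CDS span.

    A span that includes the stop codon encodes ``span/3 - 1`` residues;
    a stop-free span encodes ``span/3``.  Symmetric in start/end.
    """
    span = cds.interval.span_nt
    if span % 3 != 0:
        raise FrameError(f"span {span} nt is not a whole number of codons")
    if cds.includes_stop:
        if span < 6:
            raise CoordinateError("a stop-inclusive CDS must span at least two codons")
        return span // 3 - 1
    return span // 3


def utr5_length(tss: int, cds_start_position: int, strand: str) -> int:
    """Number of transcribed nucleotides preceding the first CDS base.

    0 means a leaderless transcript.  ``cds_start_position`` is the genomic
    position of the first base of the start codon on the given strand.
    """
    if strand not in STRANDS:
        raise CoordinateError(f"strand must be one of {STRANDS}")
    d = cds_start_position - tss if strand == "+" else tss - cds_start_position
    if d < 0:
        raise CoordinateError(
            f"TSS {tss} lies downstream of CDS start {cds_start_position} on strand {strand}"
        )
    return d


@dataclass(frozen=True)
class GenomeRecord:
    """A replicon sequence; ``topology='circular'`` allows wrap-around reads."""

    replicon_id: str
    sequence: str
    topology: str = "linear"

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise ValueError(f"{self.replicon_id}: empty sequence")
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(f"{self.replicon_id}: non-nucleotide characters {sorted(bad)}")
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"topology must be linear or circular, got {self.topology!r}")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


def extract_sequence(genome: GenomeRecord, interval: GenomicInterval) -> str:
    """Strand-corrected sequence of ``interval`` (reverse-complemented for '-').

    On linear replicons the interval must fit inside the sequence; on circular
    replicons an ``end`` past the sequence length wraps around the origin.
    """
    n = len(genome)
    if interval.start < 1:
        raise CoordinateError("interval start below 1")
    if interval.end > n:
        if genome.topology != "circular":
            raise CoordinateError(
                f"interval {interval.start}-{interval.end} exceeds linear replicon "
                f"{genome.replicon_id} of length {n}"
            )
        if interval.span_nt > n:
            raise CoordinateError("wrap-around interval longer than the replicon")
        doubled = genome.sequence + genome.sequence
        seq = doubled[interval.start - 1 : interval.end]
    else:
        seq = genome.sequence[interval.start - 1 : interval.end]
    if interval.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


TU_CATEGORIES = ("coding", "non-coding", "mixed")


@dataclass(frozen=True)
class TranscriptionalUnit:
    """A transcribed region anchored at its primary TSS.

    The TSS sits at the 5' end of the interval on the TU's strand (that is
    how TUs are delimited from differential RNA-seq data).
    """

    tu_id: str
    interval: GenomicInterval
    tss_position: int
    category: str = "coding"

    def __post_init__(self) -> None:
        if self.category not in TU_CATEGORIES:
            raise ValueError(f"category must be one of {TU_CATEGORIES}")
        if self.tss_position != self.interval.five_prime:
            raise CoordinateError(
                f"{self.tu_id}: TSS {self.tss_position} is not the 5' end of "
                f"{self.interval.start}-{self.interval.end} ({self.interval.strand})"
            )

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def replicon_id(self) -> str:
        return self.interval.replicon_id
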
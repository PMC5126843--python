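"""Stage 1: candidate small ORFs inside transcribed intergenic regions.

The transcriptional-unit (TU) map tells us which genomic stretches are
expressed; subtracting annotated CDS leaves transcribed intergenic sequence,
which is scanned for short open reading frames on the TU's strand.  Only the
longest ORF per stop codon within a frame is reported, truncated ORFs (no
in-region stop) are dropped, and the amino-acid length is capped (default 80,
the conventional upper bound for bacterial mu-proteins).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .coords import CdsRecord, GenomeRecord, GenomicInterval, TranscriptionalUnit, extract_sequence

DEFAULT_MIN_LEN_AA = 15
DEFAULT_MAX_LEN_AA = 80
DEFAULT_START_CODONS = ("ATG",)
STOP_CODONS = ("TAA", "TAG", "TGA")


class AlphabetError(ValueError):
    """Sequence contains characters outside {A, C, G, T}."""


class RepliconMismatchError(KeyError):
    """TU table and annotation do not share replicon identifiers."""


@dataclass(frozen=True)
class IntergenicTranscribedRegion:
    """A maximal transcribed sub-interval free of annotated CDS overlap."""

    interval: GenomicInterval
    parent_tu_id: str


@dataclass(frozen=True)
class OrfCandidate:
    """A candidate small ORF; the interval and nt_sequence include the stop codon."""

    interval: GenomicInterval
    parent_tu_id: str
    nt_sequence: str
    aa_length: int

    def __post_init__(self) -> None:
        if len(self.nt_sequence) != self.interval.span_nt:
            raise ValueError("nt_sequence length disagrees with interval span")
        if len(self.nt_sequence) % 3 != 0:
            raise ValueError("ORF length must be a whole number of codons")


def transcribed_intergenic_regions(
    tus: Sequence[TranscriptionalUnit],
    annotation: Sequence[CdsRecord],
    overlap_tolerance_nt: int = 0,
) -> list[IntergenicTranscribedRegion]:
    """Maximal sub-intervals of each TU not covered by annotated CDS.

    CDS on either strand mask the TU (an ORF overlapping annotation is not
    "intergenic" regardless of orientation).  ``overlap_tolerance_nt`` allows
    that many bases of overlap at each CDS edge.  Output is sorted by
    (replicon, start, parent TU).
    """
    tu_replicons = {tu.replicon_id for tu in tus}
    cds_replicons = {c.interval.replicon_id for c in annotation}
    if tus and annotation and not (tu_replicons & cds_replicons):
        raise RepliconMismatchError(
            f"no shared replicons between TUs {sorted(tu_replicons)} "
            f"and annotation {sorted(cds_replicons)}"
        )
    regions: list[IntergenicTranscribedRegion] = []
    for tu in tus:
        blocks = []
        for cds in annotation:
            iv = cds.interval
            if iv.replicon_id != tu.replicon_id or not iv.overlaps(tu.interval):
                continue
            lo = max(iv.start + overlap_tolerance_nt, tu.interval.start)
            hi = min(iv.end - overlap_tolerance_nt, tu.interval.end)
            if lo <= hi:
                blocks.append((lo, hi))
        blocks.sort()
        merged: list[list[int]] = []
        for lo, hi in blocks:
            if merged and lo <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], hi)
            else:
                merged.append([lo, hi])
        cursor = tu.interval.start
        pieces = []
        for lo, hi in merged:
            if cursor < lo:
                pieces.append((cursor, lo - 1))
            cursor = hi + 1
        if cursor <= tu.interval.end:
            pieces.append((cursor, tu.interval.end))
        for lo, hi in pieces:
            regions.append(
                IntergenicTranscribedRegion(
                    interval=GenomicInterval(tu.replicon_id, lo, hi, tu.strand),
                    parent_tu_id=tu.tu_id,
                )
            )
    regions.sort(key=lambda r: (r.interval.replicon_id, r.interval.start, r.parent_tu_id))
    return regions


def scan_orfs(
    region_sequence: str,
    min_len_aa: int = DEFAULT_MIN_LEN_AA,
    max_len_aa: int = DEFAULT_MAX_LEN_AA,
    start_codons: Sequence[str] = DEFAULT_START_CODONS,
) -> list[tuple[int, int, int]]:
    """ORFs in the given (already strand-oriented) sequence, all three frames.

    Returns ``(start_idx, end_idx, aa_length)`` tuples with 0-based inclusive
    indices into ``region_sequence``; the end index is the last base of the
    stop codon.  Within a frame only the longest ORF per stop (earliest start
    codon since the previous stop) is reported.  ``aa_length`` excludes the
    stop codon.
    """
    seq = region_sequence.upper()
    bad = set(seq) - set("ACGT")
    if bad:
        raise AlphabetError(f"non-nucleotide characters {sorted(bad)}")
    if min_len_aa < 1:
        raise ValueError("min_len_aa must be >= 1")
    starts = {s.upper() for s in start_codons}
    hits = []
    n = len(seq)
    for frame in range(3):
        open_start: Optional[int] = None
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if codon in STOP_CODONS:
                if open_start is not None:
                    aa = (i - open_start) // 3
                    if min_len_aa <= aa <= max_len_aa:
                        hits.append((open_start, i + 2, aa))
                open_start = None
            elif open_start is None and codon in starts:
                open_start = i
        # an ORF still open at the region boundary has no in-region stop: dropped
    hits.sort()
    return hits


def find_candidate_orfs(
    genomes: dict[str, GenomeRecord],
    regions: Sequence[IntergenicTranscribedRegion],
    min_len_aa: int = DEFAULT_MIN_LEN_AA,
    max_len_aa: int = DEFAULT_MAX_LEN_AA,
    start_codons: Sequence[str] = DEFAULT_START_CODONS,
) -> list[OrfCandidate]:
    """Scan every region on its transcribed strand and map ORFs to genome coordinates."""
    candidates = []
    for region in regions:
        iv = region.interval
        genome = genomes[iv.replicon_id]
        seq = extract_sequence(genome, iv)
        for s, e, aa in scan_orfs(seq, min_len_aa, max_len_aa, start_codons):
            if iv.strand == "+":
                g_start, g_end = iv.start + s, iv.start + e
            else:
                g_start, g_end = iv.end - e, iv.end - s
            candidates.append(
                OrfCandidate(
                    interval=GenomicInterval(iv.replicon_id, g_start, g_end, iv.strand),
                    parent_tu_id=region.parent_tu_id,
                    nt_sequence=seq[s : e + 1],
                    aa_length=aa,
                )
            )
    candidates.sort(key=lambda c: (c.interval.replicon_id, c.interval.start, c.interval.strand))
    return candidates


def merge_with_annotation(
    candidates: Iterable[OrfCandidate],
    annotation: Sequence[CdsRecord] = (),
    novel_prefix: Optional[dict[str, str]] = None,
) -> pd.DataFrame:
    """Merge candidates with pre-existing annotation into a catalogue table.

    Candidates whose coordinates coincide with an annotated CDS adopt its
    locus_tag / gene / product; novel candidates receive generated ids such as
    ``Chr_ORF_1`` (prefix per replicon; defaults to the replicon id).
    Duplicate candidates (identical coordinates, e.g. from overlapping TUs)
    collapse to one row.
    """
    by_coords = {}
    for cds in annotation:
        iv = cds.interval
        by_coords[(iv.replicon_id, iv.start, iv.end, iv.strand)] = cds
    novel_prefix = novel_prefix or {}
    seen: dict[tuple, dict] = {}
    counters: dict[str, int] = {}
    ordered = sorted(
        candidates, key=lambda c: (c.interval.replicon_id, c.interval.start, c.interval.end, c.interval.strand)
    )
    for cand in ordered:
        iv = cand.interval
        key = (iv.replicon_id, iv.start, iv.end, iv.strand)
        if key in seen:
            continue
        cds = by_coords.get(key)
        if cds is not None:
            cid, locus, gene, product = cds.locus_tag, cds.locus_tag, cds.gene_name, cds.product
        else:
            prefix = novel_prefix.get(iv.replicon_id, iv.replicon_id)
            counters[prefix] = counters.get(prefix, 0) + 1
            cid = f"{prefix}_ORF_{counters[prefix]}"
            locus, gene, product = None, None, None
        seen[key] = {
            "candidate_id": cid,
            "replicon": iv.replicon_id,
            "start": iv.start,
            "end": iv.end,
            "strand": iv.strand,
            "length_aa": cand.aa_length,
            "locus_tag": locus,
            "gene": gene,
            "product": product,
            "parent_tu": cand.parent_tu_id,
            "nt_sequence": cand.nt_sequence,
        }
    return pd.DataFrame(
        list(seen.values()),
        columns=[
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
            "nt_sequence",
        ],
    )
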
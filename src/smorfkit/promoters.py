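"""Promoter annotation: 5'UTR geometry and NtcA-binding-site positioning.

NtcA, the cyanobacterial nitrogen-control regulator, binds a palindromic
GTA-N8-TAC-like site; when it activates transcription the site center sits
close to -41.5 relative to the transcriptional start site (TSS), overlapping
the -35 promoter element.  The scan reports, for every motif match on the
transcribed strand, the site center relative to the TSS.  The TSS is +1 and
there is no position 0, so an even-length site centered between two upstream
bases has a half-integer center (e.g. -41.5); because the field's shorthand
often floors this to a whole number of nucleotides ("centered 42 nt
upstream"), both conventions are reported.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass
from typing import Optional

from .coords import GenomeRecord, GenomicInterval, extract_sequence

DEFAULT_ACTIVATION_CENTER = -41.5
DEFAULT_ACTIVATION_HALFWIDTH = 4.0
DEFAULT_UPSTREAM_NT = 60


@dataclass(frozen=True)
class MotifModel:
    """Anchored triplet-spacer-triplet motif (default: the NtcA consensus
    GTA-N8-[GT]AC, a 14-nt site)."""

    name: str = "NtcA"
    pattern: str = "GTA[ACGT]{8}[GT]AC"
    site_length: int = 14

    @classmethod
    def exact(cls, site: str, name: str = "exact") -> "MotifModel":
        return cls(name=name, pattern=re.escape(site.upper()), site_length=len(site))


@dataclass(frozen=True)
class MotifHit:
    """One motif match on the transcribed strand.

    ``center_offset`` is the half-integer site center on the TSS = +1 axis
    (negative = upstream); ``floor_offset`` is the same center floored to a
    whole nucleotide, matching the "centered N nt upstream" convention.
    """

    matched_sequence: str
    center_offset: float
    floor_offset: int
    interval: Optional[GenomicInterval] = None

    @property
    def classification(self) -> str:
        return classify_activation_geometry(self)


def _relative_position(index: int, tss_index: int) -> int:
    """Map a 0-based sequence index to the 1-based no-zero TSS axis."""
    d = index - tss_index
    return d + 1 if d >= 0 else d


def scan_motif(
    promoter_sequence: str,
    tss_index: int,
    model: Optional[MotifModel] = None,
) -> list[MotifHit]:
    """All motif matches in a promoter sequence given on the transcribed strand.

    ``tss_index`` is the 0-based index of the TSS base (+1) within
    ``promoter_sequence``.  Matches may overlap.  If fewer than 60 nt upstream
    of the TSS are available a coverage warning is issued and the available
    span is scanned.
    """
    model = model or MotifModel()
    seq = promoter_sequence.upper()
    if not 0 <= tss_index < len(seq):
        raise ValueError("tss_index outside the promoter sequence")
    if tss_index < DEFAULT_UPSTREAM_NT:
        warnings.warn(
            f"only {tss_index} nt upstream of the TSS available "
            f"(< {DEFAULT_UPSTREAM_NT}); scanning the available span",
            stacklevel=2,
        )
    hits = []
    for m in re.finditer(f"(?=({model.pattern}))", seq):
        site = m.group(1)
        first = _relative_position(m.start(), tss_index)
        last = _relative_position(m.start() + len(site) - 1, tss_index)
        # half-integer center on a continuous axis: average after removing the
        # gap between -1 and +1 (there is no position 0)
        cont = [p if p < 0 else p - 1 for p in (first, last)]
        center_cont = (cont[0] + cont[1]) / 2.0
        center = center_cont if center_cont < 0 else center_cont + 1
        hits.append(
            MotifHit(
                matched_sequence=site,
                center_offset=center,
                floor_offset=math.floor(center),
            )
        )
    return hits


def scan_promoter(
    genome: GenomeRecord,
    tss_position: int,
    strand: str,
    model: Optional[MotifModel] = None,
    upstream_nt: int = DEFAULT_UPSTREAM_NT,
    downstream_nt: int = 5,
) -> list[MotifHit]:
    """Scan the promoter region of a TSS on its transcribed strand.

    Extracts ``upstream_nt`` bases upstream and ``downstream_nt`` downstream
    of the TSS (clipped to the replicon), scans on the transcribed strand and
    maps hits back to genomic coordinates.
    """
    model = model or MotifModel()
    n = len(genome)
    if strand == "+":
        lo = max(1, tss_position - upstream_nt)
        hi = min(n, tss_position + downstream_nt)
        tss_index = tss_position - lo
    else:
        lo = max(1, tss_position - downstream_nt)
        hi = min(n, tss_position + upstream_nt)
        tss_index = hi - tss_position
    window = GenomicInterval(genome.replicon_id, lo, hi, strand)
    seq = extract_sequence(genome, window)
    hits = scan_motif(seq, tss_index, model)
    out = []
    for hit, m in zip(hits, re.finditer(f"(?=({model.pattern}))", seq)):
        s = m.start()
        e = s + len(m.group(1)) - 1
        if strand == "+":
            g_lo, g_hi = lo + s, lo + e
        else:
            g_lo, g_hi = hi - e, hi - s
        out.append(
            MotifHit(
                matched_sequence=hit.matched_sequence,
                center_offset=hit.center_offset,
                floor_offset=hit.floor_offset,
                interval=GenomicInterval(genome.replicon_id, g_lo, g_hi, strand),
            )
        )
    return out


def classify_activation_geometry(
    hit: MotifHit,
    center: float = DEFAULT_ACTIVATION_CENTER,
    halfwidth: float = DEFAULT_ACTIVATION_HALFWIDTH,
) -> str:
    """'activating-range' iff the site center lies within ``halfwidth`` of the
    canonical activating position (default -41.5, i.e. [-45.5, -37.5])."""
    if center - halfwidth <= hit.center_offset <= center + halfwidth:
        return "activating-range"
    return "other"
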
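"""Physicochemical characterization of candidate mu-proteins.

Covers translation (bacterial genetic code), average molecular weight,
isoelectric point (Henderson-Hasselbalch net charge, solved by bisection with
an injectable pKa table), hydropathy-based transmembrane segment prediction
(Kyte-Doolittle sliding window), and C-terminal epitope-tag fusion arithmetic
for the 3xFLAG tag used in immunodetection of small proteins.

Transmembrane prediction here is a documented hydropathy-window method, not a
trained topology HMM; only the segment count should be compared across methods
and the report metadata says so.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.SeqUtils import molecular_weight as _bio_molecular_weight

WATER_DA = 18.0153

# the 69-nt triple-FLAG coding sequence used for C-terminal tagging
FLAG_3X_DNA = (
    "ATGGATTATAAAGATCATGATGGCGATTATAAAGATCATGATATTGATTATAAAGATGATGATGATAAA"
)

_TABLE11 = unambiguous_dna_by_id[11]

# Bjellqvist pKa values (ExPASy convention), including the residue-specific
# terminal pKa corrections of the original method
DEFAULT_PKA = {
    "Nterm": 7.5,
    "Cterm": 3.55,
    "D": 4.05,
    "E": 4.45,
    "C": 9.0,
    "Y": 10.0,
    "H": 5.98,
    "K": 10.0,
    "R": 12.0,
    "nterm_overrides": {"A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44, "E": 7.7},
    "cterm_overrides": {"D": 4.55, "E": 4.75},
}

KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

DEFAULT_TM_WINDOW = 19
DEFAULT_TM_THRESHOLD = 1.6
DEFAULT_TM_MERGE_GAP = 5


class InternalStopError(ValueError):
    """Stop codon before the end of the coding sequence."""


class AlphabetError(ValueError):
    """Residue or base outside the accepted alphabet."""


class Translation(NamedTuple):
    peptide: str
    had_terminal_stop: bool


def translate(dna: str, readthrough: bool = False) -> Translation:
    """Translate a frame-0 coding sequence with the bacterial genetic code.

    A trailing stop codon is removed and recorded; an internal stop raises
    :class:`InternalStopError` unless ``readthrough`` keeps it as ``*``.
    """
    seq = dna.upper()
    if len(seq) % 3 != 0 or not seq:
        raise ValueError(f"length {len(seq)} is not a whole number of codons")
    bad = set(seq) - set("ACGT")
    if bad:
        raise AlphabetError(f"non-nucleotide characters {sorted(bad)}")
    residues = []
    n_codons = len(seq) // 3
    had_stop = False
    for i in range(n_codons):
        codon = seq[3 * i : 3 * i + 3]
        if codon in _TABLE11.stop_codons:
            if i == n_codons - 1:
                had_stop = True
            elif readthrough:
                residues.append("*")
            else:
                raise InternalStopError(f"internal stop codon {codon} at codon {i + 1}")
        else:
            residues.append(_TABLE11.forward_table[codon])
    return Translation(peptide="".join(residues), had_terminal_stop=had_stop)


def molecular_weight_kda(aa_sequence: str) -> float:
    """Average molecular mass in kDa (residue masses + one water)."""
    seq = aa_sequence.upper()
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - set(KYTE_DOOLITTLE)
    if bad:
        raise AlphabetError(f"unknown residues {sorted(bad)} (X is not allowed for mass)")
    return _bio_molecular_weight(seq, seq_type="protein", monoisotopic=False) / 1000.0


def net_charge(aa_sequence: str, ph: float, pka_table: Optional[dict] = None) -> float:
    """Net charge at a given pH by Henderson-Hasselbalch over termini and
    ionizable side chains (D, E, C, Y acidic; H, K, R basic)."""
    pka = dict(DEFAULT_PKA if pka_table is None else pka_table)
    seq = aa_sequence.upper()
    positive = seq.count("K") * [pka["K"]] + seq.count("R") * [pka["R"]] + seq.count("H") * [pka["H"]]
    positive.append(pka.get("nterm_overrides", {}).get(seq[0], pka["Nterm"]))
    negative = seq.count("D") * [pka["D"]] + seq.count("E") * [pka["E"]]
    negative += seq.count("C") * [pka["C"]] + seq.count("Y") * [pka["Y"]]
    negative.append(pka.get("cterm_overrides", {}).get(seq[-1], pka["Cterm"]))
    charge = sum(1.0 / (1.0 + 10 ** (ph - pk)) for pk in positive)
    charge -= sum(1.0 / (1.0 + 10 ** (pk - ph)) for pk in negative)
    return charge


def isoelectric_point(
    aa_sequence: str,
    pka_table: Optional[dict] = None,
    tolerance: float = 1e-4,
) -> float:
    """pH at which the net charge is zero, by bisection on [0, 14]."""
    if not aa_sequence:
        raise ValueError("empty sequence")
    lo, hi = 0.0, 14.0
    while hi - lo > tolerance:
        mid = 0.5 * (lo + hi)
        if net_charge(aa_sequence, mid, pka_table) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def predict_tm_segments(
    aa_sequence: str,
    window: int = DEFAULT_TM_WINDOW,
    threshold: float = DEFAULT_TM_THRESHOLD,
    merge_gap: int = DEFAULT_TM_MERGE_GAP,
) -> list[tuple[int, int]]:
    """Putative transmembrane segments by Kyte-Doolittle hydropathy windows.

    A segment is a maximal run of residues covered by windows whose mean
    hydropathy is >= threshold; segments separated by fewer than ``merge_gap``
    residues merge.  Coordinates are 1-based inclusive; sequences shorter than
    the window yield no segments.
    """
    seq = aa_sequence.upper()
    n = len(seq)
    if n < window:
        return []
    values = [KYTE_DOOLITTLE.get(ch, 0.0) for ch in seq]
    spans = []
    running = sum(values[:window])
    for i in range(n - window + 1):
        if i:
            running += values[i + window - 1] - values[i - 1]
        if running / window >= threshold:
            spans.append((i + 1, i + window))  # 1-based, covers the full window
    if not spans:
        return []
    merged = [list(spans[0])]
    for lo, hi in spans[1:]:
        if lo - merged[-1][1] - 1 < merge_gap:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [(lo, hi) for lo, hi in merged]


@dataclass(frozen=True)
class TagSpec:
    """An epitope tag appended at the C terminus, defined by its coding DNA."""

    dna_sequence: str = FLAG_3X_DNA
    fusion_terminus: str = "C"
    stop_codon: str = "TAG"

    def __post_init__(self) -> None:
        if self.fusion_terminus != "C":
            raise ValueError("only C-terminal tag fusion is supported")
        if len(self.dna_sequence) % 3 != 0:
            raise ValueError("tag DNA length must be a whole number of codons")
        translate(self.dna_sequence)  # raises on internal stop

    @property
    def peptide(self) -> str:
        return translate(self.dna_sequence).peptide


@dataclass(frozen=True)
class ProteinFeatureSet:
    """Computed physicochemical features of one protein (Table-style report row)."""

    protein_id: str
    aa_sequence: str
    length_aa: int
    mw_kda: float
    pi: float
    tm_segments: tuple[tuple[int, int], ...]
    domains: str = ""
    tagged_variant: Optional["ProteinFeatureSet"] = None

    @classmethod
    def from_sequence(
        cls,
        protein_id: str,
        aa_sequence: str,
        tag: Optional[TagSpec] = None,
        domains: str = "",
        pka_table: Optional[dict] = None,
    ) -> "ProteinFeatureSet":
        seq = aa_sequence.upper()
        tagged = None
        if tag is not None:
            tagged = cls.from_sequence(
                protein_id + "+tag", seq + tag.peptide, tag=None, domains=domains, pka_table=pka_table
            )
        return cls(
            protein_id=protein_id,
            aa_sequence=seq,
            length_aa=len(seq),
            mw_kda=round(molecular_weight_kda(seq), 2),
            pi=round(isoelectric_point(seq, pka_table), 2),
            tm_segments=tuple(predict_tm_segments(seq)),
            domains=domains,
            tagged_variant=tagged,
        )

    @property
    def tmr_count(self) -> int:
        return len(self.tm_segments)


def fuse_tag(features: ProteinFeatureSet, tag: TagSpec) -> ProteinFeatureSet:
    """C-terminal tag fusion: native sequence + translated tag peptide."""
    return ProteinFeatureSet.from_sequence(
        features.protein_id, features.aa_sequence, tag=tag, domains=features.domains
    ).tagged_variant


def feature_table(
    proteins: Sequence[tuple[str, str]],
    tag: Optional[TagSpec] = None,
    domains: Optional[dict[str, str]] = None,
) -> pd.DataFrame:
    """Physicochemical report: one row per (id, sequence) with untagged and
    tagged mass/pI, transmembrane count and pass-through domain annotation."""
    tag = tag if tag is not None else TagSpec()
    domains = domains or {}
    rows = []
    for pid, seq in proteins:
        fs = ProteinFeatureSet.from_sequence(pid, seq, tag=tag, domains=domains.get(pid, ""))
        rows.append(
            {
                "protein": pid,
                "length_aa": fs.length_aa,
                "mw_untagged_kda": fs.mw_kda,
                "pi_untagged": fs.pi,
                "mw_tagged_kda": fs.tagged_variant.mw_kda,
                "pi_tagged": fs.tagged_variant.pi,
                "tmr": fs.tmr_count,
                "domains": fs.domains,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "protein", "length_aa", "mw_untagged_kda", "pi_untagged",
            "mw_tagged_kda", "pi_tagged", "tmr", "domains",
        ],
    )
    df.attrs["tm_method"] = (
        f"Kyte-Doolittle window {DEFAULT_TM_WINDOW}, threshold {DEFAULT_TM_THRESHOLD} "
        "(hydropathy heuristic, not a topology HMM)"
    )
    return df
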
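"""Synthetic data with the statistical structure the pipeline assumes.

Three generators, all pure functions of (spec, seed):

* paired strain genomes with planted intergenic mu-ORFs under transcriptional
  units, where the second strain carries codon-wise mutated orthologs with a
  tunable synonymous bias (dN/dS), plus annotation, TU tables and a truth
  table for mechanical recovery metrics;
* coding / non-coding nucleotide alignments for calibrating the
  coding-potential scorer (coding rows mutate with synonymous preference and
  never gain in-frame stops; non-coding rows mutate position-independently);
* condition x TU count matrices with planted single-condition inductions.

Counts are negative binomial around ``mean_count`` with a mild quasi-Poisson
overdispersion, var = (1 + dispersion) * mean: under this noise the UEF
estimator converges to the planted fold as counts grow.  ``noise=False``
yields the expectations exactly, for conservation-style checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .coding import CODON_AA, CODONS, CodonAlignment, STOP_CODON_IDX
from .coords import CdsRecord, GenomeRecord, GenomicInterval, TranscriptionalUnit
from . import io as _io
from .orthology import ProteinRecord

DEFAULT_CONDITIONS = ("Exp.", "Stat.", "cold", "heat", "-C", "dark", "-Fe", "HL", "-N", "-P")

_NONSTOP = [i for i in range(64) if i not in STOP_CODON_IDX]
_STOPS = [CODONS[i] for i in sorted(STOP_CODON_IDX)]

# synonymous alternatives per codon (same amino acid, different codon)
_SYNONYMS = {
    i: [j for j in _NONSTOP if j != i and CODON_AA[j] == CODON_AA[i]] for i in _NONSTOP
}
# single-nucleotide, non-stop, amino-acid-changing neighbours per codon
_NONSYN_NEIGHBOURS = {}
for i in _NONSTOP:
    neigh = []
    for pos, shift in ((0, 16), (1, 4), (2, 1)):
        cur = (i // shift) % 4
        for b in range(4):
            if b == cur:
                continue
            j = i + (b - cur) * shift
            if j in STOP_CODON_IDX or CODON_AA[j] == CODON_AA[i]:
                continue
            neigh.append(j)
    _NONSYN_NEIGHBOURS[i] = neigh


class SpecError(ValueError):
    """Infeasible or inconsistent synthetic-data specification."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic study conditions.

    Defaults mirror the scale of the real comparative study: 80-aa length cap,
    ~10% nucleotide divergence between the two strains with strong synonymous
    bias (dN/dS = 0.2), ten growth conditions with TSS read counts around
    1000, ten-fold single-condition inductions, and a 4091-TU transcriptome of
    which 70 TUs are dark-maximal.
    """

    seed: int = 0
    n_planted_orfs: int = 20
    orf_length_range_aa: tuple[int, int] = (20, 80)
    divergence: float = 0.1
    dnds: float = 0.2
    n_decoys: int = 5
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    induction_fold: float = 10.0
    mean_count: float = 1000.0
    dispersion: float = 0.1
    noise: bool = True
    n_tus: int = 4091
    n_induced: int = 70
    induced_condition: str = "dark"
    background_fold: float = 2.0
    utr5_nt: int = 26
    utr3_nt: int = 30
    genome_length: Optional[int] = None

    def __post_init__(self) -> None:
        lo, hi = self.orf_length_range_aa
        if not (1 <= lo <= hi <= 80):
            raise SpecError("orf_length_range_aa must satisfy 1 <= min <= max <= 80")
        for name, p in (("divergence", self.divergence),):
            if not 0.0 <= p <= 1.0:
                raise SpecError(f"{name} must be in [0, 1]")
        if self.dnds <= 0:
            raise SpecError("dnds must be > 0")
        if len(self.conditions) < 2:
            raise SpecError("need at least 2 conditions")
        if self.induced_condition not in self.conditions:
            raise SpecError(f"induced_condition {self.induced_condition!r} not in conditions")


def _random_codon_indices(rng: np.random.Generator, n: int) -> list[int]:
    return [int(_NONSTOP[k]) for k in rng.integers(0, len(_NONSTOP), size=n)]


def _random_orf_nt(rng: np.random.Generator, aa_length: int) -> str:
    """ATG + (aa_length - 1) random non-stop codons + a random stop codon."""
    internal = "".join(CODONS[i] for i in _random_codon_indices(rng, aa_length - 1))
    stop = _STOPS[int(rng.integers(0, len(_STOPS)))]
    return "ATG" + internal + stop


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[b] for b in rng.integers(0, 4, size=n))


def mutate_coding(
    nt: str, rng: np.random.Generator, divergence: float, dnds: float,
    keep_first: bool = True, keep_last: bool = True,
) -> str:
    """Codon-wise mutation with synonymous bias.

    Each codon mutates with probability 1 - (1 - divergence)^3; a mutating
    codon takes a synonymous alternative with probability 1 / (1 + dnds),
    otherwise a single-nucleotide non-stop amino-acid-changing neighbour.
    Start and stop codons can be pinned.  No in-frame stop is ever introduced.
    """
    codons = [nt[i : i + 3] for i in range(0, len(nt), 3)]
    p_mut = 1.0 - (1.0 - divergence) ** 3
    out = []
    for ci, codon in enumerate(codons):
        idx = CODONS.index(codon)
        pinned = (keep_first and ci == 0) or (keep_last and ci == len(codons) - 1)
        if pinned or idx in STOP_CODON_IDX or rng.random() >= p_mut:
            out.append(codon)
            continue
        if rng.random() < 1.0 / (1.0 + dnds) and _SYNONYMS[idx]:
            choice = _SYNONYMS[idx][int(rng.integers(0, len(_SYNONYMS[idx])))]
        elif _NONSYN_NEIGHBOURS[idx]:
            choice = _NONSYN_NEIGHBOURS[idx][int(rng.integers(0, len(_NONSYN_NEIGHBOURS[idx])))]
        else:
            choice = idx
        out.append(CODONS[choice])
    return "".join(out)


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


@dataclass
class SyntheticStrain:
    name: str
    genome: GenomeRecord
    tus: list[TranscriptionalUnit]
    annotation: list[CdsRecord]


@dataclass
class SyntheticBundle:
    spec: SyntheticSpec
    strain_a: SyntheticStrain
    strain_b: SyntheticStrain
    truth: pd.DataFrame

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for strain in (self.strain_a, self.strain_b):
            _io.write_genome_fasta([strain.genome], outdir / f"genome_{strain.name}.fasta")
            _io.write_tu_table(strain.tus, outdir / f"tus_{strain.name}.tsv")
            _io.write_gff3_cds(strain.annotation, outdir / f"annotation_{strain.name}.gff3")
        self.truth.to_csv(outdir / "truth_orfs.tsv", sep="\t", index=False)


def _assemble_strain(
    name: str,
    replicon_id: str,
    orf_nts: Sequence[str],
    rng: np.random.Generator,
    spec: SyntheticSpec,
) -> tuple[SyntheticStrain, list[dict]]:
    """Lay out filler CDS and ORF-bearing TUs on one genome; returns the
    strain plus per-ORF placement records (genomic interval, parent TU)."""
    parts: list[str] = []
    pos = 1  # next free 1-based position
    tus: list[TranscriptionalUnit] = []
    annotation: list[CdsRecord] = []
    placements: list[dict] = []

    def emit(seq: str) -> tuple[int, int]:
        nonlocal pos
        parts.append(seq)
        start = pos
        pos += len(seq)
        return start, pos - 1

    for i, orf_nt in enumerate(orf_nts):
        emit(_random_dna(rng, int(rng.integers(40, 81))))
        filler = _random_orf_nt(rng, int(rng.integers(40, 81)))
        f_strand = "+" if rng.random() < 0.5 else "-"
        f_seq = filler if f_strand == "+" else _revcomp(filler)
        f_start, f_end = emit(f_seq)
        annotation.append(
            CdsRecord(
                interval=GenomicInterval(replicon_id, f_start, f_end, f_strand),
                includes_stop=True,
                locus_tag=f"{name}_filler_{i + 1}",
                product="filler protein",
            )
        )
        emit(_random_dna(rng, int(rng.integers(40, 81))))
        strand = "+" if rng.random() < 0.5 else "-"
        # the 5'UTR ends with an in-frame stop so the planted ATG is the true
        # ORF start (no silent N-terminal extension into the leader)
        utr5 = _random_dna(rng, max(spec.utr5_nt - 3, 0)) + "TAA"[: min(spec.utr5_nt, 3)]
        transcript = utr5 + orf_nt + _random_dna(rng, spec.utr3_nt)
        t_seq = transcript if strand == "+" else _revcomp(transcript)
        t_start, t_end = emit(t_seq)
        tu_id = f"TU_{name}_{i + 1:04d}"
        iv = GenomicInterval(replicon_id, t_start, t_end, strand)
        tus.append(
            TranscriptionalUnit(tu_id=tu_id, interval=iv, tss_position=iv.five_prime, category="coding")
        )
        if strand == "+":
            o_start = t_start + spec.utr5_nt
            o_end = o_start + len(orf_nt) - 1
        else:
            o_end = t_end - spec.utr5_nt
            o_start = o_end - len(orf_nt) + 1
        placements.append(
            {"start": o_start, "end": o_end, "strand": strand, "tu": tu_id, "nt": orf_nt}
        )
    for d in range(spec.n_decoys):
        emit(_random_dna(rng, int(rng.integers(40, 81))))
        strand = "+" if rng.random() < 0.5 else "-"
        d_start, d_end = emit(_random_dna(rng, int(rng.integers(120, 181))))
        iv = GenomicInterval(replicon_id, d_start, d_end, strand)
        tus.append(
            TranscriptionalUnit(
                tu_id=f"TU_{name}_decoy_{d + 1:03d}",
                interval=iv,
                tss_position=iv.five_prime,
                category="non-coding",
            )
        )
    emit(_random_dna(rng, 60))
    sequence = "".join(parts)
    if spec.genome_length is not None:
        if spec.genome_length < len(sequence):
            raise SpecError(
                f"genome_length {spec.genome_length} cannot hold "
                f"{len(sequence)} nt of planted content (infeasible packing)"
            )
        sequence += _random_dna(rng, spec.genome_length - len(sequence))
    genome = GenomeRecord(replicon_id=replicon_id, sequence=sequence)
    return SyntheticStrain(name=name, genome=genome, tus=tus, annotation=annotation), placements


def generate_genome_pair(spec: SyntheticSpec) -> SyntheticBundle:
    """Two strain genomes with planted orthologous mu-ORFs and a truth table.

    Strain A carries ``n_planted_orfs`` intergenic ORFs, each inside its own
    TU and flanked by annotated filler CDS; strain B carries codon-wise
    mutated orthologs (same amino-acid length, start and stop pinned) in an
    independently laid-out genome.  Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.orf_length_range_aa
    aa_lengths = [int(x) for x in rng.integers(lo, hi + 1, size=spec.n_planted_orfs)]
    orfs_a = [_random_orf_nt(rng, L) for L in aa_lengths]
    orfs_b = [mutate_coding(nt, rng, spec.divergence, spec.dnds) for nt in orfs_a]
    strain_a, placed_a = _assemble_strain("A", "chrA", orfs_a, rng, spec)
    strain_b, placed_b = _assemble_strain("B", "chrB", orfs_b, rng, spec)

    from .features import translate

    rows = []
    for i, (pa, pb) in enumerate(zip(placed_a, placed_b)):
        aa_a = translate(pa["nt"]).peptide
        aa_b = translate(pb["nt"]).peptide
        identity = sum(x == y for x, y in zip(aa_a, aa_b)) / len(aa_a)
        rows.append(
            {
                "orf_id": f"planted_{i + 1:03d}",
                "aa_length": aa_lengths[i],
                "start_a": pa["start"], "end_a": pa["end"], "strand_a": pa["strand"], "tu_a": pa["tu"],
                "start_b": pb["start"], "end_b": pb["end"], "strand_b": pb["strand"], "tu_b": pb["tu"],
                "aa_seq_a": aa_a, "aa_seq_b": aa_b, "aa_identity": identity,
            }
        )
    truth = pd.DataFrame(
        rows,
        columns=[
            "orf_id", "aa_length",
            "start_a", "end_a", "strand_a", "tu_a",
            "start_b", "end_b", "strand_b", "tu_b",
            "aa_seq_a", "aa_seq_b", "aa_identity",
        ],
    )
    return SyntheticBundle(spec=spec, strain_a=strain_a, strain_b=strain_b, truth=truth)


def generate_alignment(
    coding: bool,
    n_rows: int = 4,
    n_codons: int = 60,
    divergence: float = 0.1,
    dnds: float = 0.2,
    seed: int = 0,
) -> CodonAlignment:
    """A gapless alignment of ``n_rows`` sequences derived from one ancestor.

    ``coding=True`` starts from a stop-free codon ancestor and mutates
    codon-wise with synonymous preference, never introducing an in-frame
    stop; ``coding=False`` starts from uniform random DNA (no codon
    structure, stops allowed) and mutates every position independently - the
    null the scorer should not reward.
    """
    if n_rows < 2:
        raise ValueError("n_rows must be >= 2")
    rng = np.random.default_rng(seed)
    if coding:
        ref = "".join(CODONS[i] for i in _random_codon_indices(rng, n_codons))
    else:
        ref = _random_dna(rng, 3 * n_codons)
    rows = [ref]
    for _ in range(n_rows - 1):
        if coding:
            rows.append(mutate_coding(ref, rng, divergence, dnds, keep_first=False, keep_last=False))
        else:
            bases = list(ref)
            for j in range(len(bases)):
                if rng.random() < divergence:
                    alternatives = [b for b in "ACGT" if b != bases[j]]
                    bases[j] = alternatives[int(rng.integers(0, 3))]
            rows.append("".join(bases))
    return CodonAlignment(rows=tuple(rows))


def generate_count_matrix(spec: SyntheticSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Condition x TU count matrix with planted single-condition maxima.

    The first ``n_induced`` TUs are maximal under ``induced_condition`` with
    fold ``induction_fold``; the remaining TUs get a milder planted maximum
    (``background_fold``) cycled round-robin over the other conditions, so
    every TU has a well-defined truth label.  Counts are negative binomial
    with var = (1 + dispersion) * mean, or exact expectations if noise is off.
    """
    rng = np.random.default_rng(spec.seed)
    conditions = list(spec.conditions)
    n = spec.n_tus
    if spec.n_induced > n:
        raise SpecError("n_induced exceeds n_tus")
    tu_ids = [f"TU{i + 1:05d}" for i in range(n)]
    others = [c for c in conditions if c != spec.induced_condition]
    max_cond = [spec.induced_condition] * spec.n_induced + [
        others[i % len(others)] for i in range(n - spec.n_induced)
    ]
    fold = np.full(n, spec.background_fold)
    fold[: spec.n_induced] = spec.induction_fold
    expected = np.full((n, len(conditions)), spec.mean_count)
    col_index = {c: k for k, c in enumerate(conditions)}
    for i in range(n):
        expected[i, col_index[max_cond[i]]] *= fold[i]
    if spec.noise:
        r = expected / spec.dispersion  # NB size parameter: var = mu * (1 + dispersion)
        p = r / (r + expected)
        counts = rng.negative_binomial(r, p).astype(float)
    else:
        counts = expected.copy()
    matrix = pd.DataFrame(counts, index=pd.Index(tu_ids, name="tu_id"), columns=conditions)
    truth = pd.DataFrame(
        {"tu_id": tu_ids, "max_condition": max_cond, "fold": fold},
        columns=["tu_id", "max_condition", "fold"],
    )
    return matrix, truth


def make_reference_proteome(
    truth: pd.DataFrame,
    orf_ids: Sequence[str],
    set_name: str,
    n_decoys: int = 10,
    divergence: float = 0.1,
    dnds: float = 0.2,
    seed: int = 0,
) -> list[ProteinRecord]:
    """A named reference proteome containing mutated orthologs of the chosen
    planted ORFs plus random decoy proteins, for presence-flag tests."""
    from .features import translate

    rng = np.random.default_rng(seed)
    wanted = set(orf_ids)
    proteins = []
    for _, row in truth.iterrows():
        if row["orf_id"] not in wanted:
            continue
        # derive a homolog by mutating a coding sequence for the strain-A protein
        source_nt = _aa_to_nt(row["aa_seq_a"], rng)
        mutated = mutate_coding(source_nt, rng, divergence, dnds, keep_last=False)
        proteins.append(
            ProteinRecord(
                id=f"{set_name}_{row['orf_id']}",
                sequence=translate(mutated).peptide,
                source_set=set_name,
            )
        )
    for d in range(n_decoys):
        length = int(rng.integers(20, 81))
        seq = "".join(CODON_AA[i] for i in _random_codon_indices(rng, length))
        proteins.append(ProteinRecord(id=f"{set_name}_decoy_{d + 1:03d}", sequence=seq, source_set=set_name))
    return proteins


def _aa_to_nt(aa: str, rng: np.random.Generator) -> str:
    """A random coding sequence (no stop) for a peptide."""
    choices = []
    for ch in aa:
        codons = [i for i in _NONSTOP if CODON_AA[i] == ch]
        choices.append(CODONS[codons[int(rng.integers(0, len(codons)))]])
    return "".join(choices)
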
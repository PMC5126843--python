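"""Stage 2: evolutionary coding-potential scoring of candidate ORFs.

A protein-coding region evolving under purifying selection leaves a codon-level
signature in a nucleotide alignment: substitutions concentrate at synonymous
sites, in-frame stop codons are avoided, and gaps come in multiples of three.
The score below rewards exactly these signatures.  For every reference codon
and every non-reference row it adds

    B(aa_ref, aa_row) - E_neutral(codon_ref, k)

where ``B`` is the BLOSUM62 amino-acid substitution score and ``E_neutral`` is
the mean BLOSUM62 score over all non-stop codons reachable from the reference
codon by ``k`` uniform nucleotide changes (``k`` = the observed number of
nucleotide differences in that codon).  A synonymous change therefore scores
well above its neutral expectation, a radical change below it.  In-frame stop
codons in any row incur a fixed penalty, as do frame-shifting gaps (gap runs
whose length is not a multiple of three).  Codon columns identical across all
rows contribute nothing, so an alignment of identical sequences scores 0.

Significance comes from a column-permutation null: shuffling alignment columns
preserves the per-column composition but destroys the codon structure, giving
an empirical p-value with the standard +1 pseudocount.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data.CodonTable import unambiguous_dna_by_id

DEFAULT_STOP_PENALTY = 10.0
DEFAULT_FRAMESHIFT_PENALTY = 8.0
DEFAULT_N_PERMUTATIONS = 1000
DEFAULT_ALPHA = 0.05

_BASES = "ACGT"
_BASE_CODE = {b: i for i, b in enumerate(_BASES)}
_GAP_CODE = -1
_OTHER_CODE = -2

_TABLE = unambiguous_dna_by_id[11]  # bacterial code; identical codon->aa map to the standard table
CODONS = ["".join((a, b, c)) for a in _BASES for b in _BASES for c in _BASES]
CODON_AA = np.array(
    ["*" if codon in _TABLE.stop_codons else _TABLE.forward_table[codon] for codon in CODONS]
)
STOP_CODON_IDX = frozenset(i for i, aa in enumerate(CODON_AA) if aa == "*")

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


class InsufficientDataError(ValueError):
    """Fewer than two alignment rows; no evolutionary signal to score."""


@dataclass(frozen=True)
class CodonAlignment:
    """A nucleotide alignment whose first row is the candidate ORF (reference).

    ``rows`` are equal-length aligned sequences over {A,C,G,T,N,-}; the
    reference row, after gap removal and skipping ``frame_offset`` leading
    bases, must be a whole number of codons.
    """

    rows: tuple[str, ...]
    frame_offset: int = 0
    ids: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        rows = tuple(r.upper() for r in self.rows)
        object.__setattr__(self, "rows", rows)
        if not rows:
            raise ValueError("alignment has no rows")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise ValueError(f"rows have unequal lengths {sorted(lengths)}")
        if not 0 <= self.frame_offset <= 2:
            raise ValueError("frame_offset must be 0, 1 or 2")
        gapfree = len(rows[0].replace("-", "")) - self.frame_offset
        if gapfree < 3 or gapfree % 3 != 0:
            raise ValueError(
                "reference row must be a whole number of codons after gap removal"
            )

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_codons(self) -> int:
        return (len(self.rows[0].replace("-", "")) - self.frame_offset) // 3

    @property
    def reference(self) -> str:
        return self.rows[0].replace("-", "")


@dataclass(frozen=True)
class CodingAssessment:
    score: float
    p_value: float
    n_permutations: int
    seed: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")


def _hamming_mutants(codon_idx: int, k: int) -> list[int]:
    """All codon indices at exactly k nucleotide differences from codon_idx."""
    from itertools import combinations, product

    digits = [(codon_idx // 16) % 4, (codon_idx // 4) % 4, codon_idx % 4]
    out = []
    for positions in combinations(range(3), k):
        choices = []
        for p in positions:
            choices.append([b for b in range(4) if b != digits[p]])
        for repl in product(*choices):
            d = digits.copy()
            for p, b in zip(positions, repl):
                d[p] = b
            out.append(d[0] * 16 + d[1] * 4 + d[2])
    return out


@lru_cache(maxsize=None)
def _neutral_means() -> np.ndarray:
    """mean BLOSUM62(aa_ref, aa_mut) over non-stop Hamming-k mutants; shape (64, 4)."""
    means = np.zeros((64, 4))
    for ci in range(64):
        aa_ref = CODON_AA[ci]
        for k in (1, 2, 3):
            scores = [
                float(_BLOSUM62[aa_ref, CODON_AA[m]])
                for m in _hamming_mutants(ci, k)
                if m not in STOP_CODON_IDX
            ]
            means[ci, k] = float(np.mean(scores)) if scores else 0.0
    return means


@lru_cache(maxsize=None)
def _contribution_table(stop_penalty: float) -> np.ndarray:
    """Per-codon contribution lookup C[ref_codon, observed_codon]."""
    neutral = _neutral_means()
    table = np.zeros((64, 64))
    for ref in range(64):
        for obs in range(64):
            if ref == obs:
                continue
            if obs in STOP_CODON_IDX or ref in STOP_CODON_IDX:
                table[ref, obs] = -stop_penalty
                continue
            k = sum(
                1
                for shift in (16, 4, 1)
                if (ref // shift) % 4 != (obs // shift) % 4
            )
            table[ref, obs] = float(_BLOSUM62[CODON_AA[ref], CODON_AA[obs]]) - neutral[ref, k]
    return table


def _encode(rows: Sequence[str]) -> np.ndarray:
    arr = np.full((len(rows), len(rows[0])), _OTHER_CODE, dtype=np.int8)
    for i, row in enumerate(rows):
        for j, ch in enumerate(row):
            if ch in _BASE_CODE:
                arr[i, j] = _BASE_CODE[ch]
            elif ch == "-":
                arr[i, j] = _GAP_CODE
    return arr


def _gap_run_penalties(matrix: np.ndarray, frameshift_penalty: float) -> float:
    """Frameshift penalties: per non-reference row, gap runs (in the row, or
    insertions relative to the reference) whose length is not a multiple of 3."""
    total = 0.0
    ref_gap = matrix[0] == _GAP_CODE
    for r in range(1, matrix.shape[0]):
        row_gap = matrix[r] == _GAP_CODE
        for mask in (row_gap & ~ref_gap, ref_gap & ~row_gap):
            run = 0
            for flag in mask:
                if flag:
                    run += 1
                elif run:
                    if run % 3:
                        total -= frameshift_penalty
                    run = 0
            if run and run % 3:
                total -= frameshift_penalty
    return total


def _score_matrix(
    matrix: np.ndarray,
    frame_offset: int,
    stop_penalty: float,
    frameshift_penalty: float,
) -> float:
    table = _contribution_table(stop_penalty)
    ref = matrix[0]
    if (matrix >= 0).all():
        # gapless fast path
        ncod = (matrix.shape[1] - frame_offset) // 3
        cols = matrix[:, frame_offset : frame_offset + 3 * ncod].reshape(matrix.shape[0], ncod, 3)
        idx = cols[:, :, 0].astype(np.int32) * 16 + cols[:, :, 1] * 4 + cols[:, :, 2]
        return float(table[idx[0][None, :], idx[1:]].sum())
    score = _gap_run_penalties(matrix, frameshift_penalty)
    ref_cols = np.flatnonzero(ref >= 0)[frame_offset:]
    ncod = len(ref_cols) // 3
    for c in range(ncod):
        cols = ref_cols[3 * c : 3 * c + 3]
        ref_codon = ref[cols]
        ref_idx = int(ref_codon[0]) * 16 + int(ref_codon[1]) * 4 + int(ref_codon[2])
        for r in range(1, matrix.shape[0]):
            obs = matrix[r, cols]
            if (obs < 0).any():
                continue  # gaps already penalized; ambiguous bases uninformative
            obs_idx = int(obs[0]) * 16 + int(obs[1]) * 4 + int(obs[2])
            score += table[ref_idx, obs_idx]
    return float(score)


def coding_score(
    alignment: CodonAlignment,
    stop_penalty: float = DEFAULT_STOP_PENALTY,
    frameshift_penalty: float = DEFAULT_FRAMESHIFT_PENALTY,
) -> float:
    """Evolutionary coding score of an alignment (higher = more coding-like)."""
    if alignment.n_rows < 2:
        raise InsufficientDataError("coding_score needs at least 2 aligned rows")
    matrix = _encode(alignment.rows)
    return _score_matrix(matrix, alignment.frame_offset, stop_penalty, frameshift_penalty)


def coding_pvalue(
    alignment: CodonAlignment,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
    stop_penalty: float = DEFAULT_STOP_PENALTY,
    frameshift_penalty: float = DEFAULT_FRAMESHIFT_PENALTY,
) -> CodingAssessment:
    """Column-permutation significance of the coding score.

    The null shuffles whole alignment columns uniformly at random, preserving
    per-column composition while destroying codon structure.
    p = (1 + #{permuted >= observed}) / (1 + n_permutations).
    """
    if n_permutations < 19:
        raise ValueError("n_permutations must be >= 19 for a meaningful p-value")
    if alignment.n_rows < 2:
        raise InsufficientDataError("coding_pvalue needs at least 2 aligned rows")
    matrix = _encode(alignment.rows)
    observed = _score_matrix(matrix, alignment.frame_offset, stop_penalty, frameshift_penalty)
    rng = np.random.default_rng(seed)
    ncols = matrix.shape[1]
    ge = 0
    if (matrix >= 0).all():
        # vectorized permutations for gapless alignments
        table = _contribution_table(stop_penalty)
        perms = np.argsort(rng.random((n_permutations, ncols)), axis=1)
        shuffled = matrix[:, perms]  # (rows, n_permutations, ncols)
        off = alignment.frame_offset
        ncod = (ncols - off) // 3
        cols = shuffled[:, :, off : off + 3 * ncod].reshape(
            matrix.shape[0], n_permutations, ncod, 3
        )
        idx = cols[:, :, :, 0].astype(np.int32) * 16 + cols[:, :, :, 1] * 4 + cols[:, :, :, 2]
        null = table[idx[0][None, :, :], idx[1:]].sum(axis=(0, 2))
        ge = int((null >= observed - 1e-9).sum())
    else:
        for _ in range(n_permutations):
            perm = rng.permutation(ncols)
            s = _score_matrix(
                matrix[:, perm], alignment.frame_offset, stop_penalty, frameshift_penalty
            )
            if s >= observed - 1e-9:
                ge += 1
    p = (1 + ge) / (1 + n_permutations)
    return CodingAssessment(score=observed, p_value=p, n_permutations=n_permutations, seed=seed)


def filter_significant(
    assessments: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    benjamini_hochberg: bool = False,
    borderline_above: float = 0.01,
) -> pd.DataFrame:
    """Retain rows with p_value <= alpha (boundary inclusive).

    With ``benjamini_hochberg=True`` the threshold applies to BH-adjusted
    p-values instead.  A ``borderline`` column flags retained candidates with
    borderline_above < p <= alpha, standing in for the manual-curation step a
    human would apply to marginal calls.
    """
    if assessments.empty:
        out = assessments.copy()
        out["borderline"] = pd.Series(dtype=bool)
        return out
    df = assessments.copy()
    if benjamini_hochberg:
        p = df["p_value"].to_numpy()
        order = np.argsort(p, kind="stable")
        m = len(p)
        adj = np.empty(m)
        running = 1.0
        for rank_from_end, i in enumerate(order[::-1]):
            rank = m - rank_from_end
            running = min(running, p[i] * m / rank)
            adj[i] = running
        keep = adj <= alpha
    else:
        keep = df["p_value"].to_numpy() <= alpha
    out = df.loc[keep].copy()
    out["borderline"] = (out["p_value"] > borderline_above) & (out["p_value"] <= alpha)
    return out


def align_pair(a: str, b: str, match: float = 1.0, mismatch: float = -1.0, gap: float = -2.0):
    """Convenience global nucleotide aligner for building fixture alignments."""
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    aln = aligner.align(a.upper(), b.upper())[0]
    return str(aln[0]), str(aln[1])
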
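"""Stage 3: reciprocal-best-hit (RBH) orthology with mu-protein thresholds.

Similarity search is exact Smith-Waterman local alignment (BLOSUM62, affine
gap cost 11 + g for a gap of length g) with Karlin-Altschul E-values

    E = K * m * n * exp(-lambda * S)

using the standard gapped BLOSUM62 constants lambda = 0.267, K = 0.041, where
``m`` is the query length and ``n`` the summed length of the target set.  Two
proteins form an ortholog pair when each is the other's best hit, both
E-values pass the cutoff (default 1e-2), both are at most ``max_len`` residues
(default 80, the mu-protein bound), and their lengths differ by at most
``max_len_diff`` (default 20%, measured against the longer sequence).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices

KARLIN_ALTSCHUL_LAMBDA = 0.267
KARLIN_ALTSCHUL_K = 0.041
DEFAULT_E_MAX = 1e-2
DEFAULT_MAX_LEN_DIFF = 0.2
DEFAULT_MAX_LEN_AA = 80

_AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


class EmptySetError(ValueError):
    """A similarity search over an empty protein set."""


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    sequence: str
    source_set: str = ""

    def __post_init__(self) -> None:
        seq = self.sequence.upper().rstrip("*")
        if not seq:
            raise ValueError(f"{self.id}: empty protein sequence")
        bad = set(seq) - _AA_ALPHABET
        if bad:
            raise ValueError(f"{self.id}: invalid residues {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class BestHit:
    query_id: str
    target_id: str
    raw_score: float
    evalue: float


@dataclass(frozen=True)
class OrthologPair:
    id_a: str
    id_b: str
    evalue_ab: float
    evalue_ba: float
    length_ratio: float

    def __post_init__(self) -> None:
        if not 0.0 < self.length_ratio <= 1.0:
            raise ValueError("length_ratio must be in (0, 1]")


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # BLAST-style affine cost 11 + g: first gapped residue -12, each further -1
    aligner.open_gap_score = -12.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


def local_alignment_score(a: str, b: str) -> float:
    """Smith-Waterman score under BLOSUM62 with affine gaps (11 + g)."""
    return float(_ALIGNER.score(a.upper(), b.upper()))


def karlin_altschul_evalue(score: float, query_len: int, db_len: int) -> float:
    return KARLIN_ALTSCHUL_K * query_len * db_len * math.exp(-KARLIN_ALTSCHUL_LAMBDA * score)


def search_best_hits(
    query_set: Sequence[ProteinRecord],
    target_set: Sequence[ProteinRecord],
    e_max: float = DEFAULT_E_MAX,
) -> dict[str, BestHit]:
    """Best target per query: highest-scoring target with E <= e_max.

    The E-value is computed against the whole target set (db length = summed
    target residues).  Ties on score resolve to the lexicographically smaller
    target id.  Queries without a qualifying hit are absent from the result.
    """
    if not query_set or not target_set:
        raise EmptySetError("similarity search requires non-empty query and target sets")
    db_len = sum(len(t) for t in target_set)
    targets = sorted(target_set, key=lambda t: t.id)
    hits: dict[str, BestHit] = {}
    for q in query_set:
        best: Optional[BestHit] = None
        for t in targets:
            s = local_alignment_score(q.sequence, t.sequence)
            if best is None or s > best.raw_score:
                e = karlin_altschul_evalue(s, len(q), db_len)
                best = BestHit(query_id=q.id, target_id=t.id, raw_score=s, evalue=e)
        if best is not None and best.evalue <= e_max:
            hits[q.id] = best
    return hits


def reciprocal_best_hits(
    set_a: Sequence[ProteinRecord],
    set_b: Sequence[ProteinRecord],
    e_max: float = DEFAULT_E_MAX,
    max_len_diff: float = DEFAULT_MAX_LEN_DIFF,
    max_len: int = DEFAULT_MAX_LEN_AA,
) -> list[OrthologPair]:
    """Ortholog pairs by reciprocal best hit with length rules.

    A pair (a, b) is reported iff best(a -> B) = b, best(b -> A) = a, both
    E-values <= e_max, both lengths <= max_len, and
    |len(a) - len(b)| / max(len) <= max_len_diff.
    """
    if not set_a or not set_b:
        return []
    ab = search_best_hits(set_a, set_b, e_max=e_max)
    ba = search_best_hits(set_b, set_a, e_max=e_max)
    len_a = {p.id: len(p) for p in set_a}
    len_b = {p.id: len(p) for p in set_b}
    pairs = []
    for qa, hit in sorted(ab.items()):
        back = ba.get(hit.target_id)
        if back is None or back.target_id != qa:
            continue
        la, lb = len_a[qa], len_b[hit.target_id]
        if la > max_len or lb > max_len:
            continue
        if abs(la - lb) / max(la, lb) > max_len_diff:
            continue
        pairs.append(
            OrthologPair(
                id_a=qa,
                id_b=hit.target_id,
                evalue_ab=hit.evalue,
                evalue_ba=back.evalue,
                length_ratio=min(la, lb) / max(la, lb),
            )
        )
    return pairs


def cross_reference_flags(
    candidates: Sequence[ProteinRecord],
    reference_sets: dict[str, Sequence[ProteinRecord]],
    e_max: float = DEFAULT_E_MAX,
    max_len_diff: float = DEFAULT_MAX_LEN_DIFF,
    max_len: int = DEFAULT_MAX_LEN_AA,
) -> pd.DataFrame:
    """Y/N presence flags: one column per named reference set.

    A candidate is flagged 'Y' for a reference set iff it has an RBH partner
    there under the same thresholds as :func:`reciprocal_best_hits`.
    """
    for name, refs in reference_sets.items():
        if not refs:
            raise EmptySetError(f"reference set {name!r} is empty")
    flags = pd.DataFrame(
        "N",
        index=pd.Index([c.id for c in candidates], name="candidate_id"),
        columns=list(reference_sets.keys()),
    )
    if not candidates:
        return flags
    for name, refs in reference_sets.items():
        for pair in reciprocal_best_hits(candidates, list(refs), e_max, max_len_diff, max_len):
            flags.loc[pair.id_a, name] = "Y"
    return flags


def pairs_as_table(pairs: Sequence[OrthologPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id_a": p.id_a,
                "id_b": p.id_b,
                "evalue_ab": p.evalue_ab,
                "evalue_ba": p.evalue_ba,
                "length_ratio": p.length_ratio,
            }
            for p in pairs
        ],
        columns=["id_a", "id_b", "evalue_ab", "evalue_ba", "length_ratio"],
    )
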
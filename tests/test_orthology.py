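"""Reciprocal-best-hit orthology against an independent DP oracle."""

import math

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from smorfkit.orthology import (
    EmptySetError,
    ProteinRecord,
    cross_reference_flags,
    karlin_altschul_evalue,
    local_alignment_score,
    reciprocal_best_hits,
    search_best_hits,
)
from smorfkit.simulate import SyntheticSpec, generate_genome_pair, make_reference_proteome

B62 = substitution_matrices.load("BLOSUM62")
AA = "ACDEFGHIKLMNPQRSTVWY"


def sw_oracle(a, b, gap_open=12.0, gap_extend=1.0):
    """Gotoh Smith-Waterman with affine gaps, written independently of the
    package's aligner (explicit dynamic-programming matrices)."""
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), -np.inf)  # gap in a (deletion in b direction)
    F = np.full((n + 1, m + 1), -np.inf)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] - gap_open, E[i, j - 1] - gap_extend)
            F[i, j] = max(H[i - 1, j] - gap_open, F[i - 1, j] - gap_extend)
            diag = H[i - 1, j - 1] + float(B62[a[i - 1], b[j - 1]])
            H[i, j] = max(0.0, diag, E[i, j], F[i, j])
            best = max(best, H[i, j])
    return best


def rbh_oracle(set_a, set_b, e_max=1e-2, max_len_diff=0.2, max_len=80):
    """All-pairs brute force RBH with the same published thresholds."""
    lam, K = 0.267, 0.041

    def best(queries, targets):
        db = sum(len(t.sequence) for t in targets)
        out = {}
        for q in queries:
            scored = sorted(
                ((sw_oracle(q.sequence, t.sequence), t.id) for t in targets),
                key=lambda x: (-x[0], x[1]),
            )
            s, tid = scored[0]
            e = K * len(q.sequence) * db * math.exp(-lam * s)
            if e <= e_max:
                out[q.id] = (tid, e)
        return out

    ab, ba = best(set_a, set_b), best(set_b, set_a)
    pairs = []
    for qa, (tb, e_ab) in ab.items():
        if tb in ba and ba[tb][0] == qa:
            la = len(next(p.sequence for p in set_a if p.id == qa))
            lb = len(next(p.sequence for p in set_b if p.id == tb))
            if la <= max_len and lb <= max_len and abs(la - lb) / max(la, lb) <= max_len_diff:
                pairs.append((qa, tb))
    return sorted(pairs)


def random_proteins(rng, n, prefix, lengths=(20, 80)):
    return [
        ProteinRecord(
            id=f"{prefix}{i}",
            sequence="".join(rng.choice(list(AA), size=rng.integers(*lengths))),
        )
        for i in range(n)
    ]


class TestSearchBestHits:
    def test_identical_query_hits_itself(self):
        target = ProteinRecord("t1", "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSG")
        decoy = ProteinRecord("t2", "GGGGGGGGGGGGGGGGGGGG")
        hits = search_best_hits([ProteinRecord("q", target.sequence)], [target, decoy])
        assert hits["q"].target_id == "t1"
        assert hits["q"].evalue < 1e-20

    def test_unrelated_random_query_has_no_hit(self):
        rng = np.random.default_rng(99)
        query = ProteinRecord("q", "".join(rng.choice(list(AA), size=20)))
        targets = random_proteins(rng, 10, "t", (30, 60))
        hits = search_best_hits([query], targets, e_max=1e-2)
        assert "q" not in hits

    def test_tie_breaks_to_lexicographically_smaller_id(self):
        seq = "MKLVINLVLLFTAWPSHAAE"
        targets = [ProteinRecord("zz", seq), ProteinRecord("aa", seq)]
        hits = search_best_hits([ProteinRecord("q", seq)], targets)
        assert hits["q"].target_id == "aa"

    def test_empty_set_errors(self):
        with pytest.raises(EmptySetError):
            search_best_hits([], [ProteinRecord("t", "MKL")])


class TestReciprocalBestHits:
    def test_identical_protein_in_both_sets(self):
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSG"
        pairs = reciprocal_best_hits([ProteinRecord("a1", seq)], [ProteinRecord("b1", seq)])
        assert [(p.id_a, p.id_b) for p in pairs] == [("a1", "b1")]
        assert pairs[0].length_ratio == 1.0

    def test_length_difference_rule_rejects_30_vs_40(self):
        core = "MKTAYIAKQRQISFVKSHFSRQLEERLGL"  # 29 aa shared core
        a = ProteinRecord("a1", core + "A")          # 30 aa
        b = ProteinRecord("b1", core + "AAAAAAAAAAA")  # 40 aa
        assert reciprocal_best_hits([a], [b]) == []
        # the same pair passes with the length rule relaxed
        assert len(reciprocal_best_hits([a], [b], max_len_diff=0.3)) == 1

    def test_length_cap_rejects_81mers(self):
        seq = ("MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQVKVKALPDAQFEVVHSLAKWKRQTL" * 2)[:81]
        assert len(seq) == 81
        assert reciprocal_best_hits([ProteinRecord("a", seq)], [ProteinRecord("b", seq)]) == []
        assert len(reciprocal_best_hits([ProteinRecord("a", seq)], [ProteinRecord("b", seq)], max_len=81)) == 1

    def test_symmetry(self):
        bundle = generate_genome_pair(SyntheticSpec(seed=21, n_planted_orfs=6))
        set_a = [ProteinRecord(r.orf_id + "a", r.aa_seq_a) for r in bundle.truth.itertuples()]
        set_b = [ProteinRecord(r.orf_id + "b", r.aa_seq_b) for r in bundle.truth.itertuples()]
        fwd = {(p.id_a, p.id_b) for p in reciprocal_best_hits(set_a, set_b)}
        rev = {(p.id_b, p.id_a) for p in reciprocal_best_hits(set_b, set_a)}
        assert fwd == rev and fwd

    def test_matches_bruteforce_oracle_on_random_sets(self):
        rng = np.random.default_rng(7)
        set_a = random_proteins(rng, 8, "a")
        set_b = random_proteins(rng, 8, "b")
        # plant three genuine homolog pairs (identical sequences)
        for k in range(3):
            set_b[k] = ProteinRecord(f"b{k}", set_a[k].sequence)
        got = sorted((p.id_a, p.id_b) for p in reciprocal_best_hits(set_a, set_b))
        assert got == rbh_oracle(set_a, set_b)

    def test_planted_ortholog_recovery(self):
        """>= 95% of planted ortholog pairs that satisfy the length rules are
        recovered across the divergence the generator produces."""
        bundle = generate_genome_pair(SyntheticSpec(seed=33, n_planted_orfs=20))
        set_a = [ProteinRecord(r.orf_id, r.aa_seq_a) for r in bundle.truth.itertuples()]
        set_b = [ProteinRecord(r.orf_id + "_b", r.aa_seq_b) for r in bundle.truth.itertuples()]
        pairs = {(p.id_a, p.id_b) for p in reciprocal_best_hits(set_a, set_b)}
        expected = {(r.orf_id, r.orf_id + "_b") for r in bundle.truth.itertuples()}
        assert len(pairs & expected) / len(expected) >= 0.95


class TestCrossReferenceFlags:
    def test_planted_flags(self):
        bundle = generate_genome_pair(SyntheticSpec(seed=5, n_planted_orfs=6))
        truth = bundle.truth
        candidates = [ProteinRecord(r.orf_id, r.aa_seq_a) for r in truth.itertuples()]
        ids = list(truth.orf_id)
        refs = {
            "6714": make_reference_proteome(truth, ids[:4], "6714", seed=1),
            "A.th.": make_reference_proteome(truth, ids[:2], "A.th.", seed=2),
            "E.coli": make_reference_proteome(truth, [], "E.coli", seed=3),
        }
        flags = cross_reference_flags(candidates, refs)
        assert list(flags.columns) == ["6714", "A.th.", "E.coli"]
        assert (flags["E.coli"] == "N").all()
        assert (flags.loc[ids[:4], "6714"] == "Y").all()
        assert (flags.loc[ids[4:], "6714"] == "N").all()
        assert (flags.loc[ids[:2], "A.th."] == "Y").all()

    def test_no_orthologs_anywhere(self):
        rng = np.random.default_rng(3)
        cand = random_proteins(rng, 2, "c")
        refs = {"setX": random_proteins(rng, 5, "x")}
        flags = cross_reference_flags(cand, refs)
        assert (flags["setX"] == "N").all()

    def test_empty_reference_set_errors(self):
        with pytest.raises(EmptySetError):
            cross_reference_flags([ProteinRecord("c", "MKL")], {"empty": []})


def test_evalue_formula_matches_direct_computation():
    s = local_alignment_score("MKTAYIAKQR", "MKTAYIAKQR")
    assert karlin_altschul_evalue(s, 10, 100) == pytest.approx(
        0.041 * 10 * 100 * math.exp(-0.267 * s)
    )
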
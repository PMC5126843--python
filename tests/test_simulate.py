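"""The synthetic-data generators: determinism, truth audits, model structure."""

import numpy as np
import pandas as pd
import pytest

from smorfkit.coding import CODON_AA, CODONS
from smorfkit.features import translate
from smorfkit.simulate import (
    SpecError,
    SyntheticSpec,
    generate_alignment,
    generate_count_matrix,
    generate_genome_pair,
    mutate_coding,
)

STOPS = {"TAA", "TAG", "TGA"}


class TestSpecValidation:
    def test_bad_length_range(self):
        with pytest.raises(SpecError):
            SyntheticSpec(orf_length_range_aa=(30, 100))

    def test_bad_divergence(self):
        with pytest.raises(SpecError):
            SyntheticSpec(divergence=1.5)

    def test_unknown_induced_condition(self):
        with pytest.raises(SpecError):
            SyntheticSpec(induced_condition="plasma")


class TestGenomePair:
    def test_no_planted_orfs_gives_empty_truth(self):
        bundle = generate_genome_pair(SyntheticSpec(seed=1, n_planted_orfs=0))
        assert len(bundle.truth) == 0
        assert bundle.strain_a.annotation == []
        assert len(bundle.strain_a.tus) == SyntheticSpec().n_decoys

    def test_determinism_byte_identical(self, tmp_path):
        spec = SyntheticSpec(seed=9, n_planted_orfs=5)
        d1, d2 = tmp_path / "run1", tmp_path / "run2"
        generate_genome_pair(spec).write(d1)
        generate_genome_pair(spec).write(d2)
        for f in d1.iterdir():
            assert f.read_bytes() == (d2 / f.name).read_bytes()

    def test_truth_table_audit(self):
        spec = SyntheticSpec(seed=2, n_planted_orfs=20, orf_length_range_aa=(20, 80))
        bundle = generate_genome_pair(spec)
        truth = bundle.truth
        assert len(truth) == 20
        assert truth["aa_length"].between(20, 80).all()
        # planted coordinates really contain the recorded ORFs
        for strain, prefix in ((bundle.strain_a, "a"), (bundle.strain_b, "b")):
            genome = strain.genome
            for _, row in truth.iterrows():
                start, end, strand = row[f"start_{prefix}"], row[f"end_{prefix}"], row[f"strand_{prefix}"]
                from smorfkit.coords import GenomicInterval, extract_sequence

                nt = extract_sequence(genome, GenomicInterval(genome.replicon_id, start, end, strand))
                assert nt.startswith("ATG") and nt[-3:] in STOPS
                assert translate(nt).peptide == row[f"aa_seq_{prefix}"]

    def test_orthologs_have_same_length_and_high_identity(self):
        bundle = generate_genome_pair(SyntheticSpec(seed=3))
        truth = bundle.truth
        assert (truth["aa_seq_a"].str.len() == truth["aa_seq_b"].str.len()).all()
        assert (truth["aa_identity"] > 0.6).all()

    def test_infeasible_packing(self):
        with pytest.raises(SpecError, match="packing"):
            generate_genome_pair(SyntheticSpec(seed=1, n_planted_orfs=20, genome_length=500))

    def test_tus_do_not_overlap_annotation(self):
        bundle = generate_genome_pair(SyntheticSpec(seed=4))
        for strain in (bundle.strain_a, bundle.strain_b):
            for tu in strain.tus:
                for cds in strain.annotation:
                    assert not tu.interval.overlaps(cds.interval)


class TestMutationModel:
    def test_zero_divergence_identity(self):
        rng = np.random.default_rng(0)
        nt = "ATG" + "GCTAAAGTT" * 5 + "TAA"
        assert mutate_coding(nt, rng, 0.0, 0.2) == nt

    def test_never_introduces_inframe_stop(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            mutated = mutate_coding("ATG" + "GCTAAAGTTCGT" * 6 + "TAA", rng, 0.5, 0.2)
            internal = [mutated[i : i + 3] for i in range(3, len(mutated) - 3, 3)]
            assert not (set(internal) & STOPS)

    def test_synonymous_fraction_exceeds_noncoding_expectation(self):
        """With dN/dS = 0.2 most codon changes are synonymous, far above what
        position-independent mutation yields."""
        syn = nonsyn = 0
        for seed in range(40):
            aln = generate_alignment(True, 2, 80, 0.2, 0.2, seed=seed)
            ref, row = aln.rows
            for i in range(0, len(ref), 3):
                a, b = ref[i : i + 3], row[i : i + 3]
                if a != b:
                    if CODON_AA[CODONS.index(a)] == CODON_AA[CODONS.index(b)]:
                        syn += 1
                    else:
                        nonsyn += 1
        observed = syn / (syn + nonsyn)
        # under neutral nucleotide mutation ~25% of single-nt codon changes are
        # synonymous; the coding generator targets 1/(1+0.2) ~ 0.83
        assert observed > 0.6

    def test_noncoding_inframe_stop_rate_matches_neutral_expectation(self):
        """Position-independent mutation creates in-frame stops at roughly the
        neutral rate (stops are 3/64 of codon space)."""
        stops = total = 0
        for seed in range(60):
            aln = generate_alignment(False, 2, 80, 0.3, 0.2, seed=100 + seed)
            row = aln.rows[1]
            for i in range(0, len(row), 3):
                total += 1
                if row[i : i + 3] in STOPS:
                    stops += 1
        rate = stops / total
        # ancestor is uniform random DNA: expect ~3/64 = 4.7% in-frame stops
        assert 0.02 < rate < 0.08


class TestAlignmentGenerator:
    def test_zero_divergence_identical_rows(self):
        aln = generate_alignment(True, 4, 30, 0.0, 0.2, seed=0)
        assert len(set(aln.rows)) == 1

    def test_row_and_codon_counts(self):
        aln = generate_alignment(True, 5, 42, 0.1, 0.2, seed=1)
        assert aln.n_rows == 5 and aln.n_codons == 42

    def test_determinism(self):
        a = generate_alignment(False, 3, 25, 0.2, 0.2, seed=77)
        b = generate_alignment(False, 3, 25, 0.2, 0.2, seed=77)
        assert a.rows == b.rows


class TestCountMatrix:
    def test_shapes_and_truth_labels(self):
        spec = SyntheticSpec(seed=5, n_tus=100, n_induced=10)
        matrix, truth = generate_count_matrix(spec)
        assert matrix.shape == (100, 10)
        assert len(truth) == 100
        assert (truth["fold"].iloc[:10] == 10.0).all()

    def test_unit_fold_means_no_specificity(self):
        spec = SyntheticSpec(seed=6, n_tus=50, n_induced=50, induction_fold=1.0, noise=False)
        matrix, _ = generate_count_matrix(spec)
        from smorfkit.expression import uef_table

        table = uef_table(matrix)
        assert (table["uef"] == 1.0).all()

    def test_determinism(self):
        spec = SyntheticSpec(seed=12, n_tus=30, n_induced=5)
        m1, t1 = generate_count_matrix(spec)
        m2, t2 = generate_count_matrix(spec)
        pd.testing.assert_frame_equal(m1, m2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_counts_nonnegative(self):
        matrix, _ = generate_count_matrix(SyntheticSpec(seed=13, n_tus=200))
        assert (matrix.values >= 0).all()
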
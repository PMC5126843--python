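"""ORF scanning against a brute-force oracle, interval subtraction, merging."""

import pytest
from hypothesis import given, strategies as st

from smorfkit.coords import CdsRecord, GenomeRecord, GenomicInterval, TranscriptionalUnit
from smorfkit.discovery import (
    AlphabetError,
    find_candidate_orfs,
    merge_with_annotation,
    scan_orfs,
    transcribed_intergenic_regions,
)
from smorfkit.simulate import SyntheticSpec, generate_genome_pair

STOPS = {"TAA", "TAG", "TGA"}


def oracle_scan(seq, min_len, max_len, starts=("ATG",)):
    """Enumerate every (start, stop) codon pair in all frames, then keep the
    longest ORF per stop (earliest start since the previous stop)."""
    seq = seq.upper()
    found = {}
    for frame in range(3):
        codons = [(i, seq[i : i + 3]) for i in range(frame, len(seq) - 2, 3)]
        for si, (spos, codon) in enumerate(codons):
            if codon not in starts:
                continue
            for ei in range(si + 1, len(codons)):
                epos, ecod = codons[ei]
                if ecod in STOPS:
                    aa = ei - si
                    key = (frame, epos)
                    if key not in found or spos < found[key][0]:
                        found[key] = (spos, epos + 2, aa)
                    break
    out = [
        (s, e, aa)
        for (s, e, aa) in found.values()
        if min_len <= aa <= max_len
    ]
    return sorted(out)


class TestScanOrfs:
    def test_no_start_codon(self):
        assert scan_orfs("CCCCCCCCC") == []

    def test_manual_codon_walk(self):
        # M-K-F-stop
        assert scan_orfs("ATGAAATTTTAA", min_len_aa=1) == [(0, 11, 3)]

    def test_length_cap(self):
        seq = "ATG" + "GCT" * 85 + "TAA"
        assert scan_orfs(seq, min_len_aa=1, max_len_aa=80) == []
        assert scan_orfs(seq, min_len_aa=1, max_len_aa=90) == [(0, len(seq) - 1, 86)]

    def test_longest_per_stop(self):
        # two in-frame ATGs before one stop: only the upstream one reported
        seq = "ATGCCCATGCCCTAA"
        assert scan_orfs(seq, min_len_aa=1) == [(0, 14, 4)]

    def test_truncated_orf_dropped(self):
        assert scan_orfs("ATGAAAAAA", min_len_aa=1) == []

    def test_alphabet_error(self):
        with pytest.raises(AlphabetError):
            scan_orfs("ATGNNNTAA")

    def test_alternative_start_codons(self):
        seq = "GTGAAATAA"
        assert scan_orfs(seq, min_len_aa=1) == []
        assert scan_orfs(seq, min_len_aa=1, start_codons=("ATG", "GTG", "TTG")) == [(0, 8, 2)]

    @given(st.text(alphabet="ACGT", min_size=1, max_size=300))
    def test_agrees_with_bruteforce_oracle(self, seq):
        assert scan_orfs(seq, min_len_aa=1, max_len_aa=80) == oracle_scan(seq, 1, 80)


class TestIntergenicRegions:
    def tu(self, start, end, strand="+"):
        iv = GenomicInterval("chr", start, end, strand)
        return TranscriptionalUnit("tu1", iv, iv.five_prime)

    def cds(self, start, end, strand="+", tag="g1"):
        return CdsRecord(GenomicInterval("chr", start, end, strand), True, tag)

    def test_no_overlap_keeps_whole_tu(self):
        regions = transcribed_intergenic_regions(
            [self.tu(100, 500)], [self.cds(1, 99), self.cds(501, 599, tag="g2")]
        )
        assert [(r.interval.start, r.interval.end) for r in regions] == [(100, 500)]

    def test_internal_cds_splits_tu(self):
        regions = transcribed_intergenic_regions([self.tu(100, 500)], [self.cds(200, 301)])
        assert [(r.interval.start, r.interval.end) for r in regions] == [(100, 199), (302, 500)]

    def test_tu_inside_cds_vanishes(self):
        assert transcribed_intergenic_regions([self.tu(200, 300)], [self.cds(100, 399, "-")]) == []

    def test_antisense_cds_masks_too(self):
        regions = transcribed_intergenic_regions([self.tu(100, 500, "+")], [self.cds(100, 201, "-")])
        assert [(r.interval.start, r.interval.end) for r in regions] == [(202, 500)]

    def test_conservation_of_tu_bases(self):
        # intergenic pieces + CDS-covered pieces reconstruct the TU exactly
        tu = self.tu(100, 1000)
        annotation = [self.cds(150, 299), self.cds(280, 399, "-", "g2"), self.cds(900, 1100, tag="g3")]
        regions = transcribed_intergenic_regions([tu], annotation)
        covered = set()
        for cds in annotation:
            covered.update(
                range(max(cds.interval.start, 100), min(cds.interval.end, 1000) + 1)
            )
        free = set()
        for r in regions:
            span = set(range(r.interval.start, r.interval.end + 1))
            assert not span & covered
            assert not span & free  # regions are disjoint
            free |= span
        assert free | covered == set(range(100, 1001))


class TestMergeWithAnnotation:
    def make_candidate(self, start, end, strand="+", tu="tu1"):
        from smorfkit.discovery import OrfCandidate

        n = end - start + 1
        return OrfCandidate(
            interval=GenomicInterval("Chr", start, end, strand),
            parent_tu_id=tu,
            nt_sequence="ATG" + "A" * (n - 6) + "TAA",
            aa_length=n // 3 - 1,
        )

    def test_candidate_matching_annotation_adopts_locus_tag(self):
        cds = CdsRecord(GenomicInterval("Chr", 10, 90, "+"), True, "sml0004", "petN")
        cat = merge_with_annotation([self.make_candidate(10, 90)], [cds])
        assert list(cat["candidate_id"]) == ["sml0004"]
        assert list(cat["gene"]) == ["petN"]

    def test_novel_candidate_gets_generated_id(self):
        cat = merge_with_annotation([self.make_candidate(10, 90)], [])
        assert list(cat["candidate_id"]) == ["Chr_ORF_1"]
        assert cat["locus_tag"].isna().all()

    def test_duplicates_collapse(self):
        cands = [self.make_candidate(10, 90, tu="tu1"), self.make_candidate(10, 90, tu="tu2")]
        cat = merge_with_annotation(cands, [])
        assert len(cat) == 1


class TestPlantedRecovery:
    def test_scanning_recovers_every_planted_orf(self):
        """The scanning stage alone finds 100% of planted ORFs at their exact
        genomic coordinates."""
        bundle = generate_genome_pair(SyntheticSpec(seed=11, n_planted_orfs=15))
        strain = bundle.strain_a
        genomes = {strain.genome.replicon_id: strain.genome}
        regions = transcribed_intergenic_regions(strain.tus, strain.annotation)
        cands = find_candidate_orfs(genomes, regions, min_len_aa=15)
        coords = {(c.interval.start, c.interval.end, c.interval.strand) for c in cands}
        for _, row in bundle.truth.iterrows():
            assert (row.start_a, row.end_a, row.strand_a) in coords
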
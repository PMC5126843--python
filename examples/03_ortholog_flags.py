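"""Reciprocal-best-hit orthology with mu-protein thresholds.

Plants orthologs of six candidate proteins in one reference set and none in
another, then reports Table-style Y/N presence flags.  Thresholds: E <= 1e-2
both ways, length difference <= 20%, both proteins <= 80 aa.
"""

from smorfkit import ProteinRecord, cross_reference_flags
from smorfkit.simulate import SyntheticSpec, generate_genome_pair, make_reference_proteome

bundle = generate_genome_pair(SyntheticSpec(seed=5, n_planted_orfs=6))
truth = bundle.truth
candidates = [ProteinRecord(r.orf_id, r.aa_seq_a) for r in truth.itertuples()]
ids = list(truth.orf_id)

references = {
    "strain6714": make_reference_proteome(truth, ids[:4], "strain6714", seed=1),
    "A_thaliana": make_reference_proteome(truth, ids[:2], "A_thaliana", seed=2),
    "E_coli": make_reference_proteome(truth, [], "E_coli", seed=3),
}
flags = cross_reference_flags(candidates, references)
print(flags)
print("\n'Y' marks a reciprocal best hit in that reference set: the first four")
print("candidates were planted in strain6714, the first two also in A_thaliana,")
print("none in E_coli.")
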
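# Methods

This note documents the models, parameter choices and numerical details
behind `smorfkit`, and what the synthetic-data validation does and does not
demonstrate.

## Coordinate model

All coordinates are 1-based and inclusive on both ends (GenBank convention);
GFF3 I/O shares that convention, so no conversion is applied there.
Published μ-protein catalogues list reverse-strand features in either
orientation, so intervals normalize to `start ≤ end` internally and carry
strand separately; the span `|end − start| + 1` and the derived protein
length are orientation-free.  Whether a CDS span includes its stop codon is
an explicit, mandatory flag (`includes_stop`), never inferred: catalogue
spans typically include the stop (`span/3 − 1` residues) while fusion
constructs omit it (`span/3` residues), and both conventions occur in
real coordinate tables — occasionally within the same table.  Circular
replicons are supported (`topology="circular"` allows wrap-around
extraction) but off by default.

The 5′UTR length is the number of transcribed nucleotides strictly before
the first CDS base on the TU's strand; 0 denotes a leaderless transcript.

## ORF scanning

Candidates are searched only in *transcribed intergenic regions*: maximal
sub-intervals of each TU not overlapped by annotated CDS on either strand
(overlap tolerance configurable, default 0 nt), scanned on the TU's strand
only — antisense ORFs are excluded by default.  Start codons default to
`{ATG}` (`{ATG, GTG, TTG}` selectable); within a reading frame only the
longest ORF per stop codon is reported (earliest start since the previous
stop), and ORFs without an in-region stop are dropped rather than extended
into annotation.  Length bounds: the 80-aa μ-protein cap, and a default
minimum of 15 aa — below the shortest well-known cyanobacterial μ-proteins
(~26 aa) with margin, but high enough not to flood the catalogue with
few-codon noise.  Both bounds are configurable.

## Coding-potential score

The scorer looks for the evolutionary signature of protein-coding sequence
in a nucleotide alignment whose first row is the candidate ORF.  For every
reference codon and every other row it adds

    B(aa_ref, aa_obs) − E_neutral(codon_ref, k)

where `B` is BLOSUM62, `k` is the observed number of nucleotide differences
in that codon (1–3), and `E_neutral(c, k)` is the mean BLOSUM62 score of
`aa(c)` against all non-stop codons at Hamming distance `k` from `c` — the
expected amino-acid-level score if the same number of nucleotide changes
had landed uniformly at random.  Synonymous and conservative changes
therefore score positively, radical changes negatively, and codons
identical across rows contribute 0 (an alignment of identical sequences
scores exactly 0).  Two fixed penalties capture the strongest negative
signals: −10 per in-frame stop codon observed in any row, and −8 per
frame-shifting gap run (length not a multiple of 3, counted per row in both
gap directions).  The 64×64 contribution table is precomputed, so scoring
is a table lookup.

Significance: the null shuffles whole alignment columns uniformly at
random, preserving per-column composition while destroying codon structure,
and `p = (1 + #{null ≥ observed}) / (1 + N)` with `N = 1000` permutations by
default (+1 pseudocount, so p is never 0).  Because the statistic is
evaluated on a random column permutation of the data, the test is exact
under column exchangeability; measured type-I error at α = 0.05 over 500
non-coding alignments is ~0.05–0.07.  The retention threshold is p ≤ 0.05,
boundary inclusive; a `borderline` flag (0.01 < p ≤ 0.05) replaces the
manual curation a human would apply to marginal calls, and an optional
Benjamini–Hochberg mode (off by default) is available.

This scorer is a self-contained statistic of the same family as
phylogenetic coding-potential tools (synonymous bias, stop and frameshift
penalties); it does not estimate a tree or reproduce any external tool's
p-values.

## Orthology

Similarity search is exact Smith–Waterman (Biopython's `PairwiseAligner`,
local mode) under BLOSUM62 with BLAST-style affine gaps — a gap of length g
costs 11 + g (open −12, extend −1).  E-values use the Karlin–Altschul form
`E = K·m·n·exp(−λS)` with the standard gapped BLOSUM62 constants λ = 0.267,
K = 0.041, `m` the query length and `n` the summed residue length of the
target set.  A reciprocal best hit requires E ≤ 1e−2 in both directions;
ties on score resolve to the lexicographically smaller target id.  The
length rules of the μ-protein screen apply at the pair level: both
sequences ≤ 80 aa, and a length difference of at most 20% — interpreted
against the *longer* sequence (the stricter, symmetric reading) and
configurable.  Presence flags ("Y"/"N" per named reference proteome) are
derived with the same machinery.  Counts against public databases are
inherently database-version-dependent and are out of scope; the package
searches only the sequence sets it is given.

## Expression specificity (UEF)

For one TU with counts across ≥ 2 conditions,
`UEF = (highest + c) / (second-highest + c)` with pseudocount `c = 1` by
default; `c = 0` restores the literal ratio and flags division by zero as an
infinite UEF.  The argmax condition is reported, ties resolving to the first
condition in column order with a `tied` flag.  The condition-maximum census
partitions all TUs by argmax and always sums to the number of TUs.  No
library normalization is applied by default (dRNA-seq TSS counts are used as
given); a per-condition library-size scaling hook exists but is off.

Because the denominator is an order statistic (the largest of the
non-induced conditions), the UEF of a planted induction is biased slightly
below the true fold at finite counts: with counts of mean μ and variance
(1 + φ)μ the second-highest of 9 baseline conditions exceeds μ by about
1.49·σ, a ~4.8% relative shortfall at μ = 1000, vanishing as μ grows.

## Protein features

* **Translation**: bacterial genetic code (translation table 11); a trailing
  stop is removed and recorded, an internal stop is an error unless
  readthrough is requested.
* **Mass**: average (not monoisotopic) residue masses plus one water,
  reported in kDa and rounded to 2 decimals only at the reporting boundary —
  matching how gel-scale masses are quoted.  `X` is not accepted for mass.
* **Isoelectric point**: Henderson–Hasselbalch net charge over the termini
  and D, E, C, Y, H, K, R side chains, solved by bisection on pH ∈ [0, 14]
  to 1e−4.  The pKa set is Bjellqvist/ExPASy-style, including the original
  method's residue-specific N- and C-terminal corrections; the table is
  injectable so alternative sets (e.g. EMBOSS) can be swapped in.
* **Transmembrane segments**: maximal runs of residues covered by 19-residue
  Kyte–Doolittle windows with mean hydropathy ≥ 1.6, merged when separated
  by fewer than 5 residues; sequences shorter than the window yield none.
  This is a documented hydropathy heuristic, not a trained topology HMM;
  only the segment *count* is surfaced, and the report metadata carries the
  method caveat.  Domain labels are pass-through annotation, never computed.
* **Tag fusion**: C-terminal only.  The default tag is the 69-nt 3xFLAG
  coding sequence used for immunodetection of small proteins; it translates
  to the 23-mer MDYKDHDGDYKDHDIDYKDDDDK, adds exactly its residue-mass sum
  (≈ 2.84 kDa, tag mass minus one water) to any protein, and, being rich in
  aspartate, lowers the fusion pI substantially.

## Promoter geometry

The NtcA scan uses the anchored degenerate consensus GTA–N8–[GT]AC (14 nt),
covering both the canonical palindrome and the printed GAC-variant site; an
exact-string mode is available.  The TSS is +1 and there is no position 0;
positions upstream are negative.  An even-length site has a half-integer
center on the contiguous axis (e.g. a site spanning −48..−35 is centered at
−41.5); because the field's prose often floors this ("centered 42 nt
upstream"), hits report both the half-integer center and its floor.  Sites
whose center falls within ±4 nt of −41.5 are classified `activating-range`
(window configurable).  Scans run on the transcribed strand, by default over
60 nt upstream (+ 5 downstream) of the TSS; shorter available context
triggers a warning and scans what is there.

## Synthetic data

The generators are pure functions of their spec (seed included) and write
truth tables keyed by the same ids as the pipeline outputs, so sensitivity
and FDR are computable mechanically.

* **Genome pairs**: strain A carries `n_planted_orfs` (default 20) random
  ORFs of 20–80 aa, each inside its own TU (26-nt 5′UTR, 30-nt 3′UTR),
  flanked by annotated filler CDS and random intergenic spacers; decoy
  non-coding TUs are added.  The 5′UTR ends with an in-frame TAA immediately
  before the planted ATG so the planted start codon is the true ORF start —
  otherwise a chance in-frame ATG in the random leader would silently extend
  the ORF and coordinate-exact recovery could not be expected.  Strain B
  carries codon-wise mutated orthologs (same length; start/stop pinned): a
  codon mutates with probability 1 − (1 − divergence)³ (divergence 0.1 per
  site by default) and takes a synonymous alternative with probability
  1/(1 + dN/dS) (dN/dS = 0.2), otherwise a single-nucleotide, non-stop,
  amino-acid-changing neighbour.  In-frame stops are never introduced.
* **Alignments**: coding alignments derive `n_rows` sequences from a
  stop-free codon ancestor under the same mutation model; non-coding
  alignments derive from *uniform random DNA* with position-independent
  substitutions (stops allowed).  The non-coding ancestor must not have
  codon structure: that is what makes it a correct null for the
  column-permutation test.
* **Count matrices**: every TU gets a truth argmax condition — by default
  4091 TUs over the 10 standard growth conditions, 70 of them dark-maximal
  (induction fold 10 for planted inductions, 2 for the background round-robin
  assignment, baseline mean 1000).  Counts are negative binomial with
  variance (1 + φ)·mean, φ = 0.1 — mild quasi-Poisson overdispersion, under
  which the UEF estimator converges to the planted fold as counts grow.
  `noise=False` returns the expectations exactly, for conservation checks.

What passing on synthetic data shows — and does not.  The generators
reproduce the *statistical structure* the method assumes: intergenic ORFs
under TUs, synonymous-biased divergence between orthologs, single-condition
inductions over overdispersed counts.  They deliberately do not model
sequencing error, mapping artifacts, operonic read-through, indel-rich
alignments, GC skew or compositional bias, so recovery rates measured here
are upper bounds on what identical settings would achieve on real dRNA-seq
data.  Catalogue sizes from real screens additionally depend on the input
genome builds, TU maps and database versions and are not reproducible from
synthetic data.

## Pipeline

`run_discovery` executes: discovery on strain A (and B when configured) →
per-candidate pairing with its best strain-B hit and pairwise global
nucleotide alignment (match/mismatch/gap = 1/−1/−2) → coding-potential
p-values (per-candidate seeds derived deterministically from the run seed)
→ p ≤ α filter → RBH flags (strain B plus any reference proteomes) → UEF
join on the parent TU → feature and promoter reports.  Candidates without a
strain-B homolog cannot be aligned and are recorded with `p = NaN` and
reason `no_homolog` rather than silently dropped.  All outputs are written
with fixed ordering and float formatting, and the manifest excludes
timestamps, so reruns under the same config are byte-identical.  Stage
counts (in/out per filter) are logged and stored in the manifest so
filter attrition is auditable.

## Problem sizes used in validation

The shipped tests and the acceptance script run at desk scale: 500
column-shuffled alignments for the type-I error (199 permutations each, the
smallest count that still makes α = 0.05 attainable exactly), 60–100 coding
alignments for power, 2000-TU matrices with 1000 planted inductions for UEF
recovery (the large cohort makes the measured error reflect the ~4.8%
structural bias rather than Monte-Carlo wobble), the full 4091-TU census,
and a 20-ORF strain pair for the end-to-end run.  Each piece completes in
seconds on one CPU.

## Known limitations

* The coding score assumes a fixed reading frame anchored on the candidate;
  it does not search frames, estimate phylogeny, or weight rows by
  relatedness (deep, unbalanced homolog sets will over-count correlated
  evidence).
* E-values use fixed Karlin–Altschul constants rather than
  sequence-composition-adjusted ones; for the short, desk-scale sets used
  here that is adequate, but absolute E-values differ from BLAST's.
* The hydropathy TM predictor reports segment counts only and is not a
  substitute for topology modelling.
* UEF has no replicate structure and no normalization; it is a screening
  statistic, not a differential-expression test.
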
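# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical and design choices made where the
procedure left room.

## Read mapping

Alignment is ungapped, forward-strand only, and requires the read to fit
fully inside the reference (no overhang). The acceptance rule is at most
`max_seed_mm` (default 1) mismatches within the leftmost min(20, read
length) nt of the read; mismatches beyond the seed are unlimited by
default (`max_total_mm` caps them when set). All qualifying (reference,
offset) placements are kept and passed downstream — ties are resolved by
the EM, not by best-hit pruning.

Candidates come from an exact k-mer index (k = 10). With at most one seed
mismatch, one of the two disjoint 10-mers in the 20-nt seed must be
exact, so the lookup is lossless; reads shorter than (max_seed_mm + 1)·k
fall back to an exhaustive scan over all offsets. Reads containing
non-ACGT symbols are skipped with a warning. Reference FASTA is read
through Biopython with U→T normalization so RNA-space files work.

Assumptions: small ncRNA references are strand-resolved, and quality
scores carry no information after upstream trimming — adapter trimming
is out of scope and reads are assumed trimmed; the only read-level filter
is the inclusive 15–51 nt length window.

## EM multiread allocation

Reads with identical candidate sets collapse into equivalence classes.
Starting from uniform abundances over the references that received any
hit, the E-step splits each class's mass proportionally to current
abundances and the M-step re-estimates abundances from assigned mass.
Convergence: largest absolute change in expected counts < 1e−8, cap 200
iterations. Two invariants are enforced by construction and tested: mass
conservation at every iteration (Σ expected counts = aligned reads,
within 1e−9) and non-decreasing multinomial log-likelihood.

## Cluster-cardinality TMM normalization

Greedy clustering processes unique sequences in decreasing
total-abundance order, lexicographic on ties, which makes the partition
deterministic and independent of input record order; abundant sequences
found clusters and become virtual centres. Membership: the member is slid
along the centre at every ungapped shift; the unaligned residues at the
two ends (summed over both sequences) must not exceed `max_overhang`
(default 3, total across both ends; a `per_end` flag switches to a
per-end cap) and mismatches over the overlap must not exceed
`max_mismatch` (default 3). The member may be shorter or longer than the
centre.

Cluster cardinalities (per-sample summed member counts) feed the TMM
computation. The reference sample is the one whose upper quartile of
positive count proportions is closest to the mean upper quartile (ties:
first sample). Trimming drops the floor(n·0.30) smallest and largest
features by M and floor(n·0.05) by A, using stable ranks (position
breaks ties), and the factor is 2 to the precision-weighted mean of the
surviving M values with weights 1/[(N_s−y_s)/(N_s y_s) +
(N_r−y_r)/(N_r y_r)]. Factors are centred to geometric mean 1. A sample
sharing no positive feature with the reference, or losing every feature
to the trim, gets factor 1 with a warning.

Normalization rescales counts to counts-per-effective-library at the
cohort's mean effective depth, so normalized magnitudes remain comparable
to raw counts (tens to thousands) rather than fractions. The output
table's `library_sizes` hold that common depth — the correct denominator
for count tests on the normalized scale — and the per-sample effective
library sizes (library size × factor) are attached as metadata.

Known limitation: TMM factors are exactly invariant to proportional
columns, but only asymptotically invariant to rescaling a single column —
M, A and the trim are depth-free while the precision weights keep a weak
absolute-depth dependence (about 0.4 % drift at depth ~2·10³). The
property tests assert invariance at 2 % relative tolerance for this
reason.

## Differential expression

Effect size: log2((a + pseudocount)/(b + pseudocount)) with pseudocount
1.0 (configurable); values are rounded only at reporting time, half-up to
2 decimals. Evidence: two-sided Fisher exact test on
[[count, library − count] per group], fractional normalized values
rounded half-up to integers cell by cell. Two-sidedness follows the
point-probability rule — the sum of hypergeometric probabilities at the
observed margins that do not exceed the observed table's probability
(relative slack 1e−7 for float ties); the implementation evaluates the
hypergeometric pmf over the whole support in one vectorized call, and a
full-support sum within 1e−9 of 1 is reported as exactly 1. BH adjustment
is the standard step-up procedure (statsmodels), reported in input order;
significance uses the raw p (p < α = 0.05) together with |log2FC| ≥ 1.

Pooled-control comparisons report the mean normalized control count as
the control value and pool the Fisher table (summed counts, summed
depths), so each control keeps its weight. Sibling comparisons are
unpooled, and their per-class summary counts features common to both
samples (with significant up/down splits) and features exclusive to
either sample. Cross-couple common features must be significant in every
comparison with the same sign.

Caveat: a Fisher test on per-sample counts treats sequencing as binomial
sampling and ignores biological replication — with a single case sample
per comparison that is the only option, but p-values are anti-
conservative relative to a replicated negative-binomial test and should
be read as within-study rankings.

## Published reference values

The package bundles the published normalized count pairs, fold changes
and p-values for the 52 ncRNAs concordantly dysregulated in two sibling
couples (8 miRNAs, 44 piRNAs). The pseudocount-1 formula reproduces the
published log2FC exactly for the 8 machine-checked reference pairs and
for roughly two thirds of all 104 values; the remainder differ by
0.01–0.04 only because the published counts are printed rounded to one
decimal while the published fold changes were computed on unrounded
values. The sharpest property the printed precision supports — every
published log2FC lies in the exact interval implied by ±0.05 input
quantization — holds for all 104 values and is asserted in the tests; the
strict all-rows 2-decimal test is kept, and fails, to document the limit.

## Target intersection

Pure set algebra on TSV snapshots of target databases (no live queries;
cited databases are unversioned). miRNA maps keep evidence = validated
rows; piRNA maps keep, per ncRNA, rows at that ncRNA's maximum alignment
support. Gene symbols are uppercased on read-in. Membership annotation
against GMT collections reports hit genes and counts only — no
over-representation statistic is computed, because the procedure being
reproduced reports membership, not enrichment. The minimum supporting
sample count is a parameter (`min_samples` ≥ 2) rather than a constant,
since different analyses use 3 ("common to three samples") or "more than
two".

## Microbiome summaries

Rank aggregation pools OTUs unassigned at the requested rank under
`unassigned_<deepest assigned ancestor>`, so per-sample totals are
conserved exactly. Diversity follows the common marker-gene conventions:
Shannon in natural log and Simpson as 1 − Σ p² (inverse Simpson behind a
flag), both computed through scikit-bio. Group-level relative abundance
and taxon ratios are means over member samples (samples with a zero
denominator are excluded from ratio means with a warning). The
prevalence partition calls a family present in a group when more than
`presence_threshold` (default 0.5) of the group's samples exceed a
`detection_floor` of 1e−4 relative abundance; this is a deliberate,
simpler stand-in for model-based detection calls, comparable in kind but
not in letter. The group-mean convention for the phylum ratio is a
documented choice — pooled and per-sample-mean conventions genuinely
disagree on compositional data, and no result here depends on which is
used.

## Synthetic data

The generator's defaults are the study conditions the tests exercise: a
6-case / 6-control cohort; 15–51 nt references with a class mix of 20 %
miRNA / 50 % piRNA / 30 % other (the approximate detected-class
proportions in stool); multimap families sharing an identical internal
20-nt core; per-base substitution error 0.001; two-group gamma-Poisson
counts with 200 features at base mean 100 (uniform on [50, 200]), 10 %
of features spiked at log2FC 3 (half up, half down), dispersion 0.1 and
per-sample depth spread up to 4-fold (the depth spread is a free choice,
as no per-sample library sizes are published); Dirichlet-multinomial OTU
tables over a fixed bank of realistic gut lineages with designated
families given exactly zero expectation in the excluded group. One root
seed drives every generator through fixed per-product sub-streams, so
identical configurations give byte-identical FASTA/FASTQ/TSV outputs.

What the generator does not emulate — and hence what passing tests do
not show about real data: sequencing quality-score profiles, adapter
read-through and chimeras, strand errors, amplicon-specific biases
(the OTU table is simulated directly, not from reads), phylogenetic
correlation between taxa, and the heavy-tailed sparsity of real stool
small-RNA libraries. Recovery results on synthetic data bound what the
pipeline can do when its model assumptions hold, not field performance.

## Problem sizes

The test suite runs the alignment oracle at ≤ 30 reads × 10 references,
the clustering oracle at 50 sequences × 20 seeds, the Fisher sweep over
every valid 2×2 table with grand total ≤ 60, and the recovery experiment
at 200 features × 12 samples × 20 seeds; the end-to-end demo uses 60
references, 1 200 reads per sample and 60 OTUs across 4 samples. These
sizes were chosen to make every oracle exhaustive at desk scale while the
full suite stays fast.
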
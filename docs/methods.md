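# Methods

This note records the models, conventions and numerical choices behind
characlock, in the order a user meets them.

## Patristic-ratio clock dating

**Model.** The dating procedure assumes patristic distance on a protein
tree is linearly related to evolutionary time (a strict clock in
distance space). For an internal node, "the sequences connected through
the node" are formalised as the cross-pairs of the node's bipartition:
for a rooted binary node, every pair with one tip in each child clade;
for a multifurcation, every pair of tips drawn from two different child
clades. The node's depth is the arithmetic mean d̄ of those cross-pair
patristic distances, its dispersion the sample (n−1) standard
deviation, reported as absent when only one pair exists. With one
calibrated node (d̄_cal, T_cal), any node's date is
T = T_cal · d̄ / d̄_cal.

**Properties relied on.** The estimator is invariant to rescaling all
branch lengths by a positive constant and linear in T_cal. On an
ultrametric tree with branch lengths = rate × duration, every
cross-pair through a node has distance 2 × rate × height, so ratio
dates equal true node heights exactly; on real (non-ultrametric) trees
a child can be dated older than its parent — such violations are
flagged (`older_than_parent`), never corrected, because reconciling
them would smuggle in a rate-smoothing model the method deliberately
avoids.

**Uncertainty.** Published depths come with ± dispersions; the point
date is the primary quantity. When both the target and calibration
dispersions exist, a first-order delta-method band
T·√(cv_target² + cv_cal²) is attached. It treats cross-pair distances
as independent, which they are not (they share branches), so the band
is indicative, not a confidence interval.

**Calibration matching.** `date_all_nodes` requires the calibration
bipartition to be realised by a tree node (child-clade split, or clade
versus the rest). `strict_calibration=False` relaxes this: the
calibration depth is a functional of the distance matrix alone, so it
remains well-defined on a tree — e.g. one re-estimated from noisy
alignments — that fails to recover the calibration clade. The
simulation-recovery tests use the relaxed mode for exactly that reason.

**Gap partitioning.** Indel-rich protein alignments can be trimmed by
dropping every column whose gap fraction exceeds a threshold
(`max_gap_fraction`, default 0.5). The operation keeps columns in
order, is monotone in the threshold, and reports the retained site
count and mean gaps per sequence. The threshold is exposed because the
published trimming of the charavirus/tobamovirus CP alignment (447 →
165 sites) does not state its cutoff.

## Trees

Newick parsing/writing and tree surgery are delegated to dendropy;
internal-node labels are kept as support-value strings and otherwise
unused. Branch lengths are non-negative reals in substitutions/site;
duplicate tip labels and negative lengths are parse errors naming the
offender. Patristic distances are computed by one postorder sweep
merging per-clade tip-distance maps (O(n²) total) and are independent
of root placement; matrices are returned as validated symmetric,
zero-diagonal `skbio.DistanceMatrix` objects. The triangle inequality
is not enforced — estimated distances may violate it.

Midpoint rooting finds the longest tip-to-tip path from the patristic
matrix (ties broken by the lexicographically smallest tip pair, so
output is deterministic), walks the path to locate the midpoint's edge,
and reroots there; the two maximal root-to-tip distances agree to
1e-9. Neighbor joining is the standard Saitou–Nei algorithm with
deterministic tie-breaking on the Q-matrix argmin; a negative estimated
limb is clamped to zero with the deficit transferred to its sibling so
their sum is preserved, and a warning is issued. On additive input NJ
returns the generating topology and lengths to 1e-9. All length
comparisons use 1e-9 absolute tolerance.

## Genome comparison

Coordinates are 1-based inclusive. Translation uses the standard
genetic code; a trailing stop is dropped, an internal stop warns (the
'*' stays). An ORF whose span is not a codon multiple must be declared
`incomplete` (e.g. a coat-protein gene whose annotated 3′ end lies
beyond an incomplete assembly); `clamp_orf` trims it to the genome.

Identity comes from one global Needleman–Wunsch alignment
(Bio.Align.PairwiseAligner). Default scoring: nucleotide match +2 /
mismatch −3, first gap position −5, each further −2; amino acid
BLOSUM62, gaps −11/−1. The identity denominator is every core column
where at least one sequence is non-gap — "core" meaning terminal-gap
overhangs (such as a truncated CP tail) are excluded — with an
`ungapped` alternative restricted to doubly-aligned columns. The
denominator and scoring are configurable because published identities
depend on the aligning tool's conventions; percentages are reported to
one decimal place. Amino-acid similarity counts identical residues plus
positive-scoring BLOSUM62 pairs, so similarity ≥ identity. For
two annotated genomes the primary summary is concatenate-then-align
identity over the shared ORFs, with the per-ORF table and its
aligned-length-weighted mean as the breakdown. The sliding-window
track computes per-window identity over the columns of a single global
alignment — a numeric stand-in for an mVISTA-style similarity panel,
not an alignment visualization.

Composition is reported over non-N positions; A+C+G+T fractions sum to
1 and G+C = G + C exactly. (Aside: a 6732-nt ORF of a 9593-nt genome is
70.2% of it; the package reports the computed ratio.)

## K-mer correspondence analysis

Counts are overlapping, on the given (coding) strand only — the inputs
are mRNA-sense ORFs, so no reverse-complement canonicalization —
with windows containing ambiguity codes skipped. k defaults to 4
(tetranucleotides carry the clearest host signature) and 2..7 are
supported. Raw counts, not frequencies, enter CA: CA normalizes by the
table margins internally, and length differences between genes are
part of the margin structure (a length-normalized route can be had by
passing scaled profiles, but raw is the default).

CA itself: with P the table over its grand total, r and c the margins,
the standardized residuals S = (P − rcᵀ)/√(rcᵀ) are decomposed by SVD;
row/column principal coordinates are the singular vectors scaled by
√margins and singular values; axes are ordered by decreasing singular
value; total inertia ΣS² equals the Pearson chi-square statistic over
the grand total. Axis signs are fixed by making the first non-zero
*column* loading of each axis positive — keyed to columns so that
permuting rows permutes row coordinates without flipping axes. Axes
with singular value below 1e-10 of the largest are dropped; a rank-1
(independence) table therefore yields zero axes, and all-zero rows or
columns are pruned with a warning. Group cohesion is the mean
silhouette score per group on the first two principal axes (zero-padded
if only one axis survives), computed with scikit-learn.

## Virome profiling

**Rarefaction.** Each iteration draws the configured depth without
replacement from each sample's contig counts (numpy's multivariate
hypergeometric), so per-iteration column sums equal the depth exactly;
the reported table is the per-cell mean over iterations (defaults:
depth 158,376 — the smallest library of the motivating study — and
1000 iterations), with the raw draws available for dispersion. Strict
mode rejects samples shallower than the depth; non-strict drops them
with a warning. Everything is reproducible under the config seed.

**Normalization.** The default divides each contig's rarefied count by
its length relative to the mean contig length (a contig twice the
average length gets half the abundance for equal reads). The source
phrase "normalized by the number of reads divided by the average contig
size" is grammatically ambiguous; the alternative reading — divide all
counts uniformly by the mean length — is available as
`mode="mean_length"` and differs only by a per-sample constant.

**SNV calling.** One record per non-reference base with at least
`min_count` supporting reads (default 2, the quality-based-detection
threshold the pipeline mirrors); several alternatives at a position
give several records; deletions are reported (`alt='-'`) but never
classified; zero-depth columns are skipped with a warning. Per-base
qualities are not modelled because they are not preserved in the
consumed pileup tables. Classification substitutes the alternative
base into its codon and translates both codons with the standard code;
positions outside every ORF, or in a trailing incomplete codon of a
truncated ORF, are noncoding. The summary reports per-ORF counts and
nonsynonymous fractions, a frequency spectrum in ten equal bins (last
bin closed at 1.0), and an `infrequent` flag defined as median variant
frequency < 0.5.

## Synthetic data

**Clock alignments.** Amino-acid evolution on an ultrametric dated tree
under a Poisson equal-rates model: each branch of duration t receives
Poisson(rate·t·sites) events, each hitting a uniform site and replacing
the residue with one of the 19 others uniformly. This is the 20-state
Jukes–Cantor-type model, chosen over a rate matrix because the dating
method assumes only linearity and the equal-rates model has closed
forms for tests: expected distance 2·rate·TMRCA, observed difference
fraction p = (19/20)(1 − e^(−20d/19)), inverted by
`protein_distance_matrix(correction="jc20")` for the recovery loop.
Default rate 2e-3 substitutions/site/my on trees with root height
100–130 my, giving depths up to ~0.5 subs/site — comfortably below
saturation. Random dated trees use sorted-uniform node heights with
uniform random joins; random additive (non-clock) trees use uniform
branch lengths, for exact NJ recovery checks.

**Host-biased CDS.** Host signatures are positive, normalized
tetranucleotide weight vectors. Sequences are emitted by an order-3
Markov chain — P(next base | previous 3) ∝ weight(tetramer)^strength —
in whole-codon lengths. The chain operates on nucleotides rather than
codons so that strength 0 reduces exactly to uniform i.i.d. bases
(uniform expected tetramer composition), a property per-codon sampling
over the 61 sense codons cannot provide; the cost is that simulated
"coding" sequences can contain in-frame stops, which is irrelevant to
the k-mer analyses they feed.

**Pileups.** At each planted position the alternative count is
Binomial(depth, frequency), remainder reference; no sequencing-error
model by default (an `error_rate` flag flips reference reads uniformly
to other bases), so recall/precision against the truth table are
exact. Conflicting variants at one position are rejected; frequency-0
entries are dropped. The truth table carries each variant's
synonymous/non-synonymous status from the codon table.

All generators are byte-deterministic under a seed.

## What the synthetic tests do and do not show

The generators emulate the *statistical* structure the methods assume:
clock-like divergence, compositional host bias, binomially sampled
variant frequencies. They do not emulate alignment error, among-site
rate variation, codon structure in the clock model, mapping artefacts,
strand bias, or sequencing error (unless enabled). Passing the recovery
tests therefore shows the estimators are correct under their stated
models, not that real trees, real pileups or real k-mer tables satisfy
those models. Comparisons against the deposited charavirus genomes
(GenBank MK521928, JF824737) are included as tests that run only when
those sequences have been fetched into `data/accessions/`; they are not
redistributed here.

## Problem sizes in the default test run

Property suites use 10-tip trees (100 replicates for NJ recovery and
the clock-recovery error bound, 500 sites per alignment), 6×16 CA
tables (20 replicates), rarefaction at depth 100 with 1000 iterations,
the exhaustive 576-case codon-change enumeration, and 50-seed
planted-variant calling at depth 200. These sizes make the full suite
run in well under a minute while leaving the Monte-Carlo bounds (3
standard errors; median relative error < 25%) statistically meaningful.
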
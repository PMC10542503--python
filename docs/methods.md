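# Methods

This note documents the statistical models, numerical choices and
design decisions behind orthoexpress, and what the synthetic-data tests
do and do not establish about real data.

## Count model and normalization

Counts for locus *g*, sample *j* of taxon *t* are modelled as negative
binomial with mean `μ_gt · s_j` and common dispersion φ, variance
`μ + φμ²`; φ = 0 degenerates to Poisson. This is the standard
mean/dispersion parameterization for bulk RNA-seq, and the single
common dispersion (no tagwise or trended shrinkage) is the minimal
model that is fully testable by parameter recovery.

TMM factors compare each sample against a reference (the sample whose
75th-percentile relative abundance is closest to the mean). Per locus,
`M = log2((y_k/N_k)/(y_r/N_r))` and `A = ½·log2((y_k/N_k)·(y_r/N_r))`
are computed over loci positive in both samples; the top and bottom
30% by M and 5% by A (rank-based, defaults configurable) are trimmed
and the factor is `2^(Σ w·M / Σ w)` with inverse asymptotic-binomial
variance weights `1/w = (N_k−y_k)/(N_k·y_k) + (N_r−y_r)/(N_r·y_r)`.
Factors are renormalized to geometric mean exactly 1. A sample with
all M-values below 1e−6 in magnitude gets factor 1 directly. CPM
divides by the effective library size (raw size × factor) times 1e−6;
Fig-style summaries use `log2(CPM + 1)` (pseudocount configurable; 1
is the convention).

Depth invariance of the factors is exact in the M-values; the
inverse-variance weights are depth dependent, so invariance is
asymptotic. The test suite asserts a <0.02 log2-unit leak under a 9×
depth change on expression-like data rather than exact equality.

## Dispersion and the exact test

Libraries are first equalized: counts are scaled to the geometric-mean
effective library size and rounded to integers. This deviates from
edgeR's quantile adjustment deliberately — it makes the conditional
distributions exact and simple at the cost of a rounding perturbation
that is negligible at realistic depths.

With equal libraries, the per-group totals-conditional likelihood of a
locus is Dirichlet-multinomial in r = 1/φ:

    log P(y | z) = Σ_i log Γ(y_i + r) − n log Γ(r) + log Γ(n r)
                   − log Γ(z + n r) + log Γ(z+1) − Σ_i log Γ(y_i+1)

summed over loci and over every taxon with ≥2 replicates. φ is found
by a 41-point log-spaced grid search on [1e−6, 5] refined by bounded
scalar minimization; the Poisson limit is evaluated explicitly and the
estimate is clamped at 0. Recovery tests place the estimate within
[0.07, 0.13] at truth 0.1 with 1000 loci.

For the pairwise test, the sum of n i.i.d. NB(μ, φ) counts is
NB(n·μ, φ/n) exactly (size n·r), so conditional on the grand total z
the group-A total follows a beta-binomial-type law over 0..z, computed
in log space and normalized. The two-sided p doubles the smaller tail
(both tails include the observed point) and is capped at 1; at φ = 0
the conditional law is Binomial(z, n_A/(n_A+n_B)). An independent
oracle in the tests builds the same law by brute-force convolution of
per-replicate pmfs and agrees to 1e−10 for totals ≤ 200.

log2 fold changes use normalized group means with 0.125 pseudo-counts
added per group (configurable): finite at zero counts, negligible
elsewhere. DE calls use strict `q < α` (α = 0.05 default) after
Benjamini–Hochberg adjustment (statsmodels step-up; brute-force oracle
in tests). No fold-change cutoff is applied, and low-expression
filtering is off by default with an optional min-CPM flag — the main
analysis design keeps all loci.

## RBBH diagnostics

Best hits are resolved per query by bitscore, then lower e-value, then
longer alignment, then lexicographic subject id; multiple HSPs of one
query/subject pair collapse to the best under the same ordering. The
tie-break chain makes extraction deterministic and order-independent;
a brute-force all-pairs enumeration oracle checks equivalence on
random tables.

The contingency null is independence of the two members' DE states
with the marginal rate estimated from the 2N members themselves —
expected counts `(N p̂², 2N p̂(1−p̂), N(1−p̂)²)`, χ² with df = 1 (three
cells minus one constraint minus one estimated parameter), effect size
φ = √(χ²/N). An externally supplied marginal (e.g. the
transcriptome-wide DE rate) is exposed as an alternative null because
the choice is not uniquely determined; the member-based null is
self-contained and calibrates correctly under simulation (5%-level
rejection rate within [0.02, 0.09] across 200 null seeds). Degenerate
marginals (p̂ ∈ {0,1}) return a report flagged undefined rather than a
fabricated statistic.

The direction partition reports the observed reciprocal fraction
against `2q̂(1−q̂)` with q̂ the bro>fru frequency among both-DE
members. The attached exact binomial test is an extension (flagged in
the report's metadata); the comparison itself is the scientifically
meaningful part: reciprocal excess ⇒ non-co-assembling orthologs,
same-direction excess ⇒ DE paralogs.

## Orthogroup filter

Distances are alignment-free: 1 − cosine similarity of overlapping
6-mer count vectors. This keeps the stage dependency-light and fast;
the distance backend is pluggable and k configurable. Neighbor joining
is implemented directly (Q-matrix agglomeration, smallest-index tie
break, negative branch lengths clamped to 0, trifurcating root) so its
numerical behaviour is pinned; scikit-bio's NJ serves as an
independent cross-check in the tests, and NJ provably recovers the
generating topology on additive inputs (checked on 50 random 6–8 leaf
trees).

A genus is monophyletic when its leaves form one side of a tree
bipartition — equivalent to the rooted clade criterion for any root
outside the genus, which an outgroup-genus leaf provides; with ≤1
outside leaf the test is vacuous. Orthogroups with <4 members, <2
genera or missing sequences are kept but flagged untested rather than
silently passed; the filter report partitions the input into
kept/removed/untested, with removed = any tested genus (or just the
focal genus, if one is named) having ≥2 members that are
non-monophyletic.

## Phenotype classification

A class row matches when every constrained comparison agrees (DE cells
observed DE, not-DE cells observed not-DE; free cells unconstrained).
Because free cells let rows overlap, a single primary label is
resolved by precedence: shared hybrid classes (novel both, both
bro-like, both fru-like) over species-specific parent-like classes
over species-specific novel classes over bare parental DE. Shared
before species-specific reproduces the additivity of combined
parent-bias counts; parent-like before species-specific novel was
chosen because every exact mean pattern realising a species-specific
parent-like class in one hybrid necessarily makes the other hybrid's
expression novel, and the parent-like reading is the more conservative
one. The parental-DE and hybrid-DE rows are reported as marginal
counts — that is how the class accounting adds up. A locus matching
both species-specific novel rows (all four hybrid–parent comparisons
DE plus hybrid–hybrid DE) is counted once in each hybrid's novel tally
and flagged `dual_novel`.

Novel loci are annotated per hybrid from TMM-normalized CPM group
means: transgressive up/down when the hybrid mean lies outside the
parental range, intermediate otherwise. The mean-ordering rule for
intermediacy is a documented choice. Parental-bias ratios round the
bro-like share to the nearest percent with the complement forced to
100.

## Synthetic data: what it emulates and what it does not

Defaults mirror the study design: 6 replicates × 4 taxa, NB dispersion
0.1 and baseline mean 50 per locus (typical bulk-RNA-seq values; not
stated by the design, chosen once), effect size 2 log2 units, and
phenotype-class fractions matching the class proportions of a ~37k
orthogroup accounting. Each class has one canonical mean pattern, with
a random ± sign on the effect; "parental_de" places hybrids at the
parental geometric midpoint, which under the class table is itself a
shared novel (intermediate) phenotype once the half-effect is
detectable — its expected class is therefore recorded as novel_both. A
locus DE between the parents whose hybrids are indistinguishable from
*both* parents is not realisable with exact means; in real data that
disjoint "bare A" class arises from effects near the detection limit.

Split-ortholog injection replaces a no-DE locus by two transcripts
carrying the bro- and fru-lineage samples' counts, with a binomial 1%
leak crossing lineages (exact per-sample mass conservation, no
degenerate all-zero rows). Hybrids follow the bro lineage by default,
echoing the hybrids' strongly bro-biased genomic composition; this is
a modelling choice, configurable, because transcript-level inheritance
at split loci is not observable from the design. DE-paralog injection
draws two fresh transcripts at half the locus baseline, both DE in the
same random direction. The emitted hit table makes partner pairs
mutual best hits, adds optional benign background RBBH pairs between
random opposite-lineage transcripts (these supply the one/neither-DE
categories), and adds one-directional noise hits with strictly lower
bitscores and no reciprocal duplicates — so the recoverable RBBH set
is exactly known.

Orthogroup sequences evolve by uniform per-site substitution (a
Jukes–Cantor-style model without rate variation) down a fixed
((focal),(outgroup)) topology, one transcript per focal taxon plus two
outgroup genera; contaminated orthogroups graft an extra focal-genus
transcript *inside* the outgroup clade (sister to one outgroup leaf),
which guarantees non-monophyly of the focal genus in the true tree.

Not emulated: locus-to-locus baseline variation, GC/length biases,
isoform structure, read-level errors, correlated replicates,
rate-heterogeneous or indel-bearing sequence evolution, and partial
(as opposed to complete) assembly splitting. Passing recovery tests
therefore demonstrates correctness of the algorithms under the stated
model, not robustness to every artifact of real libraries.

## Problem sizes and determinism

Recovery suites run at desk scale, chosen once: 1000-locus dispersion
recovery, 200-seed all-null family-wise error and χ²-calibration
checks, 1500-locus diagnostics at split fractions {0, 0.02, 0.05,
0.10}, 200 orthogroups for the monophyly filter, 2000-locus phenotype
recovery. All randomness flows through numpy Generators seeded from
explicit integers; identical configuration and seed give
byte-identical outputs, including the pipeline runner, whose manifest
records the configuration echo, stage timings and outputs.

## Known limitations

- The DE stand-in is oracle-verified but not numerically identical to
  edgeR (different library equalization; common dispersion only).
- The member-based χ² null and df = 1 are one defensible reading of
  "expected by chance"; the alternative external-rate null is exposed
  but not the default.
- k-mer cosine distances saturate for divergent sequences; the filter
  is tuned for congeneric transcripts plus moderate outgroups, not
  deep phylogenies.
- The precedence resolution of overlapping phenotype rows is a
  reconstruction; other orderings are defensible and the class table
  itself is exposed for callers who need a different convention.
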
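# orthoexpress

Comparative-transcriptomics toolkit for studying gene-expression
evolution in homoploid hybrid speciation: two parental species
(`bro`, `fru`) and two independently derived homoploid hybrid species
(`sun`, `lem`), six biological replicates each, quantified on de novo
assemblies where true orthologs may fail to co-assemble.

It is aimed at researchers comparing expression across closely related
non-model species, where the analysis units are transcripts, one-to-one
orthologs or orthogroups and where assembly artifacts can masquerade as
biology.

## What it computes

**Differential expression.** Counts are TMM-normalized (trimmed mean of
M-values: per-sample factor `2^(weighted mean of trimmed M-values)`,
inverse asymptotic-variance weights, geometric mean fixed to 1). Each
ordered taxon pair is tested with a conditional negative-binomial exact
test: counts are NB(μ, φ) with variance `μ + φμ²`, the common
dispersion φ is estimated by conditional maximum likelihood on
library-equalized counts, and the two-sided p-value doubles the smaller
tail of the group-total distribution conditional on the grand total.
Loci with Benjamini–Hochberg `q < 0.05` are DE; no fold-change cutoff
is applied.

**Co-assembly diagnostics.** Reciprocal best blast hits (RBBHs) between
two transcript sets are cross-tabulated by DE status (both / one /
neither DE). Deviation from independence is tested by χ² (df = 1,
marginal DE rate estimated from the 2N RBBH members) with effect size
`φ = √(χ²/N)`. Both-DE pairs are partitioned into reciprocally-DE vs
same-direction-DE; under random pairing the reciprocal fraction has
expectation `2q(1−q)` where `q` is the bro>fru direction frequency.
An excess of reciprocal pairs indicates orthologs failing to
co-assemble; same-direction pairs indicate genuinely DE paralogs.

**Orthogroup filtering.** One-to-one orthologs (exactly one member per
taxon) can be extracted directly; alternatively, orthogroups whose
neighbor-joining gene tree (alignment-free k-mer cosine distances,
k = 6) shows a genus's transcripts to be non-monophyletic are removed
as likely paralog-containing.

**Expression phenotypes.** The six pairwise DE indicators per locus —
(bro,fru), (bro,sun), (bro,lem), (fru,sun), (fru,lem), (sun,lem) — are
matched against a class table: DE between parents (A), novel expression
in one or both hybrids (B), parent-like expression (C), DE between the
hybrids (D). Novel loci are annotated transgressive (hybrid mean
outside the parental range) or intermediate, and combined parent-like
counts give a parental-bias ratio.

**Synthetic data.** A ground-truthed generator produces NB count
matrices for the 6×4 design with configurable phenotype-class mixes,
injectable split-ortholog and DE-paralog artifacts with a matching
BLAST outfmt-6 hit table, and orthogroup sequence sets with known
genus-monophyly status — so every stage is testable without any
sequencing data.

## Worked example

`examples/04_phenotype_classes.py` simulates 2,000 loci with known
phenotype-class fractions at a 3 log2-unit effect, runs the six DE
comparisons and classifies every locus:

```
parental_de      294
novel_sun         25
novel_lem         31
novel_both         7
sun_bro_like      66
sun_fru_like      48
lem_bro_like      73
lem_fru_like      40
both_bro_like     30
both_fru_like     32
hybrid_de        289
novel loci in one or both hybrids: 63
sun: 96 bro-like vs 80 fru-like (55:45)
lem: 103 bro-like vs 72 fru-like (59:41)
novel-mode (sun): {'transgressive_down': 19, 'transgressive_up': 13}
```

`parental_de` and `hybrid_de` are marginal counts (all loci DE between
the parents, respectively between the hybrids); the B/C rows are
disjoint class counts. The bias lines combine species-specific and
shared parent-like counts into a rounded percent ratio, and the novel
loci are overwhelmingly transgressive, as expected when hybrid means
sit outside the parental range. The other example scripts cover DE
calling, the RBBH diagnostics, the monophyly filter and the global
correlation/PCA summaries; `orthoexpress run-all --out results/` runs
the whole chain from a simulated dataset and writes a run manifest.

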
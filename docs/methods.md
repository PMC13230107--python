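# Methods

This note documents the models and procedures the package implements, the
conventions chosen where several defensible options exist, what the synthetic
generator does and does not emulate, and known limitations.

## Per-gene codon-usage metrics

**Unit of analysis.** One in-frame CDS over {A,C,G,T,N}. Sequences whose
length is not a multiple of three raise a frame error; in batch mode such
genes are logged and skipped rather than aborting the run.

**Exclusion conventions, applied uniformly.** The terminal stop codon is
excluded from %GC, CAI and Nc. Codons containing N, and internal stop codons
(annotation artefacts), are excluded from all codon-level computations; the
excluded count is carried on the per-gene record and internal stops are
logged. A stop-inclusive %GC variant exists behind
`positional_gc(..., include_terminal_stop=True)` for sensitivity checks,
since published web calculators do not document this choice.

**Positional GC.** %GCk = 100 × (G+C at codon position k) / (codons
counted); overall %GC is taken over all three positions of the counted
codons, so with no exclusions %GC = (%GC1 + %GC2 + %GC3)/3 exactly (asserted
as a property test).

**CAI (Sharp & Li).** Relative adaptiveness w(codon) = count / max family
count within each synonymous family of the reference table; CAI is the
geometric mean of w over the gene's codons, computed in the log domain
(equal to the direct product to 1e-12; asserted). Stop codons and the
single-codon families ATG and TGG are excluded — they carry no synonymous
information and would bias CAI toward 1. Reference codons with zero count
receive a 0.5 pseudo-count before normalisation so no weight is zero; a
family whose counts are all zero makes the reference table unusable and is
an error.

**Nc (Wright).** Per synonymous family with n ≥ 2 codons, homozygosity
F̂ = (nΣp̂ᵢ² − 1)/(n − 1); families with F̂ ≤ 0 are dropped. Class averages
F̄k over the 9 two-fold, 1 three-fold (Ile), 5 four-fold and 3 six-fold
families give Nc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆. When Ile is absent the
three-fold contribution is imputed as 1/F̄₃ = (1/F̄₂ + 1/F̄₄)/2 — i.e. the
mean of the neighbouring class contributions; this is this package's
convention (Wright's original text averages F̄₂ and F̄₄ directly; the two
differ negligibly in practice). When the two-, four- or six-fold class
average is unavailable (very short genes), Nc is **unset**, not guessed;
unset genes are dropped pairwise (not listwise) from downstream statistics
with a logged count. The estimator can exceed its theoretical maximum on
small samples and is capped at 61. The genetic code is fixed to the
standard/bacterial table (identical degeneracy structure for both).

**Functional categories.** Case-insensitive whole-word keyword matching on
product strings against five configurable vocabularies (structural:
packaging, terminase, portal, capsid, head, neck, tail, baseplate,
adsorption; regulatory: repressor, antirepressor, activator, sigma,
anti-sigma, response regulator, transcriptional regulator; lysis: endolysin,
holin, amidase, lysin, hemolysin; replication: replication initiation,
polymerase, helicase, primase, exonuclease; repair: methyltransferase,
methylation, ArdA, Lar, hydroxymethylase, DndB). Multi-category hits resolve
by the precedence lysis > replication > repair > regulatory > structural
("tail-associated lysin" is lysis); no hit is "unclassified". Word-boundary
matching prevents short keywords from firing inside longer words ("lar"
never matches "large"). The default vocabularies are a reasonable phage
annotation lexicon, not a claim of exhaustiveness.

## Combined genomic distance

Directional %ID/%Cov records (BLAST tabular style; the coverage column name
is a reader parameter because conventions vary) are averaged per unordered
pair, one direction standing on its own; duplicate directional rows are
averaged with a warning (multiple HSPs are assumed pre-aggregated upstream).
d = √((1 − %ID/100)² + (1 − %Cov/100)²) ∈ [0, √2]. Pairs with no hit in
either direction are NSS — structurally determined, with no e-value
re-thresholding — and carry exactly √2. Summaries use type-7
(linear-interpolation) quantiles and the n−1 standard deviation; the
`valid_only` scope drops NSS pairs (and additionally reports %ID/%Cov
statistics), `all_pairs` keeps them at √2. NSS-at-maximum can overstate
divergence where homology sits below detection thresholds; the dual-scope
report keeps that assumption visible.

## Statistical procedures

All tests are two-sided at α = 0.05. Kruskal–Wallis uses pooled mid-ranks
with the tie-correction divisor 1 − ΣT/(N³ − N); effect sizes are
η² = (H − k + 1)/(N − k) and ε² = (H − k + 1)/(N − 1), with ε² labelled
negligible < 0.01 ≤ small < 0.08 ≤ moderate ≤ 0.26 < large. Dunn's z uses
SE² = (N(N+1)/12 − ΣT/(12(N−1)))(1/n₁ + 1/n₂); the tie term is always
applied and vanishes without ties. Holm/Bonferroni act on unrounded
p-values. Mann–Whitney uses exact enumeration for small untied samples
(n₁n₂ ≤ 400) and the tie-corrected normal approximation otherwise. Cliff's
δ = (#{x>y} − #{x<y})/(n₁n₂), labelled at |δ| 0.147/0.33/0.474.

Spearman CIs are percentile bootstrap over paired resamples (B = 1000
default, seeded); degenerate resamples (a constant vector) are redrawn and
counted. Partial Spearman is rank residualization: rank-transform all
variables, regress the ranked x and y on the ranked covariates (with
intercept) by least squares, correlate the residuals; p uses the t
approximation with df reduced by the covariate count. A variable exactly
equal to a covariate leaves zero residual variance and returns ρ = 0, p = 1
(perfect confounding) rather than an error; collinear ranked covariates are
an error.

Scheirer–Ray–Hare ranks globally, decomposes rank sums of squares by cell
means, and refers H = SS_effect/MS_total to chi-square at the effect df;
each factor needs ≥ 2 levels and every cell ≥ 1 observation.

PERMANOVA z-scores the feature columns (after an optional seeded per-group
subsample without replacement — one fixed subsample per contrast, not
repeated subsampling), computes squared Euclidean distances, and forms
pseudo-F = (SS_b/(k−1))/(SS_w/(N−k)) through the Gower quadratic-form
identity; p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm) over label permutations
(999 default) and R² = SS_b/SS_total. Permutations are batched through one
matrix product per group, so the study-scale run (two groups of ~2,000
genes) takes seconds. PERMDISP uses distances to the group **centroid** in
the same z-scored space (the natural choice for a Euclidean embedding, vs
the spatial median) with a permuted one-way F. PERMANOVA is sensitive to
dispersion differences, which is why the dispersion companion is always
reported next to it.

## Pipeline conventions

The per-gene metrics table is the hub; the statistics bundle has seven
blocks (genome size; per-metric omnibus; pairwise contrasts for significant
metrics; correlation matrices with bootstrap CIs, BH correction, and partial
correlations controlling %GC3 and overall %GC with gene length
log10-transformed; functional-category analyses; PERMANOVA/PERMDISP per
lifestyle pair; genome size vs tRNA count). Functional-category comparisons
default to **genome-level medians** as the unit of observation (one value
per genome × category), with `category_unit="gene"` available — gene-level
units inflate n and risk pseudoreplication since genes are nested in
genomes. Genes with unset Nc are excluded pairwise per metric. Block
failures are isolated: a failing block records its error and the run
continues. Every stochastic block derives its seed from the run seed by a
fixed offset, making full runs bit-reproducible.

## Synthetic data generator

The generator emulates the study conditions the pipeline is meant for:
three lifestyle groups of 30 genomes, genome sizes from truncated-normal
mixtures (temperate 43,297 ± 1,423 bp on [39,968, 45,985]; prophage
57,000 ± 12,000 bp right-truncated at 130,595; virulent a 0.42/0.58 mixture
of 17,500 ± 600 and 135,000 ± 7,000 bp), gene lengths log-normal on codon
counts (median ~130 codons, σ = 0.9, floor 21), gene counts scaling so
summed CDS length is ~90% of genome size (giving realistic per-lifestyle
gene-set size ratios rather than a fixed count per genome).

Codon sampling: amino acids follow the reference table's amino-acid
frequencies (uniform amino-acid usage would distort Nc family
availability); within a family, a codon follows host usage with probability
`host_mix_alpha` and otherwise a GC3 tilt that weights G/C-ending codons by
gc3_target/100. The two-step draw is sampled through the equivalent joint
61-codon distribution. The tilt acts only at third positions, so GC1/GC2
emerge from amino-acid composition alone and the lifestyle signal is
synonymous by construction. Defaults: GC3 tilt targets 19.8/28.0/25.8
(virulent/temperate/prophage), NSS rates 0.591/0/0.055, %ID means
86.89/83.51/84.62, and host-mix α = 0.85/0.25/0.40 — the α values
calibrated once so generated group means of CAI and Nc fall in the observed
ranges (~0.72/37 virulent vs ~0.65/44 temperate). tRNA carriage is gated on
genome size (≥ 120 kb, presence probability 0.56, 2–15 copies), so tRNAs
appear only in large virulent genomes.

The host reference table is a **synthetic stand-in** constructed in code
(`synthetic_host_table`): staphylococcal-style amino-acid frequencies and a
strong A/T-ending within-family preference (third-base weights
0.55/0.30/0.09/0.06 for A/T/G/C), ~1.5M codons total. Real Kazusa-format
tables are read by `io.read_codon_usage_table` and drop in directly.

**What the generator does not emulate:** mosaicism/recombination structure,
phylogenetic correlation between genomes, real BLAST alignment behaviour
(hits are drawn, not aligned), annotation noise in product strings, and
ambiguity codes (generated CDSs contain no N). Passing the recovery tests
therefore shows that the pipeline detects the modelled compositional and
size structure at realistic scales — not that it is robust to every
property of real annotations.

## Problem sizes and numerical choices

Default study-scale runs use 30 genomes per lifestyle (~8,000 genes,
~1.6M codons), 999 permutations, bootstrap B = 1000, and PERMANOVA
subsampled to the smallest group's gene count; a full run completes in a few
minutes on one CPU and is bit-reproducible under a fixed seed. Examples and
most tests use scaled-down configurations (4–8 genomes per group, 49–199
permutations) chosen so each check still has clear signal. Tolerances:
oracle-equivalence checks at 1e-9 to 1e-12; quantile convention type-7
throughout; sample SD with n−1 everywhere.

## Known limitations

- CAI and Nc are reference- and length-sensitive; genes shorter than ~100
  codons give noisy Nc (and Nc may be unset for very short genes).
- Gene-level tests treat CDSs as independent despite nesting within genomes;
  the genome-median unit for category analyses mitigates but does not remove
  this.
- The NSS-at-maximum convention upper-bounds divergence; it is a selection
  and heterogeneity device, not an evolutionary distance.
- Holm/BH adjusted p-values are not idempotent under re-adjustment (the
  family-size factor re-applies); adjusted values should never be fed back
  through a correction.
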
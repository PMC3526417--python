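# Methods

`introcold` re-implements, as a tested pipeline, the comparative analysis
used to dissect cold-tolerance enhancement in an introgression line (IL)
against its recurrent parent: a two-genotype, five-timepoint (2, 6, 12,
24, 48 h), three-replicate cold-stress expression experiment with one
pooled control per genotype. This note records the models, the parameters
that matter, the numerical choices, and what the synthetic data can and
cannot show.

## Differential expression: moderated statistic + permutation null

For gene *i* and a two-group contrast, the statistic is

    d_i = (x̄_A,i − x̄_B,i) / (s_i + s0)

computed on log2(intensity + pseudocount), where `s_i` is the pooled
two-sample standard error and `s0` a fudge factor that stabilises
low-variance genes. `s0` defaults to the median (50th percentile) of the
per-gene `s_i`; with `s0 = 0`, `d` is exactly the equal-variance
two-sample t statistic. Significance requires the conjunction of a
permutation p-value below 0.05 and a linear fold change (ratio of linear
group means) above 5 or below 1/5 — the fold gate, not the p-value alone,
is what suppresses false calls among low-effect genes at three
replicates.

**Permutation null.** All C(n, n_A) two-class label assignments are
enumerated when there are at most `n_permutations` of them (20 for 3v3 —
the default design is always exhaustive); otherwise assignments are
sampled with a seeded generator, always including the identity so p > 0.
Ties |d*| = |d| count as exceedances (conservative).

**Pooling choice.** By default each gene's p is the tail fraction of the
*pooled* permuted |d*| of all genes (the convention of the original SAM
software). This is a deliberate design choice: in a 3v3 design the
label-swap assignment always reproduces |d| exactly, so a strictly
per-gene p can never fall below 2/20 = 0.10 and a 0.05 cutoff would call
nothing; pooling across genes resolves p to 1/(G·B) granularity and is
empirically well calibrated (measured null type-I rate 0.048–0.050 at
2,000 genes). A `per_gene` mode is exposed for strict single-gene
enumeration; there p is a multiple of 1/B with floor 2/B.

**q-values.** SAM-style median false-call ratio: at each observed |d|
cutoff, the median across permutations of the number of permuted
statistics exceeding it, divided by the observed calls, clipped to [0, 1]
and monotonised. q is reported for information; the stated gate is p.

## Temporal set algebra

Timepoints map to phases I (2–6 h), II (12 h), III (24–48 h). Common
genes at a phase are significant with the same direction in both
genotypes at ≥ 1 timepoint of that phase (same-phase mode; a
same-timepoint mode is exposed, since the source analysis does not state
which was used). Genotype-specific sets are global: significant with a
direction in one genotype at ≥ 1 stage and never with that direction in
the other at any stage; a gene induced in one genotype and repressed in
the other is kept in both direction ledgers and flagged as a direction
conflict rather than silently dropped. Constitutive IL-up/-down genes are
significant in the IL-vs-parent contrast under control conditions and not
significant in any within-genotype cold contrast. Continuity means ≥ 1
significant timepoint in each of the three phases.

## Clustering

Profiles are per-gene, per-genotype time courses of replicate-mean log2
values (control then each timepoint, both genotypes concatenated),
median-centered per gene. Dissimilarity is centered correlation distance
1 − r ∈ [0, 2]; constant profiles are rejected (undefined correlation).
Agglomeration is UPGMA via the exact unweighted-average Lance–Williams
recurrence, with ties in the minimum distance broken by the
lexicographically smallest pair of lowest member leaf indices — the merge
sequence is fully deterministic and order-insensitive. Average-linkage
heights are monotone, so the k-cluster cut removes the k−1 highest (last)
merges. Six clusters is the default cut, matching the six canonical
genotype-temporal patterns. CDT/GTR export and a basic heat map are
provided for viewers.

## DRE regulon

Promoter windows are −1000..−10 relative to the start codon (991 nt,
reverse-complemented for minus-strand genes, truncated with a warning at
chromosome edges). The source describes the same window as "1 kb
upstream" in one place and −10..−1000 in another; the −10..−1000 window
is implemented. The scanner reports every occurrence of GCCGAC/ACCGAC
and, by default, of their reverse complements as minus-strand hits
(DRE/CRT elements act strand-agnostically; a plus-only mode is exposed
for the strict reading). Regulon membership = commonly cold-induced ∧
≥ 1 DRE hit. Co-expression with a driver is Pearson r > 0.9 (strict) over
the concatenated genotype-wise mean-log2 time course; "specific to driver
C" means co-expressed with C and with neither other driver — the
operational reading of "exclusively regulated", recorded here because the
source does not define it. Flat profiles are flagged and excluded from
co-expression rather than erroring the batch.

## GO enrichment

Flat term → gene map (GO-slim style; graph propagation must be
pre-applied to the GMT). Exact upper hypergeometric tail P(X ≥ k) with
study size n, term sizes K, population N; unannotated genes count in N
only. Benjamini–Hochberg across tested terms is emitted alongside raw p.
The reported `fraction` is k/n.

## Co-localization

Intervals are 0-based half-open (BED native; a 1-based fully-closed
import flag serves marker tables). Overlap requires a shared chromosome
and max(starts) < min(ends) — abutment is not overlap. "Near" a segment
is a configurable flank, default 0 bp, since marker-resolution segment
boundaries make "near" otherwise undefined. The report lists per-segment
overlapping DEGs (with their set labels) and QTLs, flags full
containment, and lists unlinked or unplaced DEGs separately.

## Physiology

Percent injury = (L_t − L_c)/(100 − L_c) × 100 from treated/control
percent conductivities; strictly increasing in L_t, zero iff L_t = L_c,
100 at full leakage. Negative values are reported and flagged, not
clipped.

## Synthetic data: what it emulates and what it does not

The generator plants genes into eleven truth classes (commonly
induced/repressed, genotype-specific per direction, constitutive IL
up/down, repressed-then-induced in both genotypes, induced-then-repressed
in the IL, and null) under the additive log2 model

    log2 x = baseline(gene) + genotype offset + cold effect(class, genotype, t) + N(0, σ).

Defaults: baseline ~ N(8, 1.5²) log2 units; noise σ = 0.25 log2 units
(the source reports no within-genotype variance; 0.25 is a typical
between-replicate spread for seedling array data and is an exposed
parameter); planted effect 3.0 log2 units (8-fold), clearing the 5-fold
gate with margin; class proportions scaled from the source's set-size
ratios to a 2,000-gene desk scale. Promoters are uniform-composition
991-nt windows with DRE words planted in half the commonly induced class;
accidental motif occurrences are allowed and deliberately *not* recorded
in the truth table (the scanner finds them; tests compare against a
naive-scan oracle, not planted positions alone). The toy genome has 12
chromosomes of 4 Mb, 17 pairwise-disjoint introgressed segments,
genotype-dependent classes placed inside segments, 31 QTLs straddling 15
of them, and a 20-term flat GO map with one term planted at 10× base rate
in the IL-specific induced class.

Not emulated: probe-level structure and array spatial artifacts,
intensity-dependent (non-multiplicative) noise, correlated co-expression
beyond the planted class patterns, realistic promoter base composition,
gene-density and segment-length heterogeneity. Passing the planted-truth
tests therefore demonstrates correctness of the statistics and set
algebra under the stated model, not performance on real arrays.

**Problem sizes.** Validation runs use 2,000 genes for calling/recovery
and the null calibration (5 seeds), 360 genes for clustering recovery,
200–500 promoters for scanner checks, and a 400-gene demo pipeline —
sizes at which permutation enumeration (20 assignments) and the O(n²)
UPGMA updates are fast while class counts remain large enough for stable
rates.

## Numerical choices and degenerate inputs

Normalization is per-array median scaling to the global median of
per-array medians — a documented simplification of invariant-set
rescaling; it is idempotent (≤ 1e-12 drift) and preserves within-array
ratios, which is all downstream contracts use. Log views use pseudocount
1.0 on the linear scale. Fold change 0/0 is reported as 1 (no evidence);
x/0 as +inf (caught by the gate). Presence calling uses a fixed linear
threshold (default 100) rather than an unstated detection-call rule,
inclusive at the boundary. d with zero denominator and equal means is 0;
with unequal means ±inf. Correlations are clipped to [−1, 1] before
distances.

## Known limitations

Invariant-set (dChip-style) array normalization and MAS5-style presence
calls are intentionally replaced by the simpler documented rules;
absolute DEG counts from real CEL-derived data will differ. The per-gene permutation
mode cannot reach p < 2/B by construction (see pooling discussion). GO
enrichment has no ontology-graph awareness. QTL/segment analysis trusts
the provided intervals; no marker-based inference is attempted.
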
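# Methods

This note documents the models, parameter choices, numerical decisions, and
known limitations of the `varlink` pipeline.

## Hotspot model

Windows are **non-overlapping tiles**, not a sliding window: tiling gives
each base exactly one test, keeps the effective number of tests equal to
⌊G/w⌋, and matches how recurrence is usually binned. Trailing partial tiles
(width < w) are dropped so the null is identical for every tested window.

The per-sample hit probability `p_i = 1 − (1 − w/G)^{m_i}` treats the `m_i`
mutations of sample *i* as independent uniform placements on the usable
genome (all non-excluded chromosomes; `m_i` likewise counts only mutations
on those chromosomes). This is the natural closed form for "window contains
≥ 1 of m uniform points" under independence; it ignores the (negligible at
genome scale) without-replacement correction and any mutational covariates.
The window count is then Poisson-binomial across samples; its tail is
computed by an O(n²) convolution of the PMF, which is exact to floating
precision (verified against 2ⁿ enumeration and the equal-p binomial
reduction). Because `p_i` does not depend on the window, the PMF is built
once per cohort and shared by all windows.

Selection defaults to raw p < 0.001, the threshold the procedure is
normally quoted with; an optional Bonferroni mode divides α by the number of
tested (k ≥ 1) windows and is what the type-I-error property uses. The
count of tested windows is taken **before** problematic-region filtering;
filtering (mappability-masked intervals, repeat tracks, chrY) happens after
significance computation, and flagged windows are excluded from output —
significance first, filters second, mirroring the usual order of such
pipelines. Window-size sweeps (9/21/50/5000 bp) report k-histograms only;
max-k monotonicity across sizes holds only when one size divides the other
(tiles nest), and the sweep makes no stronger claim.

Moment diagnostics (used to eyeball which count distribution fits the
occupied-window k values) are population moments: skewness m₃/m₂^1.5 and
non-excess kurtosis m₄/m₂², biased estimators chosen for reproducibility of
the diagnostic values.

## CNV-region association

Coverage only changes at CNV endpoints, so the per-base Fisher test is
evaluated once per constant-coverage segment — results are identical to a
per-base loop. Per-sample intervals are merged first so a sample never
counts twice at a base. The one-sided p is an exact integer hypergeometric
tail (a single float division at the end) rather than a floating-point
library routine, because downstream tests require agreement with exact
enumeration at 1e-12; `scipy.stats.fisher_exact` is used as an independent
cross-check in the test suite, never as the implementation.

Cohort sizes must be supplied when known: inferring them from the records
present undercounts whenever a sample carries no CNV, which biases every
2×2 table.

**Uniqueness** of a candidate is |S_i \ ∪_{j≠i} S_j| within the candidates
of the same chromosome and direction — the union reading of "subtracting
the common samples between each pair", chosen because it is
order-independent and strictly harsher than any pairwise scheme.

**Clustering** is DBSCAN (scikit-learn) on two features, genomic midpoint
and uniqueness, z-scored per chromosome/direction group so eps has a
scale-free default (0.5, minPts 1). Noise points are remapped to singleton
clusters so every candidate remains eligible for selection.

**IR score.** The published definition of the independence score is verbal
("detected in the greatest number of cases, minimum co-occurrence with
other CNVRs"); the formula used here, IR(i) = |S_i| − mean_{j≠i}|S_i∩S_j|,
is this package's operationalization and is deliberately kept in one small
function so alternatives can be swapped in. Ties break toward larger
support, then leftmost start. Deletions and duplications are processed
fully independently throughout.

## Gene annotation

The reference gene list keeps every backbone (FANTOM5-style) gene and adds
genes from the second and third source only when the case-insensitive
symbol is new — symbol, not coordinate, is the identity key, because the
sources disagree on spans far more than on names. Variant–gene linkage is
≥ 1 bp overlap with the full annotated gene body (no promoter extension
here; promoters belong to the interaction stage). In per-class summaries a
variant hitting both a coding and a non-coding gene counts as
coding-associated (the per-hit table keeps everything); biotype histograms
count distinct genes.

## Enhancer–promoter interactions

Interaction filters follow the stated defaults: cis only, p < 0.01,
read count ≥ 10, and anchor-start separation strictly between 5 kb and
10 Mb (at fixed bin width, start separation equals midpoint separation).
Replicates are merged by exact bin pair, summing read counts and keeping
the smaller p-value, flagged as merged.

Anchor–gene annotation uses ≥ 10% overlap where the denominator is
min(gene width, anchor width), so a short gene inside a large bin and a
short bin inside a long gene are treated symmetrically; the threshold is
inclusive (exactly 10% passes).

Promoters are strand-aware TSS windows: `[tss − up, tss + down)` on the
plus strand and the mirrored `[tss − down, tss + up + 1)` on the minus
strand (TSS = end − 1), ± 2 kb by default, clipped to chromosome bounds.

An interaction may be an EPI in both orientations when both anchors carry
peaks and promoters; both records are emitted rather than discarding the
ambiguous case. Enhancer-side peak support is ≥ 1 bp. Condition-specific
EPIs are defined by exact bin-pair identity — the same pair with different
target genes in the two conditions is still shared.

## Regulatory integration

Only enhancer-side overlaps make a variant a candidate; promoter-side
overlaps never do. WGS replication is class-specific: position identity for
SNPs (allele-agnostic by default — the matching data rarely report matched
alleles; an allele-aware comparison can be layered on the reported
positions), containment of any SNV for hotspot windows, and ≥ 1 bp
same-direction overlap for CNV regions (a reciprocal-overlap fraction is
available, default 0). The WGS filter keeps records with QUAL > 30 **and**
DP > 10, both strict; records lacking DP are removed, since the filter
expression defines the removal set as everything that cannot demonstrate
both confidence and depth.

## Enrichment

Over-representation uses the same exact hypergeometric tail; fold
enrichment is (x/n)/(K/N), zero when x = 0. The universe defaults to the
union of all genes in the loaded GMT collection (optionally extended by the
reference gene list) because ORA front-ends rarely document their universe;
it is always configurable. Raw p < 0.05 is the default report filter,
matching common practice for such tools; Benjamini–Hochberg q-values
(statsmodels) are computed over all sets before any filtering.

## Synthetic fixtures

The generators emulate the statistical structure of the real inputs, not
their biology. Defaults: a 2 × 1 Mb two-chromosome genome; a 100-sample
mutation cohort with Poisson(50) uniform mutations per sample and one
planted tile-aligned 21 bp window carried by 30% of samples; 30 + 30 CNV
cohorts with one planted case-enriched duplication (20/30 vs 1/30 carriers,
noise-free breakpoints — background CNV rate and breakpoint jitter are
available but default to zero so boundary recovery is exactly checkable);
and a fully constructed regulatory scenario with 5 kb bins where two EPIs
exist only in the tumor condition, one planted variant sits in each
enhancer bin, and distractors sit in a promoter bin, in intergenic space,
and in the enhancer bin of a condition-shared interaction. These sizes keep
the complete test suite and the acceptance script in the seconds-to-a-
minute range while still exercising every filter and code path.

Background mutations are uniform by design — the same assumption the
Poisson-binomial null makes — so the type-I-error property is a calibration
check of the implementation, not of the model. Consequently, passing these
tests demonstrates correctness of the machinery, **not** that real genomes
satisfy the null: real mutation rates vary with replication timing,
chromatin state and sequence context, real CNV breakpoints are noisy, and
real Hi-C significance calls carry their own model assumptions. On real
data the mappability/repeat filters and the condition-specific comparison
carry correspondingly more weight.

## Numerical and degenerate-input conventions

All internal coordinates are 0-based half-open; 1-based formats are shifted
on read, chromosome names normalized to the `chr` prefix. Exact integer
arithmetic backs both discrete tails (single final float division).
`P(K ≥ k)` returns 1 for k ≤ 0 and 0 for k > n (impossible, not an error).
Zero-variance input to the moment diagnostics, an empty universe, an
all-excluded genome, eps ≤ 0, and mismatched bin widths raise; unknown
chromosomes in mutation input warn and skip. Deterministic orderings
(p-value then coordinate for hotspots; class/chromosome/start for
candidate reports) make reruns byte-identical.

## Known limitations

Upstream computations are consumed, never reproduced: read mapping, variant
and peak calling, Hi-C processing and interaction significance, and
mappability thresholding all happen before this package's inputs. The
hotspot `p_i` is an independence approximation with no covariates. The IR
score is a reconstruction (above). Expression-based filtering of
candidates (testing whether a candidate actually shifts target-gene
expression) is out of scope, as no defined statistical procedure exists for
it here; the candidate list is the final product.
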
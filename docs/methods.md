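# Methods

This note documents the models and procedures `tmeprofiler` implements,
the defaults it pins where the emulated analysis pipeline leaves choices
open, and what the synthetic validation does and does not establish.

## Immune signature scoring

The single-sample enrichment score follows the weighted-ECDF-difference
family: per sample, genes are ordered by decreasing expression (ties
broken deterministically by gene id) and the gene at descending position
*i* of *G* carries rank weight (G − i + 1)^α, so the most highly
expressed gene is weighted most. The score integrates the difference
between the weighted in-set ECDF and the unweighted out-of-set ECDF over
all ranked positions, and the signature × sample matrix is normalized by
its global range (max − min). The exponent α defaults to 0.25. Because
the score depends on expression only through within-sample ranks, it is
invariant to any monotone transform of a sample's values — FPKM, TPM or
log-scale input give identical scores.

Per-patient enrichment calling uses a preranked approach: genes are
z-scored per gene across samples (sample standard deviation, ddof 1;
zero-variance genes are zeroed and flagged), ranked per patient, and each
signature's weighted Kolmogorov–Smirnov running-sum statistic (weight
exponent 1, weights |z|) is referred to a null distribution of `n_perm`
random same-size gene sets (default 1000; the null is drawn per sample
and cached per set size, seeded reproducibly per sample). One-sided
permutation p-values use the add-one rule p = (1 + #{null ≥ ES})/(1 +
n_perm) for positive scores, mirrored for negative scores. The BH family
is the 26 signatures within one patient — enrichment is a per-patient
call, so the correction is per-patient rather than cohort-wide. A
signature is *enriched* when ES > 0 and q ≤ 0.1; the boundary is
inclusive. Phenotype permutation is impossible in a single-sample
setting, which is why the null permutes gene-set membership.

The TIL ("tumor-infiltrating lymphocyte") profile reports, per stratum,
the percent of patients enriched per signature, plus an `any_TIL` row:
the percent enriched for at least one adaptive-category (T/B-lineage)
signature. Which signature family defines "TILs present" is exposed as a
parameter because reasonable analysts differ on it.

## Immune grouping

Samples are clustered on their normalized score profiles by agglomerative
clustering. The default is Euclidean distance with average linkage, and
clusters are mapped to groups by descending mean score so cluster 1 is
always the most infiltrated. Correlation (1 − Pearson) distance is
selectable but not the default for two reasons: it is blind to score
magnitude (a uniformly infiltrated and a uniformly cold sample have
equally flat profiles and undefined mutual correlation), and it breaks
the intended monotonicity of the classification — raising every score of
a sample should never demote it. Average linkage is preferred over Ward
because Ward's size-weighted merge cost can cut a small HIGH arm away
from MIX + LOW rather than separating LOW, inverting the intended
two-cluster topology in ADC cohorts with unbalanced arms.

The histology-specific refinements encode the three-level classification:
ADC uses k = 2; the low cluster is LOW, and high-cluster samples with
both T-cell and B-cell signature scores above the cohort median are HIGH,
the rest MIX. SQCC uses k = 3 mapped HIGH/MIX/LOW by mean score; MIX
samples whose T/B scores and PD-1 (PDCD1) and CD8 (CD8A) expression all
exceed the cohort 75th percentile are promoted to HIGH, recorded with
`refinement_rule = "sqcc_mix_promotion"`. The median and 75th-percentile
cut points are explicit stand-ins for qualitative "levels"/"elevated"
descriptions; both are parameters, and every assignment carries its
cluster id and refinement rule as provenance.

## Somatic variant consensus and filtering

Per-caller calls are unioned over (sample, chrom, pos, ref, alt). The
caller set accumulates, the maximum ALT supporting-read count across
callers is retained (callers do not share a depth definition, so the
maximum is the least arbitrary cross-caller reconciliation), population
flags union, and disagreeing effect annotations resolve to the most
deleterious class in the order nonsynonymous > synonymous > UTR > other.
Inconsistent REF alleles at one site are an error.

The filter cascade applies, in order: minimum supporting reads (default
8; removal is strictly "fewer than", so an 8-read variant survives),
exclusion of synonymous and UTR effects, subtraction of matched-normal
germline keys, exclusion of variants flagged in 1000 Genomes or ExAC
(presence-based, flag-driven — no frequency threshold), and subtraction
of panel-of-normals site keys. The report counts survivors per stage;
counts are monotone non-increasing and the cascade is idempotent.

Burden divides post-filter counts (total, and the nonsynonymous subset)
by the exome target size, default 38 Mb — a parameter, since per-Mb
rates are meaningless without the denominator. Substitution spectra
collapse SNVs to the six pyrimidine-reference classes (G>T ≡ C>A);
samples without SNVs have no defined spectrum and are excluded with a
warning. Group spectra are compared per class by Welch t-test with BH
adjustment.

## Fusion prioritization

Candidates are scored additively on five evidence features with
config-exposed weights: junction + spanning read support tiered (≥10
reads → 3, 3–9 → 2, 1–2 → 1), canonical literature pair → 3, one point
per detecting caller (max 3), one point per cancer-census partner (max
2), and one point per additional cohort sample sharing the unordered
gene pair (max 2; recurrence counts distinct samples, not call
instances). High confidence requires a total strictly greater than 9;
the default maximum is 13. Knowledge lookups treat gene pairs as
unordered, so 5'/3' orientation never changes a score. The tier/point
structure is a declared reconstruction: it is chosen so that the >9
threshold is attainable only by candidates with support on several
independent features, and every weight is a parameter.

## Copy-number summaries

Gene-level states use the 5-level landscape convention (−2, −1, 0, +1,
+2) thresholded on the length-weighted mean log2 ratio of segments
overlapping the gene span (defaults −1.3 / −0.3 / +0.3 / +0.9, the
GISTIC-style convention). The length-weighted mean (rather than the
extreme segment) is used for genes spanning breakpoints so that a small
overlapping fragment cannot dominate the call; genes with no covering
segment get a missing state and a warning. Focal peaks from two studies
match when their known target genes are equal, or when they share a
cytoband and their intervals overlap after padding each peak by 1 Mb on
both sides; the padding is applied to the peak intervals (the natural
reading of a peak-comparison rule), and peaks on different chromosomes
never match.

## Cohort statistics

Fisher's exact test is two-sided with the standard "probability mass at
most observed" convention; the reported odds ratio is the sample estimate
ad/bc (infinite when bc = 0). The differential-expression screen across
the three immune groups applies three criteria jointly: one-way ANOVA
and Kruskal–Wallis both significant at BH-FDR < 0.01 (each test family
adjusted separately), absolute Pearson correlation with every
classification marker gene below 0.6 (computed on z-scored expression,
to keep the filter about co-variation rather than scale), and a maximum
pairwise fold change above 2 among the three group means on the linear
FPKM scale. The fold-change pseudocount is relative — 0.1 × the global
mean FPKM — so that selection is invariant to a global rescaling of the
matrix, which an absolute pseudocount would break. Pathway–target
correlation uses Spearman's rank correlation with average ranks for
ties; a constant target has no defined rank correlation and is returned
as NaN with the flag left to the caller.

## Survival

Survival data are right-censored at 1200 days before any analysis: times
beyond the horizon become (1200, censored); an event exactly at 1200
keeps its event status. Kaplan–Meier curves and the log-rank test come
from lifelines. Cox regression uses Efron tie handling. Stage is encoded
ordinally (I–IV → 1–4). Signature-based strata are dichotomized at the
cohort median by default.

The Firth option maximizes the penalized partial likelihood
l*(β) = l(β) + ½ log det I(β), with l the Efron partial log-likelihood
and I the observed information, both computed analytically (vectorized
over tie groups); the penalty gradient is obtained by central differences
of log det I on the analytic information, and BFGS performs the
maximization on centered/scaled covariates. Confidence intervals for the
Firth fit are Wald intervals from the information at the penalized
estimate — a deliberate simplification over profile-penalized-likelihood
intervals, which require a nested constrained optimization per covariate
and change little at the cohort sizes this package targets; under strong
separation Wald intervals are known to be narrower than profile
intervals, which users should keep in mind when the standard fit fails.
A standard fit that does not converge, or converges with enormous
standard errors (monotone likelihood), raises an error advising the
Firth method.

## Synthetic cohort generator

The generator emulates an NSCLC cohort with planted, fully recorded
ground truth; a single seeded NumPy generator drives everything, so a
fixed seed reproduces the cohort bit-for-bit.

*Expression.* Log-normal baseline FPKM (per-gene log2 means ~ N(3, 1.5),
within-gene noise sd 1 log2 unit). Each sample's infiltrated signature
set is drawn from group- and category-conditional probabilities; the
default is the homogeneous three-block structure the classifier encodes
(HIGH: all 26 signatures; MIX: the innate and other categories but never
the adaptive T/B lineage; LOW: none), and fractional probabilities
generate heterogeneous or sparsely infiltrated cohorts. Infiltration
adds δ (default 2) to the log2 expression of the signature's genes;
immune marker genes (IFNG, CD274, PDCD1, CD8A, CCL4) are co-shifted
(full δ in HIGH, δ/2 in MIX). Signature blocks are disjoint and small
relative to the 5000-gene default universe; this matters, because when
signature genes dominate the universe, rank competition depresses
non-infiltrated signatures' scores below the cold-sample baseline and
the planted geometry inverts.

*Genomics.* Passing somatic variants are drawn at the planted per-Mb
rates (ADC 8.0 total / 4.6 nonsynonymous; SQCC 11.8 / 7.1 over a 38-Mb
target); substitution classes follow smoking-conditional probabilities
with a C>A excess in smokers (0.45 vs 0.25). Driver mutations (KRAS,
EGFR, TP53) are drawn with immune-group-conditional prevalence — KRAS
enriched in HIGH (0.40 vs 0.05 in LOW), EGFR enriched in LOW (0.50 vs
0.05 in HIGH) — and placed at real hg19 coordinates inside the driver
gene spans so positional annotation recovers them. Each variant is
emitted by 1–5 callers with per-caller read counts; contaminant classes
(low-read, synonymous/UTR, matched germline, population-database,
panel-of-normals) are planted at known fractions at globally unique
sites, so the filter cascade's per-stage survivor counts are exactly
predictable and recorded. Segments encode planted 5-state gene CNVs
(PTEN loss and PIK3CA gain in SQCC LOW/MIX, KRAS gain in HIGH) around a
diploid baseline with small log-ratio noise. Fusion lists mix planted
multi-evidence EML4–ALK events (~4% of ADC), a recurrent
moderate-evidence novel pair, and single-caller low-read noise.

*Survival.* Event times are exponential with log-hazard
log(λ₀) + β·1[group = HIGH]; defaults λ₀ = ln 2 / 600 days and
β = −ln 2 (immune-HIGH halves the hazard), with independent uniform
censoring on (100, 2400) days so some observations exceed the 1200-day
horizon and exercise the censoring rule. The exponential model is the
simplest data-generating process with a constant hazard ratio; nothing
in the pipeline assumes it.

*Cohort sizes.* Defaults are 131 ADC + 114 SQCC samples with a 30/40/30
HIGH/MIX/LOW split and ADC smoker fraction 84/131. Tests use smaller
cohorts (tens of samples, 1500–4000 genes) chosen to keep the planted
effects comfortably detectable while the full suite runs in minutes; the
acceptance script uses the full default sizes.

*What passing tests show — and don't.* The generator plants additive,
block-structured, noise-free-membership signals: real tumors have graded
infiltration, overlapping signatures, correlated genes, purity and batch
effects, and callers with correlated (not independent) errors. Recovery
of planted truth therefore validates the implementation — the
statistics compute what they claim, the cascade counts exactly, the
classifier recovers structure of the kind it encodes — not the
biological accuracy of the signatures or thresholds on patient data.
Published cohort-level figures (TIL percentages, per-gene mutation
frequencies, survival p-values) depend on the study's raw data and are
not reproduced here; the package validates the machinery that produced
them.

## Numerical and degenerate-input choices

Rank ties break by stable gene-id order everywhere, making all rank
statistics deterministic. Permutation p-values use the add-one rule and
are never zero. A zero-variance score matrix, an empty stratum, a
signature without overlap with the expression matrix, a constant Cox
covariate, or a gene set equal to the whole universe are errors, not
silent degeneracies. The Firth optimizer treats a non-positive-definite
information as a barrier (large objective) rather than a crash. All
genomic coordinates are 1-based inclusive; purine-reference SNVs are
complemented before classification.
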
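# tmeprofiler

Tumor immune microenvironment profiling for bulk RNA-seq NSCLC cohorts.

`tmeprofiler` re-implements, as a tested Python library, the analytical
pipeline used in integrated molecular/immune profiling studies of
non-small-cell lung cancer: immune signature scoring and per-patient
enrichment calling from FPKM expression data, immune HIGH/MIX/LOW subtype
classification, multi-caller somatic variant consensus filtering with
tumor mutational burden and substitution spectra, gene fusion candidate
prioritization, gene-level copy-number summaries, genotype–immune
association testing, and survival analysis with Firth-penalized Cox
regression. It is written for computational biologists who want each of
these stages as a reusable, unit-tested function rather than a one-off
analysis script, and it ships a synthetic cohort generator with planted
ground truth so the whole pipeline can be exercised and validated without
access to patient data.

## The statistics at the core

**ssGSEA score.** For sample *j*, rank the *G* genes by expression
(descending); the gene at position *i* gets rank weight
*w*ᵢ = (*G* − *i* + 1)^α (α = 0.25). For gene set *S*,

ES(S, j) = Σᵢ [ P_in(i) − P_out(i) ],  where P_in accumulates wᵢ/Σ_{S} w
over in-set genes and P_out accumulates 1/(G − |S|) over the rest.

Scores are range-normalized across the signature × sample matrix.

**Per-patient enrichment.** Genes are z-scored per gene across the
cohort, ranked per patient, and each signature's weighted
Kolmogorov–Smirnov running-sum statistic (weight exponent 1) is compared
with a null of random same-size gene sets; p-values are BH-adjusted
within each patient's 26-signature family, and a signature is *enriched*
at q ≤ 0.1.

**Immune groups.** Hierarchical clustering of the normalized score matrix
(Euclidean, average linkage), k = 2 for adenocarcinoma (ADC) and k = 3
for squamous carcinoma (SQCC); the ADC high cluster is split into
HIGH/MIX by T-cell and B-cell signature levels versus the cohort median,
and SQCC MIX samples with T/B scores and PD-1/CD8 expression all above
the 75th percentile are promoted to HIGH.

**Somatic filtering.** Per-caller VCFs are merged over
(sample, chrom, pos, ref, alt); the cascade then removes variants with
< 8 supporting reads, synonymous/UTR effects, matched-normal germline
variants, 1000G/ExAC population variants, and panel-of-normals variants,
in that order, with exact per-stage accounting. Burden is mutations per
Mb of a 38-Mb exome target.

**Fusion score.** Additive over read support (tiers 0–3), canonical pair
(3), callers (≤3), census partners (≤2) and cohort recurrence (≤2);
candidates scoring strictly above 9 are high-confidence (maximum 13).

**Survival.** Overall survival is right-censored at 1200 days;
Kaplan–Meier/log-rank across groups; Cox proportional hazards (Efron
ties) with an optional Firth penalty l*(β) = l(β) + ½ log det I(β) that
keeps estimates finite under monotone likelihood.

## Worked example

```python
from sklearn.metrics import adjusted_rand_score
from tmeprofiler import (SimulationParams, generate_cohort, ssgsea_scores,
                         assign_immune_groups)

cohort = generate_cohort(SimulationParams(n_adc=50, n_sqcc=50, n_genes=4000,
                                          signature_size=20, delta=2.0, seed=0))
scores = ssgsea_scores(cohort.expression, cohort.signatures)
histology = cohort.clinical.table.set_index("sample")["histology"]
assignment = assign_immune_groups(scores, cohort.expression.values, histology)
truth = cohort.truth.set_index("sample")["group"]
pred = assignment.as_series()
print(assignment.table["group"].value_counts().to_dict())
print(round(adjusted_rand_score(truth.loc[pred.index], pred), 3))
```

prints

```
{'MIX': 41, 'LOW': 32, 'HIGH': 27}
1.0
```

— the cohort plants 100 samples in three immune groups with a 2-log2-unit
infiltration shift; clustering plus the histology-specific refinement
rules recover the planted labels exactly (adjusted Rand index 1.0; values
≥ 0.8 indicate reliable recovery). The `examples/` directory has one
short script per capability (simulation, scoring, grouping, variant
filtering, fusion ranking, CNV summaries, association + survival), each
printing the numbers it computes and what they mean.

A thin CLI mirrors the library:

```bash
tmeprofiler simulate --seed 7 --out fixtures/
tmeprofiler run --expr fixtures/expression.tsv --gmt fixtures/signatures.gmt \
    --categories fixtures/signature_categories.tsv \
    --clinical fixtures/clinical.tsv --out results/
```

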
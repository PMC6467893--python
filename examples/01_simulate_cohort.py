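"""Generate a small synthetic NSCLC-like cohort with planted ground truth.

The cohort carries planted immune groups (HIGH/MIX/LOW), group-dependent
driver mutations, contaminated multi-caller variant calls, copy-number
segments, fusion candidates and survival times whose hazard depends on the
immune group — everything the downstream analyses consume.
"""

from tmeprofiler import SimulationParams, generate_cohort

params = SimulationParams(n_adc=30, n_sqcc=25, n_genes=2000,
                          signature_size=15, delta=2.0, seed=7)
cohort = generate_cohort(params)

print(f"samples: {cohort.expression.n_samples} "
      f"({params.n_adc} ADC + {params.n_sqcc} SQCC), "
      f"genes: {cohort.expression.n_genes}")
print("planted immune groups:",
      cohort.truth["group"].value_counts().to_dict())
print(f"variant calls across 5 callers: {len(cohort.variant_calls)}")
print("expected filter-cascade survivors per stage:", cohort.filter_truth)
print(f"fusion candidates: {len(cohort.fusion_candidates)}, "
      f"segments: {len(cohort.segments.table)}")
# The filter_truth counts are exact: the generator knows which planted
# variants each cascade stage must remove.
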
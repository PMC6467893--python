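"""Multi-caller variant consensus, the somatic filter cascade, mutation
burden and substitution spectra.

The filter cascade applies, in order: (1) drop variants with fewer than 8
supporting reads, (2) drop synonymous and UTR variants, (3) subtract
matched-normal germline variants, (4) drop variants present in the
population databases (1000 Genomes / ExAC), (5) drop variants present in
the panel of normals pooled from unmatched blood samples. A per-stage
survivor count is reported; a variant with exactly 8 reads survives stage
1 (removal is strictly "fewer than").
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    EFFECT_SEVERITY,
    FILTER_STAGES,
    SUBSTITUTION_CLASSES,
    FilterReport,
    MergedVariant,
    ValidationError,
    VariantCall,
)
from .scoring import bh_adjust

# effect classes removed by the cascade's effect-class stage
_EXCLUDED_EFFECTS = {"synonymous", "UTR"}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def merge_caller_calls(calls: Sequence[VariantCall]) -> list[MergedVariant]:
    """Union per-caller calls over the (sample, chrom, pos, ref, alt) key.

    The caller set is accumulated, the maximum supporting-read count is
    retained, population-db flags are unioned, and disagreeing effect
    annotations resolve to the most deleterious class
    (nonsynonymous > synonymous > UTR > other).
    """
    # detect inconsistent REF alleles reported at the same site
    refs_at_site: dict[tuple, set] = defaultdict(set)
    for c in calls:
        refs_at_site[(c.sample_id, c.chrom, c.pos)].add(c.ref)
    for site, refs in refs_at_site.items():
        if len(refs) > 1:
            raise ValidationError(
                f"conflicting ref alleles {sorted(refs)} at {site[0]} {site[1]}:{site[2]}"
            )
    grouped: dict[tuple, list[VariantCall]] = defaultdict(list)
    for c in calls:
        grouped[c.key].append(c)
    merged = []
    for key in sorted(grouped):
        grp = grouped[key]
        effect = min((c.effect_class for c in grp), key=lambda e: EFFECT_SEVERITY[e])
        merged.append(MergedVariant(
            sample_id=key[0], chrom=key[1], pos=key[2], ref=key[3], alt=key[4],
            callers=frozenset(c.caller_id for c in grp),
            max_supporting_reads=max(c.supporting_reads for c in grp),
            effect_class=effect,
            popdb_flags=frozenset().union(*(c.popdb_flags for c in grp)),
        ))
    return merged


def apply_somatic_filters(
    merged: Sequence[MergedVariant],
    germline_keys: frozenset = frozenset(),
    pon_keys: frozenset = frozenset(),
    min_reads: int = 8,
) -> tuple[list[MergedVariant], FilterReport]:
    """Apply the four-step somatic filter cascade in order.

    ``germline_keys`` holds matched-normal variant keys
    (sample, chrom, pos, ref, alt); ``pon_keys`` holds sample-agnostic
    panel-of-normals keys (chrom, pos, ref, alt). Returns the surviving
    variants and a per-stage survivor report.
    """
    counts = {"input": len(merged)}
    current = list(merged)
    current = [v for v in current if v.max_supporting_reads >= min_reads]
    counts["min_reads"] = len(current)
    current = [v for v in current if v.effect_class not in _EXCLUDED_EFFECTS]
    counts["effect_class"] = len(current)
    current = [v for v in current if v.key not in germline_keys]
    counts["matched_germline"] = len(current)
    current = [v for v in current if not v.popdb_flags]
    counts["popdb"] = len(current)
    current = [v for v in current if v.site_key not in pon_keys]
    counts["panel_of_normals"] = len(current)
    return current, FilterReport(surviving=counts)


def mutation_burden(
    filtered: Sequence[MergedVariant],
    target_mb: float = 38.0,
    sample_ids: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Mutations per megabase of interrogated exome, per sample.

    Counts post-filter variants; ``nonsyn_per_mb`` counts the
    nonsynonymous subset. ``sample_ids`` forces rows (with zero burden)
    for samples without surviving variants.
    """
    if target_mb <= 0:
        raise ValidationError(f"target_mb must be > 0, got {target_mb}")
    totals: dict[str, int] = defaultdict(int)
    nonsyn: dict[str, int] = defaultdict(int)
    for v in filtered:
        totals[v.sample_id] += 1
        if v.effect_class == "nonsynonymous":
            nonsyn[v.sample_id] += 1
    samples = list(sample_ids) if sample_ids is not None else sorted(totals)
    rows = [{
        "sample": s,
        "total_per_mb": totals[s] / target_mb,
        "nonsyn_per_mb": nonsyn[s] / target_mb,
        "target_mb": target_mb,
    } for s in samples]
    return pd.DataFrame(rows, columns=["sample", "total_per_mb", "nonsyn_per_mb", "target_mb"])


def gene_mutation_status(
    filtered: Sequence[MergedVariant],
    gene_model,
    sample_ids: Iterable[str],
) -> pd.DataFrame:
    """Samples x genes boolean mutation status by positional annotation.

    A sample carries a gene mutation when any surviving variant falls
    inside the gene's span (``gene_model``: gene -> (chrom, start, end),
    1-based inclusive).
    """
    samples = list(sample_ids)
    out = pd.DataFrame(False, index=samples, columns=list(gene_model))
    for v in filtered:
        for gene, (chrom, start, end) in gene_model.items():
            if v.chrom == chrom and start <= v.pos <= end and v.sample_id in out.index:
                out.loc[v.sample_id, gene] = True
    return out


def substitution_class(ref: str, alt: str) -> str | None:
    """Collapse an SNV to its pyrimidine-reference class (G>T == C>A)."""
    if len(ref) != 1 or len(alt) != 1 or ref not in _COMPLEMENT or alt not in _COMPLEMENT:
        return None
    if ref in ("G", "A"):
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    cls = f"{ref}>{alt}"
    return cls if cls in SUBSTITUTION_CLASSES else None


def substitution_spectrum(filtered: Sequence[MergedVariant]) -> pd.DataFrame:
    """Per-sample proportions over the six substitution classes.

    Indels are excluded; samples without any SNV are omitted (their
    spectrum is undefined) and listed in ``attrs["excluded_samples"]``.
    """
    counts: dict[str, np.ndarray] = defaultdict(lambda: np.zeros(len(SUBSTITUTION_CLASSES)))
    seen: set[str] = set()
    for v in filtered:
        seen.add(v.sample_id)
        cls = substitution_class(v.ref, v.alt)
        if cls is not None:
            counts[v.sample_id][SUBSTITUTION_CLASSES.index(cls)] += 1
    rows, excluded = {}, []
    for s in sorted(seen):
        total = counts[s].sum()
        if total == 0:
            excluded.append(s)
            continue
        rows[s] = counts[s] / total
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(SUBSTITUTION_CLASSES))
    df.index.name = "sample"
    df.attrs["excluded_samples"] = excluded
    return df


def compare_spectra(spectra: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Two-sample t-test per substitution class between two groups, BH-adjusted.

    ``groups`` maps sample -> group label; exactly two labels required.
    """
    labels = pd.unique(groups.loc[spectra.index])
    if len(labels) != 2:
        raise ValidationError(f"expected exactly 2 groups, got {list(labels)}")
    a = spectra.loc[[s for s in spectra.index if groups[s] == labels[0]]]
    b = spectra.loc[[s for s in spectra.index if groups[s] == labels[1]]]
    rows = []
    for cls in SUBSTITUTION_CLASSES:
        t, p = stats.ttest_ind(a[cls], b[cls], equal_var=False)
        rows.append({"class": cls, "mean_a": a[cls].mean(), "mean_b": b[cls].mean(),
                     "t": t, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    out.attrs["group_a"], out.attrs["group_b"] = labels[0], labels[1]
    return out
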
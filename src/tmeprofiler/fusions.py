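"""Fusion candidate prioritization.

Candidates compiled from multiple RNA fusion callers are scored additively
on five evidence features: junction + spanning read support (tiered),
membership of the gene pair in literature canonical fusions, number of
callers detecting the event, partner membership in the cancer gene census,
and recurrence of the same gene pair across the cohort. A candidate is
high-confidence when its total score is strictly greater than 9. Under the
default weights the maximum attainable total is 13 (3 reads + 3 canonical
+ 3 callers + 2 census + 2 recurrence).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .config import RunConfig
from .datatypes import FusionCandidate, FusionKnowledge, ValidationError


@dataclass(frozen=True)
class FusionScore:
    candidate: FusionCandidate
    read_support: int
    canonical: int
    caller_count: int
    census: int
    recurrence: int
    threshold: float = 9.0

    @property
    def total(self) -> int:
        return self.read_support + self.canonical + self.caller_count + self.census + self.recurrence

    @property
    def high_confidence(self) -> bool:
        return self.total > self.threshold


def _read_tier_points(reads: int, tiers) -> int:
    for min_reads, points in sorted(tiers, key=lambda t: -t[0]):
        if reads >= min_reads:
            return points
    return 0


def score_fusion(
    candidate: FusionCandidate,
    knowledge: FusionKnowledge,
    cohort: Sequence[FusionCandidate] = (),
    config: RunConfig | None = None,
) -> FusionScore:
    """Score one candidate against knowledge priors and the cohort.

    Recurrence counts the number of *other* cohort samples reporting the
    same unordered gene pair (capped); knowledge lookups are unordered, so
    gene-pair orientation never matters.
    """
    cfg = config or RunConfig()
    reads = candidate.junction_reads + candidate.spanning_mates
    read_pts = _read_tier_points(reads, cfg.fusion_read_tiers)
    canonical_pts = cfg.fusion_canonical_points if candidate.pair in knowledge.canonical_fusions else 0
    caller_pts = min(len(candidate.callers), cfg.fusion_caller_max) * cfg.fusion_caller_points
    census_hits = sum(1 for g in (candidate.gene5, candidate.gene3) if g in knowledge.census_genes)
    census_pts = min(census_hits, cfg.fusion_census_max) * cfg.fusion_census_points
    other_samples = {
        c.sample_id for c in cohort
        if c.pair == candidate.pair and c.sample_id != candidate.sample_id
    }
    rec_pts = min(len(other_samples), cfg.fusion_recurrence_max) * cfg.fusion_recurrence_points
    return FusionScore(
        candidate=candidate, read_support=read_pts, canonical=canonical_pts,
        caller_count=caller_pts, census=census_pts, recurrence=rec_pts,
        threshold=cfg.fusion_high_confidence_threshold,
    )


def rank_fusions(
    candidates: Sequence[FusionCandidate],
    knowledge: FusionKnowledge,
    config: RunConfig | None = None,
) -> list[FusionScore]:
    """Score every candidate (recurrence over the whole input cohort) and
    rank by descending total; ties broken by caller count, read support,
    then gene pair lexicographically, for full determinism."""
    scores = [score_fusion(c, knowledge, cohort=candidates, config=config) for c in candidates]
    return sorted(scores, key=lambda s: (
        -s.total,
        -len(s.candidate.callers),
        -(s.candidate.junction_reads + s.candidate.spanning_mates),
        tuple(sorted((s.candidate.gene5, s.candidate.gene3))),
        s.candidate.sample_id,
    ))


def fusion_table(scores: Sequence[FusionScore]) -> pd.DataFrame:
    rows = [{
        "sample": s.candidate.sample_id,
        "gene5": s.candidate.gene5, "gene3": s.candidate.gene3,
        "junction_reads": s.candidate.junction_reads,
        "spanning_mates": s.candidate.spanning_mates,
        "callers": ",".join(sorted(s.candidate.callers)),
        "read_support_pts": s.read_support, "canonical_pts": s.canonical,
        "caller_pts": s.caller_count, "census_pts": s.census,
        "recurrence_pts": s.recurrence, "total": s.total,
        "high_confidence": s.high_confidence,
    } for s in scores]
    return pd.DataFrame(rows)
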
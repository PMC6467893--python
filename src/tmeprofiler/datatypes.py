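"""Core domain containers shared across the pipeline.

Conventions: genomic coordinates are 1-based inclusive throughout (the SEG
and VCF convention); expression matrices are genes x samples DataFrames of
non-negative FPKM values; signature collections map signature names to gene
sets plus an immunity-category label.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

CATEGORIES = ("adaptive", "innate", "other")
EFFECT_CLASSES = ("nonsynonymous", "synonymous", "UTR", "other")
# resolution order when caller annotations disagree, most deleterious first
EFFECT_SEVERITY = {"nonsynonymous": 0, "synonymous": 1, "UTR": 2, "other": 3}
POPDB_SOURCES = ("1000G", "ExAC")
HISTOLOGIES = ("ADC", "SQCC")
STAGES = ("I", "II", "III", "IV")
SMOKING = ("smoker", "non-smoker")
IMMUNE_GROUPS = ("HIGH", "MIX", "LOW")
SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene-by-sample FPKM matrix.

    ``values`` is a DataFrame indexed by unique gene ids with unique sample
    id columns; entries are finite and non-negative.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] < 2 or v.shape[1] < 2:
            raise ValidationError(
                f"expression matrix needs >=2 genes and >=2 samples, got {v.shape}"
            )
        if v.index.duplicated().any():
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups[:5]}")
        if v.columns.duplicated().any():
            raise ValidationError("duplicate sample ids")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("expression matrix must be numeric")
        if not np.isfinite(arr).all():
            raise ValidationError("expression matrix contains non-finite values")
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative expression at gene {v.index[g]!r}, sample {v.columns[s]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class SignatureCollection:
    """Named immune gene sets with adaptive / innate / other categories."""

    signatures: dict[str, frozenset[str]]
    category: dict[str, str]

    def __post_init__(self) -> None:
        for name, genes in self.signatures.items():
            if len(genes) == 0:
                raise ValidationError(f"signature {name!r} is empty")
        unknown = set(self.category.values()) - set(CATEGORIES)
        if unknown:
            raise ValidationError(f"unknown categories: {sorted(unknown)}")
        missing = set(self.signatures) - set(self.category)
        if missing:
            raise ValidationError(f"signatures without category: {sorted(missing)[:5]}")

    def __len__(self) -> int:
        return len(self.signatures)

    def names(self) -> list[str]:
        return list(self.signatures)

    def by_category(self, cat: str) -> list[str]:
        return [n for n in self.signatures if self.category[n] == cat]


@dataclass(frozen=True)
class VariantCall:
    """A single variant record as emitted by one caller."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    caller_id: str
    supporting_reads: int = 0
    effect_class: str = "other"
    popdb_flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"pos must be >=1, got {self.pos}")
        if self.ref == self.alt:
            raise ValidationError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if self.supporting_reads < 0:
            raise ValidationError("supporting_reads must be >= 0")
        if self.effect_class not in EFFECT_CLASSES:
            raise ValidationError(f"unknown effect class {self.effect_class!r}")

    @property
    def key(self) -> tuple[str, str, int, str, str]:
        return (self.sample_id, self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class MergedVariant:
    """A multi-caller consensus variant (union over the merge key)."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    callers: frozenset[str]
    max_supporting_reads: int
    effect_class: str
    popdb_flags: frozenset[str] = frozenset()

    @property
    def caller_count(self) -> int:
        return len(self.callers)

    @property
    def key(self) -> tuple[str, str, int, str, str]:
        return (self.sample_id, self.chrom, self.pos, self.ref, self.alt)

    @property
    def site_key(self) -> tuple[str, int, str, str]:
        """Sample-agnostic key used for panel-of-normals lookups."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1 and self.ref != "-" and self.alt != "-"


SEG_COLUMNS = ["sample", "chrom", "start", "end", "log2_ratio", "n_probes"]


@dataclass(frozen=True)
class SegmentTable:
    """Segmented copy-number data (1-based inclusive coordinates)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in SEG_COLUMNS if c not in t.columns]
        if missing:
            raise ValidationError(f"segment table missing columns: {missing}")
        if len(t) and (t["start"] >= t["end"]).any():
            bad = t[t["start"] >= t["end"]].iloc[0]
            raise ValidationError(
                f"segment start >= end for {bad['sample']} {bad['chrom']}:{bad['start']}-{bad['end']}"
            )
        for (samp, chrom), grp in t.groupby(["sample", "chrom"], sort=False):
            g = grp.sort_values("start")
            if (g["start"].to_numpy()[1:] <= g["end"].to_numpy()[:-1]).any():
                raise ValidationError(f"overlapping segments for {samp} chr{chrom}")

    @property
    def sample_ids(self) -> list[str]:
        return list(pd.unique(self.table["sample"]))


CLINICAL_COLUMNS = [
    "sample", "histology", "age", "sex", "stage", "smoking",
    "os_days", "os_event", "treatment",
]

# sub-stage labels collapse to the major Roman-numeral stage
_STAGE_MAP = {}
for _major in STAGES:
    _STAGE_MAP[_major] = _major
    for _sub in ("A", "B", "C"):
        _STAGE_MAP[_major + _sub] = _major


def normalize_stage(label: str) -> str:
    s = str(label).strip().upper()
    if s not in _STAGE_MAP:
        raise ValidationError(f"unknown stage label {label!r}")
    return _STAGE_MAP[s]


@dataclass(frozen=True)
class ClinicalTable:
    """Per-sample clinical annotations including overall survival."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in CLINICAL_COLUMNS if c not in t.columns]
        if missing:
            raise ValidationError(f"clinical table missing columns: {missing}")
        if t["sample"].duplicated().any():
            raise ValidationError("duplicate sample ids in clinical table")
        bad_hist = set(t["histology"]) - set(HISTOLOGIES)
        if bad_hist:
            raise ValidationError(f"unknown histology labels: {sorted(bad_hist)}")
        bad_smoke = set(t["smoking"]) - set(SMOKING)
        if bad_smoke:
            raise ValidationError(f"unknown smoking labels: {sorted(bad_smoke)}")
        if (t["os_days"] < 0).any():
            raise ValidationError("negative os_days")
        if not set(t["os_event"]).issubset({0, 1}):
            raise ValidationError("os_event must be 0/1")
        bad_stage = set(t["stage"]) - set(STAGES)
        if bad_stage:
            raise ValidationError(f"unnormalized stage labels: {sorted(bad_stage)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample"])


@dataclass(frozen=True)
class ScoreMatrix:
    """Signatures-by-samples score matrix from ssGSEA."""

    values: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValidationError("score matrix contains non-finite values")


ENRICHMENT_COLUMNS = ["sample", "signature", "ES", "NES", "p", "q", "enriched"]


@dataclass(frozen=True)
class EnrichmentResult:
    """Long-form per (sample, signature) preranked enrichment calls."""

    table: pd.DataFrame
    q_threshold: float = 0.1

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in ENRICHMENT_COLUMNS if c not in t.columns]
        if missing:
            raise ValidationError(f"enrichment table missing columns: {missing}")
        if len(t):
            if ((t["p"] < 0) | (t["p"] > 1)).any() or ((t["q"] < 0) | (t["q"] > 1)).any():
                raise ValidationError("p/q values outside [0, 1]")


@dataclass(frozen=True)
class ImmuneGroupAssignment:
    """Per-sample HIGH/MIX/LOW immune group with provenance."""

    table: pd.DataFrame  # columns: sample, group, cluster_id, refinement_rule

    def __post_init__(self) -> None:
        t = self.table
        for c in ("sample", "group", "cluster_id", "refinement_rule"):
            if c not in t.columns:
                raise ValidationError(f"assignment missing column {c!r}")
        if t["sample"].duplicated().any():
            raise ValidationError("sample assigned more than once")
        bad = set(t["group"]) - set(IMMUNE_GROUPS)
        if bad:
            raise ValidationError(f"unknown immune groups: {sorted(bad)}")

    def as_series(self) -> pd.Series:
        return self.table.set_index("sample")["group"]


FILTER_STAGES = [
    "input", "min_reads", "effect_class", "matched_germline", "popdb", "panel_of_normals",
]


@dataclass(frozen=True)
class FilterReport:
    """Variants surviving after each stage of the somatic filter cascade."""

    surviving: dict[str, int]

    def __post_init__(self) -> None:
        missing = [s for s in FILTER_STAGES if s not in self.surviving]
        if missing:
            raise ValidationError(f"filter report missing stages: {missing}")
        counts = [self.surviving[s] for s in FILTER_STAGES]
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise ValidationError("filter stage counts must be non-increasing")

    def removed_at(self, stage: str) -> int:
        i = FILTER_STAGES.index(stage)
        if i == 0:
            return 0
        return self.surviving[FILTER_STAGES[i - 1]] - self.surviving[stage]


@dataclass(frozen=True)
class FusionCandidate:
    """A candidate fusion event reported by one or more RNA fusion callers."""

    sample_id: str
    gene5: str
    gene3: str
    junction_reads: int
    spanning_mates: int
    callers: frozenset[str]

    def __post_init__(self) -> None:
        if self.gene5 == self.gene3:
            raise ValidationError(f"fusion partners identical: {self.gene5}")
        if self.junction_reads < 0 or self.spanning_mates < 0:
            raise ValidationError("read counts must be >= 0")
        if len(self.callers) < 1:
            raise ValidationError("fusion candidate needs >= 1 caller")

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.gene5, self.gene3))


@dataclass(frozen=True)
class FusionKnowledge:
    """Literature-derived priors for fusion scoring."""

    canonical_fusions: frozenset[frozenset[str]] = frozenset()
    census_genes: frozenset[str] = frozenset()


@dataclass(frozen=True)
class FocalPeak:
    """A recurrent focal copy-number peak with significance q-value."""

    cytoband: str
    chrom: str
    start: int
    end: int
    q_value: float
    target_gene: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError("peak start must be < end")
        if not (0.0 <= self.q_value <= 1.0):
            raise ValidationError("peak q-value must be in [0, 1]")


def dataclass_replace(obj, **changes):
    return dataclasses.replace(obj, **changes)
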
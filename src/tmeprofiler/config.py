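"""Run configuration: every tunable constant of the pipeline in one place."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml


@dataclass
class RunConfig:
    """Pipeline constants with their published defaults.

    Enrichment is called at BH q <= 0.1 per patient; somatic variants need
    at least 8 supporting reads; fusion candidates are high-confidence at a
    score strictly greater than 9; survival is right-censored at 1200 days.
    """

    # ssGSEA
    ssgsea_alpha: float = 0.25
    # preranked enrichment
    n_permutations: int = 1000
    permutation_seed: int = 0
    enrichment_q_threshold: float = 0.1
    # somatic filtering
    min_supporting_reads: int = 8
    exome_target_mb: float = 38.0
    depth_key: str = "AD"              # FORMAT key holding (ref, alt) depths
    effect_key: str = "EFF"            # INFO key holding the effect class
    popdb_key: str = "PDB"             # INFO key holding population-db flags
    # fusion scoring (points per evidence feature)
    fusion_read_tiers: tuple = ((10, 3), (3, 2), (1, 1))  # (min reads, points)
    fusion_canonical_points: int = 3
    fusion_caller_points: int = 1
    fusion_caller_max: int = 3
    fusion_census_points: int = 1
    fusion_census_max: int = 2
    fusion_recurrence_points: int = 1
    fusion_recurrence_max: int = 2
    fusion_high_confidence_threshold: float = 9.0   # strict >
    # CNV 5-state thresholds on length-weighted mean log2 ratio
    cnv_homdel_threshold: float = -1.3
    cnv_hetdel_threshold: float = -0.3
    cnv_amp_threshold: float = 0.3
    cnv_homamp_threshold: float = 0.9
    peak_padding_bp: int = 1_000_000
    # clustering
    cluster_distance: str = "euclidean"     # "correlation" (1 - Pearson) also supported
    cluster_linkage: str = "average"
    # grouping refinement signatures/markers
    t_cell_signature: str = "T_cells"
    b_cell_signature: str = "B_cells"
    pd1_gene: str = "PDCD1"
    cd8_gene: str = "CD8A"
    adc_split_quantile: float = 0.5
    sqcc_promotion_quantile: float = 0.75
    # DE gene selection
    de_fdr_threshold: float = 0.01
    de_marker_corr_threshold: float = 0.6
    de_fold_change_threshold: float = 2.0
    de_pseudocount_rel: float = 0.1   # relative to global mean FPKM
    # survival
    censor_horizon_days: float = 1200.0

    def __post_init__(self) -> None:
        if not (0 < self.enrichment_q_threshold < 1):
            raise ValueError("enrichment_q_threshold must be in (0, 1)")
        if self.min_supporting_reads < 0:
            raise ValueError("min_supporting_reads must be >= 0")
        if self.exome_target_mb <= 0:
            raise ValueError("exome_target_mb must be > 0")
        if self.censor_horizon_days <= 0:
            raise ValueError("censor_horizon_days must be > 0")
        if self.ssgsea_alpha < 0:
            raise ValueError("ssgsea_alpha must be >= 0")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["fusion_read_tiers"] = [list(t) for t in d["fusion_read_tiers"]]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "fusion_read_tiers" in d:
            d["fusion_read_tiers"] = tuple(tuple(t) for t in d["fusion_read_tiers"])
        return cls(**d)
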
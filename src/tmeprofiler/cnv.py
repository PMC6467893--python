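"""Gene-level copy-number states from segmented data, and the cross-study
focal-peak similarity rule.

Gene states follow the 5-level convention used in copy-number landscape
figures: -2 homozygous deletion, -1 heterozygous deletion, 0 diploid,
+1 heterozygous amplification, +2 homozygous amplification, thresholded on
the length-weighted mean log2 ratio of the segments overlapping the gene
span (GISTIC-convention default cutoffs -1.3 / -0.3 / +0.3 / +0.9).
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .config import RunConfig
from .datatypes import FocalPeak, SegmentTable, ValidationError

logger = logging.getLogger("tmeprofiler")

GeneModel = Mapping[str, tuple[str, int, int]]  # gene -> (chrom, start, end), 1-based inclusive


def call_state(
    mean_log2: float,
    homdel: float = -1.3,
    hetdel: float = -0.3,
    amp: float = 0.3,
    homamp: float = 0.9,
) -> int:
    if mean_log2 <= homdel:
        return -2
    if mean_log2 <= hetdel:
        return -1
    if mean_log2 >= homamp:
        return 2
    if mean_log2 >= amp:
        return 1
    return 0


def gene_cnv_status(
    segments: SegmentTable,
    gene_model: GeneModel,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """5-state copy-number call per (gene, sample).

    The per-gene dosage is the length-weighted mean log2 ratio over the
    segments overlapping the gene span; genes with no covering segment in a
    sample get a missing (NaN) state and a warning. Returns a genes x
    samples frame of floats in {-2,-1,0,1,2, NaN}.
    """
    cfg = config or RunConfig()
    t = segments.table
    samples = segments.sample_ids
    genes = list(gene_model)
    out = pd.DataFrame(np.nan, index=genes, columns=samples)
    by_sample_chrom = {key: grp for key, grp in t.groupby(["sample", "chrom"], sort=False)}
    n_missing = 0
    for gene, (chrom, gstart, gend) in gene_model.items():
        for sample in samples:
            grp = by_sample_chrom.get((sample, str(chrom)))
            if grp is None:
                n_missing += 1
                continue
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            overlap = np.minimum(ends, gend) - np.maximum(starts, gstart) + 1
            mask = overlap > 0
            if not mask.any():
                n_missing += 1
                continue
            w = overlap[mask].astype(float)
            mean_log2 = float(np.average(grp["log2_ratio"].to_numpy()[mask], weights=w))
            out.loc[gene, sample] = call_state(
                mean_log2, cfg.cnv_homdel_threshold, cfg.cnv_hetdel_threshold,
                cfg.cnv_amp_threshold, cfg.cnv_homamp_threshold,
            )
    if n_missing:
        logger.warning("%d (gene, sample) pairs had no covering segment; state set missing",
                       n_missing)
    return out


def peak_similarity(
    a: FocalPeak,
    b: FocalPeak,
    cytobands: Mapping[str, tuple[str, int, int]] | None = None,
    padding_bp: int = 1_000_000,
) -> bool:
    """Whether two focal peaks from different studies match.

    True iff their known target genes are equal (and non-null), OR they lie
    in the same cytoband and their intervals overlap after symmetrically
    padding each peak by 1 Mb. Peaks on different chromosomes never match.
    ``cytobands`` (band name -> interval) is accepted for validation but the
    comparison uses the peaks' own cytoband labels.
    """
    if a.target_gene is not None and a.target_gene == b.target_gene:
        return True
    if a.chrom != b.chrom:
        return False
    if a.cytoband != b.cytoband:
        return False
    a_start, a_end = a.start - padding_bp, a.end + padding_bp
    b_start, b_end = b.start - padding_bp, b.end + padding_bp
    return a_start <= b_end and b_start <= a_end


def match_peaks(
    peaks_a: list[FocalPeak],
    peaks_b: list[FocalPeak],
    q_threshold: float = 0.25,
    padding_bp: int = 1_000_000,
) -> pd.DataFrame:
    """All-vs-all peak matches between two studies at a significance cutoff."""
    rows = []
    for pa in peaks_a:
        if pa.q_value >= q_threshold:
            continue
        for pb in peaks_b:
            if pb.q_value >= q_threshold:
                continue
            if peak_similarity(pa, pb, padding_bp=padding_bp):
                rows.append({
                    "cytoband_a": pa.cytoband, "cytoband_b": pb.cytoband,
                    "target_a": pa.target_gene, "target_b": pb.target_gene,
                    "chrom": pa.chrom,
                })
    return pd.DataFrame(rows, columns=["cytoband_a", "cytoband_b", "target_a", "target_b", "chrom"])
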
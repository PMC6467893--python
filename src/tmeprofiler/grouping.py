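"""Immune HIGH / MIX / LOW classification from normalized signature scores.

Samples are clustered hierarchically on their signature-score profiles
(default Euclidean distance with average linkage; 1 - Pearson correlation
and complete/ward linkage are selectable) and clusters
are mapped to immune groups by descending mean score, so cluster 1 is
always the most infiltrated. Two histology-specific refinements mirror how
the three-level classification is constructed for lung adenocarcinoma and
squamous carcinoma cohorts:

* ADC — two major clusters; the low cluster is LOW; within the high
  cluster, samples whose T-cell AND B-cell signature scores exceed the
  cohort median are HIGH, the rest MIX.
* SQCC — three major clusters mapped HIGH/MIX/LOW by mean score; MIX
  samples whose T-cell and B-cell scores and PD-1 and CD8 expression all
  exceed the cohort 75th percentile are promoted to HIGH.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .datatypes import ImmuneGroupAssignment, ScoreMatrix, ValidationError

_DISTANCES = {"correlation": "correlation", "1-pearson": "correlation", "euclidean": "euclidean"}
_LINKAGES = ("average", "complete", "ward")


def cluster_samples(
    scores: ScoreMatrix,
    k: int,
    distance: str = "euclidean",
    linkage_method: str = "average",
) -> pd.Series:
    """Agglomerative clustering of samples into ``k`` groups.

    Returns integer labels (1..k) indexed by sample id, ordered by
    descending mean signature score: label 1 is the most infiltrated
    cluster. Deterministic for fixed input.
    """
    v = scores.values
    n = v.shape[1]
    if k > n:
        raise ValidationError(f"k={k} exceeds number of samples ({n})")
    if distance not in _DISTANCES:
        raise ValidationError(f"distance must be one of {sorted(_DISTANCES)}")
    if linkage_method not in _LINKAGES:
        raise ValidationError(f"linkage must be one of {_LINKAGES}")
    X = v.to_numpy(dtype=float).T  # samples x signatures
    if np.allclose(X.std(axis=0), 0):
        raise ValidationError("degenerate: no immune structure (zero-variance score matrix)")
    if distance == "correlation" and np.any(X.std(axis=1) == 0):
        # correlation distance undefined for flat profiles; nudge is not
        # acceptable, fall back to euclidean for those comparisons is not
        # either -- treat as degenerate input
        raise ValidationError("degenerate: sample with zero-variance score profile")
    d = pdist(X, metric=_DISTANCES[distance])
    Z = linkage(d, method=linkage_method)
    raw = fcluster(Z, t=k, criterion="maxclust")
    if len(np.unique(raw)) < k:
        raise ValidationError(f"could not separate {k} clusters")
    # relabel by descending mean score
    means = {c: X[raw == c].mean() for c in np.unique(raw)}
    order = sorted(means, key=lambda c: -means[c])
    relabel = {c: i + 1 for i, c in enumerate(order)}
    return pd.Series([relabel[c] for c in raw], index=v.columns, name="cluster_id")


def assign_immune_groups(
    scores: ScoreMatrix,
    marker_expr: pd.DataFrame,
    histology: pd.Series,
    t_cell_signature: str = "T_cells",
    b_cell_signature: str = "B_cells",
    pd1_gene: str = "PDCD1",
    cd8_gene: str = "CD8A",
    distance: str = "euclidean",
    linkage_method: str = "average",
    adc_split_quantile: float = 0.5,
    sqcc_promotion_quantile: float = 0.75,
) -> ImmuneGroupAssignment:
    """Assign every sample to immune HIGH / MIX / LOW.

    ``marker_expr`` is a gene-by-sample expression frame containing at least
    the PD-1 and CD8 marker rows (used only on the SQCC promotion path);
    ``histology`` maps sample id -> ADC or SQCC. Each histology cohort is
    clustered and refined independently.
    """
    v = scores.values
    for sig in (t_cell_signature, b_cell_signature):
        if sig not in v.index:
            raise ValidationError(f"score matrix lacks required signature {sig!r}")
    missing = set(v.columns) - set(histology.index)
    if missing:
        raise ValidationError(f"samples without histology: {sorted(missing)[:5]}")
    records = []
    for hist in pd.unique(histology.loc[v.columns]):
        cohort = [s for s in v.columns if histology[s] == hist]
        sub = ScoreMatrix(values=v[cohort], normalized=scores.normalized)
        if hist == "ADC":
            records.extend(_assign_adc(
                sub, t_cell_signature, b_cell_signature,
                distance, linkage_method, adc_split_quantile))
        elif hist == "SQCC":
            records.extend(_assign_sqcc(
                sub, marker_expr, t_cell_signature, b_cell_signature,
                pd1_gene, cd8_gene, distance, linkage_method,
                sqcc_promotion_quantile))
        else:
            raise ValidationError(f"unknown histology {hist!r}")
    table = pd.DataFrame(records, columns=["sample", "group", "cluster_id", "refinement_rule"])
    # preserve input sample order
    table = table.set_index("sample").loc[list(v.columns)].reset_index()
    return ImmuneGroupAssignment(table=table)


def _assign_adc(scores, t_sig, b_sig, distance, linkage_method, split_q):
    v = scores.values
    labels = cluster_samples(scores, k=2, distance=distance, linkage_method=linkage_method)
    t_cut = v.loc[t_sig].quantile(split_q)
    b_cut = v.loc[b_sig].quantile(split_q)
    out = []
    for s in v.columns:
        if labels[s] == 2:
            out.append({"sample": s, "group": "LOW", "cluster_id": 2,
                        "refinement_rule": "none"})
        else:
            high = v.loc[t_sig, s] > t_cut and v.loc[b_sig, s] > b_cut
            out.append({"sample": s, "group": "HIGH" if high else "MIX",
                        "cluster_id": 1, "refinement_rule": "adc_high_split"})
    return out


def _assign_sqcc(scores, marker_expr, t_sig, b_sig, pd1, cd8,
                 distance, linkage_method, promo_q):
    v = scores.values
    for g in (pd1, cd8):
        if g not in marker_expr.index:
            raise ValidationError(f"marker expression lacks gene {g!r} for SQCC refinement")
    labels = cluster_samples(scores, k=3, distance=distance, linkage_method=linkage_method)
    group_of = {1: "HIGH", 2: "MIX", 3: "LOW"}
    t_cut = v.loc[t_sig].quantile(promo_q)
    b_cut = v.loc[b_sig].quantile(promo_q)
    pd1_cut = marker_expr.loc[pd1, v.columns].quantile(promo_q)
    cd8_cut = marker_expr.loc[cd8, v.columns].quantile(promo_q)
    out = []
    for s in v.columns:
        group = group_of[labels[s]]
        rule = "none"
        if group == "MIX":
            promoted = (
                v.loc[t_sig, s] > t_cut and v.loc[b_sig, s] > b_cut
                and marker_expr.loc[pd1, s] > pd1_cut
                and marker_expr.loc[cd8, s] > cd8_cut
            )
            if promoted:
                group, rule = "HIGH", "sqcc_mix_promotion"
        out.append({"sample": s, "group": group, "cluster_id": int(labels[s]),
                    "refinement_rule": rule})
    return out
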
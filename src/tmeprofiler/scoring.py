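"""Immune signature scoring and per-patient enrichment calling.

Two related rank statistics are computed from a gene-by-sample FPKM matrix:

* ``ssgsea_scores`` — the single-sample enrichment score of Barbie et al.'s
  ssGSEA family: per sample, genes are ranked by expression and the score is
  the integrated difference between the weighted in-set ECDF (rank weights
  raised to ``alpha``, default 0.25) and the unweighted out-of-set ECDF.
  Scores are range-normalized across the whole matrix (divide by max-min).

* ``preranked_enrichment`` — per-patient preranked GSEA on z-score-ranked
  genes: a weighted Kolmogorov-Smirnov running-sum statistic (weight
  exponent 1), with a permutation null built from random same-size gene
  sets, one-sided permutation p-values and Benjamini-Hochberg q-values over
  the signature family within each patient. A signature is called enriched
  when its ES is positive and q <= 0.1.

Both statistics depend on expression only through within-sample ranks, so
they are invariant to any monotone transform of a sample's values.
"""

from __future__ import annotations

import zlib

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .datatypes import (
    EnrichmentResult,
    ExpressionMatrix,
    ScoreMatrix,
    SignatureCollection,
    ValidationError,
)


def zscore_normalize(expr: ExpressionMatrix) -> pd.DataFrame:
    """Z-score each gene across samples (sample sd, ddof=1).

    Zero-variance genes are set to all-zero and recorded in the returned
    frame's ``attrs["flagged_constant_genes"]``.
    """
    if expr.n_samples < 2:
        raise ValidationError("z-score normalization needs >= 2 samples")
    v = expr.values
    mean = v.mean(axis=1)
    sd = v.std(axis=1, ddof=1)
    constant = sd == 0
    safe_sd = sd.mask(constant, 1.0)
    z = v.sub(mean, axis=0).div(safe_sd, axis=0)
    z.loc[constant] = 0.0
    z.attrs["flagged_constant_genes"] = list(v.index[constant])
    return z


def _check_sets(gene_index: pd.Index, sets: SignatureCollection) -> dict[str, np.ndarray]:
    """Map each signature to integer gene positions; validate overlap."""
    pos = {g: i for i, g in enumerate(gene_index)}
    out = {}
    for name, genes in sets.signatures.items():
        idx = np.array(sorted(pos[g] for g in genes if g in pos), dtype=np.intp)
        if idx.size == 0:
            raise ValidationError(f"signature {name!r} has no genes in the expression matrix")
        if idx.size >= len(gene_index):
            raise ValidationError(f"signature {name!r} covers the whole gene universe")
        out[name] = idx
    return out


def _rank_order(values: np.ndarray, gene_index: pd.Index) -> np.ndarray:
    """Descending order of genes for one sample; ties broken by gene id."""
    # lexsort: primary key -values (descending value), secondary stable gene order
    return np.lexsort((np.arange(len(values)), -values))


def ssgsea_scores(
    expr: ExpressionMatrix,
    sets: SignatureCollection,
    alpha: float = 0.25,
    normalize: bool = True,
) -> ScoreMatrix:
    """Single-sample GSEA score for every (signature, sample) pair.

    Per sample, genes are ordered by decreasing expression (ties broken by
    gene-id order); the gene at descending position i carries rank weight
    (G - i + 1) ** alpha, so the most highly expressed gene is weighted
    most. The score is sum over positions j of
    [weighted in-set ECDF(j) - out-of-set ECDF(j)].
    """
    if alpha < 0:
        raise ValidationError("alpha must be >= 0")
    set_idx = _check_sets(expr.values.index, sets)
    G = expr.n_genes
    values = expr.values.to_numpy(dtype=float)
    names = list(sets.signatures)
    scores = np.zeros((len(names), expr.n_samples))
    base_weights = (np.arange(G, 0, -1, dtype=float)) ** alpha  # weight at position i (0-based)
    for j in range(expr.n_samples):
        order = _rank_order(values[:, j], expr.values.index)
        # position of each gene (original index) in the ranked list
        position = np.empty(G, dtype=np.intp)
        position[order] = np.arange(G)
        for si, name in enumerate(names):
            member_pos = np.sort(position[set_idx[name]])
            k = member_pos.size
            w = base_weights[member_pos]
            cum_in = np.cumsum(w) / w.sum()
            # integrated ECDF difference, evaluated at every ranked position
            in_step = np.zeros(G)
            in_step[member_pos] = np.diff(np.concatenate(([0.0], cum_in)))
            ecdf_in = np.cumsum(in_step)
            out_mask = np.ones(G)
            out_mask[member_pos] = 0.0
            ecdf_out = np.cumsum(out_mask) / (G - k)
            scores[si, j] = np.sum(ecdf_in - ecdf_out)
    df = pd.DataFrame(scores, index=names, columns=expr.values.columns)
    if normalize:
        rng = df.to_numpy().max() - df.to_numpy().min()
        if rng > 0:
            df = df / rng
        return ScoreMatrix(values=df, normalized=True)
    return ScoreMatrix(values=df, normalized=False)


# -------------------------------------------------- preranked enrichment


def _es_from_positions(member_pos: np.ndarray, weights: np.ndarray, G: int) -> float:
    """Signed max-deviation KS statistic for a set at given ranked positions.

    ``weights`` are the per-position rank weights |z|^1 for the whole ranked
    list; ``cum_all`` their cumulative sum (both precomputed per sample).
    The running sum increases by w/W at in-set positions and decreases by
    1/(G-k) elsewhere; the statistic is the deviation of largest magnitude.
    """
    k = member_pos.size
    w = weights[member_pos]
    W = w.sum()
    if W == 0:
        W = 1.0
    cum_in = np.cumsum(w) / W
    miss = (member_pos - np.arange(k)) / (G - k)   # out-of-set mass just before each hit
    dev_after = cum_in - miss
    dev_before = np.concatenate(([0.0], cum_in[:-1])) - miss
    max_dev = max(dev_after.max(), 0.0)
    min_dev = min(dev_before.min(), 0.0)
    return float(max_dev if max_dev >= -min_dev else min_dev)


def _null_es(rng: np.random.Generator, k: int, weights: np.ndarray, G: int,
             n_perm: int) -> np.ndarray:
    """Null ES distribution from random same-size gene sets (vectorized)."""
    idx = np.argsort(rng.random((n_perm, G)), axis=1)[:, :k]
    idx.sort(axis=1)
    w = weights[idx]
    cum_in = np.cumsum(w, axis=1) / np.maximum(w.sum(axis=1, keepdims=True), 1e-300)
    miss = (idx - np.arange(k)) / (G - k)
    dev_after = cum_in - miss
    dev_before = np.concatenate(
        (np.zeros((n_perm, 1)), cum_in[:, :-1]), axis=1) - miss
    max_dev = np.maximum(dev_after.max(axis=1), 0.0)
    min_dev = np.minimum(dev_before.min(axis=1), 0.0)
    return np.where(max_dev >= -min_dev, max_dev, min_dev)


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values."""
    return multipletests(pvals, method="fdr_bh")[1]


def flag_enriched(es: float, q: float, threshold: float = 0.1) -> bool:
    """A signature is enriched when over-represented (ES > 0) at q <= threshold."""
    return bool(es > 0 and q <= threshold)


def preranked_enrichment(
    zexpr: pd.DataFrame,
    sets: SignatureCollection,
    n_perm: int = 1000,
    seed: int = 0,
    q_threshold: float = 0.1,
) -> EnrichmentResult:
    """Per-patient preranked GSEA over the signature collection.

    ``zexpr`` is a z-score-normalized gene-by-sample frame. Per sample,
    genes are ranked by z descending; the weighted KS statistic uses |z| as
    rank weight (exponent 1). The null is ``n_perm`` random same-size gene
    sets drawn once per (sample, set size) from a generator seeded by
    ``seed``. p = (1 + #{null >= ES}) / (1 + n_perm) for positive ES and the
    mirrored left tail for negative ES; q = BH across the signatures within
    each sample; enriched iff ES > 0 and q <= ``q_threshold``.
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    gene_index = zexpr.index
    set_idx = _check_sets(gene_index, sets)
    G = len(gene_index)
    names = list(sets.signatures)
    rows = []
    for sample in zexpr.columns:
        z = zexpr[sample].to_numpy(dtype=float)
        order = _rank_order(z, gene_index)
        position = np.empty(G, dtype=np.intp)
        position[order] = np.arange(G)
        weights = np.abs(z)[order]
        rng = np.random.default_rng([seed, zlib.crc32(str(sample).encode())])
        null_cache: dict[int, np.ndarray] = {}
        es_list, p_list, nes_list = [], [], []
        for name in names:
            member_pos = np.sort(position[set_idx[name]])
            k = member_pos.size
            es = _es_from_positions(member_pos, weights, G)
            if k not in null_cache:
                null_cache[k] = _null_es(rng, k, weights, G, n_perm)
            null = null_cache[k]
            if es >= 0:
                p = (1 + np.sum(null >= es)) / (1 + n_perm)
                denom = np.abs(null[null >= 0]).mean() if (null >= 0).any() else 1.0
            else:
                p = (1 + np.sum(null <= es)) / (1 + n_perm)
                denom = np.abs(null[null < 0]).mean() if (null < 0).any() else 1.0
            nes = es / denom if denom > 0 else 0.0
            es_list.append(es)
            p_list.append(p)
            nes_list.append(nes)
        q = bh_adjust(np.array(p_list))
        for name, es, nes, p, qv in zip(names, es_list, nes_list, p_list, q):
            rows.append({
                "sample": sample, "signature": name, "ES": es, "NES": nes,
                "p": p, "q": qv, "enriched": flag_enriched(es, qv, q_threshold),
            })
    return EnrichmentResult(table=pd.DataFrame(rows), q_threshold=q_threshold)


# ------------------------------------------------------------ TIL profile


def til_profile(
    enrichment: EnrichmentResult,
    strata: pd.Series,
    sets: SignatureCollection | None = None,
    any_til_signatures: list[str] | None = None,
) -> pd.DataFrame:
    """Percent of samples enriched per signature within each cohort stratum.

    ``strata`` maps sample id -> stratum label (e.g. histology). The
    returned frame also carries an ``any_TIL`` row: the percent of samples
    enriched for at least one signature in ``any_til_signatures`` (default:
    the adaptive-category signatures, the T/B-lineage reading of "TILs").
    """
    t = enrichment.table
    samples = t["sample"].unique()
    missing = set(samples) - set(strata.index)
    if missing:
        raise ValidationError(f"samples without stratum: {sorted(missing)[:5]}")
    if any_til_signatures is None:
        if sets is not None:
            any_til_signatures = sets.by_category("adaptive")
        else:
            any_til_signatures = sorted(t["signature"].unique())
    rows = []
    for stratum in pd.unique(strata.loc[samples]):
        members = [s for s in samples if strata[s] == stratum]
        if not members:
            raise ValidationError(f"empty stratum {stratum!r}")
        sub = t[t["sample"].isin(members)]
        for sig, grp in sub.groupby("signature", sort=False):
            n_enriched = int(grp["enriched"].sum())
            total = len(grp)
            rows.append({
                "stratum": stratum, "signature": sig,
                "enriched": n_enriched, "total": total,
                "percent": 100.0 * n_enriched / total,
            })
        any_mask = (
            sub[sub["signature"].isin(any_til_signatures)]
            .groupby("sample")["enriched"].any()
        )
        rows.append({
            "stratum": stratum, "signature": "any_TIL",
            "enriched": int(any_mask.sum()), "total": len(members),
            "percent": 100.0 * any_mask.sum() / len(members),
        })
    return pd.DataFrame(rows)
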
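"""Independent brute-force oracles used to check the fast implementations.

These are deliberately literal, loop-based transcriptions of the underlying
definitions and share no code with the package.
"""

from __future__ import annotations

from math import comb

import numpy as np


def ssgsea_oracle(values: dict[str, float], set_genes: set[str], alpha: float) -> float:
    """Literal running-sum transcription of the single-sample score.

    Genes ordered by decreasing value (gene id breaks ties); the gene at
    descending position i (1-based) has weight (G - i + 1) ** alpha; the
    score is the sum over positions of (weighted in-set ECDF - out-of-set
    ECDF).
    """
    ordered = sorted(values, key=lambda g: (-values[g], g))
    G = len(ordered)
    k = sum(1 for g in ordered if g in set_genes)
    weights = {}
    for i, g in enumerate(ordered, start=1):
        weights[g] = (G - i + 1) ** alpha
    W = sum(weights[g] for g in ordered if g in set_genes)
    p_in = 0.0
    p_out = 0.0
    es = 0.0
    for g in ordered:
        if g in set_genes:
            p_in += weights[g] / W
        else:
            p_out += 1.0 / (G - k)
        es += p_in - p_out
    return es


def gsea_es_oracle(z: dict[str, float], set_genes: set[str]) -> float:
    """Weighted KS running-sum statistic (weight exponent 1) by direct walk.

    Returns the deviation of largest magnitude (signed).
    """
    ordered = sorted(z, key=lambda g: (-z[g], g))
    G = len(ordered)
    k = sum(1 for g in ordered if g in set_genes)
    W = sum(abs(z[g]) for g in ordered if g in set_genes)
    running = 0.0
    best = 0.0
    for g in ordered:
        if g in set_genes:
            running += abs(z[g]) / W if W > 0 else 1.0 / k
        else:
            running -= 1.0 / (G - k)
        if abs(running) > abs(best):
            best = running
    return best


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full enumeration of tables with fixed margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def pmf(x: int) -> float:
        # P(X = x) for the hypergeometric with these margins
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = pmf(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    total = 0.0
    for x in range(lo, hi + 1):
        px = pmf(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(1.0, total)


def bh_oracle(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg q-values by sort and cumulative minimum."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvals[i] * m / rank_from_top)
        q[i] = val
        prev = val
    return q


def km_empirical_oracle(times: np.ndarray) -> dict[float, float]:
    """Survivor function with no censoring: S(t) = #(T > t) / n."""
    n = len(times)
    return {float(t): float(np.sum(times > t)) / n for t in np.unique(times)}
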
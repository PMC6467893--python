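"""Cohort-level statistics: genotype-immune association, differential
expression across immune groups, and pathway-score correlations."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import ExpressionMatrix, ImmuneGroupAssignment, ValidationError
from .scoring import bh_adjust, ssgsea_scores, zscore_normalize


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts: rows alteration yes/no, columns group membership yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("contingency counts must be non-negative")
        if self.a + self.b + self.c + self.d < 1:
            raise ValidationError("empty contingency table")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def fisher_exact_2x2(table: ContingencyTable2x2) -> tuple[float, float]:
    """Two-sided Fisher's exact test.

    Returns (odds ratio, p). The odds ratio is the sample estimate
    a*d / (b*c) (infinite when b*c = 0 and a*d > 0); the two-sided p sums
    the hypergeometric probabilities of all tables with the observed
    margins whose point probability does not exceed the observed table's.
    """
    arr = table.as_array()
    res = sps.fisher_exact(arr, alternative="two-sided")
    odds = (table.a * table.d) / (table.b * table.c) if table.b * table.c else (
        np.inf if table.a * table.d else np.nan
    )
    return float(odds), float(res.pvalue)


def association_tests(
    alterations: pd.DataFrame,
    groups: ImmuneGroupAssignment | pd.Series,
    target_group: str = "HIGH",
) -> pd.DataFrame:
    """Fisher tests of each alteration column against membership of one group.

    ``alterations`` is a samples x alterations boolean frame. Each column
    yields a 2x2 table (altered yes/no vs in-group yes/no), a sample odds
    ratio, a two-sided p and a BH q across the alteration family.
    """
    grp = groups.as_series() if isinstance(groups, ImmuneGroupAssignment) else groups
    common = [s for s in alterations.index if s in grp.index]
    if not common:
        raise ValidationError("no overlap between alteration table and group assignment")
    in_group = grp.loc[common] == target_group
    rows = []
    for col in alterations.columns:
        alt = alterations.loc[common, col].astype(bool)
        t = ContingencyTable2x2(
            a=int((alt & in_group).sum()), b=int((alt & ~in_group).sum()),
            c=int((~alt & in_group).sum()), d=int((~alt & ~in_group).sum()),
        )
        odds, p = fisher_exact_2x2(t)
        rows.append({"alteration": col, "group": target_group,
                     "a": t.a, "b": t.b, "c": t.c, "d": t.d,
                     "odds_ratio": odds, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


# ---------------------------------------------------------------- DE genes


def group_de_genes(
    expr: ExpressionMatrix,
    groups: ImmuneGroupAssignment | pd.Series,
    marker_genes: Sequence[str],
    fdr_threshold: float = 0.01,
    corr_threshold: float = 0.6,
    fold_change_threshold: float = 2.0,
    pseudocount_rel: float = 0.1,
) -> pd.DataFrame:
    """Triple-criterion differential-expression screen across three groups.

    A gene is selected when (i) both the one-way ANOVA and Kruskal-Wallis
    BH-adjusted q-values are below ``fdr_threshold``, (ii) its z-scored
    expression correlates (Pearson, absolute) below ``corr_threshold`` with
    every classification marker gene, and (iii) some pair of group means
    differs by more than ``fold_change_threshold``-fold on the linear FPKM
    scale (pseudocount = ``pseudocount_rel`` x global mean FPKM, which
    makes the criterion invariant to global rescaling).
    """
    grp = groups.as_series() if isinstance(groups, ImmuneGroupAssignment) else groups
    samples = [s for s in expr.sample_ids if s in grp.index]
    labels = pd.unique(grp.loc[samples])
    if len(labels) != 3:
        raise ValidationError(f"expected exactly 3 groups, got {list(labels)}")
    members = {lab: [s for s in samples if grp[s] == lab] for lab in labels}
    for lab, mem in members.items():
        if len(mem) < 2:
            raise ValidationError(f"group {lab!r} has fewer than 2 samples")
    missing_markers = [m for m in marker_genes if m not in expr.values.index]
    if missing_markers:
        raise ValidationError(f"marker genes absent from expression: {missing_markers}")

    v = expr.values[samples]
    z = zscore_normalize(ExpressionMatrix(values=v))
    marker_z = z.loc[list(marker_genes)].to_numpy()
    arrs = {lab: v[mem].to_numpy() for lab, mem in members.items()}
    eps = pseudocount_rel * float(v.to_numpy().mean())

    anova_p, kw_p, max_corr, max_fc = [], [], [], []
    for gi, gene in enumerate(v.index):
        vals = [arrs[lab][gi] for lab in labels]
        if np.ptp(np.concatenate(vals)) == 0:
            anova_p.append(1.0)
            kw_p.append(1.0)
        else:
            with np.errstate(all="ignore"):
                f = sps.f_oneway(*vals)
                anova_p.append(1.0 if np.isnan(f.pvalue) else float(f.pvalue))
                try:
                    k = sps.kruskal(*vals)
                    kw_p.append(1.0 if np.isnan(k.pvalue) else float(k.pvalue))
                except ValueError:  # all values identical
                    kw_p.append(1.0)
        gz = z.to_numpy()[gi]
        if np.all(gz == 0):
            max_corr.append(0.0)
        else:
            with np.errstate(all="ignore"):
                cors = [abs(np.corrcoef(gz, mz)[0, 1]) for mz in marker_z]
            max_corr.append(float(np.nanmax(cors)) if cors else 0.0)
        means = np.array([a[gi].mean() for a in arrs.values()]) + eps
        fcs = [max(x, y) / min(x, y) for i, x in enumerate(means) for y in means[i + 1:]]
        max_fc.append(float(max(fcs)))

    anova_q = bh_adjust(np.array(anova_p))
    kw_q = bh_adjust(np.array(kw_p))
    out = pd.DataFrame({
        "gene": list(v.index),
        "anova_q": anova_q, "kw_q": kw_q,
        "max_abs_corr_with_markers": max_corr,
        "max_pairwise_fold_change": max_fc,
    })
    out["selected"] = (
        (out["anova_q"] < fdr_threshold)
        & (out["kw_q"] < fdr_threshold)
        & (out["max_abs_corr_with_markers"] < corr_threshold)
        & (out["max_pairwise_fold_change"] > fold_change_threshold)
    )
    return out


def pathway_score_correlation(
    expr: ExpressionMatrix,
    pathway_set,
    target: pd.Series,
    alpha: float = 0.25,
) -> tuple[float, float]:
    """Spearman correlation between a pathway's ssGSEA score and a target.

    ``pathway_set`` is a SignatureCollection with a single pathway (or any
    collection, in which case the first is used); ``target`` is a
    per-sample series (a gene's expression or another signature's scores).
    Ties receive average ranks (scipy convention). A constant target has no
    defined rank correlation: returns (nan, nan).
    """
    if expr.n_samples < 3:
        raise ValidationError("need >= 3 samples for a rank correlation")
    scores = ssgsea_scores(expr, pathway_set, alpha=alpha)
    name = scores.values.index[0]
    s = scores.values.loc[name, list(target.index)]
    if np.ptp(target.to_numpy(dtype=float)) == 0 or np.ptp(s.to_numpy()) == 0:
        return float("nan"), float("nan")
    rho, p = sps.spearmanr(s.to_numpy(), target.to_numpy(dtype=float))
    return float(rho), float(p)
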
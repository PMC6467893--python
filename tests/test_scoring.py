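"""Immune signature scoring: ssGSEA, z-normalization, preranked enrichment."""

import numpy as np
import pandas as pd
import pytest

from tmeprofiler import (
    ExpressionMatrix,
    SignatureCollection,
    ValidationError,
    flag_enriched,
    preranked_enrichment,
    ssgsea_scores,
    til_profile,
    zscore_normalize,
)
from tmeprofiler.datatypes import EnrichmentResult

from oracles import bh_oracle, gsea_es_oracle, ssgsea_oracle


def _sets(d):
    return SignatureCollection(
        signatures={k: frozenset(v) for k, v in d.items()},
        category={k: "other" for k in d},
    )


class TestSsgseaScores:
    def test_matches_bruteforce_oracle_elementwise(self, small_expr, small_sets):
        scores = ssgsea_scores(small_expr, small_sets, alpha=0.25, normalize=False)
        for sig, genes in small_sets.signatures.items():
            for sample in small_expr.sample_ids:
                expected = ssgsea_oracle(
                    small_expr.values[sample].to_dict(), set(genes), 0.25)
                assert scores.values.loc[sig, sample] == pytest.approx(expected, abs=1e-9)

    def test_alpha_zero_equals_unweighted_running_sum(self):
        # 6-gene toy; alpha = 0 makes every rank weight 1
        values = pd.DataFrame(
            {"S1": [9.0, 7.0, 5.0, 3.0, 2.0, 1.0], "S2": [1.0, 2.0, 9.0, 8.0, 3.0, 4.0]},
            index=list("ABCDEF"))
        expr = ExpressionMatrix(values=values)
        sets = _sets({"top": {"A", "B"}})
        scores = ssgsea_scores(expr, sets, alpha=0.0, normalize=False)
        for sample in ("S1", "S2"):
            expected = ssgsea_oracle(values[sample].to_dict(), {"A", "B"}, 0.0)
            assert scores.values.loc["top", sample] == pytest.approx(expected, abs=1e-9)

    def test_set_at_top_ranks_scores_positive(self):
        values = pd.DataFrame(
            {"S1": [10.0, 9.0, 1.0, 0.5, 0.2, 0.1], "S2": [10.0, 9.0, 1.0, 0.5, 0.2, 0.1]},
            index=list("ABCDEF"))
        expr = ExpressionMatrix(values=values)
        scores = ssgsea_scores(expr, _sets({"top": {"A", "B"}}), normalize=False)
        assert (scores.values.loc["top"] > 0).all()

    def test_rank_invariance_under_monotone_transform(self, small_expr, small_sets):
        raw = ssgsea_scores(small_expr, small_sets, normalize=False)
        transformed = ExpressionMatrix(values=np.log1p(small_expr.values) ** 2)
        after = ssgsea_scores(transformed, small_sets, normalize=False)
        pd.testing.assert_frame_equal(raw.values, after.values)

    def test_normalized_scores_divided_by_range(self, small_expr, small_sets):
        raw = ssgsea_scores(small_expr, small_sets, normalize=False)
        norm = ssgsea_scores(small_expr, small_sets, normalize=True)
        rng = raw.values.to_numpy().max() - raw.values.to_numpy().min()
        pd.testing.assert_frame_equal(norm.values, raw.values / rng)
        assert norm.normalized

    def test_zero_overlap_signature_rejected(self, small_expr):
        with pytest.raises(ValidationError, match="ghost"):
            ssgsea_scores(small_expr, _sets({"ghost": {"NOPE1", "NOPE2"}}))

    def test_full_universe_signature_rejected(self, small_expr):
        with pytest.raises(ValidationError, match="universe"):
            ssgsea_scores(small_expr, _sets({"all": set(small_expr.gene_ids)}))


class TestZscoreNormalize:
    def test_closed_form_row(self):
        expr = ExpressionMatrix(values=pd.DataFrame(
            {"S1": [1.0, 5.0], "S2": [2.0, 5.0], "S3": [3.0, 5.0]}, index=["g1", "g2"]))
        z = zscore_normalize(expr)
        # sample sd (ddof=1) of (1,2,3) is 1
        assert list(z.loc["g1"]) == pytest.approx([-1.0, 0.0, 1.0])

    def test_constant_gene_zeroed_and_flagged(self):
        expr = ExpressionMatrix(values=pd.DataFrame(
            {"S1": [1.0, 5.0], "S2": [2.0, 5.0], "S3": [3.0, 5.0]}, index=["g1", "g2"]))
        z = zscore_normalize(expr)
        assert (z.loc["g2"] == 0).all()
        assert z.attrs["flagged_constant_genes"] == ["g2"]

    def test_idempotent_on_normalized_input(self, small_expr):
        z1 = zscore_normalize(small_expr)
        z2 = zscore_normalize(ExpressionMatrix(values=z1 - z1.min().min() + 0.0 + 1e-12))
        # re-normalizing shifted z-scores reproduces them (shift cancels)
        np.testing.assert_allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-12)

    def test_single_sample_rejected(self):
        values = pd.DataFrame({"S1": [1.0, 2.0]}, index=["g1", "g2"])
        with pytest.raises(ValidationError):
            ExpressionMatrix(values=values)


class TestPrerankedEnrichment:
    @pytest.fixture()
    def zexpr(self, small_expr):
        return zscore_normalize(small_expr)

    def test_es_matches_walk_oracle(self, zexpr, small_sets):
        res = preranked_enrichment(zexpr, small_sets, n_perm=100, seed=1)
        for row in res.table.itertuples(index=False):
            expected = gsea_es_oracle(
                zexpr[row.sample].to_dict(), set(small_sets.signatures[row.signature]))
            assert row.ES == pytest.approx(expected, abs=1e-12)

    def test_top_k_signature_attains_permutation_floor(self, zexpr):
        sample = zexpr.columns[0]
        top = set(zexpr[sample].sort_values(ascending=False).index[:8])
        sets = _sets({"topk": top})
        res = preranked_enrichment(zexpr, sets, n_perm=200, seed=3)
        row = res.table[(res.table["sample"] == sample)].iloc[0]
        assert row["ES"] > 0.9
        assert row["p"] == pytest.approx(1 / 201)

    def test_q_matches_bh_oracle_within_each_sample(self, zexpr, small_sets):
        res = preranked_enrichment(zexpr, small_sets, n_perm=150, seed=2)
        for _, grp in res.table.groupby("sample"):
            expected = bh_oracle(list(grp["p"]))
            assert list(grp["q"]) == pytest.approx(expected, abs=1e-12)

    def test_q_at_threshold_boundary_counts_as_enriched(self):
        assert flag_enriched(es=0.5, q=0.1, threshold=0.1)
        assert not flag_enriched(es=0.5, q=0.10000001, threshold=0.1)
        assert not flag_enriched(es=-0.5, q=0.05, threshold=0.1)

    def test_determinism_same_seed(self, zexpr, small_sets):
        r1 = preranked_enrichment(zexpr, small_sets, n_perm=120, seed=9)
        r2 = preranked_enrichment(zexpr, small_sets, n_perm=120, seed=9)
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_oversized_signature_rejected(self, zexpr):
        sets = _sets({"huge": {f"X{i}" for i in range(100)} | set(zexpr.index)})
        with pytest.raises(ValidationError):
            preranked_enrichment(zexpr, sets, n_perm=100, seed=0)


class TestPlantedRecovery:
    def test_sparse_infiltration_flags_recovered(self):
        """Planted per-sample infiltration is recovered with sens/spec >= 0.9."""
        from tmeprofiler import SimulationParams, generate_cohort

        sparse = {g: {c: p for c in ("adaptive", "innate", "other")}
                  for g, p in (("HIGH", 0.45), ("MIX", 0.3), ("LOW", 0.15))}
        params = SimulationParams(n_adc=10, n_sqcc=10, n_genes=2000,
                                  signature_size=20, delta=2.0, seed=4,
                                  infiltration_probs=sparse)
        c = generate_cohort(params)
        z = zscore_normalize(c.expression)
        res = preranked_enrichment(z, c.signatures, n_perm=1000, seed=7)
        called = res.table.pivot(index="sample", columns="signature", values="enriched")
        truth = c.enrichment_truth.loc[called.index, called.columns]
        tp = (called & truth).to_numpy().sum()
        fn = (~called & truth).to_numpy().sum()
        fp = (called & ~truth).to_numpy().sum()
        tn = (~called & ~truth).to_numpy().sum()
        assert tp / (tp + fn) >= 0.9
        assert tn / (tn + fp) >= 0.9


class TestTilProfile:
    def _result(self, n_enriched, total, signature="T_cells"):
        rows = []
        for i in range(total):
            rows.append({"sample": f"S{i}", "signature": signature,
                         "ES": 0.5, "NES": 1.0, "p": 0.01,
                         "q": 0.05 if i < n_enriched else 0.5,
                         "enriched": i < n_enriched})
        return EnrichmentResult(table=pd.DataFrame(rows))

    def test_percent_formula(self):
        res = self._result(95, 131)
        strata = pd.Series("ADC", index=[f"S{i}" for i in range(131)])
        prof = til_profile(res, strata, any_til_signatures=["T_cells"])
        row = prof[(prof["signature"] == "T_cells")].iloc[0]
        assert row["percent"] == pytest.approx(100 * 95 / 131)

    def test_zero_and_full_enrichment(self):
        strata = pd.Series("X", index=[f"S{i}" for i in range(10)])
        assert til_profile(self._result(0, 10), strata,
                           any_til_signatures=["T_cells"])["percent"].iloc[0] == 0.0
        one = pd.Series("X", index=["S0"])
        prof = til_profile(self._result(1, 1), one, any_til_signatures=["T_cells"])
        assert (prof["percent"] == 100.0).all()

    def test_unassigned_sample_rejected(self):
        res = self._result(1, 3)
        strata = pd.Series("X", index=["S0", "S1"])  # S2 missing
        with pytest.raises(ValidationError):
            til_profile(res, strata)
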
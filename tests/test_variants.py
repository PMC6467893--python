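"""Multi-caller merge, somatic filter cascade, burden and spectra."""

import numpy as np
import pandas as pd
import pytest

from tmeprofiler import (
    FilterReport,
    MergedVariant,
    ValidationError,
    VariantCall,
    apply_somatic_filters,
    compare_spectra,
    make_filter_fixture,
    merge_caller_calls,
    mutation_burden,
    substitution_class,
    substitution_spectrum,
)
from tmeprofiler.datatypes import FILTER_STAGES


def _call(caller, reads=20, effect="nonsynonymous", pos=100, sample="S1",
          ref="C", alt="T", popdb=frozenset()):
    return VariantCall(sample_id=sample, chrom="1", pos=pos, ref=ref, alt=alt,
                       caller_id=caller, supporting_reads=reads,
                       effect_class=effect, popdb_flags=popdb)


class TestMerge:
    def test_three_callers_collapse_to_one(self):
        merged = merge_caller_calls([_call("a"), _call("b"), _call("c")])
        assert len(merged) == 1
        assert merged[0].caller_count == 3

    def test_disjoint_calls_concatenate(self):
        merged = merge_caller_calls([_call("a", pos=100), _call("b", pos=200)])
        assert len(merged) == 2

    def test_max_supporting_reads_retained(self):
        merged = merge_caller_calls([_call("a", reads=5), _call("b", reads=12)])
        assert merged[0].max_supporting_reads == 12

    def test_effect_disagreement_resolves_to_most_deleterious(self):
        merged = merge_caller_calls([
            _call("a", effect="UTR"), _call("b", effect="nonsynonymous"),
            _call("c", effect="synonymous")])
        assert merged[0].effect_class == "nonsynonymous"

    def test_popdb_flags_unioned(self):
        merged = merge_caller_calls([
            _call("a", popdb=frozenset({"1000G"})),
            _call("b", popdb=frozenset({"ExAC"}))])
        assert merged[0].popdb_flags == frozenset({"1000G", "ExAC"})

    def test_conflicting_ref_rejected(self):
        with pytest.raises(ValidationError, match="conflicting ref"):
            merge_caller_calls([_call("a", ref="C", alt="T"),
                                _call("b", ref="G", alt="T")])


class TestFilterCascade:
    def test_read_boundary_seven_removed_eight_kept(self):
        merged = merge_caller_calls([_call("a", reads=7, pos=1),
                                     _call("a", reads=8, pos=2)])
        kept, report = apply_somatic_filters(merged, min_reads=8)
        assert [v.pos for v in kept] == [2]
        assert report.surviving["min_reads"] == 1

    def test_planted_contaminant_counts_match_truth_exactly(self):
        merged, germline, pon, expected = make_filter_fixture(
            n_clean=32, n_germline=10, n_popdb=5, n_pon=3, seed=1)
        assert len(merged) == 50
        kept, report = apply_somatic_filters(merged, germline, pon, min_reads=8)
        assert report.surviving == expected
        assert len(kept) == 32

    def test_all_contaminant_classes_counted_per_stage(self):
        merged, germline, pon, expected = make_filter_fixture(
            n_clean=20, n_low_read=4, n_effect=6, n_germline=3, n_popdb=2,
            n_pon=1, seed=2)
        _, report = apply_somatic_filters(merged, germline, pon)
        assert report.surviving == expected
        assert report.removed_at("min_reads") == 4
        assert report.removed_at("effect_class") == 6
        assert report.removed_at("matched_germline") == 3

    def test_no_contaminants_is_identity(self):
        merged, _, _, _ = make_filter_fixture(n_clean=10, n_germline=0,
                                              n_popdb=0, n_pon=0)
        kept, report = apply_somatic_filters(merged)
        assert kept == sorted(merged, key=lambda v: v.key) or set(kept) == set(merged)
        assert report.surviving["panel_of_normals"] == 10

    def test_cascade_idempotent(self):
        merged, germline, pon, _ = make_filter_fixture(seed=3)
        kept1, _ = apply_somatic_filters(merged, germline, pon)
        kept2, report2 = apply_somatic_filters(kept1, germline, pon)
        assert kept2 == kept1
        assert report2.surviving["input"] == report2.surviving["panel_of_normals"]

    def test_counts_monotone_and_conserved(self, cohort):
        merged = merge_caller_calls(cohort.variant_calls)
        _, report = apply_somatic_filters(merged, cohort.germline_keys,
                                          cohort.pon_keys)
        counts = [report.surviving[s] for s in FILTER_STAGES]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        removed = sum(report.removed_at(s) for s in FILTER_STAGES[1:])
        assert removed + counts[-1] == counts[0]

    def test_cohort_generator_truth_matches_report(self, cohort):
        merged = merge_caller_calls(cohort.variant_calls)
        _, report = apply_somatic_filters(merged, cohort.germline_keys,
                                          cohort.pon_keys)
        assert report.surviving == cohort.filter_truth

    def test_empty_input_gives_zero_report(self):
        kept, report = apply_somatic_filters([])
        assert kept == []
        assert all(v == 0 for v in report.surviving.values())

    def test_monotonicity_invariant_enforced(self):
        with pytest.raises(ValidationError):
            FilterReport(surviving={
                "input": 5, "min_reads": 6, "effect_class": 4,
                "matched_germline": 4, "popdb": 4, "panel_of_normals": 4})


class TestBurden:
    def _mv(self, sample="S1", pos=1, effect="nonsynonymous"):
        return MergedVariant(sample_id=sample, chrom="1", pos=pos, ref="C",
                             alt="T", callers=frozenset({"a"}),
                             max_supporting_reads=20, effect_class=effect)

    def test_per_mb_arithmetic(self):
        variants = [self._mv(pos=i + 1) for i in range(38)]
        b = mutation_burden(variants, target_mb=38.0)
        assert b.loc[0, "nonsyn_per_mb"] == pytest.approx(1.0)
        assert b.loc[0, "total_per_mb"] == pytest.approx(1.0)

    def test_zero_variants(self):
        b = mutation_burden([], target_mb=38.0, sample_ids=["S1"])
        assert b.loc[0, "total_per_mb"] == 0.0

    def test_total_includes_non_nonsynonymous_survivors(self):
        variants = [self._mv(pos=1), self._mv(pos=2, effect="other")]
        b = mutation_burden(variants, target_mb=1.0)
        assert b.loc[0, "total_per_mb"] == 2.0
        assert b.loc[0, "nonsyn_per_mb"] == 1.0

    def test_linearity_under_concatenation(self):
        va = [self._mv(sample="A", pos=i + 1) for i in range(10)]
        vb = [self._mv(sample="B", pos=i + 1) for i in range(4)]
        both = mutation_burden(va + vb, target_mb=2.0)
        sep = pd.concat([mutation_burden(va, 2.0), mutation_burden(vb, 2.0)],
                        ignore_index=True)
        pd.testing.assert_frame_equal(both, sep)

    def test_invalid_target_rejected(self):
        with pytest.raises(ValidationError):
            mutation_burden([], target_mb=0.0)


class TestSpectrum:
    def test_purine_reference_collapsed(self):
        assert substitution_class("G", "T") == "C>A"
        assert substitution_class("A", "G") == "T>C"
        assert substitution_class("C", "A") == "C>A"
        assert substitution_class("CT", "C") is None  # indel

    def test_proportions_sum_to_one(self, cohort):
        from tmeprofiler import apply_somatic_filters, merge_caller_calls
        merged = merge_caller_calls(cohort.variant_calls)
        kept, _ = apply_somatic_filters(merged, cohort.germline_keys, cohort.pon_keys)
        spec = substitution_spectrum(kept)
        np.testing.assert_allclose(spec.sum(axis=1), 1.0)

    def test_zero_snv_sample_excluded(self):
        mv = MergedVariant(sample_id="S1", chrom="1", pos=5, ref="CT", alt="C",
                           callers=frozenset({"a"}), max_supporting_reads=9,
                           effect_class="nonsynonymous")
        spec = substitution_spectrum([mv])
        assert "S1" not in spec.index
        assert spec.attrs["excluded_samples"] == ["S1"]

    def test_planted_smoker_c_to_a_excess_detected(self):
        """The C>A class separates smoker from non-smoker spectra at BH q<0.05."""
        from tmeprofiler.simulate import SimulationParams, generate_truth, generate_genomics
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            params = SimulationParams(n_adc=30, n_sqcc=30, seed=seed,
                                      smoker_fraction={"ADC": 0.5, "SQCC": 0.5})
            truth = generate_truth(params, rng)
            calls, germ, pon, _, _, _, _, _ = generate_genomics(params, truth, rng)
            merged = merge_caller_calls(calls)
            kept, _ = apply_somatic_filters(merged, germ, pon)
            spec = substitution_spectrum(kept)
            smoking = truth.set_index("sample")["smoking"]
            res = compare_spectra(spec, smoking)
            row = res[res["class"] == "C>A"].iloc[0]
            if row["q"] < 0.05:
                hits += 1
        assert hits >= 0.8 * n_seeds

    def test_equal_probabilities_calibrated_under_null(self):
        """With identical smoker/non-smoker spectra, significant classes are rare."""
        from tmeprofiler.simulate import SimulationParams, generate_truth, generate_genomics
        probs = (0.3, 0.1, 0.3, 0.1, 0.1, 0.1)
        n_sig = 0
        n_seeds = 6
        for seed in range(n_seeds):
            params = SimulationParams(
                n_adc=20, n_sqcc=20, seed=seed,
                smoker_fraction={"ADC": 0.5, "SQCC": 0.5},
                substitution_probs={"smoker": probs, "non-smoker": probs})
            rng = np.random.default_rng(seed)
            truth = generate_truth(params, rng)
            calls, germ, pon, _, _, _, _, _ = generate_genomics(params, truth, rng)
            merged = merge_caller_calls(calls)
            kept, _ = apply_somatic_filters(merged, germ, pon)
            res = compare_spectra(substitution_spectrum(kept),
                                  truth.set_index("sample")["smoking"])
            n_sig += int((res["q"] < 0.05).sum())
        # 36 class-level null tests at FDR 0.05: more than a couple of
        # rejections indicates miscalibration
        assert n_sig <= 2
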
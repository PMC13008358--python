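"""ΣFE aggregation, pseudocount FC, MISA/NASA rules, set overlap, filters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ac4c.models import (
    NasaCategory,
    Peak,
    TranscriptAcetylation,
    TranscriptModel,
)
from ac4c.stats import (
    classify_misa,
    classify_nasa,
    fold_change,
    overlap_sets,
    syn_reliability_filter,
    transcript_fe,
)


def acet(tid, n, fe):
    return TranscriptAcetylation(tid, n, fe)


def peak(tid, start, fe):
    return Peak(tid, start, start + 100, start + 50, 40, 10, fe, 1e-6, 1e-5)


MODELS = {
    f"tx{i}": TranscriptModel(f"tx{i}", f"g{i}", 100, 900, 400) for i in range(1, 6)
}


class TestTranscriptFE:
    def test_sums_member_fes(self):
        recs = transcript_fe([peak("tx1", 0, 3.0), peak("tx1", 500, 2.5)], MODELS)
        assert recs["tx1"].fe_sum == pytest.approx(5.5)
        assert recs["tx1"].n_peaks == 2

    def test_zero_record_for_peakless_transcripts(self):
        recs = transcript_fe([peak("tx1", 0, 3.0)], MODELS)
        assert recs["tx2"].fe_sum == 0.0
        assert recs["tx2"].n_peaks == 0
        assert set(recs) == set(MODELS)

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(
            st.tuples(st.integers(1, 5), st.floats(0.1, 50.0)),
            max_size=30,
        )
    )
    def test_matches_grouping_oracle(self, items):
        peaks = [
            peak(f"tx{tid}", 100 * j, fe) for j, (tid, fe) in enumerate(items)
        ]
        recs = transcript_fe(peaks, MODELS)
        oracle = {tid: 0.0 for tid in MODELS}
        for _, (tid, fe) in zip(peaks, items):
            oracle[f"tx{tid}"] += fe
        for tid in MODELS:
            assert recs[tid].fe_sum == pytest.approx(oracle[tid])


class TestFoldChange:
    def test_substitution(self):
        fc = fold_change({"t": acet("t", 1, 3.0)}, {"t": acet("t", 1, 1.0)})
        assert fc["t"].fc == pytest.approx(2.0)

    def test_double_zero_gives_one(self):
        fc = fold_change({}, {"t": acet("t", 0, 0.0)})
        assert fc["t"].fc == pytest.approx(1.0)

    def test_pseudocount_rescues_zero_denominator(self):
        fc = fold_change({"t": acet("t", 2, 5.0)}, {})
        assert fc["t"].fc == pytest.approx(6.0)

    def test_monotone_and_identity(self):
        base = {"t": acet("t", 1, 4.0)}
        assert fold_change(base, base)["t"].fc == pytest.approx(1.0)
        hi = fold_change({"t": acet("t", 1, 8.0)}, base)["t"].fc
        lo = fold_change({"t": acet("t", 1, 2.0)}, base)["t"].fc
        assert lo < 1.0 < hi


def fc_map(**kwargs):
    from ac4c.models import FoldChangeRecord

    out = {}
    for tid, (case, ref) in kwargs.items():
        out[tid] = FoldChangeRecord(tid, case, ref)
    return out


class TestClassifyMisa:
    def test_day6_specific_upregulation(self):
        d1 = fc_map(t=(0.5, 0.4))    # fc ~ 1.07
        d6 = fc_map(t=(6.0, 1.5))    # fc = 2.8
        d20 = fc_map(t=(0.2, 0.3))   # fc ~ 0.92
        calls = classify_misa(d1, d6, d20)
        assert calls["t"].is_misa

    def test_day1_elevation_violates_specificity(self):
        d1 = fc_map(t=(6.0, 1.5))
        d6 = fc_map(t=(6.0, 1.5))
        d20 = fc_map(t=(0.2, 0.3))
        assert not classify_misa(d1, d6, d20)["t"].is_misa

    def test_boundary_strictness(self):
        # day 6 exactly at cutoff is NOT misa (strict >); day 1 exactly at
        # the cutoff does not disqualify (non-strict <=)
        d6_at = fc_map(t=(3.0, 1.0))    # fc = 2.0 exactly
        ones = fc_map(t=(0.0, 0.0))
        assert not classify_misa(ones, d6_at, ones)["t"].is_misa
        d1_at = fc_map(t=(3.0, 1.0))
        d6_hi = fc_map(t=(9.0, 1.0))    # fc = 5
        assert classify_misa(d1_at, d6_hi, ones)["t"].is_misa

    def test_missing_day_defaults_to_no_change(self):
        d6 = fc_map(t=(6.0, 1.0))
        calls = classify_misa({}, d6, {})
        assert calls["t"].is_misa and calls["t"].fc_d1 == 1.0

    def test_strict_mode_excludes_incomplete(self):
        d6 = fc_map(t=(6.0, 1.0))
        assert classify_misa({}, d6, {}, strict=True) == {}


class TestClassifyNasa:
    def test_peak_lost_is_diminished(self):
        calls = classify_nasa({"t": acet("t", 2, 5.0)}, {"t": acet("t", 0, 0.0)})
        assert calls["t"].category is NasaCategory.DIMINISHED

    def test_low_fe_is_diminished(self):
        calls = classify_nasa({"t": acet("t", 1, 5.0)}, {"t": acet("t", 1, 0.5)})
        assert calls["t"].category is NasaCategory.DIMINISHED

    def test_attenuated_is_downregulated(self):
        calls = classify_nasa({"t": acet("t", 2, 9.0)}, {"t": acet("t", 1, 3.0)})
        assert calls["t"].category is NasaCategory.DOWNREGULATED

    def test_mild_change_is_unchanged(self):
        calls = classify_nasa({"t": acet("t", 1, 4.0)}, {"t": acet("t", 1, 3.5)})
        assert calls["t"].category is NasaCategory.UNCHANGED

    def test_not_acetylated_in_control(self):
        calls = classify_nasa({"t": acet("t", 0, 0.0)}, {"t": acet("t", 1, 3.0)})
        assert calls["t"].category is NasaCategory.NOT_ACETYLATED
        assert not calls["t"].is_nasa

    def test_categories_disjoint_exhaustive(self):
        rng = np.random.default_rng(0)
        ctrl, cko = {}, {}
        for i in range(200):
            tid = f"t{i}"
            fe_c = float(rng.choice([0.0, rng.uniform(0.1, 20)]))
            fe_k = float(rng.choice([0.0, rng.uniform(0.1, 20)]))
            ctrl[tid] = acet(tid, int(fe_c > 0), fe_c)
            cko[tid] = acet(tid, int(fe_k > 0), fe_k)
        calls = classify_nasa(ctrl, cko)
        assert set(calls) == set(ctrl)
        for tid, c in calls.items():
            if ctrl[tid].fe_sum > 0:
                assert c.category in (
                    NasaCategory.DIMINISHED,
                    NasaCategory.DOWNREGULATED,
                    NasaCategory.UNCHANGED,
                )
            else:
                assert c.category is NasaCategory.NOT_ACETYLATED


class TestOverlapAndFilter:
    def test_overlap_example(self):
        res = overlap_sets({"x", "y", "z"}, {"y", "z", "w"})
        assert res["n_intersection"] == 2
        assert res["n_a_only"] == 1 and res["n_b_only"] == 1
        assert res["n_intersection"] + res["n_a_only"] == res["n_a"]

    def test_identical_sets(self):
        res = overlap_sets({"a", "b"}, {"a", "b"})
        assert res["n_a_only"] == res["n_b_only"] == 0

    def test_syn_filter_requires_two_of_three(self):
        refs = [{"a", "b"}, {"a", "c"}, {"d"}]
        kept = syn_reliability_filter({"a", "b", "d", "e"}, refs)
        assert kept == {"a"}  # b: 1/3 refs; d: 1/3; e: 0/3

    def test_syn_filter_is_conjunction(self):
        refs = [{"a"}, {"a"}, {"a"}]
        assert syn_reliability_filter({"b"}, refs) == set()

    def test_syn_filter_needs_enough_references(self):
        with pytest.raises(ValueError):
            syn_reliability_filter({"a"}, [{"a"}], min_support=2)


class TestMisaRecovery:
    def test_sensitivity_degrades_toward_null(self):
        """Recovery falls monotonically as the day-6 effect shrinks to 1."""
        from ac4c.simulate import SimConfig
        from ac4c.workflow import RunConfig, run_full

        sens = []
        for eff in (1.0, 2.0, 3.0):
            rep = run_full(
                RunConfig(
                    sim=SimConfig(n_transcripts=300, misa_effect=eff, seed=11),
                    knockout=False,
                )
            )
            sens.append(rep["recovery"]["misa"]["sensitivity"])
        assert sens[0] <= sens[1] <= sens[2]
        assert sens[0] < 0.1 and sens[2] > 0.8
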
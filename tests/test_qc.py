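"""Sample/call QC filters, the merge rule, and the size comparison."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cnvassoc.qc import (
    DropReason,
    QcConfig,
    call_filter,
    flag_and_filter_segdup,
    iqr_upper_fence,
    merge_adjacent,
    post_cnv_sample_filter_A,
    post_cnv_sample_filter_B,
    pre_cnv_sample_filter,
    size_summary,
)
from cnvassoc.types import (
    Caller,
    CnvCall,
    CnvType,
    FLAG_SEGDUP,
    SampleRecord,
    Sex,
    Status,
    ValidationError,
)


def _sample(sid="S1", **kw):
    defaults = dict(
        status=Status.CASE,
        call_rate=0.99,
        reported_sex=Sex.FEMALE,
        computed_sex=Sex.FEMALE,
        lrr_sd=0.2,
        baf_median=0.5,
        baf_drift=0.001,
        waviness=0.01,
        n_cnv_A=30,
        n_cnv_B=100,
    )
    defaults.update(kw)
    return SampleRecord(sample_id=sid, **defaults)


def _call(start, end, sid="S1", cnv_type=CnvType.DUP, caller=Caller.A, n_markers=25,
          chrom="1", score=None, source=None, cn=None):
    if cn is None:
        cn = 3 if cnv_type is CnvType.DUP else 1
    return CnvCall(
        sample_id=sid, chrom=chrom, start=start, end=end, cnv_type=cnv_type,
        copy_number=cn, n_markers=n_markers, caller=caller, score=score, source=source,
    )


class TestPreFilter:
    def test_high_missingness_dropped(self):
        kept, dropped = pre_cnv_sample_filter([_sample(call_rate=0.94)])
        assert kept == [] and dropped[0][1] is DropReason.MISSINGNESS

    def test_sex_mismatch_dropped(self):
        kept, dropped = pre_cnv_sample_filter(
            [_sample(reported_sex=Sex.FEMALE, computed_sex=Sex.MALE)]
        )
        assert dropped[0][1] is DropReason.SEX_MISMATCH

    def test_duplicate_keeps_higher_call_rate(self):
        s1 = _sample("S1", call_rate=0.99, duplicate_group="d1")
        s2 = _sample("S2", call_rate=0.97, duplicate_group="d1")
        kept, dropped = pre_cnv_sample_filter([s1, s2])
        assert [s.sample_id for s in kept] == ["S1"]
        assert dropped[0][0].sample_id == "S2"
        assert dropped[0][1] is DropReason.DUPLICATE

    def test_missing_call_rate_is_error(self):
        with pytest.raises(ValidationError):
            pre_cnv_sample_filter([_sample(call_rate=None)])


class TestIqrFence:
    def test_interpolated_quartiles(self):
        # Q1=1.75, Q3=3.25 under linear interpolation -> 3.25 + 1.5*1.5 = 5.5
        assert iqr_upper_fence([1, 2, 3, 4], 1.5) == pytest.approx(5.5)

    def test_constant_vector(self):
        assert iqr_upper_fence([5, 5, 5, 5]) == pytest.approx(5.0)

    def test_too_few_values(self):
        with pytest.raises(ValidationError):
            iqr_upper_fence([1, 2, 3])

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(-1e6, 1e6), min_size=4, max_size=40),
        st.floats(-1e3, 1e3),
    )
    def test_translation_equivariance(self, values, shift):
        fence = iqr_upper_fence(values)
        shifted = iqr_upper_fence([v + shift for v in values])
        assert shifted == pytest.approx(fence + shift, abs=1e-6 + 1e-9 * abs(fence))


class TestPostFilters:
    def test_baf_median_out_of_band_dropped(self):
        cohort = [_sample(f"S{i}") for i in range(10)] + [_sample("BAD", baf_median=0.56)]
        kept, dropped = post_cnv_sample_filter_A(cohort)
        assert ("BAD", DropReason.BAF_MEDIAN) in [(s.sample_id, r) for s, r in dropped]

    def test_all_metrics_inside_bounds_kept(self):
        cohort = [_sample(f"S{i}") for i in range(10)]
        good = _sample("OK", baf_drift=0.004, waviness=0.03, baf_median=0.5)
        kept, _ = post_cnv_sample_filter_A(cohort + [good])
        assert "OK" in {s.sample_id for s in kept}

    def test_call_count_fence_applied(self):
        # cohort engineered so the count fence is 92: quartiles of [80..92]*k
        counts = [80, 84, 86, 88, 88, 90]  # Q1=84.5, Q3=88.5, fence = 94.5
        cohort = [_sample(f"S{i}", n_cnv_A=c) for i, c in enumerate(counts)]
        over = _sample("OVER", n_cnv_A=200)
        kept, dropped = post_cnv_sample_filter_A(cohort + [over])
        assert ("OVER", DropReason.CNV_COUNT_OUTLIER) in [
            (s.sample_id, r) for s, r in dropped
        ]

    def test_caller_b_threshold_strict(self):
        at = _sample("AT", n_cnv_B=633)
        over = _sample("OVER", n_cnv_B=634)
        kept, dropped = post_cnv_sample_filter_B([at, over], threshold=633)
        assert [s.sample_id for s in kept] == ["AT"]
        assert dropped[0][0].sample_id == "OVER"

    def test_caller_b_empty_list(self):
        assert post_cnv_sample_filter_B([], threshold=633) == ([], [])


class TestCallFilter:
    def test_marker_support_threshold(self):
        assert call_filter([_call(1, 100, n_markers=19)]) == []
        assert len(call_filter([_call(1, 100, n_markers=20)])) == 1

    def test_birdseye_lod_threshold(self):
        low = _call(1, 100, caller=Caller.B, score=9.9, source="birdseye")
        ok = _call(1, 100, caller=Caller.B, score=10.0, source="birdseye")
        assert call_filter([low, ok]) == [ok]

    def test_canary_confidence_threshold(self):
        good = _call(1, 100, caller=Caller.B, score=0.05, source="canary", n_markers=25)
        bad = _call(1, 100, caller=Caller.B, score=0.1, source="canary", n_markers=25)
        assert call_filter([good, bad]) == [good]

    def test_caller_b_without_source_is_error(self):
        with pytest.raises(ValidationError):
            call_filter([_call(1, 100, caller=Caller.B, score=20.0)])

    def test_output_subset_and_filters_commute(self):
        calls = [
            _call(1, 100, n_markers=19),
            _call(1, 100, n_markers=25),
            _call(1, 100, caller=Caller.B, score=5.0, source="birdseye"),
            _call(1, 100, caller=Caller.B, score=15.0, source="birdseye"),
        ]
        once = call_filter(calls)
        assert set(once) <= set(calls)
        assert call_filter(once) == once


class TestMergeAdjacent:
    def test_gap_below_threshold_merges(self):
        merged = merge_adjacent([_call(1, 100), _call(131, 230)])
        assert [(c.start, c.end) for c in merged] == [(1, 230)]
        assert merged[0].n_markers == 50

    def test_gap_exactly_at_threshold_does_not_merge(self):
        # gap 50 over span 250 = 0.20 exactly; the rule is strict
        merged = merge_adjacent([_call(1, 100), _call(151, 250)])
        assert len(merged) == 2

    def test_touching_calls_merge(self):
        merged = merge_adjacent([_call(100, 200), _call(201, 300)])
        assert [(c.start, c.end) for c in merged] == [(100, 300)]

    def test_merge_respects_type_and_sample(self):
        calls = [
            _call(1, 100, cnv_type=CnvType.DUP),
            _call(101, 200, cnv_type=CnvType.DEL),
            _call(101, 200, sid="S2"),
        ]
        assert len(merge_adjacent(calls)) == 3

    def test_deletion_merge_keeps_min_copy_number(self):
        merged = merge_adjacent(
            [_call(1, 100, cnv_type=CnvType.DEL, cn=0), _call(101, 200, cnv_type=CnvType.DEL, cn=1)]
        )
        assert merged[0].copy_number == 0


def _covered(calls):
    out = {}
    for c in calls:
        key = (c.sample_id, c.chrom, c.cnv_type, c.caller)
        out.setdefault(key, set()).update(range(c.start, c.end + 1))
    return out


def test_merge_randomized_idempotence_and_carrier_preservation():
    """Merging is idempotent and never changes which bases a sample carries
    (beyond filling sub-threshold gaps), over thousands of random call sets."""
    rng = np.random.default_rng(2024)
    for _ in range(10_000):
        n = int(rng.integers(1, 7))
        calls = []
        for _i in range(n):
            start = int(rng.integers(1, 400))
            end = start + int(rng.integers(0, 200))
            calls.append(_call(start, end, n_markers=int(rng.integers(1, 50))))
        once = merge_adjacent(calls)
        twice = merge_adjacent(once)
        assert [(c.start, c.end) for c in twice] == [(c.start, c.end) for c in once]
        # every input base remains covered; total marker support is conserved
        before = _covered(calls)
        after = _covered(once)
        for key, bases in before.items():
            assert bases <= after[key]
        assert sum(c.n_markers for c in once) == sum(c.n_markers for c in calls)
        # output within each group is sorted and non-overlapping
        by_group = {}
        for c in once:
            by_group.setdefault((c.sample_id, c.chrom, c.cnv_type, c.caller), []).append(c)
        for group in by_group.values():
            for left, right in zip(group, group[1:]):
                assert left.end < right.start


class TestSegdup:
    SEGDUP = {"1": [(1, 51)]}

    def test_majority_overlap_dropped_in_exclude_mode(self):
        out = flag_and_filter_segdup([_call(1, 100)], self.SEGDUP, 0.5, mode="exclude")
        assert out == []

    def test_exact_half_overlap_kept(self):
        out = flag_and_filter_segdup(
            [_call(2, 101)], self.SEGDUP, 0.5, mode="exclude"
        )  # overlap 50 of 100
        assert len(out) == 1

    def test_flag_mode_annotates_without_dropping(self):
        out = flag_and_filter_segdup([_call(40, 200), _call(300, 400)], self.SEGDUP)
        assert FLAG_SEGDUP in out[0].flags
        assert FLAG_SEGDUP not in out[1].flags


class TestSizeSummary:
    def _cohort(self):
        return [
            _sample("C1"),
            _sample("C2"),
            _sample("N1", status=Status.CONTROL),
            _sample("N2", status=Status.CONTROL),
        ]

    def test_separated_groups_exact_rank_p(self):
        # sizes {1,2,3} vs {4,5,6}: U = 0, exact two-tailed p = 2/C(6,3) = 0.1
        calls = [
            _call(1, 1, sid="C1"), _call(1, 2, sid="C1"), _call(1, 3, sid="C2"),
            _call(1, 4, sid="N1"), _call(1, 5, sid="N1"), _call(1, 6, sid="N2"),
        ]
        summary = size_summary(calls, self._cohort())
        assert summary.p_value == pytest.approx(0.1)
        assert summary.median_size_case == 2
        assert summary.median_size_control == 5

    def test_identical_distributions(self):
        calls = [
            _call(1, 10, sid="C1"), _call(1, 20, sid="C2"),
            _call(1, 10, sid="N1"), _call(1, 20, sid="N2"),
        ]
        summary = size_summary(calls, self._cohort())
        assert summary.median_size_case == summary.median_size_control
        assert summary.p_value == pytest.approx(1.0)

    def test_single_call_group_flagged(self):
        calls = [_call(1, 10, sid="C1"), _call(1, 10, sid="N1"), _call(1, 20, sid="N2")]
        summary = size_summary(calls, self._cohort())
        assert summary.p_value is None
        assert summary.note
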
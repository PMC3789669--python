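"""Rare-CNV filters and the permutation burden test."""

import itertools
import math

import numpy as np
import pytest

from cnvassoc.burden import (
    BurdenConfig,
    burden_statistics,
    case_specific_genes,
    pathway_burden,
    permutation_burden,
    rare_filter,
    stratified_burden,
)
from cnvassoc.types import (
    Caller,
    CnvCall,
    CnvType,
    GeneAnnotation,
    SampleRecord,
    Status,
    ValidationError,
)


def _call(sid, start, end, cnv_type=CnvType.DUP, chrom="1"):
    return CnvCall(
        sample_id=sid, chrom=chrom, start=start, end=end, cnv_type=cnv_type,
        n_markers=25, caller=Caller.A,
    )


def _cohort(n_case=4, n_control=4):
    return [SampleRecord(f"CA{i}", Status.CASE) for i in range(n_case)] + [
        SampleRecord(f"CO{i}", Status.CONTROL) for i in range(n_control)
    ]


def _background(samples, seed=1):
    """Heterogeneous per-sample rare calls at private loci, so the cohort
    outlier fences are non-degenerate (as in real CNV profiles)."""
    rng = np.random.default_rng(seed)
    calls = []
    locus = 0
    for s in samples:
        for _ in range(int(rng.poisson(3.0))):
            start = 1 + locus * 2_000_000
            locus += 1
            calls.append(
                _call(s.sample_id, start, start + int(rng.integers(110_000, 190_000)),
                      chrom="9")
            )
    return calls


class TestRareFilter:
    def test_short_call_removed(self):
        samples = _cohort(100, 100)
        short = _call("CA0", 1, 99_000)  # 99 kb
        long = _call("CA1", 1_000_000, 1_150_000)
        kept, _ = rare_filter(
            _background(samples) + [short, long], samples, {}, BurdenConfig()
        )
        assert long in kept and short not in kept

    def test_exactly_100kb_removed(self):
        samples = _cohort(100, 100)
        at = _call("CA0", 1, 100_000)  # length exactly 100,000
        kept, _ = rare_filter(_background(samples) + [at], samples, {}, BurdenConfig())
        assert at not in kept

    def test_common_locus_removed(self):
        # 2% of 100 samples carry near-identical calls at one locus
        samples = _cohort(50, 50)
        common = [_call(f"CA{i}", 1_000_000, 1_200_000) for i in range(2)]
        rare = _call("CA5", 3_000_000, 3_200_000)
        kept, _ = rare_filter(
            _background(samples) + common + [rare], samples, {}, BurdenConfig()
        )
        assert rare in kept
        assert not any(c in kept for c in common)

    def test_known_common_overlap_inclusive(self):
        samples = _cohort(100, 100)
        # exactly 50% of the call length inside the catalogue -> removed
        call = _call("CA0", 1_000_001, 1_200_000)  # 200 kb
        catalogue = {"1": [(1_000_001, 1_100_000)]}  # covers 100 kb of it
        kept, _ = rare_filter(
            _background(samples) + [call], samples, catalogue, BurdenConfig()
        )
        assert call not in kept
        catalogue = {"1": [(1_000_001, 1_099_999)]}  # 99,999 bp < 50%
        kept, _ = rare_filter(
            _background(samples) + [call], samples, catalogue, BurdenConfig()
        )
        assert call in kept

    def test_empty_catalogue_warns_and_skips(self):
        samples = _cohort(100, 100)
        call = _call("CA0", 1_000_000, 1_200_000)
        with pytest.warns(UserWarning):
            kept, _ = rare_filter(
                _background(samples) + [call], samples, None, BurdenConfig()
            )
        assert call in kept

    def test_outlier_sample_removed(self):
        samples = _cohort(100, 100)
        extras = [
            _call("CA0", 300_000_000 + i * 1_000_000, 300_150_000 + i * 1_000_000)
            for i in range(10)
        ]
        kept, kept_samples = rare_filter(
            _background(samples) + extras, samples, {}, BurdenConfig()
        )
        assert "CA0" not in {s.sample_id for s in kept_samples}
        assert all(c.sample_id != "CA0" for c in kept)

    def test_sub_filters_commute(self):
        """The kept set equals the intersection of per-criterion kept sets."""
        rng = np.random.default_rng(8)
        samples = _cohort(30, 30)
        calls = []
        for s in samples:
            for _ in range(rng.integers(0, 4)):
                start = int(rng.integers(1, 8_000_000))
                calls.append(_call(s.sample_id, start, start + int(rng.integers(50_000, 400_000))))
        catalogue = {"1": [(2_000_000, 2_500_000)]}
        cfg = BurdenConfig()
        kept_once, _ = rare_filter(calls, samples, catalogue, cfg)
        # applying the whole filter twice is a no-op
        kept_twice, _ = rare_filter(kept_once, samples, catalogue, cfg)
        large = [c for c in kept_once if c.length > cfg.min_length]
        assert set(map(id, kept_twice)) <= set(map(id, large))


class TestBurdenStatistics:
    GENES = [
        GeneAnnotation("G1", "1", 1_000_000, 1_050_000),
        GeneAnnotation("G2", "1", 1_100_000, 1_150_000),
        GeneAnnotation("G3", "1", 5_000_000, 5_050_000),
    ]

    def test_counts_and_distinct_genes(self):
        calls = [
            _call("CA0", 990_000, 1_120_000),  # spans G1 and G2
            _call("CA0", 4_990_000, 5_010_000),  # spans G3
        ]
        stats = burden_statistics(calls, _cohort(), self.GENES, pad=20_000)
        assert stats["CA0"] == (2, 3)

    def test_sample_without_calls_is_zero(self):
        stats = burden_statistics([], _cohort(), self.GENES)
        assert stats["CO0"] == (0, 0)

    def test_gene_counted_once_across_calls(self):
        calls = [
            _call("CA0", 1_000_000, 1_010_000),
            _call("CA0", 1_030_000, 1_049_000),
        ]
        stats = burden_statistics(calls, _cohort(), self.GENES, pad=0)
        assert stats["CA0"] == (2, 1)


class TestPermutation:
    def test_exhaustive_toy_p(self):
        # cases (2,2,2) vs controls (0,0,0): 1 of C(6,3)=20 assignments ties the max
        samples = _cohort(3, 3)
        stats = {"CA0": 2, "CA1": 2, "CA2": 2, "CO0": 0, "CO1": 0, "CO2": 0}
        res = permutation_burden(stats, samples, BurdenConfig(n_perm=10_000))
        assert res.exhaustive
        assert res.p_value == pytest.approx(1 / 20)

    def test_identical_vectors_p_at_least_half(self):
        samples = _cohort(3, 3)
        stats = {s.sample_id: 1.0 for s in samples}
        res = permutation_burden(stats, samples, BurdenConfig(n_perm=1000))
        assert res.p_value >= 0.5

    def test_single_class_rejected(self):
        samples = [SampleRecord("A", Status.CASE), SampleRecord("B", Status.CASE)]
        with pytest.raises(ValidationError):
            permutation_burden({"A": 1, "B": 2}, samples, BurdenConfig())

    def test_monte_carlo_agrees_with_exhaustive(self):
        """MC p within 3 binomial SEs of the exhaustive enumeration p."""
        rng = np.random.default_rng(55)
        samples = _cohort(5, 5)
        values = {s.sample_id: float(v) for s, v in zip(samples, rng.poisson(2, 10))}
        exact = permutation_burden(values, samples, BurdenConfig(n_perm=10**6))
        assert exact.exhaustive
        # C(16,8) = 12,870 > 10,000 permutations forces the Monte-Carlo path
        samples = _cohort(8, 8)
        values = {s.sample_id: float(v) for s, v in zip(samples, rng.poisson(2, 16))}
        exact = permutation_burden(values, samples, BurdenConfig(n_perm=10**6))
        mc = permutation_burden(values, samples, BurdenConfig(n_perm=10_000, seed=1))
        assert exact.exhaustive and not mc.exhaustive
        se = math.sqrt(exact.p_value * (1 - exact.p_value) / 10_000)
        assert abs(mc.p_value - exact.p_value) <= 3 * se + 1e-4

    def test_p_never_below_add_one_floor(self):
        samples = _cohort(10, 10)
        stats = {s.sample_id: (10.0 if s.status is Status.CASE else 0.0) for s in samples}
        res = permutation_burden(stats, samples, BurdenConfig(n_perm=999, seed=2))
        assert res.p_value >= 1 / 1000

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(3)
        samples = _cohort(8, 8)
        stats = {s.sample_id: float(v) for s, v in zip(samples, rng.poisson(2, 16))}
        r1 = permutation_burden(stats, samples, BurdenConfig(n_perm=2000, seed=9))
        r2 = permutation_burden(stats, samples, BurdenConfig(n_perm=2000, seed=9))
        assert r1.p_value == r2.p_value


class TestStrataAndPathways:
    GENES = [GeneAnnotation("G1", "1", 1_000_000, 1_050_000)]

    def test_strata_cover_types_and_bins(self):
        calls = [_call("CA0", 1, 150_000), _call("CO0", 1, 700_000, CnvType.DEL)]
        results = stratified_burden(calls, _cohort(), self.GENES, BurdenConfig(n_perm=99))
        strata = {r.stratum for r in results}
        assert "all" in strata
        assert "DUP:100-200kb" in strata and "DEL:500-1000kb" in strata
        assert len(results) == (1 + 8) * 2  # (all + 2 types x 4 bins) x 2 statistics

    def test_pathway_with_no_overlap_p_is_one(self):
        calls = [_call("CA0", 5_000_000, 5_200_000)]
        results = pathway_burden(
            calls, _cohort(), self.GENES, {"tgfb": ["G1"]}, BurdenConfig(n_perm=99)
        )
        assert all(r.p_value == 1.0 for r in results)
        assert all(r.case_mean == 0 for r in results)

    def test_planted_case_only_pathway_signal(self):
        calls = [_call(f"CA{i}", 1_000_000, 1_200_000) for i in range(4)]
        results = pathway_burden(
            calls, _cohort(4, 4), self.GENES, {"tgfb": ["G1"]}, BurdenConfig(n_perm=9999)
        )
        count_res = [r for r in results if r.statistic == "cnv_count"][0]
        assert count_res.p_value == pytest.approx(1 / math.comb(8, 4))

    def test_unresolvable_pathway_skipped_with_warning(self):
        with pytest.warns(UserWarning):
            results = pathway_burden([], _cohort(), self.GENES, {"empty": ["NOPE"]})
        assert results == []

    def test_seven_sets_in_seven_out(self):
        sets = {f"p{i}": ["G1"] for i in range(7)}
        results = pathway_burden([], _cohort(), self.GENES, sets, BurdenConfig(n_perm=19))
        assert len({r.stratum for r in results}) == 7


class TestCaseSpecific:
    GENES = [
        GeneAnnotation("G1", "1", 1_000_000, 1_050_000),
        GeneAnnotation("G2", "1", 3_000_000, 3_050_000),
    ]

    def test_two_case_zero_control_flagged(self):
        calls_a = [_call("CA0", 1_000_000, 1_040_000), _call("CA1", 1_000_000, 1_040_000)]
        calls_b = list(calls_a)
        out = case_specific_genes({"A": calls_a, "B": calls_b}, _cohort(), self.GENES)
        (hit,) = out
        assert hit.gene == "G1" and hit.two_plus_both_callers

    def test_control_carrier_excludes_gene(self):
        calls = [_call("CA0", 1_000_000, 1_040_000), _call("CO0", 1_000_000, 1_040_000)]
        out = case_specific_genes({"A": calls}, _cohort(), self.GENES)
        assert out == []

    def test_empty_calls_empty_list(self):
        assert case_specific_genes({"A": []}, _cohort(), self.GENES) == []
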
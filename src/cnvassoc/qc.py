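"""Pre- and post-calling quality control for samples and CNV calls.

Sample-level filters operate on array QC metrics carried in
:class:`~cnvassoc.types.SampleRecord` (genotyping call rate, sex
concordance, LRR standard deviation, BAF median/drift, waviness factor and
per-sample call counts); outlier fences are the classic Tukey upper fence
Q3 + k*IQR with linearly interpolated quartiles.  Call-level filters
enforce minimum marker support and caller-specific confidence thresholds,
and adjacent same-type calls artificially split by the HMM are re-joined
when the gap is small relative to the joint span.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import mannwhitneyu

from .types import (
    Caller,
    CnvCall,
    CnvType,
    FLAG_SEGDUP,
    SampleRecord,
    Status,
    ValidationError,
    group_calls,
)

__all__ = [
    "QcConfig",
    "DropReason",
    "pre_cnv_sample_filter",
    "iqr_upper_fence",
    "post_cnv_sample_filter_A",
    "post_cnv_sample_filter_B",
    "call_filter",
    "merge_adjacent",
    "flag_and_filter_segdup",
    "size_summary",
    "SizeSummary",
]


class DropReason(str, Enum):
    MISSINGNESS = "MISSINGNESS"
    SEX_MISMATCH = "SEX_MISMATCH"
    DUPLICATE = "DUPLICATE"
    LRR_SD_OUTLIER = "LRR_SD_OUTLIER"
    BAF_MEDIAN = "BAF_MEDIAN"
    BAF_DRIFT = "BAF_DRIFT"
    WAVINESS = "WAVINESS"
    CNV_COUNT_OUTLIER = "CNV_COUNT_OUTLIER"


@dataclass
class QcConfig:
    """Thresholds for sample- and call-level QC.

    Defaults follow common array-CNV practice: calls supported by >= 20
    markers; Birdseye LOD >= 10; Canary confidence < 0.1; BAF median within
    [0.45, 0.55]; BAF drift <= 0.005; |waviness| <= 0.04; Tukey fence
    multiplier 1.5; adjacent calls merged when the gap is < 20% of the
    joint span; samples dropped above 5% missing genotypes.  The realized
    per-cohort fences (e.g. a ">92 CNVs/sample" cutoff) are data-dependent
    outputs of these rules, not constants.
    """

    min_markers: int = 20
    min_lod: float = 10.0
    max_canary_conf: float = 0.1
    baf_median_lo: float = 0.45
    baf_median_hi: float = 0.55
    max_baf_drift: float = 0.005
    max_abs_waviness: float = 0.04
    iqr_multiplier: float = 1.5
    merge_gap_fraction: float = 0.20
    max_missing: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.merge_gap_fraction < 1:
            raise ValidationError("merge_gap_fraction must be in (0, 1)")
        for name in ("min_markers", "min_lod", "max_canary_conf", "iqr_multiplier"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


Dropped = list[tuple[SampleRecord, DropReason]]


def pre_cnv_sample_filter(
    samples: Sequence[SampleRecord], cfg: QcConfig | None = None
) -> tuple[list[SampleRecord], Dropped]:
    """Genotyping-stage sample QC.

    Drops samples with more than ``max_missing`` missing genotypes, with
    discordant reported vs computed sex, and the lower-call-rate member of
    each duplicate pair.
    """
    cfg = cfg or QcConfig()
    for s in samples:
        if s.call_rate is None:
            raise ValidationError(f"sample {s.sample_id}: call_rate missing")

    # duplicates: keep the highest call rate in each duplicate group
    dup_losers: set[str] = set()
    groups: dict[str, list[SampleRecord]] = {}
    for s in samples:
        if s.duplicate_group is not None:
            groups.setdefault(s.duplicate_group, []).append(s)
    for members in groups.values():
        if len(members) > 1:
            best = max(members, key=lambda s: s.call_rate)
            dup_losers.update(s.sample_id for s in members if s is not best)

    kept: list[SampleRecord] = []
    dropped: Dropped = []
    for s in samples:
        if s.call_rate < 1.0 - cfg.max_missing:
            dropped.append((s, DropReason.MISSINGNESS))
        elif (
            s.reported_sex is not None
            and s.computed_sex is not None
            and s.reported_sex is not s.computed_sex
        ):
            dropped.append((s, DropReason.SEX_MISMATCH))
        elif s.sample_id in dup_losers:
            dropped.append((s, DropReason.DUPLICATE))
        else:
            kept.append(s)
    return kept, dropped


def iqr_upper_fence(values: Sequence[float], k: float = 1.5) -> float:
    """Tukey upper outlier fence Q3 + k * (Q3 - Q1).

    Quartiles use linear interpolation (numpy's default, R type 7).
    """
    if len(values) < 4:
        raise ValidationError("need >= 4 values to estimate quartiles")
    q1, q3 = np.percentile(np.asarray(values, dtype=float), [25, 75])
    return float(q3 + k * (q3 - q1))


def post_cnv_sample_filter_A(
    samples: Sequence[SampleRecord], cfg: QcConfig | None = None
) -> tuple[list[SampleRecord], Dropped]:
    """Post-calling sample QC for the caller-A (HMM/LRR-BAF) call set.

    Drops cohort outliers on LRR standard deviation and per-sample call
    count (upper IQR fence, computed jointly on the provided cohort), and
    samples with BAF median outside the configured band, excess BAF drift,
    or excess |waviness|.
    """
    cfg = cfg or QcConfig()
    if not samples:
        raise ValidationError("empty cohort")
    lrr_fence = iqr_upper_fence([s.lrr_sd for s in samples], cfg.iqr_multiplier)
    count_fence = iqr_upper_fence([s.n_cnv_A for s in samples], cfg.iqr_multiplier)
    kept: list[SampleRecord] = []
    dropped: Dropped = []
    for s in samples:
        if s.lrr_sd > lrr_fence:
            dropped.append((s, DropReason.LRR_SD_OUTLIER))
        elif not cfg.baf_median_lo <= s.baf_median <= cfg.baf_median_hi:
            dropped.append((s, DropReason.BAF_MEDIAN))
        elif s.baf_drift > cfg.max_baf_drift:
            dropped.append((s, DropReason.BAF_DRIFT))
        elif abs(s.waviness) > cfg.max_abs_waviness:
            dropped.append((s, DropReason.WAVINESS))
        elif s.n_cnv_A > count_fence:
            dropped.append((s, DropReason.CNV_COUNT_OUTLIER))
        else:
            kept.append(s)
    return kept, dropped


def post_cnv_sample_filter_B(
    samples: Sequence[SampleRecord],
    threshold: float | None = None,
    cfg: QcConfig | None = None,
) -> tuple[list[SampleRecord], Dropped]:
    """Drop samples with an excess caller-B call count (strictly above threshold).

    When ``threshold`` is None it is derived as the cohort upper IQR fence.
    """
    cfg = cfg or QcConfig()
    if not samples:
        return [], []
    if threshold is None:
        threshold = iqr_upper_fence([s.n_cnv_B for s in samples], cfg.iqr_multiplier)
    kept, dropped = [], []
    for s in samples:
        if s.n_cnv_B > threshold:
            dropped.append((s, DropReason.CNV_COUNT_OUTLIER))
        else:
            kept.append(s)
    return kept, dropped


def call_filter(calls: Iterable[CnvCall], cfg: QcConfig | None = None) -> list[CnvCall]:
    """Marker-support and confidence filter for calls.

    All calls need ``n_markers >= min_markers``.  Caller-B calls also need
    LOD >= ``min_lod`` (birdseye source) or confidence < ``max_canary_conf``
    (canary source); a caller-B call without a source annotation is invalid.
    """
    cfg = cfg or QcConfig()
    kept: list[CnvCall] = []
    for c in calls:
        if c.caller is Caller.B and c.source is None:
            raise ValidationError(
                f"caller-B call {c.sample_id} {c.chrom}:{c.start} lacks a source tag"
            )
        if c.n_markers < cfg.min_markers:
            continue
        if c.caller is Caller.B:
            if c.source == "birdseye" and not c.score >= cfg.min_lod:
                continue
            if c.source == "canary" and not c.score < cfg.max_canary_conf:
                continue
        kept.append(c)
    return kept


def _merge_pair(left: CnvCall, right: CnvCall) -> CnvCall:
    # copy number of a merged call keeps the carrier-consistent extreme:
    # min for deletions, max for duplications
    cns = [cn for cn in (left.copy_number, right.copy_number) if cn is not None]
    cn = None
    if cns:
        cn = min(cns) if left.cnv_type is CnvType.DEL else max(cns)
    scores = [s for s in (left.score, right.score) if s is not None]
    return replace(
        left,
        end=max(left.end, right.end),
        copy_number=cn,
        n_markers=left.n_markers + right.n_markers,
        score=max(scores) if scores else None,
        flags=left.flags | right.flags,
    )


def merge_adjacent(
    calls: Iterable[CnvCall], gap_fraction: float = 0.20
) -> list[CnvCall]:
    """Re-join same-type calls artificially split by the calling HMM.

    Within each (sample, chromosome, type, caller) group, two neighbouring
    calls are combined when the gap between them is strictly less than
    ``gap_fraction`` of the total span of both calls including the gap.
    Overlapping calls have gap 0 and always merge.  The pass is repeated
    until no merge applies, so the operation is idempotent; output groups
    are sorted and non-overlapping.
    """
    out: list[CnvCall] = []
    for group in group_calls(calls).values():
        merged = list(group)
        changed = True
        while changed:
            changed = False
            result: list[CnvCall] = []
            for call in merged:
                if not result:
                    result.append(call)
                    continue
                prev = result[-1]
                gap = call.start - prev.end - 1
                span = max(prev.end, call.end) - prev.start + 1
                if gap <= 0 or gap / span < gap_fraction:
                    result[-1] = _merge_pair(prev, call)
                    changed = True
                else:
                    result.append(call)
            merged = result
        out.extend(merged)
    out.sort(key=lambda c: (c.chrom, c.start, c.end, c.sample_id))
    return out


def _merged_intervals(
    intervals: Iterable[tuple[int, int]]
) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def flag_and_filter_segdup(
    calls: Iterable[CnvCall],
    segdup_intervals: Mapping[str, Sequence[tuple[int, int]]],
    max_overlap_fraction: float = 0.5,
    mode: str = "flag",
) -> list[CnvCall]:
    """Annotate or exclude calls overlapping segmental duplications.

    ``mode='flag'`` adds the SEGDUP flag to any call with >= 1 bp of
    overlap; ``mode='exclude'`` drops calls whose summed overlap exceeds
    ``max_overlap_fraction`` of the call length (strict >, one-way: the
    fraction is of the CNV's own length).
    """
    if mode not in ("flag", "exclude"):
        raise ValidationError(f"unknown segdup mode {mode!r}")
    merged_by_chrom = {
        chrom: _merged_intervals(ivals) for chrom, ivals in segdup_intervals.items()
    }
    out: list[CnvCall] = []
    for c in calls:
        overlap = 0
        for start, end in merged_by_chrom.get(c.chrom, []):
            lo = max(c.start, start)
            hi = min(c.end, end)
            if lo <= hi:
                overlap += hi - lo + 1
        if mode == "flag":
            out.append(
                replace(c, flags=c.flags | {FLAG_SEGDUP}) if overlap > 0 else c
            )
        else:
            if not overlap / c.length > max_overlap_fraction:
                out.append(c)
    return out


@dataclass
class SizeSummary:
    median_size_case: float
    median_size_control: float
    mean_calls_per_case: float
    mean_calls_per_control: float
    p_value: float | None
    note: str = ""


def size_summary(
    calls: Sequence[CnvCall], samples: Sequence[SampleRecord]
) -> SizeSummary:
    """Case/control CNV size comparison.

    Reports per-status median call size, mean calls per sample, and a
    two-tailed Mann-Whitney U p-value on call sizes (exact for small
    untied samples, normal approximation with tie correction otherwise).
    """
    status = {s.sample_id: s.status for s in samples}
    n_case = sum(1 for s in samples if s.status is Status.CASE)
    n_control = len(samples) - n_case
    case_sizes = [c.length for c in calls if status.get(c.sample_id) is Status.CASE]
    control_sizes = [
        c.length for c in calls if status.get(c.sample_id) is Status.CONTROL
    ]
    if len(case_sizes) < 2 or len(control_sizes) < 2:
        return SizeSummary(
            median_size_case=float(np.median(case_sizes)) if case_sizes else float("nan"),
            median_size_control=(
                float(np.median(control_sizes)) if control_sizes else float("nan")
            ),
            mean_calls_per_case=len(case_sizes) / n_case if n_case else float("nan"),
            mean_calls_per_control=(
                len(control_sizes) / n_control if n_control else float("nan")
            ),
            p_value=None,
            note="a group has < 2 calls; rank test undefined",
        )
    p = float(
        mannwhitneyu(case_sizes, control_sizes, alternative="two-sided").pvalue
    )
    return SizeSummary(
        median_size_case=float(np.median(case_sizes)),
        median_size_control=float(np.median(control_sizes)),
        mean_calls_per_case=len(case_sizes) / n_case,
        mean_calls_per_control=len(control_sizes) / n_control,
        p_value=p,
    )
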
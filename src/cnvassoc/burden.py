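"""Rare large-CNV filtering and permutation burden testing.

The rare-CNV analysis restricts to large (>100 kb by default) caller-A
calls, removes per-sample outliers and common variation, and compares
per-individual burden (call count, or distinct genes spanned) between
cases and controls with a one-sided label-permutation test, optionally
stratified by CNV type and size bin or restricted to candidate-pathway
gene sets.

Carrier frequency for the common-variant exclusion is computed by
single-linkage clustering of calls with >= 50% reciprocal overlap into
loci; the locus frequency is the fraction of all samples carrying a call
in the cluster.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genes import DEFAULT_PAD, gene_window
from .qc import iqr_upper_fence
from .types import (
    CnvCall,
    CnvType,
    GeneAnnotation,
    SampleRecord,
    Status,
    ValidationError,
)

__all__ = [
    "BurdenConfig",
    "BurdenResult",
    "rare_filter",
    "burden_statistics",
    "permutation_burden",
    "stratified_burden",
    "pathway_burden",
    "case_specific_genes",
]

DEFAULT_SIZE_BINS = (
    (100_000, 200_000),
    (200_000, 500_000),
    (500_000, 1_000_000),
    (1_000_000, None),
)


@dataclass
class BurdenConfig:
    """Rare-CNV filter thresholds and permutation settings.

    ``size_bins`` are (lo, hi] intervals in bp with ``hi=None`` meaning
    unbounded; the defaults stratify at 100-200 kb, 200-500 kb,
    500-1000 kb and >1 Mb.
    """

    min_length: int = 100_000
    max_freq: float = 0.01
    known_common_overlap: float = 0.50
    reciprocal_overlap: float = 0.50
    iqr_multiplier: float = 1.5
    size_bins: tuple = DEFAULT_SIZE_BINS
    n_perm: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValidationError("n_perm must be >= 1")
        prev_hi = 0
        for lo, hi in self.size_bins:
            if lo < prev_hi:
                raise ValidationError("size bins must be ordered and disjoint")
            prev_hi = math.inf if hi is None else hi


def _reciprocal_overlap(x: CnvCall, y: CnvCall) -> float:
    lo, hi = max(x.start, y.start), min(x.end, y.end)
    if lo > hi:
        return 0.0
    ov = hi - lo + 1
    return min(ov / x.length, ov / y.length)


def _cluster_loci(calls: Sequence[CnvCall], threshold: float) -> list[list[CnvCall]]:
    """Single-linkage clusters of same-chrom, same-type calls by reciprocal overlap."""
    clusters: list[list[CnvCall]] = []
    by_group: dict[tuple[str, CnvType], list[CnvCall]] = {}
    for c in calls:
        by_group.setdefault((c.chrom, c.cnv_type), []).append(c)
    for group in by_group.values():
        group = sorted(group, key=lambda c: (c.start, c.end))
        open_clusters: list[list[CnvCall]] = []
        for c in group:
            linked = [
                cl
                for cl in open_clusters
                if any(_reciprocal_overlap(c, other) >= threshold for other in cl)
            ]
            if not linked:
                open_clusters.append([c])
            else:
                merged = [c]
                for cl in linked:
                    merged.extend(cl)
                    open_clusters.remove(cl)
                open_clusters.append(merged)
        clusters.extend(open_clusters)
    return clusters


def rare_filter(
    calls: Sequence[CnvCall],
    samples: Sequence[SampleRecord],
    known_common: Mapping[str, Sequence[tuple[int, int]]] | None,
    cfg: BurdenConfig | None = None,
) -> tuple[list[CnvCall], list[SampleRecord]]:
    """Restrict to rare large CNVs and non-outlier individuals.

    Exclusion criteria are each evaluated on a fixed basis and applied
    jointly, so their order is immaterial: (1) samples above the cohort
    upper IQR fence on total per-sample call count or total kb span
    (computed over the full input call set, not just the large calls) are
    removed; (2) large calls (length strictly > ``min_length``) at loci
    carried by more than ``max_freq`` of all samples (single-linkage
    reciprocal-overlap clusters) are removed; (3) large calls with
    >= ``known_common_overlap`` of their length inside the known
    common-CNV catalogue are removed.
    """
    cfg = cfg or BurdenConfig()
    large = [c for c in calls if c.length > cfg.min_length]

    # criterion 1: per-sample outliers on total CNV count / total kb span
    counts = {s.sample_id: 0 for s in samples}
    spans = {s.sample_id: 0.0 for s in samples}
    for c in calls:
        if c.sample_id in counts:
            counts[c.sample_id] += 1
            spans[c.sample_id] += c.length / 1000.0
    outliers: set[str] = set()
    if len(samples) >= 4:
        count_fence = iqr_upper_fence(list(counts.values()), cfg.iqr_multiplier)
        span_fence = iqr_upper_fence(list(spans.values()), cfg.iqr_multiplier)
        outliers = {
            sid
            for sid in counts
            if counts[sid] > count_fence or spans[sid] > span_fence
        }

    # criterion 2: common loci by carrier frequency over the whole sample
    n_total = len(samples)
    common_calls: set[int] = set()
    for cluster in _cluster_loci(large, cfg.reciprocal_overlap):
        freq = len({c.sample_id for c in cluster}) / n_total
        if freq > cfg.max_freq:
            common_calls.update(id(c) for c in cluster)

    # criterion 3: overlap with the known common-CNV catalogue
    known_hits: set[int] = set()
    if known_common:
        for c in large:
            overlap = 0
            for start, end in known_common.get(c.chrom, []):
                lo, hi = max(c.start, start), min(c.end, end)
                if lo <= hi:
                    overlap += hi - lo + 1
            if overlap / c.length >= cfg.known_common_overlap:
                known_hits.add(id(c))
    else:
        warnings.warn("no known-common CNV list supplied; skipping that filter")

    kept_samples = [s for s in samples if s.sample_id not in outliers]
    kept_ids = {s.sample_id for s in kept_samples}
    kept_calls = [
        c
        for c in large
        if c.sample_id in kept_ids
        and id(c) not in common_calls
        and id(c) not in known_hits
    ]
    return kept_calls, kept_samples


def burden_statistics(
    calls: Iterable[CnvCall],
    samples: Sequence[SampleRecord],
    genes: Sequence[GeneAnnotation],
    pad: int = DEFAULT_PAD,
) -> dict[str, tuple[int, int]]:
    """Per-sample (CNV count, distinct genes spanned) over padded windows."""
    per_sample_calls: dict[str, list[CnvCall]] = {s.sample_id: [] for s in samples}
    for c in calls:
        if c.sample_id in per_sample_calls:
            per_sample_calls[c.sample_id].append(c)
    windows = [(g.key, g.chrom, *gene_window(g, pad)) for g in genes]
    out: dict[str, tuple[int, int]] = {}
    for sid, cs in per_sample_calls.items():
        spanned = {
            key
            for (key, chrom, lo, hi) in windows
            for c in cs
            if c.chrom == chrom and c.start <= hi and lo <= c.end
        }
        out[sid] = (len(cs), len(spanned))
    return out


@dataclass
class BurdenResult:
    stratum: str
    statistic: str
    case_mean: float
    control_mean: float
    p_value: float
    n_perm: int
    exhaustive: bool
    seed: int | None = None


def permutation_burden(
    stats: Mapping[str, float],
    samples: Sequence[SampleRecord],
    cfg: BurdenConfig | None = None,
    stratum: str = "all",
    statistic: str = "cnv_count",
) -> BurdenResult:
    """One-sided permutation test of case excess in mean per-sample burden.

    The observed statistic is mean(cases) - mean(controls).  Case/control
    labels are permuted ``n_perm`` times with the configured seed and the
    empirical p-value is (1 + #{permuted >= observed}) / (n_perm + 1).
    When the number of distinct label assignments C(n, n_cases) does not
    exceed ``n_perm``, the test enumerates all assignments exactly instead
    (no add-one correction needed: the observed assignment is in the
    enumeration).
    """
    cfg = cfg or BurdenConfig()
    values = np.array([float(stats.get(s.sample_id, 0.0)) for s in samples])
    labels = np.array([s.status is Status.CASE for s in samples])
    n_case = int(labels.sum())
    n_control = len(samples) - n_case
    if n_case == 0 or n_control == 0:
        raise ValidationError("need at least one case and one control")
    observed = values[labels].mean() - values[~labels].mean()

    n = len(values)
    total = math.comb(n, n_case)
    if total <= cfg.n_perm:
        count = 0
        for idx in combinations(range(n), n_case):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx)] = True
            stat = values[mask].mean() - values[~mask].mean()
            if stat >= observed - 1e-12:
                count += 1
        return BurdenResult(
            stratum,
            statistic,
            float(values[labels].mean()),
            float(values[~labels].mean()),
            count / total,
            total,
            exhaustive=True,
        )

    rng = np.random.default_rng(cfg.seed)
    count = 0
    chunk = 2000
    done = 0
    scale = 1.0 / n_case + 1.0 / n_control  # mean diff from case-sum via totals
    total_sum = values.sum()
    while done < cfg.n_perm:
        b = min(chunk, cfg.n_perm - done)
        perm = np.argsort(rng.random((b, n)), axis=1)[:, :n_case]
        case_sums = values[perm].sum(axis=1)
        stats_perm = case_sums * scale - total_sum / n_control
        count += int((stats_perm >= observed - 1e-12).sum())
        done += b
    p = (1 + count) / (cfg.n_perm + 1)
    return BurdenResult(
        stratum,
        statistic,
        float(values[labels].mean()),
        float(values[~labels].mean()),
        p,
        cfg.n_perm,
        exhaustive=False,
        seed=cfg.seed,
    )


def _in_bin(length: int, lo: int, hi: int | None) -> bool:
    return length > lo and (hi is None or length <= hi)


def stratified_burden(
    calls: Sequence[CnvCall],
    samples: Sequence[SampleRecord],
    genes: Sequence[GeneAnnotation],
    cfg: BurdenConfig | None = None,
    pad: int = DEFAULT_PAD,
) -> list[BurdenResult]:
    """Burden tests overall and per (type, size-bin) stratum, both statistics."""
    cfg = cfg or BurdenConfig()
    results: list[BurdenResult] = []
    strata: list[tuple[str, list[CnvCall]]] = [("all", list(calls))]
    for cnv_type in (CnvType.DEL, CnvType.DUP):
        for lo, hi in cfg.size_bins:
            label = f"{cnv_type.value}:{lo // 1000}-{'' if hi is None else hi // 1000}kb"
            subset = [
                c
                for c in calls
                if c.cnv_type is cnv_type and _in_bin(c.length, lo, hi)
            ]
            strata.append((label, subset))
    for label, subset in strata:
        stats = burden_statistics(subset, samples, genes, pad)
        for name, idx in (("cnv_count", 0), ("genes_spanned", 1)):
            values = {sid: float(v[idx]) for sid, v in stats.items()}
            results.append(
                permutation_burden(values, samples, cfg, stratum=label, statistic=name)
            )
    return results


def pathway_burden(
    calls: Sequence[CnvCall],
    samples: Sequence[SampleRecord],
    genes: Sequence[GeneAnnotation],
    gene_sets: Mapping[str, Sequence[str]],
    cfg: BurdenConfig | None = None,
    pad: int = DEFAULT_PAD,
) -> list[BurdenResult]:
    """Burden tests restricted to calls hitting each named pathway's genes."""
    cfg = cfg or BurdenConfig()
    by_symbol: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        by_symbol.setdefault(g.gene, []).append(g)
    results: list[BurdenResult] = []
    for name, symbols in gene_sets.items():
        members = [g for sym in symbols for g in by_symbol.get(sym, [])]
        if not members:
            warnings.warn(f"pathway {name!r}: no genes resolved; skipped")
            continue
        windows = [(g.chrom, *gene_window(g, pad)) for g in members]
        subset = [
            c
            for c in calls
            if any(c.chrom == chrom and c.start <= hi and lo <= c.end
                   for chrom, lo, hi in windows)
        ]
        stats = burden_statistics(subset, samples, members, pad)
        for stat_name, idx in (("cnv_count", 0), ("genes_spanned", 1)):
            values = {sid: float(v[idx]) for sid, v in stats.items()}
            results.append(
                permutation_burden(
                    values, samples, cfg, stratum=name, statistic=stat_name
                )
            )
    return results


@dataclass
class CaseSpecificGene:
    gene: str
    chrom: str
    start: int
    end: int
    case_carriers: dict[str, int]  # per caller value ("A"/"B") -> count
    two_plus_both_callers: bool


def case_specific_genes(
    calls_by_caller: Mapping[str, Sequence[CnvCall]],
    samples: Sequence[SampleRecord],
    genes: Sequence[GeneAnnotation],
    pad: int = DEFAULT_PAD,
    primary: str = "A",
) -> list[CaseSpecificGene]:
    """Genes hit by >= 1 case and no controls in the primary call set.

    Each result carries per-caller case-carrier counts and a flag marking
    genes with >= 2 case carriers and zero control carriers in every
    caller's call set (the replication-candidate criterion).
    """
    status = {s.sample_id: s.status for s in samples}
    per_caller: dict[str, dict[tuple, tuple[int, int]]] = {}
    for caller, calls in calls_by_caller.items():
        counts: dict[tuple, tuple[int, int]] = {}
        by_chrom: dict[str, list[CnvCall]] = {}
        for c in calls:
            by_chrom.setdefault(c.chrom, []).append(c)
        for g in genes:
            lo, hi = gene_window(g, pad)
            ids = {
                c.sample_id
                for c in by_chrom.get(g.chrom, [])
                if c.start <= hi and lo <= c.end
            }
            n_case = sum(1 for sid in ids if status.get(sid) is Status.CASE)
            n_control = sum(1 for sid in ids if status.get(sid) is Status.CONTROL)
            counts[g.key] = (n_case, n_control)
        per_caller[caller] = counts

    out: list[CaseSpecificGene] = []
    primary_counts = per_caller.get(primary, {})
    for g in genes:
        n_case, n_control = primary_counts.get(g.key, (0, 0))
        if n_case >= 1 and n_control == 0:
            two_plus = all(
                counts.get(g.key, (0, 0))[0] >= 2 and counts.get(g.key, (0, 0))[1] == 0
                for counts in per_caller.values()
            )
            out.append(
                CaseSpecificGene(
                    gene=g.gene,
                    chrom=g.chrom,
                    start=g.start,
                    end=g.end,
                    case_carriers={
                        caller: counts.get(g.key, (0, 0))[0]
                        for caller, counts in per_caller.items()
                    },
                    two_plus_both_callers=two_plus,
                )
            )
    return out
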
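"""Segment-based genome scan for case-enriched copy-number regions.

Each array marker covered by at least one QC-passing call of a given type
(duplication or deletion) is tested for case enrichment with a one-sided
Fisher exact test; the Bonferroni denominator for a (type, caller) stratum
is the number of markers actually covered by calls of that type from that
caller, so the multiple-testing burden is data-dependent and differs
between duplications and deletions and between callers.  Maximal runs of
adjacent significant markers form candidate CNV regions (CNVRs); regions
found independently significant by both callers are merged into consensus
CNVRs spanning the union of the per-caller spans.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .stats import fisher_one_sided, odds_ratio_cmle
from .types import (
    Caller,
    CnvCall,
    CnvType,
    ContingencyTable,
    GeneAnnotation,
    MarkerMap,
    SampleRecord,
    Status,
    ValidationError,
)

__all__ = [
    "CarrierMatrix",
    "MarkerResult",
    "CnvRegion",
    "build_carrier_matrix",
    "scan_markers",
    "regions_from_markers",
    "consensus_union",
    "region_concordance",
    "region_carriers",
]


@dataclass
class CarrierMatrix:
    """Per-marker carrier sets, stratified by CNV type and caller.

    ``carriers[(cnv_type, caller)][chrom][marker_index]`` is the set of
    sample ids with >= 1 filtered call of that type covering the marker.
    Markers covered by no call are absent; the number present defines the
    multiple-testing burden m for that stratum.
    """

    markers: MarkerMap
    carriers: dict[tuple[CnvType, Caller], dict[str, dict[int, set[str]]]]
    n_cases: dict[Caller, int]
    n_controls: dict[Caller, int]
    status: dict[str, Status]

    def n_tests(self, cnv_type: CnvType, caller: Caller) -> int:
        per_chrom = self.carriers.get((cnv_type, caller), {})
        return sum(len(d) for d in per_chrom.values())


def build_carrier_matrix(
    calls: Iterable[CnvCall],
    samples_by_caller: Mapping[Caller, Sequence[SampleRecord]],
    markers: MarkerMap,
) -> CarrierMatrix:
    """Project QC-filtered, merged calls onto the marker map.

    ``samples_by_caller`` gives the post-QC cohort per caller; calls from
    samples outside that cohort are ignored, and the cohort sizes become
    the per-caller test denominators.
    """
    if markers.n_markers() == 0:
        raise ValidationError("marker map is empty")
    allowed = {
        caller: {s.sample_id for s in ss} for caller, ss in samples_by_caller.items()
    }
    status: dict[str, Status] = {}
    for ss in samples_by_caller.values():
        for s in ss:
            status[s.sample_id] = s.status
    carriers: dict[tuple[CnvType, Caller], dict[str, dict[int, set[str]]]] = {}
    for c in calls:
        if c.sample_id not in allowed.get(c.caller, set()):
            continue
        stratum = carriers.setdefault((c.cnv_type, c.caller), {})
        per_chrom = stratum.setdefault(c.chrom, {})
        for idx in markers.index_range(c.chrom, c.start, c.end):
            per_chrom.setdefault(idx, set()).add(c.sample_id)
    n_cases = {
        caller: sum(1 for s in ss if s.status is Status.CASE)
        for caller, ss in samples_by_caller.items()
    }
    n_controls = {
        caller: sum(1 for s in ss if s.status is Status.CONTROL)
        for caller, ss in samples_by_caller.items()
    }
    return CarrierMatrix(markers, carriers, n_cases, n_controls, status)


@dataclass(frozen=True)
class MarkerResult:
    chrom: str
    index: int
    pos: int
    cnv_type: CnvType
    caller: Caller
    case_carriers: int
    control_carriers: int
    p_value: float
    significant: bool


def scan_markers(matrix: CarrierMatrix, alpha: float = 0.05) -> list[MarkerResult]:
    """One-sided Fisher test at every covered marker.

    A marker is significant when p <= alpha / m, with m the number of
    covered markers in its own (type, caller) stratum.  Identical carrier
    counts share a cached p-value.
    """
    results: list[MarkerResult] = []
    for (cnv_type, caller), per_chrom in sorted(
        matrix.carriers.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value)
    ):
        n_case = matrix.n_cases[caller]
        n_control = matrix.n_controls[caller]
        if n_case == 0 or n_control == 0:
            raise ValidationError(f"caller {caller.value}: empty case or control cohort")
        m = matrix.n_tests(cnv_type, caller)
        threshold = alpha / m
        cache: dict[tuple[int, int], float] = {}
        for chrom in sorted(per_chrom):
            positions = matrix.markers.positions(chrom)
            for idx in sorted(per_chrom[chrom]):
                carrier_set = per_chrom[chrom][idx]
                a = sum(
                    1 for sid in carrier_set if matrix.status[sid] is Status.CASE
                )
                c = len(carrier_set) - a
                key = (a, c)
                if key not in cache:
                    cache[key] = fisher_one_sided(
                        ContingencyTable.from_carriers(a, n_case, c, n_control)
                    )
                p = cache[key]
                results.append(
                    MarkerResult(
                        chrom=chrom,
                        index=idx,
                        pos=positions[idx],
                        cnv_type=cnv_type,
                        caller=caller,
                        case_carriers=a,
                        control_carriers=c,
                        p_value=p,
                        significant=p <= threshold,
                    )
                )
    return results


@dataclass
class CnvRegion:
    """A case-enriched genomic interval aggregated from significant markers."""

    chrom: str
    start: int
    end: int
    cnv_type: CnvType
    case_carriers: int
    control_carriers: int
    n_cases: int
    n_controls: int
    p_value: float
    odds_ratio: float
    callers: frozenset[Caller]
    carrier_ids: frozenset[str] = frozenset()
    caller_spans: dict[Caller, tuple[int, int]] = field(default_factory=dict)
    caller_stats: dict[Caller, tuple[int, int, float, float]] = field(
        default_factory=dict
    )
    genes: list[str] = field(default_factory=list)
    concordance: float | None = None

    @property
    def table(self) -> ContingencyTable:
        return ContingencyTable.from_carriers(
            self.case_carriers, self.n_cases, self.control_carriers, self.n_controls
        )


def regions_from_markers(
    marker_results: Sequence[MarkerResult], matrix: CarrierMatrix
) -> list[CnvRegion]:
    """Collapse maximal runs of adjacent significant markers into regions.

    "Adjacent" means consecutive in the marker map (same chromosome, type
    and caller) regardless of base-pair gap.  Region carriers are the union
    of carriers over the run's markers (a sample counts once however many
    markers it covers); boundaries are the first/last marker positions.
    """
    runs: dict[tuple[CnvType, Caller, str], list[list[MarkerResult]]] = {}
    for r in sorted(
        (r for r in marker_results if r.significant),
        key=lambda r: (r.cnv_type.value, r.caller.value, r.chrom, r.index),
    ):
        key = (r.cnv_type, r.caller, r.chrom)
        chrom_runs = runs.setdefault(key, [])
        if chrom_runs and chrom_runs[-1][-1].index == r.index - 1:
            chrom_runs[-1].append(r)
        else:
            chrom_runs.append([r])

    regions: list[CnvRegion] = []
    for (cnv_type, caller, chrom), chrom_runs in runs.items():
        per_chrom = matrix.carriers[(cnv_type, caller)][chrom]
        n_case = matrix.n_cases[caller]
        n_control = matrix.n_controls[caller]
        for run in chrom_runs:
            carrier_ids: set[str] = set()
            for r in run:
                carrier_ids |= per_chrom[r.index]
            a = sum(1 for sid in carrier_ids if matrix.status[sid] is Status.CASE)
            c = len(carrier_ids) - a
            table = ContingencyTable.from_carriers(a, n_case, c, n_control)
            start, end = run[0].pos, run[-1].pos
            regions.append(
                CnvRegion(
                    chrom=chrom,
                    start=start,
                    end=end,
                    cnv_type=cnv_type,
                    case_carriers=a,
                    control_carriers=c,
                    n_cases=n_case,
                    n_controls=n_control,
                    p_value=fisher_one_sided(table),
                    odds_ratio=odds_ratio_cmle(table),
                    callers=frozenset({caller}),
                    carrier_ids=frozenset(carrier_ids),
                    caller_spans={caller: (start, end)},
                    caller_stats={
                        caller: (a, c, fisher_one_sided(table), odds_ratio_cmle(table))
                    },
                )
            )
    regions.sort(key=lambda r: (r.chrom, r.start, r.cnv_type.value))
    return regions


def consensus_union(
    regions_a: Sequence[CnvRegion], regions_b: Sequence[CnvRegion]
) -> list[CnvRegion]:
    """Cross-caller consensus: same-type overlapping regions from both callers.

    Each surviving consensus region spans the union of the contributing
    per-caller spans; carrier counts and the headline statistics are taken
    from caller A (the primary call set), with caller-B statistics retained
    alongside.  Overlap chains are merged transitively so output regions do
    not overlap each other.
    """
    consensus: list[CnvRegion] = []
    used_b: dict[int, CnvRegion] = {}
    for ra in regions_a:
        partners = [
            (i, rb)
            for i, rb in enumerate(regions_b)
            if rb.cnv_type is ra.cnv_type
            and rb.chrom == ra.chrom
            and rb.start <= ra.end
            and ra.start <= rb.end
        ]
        if not partners:
            continue
        start = min([ra.start] + [rb.start for _, rb in partners])
        end = max([ra.end] + [rb.end for _, rb in partners])
        spans = dict(ra.caller_spans)
        stats = dict(ra.caller_stats)
        for _, rb in partners:
            for caller, span in rb.caller_spans.items():
                spans[caller] = (
                    min(span[0], spans.get(caller, span)[0]),
                    max(span[1], spans.get(caller, span)[1]),
                )
            stats.update(rb.caller_stats)
        consensus.append(
            CnvRegion(
                chrom=ra.chrom,
                start=start,
                end=end,
                cnv_type=ra.cnv_type,
                case_carriers=ra.case_carriers,
                control_carriers=ra.control_carriers,
                n_cases=ra.n_cases,
                n_controls=ra.n_controls,
                p_value=ra.p_value,
                odds_ratio=ra.odds_ratio,
                callers=ra.callers | frozenset(c for _, rb in partners for c in rb.callers),
                carrier_ids=ra.carrier_ids,
                caller_spans=spans,
                caller_stats=stats,
            )
        )
    # merge consensus regions that themselves overlap (transitive chains)
    merged: list[CnvRegion] = []
    for r in sorted(consensus, key=lambda r: (r.chrom, r.cnv_type.value, r.start)):
        if (
            merged
            and merged[-1].chrom == r.chrom
            and merged[-1].cnv_type is r.cnv_type
            and r.start <= merged[-1].end
        ):
            prev = merged[-1]
            prev.end = max(prev.end, r.end)
            prev.carrier_ids = prev.carrier_ids | r.carrier_ids
            prev.caller_stats.update(
                {k: v for k, v in r.caller_stats.items() if k not in prev.caller_stats}
            )
        else:
            merged.append(r)
    return merged


def region_carriers(
    region: CnvRegion, calls: Iterable[CnvCall]
) -> set[str]:
    """Samples with >= 1 call of the region's type overlapping its span."""
    return {
        c.sample_id
        for c in calls
        if c.cnv_type is region.cnv_type
        and c.chrom == region.chrom
        and c.start <= region.end
        and region.start <= c.end
    }


def region_concordance(
    region: CnvRegion,
    calls_a: Iterable[CnvCall],
    calls_b: Iterable[CnvCall],
) -> float | None:
    """Fraction of caller-A carriers of the region also called by caller B.

    Returns None (undefined) when caller A has no carriers over the region.
    """
    carriers_a = region_carriers(region, calls_a)
    if not carriers_a:
        return None
    carriers_b = region_carriers(region, calls_b)
    return len(carriers_a & carriers_b) / len(carriers_a)


def annotate_genes(
    regions: Sequence[CnvRegion], genes: Sequence[GeneAnnotation]
) -> None:
    """Attach overlapping gene symbols (1 bp of overlap suffices) in place."""
    for r in regions:
        r.genes = sorted(
            {
                g.gene
                for g in genes
                if g.chrom == r.chrom and g.start <= r.end and r.start <= g.end
            }
        )
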
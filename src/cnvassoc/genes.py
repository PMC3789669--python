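"""Gene-level CNV association over padded gene windows.

A sample is a carrier for a (gene, type) pair when at least one base pair
of one of its calls of that type intersects the gene's window (the gene
span plus a symmetric pad, 20 kb by default).  Deletions and duplications
are tested separately with the one-sided Fisher exact test, and p-values
are Bonferroni-adjusted over the set of gene loci overlapped by calls from
both callers — a data-dependent count, since it depends on where calls
land.  Duplicate gene symbols at distinct loci are distinct test rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .stats import bonferroni, fisher_one_sided, odds_ratio_cmle
from .types import (
    Caller,
    CnvCall,
    CnvType,
    ContingencyTable,
    GeneAnnotation,
    SampleRecord,
    Status,
    ValidationError,
)

__all__ = [
    "DEFAULT_PAD",
    "gene_window",
    "gene_carrier_counts",
    "both_caller_gene_set",
    "gene_association",
    "candidate_gene_screen",
    "GeneTestResult",
]

DEFAULT_PAD = 20_000

GeneKey = tuple[str, str, int, int]


def gene_window(gene: GeneAnnotation, pad: int = DEFAULT_PAD) -> tuple[int, int]:
    """Gene span extended by ``pad`` bp both ways, clamped at position 1."""
    if pad < 0:
        raise ValidationError("pad must be >= 0")
    return max(1, gene.start - pad), gene.end + pad


def _carrier_sets(
    calls: Iterable[CnvCall],
    genes: Sequence[GeneAnnotation],
    pad: int,
) -> dict[tuple[GeneKey, CnvType], set[str]]:
    """Sample ids with >= 1 bp overlap per (gene locus, CNV type)."""
    by_chrom: dict[tuple[str, CnvType], list[CnvCall]] = {}
    for c in calls:
        by_chrom.setdefault((c.chrom, c.cnv_type), []).append(c)
    out: dict[tuple[GeneKey, CnvType], set[str]] = {}
    for g in genes:
        lo, hi = gene_window(g, pad)
        for cnv_type in (CnvType.DUP, CnvType.DEL):
            hits = {
                c.sample_id
                for c in by_chrom.get((g.chrom, cnv_type), [])
                if c.start <= hi and lo <= c.end
            }
            if hits:
                out[(g.key, cnv_type)] = hits
    return out


def gene_carrier_counts(
    calls: Iterable[CnvCall],
    genes: Sequence[GeneAnnotation],
    samples: Sequence[SampleRecord],
    pad: int = DEFAULT_PAD,
) -> dict[tuple[GeneKey, CnvType], ContingencyTable]:
    """Carrier-by-status tables per (gene locus, type) over padded windows."""
    status = {s.sample_id: s.status for s in samples}
    n_cases = sum(1 for s in samples if s.status is Status.CASE)
    n_controls = len(samples) - n_cases
    tables: dict[tuple[GeneKey, CnvType], ContingencyTable] = {}
    for key, carrier_ids in _carrier_sets(calls, genes, pad).items():
        carrier_ids = {sid for sid in carrier_ids if sid in status}
        a = sum(1 for sid in carrier_ids if status[sid] is Status.CASE)
        c = len(carrier_ids) - a
        tables[key] = ContingencyTable.from_carriers(a, n_cases, c, n_controls)
    return tables


def both_caller_gene_set(
    calls_a: Iterable[CnvCall],
    calls_b: Iterable[CnvCall],
    genes: Sequence[GeneAnnotation],
    pad: int = DEFAULT_PAD,
) -> set[GeneKey]:
    """Gene loci overlapped (either CNV type) by calls from both callers.

    The size of this set is the Bonferroni denominator for the gene-based
    analysis.
    """
    hit_a = {key[0] for key in _carrier_sets(calls_a, genes, pad)}
    hit_b = {key[0] for key in _carrier_sets(calls_b, genes, pad)}
    return hit_a & hit_b


@dataclass
class GeneTestResult:
    gene: str
    chrom: str
    start: int
    end: int
    cnv_type: CnvType
    case_carriers: int
    control_carriers: int
    case_proportion: float
    control_proportion: float
    odds_ratio: float
    p_value: float
    p_adjusted: float
    in_both_caller_set: bool
    supported_by: frozenset[Caller] = frozenset()


def gene_association(
    counts: Mapping[tuple[GeneKey, CnvType], ContingencyTable],
    m: int,
    both_caller_genes: set[GeneKey] | None = None,
) -> list[GeneTestResult]:
    """One-sided Fisher test with cMLE odds ratio per (gene locus, type).

    ``m`` is the Bonferroni denominator (the both-caller gene-set size).
    Gene loci outside ``both_caller_genes`` are still reported but flagged
    as excluded from the multiplicity-corrected family.
    """
    if m < 1:
        raise ValidationError("Bonferroni denominator m must be >= 1")
    results: list[GeneTestResult] = []
    for (key, cnv_type), table in counts.items():
        gene, chrom, start, end = key
        p = fisher_one_sided(table)
        in_set = both_caller_genes is None or key in both_caller_genes
        results.append(
            GeneTestResult(
                gene=gene,
                chrom=chrom,
                start=start,
                end=end,
                cnv_type=cnv_type,
                case_carriers=table.a,
                control_carriers=table.c,
                case_proportion=table.a / table.n_cases,
                control_proportion=table.c / table.n_controls,
                odds_ratio=odds_ratio_cmle(table),
                p_value=p,
                p_adjusted=bonferroni(p, m),
                in_both_caller_set=in_set,
            )
        )
    results.sort(key=lambda r: r.p_value)
    return results


def mark_supported(
    results_by_caller: Mapping[Caller, Sequence[GeneTestResult]],
    alpha: float = 0.05,
) -> list[GeneTestResult]:
    """Flag gene results Bonferroni-significant in each caller's own analysis.

    Returns the caller-A results annotated with the set of callers in which
    the (gene locus, type) row is significant after adjustment.
    """
    significant: dict[Caller, set[tuple[GeneKey, CnvType]]] = {
        caller: {
            ((r.gene, r.chrom, r.start, r.end), r.cnv_type)
            for r in results
            if r.p_adjusted <= alpha
        }
        for caller, results in results_by_caller.items()
    }
    annotated = []
    for r in results_by_caller.get(Caller.A, []):
        key = ((r.gene, r.chrom, r.start, r.end), r.cnv_type)
        r.supported_by = frozenset(
            caller for caller, sig in significant.items() if key in sig
        )
        annotated.append(r)
    return annotated


def candidate_gene_screen(
    calls: Iterable[CnvCall],
    genes: Sequence[GeneAnnotation],
    gene_names: Sequence[str],
    samples: Sequence[SampleRecord],
    pad: int = DEFAULT_PAD,
) -> dict[str, dict[str, int]]:
    """Carrier counts by status for a named candidate gene list.

    Genes with zero carriers are reported explicitly with zero counts;
    names absent from the annotation raise an error listing them.
    """
    known = {g.gene for g in genes}
    missing = [name for name in gene_names if name not in known]
    if missing:
        raise ValidationError(
            "candidate genes absent from annotation: " + ", ".join(missing)
        )
    wanted = [g for g in genes if g.gene in set(gene_names)]
    status = {s.sample_id: s.status for s in samples}
    report = {
        name: {"case_carriers": 0, "control_carriers": 0} for name in gene_names
    }
    carrier_sets: dict[str, set[str]] = {name: set() for name in gene_names}
    for (key, _cnv_type), ids in _carrier_sets(calls, wanted, pad).items():
        carrier_sets[key[0]] |= ids
    for name, ids in carrier_sets.items():
        report[name]["case_carriers"] = sum(
            1 for sid in ids if status.get(sid) is Status.CASE
        )
        report[name]["control_carriers"] = sum(
            1 for sid in ids if status.get(sid) is Status.CONTROL
        )
    return report
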
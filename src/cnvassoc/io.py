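"""Readers and writers for every external representation the pipeline touches.

Supported formats
-----------------
* PennCNV ``rawcnv`` text dialect (caller A), e.g.::

    chr1:16741950-16987299  numsnp=123  length=245,349  state5,cn=3  S001 ...

* Birdsuite-style tab-separated call table (caller B) with header
  ``sample chrom start end cn n_markers score source`` where ``source`` is
  ``canary`` (CNP genotype, score = confidence) or ``birdseye`` (rare-CNV
  HMM call, score = LOD).
* BED4 gene annotation (0-based half-open, converted to 1-based inclusive
  on import).
* Tab-separated marker map, phenotype/covariate table, qPCR CT table.
* Tab-separated report writers mirroring the CNVR / gene result layouts.

All coordinates after import are 1-based inclusive; parsers never emit
copy-neutral or sex-chromosome calls.
"""

from __future__ import annotations

import csv
import re
from pathlib import Path
from typing import Iterable, Sequence

from .types import (
    Caller,
    CnvCall,
    CnvType,
    DnaSource,
    GeneAnnotation,
    MarkerMap,
    QpcrWell,
    SampleRecord,
    Sex,
    Status,
    ValidationError,
    normalize_chrom,
)

__all__ = [
    "ParseError",
    "read_penncnv_calls",
    "read_birdsuite_calls",
    "read_gene_bed",
    "read_marker_map",
    "read_samples",
    "read_qpcr_table",
    "write_qpcr_table",
    "write_calls",
    "read_calls",
    "write_cnvr_report",
    "write_gene_report",
]

AUTOSOMES = {str(i) for i in range(1, 23)}


class ParseError(ValueError):
    """A line of an input file could not be interpreted."""


_PENNCNV_RE = re.compile(
    r"^chr(?P<chrom>[\w]+):(?P<start>[\d,]+)-(?P<end>[\d,]+)\s+"
    r"numsnp=(?P<numsnp>\d+)\s+length=(?P<length>[\d,]+)\s+"
    r"state(?P<state>\d+),cn=(?P<cn>\d+)\s+(?P<sample>\S+)"
)


def _int(text: str) -> int:
    return int(text.replace(",", ""))


def read_penncnv_calls(path: str | Path) -> list[CnvCall]:
    """Parse a PennCNV ``rawcnv`` file into caller-A calls.

    Copy-neutral lines (cn=2) are rejected as invalid, and sex-chromosome
    lines are skipped (only the 22 autosomes are analyzed).
    """
    calls: list[CnvCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            m = _PENNCNV_RE.match(line)
            if m is None:
                raise ParseError(f"{path}: line {lineno}: unparsable rawcnv line")
            cn = int(m.group("cn"))
            if cn == 2:
                raise ValidationError(
                    f"{path}: line {lineno}: cn=2 is copy-neutral, not a CNV"
                )
            chrom = normalize_chrom(m.group("chrom"))
            if chrom not in AUTOSOMES:
                continue
            calls.append(
                CnvCall(
                    sample_id=m.group("sample"),
                    chrom=chrom,
                    start=_int(m.group("start")),
                    end=_int(m.group("end")),
                    cnv_type=CnvType.DEL if cn < 2 else CnvType.DUP,
                    copy_number=cn,
                    n_markers=int(m.group("numsnp")),
                    caller=Caller.A,
                )
            )
    return calls


def read_birdsuite_calls(path: str | Path) -> list[CnvCall]:
    """Parse a Birdsuite-style master call table into caller-B calls.

    Canary rows with copy number 2 (normal CNP genotype) are dropped, as
    are rows on the sex chromosomes.  Unknown ``source`` tags are a parse
    error.
    """
    calls: list[CnvCall] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=2):
            source = row["source"].strip().lower()
            if source not in ("canary", "birdseye"):
                raise ParseError(
                    f"{path}: line {lineno}: unknown source tag {row['source']!r}"
                )
            cn = int(row["cn"])
            chrom = normalize_chrom(row["chrom"])
            if chrom not in AUTOSOMES:
                continue
            if cn == 2:
                if source == "canary":
                    continue  # normal CNP genotype
                raise ValidationError(
                    f"{path}: line {lineno}: birdseye call with cn=2"
                )
            calls.append(
                CnvCall(
                    sample_id=row["sample"],
                    chrom=chrom,
                    start=int(row["start"]),
                    end=int(row["end"]),
                    cnv_type=CnvType.DEL if cn < 2 else CnvType.DUP,
                    copy_number=cn,
                    n_markers=int(row["n_markers"]),
                    score=float(row["score"]),
                    caller=Caller.B,
                    source=source,
                )
            )
    return calls


def read_gene_bed(path: str | Path) -> list[GeneAnnotation]:
    """Read BED4 gene annotation, converting to 1-based inclusive coordinates."""
    genes: list[GeneAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                fields = line.split()
            if len(fields) < 4:
                raise ParseError(f"{path}: line {lineno}: expected >= 4 BED columns")
            chrom, bed_start, bed_end, name = fields[:4]
            start, end = int(bed_start), int(bed_end)
            if end <= start:
                raise ValidationError(
                    f"{path}: line {lineno}: empty or inverted BED interval"
                )
            strand = fields[5] if len(fields) >= 6 else "+"
            genes.append(
                GeneAnnotation(
                    gene=name,
                    chrom=normalize_chrom(chrom),
                    start=start + 1,
                    end=end,
                    strand=strand,
                )
            )
    return genes


def read_marker_map(path: str | Path) -> MarkerMap:
    """Read a TSV marker map with columns marker_id, chrom, pos."""
    per_chrom: dict[str, list[tuple[str, int]]] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            chrom = normalize_chrom(row["chrom"])
            per_chrom.setdefault(chrom, []).append((row["marker_id"], int(row["pos"])))
    return MarkerMap(per_chrom)


_SAMPLE_COLUMNS = (
    "sample_id",
    "status",
    "age",
    "sex",
    "dna_source",
    "call_rate",
    "reported_sex",
    "computed_sex",
    "lrr_sd",
    "baf_median",
    "baf_drift",
    "waviness",
    "n_cnv_A",
    "n_cnv_B",
    "total_kb",
    "duplicate_group",
)


def _opt(value: str | None, conv):
    if value is None or value == "" or value.upper() == "NA":
        return None
    return conv(value)


def read_samples(path: str | Path) -> list[SampleRecord]:
    """Read the phenotype/covariate/QC-metric table.

    Principal components are taken from columns ``pc1``, ``pc2``, ... in
    numeric order.
    """
    samples: list[SampleRecord] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "sample_id" not in reader.fieldnames:
            raise ParseError(f"{path}: missing header with sample_id")
        pc_cols = sorted(
            (c for c in reader.fieldnames if re.fullmatch(r"pc\d+", c)),
            key=lambda c: int(c[2:]),
        )
        for row in reader:
            pcs = tuple(float(row[c]) for c in pc_cols if row.get(c, "") != "")
            samples.append(
                SampleRecord(
                    sample_id=row["sample_id"],
                    status=Status(row["status"].upper()),
                    age=_opt(row.get("age"), float),
                    sex=_opt(row.get("sex"), Sex),
                    dna_source=_opt(
                        row.get("dna_source"), lambda v: DnaSource(v.upper())
                    ),
                    call_rate=_opt(row.get("call_rate"), float),
                    reported_sex=_opt(row.get("reported_sex"), Sex),
                    computed_sex=_opt(row.get("computed_sex"), Sex),
                    pcs=pcs,
                    lrr_sd=_opt(row.get("lrr_sd"), float),
                    baf_median=_opt(row.get("baf_median"), float),
                    baf_drift=_opt(row.get("baf_drift"), float),
                    waviness=_opt(row.get("waviness"), float),
                    n_cnv_A=_opt(row.get("n_cnv_A"), int),
                    n_cnv_B=_opt(row.get("n_cnv_B"), int),
                    total_kb=_opt(row.get("total_kb"), float),
                    duplicate_group=_opt(row.get("duplicate_group"), str),
                )
            )
    return samples


def write_samples(samples: Sequence[SampleRecord], path: str | Path) -> None:
    n_pcs = max((len(s.pcs) for s in samples), default=0)
    pc_cols = [f"pc{i + 1}" for i in range(n_pcs)]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(list(_SAMPLE_COLUMNS) + pc_cols)
        for s in samples:
            row = [
                s.sample_id,
                s.status.value,
                "" if s.age is None else repr(s.age),
                "" if s.sex is None else s.sex.value,
                "" if s.dna_source is None else s.dna_source.value,
                "" if s.call_rate is None else repr(s.call_rate),
                "" if s.reported_sex is None else s.reported_sex.value,
                "" if s.computed_sex is None else s.computed_sex.value,
                "" if s.lrr_sd is None else repr(s.lrr_sd),
                "" if s.baf_median is None else repr(s.baf_median),
                "" if s.baf_drift is None else repr(s.baf_drift),
                "" if s.waviness is None else repr(s.waviness),
                "" if s.n_cnv_A is None else s.n_cnv_A,
                "" if s.n_cnv_B is None else s.n_cnv_B,
                "" if s.total_kb is None else repr(s.total_kb),
                "" if s.duplicate_group is None else s.duplicate_group,
            ]
            row += [repr(v) for v in s.pcs]
            writer.writerow(row)


_CALL_COLUMNS = (
    "sample",
    "chrom",
    "start",
    "end",
    "type",
    "cn",
    "n_markers",
    "score",
    "caller",
    "source",
    "flags",
)


def write_calls(calls: Sequence[CnvCall], path: str | Path) -> None:
    """Write calls as the package's canonical TSV; round-trips exactly."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(_CALL_COLUMNS)
        for c in calls:
            writer.writerow(
                [
                    c.sample_id,
                    c.chrom,
                    c.start,
                    c.end,
                    c.cnv_type.value,
                    "" if c.copy_number is None else c.copy_number,
                    c.n_markers,
                    "" if c.score is None else repr(c.score),
                    c.caller.value,
                    c.source or "",
                    ",".join(sorted(c.flags)),
                ]
            )


def read_calls(path: str | Path) -> list[CnvCall]:
    calls: list[CnvCall] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            calls.append(
                CnvCall(
                    sample_id=row["sample"],
                    chrom=row["chrom"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    cnv_type=CnvType(row["type"]),
                    copy_number=_opt(row.get("cn"), int),
                    n_markers=int(row["n_markers"]),
                    score=_opt(row.get("score"), float),
                    caller=Caller(row["caller"]),
                    source=_opt(row.get("source"), str),
                    flags=frozenset(f for f in row.get("flags", "").split(",") if f),
                )
            )
    return calls


_CN_TO_STATE = {0: 1, 1: 2, 3: 5, 4: 6}


def write_penncnv_calls(calls: Sequence[CnvCall], path: str | Path) -> None:
    """Write caller-A calls in the rawcnv text dialect the reader accepts."""
    with open(path, "w") as fh:
        for c in calls:
            state = _CN_TO_STATE.get(c.copy_number, 5 if c.cnv_type is CnvType.DUP else 2)
            fh.write(
                f"chr{c.chrom}:{c.start}-{c.end}\tnumsnp={c.n_markers}\t"
                f"length={c.display_length:,}\tstate{state},cn={c.copy_number}\t"
                f"{c.sample_id}\n"
            )


def write_birdsuite_calls(calls: Sequence[CnvCall], path: str | Path) -> None:
    """Write caller-B calls as the Birdsuite-style master table."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(
            ["sample", "chrom", "start", "end", "cn", "n_markers", "score", "source"]
        )
        for c in calls:
            writer.writerow(
                [
                    c.sample_id,
                    c.chrom,
                    c.start,
                    c.end,
                    c.copy_number,
                    c.n_markers,
                    "" if c.score is None else repr(c.score),
                    c.source or "birdseye",
                ]
            )


def write_marker_map(markers: MarkerMap, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["marker_id", "chrom", "pos"])
        for chrom in markers.chroms:
            for mid, pos in zip(markers.ids(chrom), markers.positions(chrom)):
                writer.writerow([mid, chrom, pos])


def write_gene_bed(genes: Sequence[GeneAnnotation], path: str | Path) -> None:
    """Write gene annotation as BED4 (converting back to 0-based half-open)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        for g in genes:
            writer.writerow([f"chr{g.chrom}", g.start - 1, g.end, g.gene])


def read_qpcr_table(path: str | Path) -> list[QpcrWell]:
    """Read CT values: columns sample, replicate, ct_target, ct_reference."""
    wells: list[QpcrWell] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            wells.append(
                QpcrWell(
                    sample_id=row["sample"],
                    replicate=int(row.get("replicate", 1)),
                    ct_target=float(row["ct_target"]),
                    ct_reference=float(row["ct_reference"]),
                )
            )
    return wells


def write_qpcr_table(wells: Sequence[QpcrWell], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["sample", "replicate", "ct_target", "ct_reference"])
        for w in wells:
            writer.writerow([w.sample_id, w.replicate, repr(w.ct_target), repr(w.ct_reference)])


def write_cnvr_report(regions: Sequence, path: str | Path) -> None:
    """Write the CNVR association report (one row per consensus region).

    Columns mirror the standard published layout: region span, display
    length (end - start), type, carrier counts with proportions to three
    decimals, odds ratio, p-value and overlapped genes ("None" when a
    region hits no annotated gene).
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(
            ["CNVR", "length_bp", "type", "cases", "controls", "OR", "P", "genes"]
        )
        for r in regions:
            genes = ",".join(r.genes) if r.genes else "None"
            writer.writerow(
                [
                    f"chr{r.chrom}:{r.start}-{r.end}",
                    r.end - r.start,
                    r.cnv_type.value,
                    f"{r.case_carriers} ({r.case_carriers / r.n_cases:.3f})",
                    f"{r.control_carriers} ({r.control_carriers / r.n_controls:.3f})",
                    "Inf" if r.odds_ratio == float("inf") else f"{r.odds_ratio:.2f}",
                    f"{r.p_value:.3G}",
                    genes,
                ]
            )


def write_gene_report(results: Sequence, path: str | Path) -> None:
    """Write gene-based association results (one row per gene locus x type)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(
            [
                "gene",
                "chrom",
                "type",
                "cases",
                "controls",
                "prop_cases",
                "prop_controls",
                "OR",
                "P_unadjusted",
                "P_bonferroni",
                "callers",
            ]
        )
        for r in results:
            writer.writerow(
                [
                    r.gene,
                    r.chrom,
                    r.cnv_type.value,
                    r.case_carriers,
                    r.control_carriers,
                    f"{r.case_proportion:.2f}",
                    f"{r.control_proportion:.2f}",
                    "Inf" if r.odds_ratio == float("inf") else f"{r.odds_ratio:.2f}",
                    f"{r.p_value:.3G}",
                    f"{r.p_adjusted:.3G}",
                    ",".join(sorted(c.value for c in r.supported_by)),
                ]
            )
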
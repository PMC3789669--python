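"""Core domain types shared across the pipeline.

Coordinate convention: every interval held in memory is 1-based and
inclusive at both ends, so a single-base feature has ``start == end`` and
``length == end - start + 1``.  BED input is converted at the boundary
(see :mod:`cnvassoc.io`).  Chromosome labels are bare autosome numbers
("1".."22"); a leading ``chr`` prefix is stripped on import.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence


class CnvType(str, Enum):
    """Dosage direction of a copy-number call."""

    DUP = "DUP"
    DEL = "DEL"


class Caller(str, Enum):
    """Which calling algorithm produced a call.

    ``A`` is the PennCNV-style HMM dialect, ``B`` the Birdsuite-style
    dialect (Canary CNP genotypes merged with Birdseye rare-CNV calls).
    """

    A = "A"
    B = "B"


class Status(str, Enum):
    CASE = "CASE"
    CONTROL = "CONTROL"


class Sex(str, Enum):
    MALE = "M"
    FEMALE = "F"


class DnaSource(str, Enum):
    BLOOD = "BLOOD"
    SALIVA = "SALIVA"


#: Region annotations attached to calls, never used to silently drop them.
FLAG_TELOMERE = "TELOMERE"
FLAG_CENTROMERE = "CENTROMERE"
FLAG_SEGDUP = "SEGDUP"

#: Birdsuite sub-sources: Canary genotypes common CNPs, Birdseye finds rare CNVs.
SOURCE_CANARY = "canary"
SOURCE_BIRDSEYE = "birdseye"


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


def normalize_chrom(label: str) -> str:
    label = label.strip()
    if label.lower().startswith("chr"):
        label = label[3:]
    return label


@dataclass(frozen=True)
class CnvCall:
    """One deletion/duplication segment in one sample from one caller."""

    sample_id: str
    chrom: str
    start: int
    end: int
    cnv_type: CnvType
    n_markers: int
    caller: Caller
    copy_number: int | None = None
    score: float | None = None
    source: str | None = None
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"call {self.sample_id} {self.chrom}:{self.start}-{self.end}: start > end"
            )
        if self.start < 1:
            raise ValidationError("coordinates are 1-based; start must be >= 1")
        if self.n_markers < 1:
            raise ValidationError("n_markers must be >= 1")
        if self.copy_number is not None:
            if not 0 <= self.copy_number <= 6:
                raise ValidationError(f"copy_number {self.copy_number} outside 0..6")
            if self.copy_number == 2:
                raise ValidationError("copy-neutral (cn=2) segments are not CNVs")
            expected = CnvType.DEL if self.copy_number < 2 else CnvType.DUP
            if expected is not self.cnv_type:
                raise ValidationError(
                    f"cnv_type {self.cnv_type.value} inconsistent with cn={self.copy_number}"
                )

    @property
    def length(self) -> int:
        """Inclusive length in bp (end - start + 1)."""
        return self.end - self.start + 1

    @property
    def display_length(self) -> int:
        """end - start, the convention used when printing region spans."""
        return self.end - self.start


@dataclass
class SampleRecord:
    """Phenotype, covariates and per-sample array QC metrics."""

    sample_id: str
    status: Status
    age: float | None = None
    sex: Sex | None = None
    dna_source: DnaSource | None = None
    call_rate: float | None = None
    reported_sex: Sex | None = None
    computed_sex: Sex | None = None
    pcs: tuple[float, ...] = ()
    lrr_sd: float | None = None
    baf_median: float | None = None
    baf_drift: float | None = None
    waviness: float | None = None
    n_cnv_A: int | None = None
    n_cnv_B: int | None = None
    total_kb: float | None = None
    duplicate_group: str | None = None

    def __post_init__(self) -> None:
        if self.baf_median is not None and not 0 <= self.baf_median <= 1:
            raise ValidationError(f"{self.sample_id}: baf_median outside [0, 1]")
        if self.call_rate is not None and not 0 <= self.call_rate <= 1:
            raise ValidationError(f"{self.sample_id}: call_rate outside [0, 1]")


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene locus; duplicate symbols at distinct loci are distinct rows."""

    gene: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"gene {self.gene}: start > end")

    @property
    def key(self) -> tuple[str, str, int, int]:
        return (self.gene, self.chrom, self.start, self.end)


class MarkerMap:
    """Ordered array markers per chromosome.

    Positions must be strictly increasing within a chromosome; marker
    lookups by interval use binary search.
    """

    def __init__(self, per_chrom: dict[str, Sequence[tuple[str, int]]]):
        self._ids: dict[str, list[str]] = {}
        self._pos: dict[str, list[int]] = {}
        for chrom, markers in per_chrom.items():
            chrom = normalize_chrom(chrom)
            ids = [m[0] for m in markers]
            pos = [int(m[1]) for m in markers]
            for p, q in zip(pos, pos[1:]):
                if q <= p:
                    raise ValidationError(
                        f"marker positions not strictly increasing on chr{chrom}"
                    )
            self._ids[chrom] = ids
            self._pos[chrom] = pos

    @property
    def chroms(self) -> list[str]:
        return list(self._pos)

    def positions(self, chrom: str) -> list[int]:
        return self._pos.get(normalize_chrom(chrom), [])

    def ids(self, chrom: str) -> list[str]:
        return self._ids.get(normalize_chrom(chrom), [])

    def n_markers(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return len(self.positions(chrom))
        return sum(len(v) for v in self._pos.values())

    def index_range(self, chrom: str, start: int, end: int) -> range:
        """Indices of markers with start <= pos <= end on ``chrom``."""
        pos = self.positions(chrom)
        lo = bisect.bisect_left(pos, start)
        hi = bisect.bisect_right(pos, end)
        return range(lo, hi)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, MarkerMap)
            and self._ids == other._ids
            and self._pos == other._pos
        )


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 carrier-by-status table: a/b case carriers/non-carriers, c/d controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("contingency cells must be non-negative")

    @classmethod
    def from_carriers(
        cls, case_carriers: int, n_cases: int, control_carriers: int, n_controls: int
    ) -> "ContingencyTable":
        return cls(
            case_carriers,
            n_cases - case_carriers,
            control_carriers,
            n_controls - control_carriers,
        )

    @property
    def n_cases(self) -> int:
        return self.a + self.b

    @property
    def n_controls(self) -> int:
        return self.c + self.d


@dataclass(frozen=True)
class QpcrWell:
    """One qPCR replicate: target and internal-reference threshold cycles."""

    sample_id: str
    ct_target: float
    ct_reference: float
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.ct_target <= 0 or self.ct_reference <= 0:
            raise ValidationError("CT values must be positive")


def group_calls(
    calls: Iterable[CnvCall],
) -> dict[tuple[str, str, CnvType, Caller], list[CnvCall]]:
    """Group calls by (sample, chrom, type, caller), each group sorted by start."""
    groups: dict[tuple[str, str, CnvType, Caller], list[CnvCall]] = {}
    for call in calls:
        key = (call.sample_id, call.chrom, call.cnv_type, call.caller)
        groups.setdefault(key, []).append(call)
    for group in groups.values():
        group.sort(key=lambda c: (c.start, c.end))
    return groups
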
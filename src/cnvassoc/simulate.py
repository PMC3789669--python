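"""Seeded synthetic cohorts for exercising the pipeline end to end.

The generator emulates the statistical structure the analysis assumes: a
case/control cohort with per-sample array QC metrics, a uniformly spaced
marker map, background CNV calls with Poisson per-sample counts and
log-normal lengths, planted case-enriched regions with independent
Bernoulli carrier draws at configured case/control frequencies, and two
pseudo-callers.

Caller A is the reference call set: it reports every background call and
every planted carrier.  Caller B reproduces each background A call with
probability ``caller_B_sensitivity`` and Gaussian boundary jitter.  For
planted carriers, B's carrier indicator is drawn so that the conditional
overlap P(B carrier | A carrier) equals ``caller_B_sensitivity`` while the
marginal B carrier frequency matches the configured frequency — mirroring
the situation where two callers each detect an association independently
but agree on only a fraction of individual carriers.

All randomness flows from the single config seed through named substreams,
so adding a component never perturbs another component's draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

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
)

__all__ = [
    "PlantedRegion",
    "SimConfig",
    "SimulatedCohort",
    "TruthRecord",
    "simulate_cohort",
    "simulate_qpcr",
]


@dataclass(frozen=True)
class PlantedRegion:
    chrom: str
    start: int
    end: int
    cnv_type: CnvType
    case_freq: float
    control_freq: float


@dataclass
class SimConfig:
    """Cohort and genome parameters for the generator.

    Defaults mirror the study conditions this package targets: 270 cases
    and 457 controls (post-QC cohort sizes), background call lengths
    log-normal around a 35 kb median, and one planted duplication region
    with carrier frequencies 0.237 (cases) vs 0.057 (controls) — the
    profile of a strongly case-enriched common duplication.  The genome is
    scaled down (a few chromosomes of 1 kb-spaced markers) so a full run
    takes seconds.
    """

    n_cases: int = 270
    n_controls: int = 457
    n_chrom: int = 4
    markers_per_chrom: int = 2000
    marker_spacing: int = 1000
    n_genes: int = 60
    background_cnv_rate: float = 3.0
    length_log_mean: float = math.log(35_000)
    length_log_sd: float = 0.8
    planted_regions: tuple[PlantedRegion, ...] = (
        PlantedRegion("1", 500_000, 650_000, CnvType.DUP, 0.237, 0.057),
    )
    caller_B_sensitivity: float = 0.4
    boundary_jitter_sd: float = 2_000.0
    qc_outlier_fraction: float = 0.05
    seed: int = 0

    @property
    def chrom_length(self) -> int:
        return self.markers_per_chrom * self.marker_spacing

    def validate(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValidationError("need at least one case and one control")
        if self.marker_spacing <= 0:
            raise ValidationError("marker_spacing must be positive")
        chroms = {str(i + 1) for i in range(self.n_chrom)}
        for r in self.planted_regions:
            if not 0 <= r.case_freq <= 1 and 0 <= r.control_freq <= 1:
                raise ValidationError("planted frequencies must be in [0, 1]")
            if r.chrom not in chroms or r.end > self.chrom_length or r.start < 1:
                raise ValidationError(
                    f"planted region chr{r.chrom}:{r.start}-{r.end} outside genome"
                )


@dataclass(frozen=True)
class TruthRecord:
    region: PlantedRegion
    sample_id: str
    status: Status
    called_by_A: bool
    called_by_B: bool
    copy_number: int


@dataclass
class SimulatedCohort:
    samples: list[SampleRecord]
    markers: MarkerMap
    genes: list[GeneAnnotation]
    calls_A: list[CnvCall]
    calls_B: list[CnvCall]
    truth: list[TruthRecord]
    config: SimConfig


# fixed substream ids: appending new components never reseeds existing ones
_STREAMS = {
    "samples": 1,
    "qc": 2,
    "background": 3,
    "planted": 4,
    "caller_b": 5,
    "genes": 6,
    "qpcr": 7,
}


def _rng(cfg_seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=cfg_seed, spawn_key=(_STREAMS[stream],))
    )


def _make_samples(cfg: SimConfig) -> list[SampleRecord]:
    rng = _rng(cfg.seed, "samples")
    qc_rng = _rng(cfg.seed, "qc")
    samples: list[SampleRecord] = []
    n = cfg.n_cases + cfg.n_controls
    outliers = set(
        qc_rng.choice(n, size=int(round(cfg.qc_outlier_fraction * n)), replace=False)
    )
    for i in range(n):
        is_case = i < cfg.n_cases
        status = Status.CASE if is_case else Status.CONTROL
        # cohort demographics: cases younger, mostly blood-derived DNA
        age = float(
            np.clip(rng.normal(38.7, 17.6) if is_case else rng.normal(50.0, 14.0), 18, 90)
        )
        sex = Sex.FEMALE if rng.random() < (0.544 if is_case else 0.498) else Sex.MALE
        source = (
            DnaSource.SALIVA
            if is_case and rng.random() < 0.26
            else DnaSource.BLOOD
        )
        pcs = tuple(float(x) for x in rng.normal(0, 1, size=3))
        rec = SampleRecord(
            sample_id=f"{'CA' if is_case else 'CO'}{i:04d}",
            status=status,
            age=age,
            sex=sex,
            dna_source=source,
            call_rate=float(min(1.0, 0.99 + rng.normal(0, 0.003))),
            reported_sex=sex,
            computed_sex=sex,
            pcs=pcs,
            lrr_sd=float(abs(rng.normal(0.20, 0.02))),
            baf_median=float(np.clip(rng.normal(0.5, 0.008), 0.46, 0.54)),
            baf_drift=float(abs(rng.normal(0, 0.001))),
            waviness=float(rng.normal(0, 0.01)),
        )
        if i in outliers:
            # plant exactly one QC violation per flagged sample
            mode = qc_rng.integers(0, 5)
            if mode == 0:
                rec.call_rate = 0.90
            elif mode == 1:
                rec.computed_sex = Sex.MALE if sex is Sex.FEMALE else Sex.FEMALE
            elif mode == 2:
                rec.baf_median = 0.60
            elif mode == 3:
                rec.baf_drift = 0.02
            else:
                rec.waviness = 0.08
        samples.append(rec)
    return samples


def _make_markers(cfg: SimConfig) -> MarkerMap:
    per_chrom = {}
    for i in range(cfg.n_chrom):
        chrom = str(i + 1)
        per_chrom[chrom] = [
            (f"mk{chrom}_{j}", (j + 1) * cfg.marker_spacing)
            for j in range(cfg.markers_per_chrom)
        ]
    return MarkerMap(per_chrom)


def _make_genes(cfg: SimConfig) -> list[GeneAnnotation]:
    rng = _rng(cfg.seed, "genes")
    genes: list[GeneAnnotation] = []
    # guarantee annotation over each planted region
    for k, region in enumerate(cfg.planted_regions):
        mid = (region.start + region.end) // 2
        genes.append(
            GeneAnnotation(
                gene=f"PLANT{k + 1}",
                chrom=region.chrom,
                start=max(1, mid - 10_000),
                end=min(cfg.chrom_length, mid + 10_000),
            )
        )
    for k in range(cfg.n_genes - len(genes)):
        chrom = str(int(rng.integers(1, cfg.n_chrom + 1)))
        length = int(rng.integers(5_000, 50_000))
        start = int(rng.integers(1, max(2, cfg.chrom_length - length)))
        genes.append(
            GeneAnnotation(
                gene=f"GENE{k + 1}", chrom=chrom, start=start, end=start + length
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def _n_markers_in(markers: MarkerMap, chrom: str, start: int, end: int) -> int:
    return len(markers.index_range(chrom, start, end))


def _background_calls(
    cfg: SimConfig, samples: Sequence[SampleRecord], markers: MarkerMap
) -> tuple[list[CnvCall], list[CnvCall]]:
    rng = _rng(cfg.seed, "background")
    b_rng = _rng(cfg.seed, "caller_b")
    calls_a: list[CnvCall] = []
    calls_b: list[CnvCall] = []
    # planted regions own their loci: background calls are redrawn away from
    # them so the realized carrier frequency at a planted region equals the
    # configured one (up to binomial noise) instead of being contaminated
    planted_spans = [(r.chrom, r.start, r.end) for r in cfg.planted_regions]
    for s in samples:
        for _ in range(int(rng.poisson(cfg.background_cnv_rate))):
            for _attempt in range(20):
                chrom = str(int(rng.integers(1, cfg.n_chrom + 1)))
                length = int(rng.lognormal(cfg.length_log_mean, cfg.length_log_sd))
                length = max(1_000, min(length, cfg.chrom_length - 1))
                start = int(rng.integers(1, cfg.chrom_length - length + 1))
                end = start + length - 1
                if not any(
                    chrom == pc and start <= pe and ps <= end
                    for pc, ps, pe in planted_spans
                ):
                    break
            else:
                continue
            is_dup = rng.random() < 0.5
            cn = (4 if rng.random() < 0.1 else 3) if is_dup else (0 if rng.random() < 0.1 else 1)
            nm = _n_markers_in(markers, chrom, start, end)
            if nm == 0:
                continue
            call = CnvCall(
                sample_id=s.sample_id,
                chrom=chrom,
                start=start,
                end=end,
                cnv_type=CnvType.DUP if is_dup else CnvType.DEL,
                copy_number=cn,
                n_markers=nm,
                caller=Caller.A,
            )
            calls_a.append(call)
            if b_rng.random() < cfg.caller_B_sensitivity:
                bs = max(1, int(round(start + b_rng.normal(0, cfg.boundary_jitter_sd))))
                be = min(cfg.chrom_length, int(round(end + b_rng.normal(0, cfg.boundary_jitter_sd))))
                if be <= bs:
                    bs, be = start, end
                nm_b = _n_markers_in(markers, chrom, bs, be)
                if nm_b == 0:
                    continue
                calls_b.append(
                    CnvCall(
                        sample_id=s.sample_id,
                        chrom=chrom,
                        start=bs,
                        end=be,
                        cnv_type=call.cnv_type,
                        copy_number=cn,
                        n_markers=nm_b,
                        score=float(b_rng.gamma(3.0, 10.0)),
                        caller=Caller.B,
                        source="birdseye",
                    )
                )
    return calls_a, calls_b


def _planted_calls(
    cfg: SimConfig, samples: Sequence[SampleRecord], markers: MarkerMap
) -> tuple[list[CnvCall], list[CnvCall], list[TruthRecord]]:
    rng = _rng(cfg.seed, "planted")
    calls_a: list[CnvCall] = []
    calls_b: list[CnvCall] = []
    truth: list[TruthRecord] = []
    conc = cfg.caller_B_sensitivity
    for region in cfg.planted_regions:
        nm = _n_markers_in(markers, region.chrom, region.start, region.end)
        cn = 3 if region.cnv_type is CnvType.DUP else 1
        for s in samples:
            f = region.case_freq if s.status is Status.CASE else region.control_freq
            in_a = rng.random() < f
            if in_a:
                in_b = rng.random() < conc
            else:
                # keep the marginal B frequency equal to f while the
                # conditional overlap with A equals the concordance setting
                p_b_given_not_a = 0.0 if f >= 1.0 else f * (1.0 - conc) / (1.0 - f)
                in_b = rng.random() < p_b_given_not_a
            if not (in_a or in_b):
                continue
            truth.append(
                TruthRecord(region, s.sample_id, s.status, in_a, in_b, cn)
            )
            if in_a:
                calls_a.append(
                    CnvCall(
                        sample_id=s.sample_id,
                        chrom=region.chrom,
                        start=region.start,
                        end=region.end,
                        cnv_type=region.cnv_type,
                        copy_number=cn,
                        n_markers=nm,
                        caller=Caller.A,
                    )
                )
            if in_b:
                bs = max(1, int(round(region.start + rng.normal(0, cfg.boundary_jitter_sd))))
                be = min(
                    cfg.chrom_length,
                    int(round(region.end + rng.normal(0, cfg.boundary_jitter_sd))),
                )
                if be <= bs:
                    bs, be = region.start, region.end
                calls_b.append(
                    CnvCall(
                        sample_id=s.sample_id,
                        chrom=region.chrom,
                        start=bs,
                        end=be,
                        cnv_type=region.cnv_type,
                        copy_number=cn,
                        n_markers=_n_markers_in(markers, region.chrom, bs, be),
                        score=float(25.0 + rng.gamma(2.0, 5.0)),
                        caller=Caller.B,
                        source="birdseye",
                    )
                )
    return calls_a, calls_b, truth


def simulate_cohort(cfg: SimConfig | None = None) -> SimulatedCohort:
    """Generate a full synthetic cohort (samples, markers, genes, calls, truth)."""
    cfg = cfg or SimConfig()
    cfg.validate()
    samples = _make_samples(cfg)
    markers = _make_markers(cfg)
    genes = _make_genes(cfg)
    bg_a, bg_b = _background_calls(cfg, samples, markers)
    pl_a, pl_b, truth = _planted_calls(cfg, samples, markers)
    calls_a = sorted(bg_a + pl_a, key=lambda c: (c.chrom, c.start, c.sample_id))
    calls_b = sorted(bg_b + pl_b, key=lambda c: (c.chrom, c.start, c.sample_id))
    count_a: dict[str, int] = {}
    count_b: dict[str, int] = {}
    kb: dict[str, float] = {}
    for c in calls_a:
        count_a[c.sample_id] = count_a.get(c.sample_id, 0) + 1
        kb[c.sample_id] = kb.get(c.sample_id, 0.0) + c.length / 1000.0
    for c in calls_b:
        count_b[c.sample_id] = count_b.get(c.sample_id, 0) + 1
    for s in samples:
        s.n_cnv_A = count_a.get(s.sample_id, 0)
        s.n_cnv_B = count_b.get(s.sample_id, 0)
        s.total_kb = kb.get(s.sample_id, 0.0)
    return SimulatedCohort(samples, markers, genes, calls_a, calls_b, truth, cfg)


def simulate_qpcr(
    copy_numbers: dict[str, int],
    calibrator_id: str | None = None,
    calibrator_cn: int = 2,
    noise_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
    base_ct_reference: float = 25.0,
    base_delta_ct: float = 2.0,
) -> list[QpcrWell]:
    """CT tables consistent with the relative-quantitation model.

    A sample with true copy number n gets dCT = base - log2(n / 2), so its
    ddCT against a diploid calibrator is -log2(n / 2) plus N(0, noise_sd)
    noise per replicate (applied to the target CT).  If ``calibrator_id``
    is given and absent from ``copy_numbers`` it is added with
    ``calibrator_cn``.
    """
    rng = np.random.default_rng(seed)
    cns = dict(copy_numbers)
    if calibrator_id is not None and calibrator_id not in cns:
        cns[calibrator_id] = calibrator_cn
    wells: list[QpcrWell] = []
    for sid, cn in cns.items():
        if cn <= 0:
            raise ValidationError(
                f"sample {sid}: copy number {cn} has no finite CT representation"
            )
        dct = base_delta_ct - math.log2(cn / 2.0)
        for rep in range(1, n_replicates + 1):
            noise = float(rng.normal(0, noise_sd)) if noise_sd > 0 else 0.0
            wells.append(
                QpcrWell(
                    sample_id=sid,
                    ct_target=base_ct_reference + dct + noise,
                    ct_reference=base_ct_reference,
                    replicate=rep,
                )
            )
    return wells
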
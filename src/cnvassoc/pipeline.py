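"""End-to-end orchestration: QC -> segment scan -> gene tests -> rare burden.

The pipeline mirrors a dual-caller CNV association study: each caller's
call set is QC-filtered and merged independently, each caller gets its own
post-QC cohort (so the test denominators can differ between callers), the
genome scan is run per caller and intersected into consensus regions, and
the gene-based and rare-CNV analyses run on the primary (caller A) call
set with caller B as confirmation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from . import io as io_formats
from .burden import BurdenConfig, case_specific_genes, pathway_burden, rare_filter, stratified_burden
from .genes import (
    DEFAULT_PAD,
    both_caller_gene_set,
    gene_association,
    gene_carrier_counts,
    mark_supported,
)
from .qc import (
    QcConfig,
    call_filter,
    merge_adjacent,
    post_cnv_sample_filter_A,
    post_cnv_sample_filter_B,
    pre_cnv_sample_filter,
    size_summary,
)
from .segment import (
    annotate_genes,
    build_carrier_matrix,
    consensus_union,
    region_carriers,
    region_concordance,
    regions_from_markers,
    scan_markers,
)
from .stats import SeparationError, logistic_cnvr
from .types import Caller, Status, ValidationError

logger = logging.getLogger("cnvassoc")

__all__ = ["PipelineConfig", "PipelineError", "ReportBundle", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    penncnv_calls: str
    birdsuite_calls: str
    marker_map: str
    samples: str
    gene_bed: str
    output_dir: str
    known_common_bed: str | None = None
    gene_sets: str | None = None
    qc: QcConfig = field(default_factory=QcConfig)
    burden: BurdenConfig = field(default_factory=BurdenConfig)
    alpha: float = 0.05
    gene_pad: int = DEFAULT_PAD
    covariates: tuple[str, ...] = ("age", "sex", "pc1", "pc2", "pc3")
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        qc = QcConfig(**raw.pop("qc", {}))
        burden = BurdenConfig(**raw.pop("burden", {}))
        cfg = cls(qc=qc, burden=burden, **raw)
        cfg.burden.seed = cfg.seed
        return cfg

    def validate(self) -> None:
        for name in ("penncnv_calls", "birdsuite_calls", "marker_map", "samples", "gene_bed"):
            path = getattr(self, name)
            if not Path(path).exists():
                raise ValidationError(f"config: {name} file not found: {path}")
        for name in ("known_common_bed", "gene_sets"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise ValidationError(f"config: {name} file not found: {path}")


@dataclass
class ReportBundle:
    consensus_regions: list
    regions_by_caller: dict
    gene_results: list
    burden_results: list
    case_specific: list
    size_summary: Any
    manifest: dict
    output_dir: Path


def _read_bed_intervals(path: str) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    for g in io_formats.read_gene_bed(path):
        out.setdefault(g.chrom, []).append((g.start, g.end))
    return out


def _read_gene_sets(path: str) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, symbol = line.split("\t")[:2]
            sets.setdefault(name, []).append(symbol)
    return sets


def run_pipeline(cfg: PipelineConfig) -> ReportBundle:
    """Execute every stage in order and write the report bundle.

    Any stage failure aborts with :class:`PipelineError` naming the stage;
    partial outputs are retained next to a ``FAILED`` marker file.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    outdir = Path(cfg.output_dir)
    stage = "config"
    try:
        cfg.validate()
        outdir.mkdir(parents=True, exist_ok=True)
        manifest: dict[str, Any] = {
            "version": __version__,
            "seed": cfg.seed,
            "alpha": cfg.alpha,
            "gene_pad": cfg.gene_pad,
            "qc": dataclasses.asdict(cfg.qc),
            "burden": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(cfg.burden).items()
            },
            "covariates": list(cfg.covariates),
            "stages": {},
        }

        stage = "load"
        samples = io_formats.read_samples(cfg.samples)
        markers = io_formats.read_marker_map(cfg.marker_map)
        genes = io_formats.read_gene_bed(cfg.gene_bed)
        raw_a = io_formats.read_penncnv_calls(cfg.penncnv_calls)
        raw_b = io_formats.read_birdsuite_calls(cfg.birdsuite_calls)
        logger.info("loaded %d A calls, %d B calls, %d samples", len(raw_a), len(raw_b), len(samples))

        stage = "qc"
        pre_kept, pre_dropped = pre_cnv_sample_filter(samples, cfg.qc)
        kept_a, dropped_a = post_cnv_sample_filter_A(pre_kept, cfg.qc)
        kept_b, dropped_b = post_cnv_sample_filter_B(pre_kept, cfg=cfg.qc)
        ids_a = {s.sample_id for s in kept_a}
        ids_b = {s.sample_id for s in kept_b}
        calls_a = merge_adjacent(
            call_filter([c for c in raw_a if c.sample_id in ids_a], cfg.qc),
            cfg.qc.merge_gap_fraction,
        )
        calls_b = merge_adjacent(
            call_filter([c for c in raw_b if c.sample_id in ids_b], cfg.qc),
            cfg.qc.merge_gap_fraction,
        )
        sizes = size_summary(calls_a, kept_a)
        manifest["stages"]["qc"] = {
            "samples_in": len(samples),
            "pre_dropped": {r.value: sum(1 for _, rr in pre_dropped if rr is r) for r in {rr for _, rr in pre_dropped}},
            "kept_A": len(kept_a),
            "kept_B": len(kept_b),
            "raw_calls_A": len(raw_a),
            "raw_calls_B": len(raw_b),
            "filtered_calls_A": len(calls_a),
            "filtered_calls_B": len(calls_b),
            "median_size_case": sizes.median_size_case,
            "median_size_control": sizes.median_size_control,
            "size_p": sizes.p_value,
        }
        logger.info(
            "QC: %d -> A %d samples / %d calls; B %d samples / %d calls",
            len(samples), len(kept_a), len(calls_a), len(kept_b), len(calls_b),
        )

        stage = "scan"
        matrix = build_carrier_matrix(
            calls_a + calls_b, {Caller.A: kept_a, Caller.B: kept_b}, markers
        )
        marker_results = scan_markers(matrix, cfg.alpha)
        all_regions = regions_from_markers(marker_results, matrix)
        regions_by_caller = {
            caller: [r for r in all_regions if caller in r.callers]
            for caller in (Caller.A, Caller.B)
        }
        consensus = consensus_union(
            regions_by_caller[Caller.A], regions_by_caller[Caller.B]
        )
        annotate_genes(consensus, genes)
        for region in consensus:
            region.concordance = region_concordance(region, calls_a, calls_b)
        manifest["stages"]["scan"] = {
            "n_tests": {
                f"{t.value}_{c.value}": matrix.n_tests(t, c)
                for (t, c) in matrix.carriers
            },
            "regions_A": len(regions_by_caller[Caller.A]),
            "regions_B": len(regions_by_caller[Caller.B]),
            "consensus": len(consensus),
        }
        io_formats.write_cnvr_report(consensus, outdir / "cnvr_consensus.tsv")

        stage = "covariate_model"
        model_rows = []
        for region in consensus:
            carriers = region_carriers(region, calls_a)
            carrier_ind = {sid: 1 for sid in carriers}
            try:
                fit = logistic_cnvr(carrier_ind, kept_a, cfg.covariates)
                model_rows.append(
                    {
                        "region": f"chr{region.chrom}:{region.start}-{region.end}",
                        "type": region.cnv_type.value,
                        "OR": fit.odds_ratio,
                        "P": fit.p_value,
                        "error": "",
                    }
                )
            except SeparationError as exc:
                model_rows.append(
                    {
                        "region": f"chr{region.chrom}:{region.start}-{region.end}",
                        "type": region.cnv_type.value,
                        "OR": None,
                        "P": None,
                        "error": str(exc),
                    }
                )
        with open(outdir / "cnvr_multivariate.tsv", "w") as fh:
            fh.write("region\ttype\tOR\tP\terror\n")
            for row in model_rows:
                or_text = "" if row["OR"] is None else f"{row['OR']:.2f}"
                p_text = "" if row["P"] is None else f"{row['P']:.3G}"
                fh.write(
                    f"{row['region']}\t{row['type']}\t{or_text}\t{p_text}\t{row['error']}\n"
                )

        stage = "genes"
        both = both_caller_gene_set(calls_a, calls_b, genes, cfg.gene_pad)
        m = max(1, len(both))
        results_by_caller = {}
        for caller, calls, cohort in (
            (Caller.A, calls_a, kept_a),
            (Caller.B, calls_b, kept_b),
        ):
            counts = gene_carrier_counts(calls, genes, cohort, cfg.gene_pad)
            results_by_caller[caller] = gene_association(counts, m, both)
        gene_results = mark_supported(results_by_caller, cfg.alpha)
        io_formats.write_gene_report(gene_results, outdir / "gene_association.tsv")
        manifest["stages"]["genes"] = {
            "bonferroni_m": m,
            "tested_A": len(results_by_caller[Caller.A]),
        }

        stage = "burden"
        known_common = (
            _read_bed_intervals(cfg.known_common_bed) if cfg.known_common_bed else None
        )
        rare_calls, rare_samples = rare_filter(calls_a, kept_a, known_common, cfg.burden)
        burden_results = stratified_burden(
            rare_calls, rare_samples, genes, cfg.burden, cfg.gene_pad
        )
        if cfg.gene_sets:
            burden_results += pathway_burden(
                rare_calls,
                rare_samples,
                genes,
                _read_gene_sets(cfg.gene_sets),
                cfg.burden,
                cfg.gene_pad,
            )
        specific = case_specific_genes(
            {"A": calls_a, "B": calls_b}, kept_a, genes, cfg.gene_pad
        )
        with open(outdir / "burden.tsv", "w") as fh:
            fh.write("stratum\tstatistic\tcase_mean\tcontrol_mean\tP\tn_perm\texhaustive\n")
            for r in burden_results:
                fh.write(
                    f"{r.stratum}\t{r.statistic}\t{r.case_mean:.4f}\t"
                    f"{r.control_mean:.4f}\t{r.p_value:.4G}\t{r.n_perm}\t{r.exhaustive}\n"
                )
        manifest["stages"]["burden"] = {
            "rare_calls": len(rare_calls),
            "rare_samples": len(rare_samples),
            "case_specific_genes": len(specific),
        }

        stage = "report"
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        return ReportBundle(
            consensus_regions=consensus,
            regions_by_caller=regions_by_caller,
            gene_results=gene_results,
            burden_results=burden_results,
            case_specific=specific,
            size_summary=sizes,
            manifest=manifest,
            output_dir=outdir,
        )
    except Exception as exc:
        try:
            outdir.mkdir(parents=True, exist_ok=True)
            (outdir / "FAILED").write_text(f"stage={stage}\n{exc}\n")
        except OSError:
            pass
        raise PipelineError(stage, exc) from exc
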
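"""End-to-end orchestration: scan -> call -> consensus -> tmb -> burden -> stats.

A :class:`RunConfig` carries every stage parameter plus the input/output
paths; :func:`run_pipeline` executes the stages in order, writing each
stage's artifact, the fully-resolved configuration, and a JSON report with
stage checksums.  Reruns on identical inputs and configuration are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import (
    cohort_burden,
    cohort_stats,
    instability_caller,
    reference_scan,
    tmb_calc,
    variant_consensus,
)
from .synthetic_cohort import CALLER_NAMES
from .tmb_calc import TMBResult

__all__ = ["RunConfig", "load_config", "run_pipeline", "PipelineError"]

logger = logging.getLogger("msiburden.pipeline")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class RunConfig:
    # inputs
    reference: str = ""
    histograms: str = ""
    samples: str = ""
    vcf_dir: str = ""
    pon: str = ""
    out_dir: str = "msiburden_out"
    # reference_scan
    min_repeats: dict[int, int] = field(
        default_factory=lambda: dict(reference_scan.DEFAULT_MIN_REPEATS)
    )
    # instability_caller
    alpha: float = instability_caller.DEFAULT_ALPHA
    min_cov: int = instability_caller.DEFAULT_MIN_COV
    fdr: str | None = instability_caller.DEFAULT_FDR
    # variant_consensus
    min_callers: int = 2
    callers: tuple[str, ...] = CALLER_NAMES
    effect_tag: str = "EFFECT"
    # tmb_calc
    denominator_mb: float = tmb_calc.DEFAULT_DENOMINATOR_MB
    excluded_contigs: tuple[str, ...] = tuple(sorted(tmb_calc.DEFAULT_EXCLUDED_CONTIGS))
    nonsynonymous_only: bool = False
    # cohort_burden
    min_samples: int = cohort_burden.DEFAULT_MIN_SAMPLES
    excluded_histotypes: tuple[str, ...] = ()
    threshold_population: str = "classified"
    # misc
    log_level: str = "INFO"


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration; unknown keys are rejected."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    if "min_repeats" in data:
        data["min_repeats"] = {int(k): int(v) for k, v in data["min_repeats"].items()}
    for key in ("callers", "excluded_contigs", "excluded_histotypes"):
        if key in data:
            data[key] = tuple(data[key])
    return RunConfig(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(path: str, stage: str, what: str) -> Path:
    p = Path(path)
    if not path or not p.exists():
        raise PipelineError(f"stage {stage}: missing {what}: {path!r}")
    return p


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage in order and return the final report dict."""
    logging.basicConfig(
        level=config.log_level,
        format="%(name)s: %(levelname)s: %(message)s",
        force=False,
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)

    # scan ------------------------------------------------------------------
    ref = _require(config.reference, "scan", "reference FASTA")
    loci = reference_scan.scan_fasta(ref, config.min_repeats)
    reference_scan.write_sites(loci, out / "sites.tsv")
    artifacts["sites"] = out / "sites.tsv"
    logger.info("scan: %d microsatellite loci", len(loci))

    # call ------------------------------------------------------------------
    hist_path = _require(config.histograms, "call", "histogram TSV")
    sheet_path = _require(config.samples, "call", "sample sheet")
    hist_df = instability_caller.read_histograms(hist_path)
    sheet = pd.read_csv(sheet_path, sep="\t")
    if not {"sample", "histotype"} <= set(sheet.columns):
        raise PipelineError("stage call: sample sheet needs sample + histotype")
    histotypes = dict(zip(sheet["sample"].astype(str), sheet["histotype"].astype(str)))
    site_keys = {l.locus_key for l in loci}
    known = hist_df["locus_key"].isin(site_keys)
    if not known.all():
        dropped = hist_df.loc[~known, "locus_key"].nunique()
        logger.info("call: %d histogram loci not in the site list; dropped", dropped)
        hist_df = hist_df[known]
    profiles, calls = instability_caller.call_cohort(
        hist_df, histotypes, alpha=config.alpha, min_cov=config.min_cov,
        fdr=config.fdr,
    )
    instability_caller.write_calls(calls, out / "calls.tsv")
    artifacts["calls"] = out / "calls.tsv"
    logger.info("call: %d samples, %d unstable events",
                len(profiles), sum(p.raw_event_count for p in profiles))

    # consensus + tmb --------------------------------------------------------
    tmb_results: list[TMBResult] = []
    mutation_counts: dict[str, int] = {}
    kept_all: list = []
    removed_all: list = []
    if config.vcf_dir:
        vcf_dir = _require(config.vcf_dir, "consensus", "VCF directory")
        pon_keys = (
            {v.key for v in variant_consensus.read_vcf(
                _require(config.pon, "consensus", "PON VCF"))}
            if config.pon else set()
        )
        for sample in sorted(histotypes):
            callsets = {}
            for caller in config.callers:
                vcf = vcf_dir / f"{sample}.{caller}.vcf"
                callsets[caller] = (
                    variant_consensus.read_vcf(
                        _require(str(vcf), "consensus", "caller VCF"),
                        caller=caller, effect_tag=config.effect_tag)
                )
            consensus = variant_consensus.consensus_vote(
                callsets, min_callers=config.min_callers)
            kept, removed = variant_consensus.apply_pon(consensus, pon_keys)
            kept_all.extend(kept)
            removed_all.extend(removed)
            mutation_counts[sample] = len(kept)
            n_cod = tmb_calc.count_coding_mutations(
                kept, excluded_contigs=config.excluded_contigs,
                nonsynonymous_only=config.nonsynonymous_only,
            )
            tmb_results.append(
                tmb_calc.compute_tmb(n_cod, config.denominator_mb, sample=sample)
            )
        variant_consensus.write_vcf(kept_all, out / "consensus.vcf")
        variant_consensus.write_audit(kept_all, removed_all, out / "consensus_audit.tsv")
        tmb_calc.write_tmb(tmb_results, out / "tmb.tsv")
        artifacts["consensus"] = out / "consensus.vcf"
        artifacts["tmb"] = out / "tmb.tsv"
        logger.info("tmb: %d samples", len(tmb_results))

    # burden -----------------------------------------------------------------
    panel = cohort_burden.build_panel(
        profiles, min_samples=config.min_samples,
        excluded_histotypes=config.excluded_histotypes,
    )
    if panel.size == 0:
        raise PipelineError(
            "stage burden: recurrent panel is empty at "
            f"min_samples={config.min_samples}"
        )
    records = [cohort_burden.msi_burden(p, panel) for p in profiles]
    records, threshold = cohort_burden.classify_cohort(
        records, threshold_population=config.threshold_population
    )
    cohort_burden.write_panel(panel, out / "panel.tsv")
    cohort_burden.write_burden(records, out / "burden.tsv")
    summary = cohort_burden.write_summary(records, threshold, panel,
                                          out / "burden_summary.json")
    artifacts["panel"] = out / "panel.tsv"
    artifacts["burden"] = out / "burden.tsv"
    logger.info("burden: panel %d loci, threshold %s", panel.size,
                f"{100 * threshold:.3g}%" if threshold is not None else "n/a")

    # stats ------------------------------------------------------------------
    report: dict = {"burden_summary": summary}
    if tmb_results:
        report["stats"] = cohort_stats.build_report(
            records, tmb_results, mutation_counts, threshold=threshold
        )
    report["checksums"] = {k: _sha256(p) for k, p in sorted(artifacts.items())}
    cohort_stats.write_report(report, out / "report.json")
    return report
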
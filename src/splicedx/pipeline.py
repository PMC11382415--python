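"""End-to-end orchestration of the two prioritization strategies.

``run_g2p`` chains junction outlier calling -> event classification ->
variant cascade -> +/-25 bp windows -> intersection -> ranking.
``run_p2g`` chains junction outlier calling -> classification -> gene-panel
restriction -> ranking. Both log per-stage counts and optionally write
intermediate tables; reruns on identical inputs are deterministic.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field

import pandas as pd

from splicedx.annotation import TranscriptSet, load_annotation
from splicedx.ase import SkewSummary, chromosome_skew_summary, read_allele_counts
from splicedx.events import SpliceEvent, annotate_consequence, classify_novel_junctions
from splicedx.expression import (
    ExpressionMatrix,
    MicrodeletionSignal,
    OutlierCall,
    assessability_class,
    call_outliers,
    filter_low_expression,
    scan_microdeletions,
)
from splicedx.junctions import build_junction_matrix, call_novel_junctions
from splicedx.prioritize import (
    Candidate,
    GenePanel,
    filter_events_by_panel,
    intersect_variants_events,
    make_variant_windows,
    rank_candidates,
)
from splicedx.variants import FilterConfig, parse_annotated_vcf, run_filter_cascade

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and thresholds for one pipeline run."""

    annotation: str
    junction_files: list[tuple[str, str]] = field(default_factory=list)
    vcfs: dict[str, str] = field(default_factory=dict)       # proband -> VCF path
    probands: list[str] = field(default_factory=list)
    counts: str | None = None
    tpm: str | None = None
    allele_counts: str | None = None
    panel: str | None = None
    outdir: str | None = None
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    min_reads: int = 5
    max_other: int = 2
    window_pad: int = 25
    expression_alpha: float = 0.05
    min_deletion_genes: int = 3
    batch_map: dict[str, str] | None = None

    def check_inputs(self) -> None:
        paths = [self.annotation, *(p for _, p in self.junction_files),
                 *self.vcfs.values()]
        for opt in (self.counts, self.tpm, self.allele_counts, self.panel):
            if opt is not None:
                paths.append(opt)
        for p in paths:
            if not os.path.exists(p):
                raise FileNotFoundError(f"pipeline input not found: {p}")


@dataclass
class CandidateReport:
    """Ranked candidates plus per-stage counts for one strategy run."""

    strategy: str
    candidates: list[Candidate]
    stage_counts: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.candidates:
            e = c.event
            rows.append(
                {
                    "proband": c.proband_id,
                    "gene": e.gene_symbol,
                    "transcript": e.transcript_id,
                    "event_class": e.event_class,
                    "chrom": e.affected_region.chrom,
                    "start": e.affected_region.start,
                    "end": e.affected_region.end,
                    "delta_nt": e.delta_length_nt,
                    "support": e.proband_support,
                    "strategy": c.strategy,
                    "variant": (
                        f"{c.variant.chrom}:{c.variant.pos}{c.variant.ref}>{c.variant.alt}"
                        if c.variant is not None
                        else ""
                    ),
                    "panel": c.panel_name or "",
                    "frame": c.consequence.frame if c.consequence else "",
                    "description": c.consequence.description if c.consequence else "",
                }
            )
        return pd.DataFrame(rows)


def _classified_events(
    cfg: RunConfig, ts: TranscriptSet, proband: str, matrix
) -> tuple[list, list[SpliceEvent]]:
    calls = call_novel_junctions(
        matrix, proband, min_reads=cfg.min_reads, max_other=cfg.max_other,
        batch_map=cfg.batch_map,
    )
    events = [
        e for e in classify_novel_junctions(calls, ts)
        if e.event_class != "unclassified"
    ]
    return calls, events


def _attach_consequences(events: list[SpliceEvent], ts: TranscriptSet,
                         cands: list[Candidate]) -> None:
    tx = {t.transcript_id: t for t in ts}
    for c in cands:
        t = tx.get(c.event.transcript_id)
        if t is not None:
            c.consequence = annotate_consequence(c.event, t)


def _write(report: CandidateReport, outdir: str | None, name: str) -> None:
    if outdir is None:
        return
    os.makedirs(outdir, exist_ok=True)
    report.to_frame().to_csv(os.path.join(outdir, f"{name}.tsv"), sep="\t", index=False)
    pd.Series(report.stage_counts).to_csv(
        os.path.join(outdir, f"{name}.stage_counts.tsv"), sep="\t", header=False
    )


def run_g2p(cfg: RunConfig) -> CandidateReport:
    """Genotype-to-phenotype: variant-anchored event prioritization."""
    cfg.check_inputs()
    ts = load_annotation(cfg.annotation)
    matrix = build_junction_matrix(cfg.junction_files, ts)
    probands = cfg.probands or sorted(cfg.vcfs)
    counts = {"novel_junctions": 0, "classified_events": 0,
              "variants_input": 0, "variants_passed": 0, "candidates": 0}
    all_cands: list[Candidate] = []
    for proband in probands:
        calls, events = _classified_events(cfg, ts, proband, matrix)
        counts["novel_junctions"] += len(calls)
        counts["classified_events"] += len(events)
        if proband not in cfg.vcfs:
            logger.warning("no VCF for proband %s; skipping variant stage", proband)
            continue
        variants = parse_annotated_vcf(cfg.vcfs[proband], sample=proband)
        counts["variants_input"] += len(variants)
        passed, _audit = run_filter_cascade(variants, cfg.filter_config)
        counts["variants_passed"] += len(passed)
        windows = make_variant_windows(passed, pad=cfg.window_pad)
        cands = intersect_variants_events(events, windows)
        _attach_consequences(events, ts, cands)
        all_cands.extend(cands)
        logger.info(
            "g2p %s: %d novel junctions, %d events, %d/%d variants passed, %d candidates",
            proband, len(calls), len(events), len(passed), len(variants), len(cands),
        )
    ranked = rank_candidates(all_cands)
    counts["candidates"] = len(ranked)
    report = CandidateReport("genotype_to_phenotype", ranked, counts)
    _write(report, cfg.outdir, "g2p_candidates")
    return report


def run_p2g(cfg: RunConfig, panel: GenePanel | None = None) -> CandidateReport:
    """Phenotype-to-genotype: gene-panel-restricted event prioritization."""
    cfg.check_inputs()
    if panel is None:
        if cfg.panel is None:
            raise ValueError("p2g needs a gene panel")
        panel = GenePanel.from_tsv(cfg.panel)
    if not panel.symbols:
        raise ValueError("p2g panel is empty")
    ts = load_annotation(cfg.annotation)
    matrix = build_junction_matrix(cfg.junction_files, ts)
    probands = cfg.probands or sorted(cfg.vcfs) or [s for s, _ in cfg.junction_files]
    counts = {"novel_junctions": 0, "classified_events": 0, "candidates": 0}
    all_cands: list[Candidate] = []
    for proband in probands:
        calls, events = _classified_events(cfg, ts, proband, matrix)
        counts["novel_junctions"] += len(calls)
        counts["classified_events"] += len(events)
        cands = filter_events_by_panel(events, panel)
        _attach_consequences(events, ts, cands)
        all_cands.extend(cands)
        logger.info("p2g %s: %d events, %d in panel", proband, len(events), len(cands))
    ranked = rank_candidates(all_cands)
    counts["candidates"] = len(ranked)
    report = CandidateReport("phenotype_to_genotype", ranked, counts)
    _write(report, cfg.outdir, "p2g_candidates")
    return report


@dataclass
class ExpressionReport:
    outliers: list[OutlierCall]
    microdeletions: list[MicrodeletionSignal]
    assessability: pd.DataFrame


def run_expression(cfg: RunConfig) -> ExpressionReport:
    """Expression outliers, microdeletion scan, and TPM assessability."""
    cfg.check_inputs()
    if cfg.counts is None:
        raise ValueError("expression analysis needs a counts table")
    m = ExpressionMatrix.from_tsv(cfg.counts, tpm_path=cfg.tpm)
    m = filter_low_expression(m)
    outliers = call_outliers(m, alpha=cfg.expression_alpha)
    signals = scan_microdeletions(outliers, m.gene_info, min_genes=cfg.min_deletion_genes)
    if m.tpm is not None:
        med = m.tpm.median(axis=1)
        assess = pd.DataFrame(
            {
                "gene": med.index,
                "median_tpm": med.values,
                "assessability": [assessability_class(v) for v in med.values],
            }
        )
    else:
        assess = pd.DataFrame(columns=["gene", "median_tpm", "assessability"])
    if cfg.outdir is not None:
        os.makedirs(cfg.outdir, exist_ok=True)
        pd.DataFrame([dataclasses.asdict(o) for o in outliers]).to_csv(
            os.path.join(cfg.outdir, "expression_outliers.tsv"), sep="\t", index=False
        )
        pd.DataFrame([dataclasses.asdict(s) for s in signals]).to_csv(
            os.path.join(cfg.outdir, "microdeletions.tsv"), sep="\t", index=False
        )
        assess.to_csv(os.path.join(cfg.outdir, "assessability.tsv"), sep="\t", index=False)
    return ExpressionReport(outliers, signals, assess)


def run_ase(cfg: RunConfig) -> list[SkewSummary]:
    """Per-(sample, chromosome) allelic-skew summaries from allele counts."""
    cfg.check_inputs()
    if cfg.allele_counts is None:
        raise ValueError("ASE analysis needs an allele-count table")
    counts = read_allele_counts(cfg.allele_counts)
    groups: dict[tuple[str, str], list] = {}
    for c in counts:
        groups.setdefault((c.sample, c.chrom), []).append(c)
    summaries = [chromosome_skew_summary(v) for _, v in sorted(groups.items())]
    if cfg.outdir is not None:
        os.makedirs(cfg.outdir, exist_ok=True)
        pd.DataFrame([dataclasses.asdict(s) for s in summaries]).to_csv(
            os.path.join(cfg.outdir, "ase_skew.tsv"), sep="\t", index=False
        )
    return summaries
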
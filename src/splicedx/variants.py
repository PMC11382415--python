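"""RNA-derived variant call filtering.

Variant calling from RNA-seq produces many spurious calls; this module
applies a two-stage cascade to VEP/SpliceAI-annotated VCFs:

site stage       QUAL >= 50, sample DP >= 8, GQ >= 16, FS <= 30, QD >= 2
annotation stage MAF < 0.01 (missing treated as rare), max SpliceAI delta
                 >= 0.2, protein-coding gene, single-nucleotide variant

Boundary inclusivity follows the criteria's wording literally: "less than
eight reads" excluded means DP = 8 passes; "lower than 16" means GQ = 16
passes; "greater than 30" means FS = 30 passes; "at least two" kept means
QD = 2 passes; MAF = 0.01 fails ("less than 0.01"); delta 0.2 passes.
Indels are excluded outright — the majority are low quality in RNA-seq
calls. Missing SpliceAI annotation fails the delta criterion (the cascade is
splice-evidence-driven); missing MAF passes with a flag (absence from
population databases is itself evidence of rarity). Both are overridable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
import pysam

logger = logging.getLogger(__name__)

SITE_CRITERIA = ("min_qual", "min_depth", "min_gq", "max_fs", "min_qd")
ANNOTATION_CRITERIA = ("max_maf", "min_delta", "protein_coding", "snv_only")
ALL_CRITERIA = SITE_CRITERIA + ANNOTATION_CRITERIA


@dataclass(frozen=True)
class SpliceAIScores:
    """Four SpliceAI delta scores (acceptor/donor gain/loss), each in [0, 1]."""

    ds_ag: float
    ds_al: float
    ds_dg: float
    ds_dl: float
    positions: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        for name in ("ds_ag", "ds_al", "ds_dg", "ds_dl"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


def max_delta(s: SpliceAIScores) -> float:
    """Maximum of the four delta scores — the per-variant splice-impact score."""
    return max(s.ds_ag, s.ds_al, s.ds_dg, s.ds_dl)


@dataclass
class VariantCall:
    """One ALT allele of a variant record with site, sample and annotation metrics."""

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float | None = None
    depth: int | None = None
    gq: int | None = None
    fs: float | None = None
    qd: float | None = None
    gene_symbol: str | None = None
    gene_type: str | None = None
    consequence: str | None = None
    maf: float | None = None
    spliceai: SpliceAIScores | None = None
    sample: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.maf is not None and not 0.0 <= self.maf <= 1.0:
            raise ValueError(f"maf={self.maf} outside [0, 1]")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the two-stage cascade (defaults as documented above)."""

    min_qual: float = 50.0
    min_depth: int = 8
    min_gq: int = 16
    max_fs: float = 30.0
    min_qd: float = 2.0
    max_maf: float = 0.01
    min_delta: float = 0.2
    require_protein_coding: bool = True
    snv_only: bool = True
    missing_maf_passes: bool = True
    missing_spliceai_fails: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_delta <= 1.0:
            raise ValueError("min_delta must be in [0, 1]")


@dataclass
class FilterResult:
    """Outcome of one cascade stage for one call."""

    passed: bool
    failed_criteria: list[str] = field(default_factory=list)
    missing: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.passed == (not self.failed_criteria)


@dataclass(frozen=True)
class AnnotationKeys:
    """INFO key names for the consumed annotations (VEP dialects vary)."""

    gene: str = "GENE"
    gene_type: str = "GENE_TYPE"
    consequence: str = "CSQ"
    maf: str = "MAF"
    ds_ag: str = "DS_AG"
    ds_al: str = "DS_AL"
    ds_dg: str = "DS_DG"
    ds_dl: str = "DS_DL"


def _scalar(value, index: int):
    """Pick the per-allele element from a tuple INFO value, else the scalar."""
    if isinstance(value, tuple):
        return value[index] if index < len(value) else value[0]
    return value


def parse_annotated_vcf(
    path: str,
    sample: str | None = None,
    keys: AnnotationKeys = AnnotationKeys(),
) -> list[VariantCall]:
    """Parse an annotated VCF into per-ALT-allele :class:`VariantCall` records.

    Multi-allelic records are split; per-allele INFO values (Number=A) are
    distributed accordingly. Missing FORMAT GQ/DP for the sample leaves the
    fields None (they then auto-fail their criteria). Malformed records are
    skipped with a warning.
    """
    calls: list[VariantCall] = []
    with pysam.VariantFile(path) as vf:
        if sample is None:
            samples = list(vf.header.samples)
            sample = samples[0] if samples else None
        for rec in vf:
            try:
                calls.extend(_record_to_calls(rec, sample, keys))
            except Exception as exc:  # malformed record
                logger.warning("skipping malformed VCF record at %s:%s (%s)",
                               rec.chrom, rec.pos, exc)
    return calls


def _record_to_calls(rec, sample: str | None, keys: AnnotationKeys) -> list[VariantCall]:
    info = rec.info
    fmt = rec.samples[sample] if sample is not None and sample in rec.samples else None
    gq = dp = None
    if fmt is not None:
        gq = fmt.get("GQ")
        dp = fmt.get("DP")
    out = []
    for i, alt in enumerate(rec.alts or ()):
        sai = None
        if keys.ds_ag in info:
            sai = SpliceAIScores(
                ds_ag=float(_scalar(info[keys.ds_ag], i)),
                ds_al=float(_scalar(info[keys.ds_al], i)),
                ds_dg=float(_scalar(info[keys.ds_dg], i)),
                ds_dl=float(_scalar(info[keys.ds_dl], i)),
            )
        maf = info.get(keys.maf)
        gt_raw = info.get(keys.gene_type)
        gene_raw = info.get(keys.gene)
        csq_raw = info.get(keys.consequence)
        out.append(
            VariantCall(
                chrom=rec.chrom,
                pos=rec.pos,
                ref=rec.ref,
                alt=alt,
                qual=float(rec.qual) if rec.qual is not None else None,
                depth=int(dp) if dp is not None else None,
                gq=int(gq) if gq is not None else None,
                fs=float(info["FS"]) if "FS" in info else None,
                qd=float(info["QD"]) if "QD" in info else None,
                gene_symbol=str(_scalar(gene_raw, i)) if gene_raw is not None else None,
                gene_type=str(_scalar(gt_raw, i)) if gt_raw is not None else None,
                consequence=str(_scalar(csq_raw, i)) if csq_raw is not None else None,
                maf=float(_scalar(maf, i)) if maf is not None else None,
                spliceai=sai,
                sample=sample,
            )
        )
    return out


def apply_site_filters(v: VariantCall, c: FilterConfig = FilterConfig()) -> FilterResult:
    """Site/sample quality stage. All criteria evaluated, never short-circuited."""
    failed: list[str] = []
    missing: list[str] = []

    def check(name: str, value, ok) -> None:
        if value is None:
            failed.append(name)
            missing.append(name)
        elif not ok(value):
            failed.append(name)

    check("min_qual", v.qual, lambda x: x >= c.min_qual)
    check("min_depth", v.depth, lambda x: x >= c.min_depth)
    check("min_gq", v.gq, lambda x: x >= c.min_gq)
    check("max_fs", v.fs, lambda x: x <= c.max_fs)
    check("min_qd", v.qd, lambda x: x >= c.min_qd)
    return FilterResult(passed=not failed, failed_criteria=failed, missing=missing)


def apply_annotation_filters(
    v: VariantCall, c: FilterConfig = FilterConfig()
) -> FilterResult:
    """Annotation stage: rarity, splice evidence, gene biotype, SNV-only."""
    failed: list[str] = []
    missing: list[str] = []

    if v.maf is None:
        if not c.missing_maf_passes:
            failed.append("max_maf")
            missing.append("max_maf")
    elif not v.maf < c.max_maf:
        failed.append("max_maf")

    if v.spliceai is None:
        if c.missing_spliceai_fails:
            failed.append("min_delta")
            missing.append("min_delta")
    elif not max_delta(v.spliceai) >= c.min_delta:
        failed.append("min_delta")

    if c.require_protein_coding and v.gene_type != "protein_coding":
        failed.append("protein_coding")
        if v.gene_type is None:
            missing.append("protein_coding")

    if c.snv_only and not v.is_snv:
        failed.append("snv_only")

    return FilterResult(passed=not failed, failed_criteria=failed, missing=missing)


def run_filter_cascade(
    calls: list[VariantCall], c: FilterConfig = FilterConfig()
) -> tuple[list[VariantCall], pd.DataFrame]:
    """Run both stages over ``calls``.

    Returns (passing calls in input order, audit table). The audit table has
    one row per criterion with the number of calls failing it, plus summary
    rows ``input``, ``passed_site``, ``passed``.
    """
    fail_counts = {name: 0 for name in ALL_CRITERIA}
    passed_site = 0
    passed: list[VariantCall] = []
    for v in calls:
        site = apply_site_filters(v, c)
        ann = apply_annotation_filters(v, c)
        for name in site.failed_criteria + ann.failed_criteria:
            fail_counts[name] += 1
        if site.passed:
            passed_site += 1
        if site.passed and ann.passed:
            passed.append(v)
    rows = [{"criterion": k, "n_failed": n} for k, n in fail_counts.items()]
    rows.append({"criterion": "input", "n_failed": len(calls)})
    rows.append({"criterion": "passed_site", "n_failed": passed_site})
    rows.append({"criterion": "passed", "n_failed": len(passed)})
    audit = pd.DataFrame(rows)
    return passed, audit


def filter_variant(v: VariantCall, c: FilterConfig = FilterConfig()) -> FilterResult:
    """Both stages for a single call; failed criteria from both are merged."""
    site = apply_site_filters(v, c)
    ann = apply_annotation_filters(v, c)
    return FilterResult(
        passed=site.passed and ann.passed,
        failed_criteria=site.failed_criteria + ann.failed_criteria,
        missing=site.missing + ann.missing,
    )
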
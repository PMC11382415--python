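"""Seeded synthetic cohorts with injected ground truth.

Generates everything the pipeline consumes — a fixture GTF, per-sample
STAR-style junction files, per-base coverage tracks, annotated VCFs,
negative-binomial expression matrices with TPM, and allele-count tables —
plus a manifest of every injection, so each analysis stage is testable
without patient data.

The cohort emulates the study conditions the pipeline assumes: a few dozen
blood RNA-seq samples sharing annotated junctions with Poisson count noise,
individual probands carrying private aberrant-splicing events supported by
at least five reads, causal SNVs within 25 bp of the event boundaries
(drawn so they pass the variant cascade unless deliberately spoiled),
decoy variants each failing exactly one cascade criterion, expression
outliers and contiguous deletion blocks, and binomial allele counts with
optional complete parental skew. Identical seeds give byte-identical
output files.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np

from splicedx.annotation import GenomicInterval, TranscriptModel, TranscriptSet, introns_of

# decoy kinds -> the single cascade criterion each is built to fail
DECOY_KINDS = (
    "min_qual",
    "min_depth",
    "min_gq",
    "max_fs",
    "min_qd",
    "max_maf",
    "min_delta",
    "protein_coding",
    "snv_only",
)

EVENT_CLASSES = (
    "exon_skipping",
    "cryptic_exon",
    "intron_retention",
    "alt_donor",
    "alt_acceptor",
)


@dataclass
class InjectedEvent:
    """One aberrant-splicing injection: who, where, what, how supported.

    ``variant_fail`` names a cascade criterion the causal variant should
    deliberately fail (e.g. ``"min_gq"`` reproduces the scenario where a
    genuine causal variant is lost to strict quality filters and the event
    is only recoverable through a gene panel). None = the variant passes.
    """

    proband: str
    gene: str
    event_class: str
    support: int = 12
    variant_fail: str | None = None

    def __post_init__(self) -> None:
        if self.event_class not in EVENT_CLASSES:
            raise ValueError(f"unknown event class {self.event_class!r}")
        if self.support < 0:
            raise ValueError("support must be >= 0")


@dataclass
class SimConfig:
    """Generator configuration; defaults are the emulated study conditions."""

    n_samples: int = 30                    # one sequencing batch
    n_genes: int = 6                       # splicing fixture genes
    exons_per_gene: int = 6
    exon_length: int = 150
    intron_length: int = 1200
    baseline_junction_mean: float = 50.0   # Poisson mean, annotated junctions
    junction_leak_mean: float = 0.0        # Poisson leak of novel junctions into controls
    injected_events: list[InjectedEvent] = field(default_factory=list)
    variant_offset: int = 10               # bp from event boundary, <= 25
    decoy_variants: bool = True
    intron_retention_ratio: float = 0.5    # proband intron/exon coverage ratio
    control_retention_ratio: float = 0.02
    exon_coverage_depth: float = 60.0
    n_expr_genes: int = 200
    expr_mean_range: tuple[float, float] = (50.0, 500.0)
    expr_dispersion: float = 0.05
    outlier_injections: list[tuple[str, str, float]] = field(default_factory=list)
    # (sample, gene, log2 fold-change); gene "auto<i>" picks the i-th expr gene
    deletion_blocks: list[tuple[str, int, int]] = field(default_factory=list)
    # (sample, first expr-gene index, n consecutive genes)
    deletion_factor: float = 0.25
    n_ase_snps: int = 9
    ase_depth_mean: float = 40.0
    ase_minor_fraction: float = 0.0        # 0 = complete monoallelic skew
    ase_skewed_parent: str = "paternal"
    ase_sample: str | None = None
    seed: int = 0

    def sample_ids(self) -> list[str]:
        return [f"S{i + 1:03d}" for i in range(self.n_samples)]

    def gene_names(self) -> list[str]:
        return [f"GENE{i + 1}" for i in range(self.n_genes)]

    def validate(self) -> None:
        samples = set(self.sample_ids())
        genes = set(self.gene_names())
        by_gene: dict[str, list[InjectedEvent]] = {}
        for ev in self.injected_events:
            if ev.proband not in samples:
                raise ValueError(f"event proband {ev.proband!r} not in cohort")
            if ev.gene not in genes:
                raise ValueError(f"event gene {ev.gene!r} not in fixture annotation")
            by_gene.setdefault(ev.gene, []).append(ev)
        for gene, evs in by_gene.items():
            if len(evs) > 1:
                raise ValueError(f"multiple events injected into {gene}; one per gene")
        for sample, start, n in self.deletion_blocks:
            if sample not in samples:
                raise ValueError(f"deletion sample {sample!r} not in cohort")
            if start < 0 or start + n > self.n_expr_genes:
                raise ValueError("deletion block outside expression gene range")
        for sample, _gene, _fc in self.outlier_injections:
            if sample not in samples:
                raise ValueError(f"outlier sample {sample!r} not in cohort")
        if not 0 <= self.variant_offset <= 25:
            raise ValueError("variant_offset must be within 0..25")


@dataclass
class SimTruth:
    """Manifest of every injection, with exact coordinates and expected labels."""

    events: list[dict] = field(default_factory=list)
    variants: list[dict] = field(default_factory=list)
    outliers: list[dict] = field(default_factory=list)
    deletions: list[dict] = field(default_factory=list)
    ase: list[dict] = field(default_factory=list)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str) -> "SimTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def _build_annotation(c: SimConfig) -> TranscriptSet:
    """Deterministic gene layout: evenly spaced plus-strand genes on chr1,
    plus one non-coding decoy gene at the end."""
    transcripts = []
    unit = c.exon_length + c.intron_length
    for gi, gene in enumerate(c.gene_names()):
        start = 100_000 + gi * (c.exons_per_gene * unit + 50_000)
        exons = [
            GenomicInterval(
                "chr1",
                start + k * unit,
                start + k * unit + c.exon_length - 1,
                "+",
            )
            for k in range(c.exons_per_gene)
        ]
        transcripts.append(
            TranscriptModel(
                transcript_id=f"TX{gi + 1}",
                gene_symbol=gene,
                gene_type="protein_coding",
                strand="+",
                exons=exons,
                cds_start=exons[0].start,
                cds_end=exons[-1].end,
            )
        )
    # non-coding decoy gene for the protein_coding filter
    nc_start = 100_000 + c.n_genes * (c.exons_per_gene * unit + 50_000)
    transcripts.append(
        TranscriptModel(
            transcript_id="TXNC",
            gene_symbol="LINC01",
            gene_type="lincRNA",
            strand="+",
            exons=[
                GenomicInterval("chr1", nc_start, nc_start + 400, "+"),
                GenomicInterval("chr1", nc_start + 1500, nc_start + 1900, "+"),
            ],
        )
    )
    return TranscriptSet(transcripts)


def _write_gtf(ts: TranscriptSet, path: str) -> None:
    with open(path, "w") as fh:
        for t in ts:
            attrs = (
                f'gene_id "{t.gene_symbol}"; transcript_id "{t.transcript_id}"; '
                f'gene_name "{t.gene_symbol}"; gene_type "{t.gene_type}";'
            )
            for exon in t.exons:
                fh.write(
                    f"{exon.chrom}\tsim\texon\t{exon.start}\t{exon.end}\t.\t{t.strand}\t.\t{attrs}\n"
                )
            if t.cds_start is not None:
                for exon in t.exons:
                    lo = max(exon.start, t.cds_start)
                    hi = min(exon.end, t.cds_end)
                    if lo <= hi:
                        fh.write(
                            f"{exon.chrom}\tsim\tCDS\t{lo}\t{hi}\t.\t{t.strand}\t.\t{attrs}\n"
                        )


def _event_geometry(ev: InjectedEvent, t: TranscriptModel) -> dict:
    """Novel junction(s), affected region, expected delta, and the causal
    variant's anchor boundary for one injected event.

    Events are built around intron 2 / exon 3 (1-based genomic order) so
    flanking structure exists on both sides.
    """
    introns = introns_of(t)
    i2, i3 = introns[1], introns[2]
    exon3 = t.exons[2]
    chrom = t.chrom
    if ev.event_class == "exon_skipping":
        j = (chrom, i2.start, i3.end, "+")
        return {
            "junctions": [j],
            "region": (exon3.start, exon3.end),
            "delta": -len(exon3),
            "anchor": exon3.start,
        }
    if ev.event_class == "cryptic_exon":
        ce_start = i2.start + 400
        ce_end = ce_start + 79  # 80 nt pseudoexon
        j1 = (chrom, i2.start, ce_start - 1, "+")
        j2 = (chrom, ce_end + 1, i2.end, "+")
        return {
            "junctions": [j1, j2],
            "region": (ce_start, ce_end),
            "delta": 80,
            "anchor": ce_start,
        }
    if ev.event_class == "alt_donor":
        # donor moves 60 bp into the intron -> intronic inclusion
        j = (chrom, i2.start + 60, i2.end, "+")
        return {
            "junctions": [j],
            "region": (i2.start, i2.start + 59),
            "delta": 60,
            "anchor": i2.start,
        }
    if ev.event_class == "alt_acceptor":
        j = (chrom, i2.start, i2.end - 45, "+")
        return {
            "junctions": [j],
            "region": (i2.end - 44, i2.end),
            "delta": 45,
            "anchor": i2.end - 44,
        }
    # intron retention: no junction; coverage-based over intron 2
    return {
        "junctions": [],
        "region": (i2.start, i2.end),
        "delta": len(i2),
        "anchor": i2.start,
    }


def _write_junction_files(
    c: SimConfig, ts: TranscriptSet, geoms: dict[str, dict],
    outdir: str, rng: np.random.Generator,
) -> dict[str, str]:
    """Per-sample SJ.out.tab files: annotated junctions in everyone, novel
    junctions in their proband (Poisson leak <= configured into others)."""
    samples = c.sample_ids()
    annotated = sorted(ts.known_junctions)
    strand_code = {"+": "1", "-": "2", ".": "0"}
    base = rng.poisson(c.baseline_junction_mean, size=(len(annotated), len(samples)))
    base = np.maximum(base, 1)  # annotated junctions are always observed
    novel_rows: dict[str, dict[tuple, int]] = {s: {} for s in samples}
    for key, g in geoms.items():
        ev: InjectedEvent = g["event"]
        for j in g["junctions"]:
            novel_rows[ev.proband][j] = ev.support
            if c.junction_leak_mean > 0:
                for s in samples:
                    if s != ev.proband:
                        leak = int(rng.poisson(c.junction_leak_mean))
                        if leak:
                            novel_rows[s][j] = leak
    paths = {}
    for si, s in enumerate(samples):
        rows = []
        for ji, j in enumerate(annotated):
            rows.append((j, int(base[ji, si])))
        for j, n in novel_rows[s].items():
            rows.append((j, n))
        rows.sort(key=lambda r: (r[0][0], r[0][1], r[0][2]))
        path = os.path.join(outdir, f"{s}.SJ.out.tab")
        with open(path, "w") as fh:
            for (chrom, jstart, jend, strand), n in rows:
                fh.write(
                    f"{chrom}\t{jstart}\t{jend}\t{strand_code[strand]}\t1\t0\t{n}\t0\t30\n"
                )
        paths[s] = path
    return paths


def _write_coverage(
    c: SimConfig, ts: TranscriptSet, geoms: dict[str, dict], outdir: str,
    rng: np.random.Generator,
) -> str | None:
    """Depth TSV (chrom, pos, one column per sample) spanning each
    intron-retention event's exon2-intron2-exon3 window."""
    ir = [g for g in geoms.values() if g["event"].event_class == "intron_retention"]
    if not ir:
        return None
    samples = c.sample_ids()
    path = os.path.join(outdir, "coverage.tsv")
    with open(path, "w") as fh:
        fh.write("chrom\tpos\t" + "\t".join(samples) + "\n")
        for g in ir:
            t = g["transcript"]
            lo, hi = t.exons[1].start, t.exons[2].end
            intron = introns_of(t)[1]
            for pos in range(lo, hi + 1):
                in_intron = intron.start <= pos <= intron.end
                vals = []
                for s in samples:
                    ratio = (
                        c.intron_retention_ratio
                        if (s == g["event"].proband and in_intron)
                        else (c.control_retention_ratio if in_intron else 1.0)
                    )
                    depth = rng.poisson(c.exon_coverage_depth * ratio)
                    vals.append(str(int(depth) if in_intron else max(int(depth), 1)))
                fh.write(f"{t.chrom}\t{pos}\t" + "\t".join(vals) + "\n")
    return path


_VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=FS,Number=1,Type=Float,Description="Phred-scaled strand bias">
##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=GENE_TYPE,Number=1,Type=String,Description="Gene biotype">
##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence class">
##INFO=<ID=MAF,Number=1,Type=Float,Description="Population minor allele frequency">
##INFO=<ID=DS_AG,Number=1,Type=Float,Description="SpliceAI acceptor gain delta">
##INFO=<ID=DS_AL,Number=1,Type=Float,Description="SpliceAI acceptor loss delta">
##INFO=<ID=DS_DG,Number=1,Type=Float,Description="SpliceAI donor gain delta">
##INFO=<ID=DS_DL,Number=1,Type=Float,Description="SpliceAI donor loss delta">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##contig=<ID=chr1,length=100000000>
"""


def _passing_metrics() -> dict:
    return dict(qual=200.0, dp=40, gq=99, fs=2.0, qd=20.0, maf=0.0001,
                sai=(0.85, 0.02, 0.8, 0.05), gene_type="protein_coding",
                ref="C", alt="T")


def _decoy_metrics(kind: str) -> dict:
    m = _passing_metrics()
    if kind == "min_qual":
        m["qual"] = 30.0
    elif kind == "min_depth":
        m["dp"] = 4
    elif kind == "min_gq":
        m["gq"] = 6
    elif kind == "max_fs":
        m["fs"] = 45.0
    elif kind == "min_qd":
        m["qd"] = 1.0
    elif kind == "max_maf":
        m["maf"] = 0.05
    elif kind == "min_delta":
        m["sai"] = (0.11, 0.0, 0.09, 0.0)
    elif kind == "protein_coding":
        m["gene_type"] = "lincRNA"
    elif kind == "snv_only":
        m["ref"], m["alt"] = "AT", "A"
    else:
        raise ValueError(f"unknown decoy kind {kind!r}")
    return m


def _write_vcfs(
    c: SimConfig, ts: TranscriptSet, geoms: dict[str, dict], outdir: str,
) -> tuple[dict[str, str], list[dict]]:
    """One VCF per proband: its causal variant(s) plus the decoy battery.

    Decoys sit in the non-coding decoy gene's region (or carry its biotype),
    far from any injected event, so genotype-to-phenotype intersection can
    never pick them up.
    """
    nc = ts.transcripts_of_gene("LINC01")[0]
    decoy_base = nc.exons[0].start + 50
    probands = sorted({g["event"].proband for g in geoms.values()})
    variant_truth: list[dict] = []
    paths: dict[str, str] = {}
    for proband in probands:
        rows = []
        for key, g in sorted(geoms.items()):
            ev: InjectedEvent = g["event"]
            if ev.proband != proband:
                continue
            m = _passing_metrics() if ev.variant_fail is None else _decoy_metrics(ev.variant_fail)
            m["gene"] = ev.gene
            pos = g["anchor"] + c.variant_offset
            rows.append((pos, m))
            variant_truth.append(
                {
                    "proband": proband,
                    "gene": ev.gene,
                    "chrom": "chr1",
                    "pos": pos,
                    "role": "causal",
                    "fails": ev.variant_fail,
                    "event_class": ev.event_class,
                }
            )
        if c.decoy_variants:
            for di, kind in enumerate(DECOY_KINDS):
                m = _decoy_metrics(kind)
                m["gene"] = "LINC01" if kind == "protein_coding" else "DECOY"
                pos = decoy_base + di * 17
                rows.append((pos, m))
                variant_truth.append(
                    {
                        "proband": proband,
                        "gene": m["gene"],
                        "chrom": "chr1",
                        "pos": pos,
                        "role": "decoy",
                        "fails": kind,
                        "event_class": None,
                    }
                )
        rows.sort(key=lambda r: r[0])
        path = os.path.join(outdir, f"{proband}.vcf")
        with open(path, "w") as fh:
            fh.write(_VCF_HEADER)
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + proband + "\n")
            for pos, m in rows:
                sai = m["sai"]
                info = (
                    f"FS={m['fs']};QD={m['qd']};GENE={m['gene']};"
                    f"GENE_TYPE={m['gene_type']};CSQ=splice_region;MAF={m['maf']};"
                    f"DS_AG={sai[0]};DS_AL={sai[1]};DS_DG={sai[2]};DS_DL={sai[3]}"
                )
                fh.write(
                    f"chr1\t{pos}\t.\t{m['ref']}\t{m['alt']}\t{m['qual']}\t.\t{info}"
                    f"\tGT:GQ:DP\t0/1:{m['gq']}:{m['dp']}\n"
                )
        paths[proband] = path
    return paths, variant_truth


def _write_expression(
    c: SimConfig, outdir: str, rng: np.random.Generator,
) -> tuple[str, str, list[dict], list[dict]]:
    """NB counts + TPM with injected outliers and deletion blocks."""
    samples = c.sample_ids()
    genes = [f"EXPR{i + 1}" for i in range(c.n_expr_genes)]
    lo, hi = c.expr_mean_range
    means = np.exp(rng.uniform(np.log(lo), np.log(hi), size=c.n_expr_genes))
    lengths = rng.integers(800, 4000, size=c.n_expr_genes)
    mu = np.tile(means[:, None], (1, len(samples)))
    sidx = {s: i for i, s in enumerate(samples)}
    gidx = {g: i for i, g in enumerate(genes)}

    outlier_truth = []
    for sample, gene, log2fc in c.outlier_injections:
        gi = gidx[gene] if gene in gidx else int(gene.removeprefix("auto"))
        mu[gi, sidx[sample]] *= 2.0 ** log2fc
        outlier_truth.append(
            {
                "gene": genes[gi],
                "sample": sample,
                "log2fc": log2fc,
                "direction": "under" if log2fc < 0 else "over",
            }
        )
    deletion_truth = []
    for sample, start, n in c.deletion_blocks:
        mu[start : start + n, sidx[sample]] *= c.deletion_factor
        deletion_truth.append(
            {
                "sample": sample,
                "genes": genes[start : start + n],
                "chrom": "chr2",
                "factor": c.deletion_factor,
            }
        )
    r = 1.0 / c.expr_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    starts = 1_000_000 + np.arange(c.n_expr_genes) * 10_000
    ends = starts + lengths - 1
    # TPM: length-normalized counts scaled to 1e6 per sample
    rate = counts / lengths[:, None]
    tpm = rate / rate.sum(axis=0, keepdims=True) * 1e6

    counts_path = os.path.join(outdir, "expression_counts.tsv")
    tpm_path = os.path.join(outdir, "expression_tpm.tsv")
    header = "gene_id\tchrom\tstart\tend\t" + "\t".join(samples)
    with open(counts_path, "w") as fh:
        fh.write(header + "\n")
        for gi, g in enumerate(genes):
            vals = "\t".join(str(int(v)) for v in counts[gi])
            fh.write(f"{g}\tchr2\t{starts[gi]}\t{ends[gi]}\t{vals}\n")
    with open(tpm_path, "w") as fh:
        fh.write(header + "\n")
        for gi, g in enumerate(genes):
            vals = "\t".join(f"{v:.4f}" for v in tpm[gi])
            fh.write(f"{g}\tchr2\t{starts[gi]}\t{ends[gi]}\t{vals}\n")
    return counts_path, tpm_path, outlier_truth, deletion_truth


def _write_allele_counts(
    c: SimConfig, outdir: str, rng: np.random.Generator,
) -> tuple[str, list[dict]]:
    """Binomial allele counts at phased het X-chromosome SNPs."""
    sample = c.ase_sample or c.sample_ids()[0]
    path = os.path.join(outdir, "allele_counts.tsv")
    truth = []
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tref_count\talt_count\tsample\tmaternal_allele\n")
        for i in range(c.n_ase_snps):
            pos = 1_000_000 + i * 5_000_000
            depth = max(int(rng.poisson(c.ase_depth_mean)), 12)
            maternal = "ref" if rng.random() < 0.5 else "alt"
            # expressed allele: the skewed parent's one
            expressed_maternal = c.ase_skewed_parent == "maternal"
            minor_n = int(rng.binomial(depth, c.ase_minor_fraction))
            major_n = depth - minor_n
            maternal_n = major_n if expressed_maternal else minor_n
            paternal_n = depth - maternal_n
            ref_n = maternal_n if maternal == "ref" else paternal_n
            alt_n = depth - ref_n
            fh.write(
                f"chrX\t{pos}\tA\tG\t{ref_n}\t{alt_n}\t{sample}\t{maternal}\n"
            )
            truth.append(
                {
                    "chrom": "chrX",
                    "pos": pos,
                    "sample": sample,
                    "minor_fraction": c.ase_minor_fraction,
                    "skewed_parent": c.ase_skewed_parent,
                }
            )
    return path, truth


def simulate_cohort(c: SimConfig, outdir: str) -> tuple[dict, SimTruth]:
    """Generate the full cohort bundle under ``outdir``.

    Returns (file manifest, truth). The file manifest maps logical names to
    paths: annotation, junction_files {sample: path}, vcfs {proband: path},
    coverage, counts, tpm, allele_counts, panel, truth.
    """
    c.validate()
    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(c.seed)
    ts = _build_annotation(c)
    gtf_path = os.path.join(outdir, "annotation.gtf")
    _write_gtf(ts, gtf_path)

    geoms: dict[str, dict] = {}
    for ev in c.injected_events:
        t = ts.transcripts_of_gene(ev.gene)[0]
        g = _event_geometry(ev, t)
        g["event"] = ev
        g["transcript"] = t
        geoms[f"{ev.proband}:{ev.gene}"] = g

    junction_paths = _write_junction_files(c, ts, geoms, outdir, rng)
    coverage_path = _write_coverage(c, ts, geoms, outdir, rng)
    vcf_paths, variant_truth = _write_vcfs(c, ts, geoms, outdir)
    counts_path, tpm_path, outlier_truth, deletion_truth = _write_expression(c, outdir, rng)
    allele_path, ase_truth = _write_allele_counts(c, outdir, rng)

    panel_path = os.path.join(outdir, "panel.tsv")
    with open(panel_path, "w") as fh:
        fh.write("gene_symbol\tconfidence\n")
        for gene in sorted({ev.gene for ev in c.injected_events}):
            fh.write(f"{gene}\tgreen\n")

    truth = SimTruth(
        events=[
            {
                "proband": g["event"].proband,
                "gene": g["event"].gene,
                "event_class": g["event"].event_class,
                "support": g["event"].support,
                "junctions": [list(j) for j in g["junctions"]],
                "region": list(g["region"]),
                "delta": g["delta"],
                "variant_fail": g["event"].variant_fail,
            }
            for g in geoms.values()
        ],
        variants=variant_truth,
        outliers=outlier_truth,
        deletions=deletion_truth,
        ase=ase_truth,
    )
    truth_path = os.path.join(outdir, "truth.json")
    truth.to_json(truth_path)
    manifest = {
        "annotation": gtf_path,
        "junction_files": junction_paths,
        "vcfs": vcf_paths,
        "coverage": coverage_path,
        "counts": counts_path,
        "tpm": tpm_path,
        "allele_counts": allele_path,
        "panel": panel_path,
        "truth": truth_path,
    }
    return manifest, truth


def evaluate_recovery(
    truth: SimTruth,
    candidates=None,
    outlier_calls=None,
    skew_summaries=None,
    microdeletions=None,
) -> dict:
    """Match pipeline outputs to the truth manifest.

    Events match candidates on (proband, gene, event class); outliers on
    (gene, sample, direction); deletions on (sample, any member gene);
    skew on complete_skew + dominant parent. Returns per-category
    sensitivity and false-discovery counts; categories with no truth
    records report sensitivity None.
    """
    report: dict = {}
    if candidates is not None:
        truth_keys = {
            (e["proband"], e["gene"], e["event_class"]) for e in truth.events
        }
        found_keys = set()
        extras = 0
        for cand in candidates:
            key = (cand.proband_id, cand.event.gene_symbol, cand.event.event_class)
            if key in truth_keys:
                found_keys.add(key)
            else:
                extras += 1
        per_class: dict[str, dict] = {}
        for e in truth.events:
            cls = e["event_class"]
            d = per_class.setdefault(cls, {"n": 0, "found": 0})
            d["n"] += 1
            key = (e["proband"], e["gene"], cls)
            if key in found_keys:
                d["found"] += 1
        report["events"] = {
            "sensitivity": len(found_keys) / len(truth_keys) if truth_keys else None,
            "n_truth": len(truth_keys),
            "n_found": len(found_keys),
            "false_discoveries": extras,
            "per_class": {
                k: {"sensitivity": v["found"] / v["n"], "n": v["n"]}
                for k, v in sorted(per_class.items())
            },
        }
    if outlier_calls is not None:
        truth_keys = {(o["gene"], o["sample"], o["direction"]) for o in truth.outliers}
        deletion_cells = {
            (g, d["sample"]) for d in truth.deletions for g in d["genes"]
        }
        found = set()
        extras = 0
        for call in outlier_calls:
            key = (call.gene, call.sample, call.direction)
            if key in truth_keys:
                found.add(key)
            elif (call.gene, call.sample) not in deletion_cells:
                extras += 1
        report["outliers"] = {
            "sensitivity": len(found) / len(truth_keys) if truth_keys else None,
            "n_truth": len(truth_keys),
            "false_discoveries": extras,
        }
    if microdeletions is not None:
        found_n = 0
        for d in truth.deletions:
            genes = set(d["genes"])
            if any(
                s.sample == d["sample"] and genes & set(s.genes)
                for s in microdeletions
            ):
                found_n += 1
        report["deletions"] = {
            "sensitivity": found_n / len(truth.deletions) if truth.deletions else None,
            "n_truth": len(truth.deletions),
        }
    if skew_summaries is not None:
        expected_parent = truth.ase[0]["skewed_parent"] if truth.ase else None
        expected_complete = bool(truth.ase) and truth.ase[0]["minor_fraction"] <= 0.05
        ok = any(
            s.complete_skew and s.dominant_parent == expected_parent
            for s in skew_summaries
        ) if expected_complete else not any(s.complete_skew for s in skew_summaries)
        report["ase"] = {"skew_recovered_as_expected": bool(ok)}
    return report
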
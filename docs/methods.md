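# Methods

This note documents the models, rules and numerical choices behind
`splicedx`, what the synthetic-cohort generator does and does not emulate,
and the known limitations.

## Coordinates and junction representation

All intervals are 1-based and fully inclusive (the native GTF/VCF
convention); conversion to 0-based half-open happens only at BED
import/export (`prioritize.interval_to_bed_line`). A splice junction is
identified by the first and last intronic base of the spliced intron —
the STAR `SJ.out.tab` convention — plus chromosome and strand. Strand code
0 in junction files maps to "." and matches either annotated strand.
Exon and intron ordinals follow transcription order (strand-aware), so
"exon 1" is the first transcribed exon also on the minus strand.

## Novel-junction calling

A junction is called cohort-private for a proband when all of:

- unannotated (absent from the reference transcript set),
- proband support ≥ `min_reads` (default 5) uniquely-mapping reads,
- every other cohort sample has ≤ `max_other` (default 2) reads.

Only uniquely-mapping read counts contribute; multimapper counts are
parsed and retained but never used for support. The "other samples"
comparison covers the whole cohort by default; an optional sample→batch
map restricts it to the proband's sequencing batch, which is appropriate
when library chemistry differs across batches. The full-cohort rule is the
stricter of the two and is the default.

Whether the five-read minimum should count unique reads only is ambiguous
in practice; unique-only is assumed here because manual review of
junction evidence effectively considers unique alignments.

`flanking_normal_junctions` implements the "no splicing abnormality"
verdict for a locus: every annotated junction of the flanking introns must
have proband support ≥ 1 and no novel call may overlap the flanking
exons/introns; otherwise the locus is abnormal or unassessable. It takes
the proband identity explicitly (support is per-sample).

## Event classification

Junction-based classes are decided per transcript by where the junction's
two ends fall relative to annotated splice sites, with rules applied in
order (mutually exclusive):

1. both ends on annotated boundaries of *different* introns → exon
   skipping; Δ = −(sum of skipped exon lengths);
2. one end annotated, the other inside an exon → alternative
   donor/acceptor with exon truncation; Δ = −(exonic bases removed);
3. one end annotated, the other inside the *same* intron → alternative
   donor/acceptor with intronic-sequence inclusion; Δ = +(intronic bases
   retained up to the annotated partner site). When a second novel
   junction in the same intron brackets an internal segment with the
   first, the pair is promoted to a cryptic exon with Δ = +(segment
   length) — both junctions must independently pass the outlier rule;
4. anything else → unclassified.

Donor/acceptor naming is strand-aware (donor = 5′ splice site in
transcription order); a coordinate-mirrored fixture with flipped strand
swaps the labels, which the tests assert. A junction that is annotated for
the evaluated transcript is a caller error: classification assumes
pre-filtered novel junctions.

Classification is evaluated against **all** transcripts of the overlapping
gene(s), one event per transcript; no canonical-transcript selection is
attempted, since consequences are transcript-specific.

### Intron retention

Retention produces no junction and is detected from per-base coverage.
With per-sample depth arrays spanning the intron and both flanking exons:

- proband ratio = median intronic coverage ÷ median flanking-exon coverage,
- called iff ratio ≥ `min_ratio` (0.15) AND flanking-exon median ≥
  `min_exon_cov` (10) AND ratio ≥ `min_fold_vs_controls` (3.0) × the best
  control ratio.

Zero flanking coverage in the proband makes the locus *not assessable*,
distinct from not-called. The three thresholds are this package's own
conservative defaults (config-exposed): retention is the class most easily
confounded by shared intronic background, so an absolute floor, a
minimum-coverage guard and a fold-change over controls are all required.

### Frame consequence

Frameshift iff |Δ| mod 3 ≠ 0; in-frame events report Δ/3 codons; events
entirely outside the CDS report frame not-applicable. Frame is judged from
length alone — no scan for stop codons inside included sequence is
performed. Consequently an in-frame-length insertion that introduces a
premature stop is still reported "in_frame"; this is a documented
limitation of the length-based rule, kept deliberately rather than
special-cased.

## Variant filter cascade

Two stages over VEP/SpliceAI-annotated calls (one record per ALT allele;
multi-allelic records are split):

| stage | criterion | rule |
|---|---|---|
| site | min_qual | QUAL ≥ 50 |
| site | min_depth | sample DP ≥ 8 |
| site | min_gq | GQ ≥ 16 |
| site | max_fs | FS ≤ 30 |
| site | min_qd | QD ≥ 2 |
| annotation | max_maf | MAF < 0.01 |
| annotation | min_delta | max(AG, AL, DG, DL) ≥ 0.2 |
| annotation | protein_coding | gene biotype = protein_coding |
| annotation | snv_only | len(ref) = len(alt) = 1 |

Boundary inclusivity follows the criteria's phrasing literally: DP = 8,
GQ = 16, FS = 30, QD = 2, QUAL = 50 and delta = 0.2 all pass; MAF = 0.01
fails. All criteria are evaluated (never short-circuited) so the audit
table counts every violation. Missing-value policy: a missing MAF passes
with a flag (absence from population databases is itself evidence of
rarity); missing SpliceAI scores fail the delta criterion (the cascade is
splice-evidence-driven); missing site metrics fail their criterion with
reason "missing". All three behaviours are config-overridable. "Reads
covering the locus" is read as the proband's sample-level DP, not site DP.
Indels are excluded outright — in RNA-seq calls the majority are low
quality — so indel-caused events are only reachable through the panel
strategy.

## Prioritization

*Genotype-to-phenotype*: each passing variant becomes a ±25 bp window
(1-based inclusive, clipped at position 1). The event interval for
intersection is the union of the event's splice-site positions and its
affected region, so both an exonic variant at a new donor site and a deep
intronic variant inside the cryptic exon it creates intersect their event.
Overlap requires ≥ 1 shared base on the same chromosome; the computation
is equivalent to a bedtools-intersect of the corresponding BED intervals.

*Phenotype-to-genotype*: events whose gene symbol (case-insensitive) is on
the supplied panel TSV. Panels are plain files — no live panel-registry
dependency — and an empty panel is a fatal error to guard against silently
empty analyses.

Ranking is deterministic and explicitly a convenience ordering, not a
validated score: variant-supported candidates first, then max SpliceAI
delta, then proband junction support, then genomic position. Final
candidacy review is manual by design.

## Expression outliers

Counts are filtered (FPKM-like ≥ threshold in ≥ 1 sample; the threshold
default of 1 is config-exposed and deliberately unaggressive), normalized
by median-of-ratios size factors (total-count fallback when no gene is
nonzero everywhere), and tested per gene × sample:

- z = (log2(norm + 1) − median) / (1.4826 × MAD), with SD fallback when
  MAD = 0 and gene skipped when both are 0;
- two-sided p from the normal approximation;
- BH adjustment across all gene × sample tests; calls at padj ≤ α (0.05);
- each call carries the sample's expression rank for the gene (rank 1 =
  lowest normalized expression in the cohort).

The output schema mirrors a denoising-autoencoder outlier caller's results
table (zscore, pvalue, padj, rank), and `read_outrider_results` imports
such a table interchangeably; the autoencoder itself is out of scope — the
robust z-score is the native detector, which means confounder correction
(batch, sex, cell-type composition) is *not* performed. Gene-subset
re-adjustment (`readjust_pvalues`) recomputes BH on any gene list, e.g.
disease-gene panels.

A putative microdeletion is a maximal run of ≥ `min_genes` (3)
genomically consecutive genes (annotation order per chromosome) all
carrying an under-expression call in the same sample; runs are maximal and
therefore non-overlapping per sample; score = mean |z|.

TPM rules: a gene is "expressed in blood" iff TPM > 1 in ≥ 4 samples;
median-TPM assessability classes are ≥ 5 RNA-seq-assessable, ≥ 0.9
RT-PCR-assessable, else not assessable in blood (both boundaries
inclusive).

## Allelic expression and X-inactivation skew

Per heterozygous SNP: informative depth = ref + alt reads (other bases
tallied separately); SNPs below `min_depth` (10) are uninformative. The
skew test is the exact two-sided binomial test against 0.5 (symmetric in
ref/alt). A monoallelic call requires minor-allele fraction ≤
`max_minor_fraction` (0.05, inclusive; this package's own default for
"visually evident" monoallelic expression). Chromosome summaries aggregate
trio-phased monoallelic calls: the dominant parent is the one whose allele
is expressed at every monoallelic SNP (conflicts → undetermined), and
complete skew requires every informative SNP monoallelic for one parent.
Parental phase is always supplied as input, never inferred; SNPs are
treated as independent (no haplotype-block modelling).

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes:

- **Cohort**: 30 samples by default (one sequencing batch of a larger
  cohort); fixture genes are evenly spaced plus-strand 6-exon transcripts
  (150 nt exons, 1200 nt introns) plus one non-coding decoy gene.
- **Junctions**: annotated junctions in every sample with Poisson counts
  (mean 50, floored at 1); injected novel junctions only in their proband
  with configured support (default 12, ≥ the 5-read rule), with optional
  Poisson leak into controls to stress the ≤ 2-read rule (default 0).
- **Events**: one per gene, built around intron 2/exon 3 so flanking
  structure exists: exon skipping (Δ −150), an 80-nt cryptic exon,
  donor/acceptor shifts into the intron (Δ +60 / +45), and coverage-based
  intron retention (proband ratio 0.5 vs control 0.02 at exon depth 60).
- **Variants**: causal SNVs placed a configurable offset (default 10 bp,
  bounded by the ±25 bp window) from the event's anchor boundary, with
  metrics drawn to pass the cascade (QUAL 200, DP 40, GQ 99, FS 2, QD 20,
  MAF 1e-4, max delta 0.85); per-event `variant_fail` spoils exactly one
  criterion (e.g. GQ 6) to reproduce the panel-rescue scenario. A decoy
  battery in the non-event gene region fails one criterion each, covering
  all nine criteria, including an indel and a common-MAF decoy.
- **Expression**: negative-binomial counts (dispersion 0.05, means
  log-uniform 50–500), injected outliers as log2 fold-changes, and
  contiguous deletion blocks scaled by 0.25. The deletion factor is
  stronger than a strict single-copy halving: it models deletions whose
  expression footprint is detectable by a robust z-score without
  confounder correction, which is the regime in which microdeletion
  scanning is informative for this detector.
- **ASE**: 9 phased X-chromosome SNPs with Poisson depth (mean 40, floor
  12) and binomial minor-allele counts; minor fraction 0 emulates complete
  skew toward a configured parent, 0.5 emulates balance.
- Identical seeds give byte-identical files; SpliceAI scores are always
  assigned by configuration, never computed.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: alignment and mapping artefacts (the main
source of false junctions in practice), sequence content and GC effects,
nonsense-mediated decay of frameshift transcripts (injected events are
fully observable), batch/covariate structure in expression, overlapping
genes and multi-isoform complexity, and realistic annotation scale.

## Problem sizes

The default test suite and the acceptance script use cohorts of 8–12
samples, 6 fixture genes, 40–200 expression genes, and 100 replicates of
the 500-gene × 20-sample outlier-recovery simulation; these sizes exercise
every code path while keeping a full run under a minute, and all
quantities of interest (threshold behaviour, recovery sensitivities) are
scale-free at these sizes.

## Known limitations

- Length-based frame calls ignore internal stop codons (above).
- The classifier reports events against the union of transcripts; it does
  not choose a biologically "primary" transcript.
- The expression detector's lack of covariate correction limits it to
  strong outliers; it will under-call in confounded cohorts.
- Panel-strategy sensitivity is bounded by panel completeness and correct
  phenotype-to-panel assignment, which are user inputs.
- Tool-detection bookkeeping in the packaged reference table records one
  published detection column verbatim; small inconsistencies between that
  column and prose tallies elsewhere (a third event attributed to one
  outlier tool, and another tool's count appearing only in prose) are
  preserved as-is rather than resolved.
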
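# splicedx

RNA-seq-centric detection and prioritization of aberrant splicing,
expression outliers and allelic imbalance for Mendelian-disorder
diagnostics.

In rare-disease cohorts, DNA sequencing frequently ends with a variant of
unknown significance (VUS) — or no candidate at all. Blood RNA-seq adds a
functional readout: private aberrant splicing, expression outliers,
microdeletion signatures and monoallelic expression can all point at a
molecular diagnosis even when DNA analysis was uninformative. `splicedx`
implements that diagnostic workflow as a reusable, tested library and CLI
for analysts working with STAR junction output, annotated VCFs and
expression matrices.

## What it computes

**Cohort-private junction calls.** From per-sample `SJ.out.tab`-style
junction files, a junction is called novel for a proband when it is absent
from the reference annotation, has ≥ 5 uniquely-mapping supporting reads in
the proband and ≤ 2 reads in every other cohort sample — the read-support
rule that separates genuine private splicing from mapping noise.

**Event classification.** Each novel junction is classified per overlapping
transcript into exon skipping, cryptic-exon inclusion, alternative donor or
alternative acceptor use (strand-aware; the donor is the 5′ splice site in
transcription order), by where its two ends fall relative to annotated
splice sites. Intron retention, which produces no junction, is detected
from per-base coverage via intron/flanking-exon median-coverage ratios.
Each event carries its length change Δ (nt); the transcript consequence is
frameshift iff |Δ| mod 3 ≠ 0.

**Variant filter cascade.** RNA-derived variant calls pass a two-stage
cascade: site stage QUAL ≥ 50, DP ≥ 8, GQ ≥ 16, FS ≤ 30, QD ≥ 2; annotation
stage MAF < 0.01, max SpliceAI delta ≥ 0.2, protein-coding gene, SNVs only.

**Two prioritization strategies.**
*Genotype-to-phenotype*: filtered variants are padded ±25 bp and
intersected with the splice-site positions and affected regions of
classified events. *Phenotype-to-genotype*: events are restricted to a
clinical gene panel chosen from the patient's phenotype — this recovers
events whose causal variant was lost to the quality filters.

**Expression outliers.** Per gene × sample robust z-scores of
log2(size-factor-normalized count + 1) with Benjamini–Hochberg FDR, gene
expression ranks (rank 1 = lowest in cohort), maximal runs of consecutive
under-expressed genes as putative microdeletions, and TPM-based
assessability (median TPM ≥ 5: assessable by RNA-seq; ≥ 0.9: by RT-PCR).

**Allelic expression.** Exact two-sided binomial tests of allelic balance
at heterozygous SNPs, monoallelic calls (minor fraction ≤ 0.05 at depth
≥ 10), and chromosome-level X-inactivation skew summaries from
trio-phased allele counts.

**Synthetic cohorts.** A seeded generator produces complete cohorts — GTF,
junction files, coverage tracks, annotated VCFs with causal and decoy
variants, expression matrices, allele counts — with a ground-truth
manifest, so every stage is testable without patient data.

## Worked example

Simulate a 12-sample cohort with three injected events — one of them
(`GENE6`) carrying a causal variant deliberately given GQ 6 so the quality
filters drop it — then run both strategies:

```python
from splicedx.simulate import SimConfig, InjectedEvent, simulate_cohort
from splicedx.pipeline import RunConfig, run_g2p, run_p2g

cfg = SimConfig(
    n_samples=12, seed=11,
    injected_events=[
        InjectedEvent("S001", "GENE1", "exon_skipping"),
        InjectedEvent("S002", "GENE2", "cryptic_exon"),
        InjectedEvent("S006", "GENE6", "cryptic_exon", variant_fail="min_gq"),
    ],
)
manifest, truth = simulate_cohort(cfg, "cohort/")
rc = RunConfig(
    annotation=manifest["annotation"],
    junction_files=sorted(manifest["junction_files"].items()),
    vcfs=manifest["vcfs"], panel=manifest["panel"],
    probands=["S001", "S002", "S006"],
)
print(run_g2p(rc).to_frame())
print(run_p2g(rc).to_frame())
```

prints (columns abridged):

```
g2p stage counts: {'novel_junctions': 5, 'classified_events': 3,
                   'variants_input': 30, 'variants_passed': 2, 'candidates': 2}
proband  gene   event_class  delta_nt  support        variant      frame
   S001 GENE1 exon_skipping      -150       12 chr1:102710C>T   in_frame
   S002 GENE2  cryptic_exon        80       12 chr1:160010C>T frameshift

p2g stage counts: {'novel_junctions': 5, 'classified_events': 3, 'candidates': 3}
proband  gene   event_class  delta_nt      frame
   S001 GENE1 exon_skipping      -150   in_frame
   S002 GENE2  cryptic_exon        80 frameshift
   S006 GENE6  cryptic_exon        80 frameshift
```

Reading: five novel junctions (a cryptic exon contributes two) classify
into three events. The variant-anchored strategy keeps 2 of 30 variant
calls after the cascade and yields two candidates; the skipped exon (150 nt)
is in-frame, the 80-nt cryptic exon is a frameshift. The panel strategy
additionally recovers the `GENE6` event whose variant the cascade had
discarded for low genotype quality — the scenario in which phenotype-driven
filtering rescues a diagnosis.

The same stages are available as CLI subcommands: `splicedx simulate`,
`splicedx junctions`, `splicedx filter-vcf`, `splicedx prioritize g2p|p2g`,
`splicedx expression`, `splicedx ase`.

## Layout

- `splicedx.annotation` — GTF transcript models, introns, interval queries
- `splicedx.junctions` — junction count matrix, novel-junction calling
- `splicedx.events` — event classification, intron retention, frame calls
- `splicedx.variants` — annotated-VCF parsing and the filter cascade
- `splicedx.prioritize` — variant windows, intersection, panels, ranking
- `splicedx.expression` — outliers, microdeletions, TPM assessability
- `splicedx.ase` — allele counts, binomial skew tests, skew summaries
- `splicedx.simulate` — synthetic cohorts with ground truth
- `splicedx.pipeline` / `splicedx.cli` — orchestration and CLI

See `docs/methods.md` for the statistical model, thresholds and known
limitations.
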
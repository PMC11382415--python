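"""Allele-specific expression at heterozygous SNPs and X-inactivation skew.

At a heterozygous SNP, balanced biallelic expression gives ref/alt read
counts near 50:50; monoallelic expression (e.g. from complete X-inactivation
skew) gives a near-zero minor-allele fraction. Each informative SNP gets an
exact two-sided binomial test against 0.5, and chromosome-level skew is
summarized from parent-of-origin-phased monoallelic calls: complete skew
means every informative SNP is monoallelic for the same parental allele.
Parental phase is supplied as input (from trio data), never inferred.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import pandas as pd
from scipy import stats


@dataclass
class AlleleCount:
    """Ref/alt read support at one heterozygous SNP in one sample.

    ``maternal_allele`` says which allele ("ref" or "alt") was maternally
    inherited, when trio phase is available.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    ref_count: int
    alt_count: int
    sample: str = ""
    maternal_allele: Literal["ref", "alt"] | None = None
    other_count: int = 0

    def __post_init__(self) -> None:
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValueError("allele counts must be >= 0")

    @property
    def depth(self) -> int:
        """Informative depth: ref + alt reads (other bases excluded)."""
        return self.ref_count + self.alt_count

    @property
    def minor_fraction(self) -> float:
        if self.depth == 0:
            return float("nan")
        return min(self.ref_count, self.alt_count) / self.depth

    @property
    def major_allele(self) -> Literal["ref", "alt"]:
        return "ref" if self.ref_count >= self.alt_count else "alt"


@dataclass
class SkewSummary:
    """Chromosome-level allelic-skew summary over phased SNPs."""

    chrom: str
    n_snps_informative: int
    n_monoallelic: int
    dominant_parent: Literal["maternal", "paternal", "undetermined"]
    complete_skew: bool
    low_confidence: bool = False

    def __post_init__(self) -> None:
        assert self.n_monoallelic <= self.n_snps_informative
        if self.complete_skew:
            assert (
                self.n_monoallelic == self.n_snps_informative
                and self.dominant_parent != "undetermined"
            )


def read_allele_counts(path: str) -> list[AlleleCount]:
    """Read a pre-computed allele-count TSV.

    Columns: chrom, pos, ref, alt, ref_count, alt_count, optional sample and
    maternal_allele ("ref"/"alt").
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out = []
    for r in df.itertuples():
        out.append(
            AlleleCount(
                chrom=str(r.chrom),
                pos=int(r.pos),
                ref=str(r.ref),
                alt=str(r.alt),
                ref_count=int(r.ref_count),
                alt_count=int(r.alt_count),
                sample=str(getattr(r, "sample", "")),
                maternal_allele=(
                    str(r.maternal_allele)
                    if "maternal_allele" in df.columns and pd.notna(r.maternal_allele)
                    else None
                ),
            )
        )
    return out


def count_alleles(
    bam_path: str,
    het_snps: pd.DataFrame,
    sample: str = "",
    min_base_quality: int = 13,
) -> list[AlleleCount]:
    """Count ref/alt bases from a BAM pileup at each heterozygous SNP.

    ``het_snps`` needs columns chrom, pos (1-based), ref, alt and optionally
    maternal_allele. Bases other than ref/alt are ignored for the allele
    counts but tallied in ``other_count``. An uncovered SNP yields (0, 0)
    and is downstream-uninformative.
    """
    import pysam

    out: list[AlleleCount] = []
    with pysam.AlignmentFile(bam_path) as bam:
        for r in het_snps.itertuples():
            ref_n = alt_n = other_n = 0
            for col in bam.pileup(
                str(r.chrom), r.pos - 1, r.pos,
                truncate=True, min_base_quality=min_base_quality,
            ):
                if col.reference_pos != r.pos - 1:
                    continue
                for base in col.get_query_sequences():
                    b = base.upper()
                    if b == str(r.ref).upper():
                        ref_n += 1
                    elif b == str(r.alt).upper():
                        alt_n += 1
                    elif b:
                        other_n += 1
            out.append(
                AlleleCount(
                    chrom=str(r.chrom),
                    pos=int(r.pos),
                    ref=str(r.ref),
                    alt=str(r.alt),
                    ref_count=ref_n,
                    alt_count=alt_n,
                    sample=sample,
                    maternal_allele=getattr(r, "maternal_allele", None),
                    other_count=other_n,
                )
            )
    return out


def snp_skew_test(a: AlleleCount, min_depth: int = 10) -> float | None:
    """Exact two-sided binomial test of allelic balance against 0.5.

    Returns the p-value, or None when informative depth is below
    ``min_depth`` (uninformative SNP). Symmetric in (ref, alt).
    """
    n = a.depth
    if n < min_depth:
        return None
    return float(stats.binomtest(a.ref_count, n, 0.5, alternative="two-sided").pvalue)


def call_monoallelic(
    a: AlleleCount, min_depth: int = 10, max_minor_fraction: float = 0.05
) -> bool | None:
    """True iff the minor-allele fraction is <= ``max_minor_fraction``.

    None (uninformative) below ``min_depth``. The boundary is inclusive:
    e.g. 1 minor read in 20 at the 0.05 default is still monoallelic.
    """
    if a.depth < min_depth:
        return None
    return a.minor_fraction <= max_minor_fraction


def chromosome_skew_summary(
    counts: Sequence[AlleleCount],
    min_depth: int = 10,
    max_minor_fraction: float = 0.05,
) -> SkewSummary:
    """Aggregate phased monoallelic calls into a chromosome skew summary.

    ``dominant_parent`` is the parent whose allele is the expressed (major)
    allele at every monoallelic SNP; conflicting SNPs give "undetermined".
    ``complete_skew`` requires every informative SNP monoallelic for a
    single parent. A single-SNP summary is flagged low-confidence.
    """
    chroms = {c.chrom for c in counts}
    chrom = chroms.pop() if len(chroms) == 1 else ",".join(sorted(chroms))
    informative = [c for c in counts if c.depth >= min_depth]
    mono = [
        c
        for c in informative
        if call_monoallelic(c, min_depth=min_depth, max_minor_fraction=max_minor_fraction)
    ]
    parents: set[str] = set()
    for c in mono:
        if c.maternal_allele is None:
            continue
        expressed_maternal = c.major_allele == c.maternal_allele
        parents.add("maternal" if expressed_maternal else "paternal")
    if len(parents) == 1:
        dominant = parents.pop()
    else:
        dominant = "undetermined"
    complete = (
        len(informative) > 0
        and len(mono) == len(informative)
        and dominant != "undetermined"
    )
    return SkewSummary(
        chrom=chrom if counts else "",
        n_snps_informative=len(informative),
        n_monoallelic=len(mono),
        dominant_parent=dominant,  # type: ignore[arg-type]
        complete_skew=complete,
        low_confidence=len(informative) <= 1,
    )
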
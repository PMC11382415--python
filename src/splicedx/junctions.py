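"""Cohort junction count matrix and cohort-private ("novel") junction calls.

A junction is called novel for a proband when it is unannotated, has at
least ``min_reads`` uniquely-mapping supporting reads in the proband, and no
more than ``max_other`` reads in any other cohort sample — the read-support
rule used to separate genuine private splicing from mapping noise. Only
uniquely-mapping read counts contribute to support; multimapper counts are
parsed and retained but never used by the caller.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from splicedx.annotation import GenomicInterval, JunctionKey, TranscriptSet, introns_of

logger = logging.getLogger(__name__)

_STRAND_CODE = {"0": ".", "1": "+", "2": "-"}


@dataclass
class JunctionCountMatrix:
    """junction x sample matrix of uniquely-mapping read support."""

    junctions: list[JunctionKey]
    samples: list[str]
    counts: np.ndarray  # shape (n_junctions, n_samples), int
    annotated_flags: np.ndarray  # shape (n_junctions,), bool

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.annotated_flags = np.asarray(self.annotated_flags, dtype=bool)
        if self.counts.shape != (len(self.junctions), len(self.samples)):
            raise ValueError("counts shape does not match junction/sample lists")
        if (self.counts < 0).any():
            raise ValueError("negative junction counts")
        if len(set(self.junctions)) != len(self.junctions):
            raise ValueError("duplicate junction keys")
        self._jidx = {j: i for i, j in enumerate(self.junctions)}
        self._sidx = {s: i for i, s in enumerate(self.samples)}

    def count(self, junction: JunctionKey, sample: str) -> int:
        return int(self.counts[self._jidx[junction], self._sidx[sample]])

    def sample_column(self, sample: str) -> np.ndarray:
        return self.counts[:, self._sidx[sample]]

    def to_frame(self) -> pd.DataFrame:
        idx = pd.MultiIndex.from_tuples(
            self.junctions, names=["chrom", "intron_start", "intron_end", "strand"]
        )
        return pd.DataFrame(self.counts, index=idx, columns=self.samples)


@dataclass
class NovelJunctionCall:
    """A cohort-private junction call for one proband."""

    junction: JunctionKey
    proband_id: str
    proband_count: int
    max_other_count: int
    n_other_samples: int
    annotated: bool = False


def read_star_sj(path: str) -> dict[JunctionKey, tuple[int, int]]:
    """Parse a STAR ``SJ.out.tab``-style file.

    Nine tab-separated columns: chrom, intron start, intron end (1-based,
    inclusive), strand code (0 undefined / 1 + / 2 -), motif, annotated flag,
    unique reads, multimapping reads, max overhang. Returns
    {junction key: (unique_reads, multimapping_reads)}; unparseable lines are
    skipped with a warning count.
    """
    out: dict[JunctionKey, tuple[int, int]] = {}
    skipped = 0
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                skipped += 1
                continue
            try:
                chrom = parts[0]
                start, end = int(parts[1]), int(parts[2])
                strand = _STRAND_CODE.get(parts[3])
                uniq, multi = int(parts[6]), int(parts[7])
            except ValueError:
                skipped += 1
                continue
            if strand is None or start < 1 or end < start or uniq < 0:
                skipped += 1
                continue
            out[(chrom, start, end, strand)] = (uniq, multi)
    if skipped:
        logger.warning("read_star_sj(%s): skipped %d unparseable lines", path, skipped)
    return out


def build_junction_matrix(
    files: list[tuple[str, str]], ts: TranscriptSet
) -> JunctionCountMatrix:
    """Union per-sample junction files into one cohort matrix.

    ``files`` is a list of (sample_id, path). A junction absent from a sample
    gets count 0. ``annotated_flags`` marks junctions present in
    ``ts.known_junctions`` (strand "." matches either strand).
    """
    if len(files) < 2:
        raise ValueError("need at least 2 samples to build a cohort matrix")
    sample_ids = [s for s, _ in files]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample_id in junction file list")
    per_sample = {sid: read_star_sj(path) for sid, path in files}
    all_junctions = sorted({j for d in per_sample.values() for j in d})
    counts = np.zeros((len(all_junctions), len(sample_ids)), dtype=np.int64)
    for si, sid in enumerate(sample_ids):
        d = per_sample[sid]
        for ji, j in enumerate(all_junctions):
            if j in d:
                counts[ji, si] = d[j][0]  # unique reads only
    flags = np.array([ts.is_known_junction(j) for j in all_junctions], dtype=bool)
    return JunctionCountMatrix(all_junctions, sample_ids, counts, flags)


def call_novel_junctions(
    m: JunctionCountMatrix,
    proband: str,
    min_reads: int = 5,
    max_other: int = 2,
    require_unannotated: bool = True,
    batch_map: dict[str, str] | None = None,
) -> list[NovelJunctionCall]:
    """Call cohort-private junctions for one proband.

    A junction is called when proband support >= ``min_reads``, every other
    sample has <= ``max_other`` reads, and (by default) the junction is not in
    the reference annotation. With ``batch_map``, "other samples" is
    restricted to samples in the proband's batch. Output is sorted by
    descending proband count, then chrom, then start.
    """
    if proband not in m.samples:
        raise ValueError(f"unknown proband {proband!r}")
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    if len(m.samples) < 2:
        raise ValueError("cohort must contain >= 2 samples")
    others = [s for s in m.samples if s != proband]
    if batch_map is not None:
        batch = batch_map.get(proband)
        others = [s for s in others if batch_map.get(s) == batch]
    pcol = m.sample_column(proband)
    ocols = (
        np.stack([m.sample_column(s) for s in others], axis=1)
        if others
        else np.zeros((len(m.junctions), 0), dtype=np.int64)
    )
    max_other_counts = ocols.max(axis=1) if ocols.shape[1] else np.zeros(len(m.junctions), dtype=np.int64)
    calls = []
    for ji, j in enumerate(m.junctions):
        if pcol[ji] < min_reads:
            continue
        if ocols.shape[1] and max_other_counts[ji] > max_other:
            continue
        if require_unannotated and m.annotated_flags[ji]:
            continue
        calls.append(
            NovelJunctionCall(
                junction=j,
                proband_id=proband,
                proband_count=int(pcol[ji]),
                max_other_count=int(max_other_counts[ji]),
                n_other_samples=len(others),
                annotated=bool(m.annotated_flags[ji]),
            )
        )
    calls.sort(key=lambda c: (-c.proband_count, c.junction[0], c.junction[1], c.junction[2]))
    return calls


def flanking_normal_junctions(
    m: JunctionCountMatrix,
    ts: TranscriptSet,
    locus: GenomicInterval,
    proband: str,
    novel_calls: list[NovelJunctionCall] | None = None,
) -> bool:
    """True iff splicing around ``locus`` looks normal in the proband.

    Requires every annotated junction of the introns flanking the locus to
    have proband support >= 1, and no novel junction call to overlap the
    flanking exons/introns. A False return distinguishes "unassessable or
    abnormal" from the True "no splicing abnormality" verdict.
    Raises when the locus overlaps no annotated transcript.
    """
    transcripts = ts.transcripts_at(locus)
    if not transcripts:
        raise ValueError(f"locus {locus} is outside all annotated genes")
    if novel_calls is None:
        novel_calls = call_novel_junctions(m, proband)

    for t in transcripts:
        introns = introns_of(t)
        flank_introns: list[tuple[int, GenomicInterval]] = []
        for i, intron in enumerate(introns):
            # flanking = overlapping the locus or immediately adjacent to an
            # exon that overlaps it
            if intron.overlaps(locus):
                flank_introns.append((i, intron))
        for i, exon in enumerate(t.exons):
            if exon.overlaps(locus):
                if i - 1 >= 0:
                    flank_introns.append((i - 1, introns[i - 1]))
                if i < len(introns):
                    flank_introns.append((i, introns[i]))
        seen = {i for i, _ in flank_introns}
        flank_introns = [(i, iv) for i, iv in sorted(set(flank_introns), key=lambda x: x[0])]
        if not flank_introns:
            continue
        flank_region = GenomicInterval(
            t.chrom,
            min(min(iv.start for _, iv in flank_introns), min(t.exons[i].start for i in seen)),
            max(max(iv.end for _, iv in flank_introns), max(t.exons[min(i + 1, len(t.exons) - 1)].end for i in seen)),
            t.strand,
        )
        for _, intron in flank_introns:
            key = (intron.chrom, intron.start, intron.end, intron.strand)
            dotted = (intron.chrom, intron.start, intron.end, ".")
            support = 0
            if key in m._jidx:
                support = m.count(key, proband)
            elif dotted in m._jidx:
                support = m.count(dotted, proband)
            if support < 1:
                return False
        for call in novel_calls:
            chrom, s, e, _ = call.junction
            if chrom == flank_region.chrom and s <= flank_region.end and e >= flank_region.start:
                return False
    return True
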
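"""Transcript annotation model: exon/intron structures and known junctions.

Coordinates are 1-based and fully inclusive throughout the package (the
native GTF/VCF convention). Conversion to 0-based half-open happens only at
BED import/export. Junctions are represented by the first and last intronic
base of the spliced intron, the convention used by STAR's ``SJ.out.tab``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

#: (chrom, first intronic base, last intronic base, strand)
JunctionKey = tuple[str, int, int, str]


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based, fully inclusive genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def contains_pos(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass
class TranscriptModel:
    """One transcript: ordered exons plus optional CDS bounds.

    ``exons`` is kept in genomic (ascending) order; use
    :meth:`exons_transcription_order` for 5'->3' order on the minus strand.
    """

    transcript_id: str
    gene_symbol: str
    gene_type: str = "protein_coding"
    strand: str = "+"
    exons: list[GenomicInterval] = field(default_factory=list)
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"overlapping exons in {self.transcript_id}: {a} / {b}"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    def exons_transcription_order(self) -> list[GenomicInterval]:
        return self.exons if self.strand != "-" else list(reversed(self.exons))

    def exon_ordinal(self, idx_genomic: int) -> int:
        """Ordinal (1-based, transcription order) of the exon at genomic index."""
        n = len(self.exons)
        return idx_genomic + 1 if self.strand != "-" else n - idx_genomic

    def intron_ordinal(self, idx_genomic: int) -> int:
        n = len(self.exons) - 1
        return idx_genomic + 1 if self.strand != "-" else n - idx_genomic


def introns_of(t: TranscriptModel) -> list[GenomicInterval]:
    """Introns as the gaps between consecutive exons, in genomic order.

    Each intron spans (exon_i.end + 1, exon_{i+1}.start - 1). Single-exon
    transcripts have no introns.
    """
    if not t.exons:
        raise ValueError(f"transcript {t.transcript_id} has no exons")
    out = []
    for a, b in zip(t.exons, t.exons[1:]):
        if b.start - a.end < 2:
            raise ValueError(
                f"adjacent/overlapping exons leave no intron in {t.transcript_id}"
            )
        out.append(GenomicInterval(t.chrom, a.end + 1, b.start - 1, t.strand))
    return out


class TranscriptSet:
    """A collection of transcripts with derived junction set and interval index."""

    def __init__(self, transcripts: Iterable[TranscriptModel] = ()) -> None:
        self.transcripts: list[TranscriptModel] = list(transcripts)
        self.gene_index: dict[str, list[TranscriptModel]] = {}
        self.known_junctions: set[JunctionKey] = set()
        self._trees: dict[str, IntervalTree] = {}
        for t in self.transcripts:
            self._index(t)

    def _index(self, t: TranscriptModel) -> None:
        self.gene_index.setdefault(t.gene_symbol, []).append(t)
        for intron in introns_of(t):
            self.known_junctions.add(
                (intron.chrom, intron.start, intron.end, intron.strand)
            )
        s = t.span
        # half-open internally for intervaltree only
        self._trees.setdefault(s.chrom, IntervalTree()).addi(s.start, s.end + 1, t)

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self.transcripts)

    def transcripts_at(self, locus: GenomicInterval) -> list[TranscriptModel]:
        tree = self._trees.get(locus.chrom)
        if tree is None:
            return []
        hits = tree.overlap(locus.start, locus.end + 1)
        return sorted((h.data for h in hits), key=lambda t: t.transcript_id)

    def transcripts_of_gene(self, gene_symbol: str) -> list[TranscriptModel]:
        return self.gene_index.get(gene_symbol, [])

    def is_known_junction(self, key: JunctionKey) -> bool:
        chrom, start, end, strand = key
        if strand == ".":
            return any(
                (chrom, start, end, s) in self.known_junctions for s in "+-"
            )
        return key in self.known_junctions


def features_at(
    ts: TranscriptSet, locus: GenomicInterval
) -> list[tuple[TranscriptModel, str, int]]:
    """Every exon/intron overlapping ``locus`` with its transcription-order ordinal.

    Returns tuples of (transcript, "exon"|"intron", ordinal), ordinal 1 = first
    transcribed feature. Empty list when nothing overlaps.
    """
    out: list[tuple[TranscriptModel, str, int]] = []
    for t in ts.transcripts_at(locus):
        for i, exon in enumerate(t.exons):
            if exon.overlaps(locus):
                out.append((t, "exon", t.exon_ordinal(i)))
        for i, intron in enumerate(introns_of(t)):
            if intron.overlaps(locus):
                out.append((t, "intron", t.intron_ordinal(i)))
    return out


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(attr_col: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_col))


def load_annotation(gtf_path: str) -> TranscriptSet:
    """Load a GTF into a :class:`TranscriptSet`.

    Only ``exon`` and ``CDS`` features are consumed. Exon lines lacking a
    ``transcript_id`` attribute are skipped with a warning; other malformed
    lines are counted and logged. Gene symbol falls back from ``gene_name``
    to ``gene_id``; gene type from ``gene_type``/``gene_biotype``.
    """
    exons: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, dict[str, str]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    skipped = 0
    with open(gtf_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                skipped += 1
                continue
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = parts[:9]
            if feature not in ("exon", "CDS"):
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                skipped += 1
                continue
            a = _parse_attributes(attrs)
            tid = a.get("transcript_id")
            if not tid:
                skipped += 1
                logger.warning("GTF %s feature without transcript_id skipped", feature)
                continue
            if feature == "exon":
                exons.setdefault(tid, []).append(
                    GenomicInterval(chrom, start_i, end_i, strand)
                )
                meta.setdefault(
                    tid,
                    {
                        "gene_symbol": a.get("gene_name", a.get("gene_id", tid)),
                        "gene_type": a.get("gene_type", a.get("gene_biotype", "")),
                        "strand": strand,
                    },
                )
            else:
                cds.setdefault(tid, []).append((start_i, end_i))
    if skipped:
        logger.warning("load_annotation: skipped %d malformed GTF lines", skipped)
    transcripts = []
    for tid, ex in exons.items():
        m = meta[tid]
        bounds = cds.get(tid)
        transcripts.append(
            TranscriptModel(
                transcript_id=tid,
                gene_symbol=m["gene_symbol"],
                gene_type=m["gene_type"],
                strand=m["strand"],
                exons=ex,
                cds_start=min(s for s, _ in bounds) if bounds else None,
                cds_end=max(e for _, e in bounds) if bounds else None,
            )
        )
    transcripts.sort(key=lambda t: t.transcript_id)
    return TranscriptSet(transcripts)
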
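"""Classification of novel junctions into aberrant-splicing event classes.

Five classes are recognised: exon skipping, cryptic-exon inclusion, intron
retention, and alternative donor / acceptor use; anything else is
``unclassified``. Junction-based classes are decided by where the two ends
of a novel junction fall relative to a transcript's annotated splice sites,
evaluated per transcript (rules applied in order, mutually exclusive):

(a) both ends on annotated intron boundaries of different introns
    -> exon skipping of the in-between exons;
(b) one end annotated, the other inside an exon -> alternative donor or
    acceptor with exon truncation (negative length change);
(c) one end annotated, the other inside the same intron -> alternative
    donor/acceptor including intronic sequence (positive length change);
    when a partner junction brackets an internal intronic segment with it,
    the pair is promoted to a cryptic exon (d);
(e) otherwise unclassified.

Intron retention produces no junction and is detected from per-base
coverage: the intron-to-flanking-exon coverage ratio must clear an absolute
threshold and a fold-change over the best control. The thresholds are
conservative defaults exposed in configuration — retention is the class most
easily confounded by shared intronic noise.

Donor/acceptor naming is strand-aware: the donor is the 5' splice site in
transcription order, so on the minus strand the genomic-right end of an
intron is the donor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np

from splicedx.annotation import (
    GenomicInterval,
    JunctionKey,
    TranscriptModel,
    TranscriptSet,
    introns_of,
)

EventClass = Literal[
    "exon_skipping",
    "cryptic_exon",
    "intron_retention",
    "alt_donor",
    "alt_acceptor",
    "unclassified",
]


@dataclass
class SpliceEvent:
    """A classified aberrant-splicing call against one transcript."""

    event_class: EventClass
    gene_symbol: str
    transcript_id: str
    junctions: tuple[JunctionKey, ...]
    affected_region: GenomicInterval
    delta_length_nt: int
    proband_id: str | None = None
    proband_support: int = 0

    def __post_init__(self) -> None:
        expected = {"cryptic_exon": 2, "intron_retention": 0}.get(self.event_class)
        if expected is None:
            expected = 0 if self.event_class == "unclassified" else 1
        if self.event_class != "unclassified" and len(self.junctions) != expected:
            raise ValueError(
                f"{self.event_class} must carry {expected} junctions, "
                f"got {len(self.junctions)}"
            )

    def interval_for_intersection(self) -> GenomicInterval:
        """Union span of splice-site positions and the affected region."""
        positions = [self.affected_region.start, self.affected_region.end]
        for _, s, e, _ in self.junctions:
            positions.extend((s, e))
        return GenomicInterval(
            self.affected_region.chrom,
            min(positions),
            max(positions),
            self.affected_region.strand,
        )


@dataclass
class ConsequenceCall:
    """Reading-frame consequence of a splice event (length-based)."""

    frame: Literal["in_frame", "frameshift", "not_applicable"]
    delta_codons: int | None
    description: str


@dataclass
class IntronRetentionCall:
    """Coverage-based intron-retention assessment for one intron."""

    intron: GenomicInterval
    proband_ratio: float
    max_control_ratio: float
    called: bool
    assessable: bool = True


def _donor_side_is_start(strand: str) -> bool:
    """On '+' the intron's genomic start is the donor side; on '-' the end."""
    return strand != "-"


def classify_junction(
    j: JunctionKey,
    ts: TranscriptSet,
    partner_candidates: Sequence[JunctionKey] = (),
    proband_id: str | None = None,
    proband_support: int = 0,
) -> list[SpliceEvent]:
    """Classify one novel junction against every overlapping transcript.

    Returns one :class:`SpliceEvent` per transcript whose span overlaps the
    junction. Raises if the junction is annotated for a transcript it is
    evaluated against (callers must pre-filter annotated junctions).
    """
    chrom, js, je, jstrand = j
    locus = GenomicInterval(chrom, js, je, jstrand if jstrand in "+-" else ".")
    transcripts = ts.transcripts_at(locus)
    events: list[SpliceEvent] = []
    for t in transcripts:
        if jstrand in "+-" and t.strand != jstrand:
            continue
        events.append(
            _classify_for_transcript(j, t, ts, partner_candidates, proband_id, proband_support)
        )
    if not events:
        events.append(
            SpliceEvent(
                event_class="unclassified",
                gene_symbol="",
                transcript_id="",
                junctions=(),
                affected_region=locus,
                delta_length_nt=0,
                proband_id=proband_id,
                proband_support=proband_support,
            )
        )
    return events


def _classify_for_transcript(
    j: JunctionKey,
    t: TranscriptModel,
    ts: TranscriptSet,
    partner_candidates: Sequence[JunctionKey],
    proband_id: str | None,
    proband_support: int,
) -> SpliceEvent:
    chrom, js, je, _ = j
    introns = introns_of(t)
    intron_starts = {iv.start: i for i, iv in enumerate(introns)}
    intron_ends = {iv.end: i for i, iv in enumerate(introns)}

    start_i = intron_starts.get(js)
    end_i = intron_ends.get(je)

    if start_i is not None and end_i is not None and start_i == end_i:
        raise ValueError(f"junction {j} is annotated for transcript {t.transcript_id}")

    def make(event_class, junctions, region, delta):
        return SpliceEvent(
            event_class=event_class,
            gene_symbol=t.gene_symbol,
            transcript_id=t.transcript_id,
            junctions=junctions,
            affected_region=region,
            delta_length_nt=delta,
            proband_id=proband_id,
            proband_support=proband_support,
        )

    # (a) exon skipping: annotated donor of intron i, annotated acceptor of
    # intron i+k (genomic); the exons in between are skipped.
    if start_i is not None and end_i is not None and end_i > start_i:
        skipped = t.exons[start_i + 1 : end_i + 1]
        delta = -sum(len(e) for e in skipped)
        region = GenomicInterval(chrom, skipped[0].start, skipped[-1].end, t.strand)
        return make("exon_skipping", (j,), region, delta)

    exon_starts = {e.start: i for i, e in enumerate(t.exons)}

    def exon_index_containing(pos: int) -> int | None:
        for i, e in enumerate(t.exons):
            if e.contains_pos(pos):
                return i
        return None

    def exonic_bases_within(lo: int, hi: int) -> int:
        return sum(
            max(0, min(e.end, hi) - max(e.start, lo) + 1) for e in t.exons
        )

    donor_is_start = _donor_side_is_start(t.strand)

    if start_i is not None and end_i is None:
        # genomic-start end annotated; the genomic-end end is novel
        novel_is_donor = not donor_is_start
        ex = exon_index_containing(je)
        if ex is not None:
            # (b) truncation: exonic bases between intron end and je removed
            intron = introns[start_i]
            removed = exonic_bases_within(intron.end + 1, je)
            region = GenomicInterval(chrom, intron.end + 1, je, t.strand)
            return make(
                "alt_donor" if novel_is_donor else "alt_acceptor",
                (j,), region, -removed,
            )
        intron = introns[start_i]
        if intron.contains_pos(je):
            # (c)/(d): novel end inside the same intron
            partner = _find_cryptic_partner(j, intron, partner_candidates, side="end")
            if partner is not None:
                return _cryptic_event(j, partner, t, make)
            included = intron.end - je
            region = GenomicInterval(chrom, je + 1, intron.end, t.strand)
            return make(
                "alt_donor" if novel_is_donor else "alt_acceptor",
                (j,), region, included,
            )
    elif end_i is not None and start_i is None:
        novel_is_donor = donor_is_start
        ex = exon_index_containing(js)
        if ex is not None:
            intron = introns[end_i]
            removed = exonic_bases_within(js, intron.start - 1)
            region = GenomicInterval(chrom, js, intron.start - 1, t.strand)
            return make(
                "alt_donor" if novel_is_donor else "alt_acceptor",
                (j,), region, -removed,
            )
        intron = introns[end_i]
        if intron.contains_pos(js):
            partner = _find_cryptic_partner(j, intron, partner_candidates, side="start")
            if partner is not None:
                return _cryptic_event(partner, j, t, make)
            included = js - intron.start
            region = GenomicInterval(chrom, intron.start, js - 1, t.strand)
            return make(
                "alt_donor" if novel_is_donor else "alt_acceptor",
                (j,), region, included,
            )

    # (e) unclassified
    return make(
        "unclassified", (), GenomicInterval(chrom, js, je, t.strand), 0
    )


def _find_cryptic_partner(
    j: JunctionKey,
    intron: GenomicInterval,
    partner_candidates: Sequence[JunctionKey],
    side: str,
) -> JunctionKey | None:
    """Find a partner junction bracketing an internal segment with ``j``.

    ``side="end"``: j's novel end is its genomic end; the partner must start
    after it inside the intron and end on the intron's annotated end.
    ``side="start"``: the mirror case.
    """
    chrom, js, je, _ = j
    for p in partner_candidates:
        pchrom, ps, pe, _ = p
        if pchrom != chrom or p == j:
            continue
        if side == "end":
            if ps > je + 1 and pe == intron.end and intron.contains_pos(ps):
                return p
        else:
            if pe < js - 1 and ps == intron.start and intron.contains_pos(pe):
                return p
    return None


def _cryptic_event(j_left, j_right, t, make) -> SpliceEvent:
    """Cryptic exon bracketed by two junctions (left ends before right starts)."""
    chrom, _, le, _ = j_left
    _, rs, _, _ = j_right
    region = GenomicInterval(chrom, le + 1, rs - 1, t.strand)
    return make("cryptic_exon", (j_left, j_right), region, len(region))


def classify_novel_junctions(
    calls,
    ts: TranscriptSet,
) -> list[SpliceEvent]:
    """Classify a proband's novel-junction calls, deduplicating cryptic pairs.

    ``calls`` are :class:`~splicedx.junctions.NovelJunctionCall` records. Each
    junction is classified against all overlapping transcripts with its
    co-called junctions as cryptic-exon partner candidates; a cryptic exon
    reported from both of its junctions is emitted once.
    """
    keys = [c.junction for c in calls]
    events: list[SpliceEvent] = []
    seen: set[tuple] = set()
    for c in calls:
        for e in classify_junction(
            c.junction, ts, partner_candidates=keys,
            proband_id=c.proband_id, proband_support=c.proband_count,
        ):
            ident = (
                e.event_class, e.transcript_id, tuple(sorted(e.junctions)),
                e.affected_region.start, e.affected_region.end,
            )
            if ident in seen:
                continue
            seen.add(ident)
            events.append(e)
    return events


def detect_intron_retention(
    cov: Mapping[str, np.ndarray],
    cov_start: int,
    intron: GenomicInterval,
    flank_exons: tuple[GenomicInterval, GenomicInterval],
    proband: str,
    min_ratio: float = 0.15,
    min_fold_vs_controls: float = 3.0,
    min_exon_cov: float = 10.0,
) -> IntronRetentionCall:
    """Call intron retention from per-base coverage.

    ``cov`` maps sample id to a depth array whose first element is genomic
    position ``cov_start``; arrays must span the intron and both flanking
    exons. The proband's intron/flank median-coverage ratio must reach
    ``min_ratio``, the flanking-exon median must reach ``min_exon_cov``, and
    the ratio must exceed ``min_fold_vs_controls`` times the best control
    ratio. Zero flanking coverage in the proband makes the locus
    not-assessable (distinct from not-called).
    """
    def region_slice(arr: np.ndarray, iv: GenomicInterval) -> np.ndarray:
        lo, hi = iv.start - cov_start, iv.end - cov_start + 1
        if lo < 0 or hi > len(arr):
            raise ValueError("coverage array does not span the requested region")
        return arr[lo:hi]

    def ratio_for(sample: str) -> tuple[float, float]:
        arr = np.asarray(cov[sample], dtype=float)
        intron_med = float(np.median(region_slice(arr, intron)))
        exon_med = float(
            np.median(np.concatenate([region_slice(arr, fe) for fe in flank_exons]))
        )
        return intron_med, exon_med

    controls = [s for s in cov if s != proband]
    if not controls:
        raise ValueError("intron-retention call needs at least one control sample")
    p_intron, p_exon = ratio_for(proband)
    if p_exon <= 0:
        return IntronRetentionCall(intron, 0.0, 0.0, called=False, assessable=False)
    proband_ratio = p_intron / p_exon
    control_ratios = []
    for s in controls:
        c_intron, c_exon = ratio_for(s)
        control_ratios.append(c_intron / c_exon if c_exon > 0 else 0.0)
    max_control = max(control_ratios)
    called = (
        proband_ratio >= min_ratio
        and p_exon >= min_exon_cov
        and proband_ratio >= min_fold_vs_controls * max_control
    )
    return IntronRetentionCall(intron, proband_ratio, max_control, called=called)


def annotate_consequence(e: SpliceEvent, t: TranscriptModel) -> ConsequenceCall:
    """Length-based reading-frame consequence of a splice event.

    Frameshift iff ``|delta| mod 3 != 0``; events entirely outside the CDS
    are reported ``not_applicable``. Frame is judged from length alone — no
    scan for stop codons inside included sequence is attempted.
    """
    delta = e.delta_length_nt
    if t.cds_start is not None and t.cds_end is not None:
        region = e.affected_region
        if region.end < t.cds_start or region.start > t.cds_end:
            return ConsequenceCall(
                frame="not_applicable",
                delta_codons=None,
                description=_describe(e, None),
            )
    if delta % 3 != 0:
        return ConsequenceCall(
            frame="frameshift", delta_codons=None, description=_describe(e, "frameshift")
        )
    return ConsequenceCall(
        frame="in_frame", delta_codons=delta // 3, description=_describe(e, "in_frame")
    )


def _describe(e: SpliceEvent, frame: str | None) -> str:
    region = e.affected_region
    loc = f"{region.chrom}:{region.start}-{region.end}"
    base = {
        "exon_skipping": f"exon skipping at {loc}, deletion of {-e.delta_length_nt} nt",
        "cryptic_exon": f"cryptic exon inclusion at {loc}, insertion of {e.delta_length_nt} nt",
        "intron_retention": f"retention of intron {loc}",
        "alt_donor": f"alternative donor site at {loc} ({e.delta_length_nt:+d} nt)",
        "alt_acceptor": f"alternative acceptor site at {loc} ({e.delta_length_nt:+d} nt)",
        "unclassified": f"unclassified splicing change at {loc}",
    }[e.event_class]
    if frame == "frameshift":
        return base + ", out of frame"
    if frame == "in_frame":
        return base + f", in-frame ({abs(e.delta_length_nt) // 3} codons)"
    return base
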
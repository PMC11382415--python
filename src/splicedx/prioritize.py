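"""Candidate prioritization: variant-event intersection and panel filtering.

Two complementary strategies narrow aberrant-splicing events to reviewable
candidates:

* genotype-to-phenotype — pad each filtered RNA variant by 25 bp on both
  sides and keep events whose splice sites or affected region overlap a
  window (the bedtools-intersect step, done natively on 1-based inclusive
  intervals);
* phenotype-to-genotype — keep events whose gene is on a clinical gene
  panel chosen from the patient's phenotype.

Ranking is a deterministic convenience ordering (variant-supported first,
then splice-evidence strength), not a validated score: final candidacy
review remains manual.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

from splicedx.annotation import GenomicInterval
from splicedx.events import ConsequenceCall, SpliceEvent
from splicedx.variants import VariantCall, max_delta


@dataclass
class VariantWindow:
    """A filtered variant padded to a +/- pad bp search interval."""

    variant: VariantCall
    interval: GenomicInterval


@dataclass
class GenePanel:
    """A clinical gene panel: canonical upper-case symbols plus optional confidence."""

    name: str
    version: str = ""
    symbols: set[str] = field(default_factory=set)
    confidence: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.symbols = {s.upper() for s in self.symbols}
        self.confidence = {k.upper(): v for k, v in self.confidence.items()}

    def __contains__(self, gene_symbol: str) -> bool:
        return gene_symbol.upper() in self.symbols

    @classmethod
    def from_tsv(cls, path: str, name: str = "", version: str = "") -> "GenePanel":
        """Read a panel TSV: first column gene symbol, optional second confidence."""
        symbols: set[str] = set()
        confidence: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                sym = parts[0].strip().upper()
                if sym.lower() in ("gene", "symbol", "gene_symbol"):
                    continue
                symbols.add(sym)
                if len(parts) > 1:
                    confidence[sym] = parts[1].strip()
        return cls(name=name or path, version=version, symbols=symbols,
                   confidence=confidence)


Strategy = Literal["genotype_to_phenotype", "phenotype_to_genotype"]


@dataclass
class Candidate:
    """A prioritized (event, variant) or (event, panel) pair."""

    proband_id: str | None
    event: SpliceEvent
    strategy: Strategy
    variant: VariantCall | None = None
    panel_name: str | None = None
    distance_bp: int | None = None
    consequence: ConsequenceCall | None = None
    rank_score: float = 0.0


def make_variant_windows(
    calls: list[VariantCall], pad: int = 25
) -> list[VariantWindow]:
    """One +/- ``pad`` bp window per call, 1-based inclusive, clipped at 1."""
    if pad < 0:
        raise ValueError("pad must be >= 0")
    return [
        VariantWindow(
            variant=v,
            interval=GenomicInterval(v.chrom, max(1, v.pos - pad), v.pos + pad),
        )
        for v in calls
    ]


def intersect_variants_events(
    events: list[SpliceEvent], windows: list[VariantWindow]
) -> list[Candidate]:
    """Genotype-to-phenotype intersection.

    A candidate is emitted for every (event, window) pair sharing >= 1 base
    on the same chromosome, with the event interval taken as the union of
    its splice-site positions and affected region — so both exonic variants
    at a new splice site and deep-intronic variants inside a cryptic exon
    intersect. ``distance_bp`` is 0 for overlapping pairs (kept for
    reporting symmetry).
    """
    out: list[Candidate] = []
    for e in events:
        if e.event_class == "unclassified":
            continue
        iv = e.interval_for_intersection()
        for w in windows:
            if iv.overlaps(w.interval):
                out.append(
                    Candidate(
                        proband_id=e.proband_id,
                        event=e,
                        strategy="genotype_to_phenotype",
                        variant=w.variant,
                        distance_bp=0,
                    )
                )
    return out


def filter_events_by_panel(
    events: list[SpliceEvent], panel: GenePanel
) -> list[Candidate]:
    """Phenotype-to-genotype restriction: events in panel genes (case-insensitive)."""
    if not panel.symbols:
        raise ValueError(f"panel {panel.name!r} is empty")
    return [
        Candidate(
            proband_id=e.proband_id,
            event=e,
            strategy="phenotype_to_genotype",
            panel_name=panel.name,
        )
        for e in events
        if e.gene_symbol and e.gene_symbol in panel
    ]


def rank_candidates(cands: list[Candidate]) -> list[Candidate]:
    """Deterministic ordering: variant-supported first, then max SpliceAI
    delta (desc), then proband junction support (desc), then position."""
    def sort_key(c: Candidate):
        delta = (
            max_delta(c.variant.spliceai)
            if c.variant is not None and c.variant.spliceai is not None
            else 0.0
        )
        region = c.event.affected_region
        return (
            0 if c.variant is not None else 1,
            -delta,
            -c.event.proband_support,
            region.chrom,
            region.start,
            region.end,
            c.event.transcript_id,
        )

    ranked = sorted(cands, key=sort_key)
    for i, c in enumerate(ranked):
        c.rank_score = float(len(ranked) - i)
    return ranked


def interval_to_bed_line(iv: GenomicInterval, name: str = ".") -> str:
    """1-based inclusive -> BED (0-based half-open) line."""
    return f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{name}"


def bed_line_to_interval(line: str) -> GenomicInterval:
    """BED (0-based half-open) -> 1-based inclusive interval."""
    chrom, start, end = line.rstrip("\n").split("\t")[:3]
    return GenomicInterval(chrom, int(start) + 1, int(end))
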
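"""Five-type alternative-splicing event classification.

Two isoforms of one locus are compared as exon chains and every maximal
genomic region where their structures differ is labelled independently:

* TSS / TTS — the difference region touches the transcript terminus on the
  5' / 3' side (alternative start / terminal exon or boundary);
* ES — exon skipping: the region is a complete exon of one isoform lying
  inside an intron of the other (intronic context on both flanks);
* IR — intron retention: the region is a complete intron of one isoform
  covered by an exon of the other (exonic context on both flanks);
* AE — alternative exon boundary (alternative donor/acceptor): an internal
  exon edge shifts, giving a region with exonic context on one flank and
  intronic on the other.

Regions whose internal structure matches none of the five definitions are
reported as ``other`` and excluded from the five-type summary.  The labels
are strand-aware: mirroring a locus' coordinates while keeping strand
labels swaps TSS and TTS and preserves ES/IR/AE, while a true reverse
complement (mirror plus strand flip) leaves all five types unchanged.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from typing import Iterable, Sequence

from .annotation_io import TranscriptModel

__all__ = [
    "EVENT_TYPES",
    "ASEvent",
    "ASEventSummary",
    "pairwise_events",
    "locus_events",
    "group_loci",
    "summarize_events",
    "spliced_fraction",
    "mirror_transcript",
]

EVENT_TYPES = ("TSS", "TTS", "ES", "IR", "AE")


@dataclass(frozen=True)
class ASEvent:
    """A typed splicing difference between two isoforms.

    ``region`` is the genomic interval (0-based half-open) localising the
    difference; ``event_type`` is one of the five categories, or ``other``
    for differences matching none of them.
    """

    event_type: str
    isoform_a: str
    isoform_b: str
    region: tuple[int, int]
    strand: str

    def __post_init__(self):
        if self.isoform_a == self.isoform_b:
            raise ValueError("an AS event needs two distinct isoforms")
        if self.region[1] <= self.region[0]:
            raise ValueError("event region must be non-empty")
        if self.event_type not in EVENT_TYPES + ("other",):
            raise ValueError(f"unknown event type {self.event_type!r}")


def _membership(chain: Sequence[tuple[int, int]], starts: list[int]):
    """Return a membership lookup: 'E' inside an exon, 'I' inside the span
    but between exons, 'O' outside the span."""
    span_start, span_end = chain[0][0], chain[-1][1]

    def mem(pos: int) -> str:
        if pos < span_start or pos >= span_end:
            return "O"
        i = bisect_right(starts, pos) - 1
        if i >= 0 and chain[i][0] <= pos < chain[i][1]:
            return "E"
        return "I"

    return mem


def pairwise_events(a: TranscriptModel, b: TranscriptModel) -> list[ASEvent]:
    """Classify all splicing differences between two isoforms.

    Both transcripts must share chromosome and strand, and their genomic
    spans must overlap (one locus).  Identical chains yield no events, as
    does a pair of single-exon isoforms (no splice structure to compare).
    One comparison may emit several events.
    """
    if a.chrom != b.chrom:
        raise ValueError(
            f"{a.transcript_id} and {b.transcript_id} are on different chromosomes"
        )
    if a.strand != b.strand:
        raise ValueError(
            f"{a.transcript_id} and {b.transcript_id} are on different strands"
        )
    if a.end <= b.start or b.end <= a.start:
        raise ValueError(
            f"{a.transcript_id} and {b.transcript_id} do not overlap; not one locus"
        )
    if a.exons == b.exons:
        return []
    if a.n_exons == 1 and b.n_exons == 1:
        return []

    exons_a, exons_b = a.exons, b.exons
    starts_a = [s for s, _ in exons_a]
    starts_b = [s for s, _ in exons_b]
    mem_a = _membership(exons_a, starts_a)
    mem_b = _membership(exons_b, starts_b)

    union_start = min(a.start, b.start)
    union_end = max(a.end, b.end)
    bounds = sorted(
        {x for s, e in exons_a + exons_b for x in (s, e)}
        | {union_start, union_end}
    )

    # Piecewise-constant membership segments over the union span.
    segments = []  # (start, end, memA, memB)
    for s, e in zip(bounds, bounds[1:]):
        segments.append((s, e, mem_a(s), mem_b(s)))

    # Connected difference regions: maximal runs of differing segments.
    regions: list[list[tuple[int, int, str, str]]] = []
    current: list[tuple[int, int, str, str]] = []
    for seg in segments:
        if seg[2] != seg[3]:
            current.append(seg)
        elif current:
            regions.append(current)
            current = []
    if current:
        regions.append(current)

    events: list[ASEvent] = []
    for reg in regions:
        r_start, r_end = reg[0][0], reg[-1][1]
        patterns = [(m1, m2) for _, _, m1, m2 in reg]
        has_o = any("O" in p for p in patterns)
        if has_o:
            touches_left = r_start == union_start
            touches_right = r_end == union_end
            if touches_left and touches_right:
                etype = "other"
            elif touches_left:
                etype = "TSS" if a.strand == "+" else "TTS"
            else:
                etype = "TTS" if a.strand == "+" else "TSS"
        elif len(set(patterns)) == 1:
            # Uniform internal region: classify by flanking context, which
            # both isoforms agree on (the region is maximal).
            left = mem_a(r_start - 1)
            right = mem_a(r_end)
            if left == "E" and right == "E":
                etype = "IR"
            elif left == "I" and right == "I":
                etype = "ES"
            else:
                etype = "AE"
        else:
            etype = "other"
        events.append(
            ASEvent(
                event_type=etype,
                isoform_a=a.transcript_id,
                isoform_b=b.transcript_id,
                region=(r_start, r_end),
                strand=a.strand,
            )
        )
    return events


def group_loci(transcripts: Iterable[TranscriptModel]) -> list[list[TranscriptModel]]:
    """Group transcripts into loci by genomic-span overlap on one strand."""
    by_key: dict[tuple[str, str], list[TranscriptModel]] = {}
    for t in transcripts:
        by_key.setdefault((t.chrom, t.strand), []).append(t)
    loci: list[list[TranscriptModel]] = []
    for group in by_key.values():
        group = sorted(group, key=lambda t: t.span)
        current: list[TranscriptModel] = []
        reach = None
        for t in group:
            if current and t.start < reach:
                current.append(t)
                reach = max(reach, t.end)
            else:
                if current:
                    loci.append(current)
                current = [t]
                reach = t.end
        if current:
            loci.append(current)
    return loci


def locus_events(
    transcripts: Sequence[TranscriptModel], count_mode: str = "locus"
) -> list[ASEvent]:
    """Union of pairwise events over all unordered isoform pairs at a locus.

    In ``locus`` mode (default) the same physical event observed in several
    pairs is counted once, keyed by (event type, genomic region); in
    ``pairwise`` mode every pair's events are kept.
    """
    if count_mode not in ("locus", "pairwise"):
        raise ValueError("count_mode must be 'locus' or 'pairwise'")
    all_events: list[ASEvent] = []
    txs = list(transcripts)
    for i in range(len(txs)):
        for j in range(i + 1, len(txs)):
            all_events.extend(pairwise_events(txs[i], txs[j]))
    if count_mode == "pairwise":
        return all_events
    seen: dict[tuple[str, tuple[int, int]], ASEvent] = {}
    for ev in all_events:
        seen.setdefault((ev.event_type, ev.region), ev)
    return list(seen.values())


@dataclass
class ASEventSummary:
    """Per-type counts and percentages of the five AS categories."""

    counts: dict[str, int]
    percentages: dict[str, float]
    total: int
    transcript_class: str = "lncRNA"
    zero_total: bool = False

    @classmethod
    def from_counts(
        cls, counts: dict[str, int], transcript_class: str = "lncRNA"
    ) -> "ASEventSummary":
        counts = {t: int(counts.get(t, 0)) for t in EVENT_TYPES}
        total = sum(counts.values())
        if total == 0:
            return cls(
                counts=counts,
                percentages={t: 0.0 for t in EVENT_TYPES},
                total=0,
                transcript_class=transcript_class,
                zero_total=True,
            )
        pct = {t: round(100.0 * c / total, 2) for t, c in counts.items()}
        return cls(
            counts=counts,
            percentages=pct,
            total=total,
            transcript_class=transcript_class,
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "events": [self.counts[t] for t in EVENT_TYPES] + [self.total],
                "percentage": [self.percentages[t] for t in EVENT_TYPES]
                + [round(sum(self.percentages.values()), 2)],
            },
            index=list(EVENT_TYPES) + ["Total"],
        )


def spliced_fraction(n_with_events: int, n_total: int) -> float:
    """Percentage of transcripts involved in at least one AS event,
    rounded to two decimals."""
    if n_total <= 0:
        return 0.0
    return round(100.0 * n_with_events / n_total, 2)


def summarize_events(
    events: Sequence[ASEvent],
    n_transcripts_with_structure: int,
    transcript_class: str = "lncRNA",
) -> tuple[ASEventSummary, float]:
    """Tally classified events into the five-type summary table.

    ``other``-labelled regions are excluded.  The spliced fraction is the
    percentage of ``n_transcripts_with_structure`` involved in >= 1 event
    (distinct isoform ids appearing in the event list).
    """
    counts = {t: 0 for t in EVENT_TYPES}
    involved: set[str] = set()
    for ev in events:
        if ev.event_type in counts:
            counts[ev.event_type] += 1
            involved.add(ev.isoform_a)
            involved.add(ev.isoform_b)
    summary = ASEventSummary.from_counts(counts, transcript_class)
    return summary, spliced_fraction(len(involved), n_transcripts_with_structure)


def mirror_transcript(t: TranscriptModel, axis: int, flip_strand: bool = False):
    """Mirror a transcript's coordinates about ``axis`` (pos -> axis - pos).

    With ``flip_strand=False`` the strand label is kept, modelling a
    coordinate mirror of the annotation; with ``flip_strand=True`` the
    operation is a genuine reverse complement of the locus.
    """
    exons = tuple((axis - e, axis - s) for s, e in t.exons)
    strand = t.strand
    if flip_strand:
        strand = "-" if strand == "+" else "+"
    return TranscriptModel(
        transcript_id=t.transcript_id,
        gene_id=t.gene_id,
        chrom=t.chrom,
        strand=strand,
        exons=exons,
        biotype=t.biotype,
    )
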
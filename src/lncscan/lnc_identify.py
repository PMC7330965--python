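"""Candidate filtering and positional classification of lncRNAs.

The identification cascade mirrors the standard genome-wide screen for long
noncoding RNAs in an assembled plant transcriptome:

1. *candidate filter* — spliced length strictly greater than 200 nt and at
   least two exons (single-exon fragments are a major source of assembly
   false positives);
2. *coding screen* — an ORF-length heuristic standing in for external
   coding-potential tools: a transcript is treated as coding when its
   longest open reading frame reaches ``orf_max_aa`` (default 100 aa).
   The identified lncRNA populations this targets have mean ORFs of ~100 nt
   (~32 aa), far below the threshold, while genuine mRNAs sit far above it;
3. *positional classification* against the coding reference annotation
   into lincRNA (intergenic), incRNA (fully intronic) and antisense
   (exon-exon overlap on the opposite strand).  Transcripts with same-strand
   exonic overlap with a coding gene are dropped as unresolvable from the
   sense mRNA population.

Only the annotated transcript strand's three frames are scanned for ORFs,
matching how coding-potential tools treat assembled, strand-resolved
transcripts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .annotation_io import (
    CountTable,
    GeneModel,
    TranscriptModel,
    extract_spliced_sequence,
)

__all__ = [
    "ORFReport",
    "PositionalClass",
    "LncRNARecord",
    "ReferenceIndex",
    "IdentificationResult",
    "find_longest_orf",
    "longest_orf_aa",
    "candidate_filter",
    "coding_heuristic",
    "classify_position",
    "run_identification",
    "truncated_isoform_screen",
]

START_CODON = "ATG"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

DEFAULT_MIN_LENGTH = 200  # candidate rule is strictly greater than this
DEFAULT_MIN_EXONS = 2
DEFAULT_ORF_MAX_AA = 100
DEFAULT_TRUNC_FRAC = 0.7
TRANSCRIBED_FPKM = 0.1


@dataclass(frozen=True)
class ORFReport:
    """Longest open reading frame of a spliced transcript sequence.

    Coordinates are 0-based half-open on the spliced transcript.  For a
    complete ORF (ATG...stop) ``aa_length`` excludes the stop codon, so
    ``aa_length = (orf_end - orf_start) / 3 - 1``.  When no complete ORF
    exists the report describes the longest ATG-to-end open stretch with
    ``has_stop=False`` and ``aa_length`` the number of whole codons.
    """

    transcript_id: str
    orf_start: int
    orf_end: int
    aa_length: int
    has_start: bool
    has_stop: bool

    @property
    def complete(self) -> bool:
        return self.has_start and self.has_stop

    @property
    def nt_length(self) -> int:
        return self.orf_end - self.orf_start


def _scan_orfs(seq: str) -> tuple[tuple[int, int] | None, tuple[int, int] | None]:
    """Single forward pass over the three frames of ``seq``.

    Returns ``(best_complete, best_open)`` as (start, end) spliced-coordinate
    pairs (end includes the stop codon for complete ORFs; open stretches are
    truncated to whole codons).  Longest wins; ties break to the smallest
    start.  Only ATG...{TAA,TAG,TGA} in the given (strand-resolved) sequence
    counts; codons containing N never match.
    """
    best_complete: tuple[int, int] | None = None
    best_open: tuple[int, int] | None = None

    def better(cand, best):
        if best is None:
            return True
        cl, bl = cand[1] - cand[0], best[1] - best[0]
        return cl > bl or (cl == bl and cand[0] < best[0])

    n = len(seq)
    for frame in range(3):
        open_start: int | None = None
        pos = frame
        while pos + 3 <= n:
            codon = seq[pos : pos + 3]
            if codon in STOP_CODONS:
                if open_start is not None:
                    cand = (open_start, pos + 3)
                    if better(cand, best_complete):
                        best_complete = cand
                    open_start = None
            elif codon == START_CODON and open_start is None:
                open_start = pos
            pos += 3
        if open_start is not None:
            cand = (open_start, pos)  # pos = last full-codon boundary
            if better(cand, best_open):
                best_open = cand
    return best_complete, best_open


def find_longest_orf(seq: str, transcript_id: str = "") -> ORFReport:
    """Longest ORF of an already strand-resolved, spliced sequence.

    A complete ORF (ATG through an in-frame stop) is always preferred; when
    none exists the longest ATG-to-end open stretch is reported with
    ``has_stop=False``.  An empty sequence, or one without any start codon,
    yields a zero-length report.
    """
    best_complete, best_open = _scan_orfs(seq.upper())
    if best_complete is not None:
        s, e = best_complete
        return ORFReport(
            transcript_id=transcript_id,
            orf_start=s,
            orf_end=e,
            aa_length=(e - s) // 3 - 1,
            has_start=True,
            has_stop=True,
        )
    if best_open is not None:
        s, e = best_open
        return ORFReport(
            transcript_id=transcript_id,
            orf_start=s,
            orf_end=e,
            aa_length=(e - s) // 3,
            has_start=True,
            has_stop=False,
        )
    return ORFReport(
        transcript_id=transcript_id,
        orf_start=0,
        orf_end=0,
        aa_length=0,
        has_start=False,
        has_stop=False,
    )


def longest_orf_aa(seq: str) -> int:
    """Length in aa of the longest coding stretch, complete or open.

    This is the quantity the coding screen thresholds: a long stop-free
    ATG-led frame is treated as coding capacity even without a stop codon
    inside the assembled fragment.
    """
    best_complete, best_open = _scan_orfs(seq.upper())
    aa = 0
    if best_complete is not None:
        aa = max(aa, (best_complete[1] - best_complete[0]) // 3 - 1)
    if best_open is not None:
        aa = max(aa, (best_open[1] - best_open[0]) // 3)
    return aa


# ---------------------------------------------------------------------------
# Filter cascade


FilterTrail = list[tuple[str, bool, float]]


def candidate_filter(
    t: TranscriptModel,
    min_length: int = DEFAULT_MIN_LENGTH,
    min_exons: int = DEFAULT_MIN_EXONS,
) -> tuple[bool, FilterTrail]:
    """Length/exon-count candidate rule.

    Pass iff spliced length > ``min_length`` (strict) AND exon count >=
    ``min_exons``.  The trail records both metrics regardless of outcome.
    Relaxed single-exon screening can be requested with ``min_exons=1``.
    """
    length_ok = t.spliced_length > min_length
    exons_ok = t.n_exons >= min_exons
    trail: FilterTrail = [
        ("length_gt_200", length_ok, float(t.spliced_length)),
        ("min_exons", exons_ok, float(t.n_exons)),
    ]
    return length_ok and exons_ok, trail


def coding_heuristic(
    t: TranscriptModel,
    genome: Mapping[str, str],
    orf_max_aa: int = DEFAULT_ORF_MAX_AA,
) -> tuple[bool, FilterTrail, ORFReport]:
    """ORF-length coding screen; pass means *noncoding*.

    Noncoding iff the longest coding stretch (complete ORF, or stop-free
    ATG-led open stretch) encodes fewer than ``orf_max_aa`` amino acids.
    """
    seq = extract_spliced_sequence(t, genome)
    report = find_longest_orf(seq, t.transcript_id)
    aa = longest_orf_aa(seq)
    noncoding = aa < orf_max_aa
    trail: FilterTrail = [("orf_below_max_aa", noncoding, float(aa))]
    return noncoding, trail, report


class PositionalClass(str, Enum):
    LINCRNA = "lincRNA"
    INCRNA = "incRNA"
    ANTISENSE = "antisense"
    SENSE_OVERLAP = "sense_overlap"  # dropped: same-strand exonic overlap
    GENIC_OTHER = "genic_other"  # dropped: genic overlap not matching a class


class ReferenceLookupError(KeyError):
    """Transcript chromosome absent from the reference index."""


class ReferenceIndex:
    """Interval index over a coding reference annotation.

    Holds per-chromosome trees of gene spans and per-strand trees of coding
    exons, plus the merged intron intervals of each gene for containment
    tests.
    """

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes: list[GeneModel] = list(genes)
        self._spans: dict[str, IntervalTree] = {}
        self._exons: dict[tuple[str, str], IntervalTree] = {}
        for g in self.genes:
            s, e = g.span
            self._spans.setdefault(g.chrom, IntervalTree())[s:e] = g
            tree = self._exons.setdefault((g.chrom, g.strand), IntervalTree())
            for xs, xe in g.exon_union:
                tree[xs:xe] = g
        self.chromosomes = sorted(self._spans)

    def has_chrom(self, chrom: str) -> bool:
        return chrom in self._spans

    def exon_overlaps(self, t: TranscriptModel, strand: str) -> bool:
        tree = self._exons.get((t.chrom, strand))
        if tree is None:
            return False
        return any(tree.overlap(s, e) for s, e in t.exons)

    def span_overlaps(self, t: TranscriptModel):
        tree = self._spans.get(t.chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(t.start, t.end)]

    def genes_on(self, chrom: str) -> list[GeneModel]:
        return [g for g in self.genes if g.chrom == chrom]


def classify_position(
    t: TranscriptModel, reference: ReferenceIndex | Sequence[GeneModel]
) -> PositionalClass:
    """Positional class of a noncoding transcript relative to coding genes.

    Precedence: same-strand exonic overlap (dropped) > antisense > incRNA >
    lincRNA.  Antisense requires at least one exonic base over a coding exon
    on the opposite strand; incRNA requires the whole transcript inside a
    single intron of a coding gene (either strand); lincRNA requires no
    overlap with any coding-gene span.  Genic overlap fitting none of these
    (e.g. an exon hanging off a gene end without touching its exons) is a
    distinct dropped outcome.
    """
    if not isinstance(reference, ReferenceIndex):
        reference = ReferenceIndex(reference)
    if not reference.has_chrom(t.chrom):
        raise ReferenceLookupError(
            f"chromosome {t.chrom} absent from reference index"
        )
    opposite = "-" if t.strand == "+" else "+"
    if reference.exon_overlaps(t, t.strand):
        return PositionalClass.SENSE_OVERLAP
    if reference.exon_overlaps(t, opposite):
        return PositionalClass.ANTISENSE
    hosts = reference.span_overlaps(t)
    if not hosts:
        return PositionalClass.LINCRNA
    for g in hosts:
        for is_, ie in g.introns_union:
            if is_ <= t.start and t.end <= ie:
                return PositionalClass.INCRNA
    return PositionalClass.GENIC_OTHER


@dataclass
class LncRNARecord:
    """A transcript that survived the whole cascade, with audit trail."""

    transcript: TranscriptModel
    positional_class: PositionalClass
    filter_trail: FilterTrail
    longest_orf_nt: int

    @property
    def transcript_id(self) -> str:
        return self.transcript.transcript_id


@dataclass
class IdentificationResult:
    """Outcome of the identification cascade over a whole assembly."""

    records: list[LncRNARecord]
    buckets: dict[str, list[str]]  # outcome -> transcript ids
    per_class: dict[str, int]
    per_chromosome: pd.DataFrame
    chrom_correlation: tuple[float, float]  # Pearson r, p (NaN when undefined)

    @property
    def lncrna_ids(self) -> list[str]:
        return [r.transcript_id for r in self.records]


def _per_chromosome_table(
    records: Sequence[LncRNARecord],
    reference: ReferenceIndex,
    genome_chroms: Sequence[str],
    counts: CountTable | None,
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Chromosome distribution: lncRNA counts, lncRNAs per hundred genes,
    transcribed-gene counts (gene FPKM >= 0.1 in >= 1 library) and the
    Pearson correlation between the per-chromosome lncRNA and
    transcribed-gene counts."""
    from .expression import fpkm  # local import to avoid cycle

    chroms = sorted(set(genome_chroms) | set(reference.chromosomes))
    lnc_per_chrom = {c: 0 for c in chroms}
    for r in records:
        lnc_per_chrom[r.transcript.chrom] = lnc_per_chrom.get(r.transcript.chrom, 0) + 1

    transcribed: dict[str, float] = {c: np.nan for c in chroms}
    if counts is not None:
        ref_tx = {
            t.transcript_id: t for g in reference.genes for t in g.transcripts
        }
        have = [tid for tid in ref_tx if tid in counts.counts.index]
        if have:
            lengths = pd.Series(
                {tid: ref_tx[tid].spliced_length for tid in have}
            )
            em = fpkm(
                CountTable(
                    counts=counts.counts.loc[have],
                    library_totals=counts.library_totals,
                ),
                lengths,
            )
            gene_max: dict[str, float] = {}
            for g in reference.genes:
                vals = [
                    em.fpkm.loc[t.transcript_id].max()
                    for t in g.transcripts
                    if t.transcript_id in em.fpkm.index
                ]
                gene_max[g.gene_id] = float(max(vals)) if vals else 0.0
            for c in chroms:
                genes_c = reference.genes_on(c)
                transcribed[c] = sum(
                    1
                    for g in genes_c
                    if gene_max.get(g.gene_id, 0.0) >= TRANSCRIBED_FPKM
                )

    rows = []
    for c in chroms:
        n_genes = len(reference.genes_on(c))
        n_lnc = lnc_per_chrom.get(c, 0)
        rows.append(
            {
                "chrom": c,
                "n_lncrna": n_lnc,
                "n_ref_genes": n_genes,
                "lnc_per_100_genes": (100.0 * n_lnc / n_genes) if n_genes else np.nan,
                "n_transcribed_genes": transcribed[c],
            }
        )
    table = pd.DataFrame(rows).set_index("chrom")

    r = p = np.nan
    x = table["n_lncrna"].astype(float)
    y = table["n_transcribed_genes"].astype(float)
    ok = ~(x.isna() | y.isna())
    if ok.sum() >= 3 and x[ok].std() > 0 and y[ok].std() > 0:
        r, p = stats.pearsonr(x[ok], y[ok])
    return table, (float(r), float(p))


def run_identification(
    assembly: Sequence[GeneModel],
    reference: Sequence[GeneModel] | ReferenceIndex,
    genome: Mapping[str, str],
    counts: CountTable | None = None,
    min_length: int = DEFAULT_MIN_LENGTH,
    min_exons: int = DEFAULT_MIN_EXONS,
    orf_max_aa: int = DEFAULT_ORF_MAX_AA,
) -> IdentificationResult:
    """Run the full cascade: candidate filter -> coding screen -> positional
    classification, dropping same-strand overlaps, and tally the
    per-chromosome distribution.

    Every assembled transcript ends in exactly one bucket:
    ``filter_failed``, ``coding``, ``sense_overlap``, ``genic_other``,
    ``lincRNA``, ``incRNA`` or ``antisense``.
    """
    index = (
        reference
        if isinstance(reference, ReferenceIndex)
        else ReferenceIndex(reference)
    )
    buckets: dict[str, list[str]] = {
        k: []
        for k in (
            "filter_failed",
            "coding",
            "sense_overlap",
            "genic_other",
            "lincRNA",
            "incRNA",
            "antisense",
        )
    }
    records: list[LncRNARecord] = []
    for gene in assembly:
        for t in gene.transcripts:
            ok, trail = candidate_filter(t, min_length, min_exons)
            if not ok:
                buckets["filter_failed"].append(t.transcript_id)
                continue
            noncoding, orf_trail, report = coding_heuristic(t, genome, orf_max_aa)
            trail += orf_trail
            if not noncoding:
                buckets["coding"].append(t.transcript_id)
                continue
            klass = classify_position(t, index)
            if klass is PositionalClass.SENSE_OVERLAP:
                buckets["sense_overlap"].append(t.transcript_id)
                continue
            if klass is PositionalClass.GENIC_OTHER:
                buckets["genic_other"].append(t.transcript_id)
                continue
            trail.append(("positional_class", True, 1.0))
            records.append(
                LncRNARecord(
                    transcript=t.with_biotype("lncRNA"),
                    positional_class=klass,
                    filter_trail=trail,
                    longest_orf_nt=report.nt_length,
                )
            )
            buckets[klass.value].append(t.transcript_id)

    per_class = {
        k: len(buckets[k]) for k in ("lincRNA", "incRNA", "antisense")
    }
    table, corr = _per_chromosome_table(records, index, list(genome), counts)
    return IdentificationResult(
        records=records,
        buckets=buckets,
        per_class=per_class,
        per_chromosome=table,
        chrom_correlation=corr,
    )


# ---------------------------------------------------------------------------
# Truncated noncoding isoforms of protein-coding genes


def truncated_isoform_screen(
    g: GeneModel,
    genome: Mapping[str, str],
    trunc_frac: float = DEFAULT_TRUNC_FRAC,
) -> list[tuple[str, ORFReport, str]]:
    """Screen a coding gene's splice isoforms for truncated noncoding forms.

    The reference isoform is the one with the longest complete ORF in the
    gene.  An isoform is ``truncated-noncoding`` when it lacks a complete
    ORF or its longest complete ORF encodes fewer than ``trunc_frac`` of the
    reference aa length; otherwise ``coding``.  Genes without any complete
    ORF are skipped with a warning.
    """
    reports: list[tuple[str, ORFReport]] = []
    for t in g.transcripts:
        seq = extract_spliced_sequence(t, genome)
        reports.append((t.transcript_id, find_longest_orf(seq, t.transcript_id)))
    complete_aa = [r.aa_length for _, r in reports if r.complete]
    if not complete_aa:
        warnings.warn(
            f"gene {g.gene_id}: no isoform with a complete ORF; skipped",
            stacklevel=2,
        )
        return []
    ref_aa = max(complete_aa)
    out = []
    for tid, report in reports:
        if report.complete and report.aa_length >= trunc_frac * ref_aa:
            verdict = "coding"
        else:
            verdict = "truncated-noncoding"
        out.append((tid, report, verdict))
    return out
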
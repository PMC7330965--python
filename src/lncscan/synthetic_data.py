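"""Synthetic transcriptome generator with planted ground truth.

The generator emulates the inputs of a four-library (root, leaf, two
developing-seed stages) organ panel over a small multi-chromosome genome
with an A/B subgenome naming scheme: multi-exon protein-coding genes with
real ORFs written into the sequence, planted lncRNAs of the three
positional classes (intergenic, intronic, antisense), isoform groups
carrying exactly one alternative-splicing event of a planned type, a
library-presence (Venn) design, and negative-binomial count matrices with
planted lncRNA-gene expression correlations.

Construction guarantees, not luck, keep the planted truth recoverable:

* coding transcripts carry a complete ORF >= ~150 aa (the spliced CDS is
  written into the genome);
* lncRNA loci are filled with ATG-free sequence interleaved with stop-codon
  blocks covering all three frames, so no planted lncRNA can harbour an
  ORF of 50 aa or more (asserted after generation), leaving ample margin
  below the 100-aa coding threshold;
* planted placements leave >= 1 kb margins so no unintended overlap changes
  a positional class.

Everything is driven by one integer seed through numpy's PCG64 generator;
identical designs produce byte-identical outputs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_io import (
    CountTable,
    GeneModel,
    TranscriptModel,
    write_counts,
    write_fasta,
    write_gtf,
)
from .lnc_identify import longest_orf_aa

__all__ = [
    "STUDY_LIBRARIES",
    "SyntheticDesign",
    "SyntheticAnnotation",
    "PlannedPair",
    "make_annotation",
    "make_counts",
    "make_as_pair",
    "null_counts",
    "write_simulation",
    "chrom_names",
]

STUDY_LIBRARIES = ("FH1-root", "FH1-leaf", "FH1-seed1", "FH1-seed2")

_STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]
# Stop codons in all three frames, G-free (cannot take part in an ATG):
_STOP_BLOCK = "TTAATTAATTAA"
_BLOCK_PERIOD = 24  # body nt between stop blocks

MIN_CODING_SPLICED = 450  # nt; guarantees a >=147 aa ORF
LNC_ORF_MARGIN_AA = 50

# Relative gene loading per chromosome (cycled): unequal, as in real
# genomes, but bounded so no chromosome exceeds ~1.35x the even share.
_CHROM_LOAD_WEIGHTS = (0.70, 1.25, 1.00, 1.35)

PlacementError = ValueError


def chrom_names(n: int) -> list[str]:
    """Peanut-style A/B subgenome chromosome names."""
    return [
        f"{'Aradu.A' if i % 2 == 0 else 'Araip.B'}{i // 2 + 1:02d}"
        for i in range(n)
    ]


@dataclass(frozen=True)
class PlannedPair:
    """A resolved planted lncRNA-gene correlation."""

    lnc_id: str  # transcript id
    gene_id: str
    target_r: float
    mode: str  # cis | trans


@dataclass
class SyntheticDesign:
    """Study design of one synthetic dataset.

    Defaults mirror the four-organ-library setting the generator emulates:
    four chromosomes, ~100 coding genes, ten planted lncRNAs per positional
    class, one locus per alternative-splicing event type, negative-binomial
    dispersion 0.1 and one million mapped reads per library.
    ``correlation_plan`` entries are (mode, target_r); the generator binds
    each to a fresh lncRNA (and, for cis, a gene co-placed within the
    100-kb window; for trans, a gene on another chromosome).
    ``n_pseudo_libraries`` replaces the four study libraries by that many
    pseudo-samples, used by correlation fixtures where four libraries give
    the thresholds no statistical room.
    """

    seed: int = 0
    n_chroms: int = 4
    chrom_length: int = 400_000
    n_coding_genes: int = 100
    n_lincrna: int = 10
    n_incrna: int = 10
    n_antisense: int = 10
    as_event_plan: tuple[str, ...] = ("TSS", "TTS", "ES", "IR", "AE")
    venn_design: Mapping[str, tuple[int, ...]] | str = "emulate"
    correlation_plan: tuple[tuple[str, float], ...] = (
        ("cis", 0.95),
        ("cis", 0.95),
        ("cis", 0.0),
        ("trans", 0.95),
    )
    nb_dispersion: float = 0.1
    library_depth: int = 1_000_000
    library_ids: tuple[str, ...] = STUDY_LIBRARIES
    n_pseudo_libraries: int | None = None
    library_variation_sd: float = 1.5  # across-library log-expression sd
    baseline_sigma: float = 1.2  # between-transcript log-abundance sd

    @property
    def libraries(self) -> tuple[str, ...]:
        if self.n_pseudo_libraries:
            return tuple(
                f"pseudo{i + 1:02d}" for i in range(self.n_pseudo_libraries)
            )
        return tuple(self.library_ids)

    def validate(self) -> None:
        if self.library_depth <= 0:
            raise ValueError("library depth must be positive")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        n_bound = len(self.correlation_plan)
        if self.n_lincrna < n_bound:
            raise ValueError(
                f"correlation plan needs {n_bound} lincRNAs, design has "
                f"{self.n_lincrna}"
            )
        n_genes_needed = (
            sum(1 for m, _ in self.correlation_plan)
            + self.n_incrna
            + self.n_antisense
        )
        if self.n_coding_genes < n_genes_needed:
            raise ValueError(
                f"design needs >= {n_genes_needed} coding genes "
                f"(plan partners + hosts), got {self.n_coding_genes}"
            )
        for mode, r in self.correlation_plan:
            if mode not in ("cis", "trans"):
                raise ValueError(f"unknown correlation mode {mode!r}")
            if not -1.0 <= r <= 1.0:
                raise ValueError("target r must be in [-1, 1]")
        for ev in self.as_event_plan:
            if ev not in ("TSS", "TTS", "ES", "IR", "AE"):
                raise ValueError(f"unknown AS event type {ev!r}")


@dataclass
class SyntheticAnnotation:
    """Generated annotation plus the planted truth."""

    design: SyntheticDesign
    reference: list[GeneModel]
    assembly: list[GeneModel]
    genome: dict[str, str]
    truth: pd.DataFrame  # transcript_id, gene_id, kind, as_event, venn
    correlation_pairs: list[PlannedPair]
    as_loci: list[tuple[str, str]]  # (gene_id, event_type)
    venn: dict[str, tuple[int, ...]]  # lncRNA transcript id -> membership

    @property
    def lnc_classes(self) -> dict[str, str]:
        """Planted transcript id -> positional class (lincRNA/incRNA/antisense)."""
        t = self.truth
        lnc = t[t.kind.isin(["lincRNA", "incRNA", "antisense"])]
        return dict(zip(lnc.transcript_id, lnc.kind))

    def all_transcripts(self) -> list[TranscriptModel]:
        return [t for g in self.assembly for t in g.transcripts]


# ---------------------------------------------------------------------------
# Sequence construction helpers


_B2C = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq_array(rng: np.random.Generator, length: int) -> np.ndarray:
    return _B2C[rng.integers(0, 4, size=length)]


def _strip_atg(rng: np.random.Generator, seq: str) -> str:
    """Replace the G of every ATG occurrence with C (no new ATG can form)."""
    while "ATG" in seq:
        chars = list(seq)
        for m in re.finditer("ATG", seq):
            chars[m.start() + 2] = "C"
        seq = "".join(chars)
    return seq


def _noncoding_seq(rng: np.random.Generator, length: int) -> str:
    """ATG-free sequence with stop codons in every frame every ~36 nt.

    Any reading frame entered at any point (e.g. via a splice-junction or
    antisense-overlap ATG) hits a stop within about one block period, so
    open stretches stay far below the 50-aa planted-lncRNA margin.
    """
    pieces = []
    remaining = length
    while remaining > 0:
        body = min(_BLOCK_PERIOD, remaining)
        pieces.append(
            _random_seq_array(rng, body).tobytes().decode("ascii")
        )
        remaining -= body
        if remaining > 0:
            take = min(len(_STOP_BLOCK), remaining)
            pieces.append(_STOP_BLOCK[:take])
            remaining -= take
    return _strip_atg(rng, "".join(pieces))[:length]


def _coding_seq(rng: np.random.Generator, length: int) -> str:
    """Spliced mRNA sense sequence with a complete ORF covering most of it."""
    if length < MIN_CODING_SPLICED:
        raise PlacementError(f"coding transcript too short ({length} nt)")
    utr5 = 9
    n_codons = (length - utr5 - 3 - 12) // 3  # leave stop + short 3' UTR
    codons = rng.choice(len(_SENSE_CODONS), size=n_codons)
    body = "".join(_SENSE_CODONS[i] for i in codons)
    stop = _STOPS[int(rng.integers(0, 3))]
    head = _random_seq_array(rng, utr5).tobytes().decode("ascii")
    cds = "ATG" + body + stop
    tail_len = length - utr5 - len(cds)
    tail = _random_seq_array(rng, tail_len).tobytes().decode("ascii")
    return head + cds + tail


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _write_spliced(
    chrom_arr: np.ndarray,
    exons: Sequence[tuple[int, int]],
    strand: str,
    sense_seq: str,
    skip: Sequence[tuple[int, int]] = (),
) -> None:
    """Write a spliced sense sequence into genomic exon intervals.

    For '-' transcripts the reverse complement is laid across the exons in
    genomic order, so re-extraction yields ``sense_seq`` exactly.
    Intervals in ``skip`` (already owned by another feature, e.g. a host
    coding exon under an antisense overlap) are left untouched.
    """
    genomic = (
        sense_seq
        if strand == "+"
        else sense_seq.translate(_COMPLEMENT)[::-1]
    )
    pos = 0
    for s, e in exons:
        chunk = genomic[pos : pos + (e - s)]
        pos += e - s
        arr = np.frombuffer(chunk.encode("ascii"), dtype=np.uint8).copy()
        mask = np.ones(e - s, dtype=bool)
        for ks, ke in skip:
            lo, hi = max(s, ks), min(e, ke)
            if lo < hi:
                mask[lo - s : hi - s] = False
        chrom_arr[s:e][mask] = arr[mask]


# ---------------------------------------------------------------------------
# Exon-chain builders


def _build_chain(
    rng: np.random.Generator,
    n_exons: int,
    exon_range: tuple[int, int],
    intron_range: tuple[int, int],
    start: int,
    long_intron: tuple[int, int] | None = None,
) -> tuple[tuple[int, int], ...]:
    """Random exon chain from ``start``; ``long_intron=(index, length)``
    forces one intron length (for intronic-lncRNA hosts)."""
    exons = []
    pos = start
    for i in range(n_exons):
        length = int(rng.integers(exon_range[0], exon_range[1] + 1))
        exons.append((pos, pos + length))
        pos += length
        if i < n_exons - 1:
            if long_intron is not None and i == long_intron[0]:
                gap = long_intron[1]
            else:
                gap = int(rng.integers(intron_range[0], intron_range[1] + 1))
            pos += gap
    return tuple(exons)


def make_as_pair(
    rng: np.random.Generator,
    event_type: str,
    chrom: str = "Aradu.A01",
    gene_id: str = "ASL",
    start: int = 1000,
    strand: str | None = None,
) -> tuple[TranscriptModel, TranscriptModel]:
    """A base isoform plus a variant carrying exactly one event of the
    given type (randomised exon/intron geometry)."""
    if strand is None:
        strand = "+" if rng.integers(0, 2) else "-"
    n = int(rng.integers(4, 7))
    base = _build_chain(rng, n, (120, 250), (150, 400), start)
    exons = list(base)
    d = int(rng.integers(40, 81))
    five_prime_left = strand == "+"

    def shrink_outer(idx: int, left_edge: bool):
        s, e = exons[idx]
        dd = min(d, (e - s) - 50)
        exons[idx] = (s + dd, e) if left_edge else (s, e - dd)

    if event_type == "TSS":
        shrink_outer(0, True) if five_prime_left else shrink_outer(n - 1, False)
    elif event_type == "TTS":
        shrink_outer(n - 1, False) if five_prime_left else shrink_outer(0, True)
    elif event_type == "ES":
        k = int(rng.integers(1, n - 1))
        del exons[k]
    elif event_type == "IR":
        k = int(rng.integers(0, n - 1))
        exons[k] = (exons[k][0], exons[k + 1][1])
        del exons[k + 1]
    elif event_type == "AE":
        k = int(rng.integers(1, n - 1))
        s, e = exons[k]
        dd = min(d, (e - s) - 50)
        if rng.integers(0, 2):
            exons[k] = (s + dd, e)  # alternative acceptor side
        else:
            exons[k] = (s, e - dd)  # alternative donor side
    else:
        raise ValueError(f"unknown AS event type {event_type!r}")

    make = lambda tid, chain: TranscriptModel(
        transcript_id=tid,
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        exons=tuple(chain),
    )
    return make(f"{gene_id}.1", base), make(f"{gene_id}.2", exons)


# ---------------------------------------------------------------------------
# Annotation generation


@dataclass
class _Unit:
    kind: str
    payload: dict = field(default_factory=dict)
    chrom_idx: int = 0


def _plan_units(
    design: SyntheticDesign, rng: np.random.Generator
) -> tuple[list[_Unit], list[dict]]:
    units: list[_Unit] = []
    gene_counter = [0]
    linc_counter = [0]

    def next_gene() -> str:
        gene_counter[0] += 1
        return f"GENE{gene_counter[0]:04d}"

    def next_linc() -> str:
        linc_counter[0] += 1
        return f"LINC{linc_counter[0]:04d}"

    pairs: list[dict] = []
    for mode, r in design.correlation_plan:
        if mode == "cis":
            units.append(
                _Unit(
                    "cis_pair",
                    {"gene": next_gene(), "linc": next_linc(), "r": r},
                )
            )
            pairs.append({"unit": units[-1], "mode": "cis", "r": r})
        else:
            linc_unit = _Unit("linc", {"linc": next_linc()})
            gene_unit = _Unit("gene", {"gene": next_gene()})
            units.append(linc_unit)
            units.append(gene_unit)
            pairs.append(
                {
                    "linc_unit": linc_unit,
                    "gene_unit": gene_unit,
                    "mode": "trans",
                    "r": r,
                }
            )
    for i in range(design.n_incrna):
        units.append(
            _Unit(
                "host_intronic",
                {"gene": next_gene(), "inc": f"INCR{i + 1:04d}"},
            )
        )
    for i in range(design.n_antisense):
        units.append(
            _Unit(
                "host_antisense",
                {"gene": next_gene(), "anti": f"ANTI{i + 1:04d}"},
            )
        )
    while linc_counter[0] < design.n_lincrna:
        units.append(_Unit("linc", {"linc": next_linc()}))
    for i, ev in enumerate(design.as_event_plan):
        units.append(_Unit("as_locus", {"gene": f"ASL{i + 1:02d}", "event": ev}))
    while gene_counter[0] < design.n_coding_genes:
        units.append(_Unit("gene", {"gene": next_gene()}))

    # Deterministic weighted assignment: chromosomes carry unequal gene
    # loads (as real genomes do, which keeps the per-chromosome
    # distribution statistics non-degenerate) while staying balanced
    # enough that placement cannot overflow.  Trans partner genes are
    # forced onto a different chromosome than their lncRNA.
    weights = [
        _CHROM_LOAD_WEIGHTS[i % len(_CHROM_LOAD_WEIGHTS)]
        for i in range(design.n_chroms)
    ]
    loads = [0.0] * design.n_chroms
    for u in units:
        i = min(
            range(design.n_chroms), key=lambda j: (loads[j] + 1.0) / weights[j]
        )
        u.chrom_idx = i
        loads[i] += 1.0
    for p in pairs:
        if p["mode"] == "trans" and design.n_chroms > 1:
            lnc_chrom = p["linc_unit"].chrom_idx
            if p["gene_unit"].chrom_idx == lnc_chrom:
                p["gene_unit"].chrom_idx = (lnc_chrom + 1) % design.n_chroms
    return units, pairs


def make_annotation(design: SyntheticDesign) -> SyntheticAnnotation:
    """Generate (reference, assembly, genome, truth) for a design."""
    design.validate()
    rng = np.random.default_rng([design.seed, 0])
    chroms = chrom_names(design.n_chroms)
    units, pair_specs = _plan_units(design, rng)

    genome_arrays = {
        c: _random_seq_array(rng, design.chrom_length) for c in chroms
    }
    cursors = {c: 1000 for c in chroms}

    coding: list[GeneModel] = []
    lnc_genes: list[GeneModel] = []
    truth_rows: list[dict] = []
    as_loci: list[tuple[str, str]] = []

    # Each writer records (transcript, kind, fill) where fill describes how
    # to write its sequence after all placements are known.
    seq_jobs: list[tuple[TranscriptModel, str, dict]] = []

    def advance(chrom: str, span_end: int):
        cursors[chrom] = span_end
        if span_end + 1000 > design.chrom_length:
            raise PlacementError(
                f"design infeasible: chromosome {chrom} of length "
                f"{design.chrom_length} overflowed at {span_end}"
            )

    def gap(lo=1500, hi=4000) -> int:
        return int(rng.integers(lo, hi + 1))

    def place_gene(
        chrom: str, gene_id: str, long_intron_len: int | None = None
    ) -> GeneModel:
        start = cursors[chrom] + gap()
        n_exons = int(rng.integers(3 if long_intron_len else 2, 11))
        long_intron = None
        if long_intron_len is not None:
            long_intron = (int(rng.integers(0, n_exons - 1)), long_intron_len)
        exons = _build_chain(rng, n_exons, (150, 400), (150, 800), start,
                             long_intron=long_intron)
        spliced = sum(e - s for s, e in exons)
        if spliced < MIN_CODING_SPLICED:
            s, e = exons[-1]
            exons = exons[:-1] + ((s, e + (MIN_CODING_SPLICED - spliced)),)
        strand = "+" if rng.integers(0, 2) else "-"
        t = TranscriptModel(
            transcript_id=f"{gene_id}.1",
            gene_id=gene_id,
            chrom=chrom,
            strand=strand,
            exons=exons,
            biotype="coding",
        )
        g = GeneModel(gene_id=gene_id, chrom=chrom, strand=strand,
                      transcripts=[t])
        coding.append(g)
        seq_jobs.append((t, "coding", {}))
        truth_rows.append(
            {"transcript_id": t.transcript_id, "gene_id": gene_id,
             "kind": "coding", "as_event": "", "chrom": chrom}
        )
        advance(chrom, t.end)
        return g

    def place_linc(chrom: str, linc_id: str) -> TranscriptModel:
        start = cursors[chrom] + gap()
        n_exons = int(rng.integers(2, 5))
        exons = _build_chain(rng, n_exons, (150, 400), (150, 500), start)
        strand = "+" if rng.integers(0, 2) else "-"
        t = TranscriptModel(
            transcript_id=f"{linc_id}.1", gene_id=linc_id, chrom=chrom,
            strand=strand, exons=exons,
        )
        lnc_genes.append(
            GeneModel(gene_id=linc_id, chrom=chrom, strand=strand,
                      transcripts=[t])
        )
        seq_jobs.append((t, "lnc", {"fill_span": True}))
        truth_rows.append(
            {"transcript_id": t.transcript_id, "gene_id": linc_id,
             "kind": "lincRNA", "as_event": "", "chrom": chrom}
        )
        advance(chrom, t.end)
        return t

    for unit in units:
        chrom = chroms[unit.chrom_idx]
        if unit.kind == "gene":
            g = place_gene(chrom, unit.payload["gene"])
            unit.payload["gene_model"] = g
        elif unit.kind == "linc":
            t = place_linc(chrom, unit.payload["linc"])
            unit.payload["linc_tx"] = t
        elif unit.kind == "cis_pair":
            g = place_gene(chrom, unit.payload["gene"])
            cursors[chrom] += int(rng.integers(2000, 15000))  # <= 100 kb window
            t = place_linc(chrom, unit.payload["linc"])
            unit.payload["gene_model"], unit.payload["linc_tx"] = g, t
        elif unit.kind == "host_intronic":
            intron_len = int(rng.integers(3000, 4001))
            host = place_gene(chrom, unit.payload["gene"],
                              long_intron_len=intron_len)
            host_t = host.transcripts[0]
            long_introns = [
                iv for iv in host_t.introns if iv[1] - iv[0] >= 3000
            ]
            is_, ie = long_introns[0]
            inc_id = unit.payload["inc"]
            inc_start = is_ + 400
            exons = _build_chain(rng, 2, (150, 300), (100, 200), inc_start)
            if exons[-1][1] > ie - 400:
                raise PlacementError("intronic lncRNA does not fit its host intron")
            strand = "+" if rng.integers(0, 2) else "-"
            t = TranscriptModel(
                transcript_id=f"{inc_id}.1", gene_id=inc_id, chrom=chrom,
                strand=strand, exons=exons,
            )
            lnc_genes.append(
                GeneModel(gene_id=inc_id, chrom=chrom, strand=strand,
                          transcripts=[t])
            )
            seq_jobs.append((t, "lnc", {"fill_span": True}))
            truth_rows.append(
                {"transcript_id": t.transcript_id, "gene_id": inc_id,
                 "kind": "incRNA", "as_event": "", "chrom": chrom}
            )
        elif unit.kind == "host_antisense":
            host = place_gene(chrom, unit.payload["gene"])
            host_t = host.transcripts[0]
            hx_s, hx_e = host_t.exons[-1]
            ov = int(rng.integers(60, 85))
            anti_id = unit.payload["anti"]
            exon1 = (hx_e - ov, hx_e + 150)
            intron = int(rng.integers(100, 201))
            exon2_len = int(rng.integers(250, 400))
            exon2 = (exon1[1] + intron, exon1[1] + intron + exon2_len)
            strand = "-" if host.strand == "+" else "+"
            t = TranscriptModel(
                transcript_id=f"{anti_id}.1", gene_id=anti_id, chrom=chrom,
                strand=strand, exons=(exon1, exon2),
            )
            lnc_genes.append(
                GeneModel(gene_id=anti_id, chrom=chrom, strand=strand,
                          transcripts=[t])
            )
            seq_jobs.append(
                (t, "lnc", {"fill_span": True, "skip": [(hx_s, hx_e)]})
            )
            truth_rows.append(
                {"transcript_id": t.transcript_id, "gene_id": anti_id,
                 "kind": "antisense", "as_event": "", "chrom": chrom}
            )
            advance(chrom, t.end)
        elif unit.kind == "as_locus":
            start = cursors[chrom] + gap()
            gene_id, event = unit.payload["gene"], unit.payload["event"]
            base, alt = make_as_pair(rng, event, chrom=chrom,
                                     gene_id=gene_id, start=start)
            lnc_genes.append(
                GeneModel(gene_id=gene_id, chrom=chrom, strand=base.strand,
                          transcripts=[base, alt])
            )
            seq_jobs.append((base, "lnc", {"fill_span": True}))
            as_loci.append((gene_id, event))
            for t, ev in ((base, ""), (alt, event)):
                truth_rows.append(
                    {"transcript_id": t.transcript_id, "gene_id": gene_id,
                     "kind": "lincRNA", "as_event": ev, "chrom": chrom}
                )
            advance(chrom, max(base.end, alt.end))

    # --- write sequences -------------------------------------------------
    for t, kind, opts in seq_jobs:
        arr = genome_arrays[t.chrom]
        if kind == "coding":
            seq = _coding_seq(rng, t.spliced_length)
            _write_spliced(arr, t.exons, t.strand, seq)
        else:
            # Fill the whole locus span (exons and introns) so every splice
            # variant over this locus stays free of long ORFs.
            span = ((t.start, t.end),)
            seq = _noncoding_seq(rng, t.end - t.start)
            _write_spliced(
                arr, span, t.strand, seq, skip=opts.get("skip", ())
            )

    genome = {
        c: genome_arrays[c].tobytes().decode("ascii") for c in chroms
    }

    # --- closed-form validation of planted ORF margins -------------------
    from .annotation_io import extract_spliced_sequence

    for g in lnc_genes:
        for t in g.transcripts:
            aa = longest_orf_aa(extract_spliced_sequence(t, genome))
            if aa >= LNC_ORF_MARGIN_AA:
                raise PlacementError(
                    f"planted lncRNA {t.transcript_id} acquired a {aa}-aa ORF"
                )
    for g in coding:
        for t in g.transcripts:
            aa = longest_orf_aa(extract_spliced_sequence(t, genome))
            if aa < 100:
                raise PlacementError(
                    f"coding transcript {t.transcript_id} ORF only {aa} aa"
                )

    # --- resolve planted correlation pairs -------------------------------
    pairs: list[PlannedPair] = []
    for p in pair_specs:
        if p["mode"] == "cis":
            u = p["unit"]
            pairs.append(
                PlannedPair(
                    lnc_id=u.payload["linc_tx"].transcript_id,
                    gene_id=u.payload["gene_model"].gene_id,
                    target_r=p["r"],
                    mode="cis",
                )
            )
        else:
            pairs.append(
                PlannedPair(
                    lnc_id=p["linc_unit"].payload["linc_tx"].transcript_id,
                    gene_id=p["gene_unit"].payload["gene_model"].gene_id,
                    target_r=p["r"],
                    mode="trans",
                )
            )

    truth = pd.DataFrame(truth_rows)

    # --- resolve the Venn membership design ------------------------------
    libs = design.libraries
    lnc_tids = [
        r["transcript_id"]
        for r in truth_rows
        if r["kind"] in ("lincRNA", "incRNA", "antisense")
    ]
    plan_lnc = {p.lnc_id for p in pairs}
    venn: dict[str, tuple[int, ...]] = {}
    if isinstance(design.venn_design, str):
        mode = design.venn_design
        if mode not in ("emulate", "all_present"):
            raise ValueError(f"unknown venn_design {mode!r}")
        seed_libs = [l for l in libs if "seed" in l.lower()]
        other_libs = [l for l in libs if l not in seed_libs]
        rot = 0
        for tid in lnc_tids:
            if mode == "all_present" or tid in plan_lnc:
                venn[tid] = tuple(1 for _ in libs)
                continue
            u = rng.random()
            if u < 0.45:
                member = tuple(1 for _ in libs)
            elif u < 0.65:
                member = tuple(
                    1 if i == rot % len(libs) else 0 for i in range(len(libs))
                )
                rot += 1
            elif u < 0.80 and seed_libs and other_libs:
                member = tuple(1 if l in seed_libs else 0 for l in libs)
            else:
                member = tuple(int(rng.random() < 0.6) for _ in libs)
                if sum(member) == 0:
                    member = tuple(
                        1 if i == rot % len(libs) else 0
                        for i in range(len(libs))
                    )
                    rot += 1
            venn[tid] = member
    else:
        for tid in lnc_tids:
            member = tuple(design.venn_design.get(tid, tuple(1 for _ in libs)))
            if len(member) != len(libs):
                raise ValueError(f"venn design for {tid} has wrong arity")
            venn[tid] = member

    truth["venn"] = [
        "".join(map(str, venn[tid])) if tid in venn else ""
        for tid in truth.transcript_id
    ]

    assembly = coding + lnc_genes
    return SyntheticAnnotation(
        design=design,
        reference=coding,
        assembly=assembly,
        genome=genome,
        truth=truth,
        correlation_pairs=pairs,
        as_loci=as_loci,
        venn=venn,
    )


# ---------------------------------------------------------------------------
# Counts


def _nb_draw(
    rng: np.random.Generator, mu: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative-binomial counts, var = mu + dispersion * mu^2."""
    mu = np.asarray(mu, dtype=float)
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    if dispersion <= 0:
        out[pos] = rng.poisson(mu[pos])
        return out
    shape = 1.0 / dispersion
    p = shape / (shape + mu[pos])
    out[pos] = rng.negative_binomial(shape, p)
    return out


def make_counts(
    design: SyntheticDesign,
    annotation: SyntheticAnnotation,
    rng: np.random.Generator | None = None,
) -> CountTable:
    """Negative-binomial count matrix honouring the planted designs.

    Baseline log-abundances are normal (log-normal expression); each
    transcript gets an across-library log-expression profile with sd
    ``library_variation_sd`` (organ-specific expression).  Venn-absent
    planted lncRNAs are zeroed in the corresponding libraries.  Planted
    correlation pairs share the lncRNA's library profile plus Gaussian
    noise whose variance is calibrated so the *observed* log-scale
    correlation — after negative-binomial counting noise (delta-method
    variance ~ dispersion + 1/mu) — is centred on the target r.
    """
    if rng is None:
        rng = np.random.default_rng([design.seed, 1])
    libs = list(design.libraries)
    n_lib = len(libs)
    if design.library_depth <= 0:
        raise ValueError("library depth must be positive")
    txs = annotation.all_transcripts()
    tids = [t.transcript_id for t in txs]
    n_tx = len(tids)
    idx = {tid: i for i, tid in enumerate(tids)}

    beta = rng.normal(0.0, design.baseline_sigma, size=n_tx)
    g = rng.normal(0.0, design.library_variation_sd, size=(n_tx, n_lib))

    # Planted pairs: elevated stable baseline and shared library profile.
    s2 = design.library_variation_sd**2
    beta_plant = 1.5
    mu_hat = (
        design.library_depth
        * np.exp(beta_plant)
        / (n_tx * np.exp(design.baseline_sigma**2 / 2.0))
    )
    v = design.nb_dispersion + 1.0 / max(mu_hat, 1.0)
    for pair in annotation.correlation_pairs:
        li = idx[pair.lnc_id]
        gene_tx = [t for t in txs if t.gene_id == pair.gene_id]
        beta[li] = beta_plant
        r = pair.target_r
        if abs(r) > 1e-12:
            var_e = (s2**2) / (r**2 * (s2 + v)) - s2 - v
            if var_e < 0:
                var_e = 0.0  # target beyond the noise-limited maximum
            shared = np.sign(r) * g[li]
            noise = rng.normal(0.0, np.sqrt(var_e), size=n_lib)
        else:
            shared = np.zeros(n_lib)
            noise = rng.normal(0.0, np.sqrt(s2), size=n_lib)
        for t in gene_tx:
            beta[idx[t.transcript_id]] = beta_plant
            g[idx[t.transcript_id]] = shared + noise

    intensity = np.exp(beta[:, None] + g)

    # Venn design: zero planted lncRNAs in their absent libraries.
    for tid, member in annotation.venn.items():
        if len(member) != n_lib:
            raise ValueError(
                "venn membership arity does not match the library count"
            )
        row = idx[tid]
        for j, m in enumerate(member):
            if not m:
                intensity[row, j] = 0.0

    depth = float(design.library_depth)
    colsum = intensity.sum(axis=0)
    mu = intensity * (depth / colsum)[None, :]
    counts = _nb_draw(rng, mu, design.nb_dispersion)

    frame = pd.DataFrame(counts, index=tids, columns=libs)
    return CountTable.from_frame(frame)


def null_counts(
    n_transcripts: int = 1000,
    n_libraries: int = 2,
    depth: int = 1_000_000,
    dispersion: float = 0.1,
    baseline_sigma: float = 1.2,
    seed: int = 0,
) -> CountTable:
    """Counts with *no* planted difference: every library draws from the
    same per-transcript mean (log-normal baseline), independent
    negative-binomial sampling per library."""
    if depth <= 0:
        raise ValueError("library depth must be positive")
    rng = np.random.default_rng([seed, 2])
    beta = rng.normal(0.0, baseline_sigma, size=n_transcripts)
    a = np.exp(beta)
    mu = depth * a / a.sum()
    counts = np.column_stack(
        [_nb_draw(rng, mu, dispersion) for _ in range(n_libraries)]
    )
    frame = pd.DataFrame(
        counts,
        index=[f"T{i + 1:05d}" for i in range(n_transcripts)],
        columns=[f"lib{j + 1}" for j in range(n_libraries)],
    )
    return CountTable.from_frame(frame)


def write_simulation(design: SyntheticDesign, outdir) -> SyntheticAnnotation:
    """Generate and write reference.gtf, assembly.gtf, genome.fa,
    counts.tsv and truth.tsv under ``outdir``."""
    import os

    os.makedirs(outdir, exist_ok=True)
    ann = make_annotation(design)
    counts = make_counts(design, ann)
    write_gtf(ann.reference, os.path.join(outdir, "reference.gtf"),
              source="synthetic")
    write_gtf(ann.assembly, os.path.join(outdir, "assembly.gtf"),
              source="synthetic")
    write_fasta(ann.genome, os.path.join(outdir, "genome.fa"))
    write_counts(counts, os.path.join(outdir, "counts.tsv"))
    ann.truth.to_csv(os.path.join(outdir, "truth.tsv"), sep="\t", index=False)
    pd.DataFrame([p.__dict__ for p in ann.correlation_pairs]).to_csv(
        os.path.join(outdir, "correlation_plan.tsv"), sep="\t", index=False
    )
    return ann
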
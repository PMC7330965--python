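"""Reading and writing of the standard formats the pipeline touches.

All coordinates are held internally as 0-based half-open intervals on the
forward genomic strand; GTF input/output converts to/from the 1-based
inclusive convention of that format.  Exon chains are normalised (sorted,
disjoint) at construction time so downstream interval arithmetic never has
to worry about ordering.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "TranscriptModel",
    "GeneModel",
    "CountTable",
    "GTFParseError",
    "read_gtf",
    "write_gtf",
    "read_fasta",
    "write_fasta",
    "extract_spliced_sequence",
    "read_counts",
    "write_counts",
    "group_into_genes",
]

VALID_STRANDS = ("+", "-")
BIOTYPES = ("coding", "candidate", "lncRNA", "unknown")

TOTALS_SIDECAR = "#library_totals"


class GTFParseError(ValueError):
    """Raised on malformed GTF input, naming the offending line."""


@dataclass(frozen=True)
class TranscriptModel:
    """An exon chain on a chromosome strand.

    ``exons`` are 0-based half-open ``(start, end)`` intervals, stored in
    ascending genomic order and required to be disjoint.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    biotype: str = "unknown"

    def __post_init__(self):
        if self.strand not in VALID_STRANDS:
            raise ValueError(
                f"transcript {self.transcript_id}: strand must be '+' or '-', "
                f"got {self.strand!r}"
            )
        exons = tuple(sorted((int(s), int(e)) for s, e in self.exons))
        if not exons:
            raise ValueError(f"transcript {self.transcript_id}: no exons")
        for s, e in exons:
            if e <= s:
                raise ValueError(
                    f"transcript {self.transcript_id}: empty exon ({s}, {e})"
                )
        for (_, e0), (s1, _) in zip(exons, exons[1:]):
            if s1 < e0:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons"
                )
        object.__setattr__(self, "exons", exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Gaps between consecutive exons, genomic order."""
        return tuple(
            (e0, s1) for (_, e0), (s1, _) in zip(self.exons, self.exons[1:])
        )

    def with_biotype(self, biotype: str) -> "TranscriptModel":
        return replace(self, biotype=biotype)


@dataclass
class GeneModel:
    """A group of transcripts sharing a ``gene_id`` on one chromosome."""

    gene_id: str
    chrom: str
    strand: str
    transcripts: list[TranscriptModel] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        return (
            min(t.start for t in self.transcripts),
            max(t.end for t in self.transcripts),
        )

    @property
    def exon_union(self) -> tuple[tuple[int, int], ...]:
        """Merged union of all member exons (ascending, disjoint)."""
        ivs = sorted(iv for t in self.transcripts for iv in t.exons)
        merged: list[list[int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        return tuple((s, e) for s, e in merged)

    @property
    def introns_union(self) -> tuple[tuple[int, int], ...]:
        """Gaps of the merged exon union = intronic intervals of the locus."""
        union = self.exon_union
        return tuple(
            (e0, s1) for (_, e0), (s1, _) in zip(union, union[1:])
        )


@dataclass
class CountTable:
    """Per-transcript read counts per library.

    ``counts`` is a transcripts x libraries integer DataFrame;
    ``library_totals`` holds total mapped reads per library and defaults to
    the column sums (it may exceed them when a sidecar line supplies the
    full mapped-read totals).
    """

    counts: pd.DataFrame
    library_totals: pd.Series

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("negative count entries are not allowed")
        colsum = self.counts.sum(axis=0)
        if (self.library_totals < colsum - 0.5).any():
            raise ValueError("library_totals must be >= column sums")

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def library_ids(self) -> list[str]:
        return list(self.counts.columns)

    @classmethod
    def from_frame(
        cls, counts: pd.DataFrame, library_totals: pd.Series | None = None
    ) -> "CountTable":
        counts = counts.astype(np.int64)
        if library_totals is None:
            library_totals = counts.sum(axis=0)
        return cls(counts=counts, library_totals=library_totals.astype(np.int64))


# ---------------------------------------------------------------------------
# GTF


def _features_from_gtf(path: str | os.PathLike):
    """Yield (lineno, gffutils.Feature) for every non-comment GTF line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            try:
                feat = gffutils.feature.feature_from_line(line)
            except Exception as exc:  # malformed line of any flavour
                raise GTFParseError(
                    f"{os.fspath(path)}:{lineno}: cannot parse GTF line: {exc}"
                ) from exc
            yield lineno, feat


def read_gtf(path: str | os.PathLike, source_tag: str | None = None) -> list[GeneModel]:
    """Read exon features from a GTF file into grouped gene models.

    Exon records sharing a ``transcript_id`` are merged into one ascending
    exon chain; 1-based inclusive GTF coordinates become 0-based half-open.
    Transcripts without a resolved strand ('.') are rejected: every
    splicing and antisense call downstream is strand-dependent.

    Parameters
    ----------
    path : file path
    source_tag : optional; if given, only records whose source column equals
        the tag are read.
    """
    per_tx: dict[str, dict] = {}
    order: list[str] = []
    for lineno, feat in _features_from_gtf(path):
        if feat.featuretype != "exon":
            continue
        if source_tag is not None and feat.source != source_tag:
            continue
        try:
            tid = feat.attributes["transcript_id"][0]
            gid = feat.attributes["gene_id"][0]
        except (KeyError, IndexError) as exc:
            raise GTFParseError(
                f"{os.fspath(path)}:{lineno}: exon record lacks "
                f"gene_id/transcript_id attribute"
            ) from exc
        if feat.strand not in VALID_STRANDS:
            raise GTFParseError(
                f"{os.fspath(path)}:{lineno}: transcript {tid} has "
                f"unresolved strand {feat.strand!r}"
            )
        biotype = feat.attributes.get("biotype", ["unknown"])[0]
        rec = per_tx.get(tid)
        if rec is None:
            per_tx[tid] = rec = {
                "gene_id": gid,
                "chrom": feat.seqid,
                "strand": feat.strand,
                "exons": [],
                "biotype": biotype,
            }
            order.append(tid)
        else:
            if rec["chrom"] != feat.seqid:
                raise GTFParseError(
                    f"{os.fspath(path)}:{lineno}: transcript {tid} spans "
                    f"chromosomes {rec['chrom']} and {feat.seqid}"
                )
            if rec["strand"] != feat.strand:
                raise GTFParseError(
                    f"{os.fspath(path)}:{lineno}: transcript {tid} mixes strands"
                )
        rec["exons"].append((feat.start - 1, feat.end))  # GTF -> half-open

    transcripts = [
        TranscriptModel(
            transcript_id=tid,
            gene_id=rec["gene_id"],
            chrom=rec["chrom"],
            strand=rec["strand"],
            exons=tuple(rec["exons"]),
            biotype=rec["biotype"],
        )
        for tid, rec in ((t, per_tx[t]) for t in order)
    ]
    return group_into_genes(transcripts)


def group_into_genes(transcripts: Iterable[TranscriptModel]) -> list[GeneModel]:
    """Group transcripts by their ``gene_id`` (the file's grouping is trusted;
    no re-clustering of overlapping transcripts into loci)."""
    genes: dict[str, GeneModel] = {}
    order: list[str] = []
    for t in transcripts:
        g = genes.get(t.gene_id)
        if g is None:
            genes[t.gene_id] = g = GeneModel(
                gene_id=t.gene_id, chrom=t.chrom, strand=t.strand
            )
            order.append(t.gene_id)
        if g.chrom != t.chrom:
            raise GTFParseError(
                f"gene {t.gene_id}: member transcripts on different chromosomes"
            )
        g.transcripts.append(t)
    return [genes[g] for g in order]


def write_gtf(
    genes: Sequence[GeneModel] | Sequence[TranscriptModel],
    path: str | os.PathLike,
    source: str = "lncscan",
) -> None:
    """Write gene/transcript models as GTF (1-based inclusive coordinates)."""
    transcripts: list[TranscriptModel] = []
    for item in genes:
        if isinstance(item, GeneModel):
            transcripts.extend(item.transcripts)
        else:
            transcripts.append(item)
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'biotype "{t.biotype}";'
            )
            fh.write(
                "\t".join(
                    [
                        t.chrom,
                        source,
                        "transcript",
                        str(t.start + 1),
                        str(t.end),
                        ".",
                        t.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
            for s, e in t.exons:
                fh.write(
                    "\t".join(
                        [
                            t.chrom,
                            source,
                            "exon",
                            str(s + 1),
                            str(e),
                            ".",
                            t.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a (multi-record, possibly line-wrapped) FASTA into a dict."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(os.fspath(path), "fasta")
    }


def write_fasta(seqs: Mapping[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, os.fspath(path), "fasta")


def extract_spliced_sequence(
    t: TranscriptModel, genome: Mapping[str, str]
) -> str:
    """Spliced transcript sequence, strand-resolved (5'->3').

    Exon sequences are concatenated in genomic order; for '-' transcripts
    the concatenation is reverse-complemented.
    """
    if t.chrom not in genome:
        raise KeyError(f"chromosome {t.chrom} absent from genome")
    chrom_seq = genome[t.chrom]
    if t.end > len(chrom_seq):
        raise IndexError(
            f"transcript {t.transcript_id}: exon ends at {t.end}, beyond "
            f"chromosome {t.chrom} length {len(chrom_seq)}"
        )
    seq = "".join(chrom_seq[s:e] for s, e in t.exons)
    if t.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


# ---------------------------------------------------------------------------
# Counts TSV


def read_counts(path: str | os.PathLike) -> CountTable:
    """Read a transcript x library count TSV.

    Header row holds library ids (first column transcript ids).  An optional
    sidecar comment line ``#library_totals<TAB>v1<TAB>v2...`` supplies total
    mapped reads per library; otherwise column sums are used.
    """
    totals_values: list[int] | None = None
    body_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(TOTALS_SIDECAR):
                parts = line.rstrip("\n").split("\t")[1:]
                totals_values = [int(v) for v in parts]
            elif line.strip():
                body_lines.append(line)
    df = pd.read_csv(io.StringIO("".join(body_lines)), sep="\t", index_col=0)
    for col in df.columns:
        vals = df[col]
        as_float = pd.to_numeric(vals, errors="coerce")
        if as_float.isna().any() or (as_float != as_float.round()).any():
            raise ValueError(f"non-integer count in library {col}")
    counts = df.astype(np.int64)
    if totals_values is not None:
        if len(totals_values) != counts.shape[1]:
            raise ValueError("library_totals sidecar length mismatch")
        totals = pd.Series(totals_values, index=counts.columns, dtype=np.int64)
    else:
        totals = counts.sum(axis=0)
    return CountTable(counts=counts, library_totals=totals)


def write_counts(table: CountTable, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        if not table.library_totals.equals(table.counts.sum(axis=0)):
            fh.write(
                TOTALS_SIDECAR
                + "\t"
                + "\t".join(str(int(v)) for v in table.library_totals)
                + "\n"
            )
        table.counts.to_csv(fh, sep="\t", index_label="transcript_id")
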
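import numpy as np
import pandas as pd
import pytest

from lncscan.annotation_io import GeneModel, TranscriptModel
from lncscan.synthetic_data import (
    SyntheticDesign,
    _coding_seq,
    _write_spliced,
    make_annotation,
    make_counts,
)


@pytest.fixture(scope="session")
def small_design():
    return SyntheticDesign(
        seed=11,
        n_coding_genes=30,
        n_lincrna=6,
        n_incrna=4,
        n_antisense=4,
        chrom_length=300_000,
    )


@pytest.fixture(scope="session")
def small_annotation(small_design):
    return make_annotation(small_design)


@pytest.fixture(scope="session")
def small_counts(small_design, small_annotation):
    return make_counts(small_design, small_annotation)


@pytest.fixture(scope="session")
def small_lengths(small_annotation):
    return pd.Series(
        {
            t.transcript_id: t.spliced_length
            for t in small_annotation.all_transcripts()
        }
    )


def build_truncation_gene(seed=5):
    """A coding gene with five isoforms: two carrying the full ORF and
    three with an internal exon removed (frameshift into an early stop),
    emulating truncated noncoding products of alternative splicing."""
    rng = np.random.default_rng([seed, 9])
    chrom = "chrT"
    exons = ((100, 250), (400, 551), (700, 800), (950, 1099), (1250, 1450))
    lookup = np.frombuffer(b"ACGT", dtype=np.uint8)
    arr = lookup[rng.integers(0, 4, 3000)].copy()
    spliced_len = sum(e - s for s, e in exons)
    _write_spliced(arr, exons, "+", _coding_seq(rng, spliced_len))
    genome = {chrom: arr.tobytes().decode("ascii")}

    def tx(tid, chain):
        return TranscriptModel(
            transcript_id=tid, gene_id="TRUNC1", chrom=chrom, strand="+",
            exons=tuple(chain),
        )

    isoforms = [
        tx("TRUNC1.1", exons),  # full ORF
        tx("TRUNC1.2", exons[:1] + exons[2:]),  # drop exon 2 (151 nt)
        tx("TRUNC1.3", exons[:4] + ((1250, 1480),)),  # 3' extension, same ORF
        tx("TRUNC1.4", exons[:2] + exons[3:]),  # drop exon 3 (100 nt)
        tx("TRUNC1.5", exons[:3] + exons[4:]),  # drop exon 4 (149 nt)
    ]
    gene = GeneModel(
        gene_id="TRUNC1", chrom=chrom, strand="+", transcripts=isoforms
    )
    return gene, genome
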
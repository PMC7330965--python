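"""ORF scanning, the candidate/coding filter cascade and positional classes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import longest_protein_oracle, orf_oracle
from conftest import build_truncation_gene
from lncscan.annotation_io import GeneModel, TranscriptModel, extract_spliced_sequence
from lncscan.lnc_identify import (
    PositionalClass,
    ReferenceIndex,
    ReferenceLookupError,
    candidate_filter,
    classify_position,
    coding_heuristic,
    find_longest_orf,
    longest_orf_aa,
    run_identification,
    truncated_isoform_screen,
)
from lncscan.synthetic_data import SyntheticDesign, make_annotation


class TestFindLongestORF:
    def test_single_complete_orf(self):
        r = find_longest_orf("ATGAAATAG")
        assert (r.orf_start, r.orf_end) == (0, 9)
        assert r.aa_length == 2
        assert r.complete

    def test_no_start_codon(self):
        r = find_longest_orf("CCCCCC")
        assert r.aa_length == 0 and not r.has_start

    def test_open_stretch_without_stop(self):
        r = find_longest_orf("ATGAAAAAA")
        assert r.has_start and not r.has_stop
        assert r.aa_length == 3  # whole codons of the open stretch

    def test_empty_sequence(self):
        r = find_longest_orf("")
        assert (r.orf_start, r.orf_end, r.aa_length) == (0, 0, 0)

    def test_ties_break_to_smallest_start(self):
        # two complete 0-aa... two equal-length ORFs in different frames
        seq = "ATGAAATAGTATGAAATAGT"
        r = find_longest_orf(seq)
        assert r.orf_start == 0

    @given(st.text(alphabet="ACGTN", min_size=0, max_size=400))
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_agrees_with_codon_pair_enumeration(self, seq):
        start, end, complete = orf_oracle(seq)
        r = find_longest_orf(seq)
        assert (r.orf_start, r.orf_end, r.complete) == (start, end, complete)


class TestCandidateFilter:
    def t(self, exons):
        return TranscriptModel("t", "g", "c", "+", exons)

    def test_two_exons_long_enough_passes(self):
        ok, trail = candidate_filter(self.t(((0, 125), (200, 325))))
        assert ok
        assert dict((n, v) for n, _, v in trail)["length_gt_200"] == 250.0

    def test_single_exon_fails_regardless_of_length(self):
        ok, trail = candidate_filter(self.t(((0, 5000),)))
        assert not ok
        assert [p for n, p, _ in trail if n == "min_exons"] == [False]

    def test_exactly_200_nt_fails_strict_rule(self):
        ok, _ = candidate_filter(self.t(((0, 100), (200, 300))))
        assert not ok

    def test_relaxed_single_exon_mode(self):
        ok, _ = candidate_filter(self.t(((0, 5000),)), min_exons=1)
        assert ok


class TestCodingHeuristic:
    def _tx_with_seq(self, seq):
        genome = {"c": seq}
        t = TranscriptModel("t", "g", "c", "+", ((0, len(seq)),))
        return t, genome

    def test_long_stop_free_frame_is_coding(self):
        seq = "ATG" + "AAC" * 300  # 900 nt, no stop: open coding capacity
        t, genome = self._tx_with_seq(seq)
        noncoding, trail, _ = coding_heuristic(t, genome)
        assert not noncoding

    def test_short_orf_is_noncoding(self):
        # 96-nt ORF (32 aa incl. Met), the regime of identified lncRNA ORFs
        seq = "CC" + "ATG" + "GCT" * 31 + "TAA" + "CC" * 40
        t, genome = self._tx_with_seq(seq)
        noncoding, trail, report = coding_heuristic(t, genome)
        assert noncoding
        assert report.nt_length == 99  # ATG + 31 codons + stop
        assert report.aa_length == 32

    def test_all_n_sequence_is_noncoding(self):
        t, genome = self._tx_with_seq("N" * 600)
        noncoding, _, report = coding_heuristic(t, genome)
        assert noncoding and report.aa_length == 0


def _gene(gene_id, chrom, strand, exons):
    t = TranscriptModel(f"{gene_id}.1", gene_id, chrom, strand, exons)
    return GeneModel(gene_id=gene_id, chrom=chrom, strand=strand, transcripts=[t])


class TestClassifyPosition:
    REF = [
        _gene("G1", "c1", "+", ((10_000, 10_500), (12_000, 12_400), (15_000, 15_600))),
    ]

    def test_distant_transcript_is_lincRNA(self):
        t = TranscriptModel("x", "gx", "c1", "+", ((30_000, 30_300), (30_600, 30_900)))
        assert classify_position(t, self.REF) is PositionalClass.LINCRNA

    def test_intron_nested_same_strand_is_incRNA(self):
        t = TranscriptModel("x", "gx", "c1", "+", ((12_600, 12_800), (13_000, 13_200)))
        assert classify_position(t, self.REF) is PositionalClass.INCRNA

    def test_opposite_strand_exon_overlap_is_antisense(self):
        t = TranscriptModel("x", "gx", "c1", "-", ((12_300, 12_700), (13_000, 13_200)))
        assert classify_position(t, self.REF) is PositionalClass.ANTISENSE

    def test_same_strand_exon_overlap_dropped(self):
        t = TranscriptModel("x", "gx", "c1", "+", ((12_300, 12_700), (13_000, 13_200)))
        assert classify_position(t, self.REF) is PositionalClass.SENSE_OVERLAP

    def test_antisense_precedes_incRNA(self):
        # fully inside the intron but touching an exon on the other strand
        t = TranscriptModel("x", "gx", "c1", "-", ((12_399, 12_800),))
        assert classify_position(t, self.REF) is PositionalClass.ANTISENSE

    def test_missing_chromosome_raises(self):
        t = TranscriptModel("x", "gx", "cZ", "+", ((0, 300),))
        with pytest.raises(ReferenceLookupError):
            classify_position(t, self.REF)

    def test_invariant_under_exon_order_permutation(self):
        shuffled = TranscriptModel(
            "x", "gx", "c1", "+", ((13_000, 13_200), (12_600, 12_800))
        )
        assert classify_position(shuffled, self.REF) is PositionalClass.INCRNA


class TestRunIdentification:
    def test_closed_loop_on_planted_truth(self, small_annotation, small_counts):
        """Every planted lncRNA is recovered with its planted class; no
        extras appear."""
        ann = small_annotation
        res = run_identification(
            ann.assembly, ann.reference, ann.genome, small_counts
        )
        truth = ann.lnc_classes
        pred = {r.transcript_id: r.positional_class.value for r in res.records}
        assert pred == truth

    def test_partition_is_total(self, small_annotation, small_counts):
        ann = small_annotation
        res = run_identification(
            ann.assembly, ann.reference, ann.genome, small_counts
        )
        n_assembly = sum(len(g.transcripts) for g in ann.assembly)
        assert sum(len(v) for v in res.buckets.values()) == n_assembly

    def test_reference_only_assembly_yields_nothing(self, small_annotation):
        ann = small_annotation
        res = run_identification(ann.reference, ann.reference, ann.genome)
        assert res.records == []

    def test_shortened_lincRNA_fails_length_rule(self, small_annotation):
        ann = small_annotation
        linc = next(
            t for t in ann.all_transcripts() if t.gene_id.startswith("LINC")
        )
        s, e = linc.exons[0]
        short = TranscriptModel(
            linc.transcript_id, linc.gene_id, linc.chrom, linc.strand,
            ((s, s + 90), (s + 150, s + 240)),  # 180 nt spliced
        )
        ok, trail = candidate_filter(short)
        assert not ok
        assert ("length_gt_200", False, 180.0) in trail
        res = run_identification(
            [GeneModel(linc.gene_id, linc.chrom, linc.strand, [short])],
            ann.reference, ann.genome,
        )
        assert short.transcript_id in res.buckets["filter_failed"]
        assert short.transcript_id not in res.lncrna_ids


class TestTruncatedIsoformScreen:
    def test_fig7_like_gene_two_coding_three_truncated(self):
        gene, genome = build_truncation_gene()
        res = truncated_isoform_screen(gene, genome)
        verdicts = {tid: v for tid, _, v in res}
        assert sum(v == "coding" for v in verdicts.values()) == 2
        assert sum(v == "truncated-noncoding" for v in verdicts.values()) == 3
        assert verdicts["TRUNC1.1"] == "coding"
        assert verdicts["TRUNC1.3"] == "coding"

    def test_agrees_with_translation_oracle(self):
        gene, genome = build_truncation_gene(seed=3)
        res = truncated_isoform_screen(gene, genome)
        for t in gene.transcripts:
            seq = extract_spliced_sequence(t, genome)
            aa, complete = longest_protein_oracle(seq)
            report = next(r for tid, r, _ in res if tid == t.transcript_id)
            assert (report.aa_length, report.complete) == (aa, complete)

    def test_single_isoform_gene_is_its_own_reference(self):
        gene, genome = build_truncation_gene()
        solo = GeneModel(
            gene_id=gene.gene_id, chrom=gene.chrom, strand=gene.strand,
            transcripts=[gene.transcripts[0]],
        )
        [(tid, _, verdict)] = truncated_isoform_screen(solo, genome)
        assert verdict == "coding"

    def test_gene_without_complete_orf_skipped_with_warning(self):
        genome = {"c": "CCA" * 400}
        g = _gene("G9", "c", "+", ((0, 300), (500, 800)))
        with pytest.warns(UserWarning, match="no isoform"):
            assert truncated_isoform_screen(g, genome) == []


def test_identification_perfect_when_margins_respected():
    """Planted lncRNAs at length >= 300 and ORF <= 50 aa are classified
    with 100% accuracy (fresh design, different seed)."""
    d = SyntheticDesign(seed=23, n_coding_genes=24, n_lincrna=4, n_incrna=3,
                        n_antisense=3, chrom_length=250_000,
                        as_event_plan=(), correlation_plan=())
    ann = make_annotation(d)
    for tid in ann.lnc_classes:
        t = next(x for x in ann.all_transcripts() if x.transcript_id == tid)
        assert t.spliced_length >= 300
        assert longest_orf_aa(extract_spliced_sequence(t, ann.genome)) <= 50
    res = run_identification(ann.assembly, ann.reference, ann.genome)
    assert {r.transcript_id: r.positional_class.value
            for r in res.records} == ann.lnc_classes
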
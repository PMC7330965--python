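"""Five-type AS classification: definitional cases, oracle agreement,
symmetry, dedup and the Table-1-style summary."""

from collections import Counter

import numpy as np
import pytest

from _oracles import as_events_oracle
from lncscan.annotation_io import TranscriptModel
from lncscan.as_events import (
    ASEvent,
    ASEventSummary,
    group_loci,
    locus_events,
    mirror_transcript,
    pairwise_events,
    spliced_fraction,
    summarize_events,
)
from lncscan.synthetic_data import make_as_pair


def tx(tid, exons, strand="+", chrom="c", gene="g"):
    return TranscriptModel(tid, gene, chrom, strand, exons)


class TestPairwiseEvents:
    def test_identical_chains_no_events(self):
        a = tx("a", ((0, 100), (200, 300)))
        b = tx("b", ((0, 100), (200, 300)))
        assert pairwise_events(a, b) == []

    def test_both_single_exon_no_events(self):
        assert pairwise_events(tx("a", ((0, 100),)), tx("b", ((0, 150),))) == []

    def test_downstream_first_exon_start_is_tss(self):
        a = tx("a", ((0, 100), (200, 300), (400, 500)))
        b = tx("b", ((50, 100), (200, 300), (400, 500)))
        events = pairwise_events(a, b)
        assert [e.event_type for e in events] == ["TSS"]
        assert events[0].region == (0, 50)

    def test_distinct_first_exon_is_tss(self):
        a = tx("a", ((0, 100), (200, 300), (400, 500)))
        b = tx("b", ((150, 300), (400, 500)))
        assert [e.event_type for e in pairwise_events(a, b)] == ["TSS"]

    def test_terminal_events_follow_strand(self):
        a = tx("a", ((0, 100), (200, 300)), strand="-")
        b = tx("b", ((50, 100), (200, 300)), strand="-")
        assert [e.event_type for e in pairwise_events(a, b)] == ["TTS"]

    def test_exon_skip(self):
        a = tx("a", ((0, 100), (200, 300), (400, 500)))
        b = tx("b", ((0, 100), (400, 500)))
        events = pairwise_events(a, b)
        assert [(e.event_type, e.region) for e in events] == [("ES", (200, 300))]

    def test_intron_retention_merging_exons(self):
        a = tx("a", ((0, 100), (200, 300), (400, 500)))
        b = tx("b", ((0, 100), (200, 500)))
        events = pairwise_events(a, b)
        assert [(e.event_type, e.region) for e in events] == [("IR", (300, 400))]

    def test_pure_ir_merges_all_introns(self):
        a = tx("a", ((0, 100), (200, 300), (400, 500)))
        b = tx("b", ((0, 500),))
        got = Counter(e.event_type for e in pairwise_events(a, b))
        assert got == Counter({"IR": 2})

    def test_alternative_acceptor_is_ae(self):
        a = tx("a", ((0, 100), (200, 300), (400, 500)))
        b = tx("b", ((0, 100), (240, 300), (400, 500)))
        events = pairwise_events(a, b)
        assert [(e.event_type, e.region) for e in events] == [("AE", (200, 240))]

    def test_multiple_events_in_one_comparison(self):
        a = tx("a", ((0, 100), (200, 300), (400, 500), (600, 700)))
        b = tx("b", ((50, 100), (200, 300), (400, 700)))
        got = Counter(e.event_type for e in pairwise_events(a, b))
        assert got == Counter({"TSS": 1, "IR": 1})

    def test_strand_mismatch_rejected(self):
        with pytest.raises(ValueError, match="strand"):
            pairwise_events(
                tx("a", ((0, 100), (200, 300))),
                tx("b", ((0, 100), (200, 300)), strand="-"),
            )

    def test_disjoint_spans_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            pairwise_events(
                tx("a", ((0, 100), (150, 200))), tx("b", ((500, 600), (700, 800)))
            )

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        for trial in range(100):
            ev = ("TSS", "TTS", "ES", "IR", "AE")[trial % 5]
            a, b = make_as_pair(rng, ev)
            fwd = {(e.event_type, e.region) for e in pairwise_events(a, b)}
            rev = {(e.event_type, e.region) for e in pairwise_events(b, a)}
            assert fwd == rev

    def test_agrees_with_membership_oracle_on_random_pairs(self):
        """Full (type, region) multisets match the per-base labelling
        oracle over randomised single-event pairs and compound variants."""
        rng = np.random.default_rng(7)
        types = ("TSS", "TTS", "ES", "IR", "AE")
        for trial in range(300):
            a, b = make_as_pair(rng, types[trial % 5])
            got = Counter((e.event_type, e.region) for e in pairwise_events(a, b))
            want = Counter(as_events_oracle(a, b))
            assert got == want


class TestLocusEvents:
    def test_three_identical_isoforms(self):
        t = ((0, 100), (200, 300))
        assert locus_events([tx("a", t), tx("b", t), tx("c", t)]) == []

    def test_shared_event_counted_once_per_locus(self):
        """An exon missing from one of three isoforms shows up in two
        pairwise comparisons but is one physical event."""
        full = ((0, 100), (200, 300), (400, 500))
        skip = ((0, 100), (400, 500))
        txs = [tx("a", full), tx("b", full), tx("c", skip)]
        locus = locus_events(txs, count_mode="locus")
        assert [(e.event_type, e.region) for e in locus] == [("ES", (200, 300))]
        pairwise = locus_events(txs, count_mode="pairwise")
        assert Counter(e.event_type for e in pairwise) == Counter({"ES": 2})

    def test_fig6_like_isoform_group(self):
        """Three sequenced variants against their assembled isoforms give
        the annotated multiset {TSS, TSS, ES, IR, ES}."""
        base1 = ((0, 120), (300, 420), (600, 720), (900, 1020))
        t2 = ((60, 120), (300, 420), (600, 720), (900, 1020))  # TSS
        base2 = ((2000, 2120), (2300, 2420), (2600, 2720), (2900, 3020))
        t3 = ((2050, 2120), (2300, 2420), (2600, 2720), (2900, 3020))  # TSS
        t4 = ((2000, 2120), (2300, 2420), (2900, 3020))  # ES
        base3 = (
            (5000, 5120), (5300, 5420), (5600, 5720), (5900, 6020), (6100, 6220)
        )
        t5 = ((5000, 5120), (5300, 5720), (6100, 6220))  # IR + ES
        events = []
        events += locus_events([tx("TC1", base1), tx("T2", t2)])
        events += locus_events([tx("TC2", base2), tx("T3", t3), tx("T4", t4)])
        events += locus_events([tx("TC3", base3), tx("T5", t5)])
        got = Counter(e.event_type for e in events)
        assert got == Counter({"TSS": 2, "ES": 2, "IR": 1})

    def test_group_loci_by_overlap_same_strand(self):
        a = tx("a", ((0, 100), (200, 300)))
        b = tx("b", ((250, 500),))
        c = tx("c", ((10_000, 10_300),))
        d = tx("d", ((0, 100), (200, 300)), strand="-")
        loci = group_loci([a, b, c, d])
        groups = sorted(
            tuple(sorted(t.transcript_id for t in locus)) for locus in loci
        )
        assert groups == [("a", "b"), ("c",), ("d",)]


class TestSummary:
    def test_percentages_from_counts(self):
        s = ASEventSummary.from_counts(
            {"TSS": 508, "TTS": 478, "ES": 39, "IR": 340, "AE": 446}
        )
        assert s.total == 1811
        assert s.percentages == {
            "TSS": 28.05, "TTS": 26.39, "ES": 2.15, "IR": 18.77, "AE": 24.63,
        }

    def test_single_event_type_is_100_percent(self):
        s = ASEventSummary.from_counts({"IR": 1})
        assert s.percentages["IR"] == 100.0
        assert sum(s.percentages.values()) == 100.0

    def test_zero_total_flagged(self):
        s = ASEventSummary.from_counts({})
        assert s.zero_total and s.total == 0
        assert all(v == 0.0 for v in s.percentages.values())

    def test_percentage_sum_close_to_100_on_random_counts(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            counts = {
                t: int(rng.integers(0, 5000))
                for t in ("TSS", "TTS", "ES", "IR", "AE")
            }
            if sum(counts.values()) == 0:
                continue
            s = ASEventSummary.from_counts(counts)
            # five independent 2-dp roundings bound the drift by 5 * 0.005
            assert abs(sum(s.percentages.values()) - 100.0) <= 0.025 + 1e-9

    def test_summarize_counts_involved_isoforms(self):
        ev = [
            ASEvent("ES", "a", "b", (0, 10), "+"),
            ASEvent("other", "a", "c", (20, 30), "+"),
        ]
        summary, frac = summarize_events(ev, 4)
        assert summary.total == 1  # 'other' excluded
        assert frac == 50.0  # isoforms a and b of 4

    def test_spliced_fraction_rounding(self):
        assert spliced_fraction(637, 1442) == 44.17


class TestStrandMirror:
    def test_mirror_swaps_terminal_types_and_preserves_internal(self):
        rng = np.random.default_rng(17)
        types = ("TSS", "TTS", "ES", "IR", "AE")
        for trial in range(50):
            a, b = make_as_pair(rng, types[trial % 5])
            axis = max(a.end, b.end) + 1000
            am, bm = mirror_transcript(a, axis), mirror_transcript(b, axis)
            fwd = Counter(e.event_type for e in pairwise_events(a, b))
            mir = Counter(e.event_type for e in pairwise_events(am, bm))
            swapped = Counter(
                {
                    {"TSS": "TTS", "TTS": "TSS"}.get(k, k): v
                    for k, v in fwd.items()
                }
            )
            assert mir == swapped

    def test_true_reverse_complement_preserves_all_types(self):
        """Mirroring coordinates AND flipping the strand is the same
        molecule, so a strand-aware classifier returns identical types."""
        rng = np.random.default_rng(19)
        types = ("TSS", "TTS", "ES", "IR", "AE")
        for trial in range(50):
            a, b = make_as_pair(rng, types[trial % 5])
            axis = max(a.end, b.end) + 1000
            am = mirror_transcript(a, axis, flip_strand=True)
            bm = mirror_transcript(b, axis, flip_strand=True)
            fwd = Counter(e.event_type for e in pairwise_events(a, b))
            mir = Counter(e.event_type for e in pairwise_events(am, bm))
            assert mir == fwd
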
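"""Obs/Exp/log-odds enrichment against genomic-functional-context backgrounds."""

from __future__ import annotations

import math
import random

import pytest

from conftest import naive_count, random_rna
from rbpkit.enrichment import (
    CONTEXTS,
    UNAVAILABLE,
    UNDEFINED,
    GFCBackground,
    build_background,
    expected_frequency,
    log_odds,
    observed_frequency,
    read_background,
    score_hits,
    write_background,
)
from rbpkit.fixtures import gen_background_pair
from rbpkit.motif_store import MotifRecord
from rbpkit.scanner import SequenceSet, scan


class TestObservedFrequency:
    def test_hand_evaluated_formula(self):
        assert observed_frequency(2, 20, 5) == pytest.approx(2 / 16)

    def test_zero_occurrences(self):
        assert observed_frequency(0, 20, 5) == 0.0

    def test_single_possible_placement(self):
        assert observed_frequency(1, 5, 5) == 1.0

    def test_sequence_shorter_than_motif_rejected(self):
        with pytest.raises(ValueError):
            observed_frequency(1, 4, 5)


class TestBuildBackground:
    def test_counts_and_positions_on_toy_sequence(self):
        bg = build_background(
            SequenceSet([("b", "ACGUACGU")]), ["ACGU"], "cds"
        )
        assert bg.counts["ACGU"] == 2
        assert bg.positions[4] == 5

    def test_absent_motif_counts_zero(self):
        bg = build_background(SequenceSet([("b", "ACGUACGU")]), ["UUUU"], "cds")
        assert bg.counts["UUUU"] == 0

    def test_short_sequences_contribute_zero_positions(self):
        bg = build_background(
            SequenceSet([("a", "A" * 10), ("b", "A" * 3)]), ["AAAAA"], "intron"
        )
        assert bg.positions[5] == 6  # 6 + 0

    def test_empty_fasta_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            build_background(SequenceSet([]), ["ACGU"], "cds")

    def test_unknown_context_rejected(self):
        with pytest.raises(ValueError, match="context"):
            build_background(SequenceSet([("b", "ACGU")]), ["ACGU"], "utr5")

    def test_ambiguous_motif_counts_sum_over_expansions(self):
        bg = build_background(SequenceSet([("b", "ACGUGCGU")]), ["RCGU"], "cds")
        assert bg.counts["RCGU"] == 2  # ACGU once + GCGU once

    def test_agrees_with_sliding_window_counter_on_random_fixtures(self):
        rng = random.Random(97)
        for _ in range(20):
            seqs = [(f"s{i}", random_rna(rng, rng.randint(3, 200))) for i in range(4)]
            motif = random_rna(rng, rng.randint(4, 6), "AC")
            bg = build_background(SequenceSet(seqs), [motif], "exon250")
            expected_c = sum(naive_count(s, motif) for _, s in seqs)
            expected_d = sum(max(0, len(s) - len(motif) + 1) for _, s in seqs)
            assert bg.counts[motif] == expected_c
            assert bg.positions[len(motif)] == expected_d


class TestExpectedFrequencyAndLogOdds:
    def test_hand_evaluated_expected_frequency(self):
        bg = GFCBackground("cds", "", {"AAAAA": 10}, {5: 101})
        assert expected_frequency(bg, "AAAAA") == pytest.approx(10 / 101)

    def test_zero_count_gives_zero_expected(self):
        bg = GFCBackground("cds", "", {"AAAAA": 0}, {5: 101})
        assert expected_frequency(bg, "AAAAA") == 0.0

    def test_zero_positions_rejected(self):
        bg = GFCBackground("cds", "", {"AAAAA": 1}, {5: 0})
        with pytest.raises(ValueError, match="no possible"):
            expected_frequency(bg, "AAAAA")

    def test_log_odds_identities(self):
        assert log_odds(0.25, 0.25) == 0.0
        assert log_odds(0.5, 0.25) == 1.0

    def test_log_odds_hand_evaluated(self):
        assert log_odds(0.125, 10 / 101) == pytest.approx(
            math.log2(0.125 * 101 / 10)
        )

    def test_absent_from_background_is_undefined_sentinel(self):
        assert log_odds(0.125, 0.0) == UNDEFINED

    def test_unfound_motif_rejected(self):
        with pytest.raises(ValueError):
            log_odds(0.0, 0.1)

    def test_monotone_in_observed_count(self):
        bg_exp = 0.01
        ors = [log_odds(observed_frequency(t, 100, 5), bg_exp) for t in (1, 2, 5, 9)]
        assert ors == sorted(ors) and len(set(ors)) == len(ors)


class TestScoreHits:
    @pytest.fixture
    def scanned(self, toy_records):
        seqs = SequenceSet([("s1", "ACAC" + "UGUGUG" + "ACACAC")])
        hits = scan(seqs, toy_records, organism="Homo sapiens")
        return seqs, [h for h in hits if h.record.motif == "UGUGUG"]

    def test_self_background_gives_zero_or_everywhere(self, toy_records):
        """Scanning a FASTA against itself as all three contexts: OR = 0."""
        seqs = SequenceSet([("s1", "ACACUGUGUGACACACGCGCCAC")])
        hits = scan(seqs, toy_records, organism="Homo sapiens")
        assert hits
        motifs = sorted({h.record.motif for h in hits})
        backgrounds = {
            ctx: build_background(seqs, motifs, ctx, organism="Homo sapiens")
            for ctx in CONTEXTS
        }
        for s in score_hits(hits, backgrounds, seqs):
            for ctx in CONTEXTS:
                assert s.odds[ctx] == 0.0

    def test_undefined_sentinel_only_for_absent_context(self, scanned, toy_records):
        seqs, hits = scanned
        present = SequenceSet([("bg", "ACUGUGUGAC")])
        absent = SequenceSet([("bg", "CCCCCCCCCC")])
        backgrounds = {
            "exon250": build_background(present, ["UGUGUG"], "exon250"),
            "cds": build_background(present, ["UGUGUG"], "cds"),
            "intron": build_background(absent, ["UGUGUG"], "intron"),
        }
        scored = score_hits(hits, backgrounds, seqs)
        for s in scored:
            assert s.odds["intron"] == UNDEFINED
            assert isinstance(s.odds["exon250"], float)
            assert isinstance(s.odds["cds"], float)

    def test_missing_background_marked_unavailable(self, scanned):
        seqs, hits = scanned
        scored = score_hits(hits, {}, seqs)
        for s in scored:
            assert all(s.odds[ctx] == UNAVAILABLE for ctx in CONTEXTS)

    def test_organism_mismatch_marked_unavailable(self, scanned):
        seqs, hits = scanned
        bg = build_background(
            SequenceSet([("bg", "UGUGUGUG")]), ["UGUGUG"], "cds", organism="Mus musculus"
        )
        scored = score_hits(hits, {"cds": bg}, seqs)
        assert all(s.odds["cds"] == UNAVAILABLE for s in scored)

    def test_planted_tenfold_enrichment_recovers_log2_ten(self):
        """A pair built with a 10x density ratio scores OR = log2(10) exactly."""
        scan_set, ctx_set, truth = gen_background_pair(seed=11, rho=10)
        rec = MotifRecord(gene_name="X", motif=truth.motif)
        hits = scan(scan_set, [rec])
        assert hits and hits[0].multiplicity == truth.t
        backgrounds = {
            ctx: build_background(ctx_set, [truth.motif], ctx) for ctx in CONTEXTS
        }
        scored = score_hits(hits, backgrounds, scan_set)
        for s in scored:
            for ctx in CONTEXTS:
                assert s.odds[ctx] == pytest.approx(math.log2(10), abs=1e-12)


def test_background_table_round_trip(tmp_path):
    bg = build_background(
        SequenceSet([("b", "ACGUACGUAC")]), ["ACGU", "UGCAUG"], "intron", organism="Homo sapiens"
    )
    path = tmp_path / "intron.tsv"
    write_background(bg, path)
    back = read_background(path)
    assert back.context == bg.context
    assert back.organism == bg.organism
    assert back.counts == bg.counts
    assert back.positions == bg.positions
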
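"""MEI annotation: tails, TSDs, transductions, decomposition, classes,
subfamily diagnostics, ERV/NUMT rules."""

import numpy as np
import pytest

from svatlas.core import revcomp
from svatlas.mei import (DEFAULT_PARAMS, MeiResources, annotate_insert, classify_erv,
                         classify_numt, detect_transductions, find_tsd, l1_subfamily,
                         scan_poly_tail, decompose_insert, gather_insert_hits,
                         classify_insert)
from svatlas.synth import (CanonicalMei, implant_truth_svs, make_consensus_db,
                           simulate_genome)


def _oracle_tail(seq, base, min_len=10, min_purity=0.90, max_offset=50):
    """Brute force: longest window ending within max_offset of the 3' end,
    starting and ending with the tract base, purity >= threshold; ties to
    smaller offset."""
    n = len(seq)
    best = None
    for j in range(n, max(n - max_offset - 1, min_len - 1), -1):
        for i in range(0, j - min_len + 1):
            w = seq[i:j]
            if w[0] != base or w[-1] != base:
                continue
            purity = w.count(base) / len(w)
            if purity >= min_purity:
                cand = (len(w), -(n - j))
                if best is None or cand > best[:2]:
                    best = (len(w), -(n - j), i, j)
    return best and (best[2], best[3])


class TestPolyTail:
    def test_pure_tail_at_end(self):
        seq = "G" * 20 + "A" * 12
        t = scan_poly_tail(seq, "3p")
        assert (t.length, t.purity, t.offset_from_end) == (12, 1.0, 0)

    def test_below_minimum_length(self):
        assert scan_poly_tail("G" * 20 + "A" * 9, "3p") is None

    def test_interrupted_tract_takes_longest_qualifying_window(self):
        """A8 G A8: the 17-bp window has purity 16/17 = 0.941 and beats
        either pure 8-mer (verified against the brute-force oracle)."""
        seq = "CCTT" * 10 + "A" * 8 + "G" + "A" * 8
        t = scan_poly_tail(seq, "3p")
        i, j = _oracle_tail(seq, "A")
        assert j - i == 17
        assert t.length == 17 and abs(t.purity - 16 / 17) < 1e-9

    def test_five_prime_polyt(self):
        seq = "T" * 15 + "G" * 40
        t = scan_poly_tail(seq, "5p")
        assert t.kind == "polyT" and t.length == 15 and t.offset_from_end == 0

    def test_matches_brute_force_on_random_sequences(self, rng):
        """Detector equals the longest-qualifying-tract oracle on random
        A-rich sequences."""
        for trial in range(300):
            n = int(rng.integers(10, 120))
            seq = "".join(rng.choice(list("ACGT"), size=n,
                                     p=[0.45, 0.18, 0.18, 0.19]))
            t = scan_poly_tail(seq, "3p")
            expected = _oracle_tail(seq, "A")
            if expected is None:
                assert t is None
            else:
                i, j = expected
                assert t is not None
                assert (t.length, t.offset_from_end) == (j - i, n - j)


class TestTsd:
    def test_prefix_duplication_of_downstream_flank(self):
        down = "ACGTACGTACGTGGGG"
        ins = down[:12] + "TTTTCCCC" * 10
        tsd = find_tsd(ins, "G" * 60, down + "C" * 44)
        assert tsd.length == 12 and tsd.end == "5p"

    def test_no_terminal_match(self):
        tsd = find_tsd("CCCC" * 20, "A" * 60, "G" * 60)
        assert tsd is None

    def test_longer_end_wins(self):
        """5-bp 5' match vs 9-bp 3' match -> the 9-bp TSD (exhaustive
        terminal-match enumeration)."""
        up = "T" * 40 + "ACGGTACGG"
        down = "ACGTC" + "T" * 55
        ins = "ACGTC" + "G" * 30 + "C" * 30 + "ACGGTACGG"
        tsd = find_tsd(ins, up, down)
        # oracle: all exact terminal matches
        l5 = max((k for k in range(0, 51) if ins[:k] == down[:k]), default=0)
        l3 = max((k for k in range(0, 51) if k == 0 or ins[-k:] == up[-k:]), default=0)
        assert (l5, l3) == (5, 9)
        assert tsd.length == 9 and tsd.end == "3p"


class TestTransductionDetection:
    def test_second_polya_splits_transduced_segment(self, consensus_db):
        genome = {"chr1": simulate_genome(100_000, 0.41, 5)}
        res = MeiResources.build(consensus_db, genome=genome)
        td = genome["chr1"][40_000:40_250].replace("A", "C")[:250]
        genome["chr1"] = genome["chr1"][:40_000] + td + genome["chr1"][40_250:]
        res = MeiResources.build(consensus_db, genome=genome)
        body = consensus_db["L1"][3000:] + "A" * 15 + td
        core, tr, inner = detect_transductions(body, res.genome_index)
        assert tr is not None and tr.side == "3p"
        assert tr.source is not None and tr.aligned_fraction >= 0.8
        assert abs(tr.source.start - 40_000) < 30
        assert len(core) == 3000

    def test_single_tail_stays_solo(self, consensus_db, consensus_resources):
        body = consensus_db["Alu"]
        core, tr, inner = detect_transductions(body, consensus_resources.genome_index)
        assert tr is None and core == body

    def test_poorly_aligning_segment_demoted(self, consensus_db):
        genome = {"chr1": simulate_genome(50_000, 0.41, 6)}
        res = MeiResources.build(consensus_db, genome=genome)
        foreign = simulate_genome(250, 0.5, 99).replace("A", "G")  # not in genome
        body = consensus_db["L1"][3000:] + "A" * 15 + foreign
        core, tr, inner = detect_transductions(body, res.genome_index)
        assert tr is None and core == body


class TestClassRules:
    def test_full_alu_with_tail_and_tsd_is_canonical_solo(self, consensus_db,
                                                          consensus_resources):
        flank_up = simulate_genome(100, 0.41, 11)
        flank_down = simulate_genome(100, 0.41, 12)
        ins = consensus_db["Alu"] + "A" * 25 + flank_up[-15:]
        ann = annotate_insert("x", ins, flank_up, flank_down, consensus_resources)
        assert ann.svclass == "solo_Alu" and ann.canonical
        assert ann.tsd.length == 15 and ann.tails[0].length == 25

    def test_tailless_alu_is_non_canonical_with_flag(self, consensus_db,
                                                     consensus_resources):
        ins = consensus_db["Alu"]
        ann = annotate_insert("x", ins, "G" * 100, "C" * 100, consensus_resources)
        assert ann.svclass == "non_canonical_MEI"
        assert "no_polyA" in ann.noncanonical_flags

    def test_exon_concatenation_is_processed_pseudogene(self, consensus_db):
        from svatlas.synth import PseudogeneIns
        bundle = implant_truth_svs([PseudogeneIns()], 100_000, seed=3,
                                   consensus=consensus_db)
        res = MeiResources.build(consensus_db, genome=bundle.genome,
                                 exons=bundle.exons)
        from svatlas.mei import annotate_record
        ann = annotate_record(bundle.records[0], bundle.genome, res)
        assert ann.svclass == "processed_pseudogene" and ann.exon_count == 2

    def test_random_sequence_unclassified(self, consensus_resources, rng):
        for _ in range(25):
            seq = simulate_genome(1000, 0.41, rng)
            ann = annotate_insert("r", seq, simulate_genome(80, 0.41, rng),
                                  simulate_genome(80, 0.41, rng), consensus_resources)
            assert ann.svclass == "unclassified"
            assert ann.components.coverage < 0.75

    def test_strand_symmetry_of_annotation(self, consensus_db, consensus_resources):
        """Annotating the reverse-complemented insert yields the same class
        with flipped orientation."""
        up = simulate_genome(100, 0.41, 21)
        down = simulate_genome(100, 0.41, 22)
        fwd_ins = consensus_db["Alu"] + "A" * 20 + up[-12:]
        fwd = annotate_insert("f", fwd_ins, up, down, consensus_resources)
        # the reverse-oriented integration of the same element
        rev_ins = revcomp(consensus_db["Alu"] + "A" * 20) + up[-12:]
        rev = annotate_insert("r", rev_ins, up, down, consensus_resources)
        assert fwd.svclass == rev.svclass == "solo_Alu"
        assert (fwd.orientation, rev.orientation) == ("+", "-")
        assert fwd.tsd.length == rev.tsd.length == 12

    def test_conservation_of_allele_length(self, consensus_db, consensus_resources):
        up = simulate_genome(100, 0.41, 31)
        ins = consensus_db["Alu"] + "A" * 22 + up[-10:]
        ann = annotate_insert("c", ins, up, simulate_genome(100, 0.41, 32),
                              consensus_resources)
        parts = ann.tsd.length + sum(t.length for t in ann.tails) \
            + ann.components.query_len
        if ann.transduction is not None:
            parts += len(ann.transduction.sequence)
        assert parts == len(ins)

    def test_twin_priming_detected(self, consensus_db, consensus_resources):
        l1 = consensus_db["L1"]
        body = revcomp(l1[2000:2500]) + l1[2500:]
        up = simulate_genome(100, 0.41, 41)
        ins = body + "A" * 20 + up[-10:]
        ann = annotate_insert("t", ins, up, simulate_genome(100, 0.41, 42),
                              consensus_resources)
        assert ann.svclass == "solo_L1" and ann.twin_priming


class TestSubfamily:
    def _annotate(self, consensus_db, triplet, b5535, b5538, truncate_to=3000):
        db = make_consensus_db(l1_triplet=triplet, l1_5535=b5535, l1_5538=b5538)
        res = MeiResources.build(db)
        core = db["L1"][len(db["L1"]) - truncate_to:] if truncate_to else db["L1"]
        hits = gather_insert_hits(core, res)
        from svatlas.align import chain_best
        return l1_subfamily(chain_best(hits, len(core)), core)

    @pytest.mark.parametrize("triplet,b5535,b5538,expected", [
        ("ACG", "G", "C", "pre-Ta"),
        ("ACG", "T", "G", "pre-Ta"),
        ("ACG", "A", "A", "pre-Ta"),
        ("ACA", "G", "C", "Ta-0"),
        ("ACA", "T", "G", "Ta-1"),
        ("ACA", "A", "C", "Ta"),
        ("ACA", "G", "G", "Ta"),
        ("ACA", "T", "C", "Ta"),
        ("ACT", "G", "C", "undetermined"),
        ("GCA", "T", "G", "undetermined"),
        ("AAA", "G", "C", "undetermined"),
        ("CCC", "T", "G", "undetermined"),
    ])
    def test_diagnostic_rule_table(self, consensus_db, triplet, b5535, b5538, expected):
        """pre-Ta ('ACG' at 5929-5931), Ta ('ACA'), Ta-0 (G/C at 5535/5538),
        Ta-1 (T/G), anything else undetermined."""
        assert self._annotate(consensus_db, triplet, b5535, b5538, truncate_to=1000) == expected

    def test_uncovered_positions_undetermined(self, consensus_db):
        """An element truncated past the diagnostic positions cannot be
        assigned."""
        db = make_consensus_db(l1_triplet="ACA")
        res = MeiResources.build(db)
        core = db["L1"][:5000]  # 3' truncated before position 5535
        from svatlas.align import chain_best
        chain = chain_best(gather_insert_hits(core, res), len(core))
        assert l1_subfamily(chain, core) == "undetermined"


class TestErvNumt:
    def test_solo_ltr(self, consensus_db, consensus_resources):
        out = classify_erv(consensus_db["LTR"], consensus_resources)
        assert out is not None and out[0] == "solo_LTR" and out[1]["ltr_count"] == 1

    def test_full_provirus(self, consensus_db, consensus_resources):
        core = consensus_db["LTR"] + consensus_db["ERVK_INT"] + consensus_db["LTR"]
        out = classify_erv(core, consensus_resources)
        assert out is not None and out[0] == "ERVK" and out[1]["ltr_count"] == 2

    def test_sixty_percent_ltr_fails_coverage(self, consensus_db, consensus_resources):
        core = consensus_db["LTR"] + simulate_genome(340, 0.5, 77)
        assert classify_erv(core, consensus_resources) is None

    def test_numt_simple_and_wrapped(self, consensus_db, consensus_resources):
        mt = consensus_db["MT"]
        frags = classify_numt(mt[200:700], consensus_resources)
        assert frags is not None
        wrap_core = mt[-250:] + mt[:250]
        frags = classify_numt(wrap_core, consensus_resources)
        assert frags is not None

    def test_half_mito_not_numt(self, consensus_db, consensus_resources):
        core = consensus_db["MT"][:250] + simulate_genome(250, 0.5, 88)
        assert classify_numt(core, consensus_resources) is None
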
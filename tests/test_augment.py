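"""Pseudo-haplotype construction, record merging, novel-bubble filter."""

import numpy as np
import pytest

from svatlas.augment import (build_pseudohaplotypes, drop_masked_records,
                             extract_allele, implant_pseudohaplotype, mask_regions,
                             max_overlap_depth, merge_contig_records,
                             novel_bubble_filter, partition_nonoverlapping)
from svatlas.core import GenomicInterval, SvRecord
from svatlas.synth import simulate_genome


def _del(id_, genome, start, length):
    return SvRecord(id_, "chr1", start, genome[start:start + length + 1],
                    genome[start])


def _ins(id_, genome, start, seq):
    return SvRecord(id_, "chr1", start, genome[start], genome[start] + seq)


class TestMasking:
    def test_mask_replaces_with_n_keeping_length(self, rng):
        g = {"chr1": simulate_genome(10_000, 0.5, rng)}
        out = mask_regions(g, [GenomicInterval("chr1", 2000, 3000)])
        assert len(out["chr1"]) == 10_000
        assert out["chr1"][2000:3000] == "N" * 1000
        assert out["chr1"][:2000] == g["chr1"][:2000]

    def test_empty_mask_is_identity(self, rng):
        g = {"chr1": simulate_genome(1000, 0.5, rng)}
        assert mask_regions(g, []) == g

    def test_out_of_bounds_mask_errors(self, rng):
        g = {"chr1": simulate_genome(1000, 0.5, rng)}
        with pytest.raises(ValueError, match="chr1:900-2000"):
            mask_regions(g, [GenomicInterval("chr1", 900, 2000)])

    def test_sv_intersecting_mask_dropped(self, rng):
        g = simulate_genome(10_000, 0.5, rng)
        inside = _del("in", g, 2500, 100)
        outside = _del("out", g, 5000, 100)
        kept = drop_masked_records([inside, outside],
                                   [GenomicInterval("chr1", 2000, 3000)])
        assert [r.id for r in kept] == ["out"]


class TestPartition:
    def test_three_mutually_overlapping_deletions_need_three_groups(self, rng):
        g = simulate_genome(5000, 0.5, rng)
        recs = [_del("a", g, 1000, 300), _del("b", g, 1100, 300), _del("c", g, 1200, 300)]
        assert len(partition_nonoverlapping(recs)) == 3

    def test_disjoint_callset_single_group(self, rng):
        g = simulate_genome(20_000, 0.5, rng)
        recs = [_del(f"d{i}", g, 1000 * (i + 1), 100) for i in range(8)]
        assert len(partition_nonoverlapping(recs)) == 1

    def test_same_position_insertions_separate(self, rng):
        g = simulate_genome(2000, 0.5, rng)
        a = _ins("a", g, 500, "ACGT" * 20)
        b = _ins("b", g, 500, "TTTT" * 20)
        assert len(partition_nonoverlapping([a, b])) == 2

    def test_group_count_equals_sweep_line_depth(self, rng):
        """Greedy first-fit is depth-optimal on random interval sets."""
        g = simulate_genome(100_000, 0.5, rng)
        for _ in range(100):
            recs = []
            for i in range(int(rng.integers(2, 25))):
                s = int(rng.integers(100, 90_000))
                if rng.random() < 0.6:
                    recs.append(_del(f"d{i}", g, s, int(rng.integers(50, 3000))))
                else:
                    recs.append(_ins(f"i{i}", g, s, "ACGT" * 15))
            groups = partition_nonoverlapping(recs)
            assert len(groups) == max_overlap_depth(recs)


class TestImplant:
    def test_single_insertion_lengthens_contig(self, rng):
        g = {"chr1": simulate_genome(3000, 0.5, rng)}
        rec = _ins("i", g["chr1"], 1000, "A" * 100)
        ph = implant_pseudohaplotype(g, [rec])
        assert len(ph.sequences["chr1"]) == 3100

    def test_balanced_del_and_ins_preserve_length(self, rng):
        g = {"chr1": simulate_genome(5000, 0.5, rng)}
        recs = [_del("d", g["chr1"], 1000, 80), _ins("i", g["chr1"], 3000, "G" * 80)]
        ph = implant_pseudohaplotype(g, recs)
        assert len(ph.sequences["chr1"]) == 5000

    def test_allele_round_trip_via_coordinate_map(self, rng):
        """Extracting each implanted allele through the map recovers the alt
        allele exactly, for random non-overlapping groups."""
        for trial in range(60):
            g = {"chr1": simulate_genome(30_000, 0.5, rng)}
            pos = np.sort(rng.choice(np.arange(500, 29_000, 400),
                                     size=int(rng.integers(2, 10)), replace=False))
            recs = []
            for i, p in enumerate(pos):
                p = int(p)
                if rng.random() < 0.5:
                    recs.append(_del(f"d{i}", g["chr1"], p, int(rng.integers(50, 200))))
                else:
                    recs.append(_ins(f"i{i}", g["chr1"], p,
                                     simulate_genome(int(rng.integers(50, 200)), 0.5, rng)))
            ph = implant_pseudohaplotype(g, recs)
            for r in recs:
                assert extract_allele(ph, r.id) == r.alt_allele

    def test_ref_mismatch_guard(self, rng):
        g = {"chr1": simulate_genome(2000, 0.5, rng)}
        bad = SvRecord("x", "chr1", 500, "A" * 60, "A")
        if g["chr1"][500:560] != "A" * 60:
            with pytest.raises(ValueError, match="REF mismatch"):
                implant_pseudohaplotype(g, [bad])

    def test_every_unmasked_sv_lands_in_exactly_one_group(self, rng):
        g = {"chr1": simulate_genome(50_000, 0.5, rng)}
        recs = [_del(f"d{i}", g["chr1"], int(p), 100)
                for i, p in enumerate(range(1000, 40_000, 700))]
        phs, _ = build_pseudohaplotypes(g, recs, [GenomicInterval("chr1", 0, 1500)])
        ids = [sv for ph in phs for sv in ph.member_sv_ids]
        assert sorted(ids) == sorted(r.id for r in recs if r.start >= 1500)
        assert len(ids) == len(set(ids))


class TestMerge:
    def test_two_deletions_merge_with_spacer(self, rng):
        g = {"chr1": simulate_genome(5000, 0.5, rng)}
        a = _del("a", g["chr1"], 1000, 60)
        b = _del("b", g["chr1"], 1361, 60)
        merged = merge_contig_records([a, b], g)
        assert merged.svtype == "COMPLEX"
        assert merged.start == 1000 and merged.end == b.end
        assert merged.ref_allele == g["chr1"][1000:b.end]

    def test_single_record_unchanged(self, rng):
        g = {"chr1": simulate_genome(2000, 0.5, rng)}
        a = _del("a", g["chr1"], 500, 60)
        assert merge_contig_records([a], g) is a

    def test_cross_chromosome_merge_errors(self, rng):
        g = {"chr1": simulate_genome(2000, 0.5, rng)}
        a = _del("a", g["chr1"], 500, 60)
        b = SvRecord("b", "chr2", 100, "ACGTA", "A")
        with pytest.raises(ValueError, match="different chromosomes"):
            merge_contig_records([a, b], g)

    def test_merged_alt_realigns_to_two_gaps(self, rng):
        """Aligning the merged alt back to the merged ref recovers the two
        original deletion gaps (alignment-path oracle)."""
        from Bio import Align
        g = {"chr1": simulate_genome(5000, 0.5, rng)}
        a = _del("a", g["chr1"], 1000, 60)
        b = _del("b", g["chr1"], 1461, 60)
        merged = merge_contig_records([a, b], g)
        aligner = Align.PairwiseAligner(match_score=1, mismatch_score=-4,
                                        open_gap_score=-10, extend_gap_score=-0.1)
        aln = aligner.align(merged.ref_allele, merged.alt_allele)[0]
        # gaps on the alt side relative to the reference
        ref_blocks = aln.aligned[0]
        gaps = [int(ref_blocks[i + 1][0] - ref_blocks[i][1])
                for i in range(len(ref_blocks) - 1)]
        gaps.append(int(ref_blocks[0][0]))                        # leading gap
        gaps.append(len(merged.ref_allele) - int(ref_blocks[-1][1]))  # trailing gap
        assert sorted(g for g in gaps if g) == [60, 60]


class TestNovelBubbles:
    def test_distance_rule(self):
        orig = [GenomicInterval("chr1", 10_000, 10_100)]
        near = GenomicInterval("chr1", 10_600, 10_700)     # 500 bp gap
        far = GenomicInterval("chr1", 11_600, 11_700)      # 1500 bp gap
        out = novel_bubble_filter([near, far], orig)
        assert out == [far]

    def test_empty_original_set_everything_novel(self):
        bubbles = [GenomicInterval("chr1", 0, 10)]
        assert novel_bubble_filter(bubbles, []) == bubbles

    def test_matches_all_pairs_oracle(self, rng):
        for _ in range(50):
            aug = [GenomicInterval("chr1", int(s), int(s) + 50)
                   for s in rng.integers(0, 100_000, size=15)]
            orig = [GenomicInterval("chr1", int(s), int(s) + 50)
                    for s in rng.integers(0, 100_000, size=15)]
            got = {(b.start, b.end) for b in novel_bubble_filter(aug, orig)}
            exp = set()
            for b in aug:
                dmin = min(max(o.start - b.end, b.start - o.end, 0) for o in orig)
                if dmin >= 1000:
                    exp.add((b.start, b.end))
            assert got == exp
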
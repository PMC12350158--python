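"""Core domain types, VCF round trips, dedup/match rules, trio statistics."""

import itertools

import numpy as np
import pytest

from svatlas.core import (SvRecord, TrioGenotypes, allele_divergence, duplicate_pair,
                          mark_duplicate_sites, match_callsets, match_pair,
                          mendelian_rate, parse_sv_vcf, trio_consistent, write_sv_vcf)
from svatlas.synth import random_callset, simulate_genome


def _vcf(tmp_path, lines, samples=()):
    head = ["##fileformat=VCFv4.2", '##contig=<ID=chr1,length=100000>',
            '##INFO=<ID=AF,Number=A,Type=Float,Description="AF">',
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">']
    cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
    if samples:
        cols += "\tFORMAT\t" + "\t".join(samples)
    path = tmp_path / "in.vcf"
    path.write_text("\n".join(head + [cols] + lines) + "\n")
    return str(path)


class TestParsing:
    def test_deletion_coordinates_and_typing(self, tmp_path):
        """POS=101 with a 61-bp REF and 1-bp ALT is a DEL with start=100,
        svlen=60 in the 0-based internal convention."""
        ref61 = "A" + "CGT" * 20
        path = _vcf(tmp_path, [f"chr1\t101\tdel1\t{ref61}\t{ref61[0]}\t.\tPASS\t."])
        (rec,) = parse_sv_vcf(path)
        assert (rec.start, rec.svtype, rec.svlen) == (100, "DEL", 60)
        assert rec.end == 161

    def test_symbolic_alt_flagged_unresolvable(self, tmp_path):
        path = _vcf(tmp_path, ["chr1\t500\tinv1\tA\t<INV>\t.\tPASS\t."])
        (rec,) = parse_sv_vcf(path)
        assert rec.unresolvable and rec.svtype is None and not rec.is_sv

    def test_reference_mismatch_and_missing_contig_errors(self, tmp_path):
        genome = {"chr1": simulate_genome(1000, 0.5, 1)}
        path = _vcf(tmp_path, ["chr1\t11\tx\tAAAA\tA\t.\tPASS\t."])
        if genome["chr1"][10:14] != "AAAA":
            with pytest.raises(ValueError, match="REF allele mismatch"):
                parse_sv_vcf(path, genome)
        path2 = _vcf(tmp_path, ["chr1\t11\tx\tAAAA\tA\t.\tPASS\t."])
        with pytest.raises(KeyError, match="chr9"):
            parse_sv_vcf(_vcf(tmp_path, ["chr9\t11\tx\tAAAA\tA\t.\tPASS\t."]),
                         {"chr1": "A" * 100})

    def test_round_trip_identity(self, tmp_path, rng):
        genome = simulate_genome(50_000, 0.45, rng)
        records = []
        for i in range(30):
            start = int(rng.integers(100, 40_000))
            if rng.random() < 0.5:
                ref = genome[start:start + int(rng.integers(51, 200))]
                alt = ref[0]
            else:
                ref = genome[start]
                alt = ref + simulate_genome(int(rng.integers(50, 200)), 0.5, rng)
            gts = {"s0": ((0, 1), True), "s1": ((1, 1), False)}
            records.append(SvRecord(f"sv{i}", "chr1", start, ref, alt,
                                    genotypes=gts, allele_freq=0.25))
        out = tmp_path / "rt.vcf"
        write_sv_vcf(str(out), records, {"chr1": 50_000}, samples=["s0", "s1"])
        back = parse_sv_vcf(str(out))
        records.sort(key=lambda r: (r.start, r.id))
        assert len(back) == len(records)
        for a, b in zip(records, back):
            assert (a.id, a.chrom, a.start, a.ref_allele, a.alt_allele) == \
                (b.id, b.chrom, b.start, b.ref_allele, b.alt_allele)
            assert a.genotypes == b.genotypes
            assert abs(a.allele_freq - b.allele_freq) < 1e-6

    def test_coordinate_bijection_on_random_records(self, rng):
        """Internal 0-based half-open <-> VCF 1-based is exact both ways."""
        starts = rng.integers(0, 10**8, size=10_000)
        pos = starts + 1
        assert np.array_equal(pos - 1, starts)


def _mk(id_, start, svlen, svtype="DEL", seq=None, carriers=(0, 1), n_samples=6):
    seq = seq if seq is not None else simulate_genome(svlen, 0.5, abs(hash(id_)) % 2**31)
    gts = {f"s{i}": (((0, 1) if i in carriers else (0, 0)), False)
           for i in range(n_samples)}
    if svtype == "DEL":
        return SvRecord(id_, "chr1", start, "T" + seq, "T", genotypes=gts)
    return SvRecord(id_, "chr1", start, "T", "T" + seq, genotypes=gts)


class TestDedup:
    def test_identical_records_collapse(self):
        a = _mk("a", 1000, 100, seq="ACGT" * 25)
        b = _mk("b", 1000, 100, seq="ACGT" * 25)
        res = mark_duplicate_sites([a, b])
        assert len(res.retained) == 1 and res.duplicate_of == {"b": "a"}

    def test_offset_beyond_500_is_kept(self):
        a = _mk("a", 1000, 100, seq="ACGT" * 25)
        b = _mk("b", 1601, 100, seq="ACGT" * 25)
        assert len(mark_duplicate_sites([a, b]).retained) == 2

    def test_size_ratio_boundary_is_strict(self):
        """100 vs 45 bp (ratio 0.45) and 100 vs 50 bp (ratio 0.50) both
        retained: the rule requires a ratio strictly greater than 0.5."""
        a = _mk("a", 1000, 100, seq="AC" * 50)
        for other_len in (45, 50):
            b = _mk("b", 1000, other_len, seq=("AC" * 50)[:other_len])
            assert len(mark_duplicate_sites([a, b]).retained) == 2
        # ratio 0.70 with divergence exactly 0.30: all rules satisfied
        c = _mk("c", 1000, 70, seq=("AC" * 50)[:70])
        assert len(mark_duplicate_sites([a, c]).retained) == 1

    def test_missing_genotypes_relax_carrier_criterion(self):
        a = SvRecord("a", "chr1", 100, "T" + "ACGT" * 20, "T")
        b = SvRecord("b", "chr1", 100, "T" + "ACGT" * 20, "T")
        res = mark_duplicate_sites([a, b])
        assert len(res.retained) == 1 and res.carrier_relaxed_pairs == [("a", "b")]

    def test_idempotent(self, rng):
        recs = random_callset(rng)
        once = mark_duplicate_sites(recs).retained
        twice = mark_duplicate_sites(once).retained
        assert [r.id for r in once] == [r.id for r in twice]

    def test_agrees_with_exhaustive_pairwise_oracle(self, rng):
        """Transitive grouping + representative selection against a from-
        scratch oracle over every record pair."""
        for trial in range(30):
            recs = random_callset(rng, n_clusters=6)
            got = {r.id for r in mark_duplicate_sites(recs).retained}
            assert got == _oracle_dedup(recs)


def _oracle_dedup(recs):
    """Independent re-evaluation: all pairs, union-find by index, smallest
    (start, -svlen, id) representative."""
    parent = list(range(len(recs)))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(len(recs)), 2):
        a, b = recs[i], recs[j]
        if a.svtype != b.svtype or abs(a.start - b.start) > 500:
            continue
        if min(a.svlen, b.svlen) / max(a.svlen, b.svlen) <= 0.5:
            continue
        if allele_divergence(a.sv_seq, b.sv_seq) > 0.30:
            continue
        ca, cb = a.carriers(), b.carriers()
        if ca is not None and cb is not None and (ca | cb):
            if len(ca & cb) / len(ca | cb) < 0.10:
                continue
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)
    groups = {}
    for i in range(len(recs)):
        groups.setdefault(find(i), []).append(recs[i])
    return {min(g, key=lambda r: (r.start, -r.svlen, r.id)).id for g in groups.values()}


class TestMatch:
    def test_identical_callsets_match_bijectively(self, rng):
        recs = random_callset(rng, n_clusters=5)
        out = match_callsets(recs, recs)
        for r in recs:
            assert r.id in out[r.id]

    def test_offset_rule(self):
        a = _mk("a", 1000, 100, seq="ACGT" * 25)
        b = _mk("b", 1060, 100, seq="ACGT" * 25)
        assert match_callsets([a], [b]) == {"a": []}

    def test_size_ratio_and_divergence_boundaries(self):
        """100 vs 79 bp (ratio 0.79 < 0.8) unmatched; 100 vs 90 bp passes the
        ratio rule and sits exactly at the inclusive 10% divergence bound."""
        seq = "ACGT" * 25
        a = _mk("a", 1000, 100, seq=seq)
        assert match_callsets([a], [_mk("b", 1000, 79, seq=seq[:79])]) == {"a": []}
        assert match_callsets([a], [_mk("c", 1000, 90, seq=seq[:90])]) == {"a": ["c"]}

    def test_empty_comparison_set(self):
        a = _mk("a", 1000, 100)
        assert match_callsets([a], []) == {"a": []}

    def test_agrees_with_exhaustive_rule_oracle(self, rng):
        for trial in range(30):
            base = random_callset(rng, n_clusters=4)
            comp = random_callset(rng, n_clusters=4)
            got = match_callsets(base, comp)
            for a in base:
                expected = sorted(b.id for b in comp if match_pair(a, b))
                assert sorted(got[a.id]) == expected


class TestMendelian:
    @pytest.mark.parametrize("f,m,c,expected", [
        ((0, 0), (0, 0), (0, 1), False),
        ((0, 1), (0, 0), (0, 0), True),
        (None, (0, 0), (0, 0), None),
    ])
    def test_examples(self, f, m, c, expected):
        assert trio_consistent(f, m, c) is expected

    def test_all_27_biallelic_combinations_match_enumeration(self):
        """Transmission consistency agrees with explicit enumeration of one
        transmitted allele per parent for every biallelic trio."""
        gts = [(0, 0), (0, 1), (1, 1)]
        for f, m, c in itertools.product(gts, repeat=3):
            expected = any(sorted((fa, ma)) == sorted(c) for fa in f for ma in m)
            assert trio_consistent(f, m, c) == expected

    def test_rate_accounting(self):
        sites = [TrioGenotypes("a", (0, 0), (0, 0), (0, 1)),
                 TrioGenotypes("b", (0, 1), (0, 0), (0, 0)),
                 TrioGenotypes("c", None, (0, 0), (0, 0))]
        s = mendelian_rate(sites)
        assert (s.consistent, s.inconsistent, s.untested) == (1, 1, 1)
        assert s.rate == 0.5
        assert mendelian_rate([]).rate is None
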
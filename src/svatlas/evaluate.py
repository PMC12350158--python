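"""Seeded end-to-end benchmarks over the synthetic fixtures.

Each function regenerates its fixtures from a seed, runs the relevant
toolkit operations from scratch, and reports summary metrics.  The brute-
force oracles used for equivalence checks are implemented here from first
principles, independently of the library code paths they validate.
"""

from __future__ import annotations

import itertools

import numpy as np

from . import synth
from .align import AlignmentHit, chain_best
from .core import (SvRecord, allele_divergence, mark_duplicate_sites, match_callsets,
                   match_pair)
from .augment import (extract_allele, implant_pseudohaplotype, max_overlap_depth,
                      merge_contig_records, partition_nonoverlapping)
from .junctions import annotate_repeat_or_sd_mediated, call_junction, microhomology_len
from .mei import MeiResources, annotate_insert, annotate_record
from .recurrence import assess_recurrence, recurrence_snps
from .tandem import canonical_rotation, classify_duplication, classify_vntr
from .transduction import SourceLocus, bias_test
from .core import GenomicInterval


# ---------------------------------------------------------------------------
# 1. MEI classifier recovery
# ---------------------------------------------------------------------------

def mei_recovery(seed: int, n_mei: int = 200, genome_length: int = 5_000_000,
                 n_random: int = 1000) -> dict:
    """Implant canonical MEIs (randomized TSD 5-30, poly(A) 10-40, 30%
    truncated/inverted, 20% transduced 50-500 bp) in a synthetic genome and
    measure exact recovery of class, TSD length, tail length, transduction
    side and source locus; count solo calls on random sequences."""
    rng = np.random.default_rng(seed)
    db = synth.make_consensus_db()
    descs = [synth.random_canonical_mei(rng) for _ in range(n_mei)]
    bundle = synth.implant_truth_svs(descs, genome_length, seed, consensus=db)
    res = MeiResources.build(db, genome=bundle.genome)
    recovered = 0
    for rec in bundle.records:
        p = bundle.truth[rec.id].params
        ann = annotate_record(rec, bundle.genome, res)
        ok = (ann is not None and ann.svclass == bundle.truth[rec.id].svclass
              and ann.tsd is not None and ann.tsd.length == p["tsd_len"]
              and any(t.length == p["polya_len"] for t in ann.tails))
        if p["td_side"]:
            ok = ok and ann.transduction is not None \
                and ann.transduction.side == p["td_side"] \
                and ann.transduction.source is not None \
                and ann.transduction.source.start < p["source"][1] \
                and ann.transduction.source.end > p["source"][0]
        recovered += ok
    res_consensus = MeiResources.build(db)
    false_solo = 0
    for _ in range(n_random):
        seq = synth.simulate_genome(1000, 0.41, rng)
        ann = annotate_insert("r", seq, synth.simulate_genome(80, 0.41, rng),
                              synth.simulate_genome(80, 0.41, rng), res_consensus)
        if ann.svclass.startswith("solo"):
            false_solo += 1
    return {"recovery_frac": recovered / n_mei, "n": n_mei,
            "false_solo": false_solo, "n_random": n_random}


# ---------------------------------------------------------------------------
# 2. L1 subfamily diagnostics
# ---------------------------------------------------------------------------

SUBFAMILY_CASES = [
    ("ACG", "G", "C", "pre-Ta"), ("ACG", "T", "G", "pre-Ta"),
    ("ACG", "A", "A", "pre-Ta"), ("ACA", "G", "C", "Ta-0"),
    ("ACA", "T", "G", "Ta-1"), ("ACA", "A", "C", "Ta"),
    ("ACA", "G", "G", "Ta"), ("ACA", "T", "C", "Ta"),
    ("ACT", "G", "C", "undetermined"), ("GCA", "T", "G", "undetermined"),
    ("AAA", "G", "C", "undetermined"), ("CCC", "T", "G", "undetermined"),
]


def subfamily_accuracy(seed: int = 0) -> dict:
    from .mei import gather_insert_hits, l1_subfamily
    correct = 0
    for triplet, b5535, b5538, expected in SUBFAMILY_CASES:
        db = synth.make_consensus_db(l1_triplet=triplet, l1_5535=b5535, l1_5538=b5538)
        res = MeiResources.build(db)
        core = db["L1"][-1500:]          # a 5'-truncated, 3'-intact element
        chain = chain_best(gather_insert_hits(core, res), len(core))
        correct += l1_subfamily(chain, core) == expected
    return {"correct": correct, "n": len(SUBFAMILY_CASES)}


# ---------------------------------------------------------------------------
# 3. Microhomology oracle equivalence
# ---------------------------------------------------------------------------

def _oracle_mh_del(seq, d1, d2, cap=50):
    left = 0
    while left < cap and d1 - left - 1 >= 0 and seq[d1 - left - 1] == seq[d2 - left - 1]:
        left += 1
    right = 0
    while right < cap and d2 + right < len(seq) and seq[d1 + right] == seq[d2 + right]:
        right += 1
    return min(left + right, cap)


def _oracle_mh_ins(seq, pos, ins, cap=50, probe=50):
    probe_n = min(probe, len(ins)) if len(ins) > 100 else len(ins)
    right = 0
    while right < probe_n and pos + right < len(seq) and ins[right] == seq[pos + right]:
        right += 1
    left = 0
    while left < probe_n and pos - left - 1 >= 0 and ins[-left - 1] == seq[pos - left - 1]:
        left += 1
    return min(left + right, len(ins), cap)


def microhomology_oracle(seed: int, n: int = 10_000) -> dict:
    """Implementation vs brute-force maximal exact junction extension on
    simulated deletions and insertions, including the 50-bp cap."""
    rng = np.random.default_rng(seed)
    agree = 0
    for i in range(n):
        seq = list(synth.simulate_genome(500, 0.5, rng))
        if i % 2 == 0:
            d1 = int(rng.integers(80, 150))
            d2 = d1 + int(rng.integers(60, 250))
            mh = int(rng.integers(0, 70))
            seq[d2:d2 + mh] = seq[d1:d1 + mh]
            seq = "".join(seq)
            rec = SvRecord("d", "chr1", d1 - 1, seq[d1 - 1:d2], seq[d1 - 1])
            agree += microhomology_len(rec, {"chr1": seq}) == _oracle_mh_del(seq, d1, d2)
        else:
            seq = "".join(seq)
            pos = int(rng.integers(80, 400))
            mh = int(rng.integers(0, 40))
            ins = seq[pos:pos + mh] + synth.simulate_genome(int(rng.integers(50, 200)),
                                                           0.5, rng)
            rec = SvRecord("i", "chr1", pos - 1, seq[pos - 1], seq[pos - 1] + ins)
            agree += microhomology_len(rec, {"chr1": seq}) == _oracle_mh_ins(seq, pos, ins)
    return {"agreement_frac": agree / n, "n": n}


# ---------------------------------------------------------------------------
# 4. Homology scan recovery + mechanism routing + mediation
# ---------------------------------------------------------------------------

def homology_recovery(seed: int, n: int = 80) -> dict:
    """Planted homologous arm pairs (100 bp-5 kb, identity 0.85-1.0): scan
    length within +-10%, correct mechanism bin, mediation iff the synthetic
    track satisfies the dual 85% rules.  Blunt/microhomology deletions are
    mixed in to exercise the short bins."""
    rng = np.random.default_rng(seed)
    db = synth.make_consensus_db()
    descs = []
    for i in range(n):
        if i % 4 == 3:
            descs.append(synth.MicrohomologyDeletion(
                mh_len=int(rng.integers(0, 50)), del_len=int(rng.integers(200, 1200))))
        else:
            descs.append(synth.RepeatPairDeletion(
                arm_len=int(rng.integers(100, 5001)),
                identity=float(rng.uniform(0.85, 1.0)),
                spacer=int(rng.integers(50, 800)),
                family="Alu",
                annotate=str(rng.choice(["same", "none", "mismatch"])),
                with_sd=bool(rng.random() < 0.3)))
        # slot must hold two arms + spacer in the breakpoint zone
    bundle = synth.implant_truth_svs(descs, n * 60_000, seed, consensus=db)
    n_arm = n_len_ok = n_mech = mech_ok = n_med = med_ok = 0
    for rec in bundle.records:
        tr = bundle.truth[rec.id]
        p = tr.params
        call = call_junction(rec, bundle.genome)
        annotate_repeat_or_sd_mediated(call, bundle.repeats, bundle.sds)
        n_mech += 1
        mech_ok += call.mechanism == p["mechanism"]
        if tr.svclass == "repeat_pair_deletion":
            n_arm += 1
            n_len_ok += (call.scan_len is not None
                         and abs(call.scan_len - p["arm_len"]) <= 0.1 * p["arm_len"])
            n_med += 1
            med_ok += ((call.mediating_repeat is not None) == p["mediated"]
                       and call.sd_mediated == p["sd_mediated"])
    return {"scan_within_10pct_frac": n_len_ok / n_arm,
            "mechanism_frac": mech_ok / n_mech,
            "mediation_frac": med_ok / n_med, "n": n}


# ---------------------------------------------------------------------------
# 5. VNTR / duplication rules
# ---------------------------------------------------------------------------

def vntr_dup_accuracy(seed: int, n: int = 100) -> dict:
    rng = np.random.default_rng(seed)
    db = synth.make_consensus_db()
    motifs_pool = ["AGGGC", "ACGGT", "TTAGGCC", "ACG", "AGGCGGGT"]
    descs = []
    for i in range(n):
        kind = i % 5
        if kind == 0:
            m = str(rng.choice(motifs_pool))
            descs.append(synth.VntrSv(motifs=(m,), copies=(int(rng.integers(15, 60)),)))
        elif kind == 1:
            m1, m2 = rng.choice(motifs_pool, size=2, replace=False)
            descs.append(synth.VntrSv(motifs=(str(m1), str(m2)),
                                      copies=(int(rng.integers(15, 40)),
                                              int(rng.integers(15, 40)))))
        elif kind == 2:
            descs.append(synth.DupIns(length=int(rng.integers(100, 800)), kind="tandem"))
        elif kind == 3:
            descs.append(synth.DupIns(length=int(rng.integers(100, 800)), kind="inverted"))
        else:
            descs.append(synth.DupIns(length=int(rng.integers(200, 800)), kind="complex"))
    bundle = synth.implant_truth_svs(descs, n * 25_000, seed, consensus=db)
    correct = 0
    rotation_ok = True
    for rec in bundle.records:
        tr = bundle.truth[rec.id]
        seq = rec.sv_seq
        if tr.svclass.startswith("VNTR"):
            out = classify_vntr(seq)
            correct += out is not None and out[0] == tr.svclass \
                and out[1] == sorted(tr.params["motifs"])
            if out is not None:
                rot = classify_vntr(seq[3:] + seq[:3])
                rotation_ok &= rot is not None and rot[0] == out[0]
        else:
            got = classify_duplication(rec.insert_seq, rec.chrom, rec.inner_start,
                                       bundle.genome)
            correct += got == tr.params["kind"]
    return {"accuracy_frac": correct / n, "rotation_invariant": rotation_ok, "n": n}


# ---------------------------------------------------------------------------
# 6. Chaining optimality
# ---------------------------------------------------------------------------

def _oracle_chain_value(hits, max_trim=10):
    best = (0, 0)
    hits = sorted(hits, key=lambda h: (h.query_start, h.query_end))
    n = len(hits)
    for mask in range(1, 2 ** n):
        sub = [hits[i] for i in range(n) if mask >> i & 1]
        ok = all(sub[k + 1].query_start >= sub[k].query_end - max_trim
                 and sub[k + 1].query_end > sub[k].query_end
                 for k in range(len(sub) - 1))
        if not ok:
            continue
        covered, last = 0, 0
        for h in sub:
            covered += max(0, h.query_end - max(h.query_start, last))
            last = max(last, h.query_end)
        best = max(best, (covered, -len(sub)))
    return best


def chain_optimality(seed: int, n_instances: int = 1000, max_hits: int = 12) -> dict:
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_instances):
        k = int(rng.integers(2, max_hits + 1))
        hits = []
        for _ in range(k):
            qs = int(rng.integers(0, 150))
            qe = qs + int(rng.integers(10, 80))
            hits.append(AlignmentHit(qs, qe, "t", qs, qe, "+", 1.0,
                                     float(rng.integers(5, 100))))
        chain = chain_best(hits, 250)
        got = (chain.covered_bases, -len(chain.hits))
        agree += got == _oracle_chain_value(hits)
    return {"agreement_frac": agree / n_instances, "n": n_instances}


# ---------------------------------------------------------------------------
# 7. Pseudo-haplotype construction
# ---------------------------------------------------------------------------

def pseudohap_checks(seed: int, n_callsets: int = 1000) -> dict:
    rng = np.random.default_rng(seed)
    depth_ok = roundtrip_ok = merge_ok = 0
    n_merge = 0
    for trial in range(n_callsets):
        genome = {"chr1": synth.simulate_genome(30_000, 0.5, rng)}
        g = genome["chr1"]
        recs = []
        for i in range(int(rng.integers(2, 15))):
            s = int(rng.integers(200, 28_000))
            if rng.random() < 0.6:
                length = int(rng.integers(50, 1500))
                recs.append(SvRecord(f"d{i}", "chr1", s, g[s:s + length + 1], g[s]))
            else:
                recs.append(SvRecord(f"i{i}", "chr1", s, g[s],
                                     g[s] + synth.simulate_genome(
                                         int(rng.integers(50, 300)), 0.5, rng)))
        groups = partition_nonoverlapping(recs)
        depth_ok += len(groups) == max_overlap_depth(recs)
        ph = implant_pseudohaplotype(genome, groups[0], 0)
        roundtrip_ok += all(extract_allele(ph, r.id) == r.alt_allele
                            for r in groups[0])
        if trial % 10 == 0:
            # merge round trip on two disjoint deletions
            a = SvRecord("a", "chr1", 1000, g[1000:1061], g[1000])
            b = SvRecord("b", "chr1", 1400, g[1400:1461], g[1400])
            merged = merge_contig_records([a, b], genome)
            n_merge += 1
            merge_ok += (merged.ref_allele == g[1000:1461]
                         and len(merged.ref_allele) - len(merged.alt_allele) == 120)
    return {"depth_agreement_frac": depth_ok / n_callsets,
            "roundtrip_exact_frac": roundtrip_ok / n_callsets,
            "merge_roundtrip_frac": merge_ok / n_merge, "n": n_callsets}


# ---------------------------------------------------------------------------
# 8. Bias test correctness
# ---------------------------------------------------------------------------

def _oracle_bh(pvals):
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, pvals[i] * m / rank)
        adj[i] = prev
    return adj


def bias_checks(seed: int, n_rep: int = 200) -> dict:
    """Closed-form binomial checks, BH step-up equivalence, and separation
    of a planted 90%-biased from a balanced source over seeded replicates."""
    l5 = SourceLocus(GenomicInterval("chr1", 0, 1), n_5p=5, n_3p=0)
    l10 = SourceLocus(GenomicInterval("chr1", 2, 3), n_5p=10, n_3p=0)
    out = bias_test([l5])[0]
    p5_err = abs(out.p_value - 2 * 0.5 ** 5)
    p10_err = abs(bias_test([l10])[0].p_value - 2 * 0.5 ** 10)
    rng = np.random.default_rng(seed)
    loci = []
    for i in range(20):
        n5, n3 = int(rng.integers(0, 15)), int(rng.integers(5, 20))
        loci.append(SourceLocus(GenomicInterval("chr1", 40_000 * i, 40_000 * i + 1),
                                n_5p=n5, n_3p=n3))
    tested = bias_test(loci)
    bh_err = max(abs(a - b) for a, b in zip([l.p_adjusted for l in tested],
                                            _oracle_bh([l.p_value for l in tested])))
    hits = 0
    for rep in range(n_rep):
        r = np.random.default_rng(seed + rep)
        n3_biased = int((r.random(40) < 0.9).sum())
        n3_bal = int((r.random(40) < 0.5).sum())
        pair = bias_test([
            SourceLocus(GenomicInterval("chr1", 0, 1), n_5p=40 - n3_biased, n_3p=n3_biased),
            SourceLocus(GenomicInterval("chr1", 10**6, 10**6 + 1), n_5p=40 - n3_bal,
                        n_3p=n3_bal)])
        hits += pair[0].bias == "3p" and pair[1].bias == "none"
    return {"p_5of5_abs_err": p5_err, "p_10of10_abs_err": p10_err,
            "bh_max_abs_err": bh_err, "separation_frac": hits / n_rep, "n": n_rep}


# ---------------------------------------------------------------------------
# 9. Recurrence screen
# ---------------------------------------------------------------------------

def recurrence_checks(seed: int, n_single: int = 1000, n_dual: int = 100,
                      n_oracle: int = 100) -> dict:
    rng = np.random.default_rng(seed)
    single_fp = sum(
        assess_recurrence(synth.simulate_recurrence_panel(
            n_origins=1, seed=seed + s)[0]).verdict == "supported"
        for s in range(n_single))
    dual_tp = sum(
        assess_recurrence(synth.simulate_recurrence_panel(
            n_origins=2, seed=seed + 10_000 + s)[0]).verdict == "supported"
        for s in range(n_dual))
    oracle_ok = 0
    for _ in range(n_oracle):
        from .recurrence import HaplotypePanel
        H, S = int(rng.integers(4, 50)), int(rng.integers(1, 60))
        m = rng.integers(0, 2, size=(H, S)).astype(np.uint8)
        d = rng.integers(0, 2, size=H).astype(np.uint8)
        positions = np.sort(rng.choice(20_000, size=S, replace=False))
        panel = HaplotypePanel(positions, m, d, 9000, 9100)
        got = {p for p, _ in recurrence_snps(panel, window=20_000)}
        exp = set()
        for j in range(S):
            pos = int(positions[j])
            if not (9050 - 10_000 <= pos <= 9050 + 10_000) or 9000 <= pos < 9100:
                continue
            maf = min(m[:, j].mean(), 1 - m[:, j].mean())
            if maf >= 0.10 and len({(int(a), int(x)) for a, x in zip(m[:, j], d)}) == 4:
                exp.add(pos)
        oracle_ok += got == exp
    return {"single_origin_supported": single_fp, "n_single": n_single,
            "dual_origin_support_frac": dual_tp / n_dual, "n_dual": n_dual,
            "snp_oracle_agreement_frac": oracle_ok / n_oracle}


# ---------------------------------------------------------------------------
# 10. Dedup / matching rules
# ---------------------------------------------------------------------------

def _oracle_dedup_ids(recs):
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


def dedup_match_oracle(seed: int, n_callsets: int = 1000) -> dict:
    rng = np.random.default_rng(seed)
    dedup_ok = match_ok = 0
    for _ in range(n_callsets):
        recs = synth.random_callset(rng, n_clusters=5)
        got = {r.id for r in mark_duplicate_sites(recs).retained}
        dedup_ok += got == _oracle_dedup_ids(recs)
        comp = synth.random_callset(rng, n_clusters=4)
        matches = match_callsets(recs, comp)
        expected = {a.id: sorted(b.id for b in comp if match_pair(a, b)) for a in recs}
        match_ok += all(sorted(matches[k]) == expected[k] for k in expected)
    return {"dedup_agreement_frac": dedup_ok / n_callsets,
            "match_agreement_frac": match_ok / n_callsets, "n": n_callsets}
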
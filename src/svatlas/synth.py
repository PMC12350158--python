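"""Seeded synthetic-fixture generator.

Produces random genomes carrying implanted SVs with per-event ground truth:
canonical and non-canonical MEIs (TSDs, poly(A) tails, 5' truncations and
twin-priming inversions, 5'/3' transductions with planted progenitor
elements), orphan transductions, processed pseudogenes, NUMTs, ERVs, VNTR
expansions/contractions, tandem/inverted/complex duplications, repeat-pair-
mediated deletions with tunable arm length/identity, blunt/microhomology
deletions, plus phased haplotype panels containing independently recurrent
deletions.  All consensus "elements" are short synthetic stand-ins generated
from a fixed seed (with the L1 subfamily-diagnostic positions planted at
their published consensus coordinates), so the suite runs with zero
downloads.

Every descriptor occupies its own genome slot: the SV breakpoint sits in
the first quarter of the slot and any reference-side construction
(progenitors, transduction sources, homology arms, exons) in the second
half, so descriptors never interact.  All randomness flows through one
numpy Generator; regeneration from (seed, descriptors) is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .core import GenomicInterval, SvRecord, revcomp
from .recurrence import HaplotypePanel
from .transduction import FullLengthElement

DEFAULT_GC = 0.41
_CONSENSUS_SEED = 271828

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def simulate_genome(length: int, gc: float = DEFAULT_GC, seed=0) -> str:
    """i.i.d. bases at the requested GC content; deterministic per seed."""
    rng = _rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(BASES, size=length, p=p).tobytes().decode("ascii")


def mutate(seq: str, divergence: float, rng: np.random.Generator) -> str:
    """Substitute a ``divergence`` fraction of positions (no indels)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    n_mut = int(round(divergence * len(arr)))
    if n_mut == 0:
        return seq
    pos = rng.choice(len(arr), size=n_mut, replace=False)
    for i in pos:
        choices = BASES[BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def _remove_polya_windows(seq: str, rng: np.random.Generator, base: str = "A",
                          win: int = 10, max_hits: int = 9) -> str:
    """Break any window that could pass the tail purity rule (>=9 of 10) so
    synthetic elements never carry accidental internal tails."""
    arr = list(seq)
    changed = True
    while changed:
        changed = False
        for i in range(len(arr) - win + 1):
            window = arr[i:i + win]
            if sum(1 for c in window if c == base) >= max_hits:
                # knock out the A nearest the window middle
                a_pos = [k for k, c in enumerate(window) if c == base]
                j = i + min(a_pos, key=lambda k: abs(k - win // 2))
                arr[j] = "C"
                changed = True
    return "".join(arr)


def _afree_tail(seq: str, n: int = 6) -> str:
    """Make the last ``n`` bases A-free so an appended poly(A) tail has an
    unambiguous 5' boundary."""
    tail = seq[-n:].replace("A", "C")
    return seq[:-n] + tail


def make_consensus_db(seed: int = _CONSENSUS_SEED, l1_triplet: str = "ACA",
                      l1_5535: str = "G", l1_5538: str = "C") -> dict[str, str]:
    """Synthetic consensus stand-ins for Alu, L1 (6 kb, with the subfamily
    diagnostic bases planted at 1-based consensus positions 5929-5931 and
    5535/5538), the SVA components, an LTR, an ERVK internal sequence and a
    circular mitochondrial genome."""
    rng = np.random.default_rng(seed)
    sizes = {
        "Alu": 300,
        "L1": 6000,
        "SVA_ALU_LIKE": 330,
        "SVA_VNTR": 700,
        "SVA_SINER": 430,
        "SVA_MAST2": 150,
        "LTR": 500,
        "ERVK_INT": 1800,
        "MT": 2200,
    }
    db = {}
    for name, n in sizes.items():
        seq = simulate_genome(n, 0.45, rng)
        seq = _remove_polya_windows(seq, rng)
        db[name] = _afree_tail(seq)
    l1 = list(db["L1"])
    l1[5928:5931] = list(l1_triplet)     # 1-based 5929-5931
    l1[5534] = l1_5535
    l1[5537] = l1_5538
    db["L1"] = "".join(l1)
    return db


SVA_COMPONENT_ORDER = ("SVA_ALU_LIKE", "SVA_VNTR", "SVA_SINER")


def element_body(db: dict[str, str], element: str) -> str:
    """Full forward-orientation body of an element; SVA is the ordered
    concatenation of its components."""
    if element == "SVA":
        return "".join(db[c] for c in SVA_COMPONENT_ORDER)
    return db[element]


# ---------------------------------------------------------------------------
# Descriptors
# ---------------------------------------------------------------------------

@dataclass
class CanonicalMei:
    element: str = "Alu"              # Alu | L1 | SVA
    tsd_len: int = 12
    polya_len: int = 20
    truncation: int = 0               # bp removed from the element 5' end
    inversion: int = 0                # bp of the (truncated) 5' end inverted
    td_side: Optional[str] = None     # None | '3p' | '5p'
    td_len: int = 0
    inner_polya_len: int = 15
    orientation: str = "+"


@dataclass
class NonCanonicalMei:
    element: str = "Alu"
    flag: str = "no_polyA"            # no_polyA | truncated_3p | internal_rearrangement
    truncation_3p: int = 120


@dataclass
class OrphanTd:
    td_len: int = 300
    polya_len: int = 20
    tsd_len: int = 10


@dataclass
class PseudogeneIns:
    n_exons: int = 2
    exon_len: int = 300
    intron_len: int = 400
    polya_len: int = 20
    tsd_len: int = 10


@dataclass
class NumtIns:
    length: int = 500
    wrap: bool = False


@dataclass
class ErvIns:
    kind: str = "solo_LTR"            # solo_LTR | ERVK


@dataclass
class VntrSv:
    motifs: tuple = ("AGGGC",)
    copies: tuple = (40,)
    svtype: str = "INS"


@dataclass
class DupIns:
    length: int = 400
    kind: str = "tandem"              # tandem | inverted | complex


@dataclass
class RepeatPairDeletion:
    arm_len: int = 300
    identity: float = 0.95
    spacer: int = 500
    family: str = "Alu"
    annotate: str = "same"            # same | none | mismatch
    with_sd: bool = False


@dataclass
class MicrohomologyDeletion:
    mh_len: int = 6
    del_len: int = 800


Descriptor = Union[CanonicalMei, NonCanonicalMei, OrphanTd, PseudogeneIns,
                   NumtIns, ErvIns, VntrSv, DupIns, RepeatPairDeletion,
                   MicrohomologyDeletion]


@dataclass
class TruthRecord:
    sv_id: str
    svclass: str
    params: dict = field(default_factory=dict)
    seed: Optional[int] = None


@dataclass
class FixtureBundle:
    genome: dict[str, str]
    records: list[SvRecord]
    truth: dict[str, TruthRecord]
    repeats: list[GenomicInterval] = field(default_factory=list)
    sds: list[GenomicInterval] = field(default_factory=list)
    exons: list[GenomicInterval] = field(default_factory=list)
    progenitors: list[FullLengthElement] = field(default_factory=list)
    consensus: dict[str, str] = field(default_factory=dict)


class _Builder:
    def __init__(self, genome: str, chrom: str, db: dict[str, str],
                 rng: np.random.Generator, seed: int):
        self.g = bytearray(genome.encode("ascii"))
        self.chrom = chrom
        self.db = db
        self.rng = rng
        self.seed = seed
        self.bundle = FixtureBundle({}, [], {}, consensus=db)

    # -- genome editing ----------------------------------------------------
    def write(self, pos: int, seq: str) -> None:
        self.g[pos:pos + len(seq)] = seq.encode("ascii")

    def read(self, lo: int, hi: int) -> str:
        return self.g[lo:hi].decode("ascii")

    def force_diff(self, pos: int, avoid: str) -> None:
        if chr(self.g[pos]) in avoid:
            for b in "CTGA":
                if b not in avoid:
                    self.g[pos] = ord(b)
                    break

    # -- record creation ---------------------------------------------------
    def add_insertion(self, sv_id: str, p: int, insert: str, svclass: str,
                      params: dict) -> SvRecord:
        anchor = chr(self.g[p - 1])
        rec = SvRecord(id=sv_id, chrom=self.chrom, start=p - 1,
                       ref_allele=anchor, alt_allele=anchor + insert)
        self.bundle.records.append(rec)
        self.bundle.truth[sv_id] = TruthRecord(sv_id, svclass, params, self.seed)
        return rec

    def add_deletion(self, sv_id: str, d1: int, d2: int, svclass: str,
                     params: dict) -> SvRecord:
        rec = SvRecord(id=sv_id, chrom=self.chrom, start=d1 - 1,
                       ref_allele=self.read(d1 - 1, d2),
                       alt_allele=chr(self.g[d1 - 1]))
        self.bundle.records.append(rec)
        self.bundle.truth[sv_id] = TruthRecord(sv_id, svclass, params, self.seed)
        return rec

    def tsd_seq(self, p: int, tsd_len: int, insert_wo_tsd: str) -> str:
        """Reference TSD copy upstream of the integration point, with the
        adjacent genome base forced to differ from the insert base that
        precedes the TSD so the detected TSD length is exact."""
        if tsd_len == 0:
            return ""
        seq = self.read(p - tsd_len, p)
        if insert_wo_tsd:
            self.force_diff(p - tsd_len - 1, insert_wo_tsd[-1])
        return seq

    def sanitize_source(self, lo: int, hi: int) -> None:
        """A-free first/last 6 bases of a transduced source segment so tail
        boundaries next to it stay exact."""
        for i in list(range(lo, min(lo + 6, hi))) + list(range(max(hi - 6, lo), hi)):
            if chr(self.g[i]) == "A":
                self.g[i] = ord("C")


def implant_truth_svs(descriptors: Sequence[Descriptor], genome_length: int,
                      seed: int, consensus: Optional[dict[str, str]] = None,
                      chrom: str = "chr1", gc: float = DEFAULT_GC) -> FixtureBundle:
    """Build a genome carrying every descriptor plus VCF-ready records,
    per-event truth, and matching repeat/SD/exon annotation tracks."""
    rng = np.random.default_rng(seed)
    db = consensus if consensus is not None else make_consensus_db()
    n = max(len(descriptors), 1)
    slot = genome_length // n
    for d in descriptors:
        point_need, mod_need = _slot_requirement(d, db)
        if slot // 5 < point_need or slot // 2 < mod_need + 100:
            need = max(5 * point_need, 2 * (mod_need + 100))
            raise ValueError(
                f"descriptor {d} does not fit: needs a {need}-bp slot, have "
                f"{slot} bp; increase genome_length to >= {need * n}")
    genome = simulate_genome(genome_length, gc, rng)
    b = _Builder(genome, chrom, db, rng, seed)
    for i, desc in enumerate(descriptors):
        s0 = i * slot
        p = s0 + slot // 4 + int(rng.integers(0, max(slot // 16, 1)))
        m0 = s0 + slot // 2
        sv_id = f"sv{i:04d}"
        _IMPLANTERS[type(desc)](b, desc, sv_id, p, m0)
    b.bundle.genome = {chrom: b.g.decode("ascii")}
    return b.bundle


def _slot_requirement(d: Descriptor, db: dict[str, str]) -> tuple[int, int]:
    """(breakpoint-zone footprint, modification-zone footprint) in bp."""
    if isinstance(d, CanonicalMei):
        return 100, 700 + len(element_body(db, d.element)) + d.td_len
    if isinstance(d, NonCanonicalMei):
        return 100, 0
    if isinstance(d, OrphanTd):
        return 100, 400 + d.td_len
    if isinstance(d, PseudogeneIns):
        return 100, 300 + d.n_exons * (d.exon_len + d.intron_len)
    if isinstance(d, (NumtIns, ErvIns)):
        return 100, 0
    if isinstance(d, VntrSv):
        allele = sum(len(m) * c for m, c in zip(d.motifs, d.copies))
        return (allele + 100 if d.svtype == "DEL" else 100), 0
    if isinstance(d, DupIns):
        return 2 * d.length + 100, 0
    if isinstance(d, RepeatPairDeletion):
        return 2 * d.arm_len + d.spacer + 100, 0
    if isinstance(d, MicrohomologyDeletion):
        return d.del_len + d.mh_len + 100, 0
    raise TypeError(type(d))


# ---------------------------------------------------------------------------
# Per-descriptor implanters
# ---------------------------------------------------------------------------

def _implant_canonical(b: _Builder, d: CanonicalMei, sv_id: str, p: int, m0: int):
    body = element_body(b.db, d.element)
    full_len = len(body)
    if d.truncation:
        body = body[d.truncation:]
    if d.inversion:
        inv = min(d.inversion, len(body) // 2)
        body = revcomp(body[:inv]) + body[inv:]
    params = dict(element=d.element, tsd_len=d.tsd_len, polya_len=d.polya_len,
                  truncation=d.truncation, inversion=d.inversion,
                  orientation=d.orientation, td_side=d.td_side, td_len=d.td_len,
                  full_length=d.truncation == 0)
    if d.td_side == "3p":
        prog = m0 + 500
        b.write(prog, element_body(b.db, d.element))
        src_lo, src_hi = prog + full_len, prog + full_len + d.td_len
        b.sanitize_source(src_lo, src_hi)
        td = b.read(src_lo, src_hi)
        body = body + "A" * d.inner_polya_len + td
        params["source"] = (src_lo, src_hi)
        b.bundle.progenitors.append(FullLengthElement(
            GenomicInterval(b.chrom, prog, prog + full_len), d.element, orientation="+"))
        b.bundle.repeats.append(GenomicInterval(b.chrom, prog, prog + full_len,
                                                label=d.element))
    elif d.td_side == "5p":
        prog = m0 + 500 + d.td_len + 100
        b.write(prog, element_body(b.db, d.element))
        src_lo, src_hi = prog - 100 - d.td_len, prog - 100
        b.sanitize_source(src_lo, src_hi)
        td = b.read(src_lo, src_hi)
        body = td + body
        params["source"] = (src_lo, src_hi)
        b.bundle.progenitors.append(FullLengthElement(
            GenomicInterval(b.chrom, prog, prog + full_len), d.element, orientation="+"))
    fwd = body + "A" * d.polya_len
    insert = fwd if d.orientation == "+" else revcomp(fwd)
    tsd = b.tsd_seq(p, d.tsd_len, insert)
    insert = insert + tsd
    cls = f"solo_{d.element}" if d.td_side is None else f"partnered_td_{d.td_side}"
    b.add_insertion(sv_id, p, insert, cls, params)


def _implant_noncanonical(b: _Builder, d: NonCanonicalMei, sv_id: str, p: int, m0: int):
    body = element_body(b.db, d.element)
    flags = {"no_polyA"}
    if d.flag == "truncated_3p":
        body = body[: len(body) - d.truncation_3p]
        flags.add("truncated_3p")
    elif d.flag == "internal_rearrangement":
        third = len(body) // 3
        body = body[third: 2 * third] + body[:third]
        flags.add("internal_rearrangement")
    b.add_insertion(sv_id, p, body, "non_canonical_MEI",
                    dict(element=d.element, flags=sorted(flags)))


def _implant_orphan(b: _Builder, d: OrphanTd, sv_id: str, p: int, m0: int):
    src_lo, src_hi = m0 + 200, m0 + 200 + d.td_len
    b.sanitize_source(src_lo, src_hi)
    td = b.read(src_lo, src_hi)
    fwd = td + "A" * d.polya_len
    tsd = b.tsd_seq(p, d.tsd_len, fwd)
    b.add_insertion(sv_id, p, fwd + tsd, "orphan_td",
                    dict(td_len=d.td_len, source=(src_lo, src_hi),
                         tsd_len=d.tsd_len, polya_len=d.polya_len))


def _implant_pseudogene(b: _Builder, d: PseudogeneIns, sv_id: str, p: int, m0: int):
    parts = []
    pos = m0 + 200
    for e in range(d.n_exons):
        lo, hi = pos, pos + d.exon_len
        b.sanitize_source(lo, hi)
        b.bundle.exons.append(GenomicInterval(b.chrom, lo, hi, label=f"{sv_id}_exon{e + 1}"))
        parts.append(b.read(lo, hi))
        pos = hi + d.intron_len
    fwd = "".join(parts) + "A" * d.polya_len
    tsd = b.tsd_seq(p, d.tsd_len, fwd)
    b.add_insertion(sv_id, p, fwd + tsd, "processed_pseudogene",
                    dict(n_exons=d.n_exons, tsd_len=d.tsd_len, polya_len=d.polya_len))


def _implant_numt(b: _Builder, d: NumtIns, sv_id: str, p: int, m0: int):
    mt = b.db["MT"]
    if d.wrap:
        a = len(mt) - d.length // 2
    else:
        a = int(b.rng.integers(0, max(len(mt) - d.length, 1)))
    insert = (mt + mt)[a: a + d.length]
    b.add_insertion(sv_id, p, insert, "NUMT",
                    dict(mt_start=a, length=d.length, wrap=d.wrap))


def _implant_erv(b: _Builder, d: ErvIns, sv_id: str, p: int, m0: int):
    ltr = b.db["LTR"]
    if d.kind == "solo_LTR":
        insert = ltr
    else:
        insert = ltr + b.db["ERVK_INT"] + ltr
    b.add_insertion(sv_id, p, insert, d.kind, dict(kind=d.kind))


def _implant_vntr(b: _Builder, d: VntrSv, sv_id: str, p: int, m0: int):
    allele = "".join(m * c for m, c in zip(d.motifs, d.copies))
    from .tandem import canonical_rotation
    params = dict(motifs=[canonical_rotation(m) for m in d.motifs],
                  copies=list(d.copies), svtype=d.svtype)
    cls = "VNTR_simple" if len(d.motifs) == 1 else "VNTR_complex"
    if d.svtype == "INS":
        b.add_insertion(sv_id, p, allele, cls, params)
    else:
        b.write(p, allele)
        b.add_deletion(sv_id, p, p + len(allele), cls, params)


def _implant_dup(b: _Builder, d: DupIns, sv_id: str, p: int, m0: int):
    if d.kind == "tandem":
        insert = b.read(p - d.length, p)
    elif d.kind == "inverted":
        insert = revcomp(b.read(p, p + d.length))
    else:
        half = d.length // 2
        insert = b.read(p - half, p) + revcomp(b.read(p, p + (d.length - half)))
    b.add_insertion(sv_id, p, insert, f"dup_{d.kind}",
                    dict(kind=d.kind, length=d.length))


def _implant_repeat_pair(b: _Builder, d: RepeatPairDeletion, sv_id: str, p: int, m0: int):
    arm = simulate_genome(d.arm_len, 0.45, b.rng)
    arm2 = mutate(arm, 1 - d.identity, b.rng)
    a1, a2 = p, p + d.arm_len + d.spacer
    b.write(a1, arm)
    b.write(a2, arm2)
    if d.annotate == "same":
        b.bundle.repeats.append(GenomicInterval(b.chrom, a1, a1 + d.arm_len, label=d.family))
        b.bundle.repeats.append(GenomicInterval(b.chrom, a2, a2 + d.arm_len, label=d.family))
    elif d.annotate == "mismatch":
        b.bundle.repeats.append(GenomicInterval(b.chrom, a1, a1 + d.arm_len, label=d.family))
        b.bundle.repeats.append(GenomicInterval(b.chrom, a2, a2 + d.arm_len, label="L1"))
    if d.with_sd:
        b.bundle.sds.append(GenomicInterval(b.chrom, a1 - 10, a1 + d.arm_len + 10,
                                            label=f"{sv_id}_sd"))
    mech = "NAHR" if d.arm_len >= 200 else ("HDR" if d.arm_len >= 50 else "NHEJ_altEJ_MMBIR")
    b.add_deletion(sv_id, a1, a2, "repeat_pair_deletion",
                   dict(arm_len=d.arm_len, identity=d.identity, spacer=d.spacer,
                        mechanism=mech, mediated=d.annotate == "same",
                        sd_mediated=d.with_sd, family=d.family))


def _implant_microhomology(b: _Builder, d: MicrohomologyDeletion, sv_id: str, p: int, m0: int):
    d1, d2 = p, p + d.del_len
    if d.mh_len:
        b.write(d2, b.read(d1, d1 + d.mh_len))
    b.force_diff(d2 + d.mh_len, chr(b.g[d1 + d.mh_len]))
    b.force_diff(d2 - 1, chr(b.g[d1 - 1]))
    if d.mh_len == 0:
        b.force_diff(d2, chr(b.g[d1]))
    mech = "NHEJ_altEJ_MMBIR" if d.mh_len <= 15 else "homology_independent"
    b.add_deletion(sv_id, d1, d2, "microhomology_deletion",
                   dict(mh_len=d.mh_len, mechanism=mech))


_IMPLANTERS = {
    CanonicalMei: _implant_canonical,
    NonCanonicalMei: _implant_noncanonical,
    OrphanTd: _implant_orphan,
    PseudogeneIns: _implant_pseudogene,
    NumtIns: _implant_numt,
    ErvIns: _implant_erv,
    VntrSv: _implant_vntr,
    DupIns: _implant_dup,
    RepeatPairDeletion: _implant_repeat_pair,
    MicrohomologyDeletion: _implant_microhomology,
}


# ---------------------------------------------------------------------------
# Randomized descriptor mixes
# ---------------------------------------------------------------------------

def random_canonical_mei(rng: np.random.Generator, p_truncated: float = 0.3,
                         p_transduced: float = 0.2) -> CanonicalMei:
    """One canonical MEI with randomized TSD (5-30 bp), poly(A) (10-40 bp),
    optional 5' truncation/twin-priming inversion and optional 3'
    transduction of 50-500 bp."""
    element = str(rng.choice(["Alu", "L1", "SVA"], p=[0.6, 0.25, 0.15]))
    full = {"Alu": 300, "L1": 6000, "SVA": 1460}[element]
    trunc = inv = 0
    if rng.random() < p_truncated:
        trunc = int(rng.integers(50, full // 2))
        if rng.random() < 0.5:
            inv = int(rng.integers(50, max((full - trunc) // 3, 51)))
    td_side, td_len = None, 0
    if rng.random() < p_transduced:
        td_side, td_len = "3p", int(rng.integers(50, 501))
    return CanonicalMei(
        element=element,
        tsd_len=int(rng.integers(5, 31)),
        polya_len=int(rng.integers(10, 41)),
        truncation=trunc,
        inversion=inv,
        td_side=td_side,
        td_len=td_len,
        inner_polya_len=int(rng.integers(10, 26)),
        orientation=str(rng.choice(["+", "-"])),
    )


# ---------------------------------------------------------------------------
# Random callsets (dedup / matching fixtures)
# ---------------------------------------------------------------------------

def random_callset(rng: np.random.Generator, n_clusters: int = 8,
                   n_samples: int = 12, contig_len: int = 500_000,
                   chrom: str = "chr1") -> list[SvRecord]:
    """Clustered random callset exercising the duplicate-marking rule space:
    breakpoint offsets straddling 500 bp, size ratios straddling 0.5,
    divergences straddling 30% and carrier overlaps straddling 10%."""
    samples = [f"s{i}" for i in range(n_samples)]
    records: list[SvRecord] = []
    rid = 0
    for c in range(n_clusters):
        base_start = int(rng.integers(2000, contig_len - 2000))
        svtype = str(rng.choice(["DEL", "INS"]))
        base_len = int(rng.integers(50, 160))
        base_seq = simulate_genome(base_len, 0.5, rng)
        base_carriers = set(rng.choice(n_samples, size=int(rng.integers(2, 7)),
                                       replace=False).tolist())
        for v in range(int(rng.integers(1, 4))):
            offset = int(rng.choice([0, 5, 60, 499, 500, 501, 650]))
            ratio = float(rng.choice([1.0, 0.9, 0.8, 0.79, 0.55, 0.5, 0.45]))
            div = float(rng.choice([0.0, 0.05, 0.1, 0.12, 0.25, 0.3, 0.35]))
            length = max(50, int(round(base_len * ratio)))
            seq = mutate(base_seq, div, rng)[:length]
            if len(seq) < length:
                seq = seq + simulate_genome(length - len(seq), 0.5, rng)
            if rng.random() < 0.7:
                carriers = set(base_carriers)
            else:
                carriers = set(rng.choice(n_samples, size=max(1, len(base_carriers)),
                                          replace=False).tolist())
            genotypes = {s: (((0, 1) if i in carriers else (0, 0)), False)
                         for i, s in enumerate(samples)}
            start = base_start + (offset if v else 0)
            anchor = "T"
            if svtype == "DEL":
                rec = SvRecord(f"r{rid:04d}", chrom, start, anchor + seq, anchor,
                               genotypes=genotypes)
            else:
                rec = SvRecord(f"r{rid:04d}", chrom, start, anchor, anchor + seq,
                               genotypes=genotypes)
            records.append(rec)
            rid += 1
    return sorted(records, key=lambda r: (r.chrom, r.start, r.id))


# ---------------------------------------------------------------------------
# Recurrence panels
# ---------------------------------------------------------------------------

def simulate_recurrence_panel(n_haplotypes: int = 200, window: int = 100_000,
                              n_origins: int = 1, n_snps: int = 150,
                              mut_rate: float = 0.01, core_divergence: float = 0.35,
                              recomb_rate: float = 0.0, seed=0
                              ) -> tuple[HaplotypePanel, bool]:
    """Phased panel around one focal deletion planted on ``n_origins``
    ancestral backgrounds (two divergent haplotype cores plus per-haplotype
    mutations; optional per-SNP recombination switches).

    Returns (panel, truth) where truth is whether the deletion is recurrent
    (planted independently on both cores)."""
    if n_origins not in (1, 2):
        raise ValueError("n_origins must be 1 or 2")
    rng = _rng(seed)
    center = window // 2
    del_start, del_end = center - 400, center + 400
    pos = np.sort(rng.choice(
        np.concatenate([np.arange(0, del_start - 10), np.arange(del_end + 10, window)]),
        size=n_snps, replace=False))
    core_a = rng.integers(0, 2, n_snps).astype(np.uint8)
    flip = rng.random(n_snps) < core_divergence
    core_b = np.where(flip, 1 - core_a, core_a).astype(np.uint8)
    assign = np.zeros(n_haplotypes, dtype=int)
    assign[n_haplotypes // 2:] = 1
    matrix = np.where(assign[:, None] == 0, core_a[None, :], core_b[None, :])
    if recomb_rate > 0:
        switch = rng.random((n_haplotypes, n_snps)) < recomb_rate
        cross = np.cumsum(switch, axis=1) % 2 == 1
        other = np.where(assign[:, None] == 0, core_b[None, :], core_a[None, :])
        matrix = np.where(cross, other, matrix)
    mut = rng.random((n_haplotypes, n_snps)) < mut_rate
    matrix = (matrix ^ mut).astype(np.uint8)
    del_state = np.zeros(n_haplotypes, dtype=np.uint8)
    idx_a = np.nonzero(assign == 0)[0]
    idx_b = np.nonzero(assign == 1)[0]
    if n_origins == 1:
        carriers = rng.choice(idx_a, size=int(round(0.8 * len(idx_a))), replace=False)
    else:
        carriers = np.concatenate([
            rng.choice(idx_a, size=int(round(0.5 * len(idx_a))), replace=False),
            rng.choice(idx_b, size=int(round(0.5 * len(idx_b))), replace=False),
        ])
    del_state[carriers] = 1
    panel = HaplotypePanel(pos, matrix, del_state, del_start, del_end)
    return panel, n_origins == 2


# ---------------------------------------------------------------------------
# Plain-text serialization
# ---------------------------------------------------------------------------

def write_fasta(path: str, seqs: dict[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_bed(path: str, intervals: Sequence[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            label = iv.label or "."
            strand = iv.strand or "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{label}\t0\t{strand}\n")


def read_bed(path: str) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            out.append(GenomicInterval(
                f[0], int(f[1]), int(f[2]),
                label=f[3] if len(f) > 3 and f[3] != "." else None,
                strand=f[5] if len(f) > 5 and f[5] in "+-" else None))
    return out
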
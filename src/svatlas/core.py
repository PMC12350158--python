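"""Core domain types, VCF I/O and callset-level operations.

Internal coordinates are 0-based half-open throughout; the VCF 1-based,
anchor-base convention is handled only at parse/write time.  An
:class:`SvRecord` stores the anchored alleles exactly as they appear in a
sequence-resolved VCF, with ``start`` being the 0-based position of the
anchor base.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import edlib
import pysam

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


def fetch(reference, chrom: str, start: int, end: int) -> str:
    """Fetch reference sequence [start, end) from a dict-of-str, a
    pyfaidx.Fasta or any object exposing ``fetch(chrom, start, end)``."""
    start = max(start, 0)
    if hasattr(reference, "fetch"):
        return str(reference.fetch(chrom, start, end)).upper()
    seq = reference[chrom]
    if hasattr(seq, "__getitem__") and not isinstance(seq, str):
        # pyfaidx FastaRecord
        return str(seq[start:end]).upper()
    return seq[start:end].upper()


def contig_length(reference, chrom: str) -> int:
    if hasattr(reference, "get_reference_length"):
        return reference.get_reference_length(chrom)
    return len(reference[chrom])


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """Half-open 0-based interval; used for repeat/SD/exon tracks and masks."""

    chrom: str
    start: int
    end: int
    strand: Optional[str] = None
    label: Optional[str] = None

    def __post_init__(self):
        if not (0 <= self.start <= self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


Genotype = Optional[tuple[int, int]]


@dataclass
class SvRecord:
    """One sequence-resolved SV with anchored REF/ALT alleles.

    ``start`` is the 0-based position of the VCF anchor base, so a VCF line
    with POS=101 yields ``start=100``.  ``end = start + len(ref_allele)``.
    """

    id: str
    chrom: str
    start: int
    ref_allele: str
    alt_allele: str
    genotypes: Optional[dict[str, tuple[Genotype, bool]]] = None
    allele_freq: Optional[float] = None
    unresolvable: bool = False
    info: dict = field(default_factory=dict)

    def __post_init__(self):
        self.ref_allele = self.ref_allele.upper()
        if not self.unresolvable:
            self.alt_allele = self.alt_allele.upper()
            for allele in (self.ref_allele, self.alt_allele):
                if not set(allele) <= VALID_BASES:
                    raise ValueError(f"{self.id}: non-ACGTN allele")

    # -- derived coordinates -------------------------------------------------
    @property
    def end(self) -> int:
        return self.start + len(self.ref_allele)

    @property
    def svtype(self) -> Optional[str]:
        if self.unresolvable:
            return None
        lr, la = len(self.ref_allele), len(self.alt_allele)
        if lr > 1 and la > 1:
            return "COMPLEX"
        return "DEL" if lr > la else "INS"

    @property
    def svlen(self) -> int:
        lr, la = len(self.ref_allele), len(self.alt_allele)
        if self.svtype == "COMPLEX":
            return max(lr, la) - 1
        return abs(la - lr)

    @property
    def is_sv(self) -> bool:
        return not self.unresolvable and self.svlen >= 50

    @property
    def inner_start(self) -> int:
        """First affected reference base (past the anchor)."""
        return self.start + 1

    @property
    def inner_end(self) -> int:
        return self.end

    @property
    def insert_seq(self) -> str:
        """Inserted sequence for INS records (alt minus the anchor base)."""
        if self.svtype != "INS":
            raise ValueError(f"{self.id} is not an insertion")
        return self.alt_allele[1:]

    @property
    def deleted_seq(self) -> str:
        if self.svtype != "DEL":
            raise ValueError(f"{self.id} is not a deletion")
        return self.ref_allele[1:]

    @property
    def sv_seq(self) -> str:
        """The allele sequence carrying the variant signal (insert for INS,
        deleted reference for DEL, alternative allele for COMPLEX)."""
        t = self.svtype
        if t == "INS":
            return self.alt_allele[1:]
        if t == "DEL":
            return self.ref_allele[1:]
        return self.alt_allele

    def carriers(self) -> Optional[frozenset]:
        if self.genotypes is None:
            return None
        return frozenset(
            s for s, (gt, _ph) in self.genotypes.items() if gt is not None and any(a == 1 for a in gt)
        )


@dataclass
class TrioGenotypes:
    site_id: str
    father: Genotype
    mother: Genotype
    child: Genotype


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def _split_gt(sample_values) -> tuple[Genotype, bool]:
    gt = sample_values.get("GT")
    phased = bool(getattr(sample_values, "phased", False))
    if gt is None or any(a is None for a in gt) or len(gt) == 0:
        return None, phased
    return tuple(int(a) for a in gt), phased


def parse_sv_vcf(path: str, reference=None) -> list[SvRecord]:
    """Parse a sequence-resolved SV VCF into internal records.

    Symbolic ALT alleles (angle-bracket tokens, breakends) are flagged
    unresolvable rather than typed.  Multiallelic lines are split into one
    record per alternative allele.  When ``reference`` is supplied, REF
    alleles are checked against it and contigs must exist.
    """
    records: list[SvRecord] = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            alts = rec.alts or ()
            multi = len(alts) > 1
            for i, alt in enumerate(alts):
                rid = rec.id or f"{rec.chrom}_{rec.pos}"
                if multi:
                    rid = f"{rid}_{i + 1}"
                start = rec.pos - 1
                symbolic = alt is None or alt.startswith("<") or any(c in alt for c in "[]")
                if reference is not None:
                    try:
                        refseq = fetch(reference, rec.chrom, start, start + len(rec.ref))
                    except KeyError:
                        raise KeyError(
                            f"contig {rec.chrom!r} (record {rid}) missing from reference"
                        ) from None
                    if refseq != rec.ref.upper():
                        raise ValueError(
                            f"REF allele mismatch at {rec.chrom}:{rec.pos} ({rid}): "
                            f"VCF {rec.ref!r} vs reference {refseq!r}"
                        )
                genotypes = None
                if rec.samples:
                    genotypes = {}
                    for sample, values in rec.samples.items():
                        gt, phased = _split_gt(values)
                        if gt is not None and multi:
                            # focal-allele view: other alternates count as ref
                            gt = tuple(1 if a == i + 1 else 0 for a in gt)
                        elif gt is not None:
                            gt = tuple(min(a, 1) for a in gt)
                        genotypes[sample] = (gt, phased)
                af = None
                if "AF" in rec.info:
                    val = rec.info["AF"]
                    af = float(val[i] if isinstance(val, tuple) else val)
                records.append(
                    SvRecord(
                        id=rid,
                        chrom=rec.chrom,
                        start=start,
                        ref_allele=rec.ref,
                        alt_allele=alt if not symbolic else (alt or "<?>"),
                        genotypes=genotypes,
                        allele_freq=af,
                        unresolvable=symbolic,
                    )
                )
    return records


def write_sv_vcf(path: str, records: Sequence[SvRecord], contig_lengths: Mapping[str, int],
                 samples: Optional[Sequence[str]] = None) -> None:
    """Write records back to VCF 4.2 (1-based, anchored alleles)."""
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for chrom, length in contig_lengths.items():
        header.contigs.add(chrom, length=length)
    if samples is None:
        seen: list[str] = []
        for r in records:
            for s in (r.genotypes or {}):
                if s not in seen:
                    seen.append(s)
        samples = seen
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(path, "w", header=header) as out:
        for r in sorted(records, key=lambda x: (x.chrom, x.start, x.id)):
            rec = out.new_record(
                contig=r.chrom, start=r.start, stop=r.end, id=r.id,
                alleles=(r.ref_allele, r.alt_allele),
            )
            if r.allele_freq is not None:
                rec.info["AF"] = r.allele_freq
            for s in samples:
                gt, phased = (r.genotypes or {}).get(s, (None, False))
                rec.samples[s]["GT"] = gt if gt is not None else (None, None)
                rec.samples[s].phased = phased
            out.write(rec)


# ---------------------------------------------------------------------------
# Allele divergence
# ---------------------------------------------------------------------------

def allele_divergence(a: str, b: str) -> float:
    """1 - identity of a global unit-cost alignment: edit distance divided by
    the longer allele length."""
    if not a and not b:
        return 0.0
    if not a or not b:
        return 1.0
    dist = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return dist / max(len(a), len(b))


# ---------------------------------------------------------------------------
# Duplicate marking (sansa markdup rules)
# ---------------------------------------------------------------------------

@dataclass
class DedupResult:
    retained: list[SvRecord]
    duplicate_of: dict[str, str]          # duplicate id -> representative id
    groups: list[list[str]]               # ids per duplicate group (size >= 2)
    carrier_relaxed_pairs: list[tuple[str, str]]


def duplicate_pair(a: SvRecord, b: SvRecord, max_offset: int = 500,
                   min_size_ratio: float = 0.5, max_divergence: float = 0.30,
                   min_carrier_frac: float = 0.10) -> tuple[bool, bool]:
    """Evaluate the four duplicate criteria for one pair.

    Returns (is_duplicate, carrier_criterion_relaxed).  The size ratio is
    strict (> min_size_ratio); offset, divergence and carrier bounds are
    inclusive.  Pairs lacking genotypes on either side skip the carrier
    criterion (treated as satisfied).
    """
    if a.svtype != b.svtype or a.chrom != b.chrom:
        return False, False
    if abs(a.start - b.start) > max_offset:
        return False, False
    sa, sb = max(a.svlen, 1), max(b.svlen, 1)
    if min(sa, sb) / max(sa, sb) <= min_size_ratio:
        return False, False
    if allele_divergence(a.sv_seq, b.sv_seq) > max_divergence:
        return False, False
    ca, cb = a.carriers(), b.carriers()
    if ca is None or cb is None:
        return True, True
    union = ca | cb
    frac = (len(ca & cb) / len(union)) if union else 1.0
    return frac >= min_carrier_frac, False


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def mark_duplicate_sites(records: Sequence[SvRecord], max_offset: int = 500,
                         min_size_ratio: float = 0.5, max_divergence: float = 0.30,
                         min_carrier_frac: float = 0.10) -> DedupResult:
    """Mark duplicate SV sites and retain one representative per group.

    Duplicate groups are the transitive closure of the pairwise rule; the
    representative is deterministic: smallest start, then longest svlen, then
    lexicographically smallest id.
    """
    recs = sorted((r for r in records if not r.unresolvable), key=lambda r: (r.chrom, r.start, r.id))
    uf = _UnionFind(len(recs))
    relaxed: list[tuple[str, str]] = []
    for i, a in enumerate(recs):
        for j in range(i + 1, len(recs)):
            b = recs[j]
            if b.chrom != a.chrom or b.start - a.start > max_offset:
                break
            dup, rel = duplicate_pair(a, b, max_offset, min_size_ratio,
                                      max_divergence, min_carrier_frac)
            if dup:
                uf.union(i, j)
                if rel:
                    relaxed.append((a.id, b.id))
    clusters: dict[int, list[SvRecord]] = {}
    for i, r in enumerate(recs):
        clusters.setdefault(uf.find(i), []).append(r)
    retained, dup_of, groups = [], {}, []
    for members in clusters.values():
        rep = min(members, key=lambda r: (r.start, -r.svlen, r.id))
        retained.append(rep)
        if len(members) > 1:
            groups.append([m.id for m in members])
            for m in members:
                if m.id != rep.id:
                    dup_of[m.id] = rep.id
                    log.info("dedup: %s marked duplicate of %s", m.id, rep.id)
    retained.sort(key=lambda r: (r.chrom, r.start, r.id))
    return DedupResult(retained, dup_of, groups, relaxed)


# ---------------------------------------------------------------------------
# Callset comparison (sansa compvcf rules)
# ---------------------------------------------------------------------------

def match_pair(a: SvRecord, b: SvRecord, max_offset: int = 50,
               min_size_ratio: float = 0.8, max_divergence: float = 0.10) -> bool:
    """Callset-comparison rule: size ratio >= min_size_ratio, breakpoint
    offset <= max_offset, allele divergence <= max_divergence."""
    if a.svtype != b.svtype or a.chrom != b.chrom:
        return False
    if abs(a.start - b.start) > max_offset:
        return False
    sa, sb = max(a.svlen, 1), max(b.svlen, 1)
    if min(sa, sb) / max(sa, sb) < min_size_ratio:
        return False
    return allele_divergence(a.sv_seq, b.sv_seq) <= max_divergence


def match_callsets(base: Sequence[SvRecord], comp: Sequence[SvRecord],
                   max_offset: int = 50, min_size_ratio: float = 0.8,
                   max_divergence: float = 0.10) -> dict[str, list[str]]:
    """For every base record, the (possibly empty, possibly multiple) list of
    matching comp record ids; one-to-many links are preserved."""
    comp_sorted = sorted((r for r in comp if not r.unresolvable), key=lambda r: (r.chrom, r.start))
    import bisect
    keys = [(r.chrom, r.start) for r in comp_sorted]
    out: dict[str, list[str]] = {}
    for a in base:
        if a.unresolvable:
            out[a.id] = []
            continue
        lo = bisect.bisect_left(keys, (a.chrom, a.start - max_offset))
        hi = bisect.bisect_right(keys, (a.chrom, a.start + max_offset))
        out[a.id] = [b.id for b in comp_sorted[lo:hi]
                     if match_pair(a, b, max_offset, min_size_ratio, max_divergence)]
    return out


# ---------------------------------------------------------------------------
# Trio Mendelian consistency
# ---------------------------------------------------------------------------

@dataclass
class MendelianSummary:
    consistent: int
    inconsistent: int
    untested: int

    @property
    def rate(self) -> Optional[float]:
        tested = self.consistent + self.inconsistent
        return self.inconsistent / tested if tested else None


def trio_consistent(father: Genotype, mother: Genotype, child: Genotype) -> Optional[bool]:
    """True iff some choice of one transmitted allele per parent explains the
    child's unordered genotype; None when any genotype is missing."""
    if father is None or mother is None or child is None:
        return None
    cset = tuple(sorted(child))
    for f in father:
        for m in mother:
            if tuple(sorted((f, m))) == cset:
                return True
    return False


def mendelian_rate(sites: Iterable[TrioGenotypes]) -> MendelianSummary:
    consistent = inconsistent = untested = 0
    for s in sites:
        verdict = trio_consistent(s.father, s.mother, s.child)
        if verdict is None:
            untested += 1
        elif verdict:
            consistent += 1
        else:
            inconsistent += 1
    return MendelianSummary(consistent, inconsistent, untested)
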
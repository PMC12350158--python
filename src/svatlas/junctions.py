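"""Breakpoint-junction homology and SV formation-mechanism classification.

Two complementary measurements per SV:

* ``microhomology_len`` — the maximal exact junction-spanning match (left +
  right extension across the junction), capped at 50 bp; for insertions
  longer than 100 bp only the first/last 50 bp of the insert are probed.
* ``homology_scan`` — windowed search for longer, imperfect homologous
  stretches flanking the two breakpoints (symmetric paddings 50 bp-100 kb
  plus SV-length-sized asymmetric windows slid in sixths), keeping
  co-directional alignments that span both breakpoints at the same relative
  position.

Mechanism bins: blunt (0 bp), NHEJ/alt-EJ/MMBIR (1-15 bp), homology-
independent (16-49 bp), HDR (>=50 bp) with NAHR as the more specific label
at >=200 bp.  VNTR, tandem-duplication and MEI alleles are excluded: their
flank homology is allele-structural.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .align import TargetIndex, chain_best, local_hits
from .core import GenomicInterval, SvRecord, contig_length, fetch

log = logging.getLogger(__name__)

SYMMETRIC_PADDINGS = (50, 100, 200, 400, 1000, 2000, 5000, 10000, 50000, 100000)

HOM_BINS = (
    (0, 0, "blunt"),
    (1, 15, "microhomology_1_15"),
    (16, 49, "microhomology_16_49"),
    (50, 199, "homology_ge50"),
    (200, None, "homology_ge200"),
)

MECHANISM_BY_CLASS = {
    "blunt": "NHEJ_altEJ_MMBIR",
    "microhomology_1_15": "NHEJ_altEJ_MMBIR",
    "microhomology_16_49": "homology_independent",
    "homology_ge50": "HDR",
    "homology_ge200": "NAHR",
}


def hom_class(hom_len: int) -> str:
    for lo, hi, name in HOM_BINS:
        if hom_len >= lo and (hi is None or hom_len <= hi):
            return name
    raise ValueError(hom_len)


@dataclass
class JunctionCall:
    sv_id: str
    hom_len: int = 0
    hom_class: str = "blunt"
    hom_intervals: Optional[tuple[GenomicInterval, GenomicInterval]] = None
    scan_len: Optional[int] = None
    mediating_repeat: Optional[str] = None
    mediating_elements: list[str] = field(default_factory=list)
    sd_mediated: bool = False
    mechanism: str = "unassigned"
    notes: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Allele implantation (insertions)
# ---------------------------------------------------------------------------

class CoordinateMap:
    """Monotone map between reference and implanted-allele coordinates for a
    single insertion of ``length`` bp at reference position ``pos``."""

    def __init__(self, pos: int, length: int):
        self.pos = pos
        self.length = length

    def to_modified(self, ref_pos: int) -> int:
        return ref_pos if ref_pos <= self.pos else ref_pos + self.length

    def to_ref(self, mod_pos: int) -> int:
        """Positions inside the implanted allele project onto the insertion
        breakpoint."""
        if mod_pos <= self.pos:
            return mod_pos
        if mod_pos >= self.pos + self.length:
            return mod_pos - self.length
        return self.pos

    def interval_to_ref(self, start: int, end: int) -> tuple[int, int]:
        return self.to_ref(start), max(self.to_ref(start), self.to_ref(end))


def implant_allele(genome, record: SvRecord, flank: int = 100000
                   ) -> tuple[str, int, int, int, CoordinateMap]:
    """Implant an insertion allele so both junctions exist on one sequence.

    Returns (sequence, seq_offset, bp1, bp2, map) where bp1/bp2 are the two
    junction coordinates on the returned sequence and ``seq_offset`` is the
    reference coordinate of its first base.
    """
    if record.unresolvable:
        raise ValueError(f"{record.id}: unresolvable record cannot be implanted")
    if record.svtype == "DEL":
        lo = max(0, record.inner_start - flank)
        hi = min(contig_length(genome, record.chrom), record.inner_end + flank)
        seq = fetch(genome, record.chrom, lo, hi)
        cmap = CoordinateMap(record.inner_start, 0)
        return seq, lo, record.inner_start, record.inner_end, cmap
    if record.svtype != "INS":
        raise ValueError(f"{record.id}: only DEL/INS records have two junctions")
    ins = record.insert_seq
    pos = record.inner_start
    lo = max(0, pos - flank)
    hi = min(contig_length(genome, record.chrom), pos + flank)
    ref = fetch(genome, record.chrom, lo, hi)
    cut = pos - lo
    seq = ref[:cut] + ins + ref[cut:]
    cmap = CoordinateMap(pos, len(ins))
    return seq, lo, pos, pos + len(ins), cmap


# ---------------------------------------------------------------------------
# Microhomology
# ---------------------------------------------------------------------------

def _match_right(a: str, b: str, cap: int) -> int:
    n = min(len(a), len(b), cap)
    i = 0
    while i < n and a[i] == b[i]:
        i += 1
    return i


def microhomology_len(record: SvRecord, genome, cap: int = 50,
                      insert_probe: int = 50, flank: int = 2000) -> int:
    """Maximal exact junction-spanning match, capped at ``cap``.

    Deletions: bases downstream of both breakpoints extended right, bases
    upstream of both extended left; the homology is the sum.  Insertions:
    the insert prefix against the downstream flank plus the insert suffix
    against the upstream flank, probing at most ``insert_probe`` bp of the
    insert per side for inserts over 100 bp (and never more than the insert
    length in total).
    """
    chrom = record.chrom
    if record.svtype == "DEL":
        bp1, bp2 = record.inner_start, record.inner_end
        down1 = fetch(genome, chrom, bp1, bp1 + flank)
        down2 = fetch(genome, chrom, bp2, bp2 + flank)
        up1 = fetch(genome, chrom, max(0, bp1 - flank), bp1)
        up2 = fetch(genome, chrom, max(0, bp2 - flank), bp2)
        right = _match_right(down1, down2, cap)
        left = _match_right(up1[::-1], up2[::-1], cap)
        return min(left + right, cap)
    if record.svtype == "INS":
        ins = record.insert_seq
        pos = record.inner_start
        probe = min(insert_probe, len(ins)) if len(ins) > 100 else len(ins)
        down = fetch(genome, chrom, pos, pos + flank)
        up = fetch(genome, chrom, max(0, pos - flank), pos)
        right = _match_right(ins[:probe], down, cap)
        left = _match_right(ins[-probe:][::-1], up[::-1], cap)
        return min(left + right, len(ins), cap)
    raise ValueError(f"{record.id}: microhomology defined for DEL/INS only")


# ---------------------------------------------------------------------------
# Windowed homology scan
# ---------------------------------------------------------------------------

def asymmetric_offsets(svlen: int, steps: int = 6) -> list[int]:
    """Upstream shifts of the SV-length-sized asymmetric windows: i/steps of
    the SV length for i = 0..steps."""
    return [round(i * svlen / steps) for i in range(steps + 1)]


def _window_pairs(bp1: int, bp2: int, svlen: int, seq_len: int,
                  paddings: Sequence[int] = SYMMETRIC_PADDINGS):
    """Non-overlapping (windowA, windowB) pairs around the two junctions."""
    pairs = []
    for pad in paddings:
        a = (max(0, bp1 - pad), min(seq_len, bp1 + pad))
        b = (max(0, bp2 - pad), min(seq_len, bp2 + pad))
        if a[1] <= b[0]:
            pairs.append((a, b))
    if svlen >= 20:
        for u in asymmetric_offsets(svlen):
            a = (max(0, bp1 - u), min(seq_len, bp1 + svlen - u))
            b = (max(0, bp2 - u), min(seq_len, bp2 + svlen - u))
            if a[1] <= b[0] and a[1] > a[0] and b[1] > b[0]:
                pairs.append((a, b))
    return pairs


def homology_scan(record: SvRecord, genome, min_identity: float = 0.8,
                  k: int = 9, rel_tol: float = 0.05,
                  paddings: Sequence[int] = SYMMETRIC_PADDINGS
                  ) -> Optional[tuple[int, GenomicInterval, GenomicInterval]]:
    """Longest co-directional homology whose alignment spans both junctions
    at the same relative position (+-``rel_tol`` of the homology length).

    Insertions are first implanted so both junctions lie on one sequence;
    reported intervals are translated back to reference coordinates.
    Returns (homology length, arm1 interval, arm2 interval) or None.
    """
    seq, offset, bp1, bp2, cmap = implant_allele(genome, record)
    b1, b2 = bp1 - offset, bp2 - offset
    svlen = record.svlen
    if b2 - b1 < 2 * paddings[0]:
        log.debug("%s: breakpoints closer than twice the smallest padding; "
                  "asymmetric windows only", record.id)
    best = None
    for (a_lo, a_hi), (b_lo, b_hi) in _window_pairs(b1, b2, svlen, len(seq), paddings):
        wa, wb = seq[a_lo:a_hi], seq[b_lo:b_hi]
        if len(wa) < k or len(wb) < k:
            continue
        index = TargetIndex({"B": wb}, k=k)
        hits = local_hits(wa, index, min_identity=min_identity,
                          min_uniqueness=0.0, both_strands=False)
        ra, rb = b1 - a_lo, b2 - b_lo
        for h in hits:
            L = h.query_span
            # terminal mismatches trim local alignments, so allow the
            # breakpoint to sit within a small slack of the alignment edge
            slack = max(5, int(rel_tol * L))
            if not (h.query_start - slack <= ra <= h.query_end + slack):
                continue
            if not (h.target_start - slack <= rb <= h.target_end + slack):
                continue
            fa = (min(max(ra, h.query_start), h.query_end) - h.query_start) / L
            fb = (min(max(rb, h.target_start), h.target_end) - h.target_start) \
                / max(h.target_end - h.target_start, 1)
            if abs(fa - fb) > rel_tol:
                continue
            if best is None or L > best[0]:
                # arm coordinates on the (possibly implanted) sequence,
                # translated to reference space via the coordinate map
                a1 = (offset + a_lo + h.query_start, offset + a_lo + h.query_end)
                a2 = (offset + b_lo + h.target_start, offset + b_lo + h.target_end)
                arm1 = (cmap.to_ref(a1[0]), cmap.to_ref(a1[1]))
                arm2 = (cmap.to_ref(a2[0]), cmap.to_ref(a2[1]))
                best = (L,
                        GenomicInterval(record.chrom, *sorted(arm1)),
                        GenomicInterval(record.chrom, *sorted(arm2)))
    return best


# ---------------------------------------------------------------------------
# Mechanism classification
# ---------------------------------------------------------------------------

def classify_mechanism(call: JunctionCall, is_vntr_dup_mei: bool = False) -> str:
    """Mechanism bin from the homology length; VNTR/tandem-duplication/MEI
    alleles are excluded (their flank homology is allele-structural)."""
    if is_vntr_dup_mei:
        call.mechanism = "unassigned"
        call.notes["exclusion"] = "VNTR/duplication/MEI allele structure"
        return call.mechanism
    length = call.scan_len if call.scan_len and call.scan_len >= 50 else call.hom_len
    call.mechanism = MECHANISM_BY_CLASS["blunt" if length == 0 else hom_class(length)]
    if length == 0:
        call.mechanism = "NHEJ_altEJ_MMBIR"
    return call.mechanism


def call_junction(record: SvRecord, genome, is_vntr_dup_mei: bool = False,
                  cap: int = 50) -> JunctionCall:
    """Full junction call: microhomology, windowed homology scan, class bin
    and mechanism label for one DEL/INS record."""
    call = JunctionCall(sv_id=record.id)
    call.hom_len = microhomology_len(record, genome, cap=cap)
    scan = homology_scan(record, genome)
    if scan is not None:
        call.scan_len = scan[0]
        call.hom_intervals = (scan[1], scan[2])
    effective = call.scan_len if (call.scan_len or 0) >= 50 else call.hom_len
    call.hom_class = hom_class(effective)
    classify_mechanism(call, is_vntr_dup_mei)
    return call


# ---------------------------------------------------------------------------
# Repeat / SD mediation
# ---------------------------------------------------------------------------

def _same_class_coverage(arm: GenomicInterval, track: Sequence[GenomicInterval]
                         ) -> dict[str, tuple[int, list[GenomicInterval]]]:
    """Per-repeat-class covered bases of the arm, with contributing elements."""
    out: dict[str, tuple[int, list[GenomicInterval]]] = {}
    for el in track:
        ov = arm.overlap(el)
        if ov > 0 and el.label:
            cov, els = out.get(el.label, (0, []))
            out[el.label] = (cov + ov, els + [el])
    return out


def annotate_repeat_or_sd_mediated(call: JunctionCall,
                                   repeat_track: Sequence[GenomicInterval] = (),
                                   sd_track: Sequence[GenomicInterval] = (),
                                   min_frac: float = 0.85) -> JunctionCall:
    """Set ``mediating_repeat`` when >=85% of both homology arms lie in
    same-class repeat annotations and at least one arm spans >=85% of its
    element; set ``sd_mediated`` when an SD covers >=85% of an arm and the
    intersection exceeds 200 bp or half the SD."""
    if call.hom_intervals is None:
        call.notes.setdefault("mediation", "no homology intervals")
        return call
    arm1, arm2 = call.hom_intervals
    if repeat_track:
        cov1 = _same_class_coverage(arm1, repeat_track)
        cov2 = _same_class_coverage(arm2, repeat_track)
        for cls in set(cov1) & set(cov2):
            c1, els1 = cov1[cls]
            c2, els2 = cov2[cls]
            if c1 < min_frac * len(arm1) or c2 < min_frac * len(arm2):
                continue
            spans_element = any(
                arm.overlap(el) >= min_frac * len(el)
                for arm, els in ((arm1, els1), (arm2, els2)) for el in els if len(el)
            )
            if spans_element:
                call.mediating_repeat = cls
                call.mediating_elements = sorted(
                    {e.label for e in els1 + els2 if e.label})
                break
    for arm in (arm1, arm2):
        for sd in sd_track:
            inter = arm.overlap(sd)
            if len(arm) and inter >= min_frac * len(arm) \
                    and (inter > 200 or (len(sd) and inter > 0.5 * len(sd))):
                call.sd_mediated = True
    return call
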
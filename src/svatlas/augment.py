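"""Pseudo-haplotype construction for pangenome graph augmentation.

Overlapping SV calls cannot be implanted into one consensus sequence, so
the callset is partitioned into groups of pairwise non-overlapping variants
(greedy first-fit, which is depth-optimal for intervals sorted by start),
each group is implanted right-to-left into the reference to produce a
pseudo-haplotype FASTA plus a monotone reference<->pseudo-haplotype
coordinate map.  Centromere masking and the novel-bubble distance filter
round out the accounting; graph insertion itself is delegated to an
external graph builder.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .core import GenomicInterval, SvRecord, fetch

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Masking
# ---------------------------------------------------------------------------

def mask_regions(genome: Mapping[str, str], mask: Sequence[GenomicInterval]
                 ) -> dict[str, str]:
    """Replace masked bases by N; sequence lengths are unchanged."""
    out = {c: s for c, s in genome.items()}
    for iv in mask:
        if iv.chrom not in out:
            raise KeyError(f"mask interval on unknown contig {iv.chrom}")
        seq = out[iv.chrom]
        if iv.end > len(seq):
            raise ValueError(
                f"mask interval {iv.chrom}:{iv.start}-{iv.end} exceeds contig "
                f"length {len(seq)}")
        out[iv.chrom] = seq[: iv.start] + "N" * len(iv) + seq[iv.end:]
    return out


def drop_masked_records(records: Sequence[SvRecord], mask: Sequence[GenomicInterval]
                        ) -> list[SvRecord]:
    """Remove SVs intersecting any masked interval (any overlap counts)."""
    kept = []
    for r in records:
        iv = _record_interval(r)
        if any(iv.overlap(m) > 0 for m in mask):
            log.info("%s dropped: intersects masked region", r.id)
        else:
            kept.append(r)
    return kept


# ---------------------------------------------------------------------------
# Partitioning
# ---------------------------------------------------------------------------

def _record_interval(r: SvRecord) -> GenomicInterval:
    """Reference footprint used for overlap: DEL/COMPLEX occupy their
    anchored span, INS a width-1 point so same-position insertions cannot
    stack in one group."""
    if r.svtype == "INS":
        return GenomicInterval(r.chrom, r.start, r.start + 1)
    return GenomicInterval(r.chrom, r.start, r.end)


def partition_nonoverlapping(records: Sequence[SvRecord]) -> list[list[SvRecord]]:
    """Greedy first-fit partition into internally non-overlapping groups;
    the group count equals the maximum overlap depth of the footprints."""
    recs = sorted(records, key=lambda r: (r.chrom, r.start, r.id))
    groups: list[list[SvRecord]] = []
    last_end: list[dict[str, int]] = []
    for r in recs:
        iv = _record_interval(r)
        placed = False
        for gi, ends in enumerate(last_end):
            if ends.get(r.chrom, 0) <= iv.start:
                groups[gi].append(r)
                ends[r.chrom] = iv.end
                placed = True
                break
        if not placed:
            groups.append([r])
            last_end.append({r.chrom: iv.end})
    return groups


def max_overlap_depth(records: Sequence[SvRecord]) -> int:
    """Sweep-line maximum overlap depth of the record footprints."""
    events: list[tuple[str, int, int]] = []
    for r in records:
        iv = _record_interval(r)
        events.append((iv.chrom, iv.start, 1))
        events.append((iv.chrom, iv.end, -1))
    depth = best = 0
    cur_chrom = None
    for chrom, pos, delta in sorted(events):
        if chrom != cur_chrom:
            depth, cur_chrom = 0, chrom
        depth += delta
        best = max(best, depth)
    return best


# ---------------------------------------------------------------------------
# Implantation
# ---------------------------------------------------------------------------

@dataclass
class PseudoHaplotype:
    group_id: int
    member_sv_ids: list[str]
    sequences: dict[str, str]
    # per contig: sorted (ref_breakpoint, cumulative offset after it)
    offsets: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    # per member: contig and half-open interval of its alt allele in
    # pseudo-haplotype coordinates
    allele_spans: dict[str, tuple[str, int, int]] = field(default_factory=dict)

    def to_pseudo(self, chrom: str, ref_pos: int) -> int:
        off = 0
        for bp, cum in self.offsets.get(chrom, []):
            if ref_pos >= bp:
                off = cum
            else:
                break
        return ref_pos + off


def implant_pseudohaplotype(genome: Mapping[str, str], group: Sequence[SvRecord],
                            group_id: int = 0) -> PseudoHaplotype:
    """Apply a non-overlapping group of alleles to the reference,
    right-to-left per contig so earlier coordinates stay valid.  REF
    alleles are checked at each implant site to guard stale coordinates."""
    seqs = {c: s for c, s in genome.items()}
    by_chrom: dict[str, list[SvRecord]] = {}
    for r in group:
        by_chrom.setdefault(r.chrom, []).append(r)
    ph = PseudoHaplotype(group_id, [r.id for r in group], seqs)
    for chrom, recs in by_chrom.items():
        recs.sort(key=lambda r: r.start)
        seq = seqs[chrom]
        for r in reversed(recs):
            have = seq[r.start:r.end]
            if have != r.ref_allele:
                raise ValueError(
                    f"{r.id}: REF mismatch at {chrom}:{r.start} "
                    f"(expected {r.ref_allele[:20]!r}..., found {have[:20]!r}...)")
            seq = seq[: r.start] + r.alt_allele + seq[r.end:]
        seqs[chrom] = seq
        # forward pass for cumulative offsets and allele spans
        cum = 0
        offs: list[tuple[int, int]] = []
        for r in recs:
            delta = len(r.alt_allele) - len(r.ref_allele)
            ph.allele_spans[r.id] = (chrom, r.start + cum, r.start + cum + len(r.alt_allele))
            cum += delta
            offs.append((r.end, cum))
        ph.offsets[chrom] = offs
    return ph


def extract_allele(ph: PseudoHaplotype, sv_id: str) -> str:
    chrom, s, e = ph.allele_spans[sv_id]
    return ph.sequences[chrom][s:e]


def build_pseudohaplotypes(genome: Mapping[str, str], records: Sequence[SvRecord],
                           mask: Sequence[GenomicInterval] = ()
                           ) -> tuple[list[PseudoHaplotype], dict[str, str]]:
    """Mask, drop masked calls, partition and implant; returns the
    pseudo-haplotypes and the masked reference."""
    masked = mask_regions(genome, mask)
    usable = drop_masked_records([r for r in records if not r.unresolvable], mask)
    groups = partition_nonoverlapping(usable)
    return [implant_pseudohaplotype(masked, g, gi) for gi, g in enumerate(groups)], masked


# ---------------------------------------------------------------------------
# Merging svtig-derived records
# ---------------------------------------------------------------------------

def merge_contig_records(records: Sequence[SvRecord], genome) -> SvRecord:
    """Connect multiple SVs called from one assembled contig into a single
    record by adding the intervening reference sequence to both alleles."""
    if not records:
        raise ValueError("nothing to merge")
    if len({r.chrom for r in records}) != 1:
        raise ValueError("members on different chromosomes cannot be merged")
    recs = sorted(records, key=lambda r: r.start)
    if len(recs) == 1:
        return recs[0]
    chrom = recs[0].chrom
    ref_parts, alt_parts = [], []
    for i, r in enumerate(recs):
        if i > 0:
            spacer = fetch(genome, chrom, recs[i - 1].end, r.start)
            ref_parts.append(spacer)
            alt_parts.append(spacer)
        ref_parts.append(r.ref_allele)
        alt_parts.append(r.alt_allele)
    return SvRecord(
        id="+".join(r.id for r in recs),
        chrom=chrom,
        start=recs[0].start,
        ref_allele="".join(ref_parts),
        alt_allele="".join(alt_parts),
        genotypes=recs[0].genotypes,
    )


# ---------------------------------------------------------------------------
# Novel bubbles
# ---------------------------------------------------------------------------

def novel_bubble_filter(bubbles_aug: Sequence[GenomicInterval],
                        bubbles_orig: Sequence[GenomicInterval],
                        min_dist: int = 1000) -> list[GenomicInterval]:
    """Bubbles of the augmented graph whose gap distance to the nearest
    original bubble on the same contig is >= ``min_dist`` (overlap counts
    as distance 0).  An empty original set makes every bubble novel."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for b in bubbles_orig:
        by_chrom.setdefault(b.chrom, []).append(b)
    novel = []
    for b in bubbles_aug:
        ivs = by_chrom.get(b.chrom)
        if not ivs:
            novel.append(b)
            continue
        if min(_gap(b, o) for o in ivs) >= min_dist:
            novel.append(b)
    return novel


def _gap(a: GenomicInterval, b: GenomicInterval) -> int:
    if a.overlap(b) > 0:
        return 0
    return max(b.start - a.end, a.start - b.end, 0)
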
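"""Transduction source-element atlas: cluster traced transductions into
source loci, assign progenitor elements, and test each locus for a 5'
versus 3' bias (exact two-tailed binomial tests with Benjamini-Hochberg
FDR control across tested loci)."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd
from scipy.stats import binomtest
from statsmodels.stats.multitest import multipletests

from .align import global_identity
from .core import GenomicInterval
from .mei import Transduction


@dataclass
class FullLengthElement:
    """A full-length L1 (>5.9 kb) or SVA (>1 kb), from the reference
    annotation or from non-reference insertion calls."""

    region: GenomicInterval
    family: str                       # 'L1' | 'SVA'
    subfamily: Optional[str] = None
    orientation: Optional[str] = None
    in_reference: bool = True

L1_FULL_LENGTH_MIN = 5900
SVA_FULL_LENGTH_MIN = 1000


def is_full_length(family: str, length: int) -> bool:
    if family == "L1":
        return length > L1_FULL_LENGTH_MIN
    if family == "SVA":
        return length > SVA_FULL_LENGTH_MIN
    return False


@dataclass
class SourceLocus:
    region: GenomicInterval
    members: list[Transduction] = field(default_factory=list)
    element: Optional[FullLengthElement] = None
    n_5p: int = 0
    n_3p: int = 0
    n_orphan: int = 0
    p_value: Optional[float] = None
    p_adjusted: Optional[float] = None
    bias: str = "untested"

    @property
    def n_tested(self) -> int:
        return self.n_5p + self.n_3p


def cluster_sources(transductions: Sequence[Transduction], buffer: int = 10000
                    ) -> list[SourceLocus]:
    """Pad traced source intervals by ``buffer`` bp on both ends and merge
    transitively; each transduction lands in exactly one locus.  Output is
    order-invariant (sorted by padded position)."""
    traced = [t for t in transductions if t.source is not None]
    traced.sort(key=lambda t: (t.source.chrom, t.source.start, t.source.end, t.side))
    loci: list[SourceLocus] = []
    cur: Optional[list] = None  # [chrom, start, end, members]
    for t in traced:
        s, e = t.source.start - buffer, t.source.end + buffer
        if cur is not None and t.source.chrom == cur[0] and s <= cur[2]:
            cur[2] = max(cur[2], e)
            cur[3].append(t)
        else:
            if cur is not None:
                loci.append(_make_locus(cur))
            cur = [t.source.chrom, s, e, [t]]
    if cur is not None:
        loci.append(_make_locus(cur))
    return loci


def _make_locus(cur) -> SourceLocus:
    chrom, s, e, members = cur
    locus = SourceLocus(GenomicInterval(chrom, max(0, s), e), members=members)
    for t in members:
        if t.side == "5p":
            locus.n_5p += 1
        elif t.side == "3p":
            locus.n_3p += 1
        else:
            locus.n_orphan += 1
    return locus


def assign_progenitor(locus: SourceLocus, full_length_db: Sequence[FullLengthElement],
                      sva_consensus_db: Optional[dict] = None,
                      sva_sequences: Optional[dict] = None) -> Optional[FullLengthElement]:
    """Intersect the locus with the full-length element database; ambiguity
    is resolved by distance to the centroid of the member alignment
    positions.  SVA subfamily, when sequence and a subfamily consensus set
    are supplied, is the best-global-identity consensus."""
    candidates = [e for e in full_length_db
                  if e.region.chrom == locus.region.chrom
                  and e.region.overlap(locus.region) > 0]
    if not candidates:
        return None
    centroid = sum((t.source.start + t.source.end) / 2 for t in locus.members) \
        / max(len(locus.members), 1)
    def dist(e: FullLengthElement) -> float:
        return abs((e.region.start + e.region.end) / 2 - centroid)
    candidates.sort(key=lambda e: (dist(e), e.region.start))
    chosen = candidates[0]
    if len(candidates) > 1 and dist(candidates[1]) == dist(chosen):
        pass  # deterministic tie toward smaller start; worth logging upstream
    if chosen.family == "SVA" and sva_consensus_db and sva_sequences:
        key = (chosen.region.chrom, chosen.region.start)
        seq = sva_sequences.get(key)
        if seq:
            chosen.subfamily = max(sva_consensus_db,
                                   key=lambda n: global_identity(seq, sva_consensus_db[n]))
    locus.element = chosen
    return chosen


def bias_test(loci: Sequence[SourceLocus], null_p: float = 0.5, min_n: int = 5,
              alpha: float = 0.05) -> list[SourceLocus]:
    """Exact two-tailed binomial test of n_5p vs n_3p per locus with at
    least ``min_n`` non-orphan transductions, BH-adjusted across the tested
    family; bias called toward the majority side at p_adjusted < alpha."""
    tested = [l for l in loci if l.n_tested >= min_n]
    for locus in loci:
        if locus not in tested:
            locus.bias = "untested"
            locus.p_value = locus.p_adjusted = None
    if not tested:
        return list(loci)
    pvals = [binomtest(l.n_5p, l.n_tested, null_p, alternative="two-sided").pvalue
             for l in tested]
    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    for locus, p, pa in zip(tested, pvals, p_adj):
        locus.p_value = float(p)
        locus.p_adjusted = float(pa)
        if pa < alpha:
            locus.bias = "5p" if locus.n_5p > locus.n_3p else "3p"
        else:
            locus.bias = "none"
    return list(loci)


def atlas_table(loci: Sequence[SourceLocus]) -> pd.DataFrame:
    """Source-locus table (region, element, counts, adjusted p, bias)."""
    rows = []
    for l in loci:
        rows.append({
            "chrom": l.region.chrom,
            "start": l.region.start,
            "end": l.region.end,
            "element_family": l.element.family if l.element else None,
            "subfamily": l.element.subfamily if l.element else None,
            "orientation": l.element.orientation if l.element else None,
            "in_reference": l.element.in_reference if l.element else None,
            "n_5p": l.n_5p,
            "n_3p": l.n_3p,
            "n_orphan": l.n_orphan,
            "p_value": l.p_value,
            "p_adjusted": l.p_adjusted,
            "bias": l.bias,
        })
    return pd.DataFrame(rows)
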
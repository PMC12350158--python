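"""Tandem-repeat decomposition of SV alleles and VNTR/duplication classes.

The tandem-repeat detector proposes periods by self-match autocorrelation
(seq[i] vs seq[i+p]) and scores candidate arrays against the tiled majority
-consensus motif, so the module is testable in isolation against a
brute-force oracle rather than tied to an external detector binary.
Motifs are canonicalized to their lexicographically smallest rotation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .align import AlignmentHit, TargetIndex, chain_best, local_hits
from .core import GenomicInterval, fetch, revcomp


@dataclass(frozen=True)
class TandemRepeatHit:
    motif: str                # canonical rotation
    period: int
    copies: float
    span: tuple[int, int]     # half-open query interval
    identity: float

    @property
    def span_len(self) -> int:
        return self.span[1] - self.span[0]


def canonical_rotation(motif: str) -> str:
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def _consensus_motif(seq: str, start: int, end: int, period: int) -> str:
    """Majority base per residue class over the array span."""
    arr = np.frombuffer(seq[start:end].encode("ascii"), dtype=np.uint8)
    motif = []
    for r in range(period):
        col = arr[r::period]
        vals, cnt = np.unique(col, return_counts=True)
        motif.append(chr(vals[np.argmax(cnt)]))
    return "".join(motif)


def _segments_with_tolerance(match: np.ndarray, min_run: int, max_gap: int,
                             min_identity: float) -> list[tuple[int, int]]:
    """Merge True-runs of the self-match array separated by short gaps, then
    keep merged segments whose overall match fraction clears the bar."""
    idx = np.nonzero(match)[0]
    if not len(idx):
        return []
    segments = []
    s = e = idx[0]
    for i in idx[1:]:
        if i - e - 1 <= max_gap:
            e = i
        else:
            segments.append((s, e + 1))
            s = e = i
    segments.append((s, e + 1))
    out = []
    for s, e in segments:
        if e - s >= min_run and match[s:e].mean() >= min_identity:
            out.append((s, e))
    return out


def detect_tandem_repeats(seq: str, min_period: int = 1, max_period: int = 2000,
                          min_identity: float = 0.8, min_copies: float = 2.0,
                          min_span: int = 10) -> list[TandemRepeatHit]:
    """Maximal tandem arrays in ``seq``.

    On perfect arrays, motif, period and copy number are exact; approximate
    arrays are scored by identity to the tiled consensus motif, with array
    boundaries trimmed to the outermost consensus-matching base.  Arrays
    that are fully explained by a smaller period at comparable identity are
    suppressed (a pure 4-mer array is not additionally reported at period
    8), and arrays shorter than ``min_span`` are ignored as noise.
    """
    n = len(seq)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    hits: list[TandemRepeatHit] = []
    hi = min(max_period, n // 2)
    for p in range(max(1, min_period), hi + 1):
        match = arr[p:] == arr[:-p]
        min_run = max(1, int(np.ceil((min_copies - 1) * p)))
        min_len = max(min_span, int(min_copies * p))
        for s, e in _segments_with_tolerance(match, min_run, max(2, p // 4), min_identity):
            # adjacent arrays sharing the period but not the motif merge into
            # one self-match segment; peel off the best consensus subsegment
            # and recurse on what remains
            stack = [(s, e + p)]
            while stack:
                lo, hi_ = stack.pop()
                if hi_ - lo < min_len:
                    continue
                span = _trim_to_consensus(seq, arr, lo, hi_, p)
                if span[1] - span[0] < min_len:
                    continue
                motif_raw = _consensus_motif(seq, span[0], span[1], p)
                tiled = (motif_raw * (1 + (span[1] - span[0]) // p))[: span[1] - span[0]]
                ident = float(np.mean(np.frombuffer(tiled.encode(), dtype=np.uint8)
                                      == arr[span[0]:span[1]]))
                if ident >= min_identity:
                    hits.append(TandemRepeatHit(
                        motif=canonical_rotation(motif_raw), period=p,
                        copies=(span[1] - span[0]) / p, span=span, identity=ident))
                if span[0] - lo >= min_len:
                    stack.append((lo, span[0]))
                if hi_ - span[1] >= min_len:
                    stack.append((span[1], hi_))
    return _suppress_multiples(hits)


def _trim_to_consensus(seq: str, arr: np.ndarray, s: int, e: int, p: int
                       ) -> tuple[int, int]:
    """Refine array boundaries to the maximum-scoring subsegment against the
    tiled consensus (match +1, mismatch -2), so chance matches in flanking
    sequence do not inflate the span; flanking drift is net-negative while
    the true array scores positively."""
    s0 = s
    motif = _consensus_motif(seq, s, e, p)
    tiled = (motif * ((e - s) // p + 2))[: e - s]
    score = np.where(np.frombuffer(tiled.encode(), dtype=np.uint8) == arr[s:e], 1, -2)
    best = cur = 0
    best_span = (0, 0)
    cur_start = 0
    for i, v in enumerate(score):
        if cur <= 0:
            cur, cur_start = 0, i
        cur += v
        if cur > best:
            best = cur
            best_span = (cur_start, i + 1)
    return s0 + best_span[0], s0 + best_span[1]


def _suppress_multiples(hits: list[TandemRepeatHit]) -> list[TandemRepeatHit]:
    """Drop hits whose span is jointly explained (>= 90%) by kept hits of
    divisor periods at comparable identity: a pure 4-mer array is not also a
    period-8 array, and two adjacent 5-mer arrays are not one 60-mer array."""
    hits = sorted(hits, key=lambda h: (h.period, h.span))
    kept: list[TandemRepeatHit] = []
    for h in hits:
        cover: list[tuple[int, int]] = []
        for k in kept:
            if h.period % k.period == 0 and k.identity >= h.identity - 0.05:
                lo = max(h.span[0], k.span[0])
                hi = min(h.span[1], k.span[1])
                if hi > lo:
                    cover.append((int(lo), int(hi)))
        covered, last = 0, h.span[0]
        for lo, hi in sorted(cover):
            covered += max(0, hi - max(lo, last))
            last = max(last, hi)
        if covered < 0.9 * h.span_len:
            kept.append(h)
    return kept


# ---------------------------------------------------------------------------
# VNTR classification
# ---------------------------------------------------------------------------

def _chain_tandem_hits(seq_len: int, hits: Sequence[TandemRepeatHit]):
    """Chain tandem arrays by query-interval scheduling (reusing the exact
    alignment chainer with span length as score)."""
    pseudo = [AlignmentHit(h.span[0], h.span[1], f"motif:{h.motif}", 0, h.span_len,
                           "+", h.identity, h.span_len * h.identity) for h in hits]
    return chain_best(pseudo, seq_len)


def classify_vntr(seq: str, hits: Optional[Sequence[TandemRepeatHit]] = None,
                  min_coverage: float = 0.75, min_identity: float = 0.8
                  ) -> Optional[tuple[str, list[str]]]:
    """VNTR_simple (>=75% of the allele is one repeated motif) vs
    VNTR_complex (>=75% from more than one motif); None below coverage."""
    if hits is None:
        hits = detect_tandem_repeats(seq, min_identity=min_identity)
    if not hits:
        return None
    chain = _chain_tandem_hits(len(seq), hits)
    if chain.coverage < min_coverage:
        return None
    motifs = sorted({h.target_name.removeprefix("motif:") for h in chain.hits})
    label = "VNTR_simple" if len(motifs) == 1 else "VNTR_complex"
    return label, motifs


# ---------------------------------------------------------------------------
# Duplication classification
# ---------------------------------------------------------------------------

def classify_duplication(insert: str, chrom: str, breakpoint: int, genome,
                         window: int = 2000, min_coverage: float = 0.75,
                         min_identity: float = 0.8, k: int = 13
                         ) -> Optional[str]:
    """tandem / inverted / complex duplication per the orientation >=75%
    rules, with hits restricted to a +-``window`` bp region around the
    insertion breakpoint (truncated at contig edges)."""
    lo = max(0, breakpoint - window)
    hi = breakpoint + window
    ctx = fetch(genome, chrom, lo, hi)
    if len(insert) < k or len(ctx) < k:
        return None
    index = TargetIndex({"ctx": ctx}, k=k)
    hits = local_hits(insert, index, min_identity=min_identity, min_uniqueness=0.0)
    chain = chain_best(hits, len(insert))
    if chain.coverage < min_coverage:
        return None
    fwd = _strand_coverage(chain, len(insert), "+")
    rev = _strand_coverage(chain, len(insert), "-")
    if fwd >= min_coverage:
        return "tandem"
    if rev >= min_coverage:
        return "inverted"
    if fwd > 0 and rev > 0:
        return "complex"
    return None


def _strand_coverage(chain, qlen: int, strand: str) -> float:
    covered, last = 0, 0
    for h in sorted((h for h in chain.hits if h.strand == strand),
                    key=lambda h: h.query_start):
        covered += max(0, h.query_end - max(h.query_start, last))
        last = max(last, h.query_end)
    return covered / qlen if qlen else 0.0


def classify_tandem_allele(seq: str, chrom: str, breakpoint: int, genome,
                           min_coverage: float = 0.75) -> Optional[tuple[str, object]]:
    """Combined VNTR-vs-duplication routing: VNTR wins when >=2 motif copies
    lie within the allele; single-copy-unit gains are duplications."""
    vntr = classify_vntr(seq, min_coverage=min_coverage)
    if vntr is not None:
        return vntr[0], vntr[1]
    dup = classify_duplication(seq, chrom, breakpoint, genome, min_coverage=min_coverage)
    if dup is not None:
        return f"dup_{dup}", None
    return None
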
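"""Local similarity search and optimal chaining.

A self-contained seed-and-extend engine over k-mer indexed target
collections, plus an exact weighted-interval-scheduling chainer that picks
the minimum set of non-overlapping hits spanning the maximum fraction of a
query.  Hit "uniqueness" is the score gap to the best alternative placement
of (roughly) the same query interval, a contract-level surrogate for
aligner mapping quality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import edlib
import numpy as np

from .core import revcomp

_BASE_CODE = np.full(256, -1, dtype=np.int64)
for i, b in enumerate("ACGT"):
    _BASE_CODE[ord(b)] = i
    _BASE_CODE[ord(b.lower())] = i


def _encode(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Rolling k-mer codes and a validity mask (no N inside the window)."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    out = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for i in range(k):
        col = codes[i:i + n]
        out = out * 4 + np.where(col < 0, 0, col)
        valid &= col >= 0
    return out, valid


@dataclass(frozen=True)
class AlignmentHit:
    """One local alignment of a query interval onto a named target."""

    query_start: int
    query_end: int
    target_name: str
    target_start: int
    target_end: int
    strand: str                      # '+' or '-'
    identity: float
    score: float
    uniqueness: float = float("inf")

    def __post_init__(self):
        if self.query_end <= self.query_start:
            raise ValueError("empty hit on query")

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start


@dataclass
class AlignmentChain:
    """Ordered non-overlapping hits over one query."""

    hits: list[AlignmentHit]
    query_len: int

    @property
    def covered_bases(self) -> int:
        covered, last = 0, 0
        for h in sorted(self.hits, key=lambda h: h.query_start):
            covered += max(0, h.query_end - max(h.query_start, last))
            last = max(last, h.query_end)
        return covered

    @property
    def coverage(self) -> float:
        return self.covered_bases / self.query_len if self.query_len else 0.0


class TargetIndex:
    """Exact k-mer seed index over a named collection of target sequences."""

    def __init__(self, targets: Mapping[str, str], k: int = 13):
        self.k = k
        self.names: list[str] = list(targets)
        self.seqs: dict[str, str] = {n: targets[n].upper() for n in self.names}
        sep = "N" * k
        concat = sep.join(self.seqs[n] for n in self.names)
        self.offsets = np.zeros(len(self.names), dtype=np.int64)
        pos = 0
        for i, n in enumerate(self.names):
            self.offsets[i] = pos
            pos += len(self.seqs[n]) + k
        codes, valid = _kmer_codes(_encode(concat), k)
        idx = np.nonzero(valid)[0]
        kc = codes[idx]
        order = np.argsort(kc, kind="stable")
        self._sorted_codes = kc[order]
        self._sorted_pos = idx[order]

    def target_of(self, concat_pos: int) -> tuple[int, int]:
        """Map concatenated position to (target index, local position)."""
        ti = int(np.searchsorted(self.offsets, concat_pos, side="right")) - 1
        return ti, concat_pos - int(self.offsets[ti])

    def seed_matches(self, query: str) -> np.ndarray:
        """(qpos, concat_tpos) pairs of exact k-mer matches."""
        codes, valid = _kmer_codes(_encode(query), self.k)
        if not len(codes):
            return np.empty((0, 2), dtype=np.int64)
        qpos_all = np.nonzero(valid)[0]
        qc = codes[qpos_all]
        lo = np.searchsorted(self._sorted_codes, qc, side="left")
        hi = np.searchsorted(self._sorted_codes, qc, side="right")
        counts = hi - lo
        total = int(counts.sum())
        if total == 0:
            return np.empty((0, 2), dtype=np.int64)
        qrep = np.repeat(qpos_all, counts)
        gather = np.concatenate([np.arange(l, h) for l, h in zip(lo, hi) if h > l])
        return np.column_stack([qrep, self._sorted_pos[gather]])


def _extend_diagonal(q: np.ndarray, t: np.ndarray, qs: int, qe: int, diag: int,
                     xdrop: int = 12) -> tuple[int, int]:
    """Greedy ungapped X-drop extension of [qs, qe) along diagonal
    tpos = qpos + diag (match +1, mismatch -2)."""
    # rightwards
    best, score, i, best_i = 0, 0, qe, qe
    while i < len(q) and 0 <= i + diag < len(t):
        score += 1 if (q[i] >= 0 and q[i] == t[i + diag]) else -2
        i += 1
        if score > best:
            best, best_i = score, i
        elif best - score > xdrop:
            break
    qe = best_i
    # leftwards
    best, score, i, best_i = 0, 0, qs - 1, qs
    while i >= 0 and 0 <= i + diag < len(t):
        score += 1 if (q[i] >= 0 and q[i] == t[i + diag]) else -2
        if score > best:
            best, best_i = score, i
        elif best - score > xdrop:
            break
        i -= 1
    return best_i, qe


def _cluster_seeds(matches: np.ndarray, max_gap: int = 120) -> list[tuple[int, int, int]]:
    """Group (qpos, tpos) seeds sharing one exact diagonal into runs split at
    query gaps > ``max_gap``; returns (qlo, qhi, diag) per cluster.  The
    extension stage is ungapped, so each true hit lives on one diagonal;
    stray seeds on neighbouring diagonals form their own (failing) clusters
    instead of corrupting the extension diagonal."""
    if not len(matches):
        return []
    diag = matches[:, 1] - matches[:, 0]
    order = np.lexsort((matches[:, 0], diag))
    clusters = []
    cd = cq_lo = cq_hi = None
    for idx in order:
        d, qp = int(diag[idx]), int(matches[idx, 0])
        if cd is None or d != cd or qp - cq_hi > max_gap:
            if cd is not None:
                clusters.append((cq_lo, cq_hi, cd))
            cd, cq_lo, cq_hi = d, qp, qp
        else:
            cq_hi = max(cq_hi, qp)
    clusters.append((cq_lo, cq_hi, cd))
    return clusters


def _identity_segment(q: np.ndarray, t: np.ndarray, qs: int, qe: int, diag: int) -> float:
    seg_q = q[qs:qe]
    seg_t = t[qs + diag:qe + diag]
    return float(np.mean((seg_q == seg_t) & (seg_q >= 0)))


def local_hits(query: str, index: TargetIndex, min_identity: float = 0.8,
               min_uniqueness: float = 10.0, min_length: Optional[int] = None,
               both_strands: bool = True) -> list[AlignmentHit]:
    """All seed-and-extend local alignments of ``query`` against the indexed
    targets meeting the identity and uniqueness thresholds, on both strands.

    Queries shorter than the seed word give an empty result.
    """
    k = index.k
    if len(query) < k:
        return []
    min_length = min_length if min_length is not None else k
    raw: list[AlignmentHit] = []
    strands = ["+", "-"] if both_strands else ["+"]
    for strand in strands:
        qseq = query if strand == "+" else revcomp(query)
        q = _encode(qseq)
        matches = index.seed_matches(qseq)
        # split matches per target to keep diagonals meaningful
        if not len(matches):
            continue
        ti = np.searchsorted(index.offsets, matches[:, 1], side="right") - 1
        for t_idx in np.unique(ti):
            name = index.names[int(t_idx)]
            t = _encode(index.seqs[name])
            local = matches[ti == t_idx].copy()
            local[:, 1] -= int(index.offsets[int(t_idx)])
            seen: set[tuple[int, int, int]] = set()
            for qlo, qhi, diag in _cluster_seeds(local):
                qs, qe = _extend_diagonal(q, t, qlo, qhi + k, diag)
                key = (qs, qe, diag)
                if key in seen or qe - qs < min_length:
                    continue
                seen.add(key)
                ident = _identity_segment(q, t, qs, qe, diag)
                if ident < min_identity:
                    # trim to best-identity core via shrink from both ends
                    qs, qe, ident = _shrink_to_identity(q, t, qs, qe, diag, min_identity)
                    if qe - qs < min_length or ident < min_identity:
                        continue
                matches_n = int(round(ident * (qe - qs)))
                score = matches_n - 2 * ((qe - qs) - matches_n)
                if strand == "+":
                    h = AlignmentHit(qs, qe, name, qs + diag, qe + diag, "+", ident, score)
                else:
                    n = len(query)
                    h = AlignmentHit(n - qe, n - qs, name, qs + diag, qe + diag, "-", ident, score)
                raw.append(h)
    return _apply_uniqueness(_dedup_hits(raw), min_uniqueness)


def _shrink_to_identity(q, t, qs, qe, diag, min_identity):
    """Trim mismatching ends until the segment identity clears the bar."""
    while qe - qs > 0:
        if q[qs] != t[qs + diag]:
            qs += 1
            continue
        if q[qe - 1] != t[qe - 1 + diag]:
            qe -= 1
            continue
        ident = _identity_segment(q, t, qs, qe, diag)
        if ident >= min_identity:
            return qs, qe, ident
        # drop the end adjacent to the worse half
        left = _identity_segment(q, t, qs, (qs + qe) // 2, diag)
        right = _identity_segment(q, t, (qs + qe) // 2, qe, diag)
        if left < right:
            qs += 1
        else:
            qe -= 1
    return qs, qe, 0.0


def _dedup_hits(hits: list[AlignmentHit]) -> list[AlignmentHit]:
    """Collapse hits that duplicate the same (target, strand, near-identical
    placement); keep the higher scoring one."""
    best: dict[tuple, AlignmentHit] = {}
    for h in hits:
        key = (h.target_name, h.strand, h.query_start // 8, h.target_start // 8)
        cur = best.get(key)
        if cur is None or h.score > cur.score:
            best[key] = h
    return sorted(best.values(), key=lambda h: (h.query_start, h.query_end, h.target_name, h.strand))


def _apply_uniqueness(hits: list[AlignmentHit], min_uniqueness: float) -> list[AlignmentHit]:
    """Uniqueness = score gap to the best other hit overlapping >= 50% of the
    same query interval (the hit's own score when unambiguous)."""
    out = []
    for h in hits:
        alt = 0.0
        found = False
        for g in hits:
            if g is h:
                continue
            ov = min(h.query_end, g.query_end) - max(h.query_start, g.query_start)
            if ov >= 0.5 * h.query_span:
                found = True
                alt = max(alt, g.score)
        uniq = h.score - alt if found else h.score
        if uniq >= min_uniqueness:
            out.append(AlignmentHit(h.query_start, h.query_end, h.target_name,
                                    h.target_start, h.target_end, h.strand,
                                    h.identity, h.score, uniq))
    return out


# ---------------------------------------------------------------------------
# Chaining
# ---------------------------------------------------------------------------

MAX_TRIM_OVERLAP = 10


def chain_best(hits: Sequence[AlignmentHit], query_len: int,
               max_trim_overlap: int = MAX_TRIM_OVERLAP) -> AlignmentChain:
    """Exact best chain: maximize covered query bases, then fewest hits, then
    highest summed score.  Hits overlapping by <= ``max_trim_overlap`` bp on
    the query may coexist (counted once); larger overlaps are exclusive.
    """
    hits = sorted(hits, key=lambda h: (h.query_end, h.query_start))
    n = len(hits)
    if n == 0:
        return AlignmentChain([], query_len)
    # dp over hits ordered by query_end; value = (covered, -nhits, score)
    best_val = [None] * n
    best_prev = [-1] * n
    for i, h in enumerate(hits):
        val = (h.query_span, -1, h.score)
        prev = -1
        for j in range(i):
            g = hits[j]
            ov = g.query_end - h.query_start
            if ov > max_trim_overlap:
                continue
            add = h.query_end - max(h.query_start, g.query_end)
            if add <= 0:
                continue
            cand = (best_val[j][0] + add, best_val[j][1] - 1, best_val[j][2] + h.score)
            if cand > val:
                val, prev = cand, j
        best_val[i] = val
        best_prev[i] = prev
    end = max(range(n), key=lambda i: best_val[i])
    chain = []
    while end != -1:
        chain.append(hits[end])
        end = best_prev[end]
    chain.reverse()
    return AlignmentChain(_trim_chain_overlaps(chain), query_len)


def _trim_chain_overlaps(chain: list[AlignmentHit]) -> list[AlignmentHit]:
    """Resolve residual small query overlaps at the midpoint so reported
    chain hits are pairwise non-overlapping."""
    out: list[AlignmentHit] = []
    for h in chain:
        if out and out[-1].query_end > h.query_start:
            prev = out[-1]
            mid = (h.query_start + prev.query_end) // 2
            cut_prev = prev.query_end - mid
            cut_h = mid - h.query_start
            if prev.query_end - cut_prev > prev.query_start:
                out[-1] = _trim_hit(prev, right=cut_prev)
            if cut_h:
                h = _trim_hit(h, left=cut_h)
        out.append(h)
    return out


def _trim_hit(h: AlignmentHit, left: int = 0, right: int = 0) -> AlignmentHit:
    qs, qe = h.query_start + left, h.query_end - right
    if h.strand == "+":
        ts, te = h.target_start + left, h.target_end - right
    else:
        ts, te = h.target_start + right, h.target_end - left
    return AlignmentHit(qs, qe, h.target_name, ts, te, h.strand, h.identity,
                        h.score * (qe - qs) / h.query_span, h.uniqueness)


def global_identity(a: str, b: str) -> float:
    """Identity of a unit-cost global alignment (1 - dist / longer length)."""
    if not a or not b:
        return 0.0
    dist = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - dist / max(len(a), len(b))
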
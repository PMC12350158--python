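"""Mobile-element-insertion annotation.

Implements the retrotransposition classification cascade: poly(A/T) tail and
target-site-duplication (TSD) detection, orientation normalization,
3' transduction detection with genomic source tracing, insert decomposition
against a consensus-element database plus the reference genome, and the
final >=75%-coverage class rules (processed pseudogene, partnered 5'/3'
transduction, orphan transduction, solo element, ERV, NUMT, non-canonical
MEI).  L1 subfamily diagnostics read consensus positions 5929-5931 (pre-Ta
'ACG' vs Ta 'ACA') and 5535/5538 (Ta-0: G,C; Ta-1: T,G).

The consensus database is configuration, not code: callers supply a mapping
of element-component names to sequences.  Component names are mapped to
element families via :data:`ELEMENT_FAMILY` prefixes (``SVA_*`` components
all count as the SVA family, mirroring the separate Alu-like/VNTR/SINE-R/
MAST2-exon components of SVA).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .align import AlignmentChain, AlignmentHit, TargetIndex, chain_best, local_hits
from .core import GenomicInterval, SvRecord, fetch, revcomp

log = logging.getLogger(__name__)

#: component-name prefix -> element family
ELEMENT_FAMILY = {
    "Alu": "Alu",
    "L1": "L1",
    "SVA": "SVA",
}

MEI_FAMILIES = ("Alu", "L1", "SVA")

# 1-based positions on the L1 consensus used for subfamily diagnostics
L1_TRIPLET_POS = (5929, 5930, 5931)
L1_TA_POS = (5535, 5538)


def element_family(target_name: str) -> Optional[str]:
    for prefix, fam in ELEMENT_FAMILY.items():
        if target_name == prefix or target_name.startswith(prefix + "_"):
            return fam
    return None


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PolyTail:
    kind: str                 # 'polyA' | 'polyT'
    length: int
    purity: float
    offset_from_end: int


@dataclass(frozen=True)
class Tsd:
    sequence: str
    length: int
    end: str                  # '5p' | '3p'


@dataclass
class Transduction:
    side: str                 # '5p' | '3p' | 'orphan'
    sequence: str
    source: Optional[GenomicInterval]
    aligned_fraction: float


@dataclass
class InsertAnnotation:
    sv_id: str
    svclass: str              # solo_Alu ... unclassified
    canonical: bool
    tails: list[PolyTail]
    tsd: Optional[Tsd]
    transduction: Optional[Transduction]
    components: AlignmentChain
    subfamily: Optional[str] = None
    full_length: bool = False
    noncanonical_flags: frozenset = frozenset()
    twin_priming: bool = False
    orientation: str = "+"
    exon_count: int = 0
    notes: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Resources / parameters
# ---------------------------------------------------------------------------

@dataclass
class MeiResources:
    """Indexed inputs shared across annotations."""

    consensus: Mapping[str, str]
    consensus_index: TargetIndex
    genome_index: Optional[TargetIndex] = None
    retro_index: Optional[TargetIndex] = None
    mito: Optional[str] = None
    mito_index: Optional[TargetIndex] = None
    exons: Sequence[GenomicInterval] = ()

    @classmethod
    def build(cls, consensus: Mapping[str, str], genome: Optional[Mapping[str, str]] = None,
              retro: Optional[Mapping[str, str]] = None, mito: Optional[str] = None,
              exons: Sequence[GenomicInterval] = (), consensus_k: int = 11,
              genome_k: int = 13) -> "MeiResources":
        mei_db = {n: s for n, s in consensus.items() if element_family(n)}
        res = cls(
            consensus=dict(consensus),
            consensus_index=TargetIndex(mei_db, k=consensus_k),
            exons=list(exons),
        )
        if genome is not None:
            res.genome_index = TargetIndex(genome, k=genome_k)
        if retro:
            res.retro_index = TargetIndex(retro, k=consensus_k)
        if mito:
            res.mito = mito
            # doubled sequence so alignments may wrap the circular origin
            res.mito_index = TargetIndex({"MT": mito + mito}, k=consensus_k)
        return res

    def exon_overlap(self, iv: GenomicInterval) -> int:
        return sum(iv.overlap(e) for e in self.exons)


@dataclass
class MeiParams:
    min_tail_len: int = 10
    min_tail_purity: float = 0.90
    max_tail_offset: int = 50
    max_tsd_len: int = 50
    max_td_len: int = 1000
    min_td_len: int = 10
    min_td_aligned_frac: float = 0.8
    min_identity: float = 0.8
    min_uniqueness: float = 10.0
    min_class_coverage: float = 0.75
    min_component_len: int = 25  # shorter hits are seed noise, not components
    end_tolerance: int = 30   # bp slack when judging full-length / 3' truncation


DEFAULT_PARAMS = MeiParams()


# ---------------------------------------------------------------------------
# Poly(A/T) tails
# ---------------------------------------------------------------------------

def _base_prefix_counts(seq: str, base: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8) == ord(base)
    return np.concatenate([[0], np.cumsum(arr)])


def _best_window(seq: str, base: str, min_offset: int, max_offset: int,
                 min_len: int, min_purity: float) -> Optional[tuple[int, int, float]]:
    """Longest window [i, j) with purity >= min_purity whose offset from the
    3' end (len - j) lies in [min_offset, max_offset]; ties -> smaller
    offset.  Returns (start, end, purity).

    Windows are normalized to maximal tracts: they must begin and end with
    the tract base (leading/trailing foreign bases never belong to a tail).
    Purity(i, j) >= p  <=>  g(i) <= g(j) with g(x) = counts[x] - p*x, so the
    longest window ending at j starts at the earliest i with g(i) <= g(j),
    found by binary search over the (non-increasing) prefix minimum of g,
    then advanced to the first tract base (which can only raise purity).
    """
    n = len(seq)
    if n < min_len:
        return None
    counts = _base_prefix_counts(seq, base)
    is_base = np.frombuffer(seq.encode("ascii"), dtype=np.uint8) == ord(base)
    p = min_purity - 1e-9  # inclusive threshold despite float rounding
    g = counts - p * np.arange(n + 1)
    prefix_min = np.minimum.accumulate(g)
    if not is_base.any():
        return None
    # next index >= x carrying the tract base
    vals = np.where(is_base, np.arange(n), n)
    nxt = np.append(np.minimum.accumulate(vals[::-1])[::-1], n)
    j_lo = max(min_len, n - max_offset)
    j_hi = n - min_offset
    if j_hi < j_lo:
        return None
    js = np.arange(j_lo, j_hi + 1)
    ends_with_base = is_base[js - 1]
    js = js[ends_with_base]
    if not len(js):
        return None
    i_star = np.searchsorted(-prefix_min, -g[js], side="left")
    i_star = nxt[np.minimum(i_star, n)]
    lengths = js - i_star
    valid = lengths >= min_len
    if not valid.any():
        return None
    lengths, js, i_star = lengths[valid], js[valid], i_star[valid]
    k = np.lexsort((js, lengths))[-1]  # longest, tie -> larger j = smaller offset
    i, j = int(i_star[k]), int(js[k])
    return i, j, (counts[j] - counts[i]) / (j - i)


def scan_poly_tail(seq: str, end: str, min_len: int = 10, min_purity: float = 0.90,
                   max_offset: int = 50) -> Optional[PolyTail]:
    """Longest qualifying poly(A) tract near the 3' end (``end='3p'``) or
    poly(T) tract near the 5' end (``end='5p'``); ties broken toward the
    smaller offset from the respective end."""
    if end == "3p":
        win = _best_window(seq, "A", 0, max_offset, min_len, min_purity)
        if win is None:
            return None
        i, j, purity = win
        return PolyTail("polyA", j - i, purity, len(seq) - j)
    if end == "5p":
        win = _best_window(seq[::-1], "T", 0, max_offset, min_len, min_purity)
        if win is None:
            return None
        i, j, purity = win
        return PolyTail("polyT", j - i, purity, len(seq) - j)
    raise ValueError(f"end must be '5p' or '3p', got {end!r}")


# ---------------------------------------------------------------------------
# TSD
# ---------------------------------------------------------------------------

def _common_prefix(a: str, b: str, cap: int) -> int:
    n = min(len(a), len(b), cap)
    i = 0
    while i < n and a[i] == b[i]:
        i += 1
    return i


def find_tsd(alt_seq: str, ref_up: str, ref_down: str, max_len: int = 50) -> Optional[Tsd]:
    """Longest exact terminal duplication of adjacent reference sequence.

    The insert prefix is compared against the downstream flank (a 5'-end
    TSD) and the insert suffix against the upstream flank (3'-end TSD);
    ties resolve toward the longer match, then toward the 3' end.
    """
    l5 = _common_prefix(alt_seq, ref_down, max_len)
    l3 = _common_prefix(alt_seq[::-1], ref_up[::-1], max_len)
    if max(l5, l3) == 0:
        return None
    if l3 >= l5:
        return Tsd(alt_seq[len(alt_seq) - l3:], l3, "3p")
    return Tsd(alt_seq[:l5], l5, "5p")


# ---------------------------------------------------------------------------
# Orientation
# ---------------------------------------------------------------------------

def orient_and_trim(trimmed: str, params: MeiParams = DEFAULT_PARAMS) -> tuple[str, str, list[PolyTail]]:
    """Resolve orientation from the terminal tails and strip the outer tail.

    Returns (body, orientation, tails-as-found-on-the-input).  Inserts with
    a dominant leading poly(T) are reverse-complemented so every candidate
    is processed in forward orientation.
    """
    t3 = scan_poly_tail(trimmed, "3p", params.min_tail_len, params.min_tail_purity,
                        params.max_tail_offset)
    t5 = scan_poly_tail(trimmed, "5p", params.min_tail_len, params.min_tail_purity,
                        params.max_tail_offset)
    tails = [t for t in (t5, t3) if t is not None]
    orientation = "+"
    if t5 is not None and (t3 is None or t5.length > t3.length):
        orientation = "-"
    elif t5 is not None and t3 is not None and t5.length == t3.length:
        log.info("equal 5' polyT / 3' polyA evidence; keeping forward orientation")
    body = revcomp(trimmed) if orientation == "-" else trimmed
    tail = scan_poly_tail(body, "3p", params.min_tail_len, params.min_tail_purity,
                          params.max_tail_offset)
    if tail is not None:
        body = body[: len(body) - tail.offset_from_end - tail.length] \
            + body[len(body) - tail.offset_from_end:]
    return body, orientation, tails


# ---------------------------------------------------------------------------
# Transductions
# ---------------------------------------------------------------------------

def _trace_segment(seq: str, genome_index: TargetIndex, params: MeiParams
                   ) -> tuple[float, Optional[GenomicInterval]]:
    hits = local_hits(seq, genome_index, min_identity=params.min_identity,
                      min_uniqueness=params.min_uniqueness)
    if not hits:
        return 0.0, None
    covered, last = 0, 0
    for h in sorted(hits, key=lambda h: h.query_start):
        covered += max(0, h.query_end - max(h.query_start, last))
        last = max(last, h.query_end)
    best = max(hits, key=lambda h: h.score)
    iv = GenomicInterval(best.target_name, best.target_start, best.target_end,
                         strand=best.strand)
    return covered / len(seq), iv


def detect_transductions(body: str, genome_index: Optional[TargetIndex],
                         params: MeiParams = DEFAULT_PARAMS
                         ) -> tuple[str, Optional[Transduction], Optional[PolyTail]]:
    """Search for a second (inner) poly(A) near the 3' end of the
    tail-trimmed body; the segment past it is the 3'-transduction candidate,
    traced against the genome and accepted at >= 80% aligned fraction.

    Returns (core, transduction-or-None, inner-tail-or-None).
    """
    win = _best_window(body, "A", params.min_td_len, params.max_td_len,
                       params.min_tail_len, params.min_tail_purity)
    if win is None:
        return body, None, None
    i, j, purity = win
    td_seq = body[j:]
    inner = PolyTail("polyA", j - i, purity, len(td_seq))
    core = body[:i]
    if genome_index is None or len(td_seq) < genome_index.k:
        log.info("transduced segment of %d bp untraceable", len(td_seq))
        return core, Transduction("3p", td_seq, None, 0.0), inner
    frac, source = _trace_segment(td_seq, genome_index, params)
    if frac >= params.min_td_aligned_frac and source is not None:
        return core, Transduction("3p", td_seq, source, frac), inner
    log.info("transduction candidate aligned over %.0f%% < %.0f%%; demoted to solo",
             100 * frac, 100 * params.min_td_aligned_frac)
    return body, None, None


# ---------------------------------------------------------------------------
# Decomposition
# ---------------------------------------------------------------------------

def gather_insert_hits(core: str, res: MeiResources, params: MeiParams = DEFAULT_PARAMS
                       ) -> list[AlignmentHit]:
    """Local hits of the trimmed core against the consensus-element database
    and (when available) the reference genome."""
    hits = list(local_hits(core, res.consensus_index, min_identity=params.min_identity,
                           min_uniqueness=params.min_uniqueness))
    if res.genome_index is not None:
        hits += local_hits(core, res.genome_index, min_identity=params.min_identity,
                           min_uniqueness=params.min_uniqueness)
    return hits


def decompose_insert(core: str, res: MeiResources, params: MeiParams = DEFAULT_PARAMS
                     ) -> AlignmentChain:
    """Best chain over consensus-element and reference-genome hits."""
    return chain_best(gather_insert_hits(core, res, params), len(core))


def _chain_coverage(chain: AlignmentChain, keep) -> float:
    if chain.query_len == 0:
        return 0.0
    sel = [h for h in chain.hits if keep(h)]
    covered, last = 0, 0
    for h in sorted(sel, key=lambda h: h.query_start):
        covered += max(0, h.query_end - max(h.query_start, last))
        last = max(last, h.query_end)
    return covered / chain.query_len


def _exonic_coverage(chain: AlignmentChain, res: MeiResources) -> tuple[float, int]:
    if chain.query_len == 0 or not res.exons:
        return 0.0, 0
    covered = 0
    exons_hit = set()
    for h in chain.hits:
        if element_family(h.target_name):
            continue
        iv = GenomicInterval(h.target_name, h.target_start, h.target_end)
        ov = 0
        for e in res.exons:
            o = iv.overlap(e)
            if o > 0:
                exons_hit.add((e.chrom, e.start, e.end))
                ov += o
        covered += min(ov, h.query_span)
    return covered / chain.query_len, len(exons_hit)


# ---------------------------------------------------------------------------
# ERV / NUMT
# ---------------------------------------------------------------------------

def classify_erv(core: str, res: MeiResources, params: MeiParams = DEFAULT_PARAMS
                 ) -> Optional[tuple[str, dict]]:
    """Solo-LTR vs ERVK by >=75% coverage on the retroviral database."""
    if res.retro_index is None or len(core) < res.retro_index.k:
        return None
    hits = local_hits(core, res.retro_index, min_identity=params.min_identity,
                      min_uniqueness=params.min_uniqueness)
    chain = chain_best(hits, len(core))
    if chain.coverage < params.min_class_coverage:
        return None
    ltr = [h for h in chain.hits if h.target_name.startswith("LTR")]
    internal = [h for h in chain.hits if not h.target_name.startswith("LTR")]
    notes = {"ltr_count": len(ltr), "internal": bool(internal)}
    return ("ERVK" if internal else "solo_LTR"), notes


def classify_numt(core: str, res: MeiResources, params: MeiParams = DEFAULT_PARAMS
                  ) -> Optional[list[tuple[int, int]]]:
    """NUMT iff the union of mitochondrial hits covers >= 75% of the core;
    the mitochondrial genome is treated as circular, so fragments may wrap
    the origin (reported as two wrapped pieces)."""
    if res.mito_index is None or len(core) < res.mito_index.k:
        return None
    # the doubled circular target duplicates every placement, so the
    # uniqueness (mapping-quality surrogate) filter must be disabled here
    hits = local_hits(core, res.mito_index, min_identity=params.min_identity,
                      min_uniqueness=0.0)
    chain = chain_best(hits, len(core))
    if chain.coverage < params.min_class_coverage:
        return None
    L = len(res.mito)
    fragments: list[tuple[int, int]] = []
    for h in chain.hits:
        s, e = h.target_start % L, h.target_end
        if e - h.target_start > L:
            s, e = 0, L
        elif e > L and s + (h.target_end - h.target_start) > L:
            fragments.append((s, L))
            fragments.append((0, (s + h.target_end - h.target_start) - L))
            continue
        else:
            e = s + (h.target_end - h.target_start)
        fragments.append((s, e))
    return fragments


# ---------------------------------------------------------------------------
# L1 subfamily diagnostics
# ---------------------------------------------------------------------------

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _consensus_base(chain: AlignmentChain, core: str, element: str, pos_1based: int
                    ) -> Optional[str]:
    """Base of the core sequence at a 1-based consensus position, via the
    (ungapped, diagonal) element hits of the chain."""
    p = pos_1based - 1
    for h in chain.hits:
        if h.target_name != element:
            continue
        if h.target_start <= p < h.target_end:
            if h.strand == "+":
                q = h.query_start + (p - h.target_start)
                return core[q]
            q = h.query_start + (h.target_end - 1 - p)
            return _COMP[core[q]]
    return None


def l1_subfamily(chain: AlignmentChain, core: str, element: str = "L1") -> Optional[str]:
    """pre-Ta / Ta-0 / Ta-1 / Ta / undetermined from diagnostic consensus
    positions; None when no L1 component is present."""
    if not any(h.target_name == element for h in chain.hits):
        return None
    triplet = "".join(_consensus_base(chain, core, element, p) or "?" for p in L1_TRIPLET_POS)
    if "?" in triplet:
        return "undetermined"
    if triplet == "ACG":
        return "pre-Ta"
    if triplet == "ACA":
        b1 = _consensus_base(chain, core, element, L1_TA_POS[0])
        b2 = _consensus_base(chain, core, element, L1_TA_POS[1])
        if b1 == "G" and b2 == "C":
            return "Ta-0"
        if b1 == "T" and b2 == "G":
            return "Ta-1"
        return "Ta"
    return "undetermined"


# ---------------------------------------------------------------------------
# Final classification
# ---------------------------------------------------------------------------

def _element_hits(chain: AlignmentChain) -> list[AlignmentHit]:
    return [h for h in chain.hits if element_family(h.target_name)]


def _genome_hits(chain: AlignmentChain) -> list[AlignmentHit]:
    return [h for h in chain.hits if not element_family(h.target_name)]


def _structure_flags(chain: AlignmentChain, res: MeiResources, has_tail: bool,
                     params: MeiParams) -> tuple[set, bool]:
    """(non-canonical flags, twin_priming) from the element components."""
    flags: set[str] = set()
    if not has_tail:
        flags.add("no_polyA")
    elems = sorted(_element_hits(chain), key=lambda h: h.query_start)
    twin = False
    if not elems:
        return flags, twin
    last = elems[-1]
    elem_len = len(res.consensus.get(last.target_name, ""))
    if elem_len and last.target_end < elem_len - params.end_tolerance:
        flags.add("truncated_3p")
    strands = [h.strand for h in elems]
    fams = {element_family(h.target_name) for h in elems}
    if len(elems) >= 2 and strands[0] == "-" and all(s == "+" for s in strands[1:]) \
            and len(fams) == 1:
        twin = True
    elif any(s == "-" for s in strands):
        flags.add("internal_rearrangement")
    else:
        # plus-strand components must be colinear on the element
        per_target: dict[str, list[AlignmentHit]] = {}
        for h in elems:
            per_target.setdefault(h.target_name, []).append(h)
        for hits in per_target.values():
            starts = [h.target_start for h in hits]
            if starts != sorted(starts):
                flags.add("internal_rearrangement")
    return flags, twin


def classify_insert(hits: Sequence[AlignmentHit], tails: Sequence[PolyTail],
                    transduction: Optional[Transduction], tsd: Optional[Tsd],
                    res: MeiResources, core: str, orientation: str = "+",
                    sv_id: str = "", params: MeiParams = DEFAULT_PARAMS) -> InsertAnnotation:
    """Apply the >=75%-coverage class rules in fixed precedence.

    Element-family coverage is computed on a consensus-only chain and
    reference coverage on a genome-only chain, so an element whose
    progenitor also sits in the reference cannot shadow its consensus
    decomposition.
    """
    min_cov = params.min_class_coverage
    has_tail = bool(tails)
    qlen = len(core)
    hits = [h for h in hits if h.query_span >= min(params.min_component_len, max(qlen // 2, 1))]
    elem_chain = chain_best([h for h in hits if element_family(h.target_name)], qlen)
    gen_chain = chain_best([h for h in hits if not element_family(h.target_name)], qlen)
    chain = elem_chain if elem_chain.coverage >= gen_chain.coverage \
        else chain_best(list(hits), qlen)
    cov_exon, exon_count = _exonic_coverage(gen_chain, res)
    cov_genome = gen_chain.coverage
    cov_mei = elem_chain.coverage
    fam_cov = {f: _chain_coverage(elem_chain,
                                  lambda h, f=f: element_family(h.target_name) == f)
               for f in MEI_FAMILIES}
    best_fam = max(fam_cov, key=fam_cov.get) if fam_cov else None
    elems = _element_hits(elem_chain)
    genome_h = _genome_hits(gen_chain)
    satisfied: list[str] = []

    flags, twin = _structure_flags(elem_chain, res, has_tail, params)
    canonical = (has_tail and tsd is not None
                 and "truncated_3p" not in flags and "internal_rearrangement" not in flags)
    full_length = False
    if elems:
        first = min(elems, key=lambda h: h.query_start)
        last = max(elems, key=lambda h: h.query_end)
        elen = len(res.consensus.get(last.target_name, ""))
        start_ok = first.target_start <= params.end_tolerance if first.strand == "+" else True
        full_length = bool(elen) and start_ok and last.target_end >= elen - params.end_tolerance

    def annotation(svclass: str, transd=transduction, canonical_=None, subfam=None) -> InsertAnnotation:
        return InsertAnnotation(
            sv_id=sv_id, svclass=svclass,
            canonical=canonical if canonical_ is None else canonical_,
            tails=list(tails), tsd=tsd, transduction=transd, components=chain,
            subfamily=subfam, full_length=full_length,
            noncanonical_flags=frozenset(flags), twin_priming=twin,
            orientation=orientation, exon_count=exon_count,
            notes={"satisfied_rules": satisfied, "coverage": {
                "exon": round(cov_exon, 4), "genome": round(cov_genome, 4),
                "mei": round(cov_mei, 4), **{f: round(c, 4) for f, c in fam_cov.items()}}},
        )

    # 1. processed pseudogene: >=75% on the reference over annotated exons
    if cov_exon >= min_cov:
        satisfied.append("pseudogene")
    # 2. partnered 5' transduction: a genomic component strictly 5' of the
    #    element component(s), jointly covering >=75%
    td5 = None
    if elems and genome_h:
        first_elem_q = min(h.query_start for h in elems)
        lead = [h for h in genome_h if h.query_end <= first_elem_q + 10]
        if lead and first_elem_q >= 20:
            cov_joint = chain_best(list(elems) + lead, qlen).coverage
            if cov_joint >= min_cov and fam_cov[best_fam] > 0:
                satisfied.append("td_5p")
                src = max(lead, key=lambda h: h.score)
                td5 = Transduction("5p", core[: first_elem_q],
                                   GenomicInterval(src.target_name, src.target_start,
                                                   src.target_end, strand=src.strand),
                                   sum(h.query_span for h in lead) / max(first_elem_q, 1))
    # 3. orphan transduction: >=75% genomic, outside exons, not element-like
    orphan = (has_tail and cov_genome >= min_cov and cov_exon < min_cov
              and cov_mei < 0.25)
    if orphan:
        satisfied.append("orphan_td")
    # 4. solo: >=75% within a single element family
    solo = best_fam is not None and fam_cov[best_fam] >= min_cov
    if solo:
        satisfied.append(f"solo_{best_fam}")
    if len(satisfied) > 1:
        log.info("%s: multiple classification rules satisfied: %s", sv_id, satisfied)

    if cov_exon >= min_cov:
        return annotation("processed_pseudogene", canonical_=canonical)
    if td5 is not None and not (solo and transduction is not None):
        return annotation("partnered_td_5p", transd=td5)
    if orphan:
        src_frac, src = (1.0, None)
        if genome_h:
            best = max(genome_h, key=lambda h: h.score)
            src = GenomicInterval(best.target_name, best.target_start, best.target_end,
                                  strand=best.strand)
        return annotation("orphan_td", transd=Transduction("orphan", core, src, cov_genome))
    if solo and has_tail:
        subfam = l1_subfamily(elem_chain, core) if best_fam == "L1" else None
        if transduction is not None and transduction.side == "3p":
            return annotation("partnered_td_3p", subfam=subfam)
        return annotation(f"solo_{best_fam}", subfam=subfam)
    erv = classify_erv(core, res, params)
    if erv is not None:
        cls, notes = erv
        ann = annotation(cls, canonical_=False)
        ann.notes.update(notes)
        return ann
    numt = classify_numt(core, res, params)
    if numt is not None:
        ann = annotation("NUMT", canonical_=False)
        ann.notes["mito_fragments"] = numt
        return ann
    if cov_mei >= min_cov:
        return annotation("non_canonical_MEI", canonical_=False)
    return annotation("unclassified", canonical_=False)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def annotate_insert(sv_id: str, insert_seq: str, ref_up: str, ref_down: str,
                    res: MeiResources, params: MeiParams = DEFAULT_PARAMS) -> InsertAnnotation:
    """Full retrotransposition annotation of one inserted sequence.

    Steps: TSD detection/trimming, tail scan, orientation normalization,
    outer-tail trimming, inner-poly(A)/transduction split with genomic
    source tracing, decomposition, class assignment.
    """
    tsd = find_tsd(insert_seq, ref_up, ref_down, params.max_tsd_len)
    trimmed = insert_seq
    if tsd is not None:
        trimmed = insert_seq[tsd.length:] if tsd.end == "5p" else insert_seq[: len(insert_seq) - tsd.length]
    body, orientation, tails = orient_and_trim(trimmed, params)
    core, transduction, inner_tail = detect_transductions(body, res.genome_index, params)
    all_tails = list(tails)
    if inner_tail is not None and transduction is not None:
        all_tails.append(inner_tail)
    hits = gather_insert_hits(core, res, params)
    ann = classify_insert(hits, all_tails, transduction, tsd, res, core,
                          orientation=orientation, sv_id=sv_id, params=params)
    return ann


def annotate_record(record: SvRecord, reference, res: MeiResources,
                    params: MeiParams = DEFAULT_PARAMS, flank: int = 100) -> Optional[InsertAnnotation]:
    """Annotate an INS record (or the deleted sequence of a DEL, labelling
    reference MEIs through the same engine).  Returns None for records with
    no usable allele sequence."""
    if record.unresolvable or not record.is_sv:
        return None
    if record.svtype == "INS":
        seq = record.insert_seq
        up = fetch(reference, record.chrom, record.inner_start - flank, record.inner_start)
        down = fetch(reference, record.chrom, record.inner_start, record.inner_start + flank)
    elif record.svtype == "DEL":
        seq = record.deleted_seq
        up = fetch(reference, record.chrom, record.inner_start - flank, record.inner_start)
        down = fetch(reference, record.chrom, record.inner_end, record.inner_end + flank)
    else:
        return None
    return annotate_insert(record.id, seq, up, down, res, params)
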
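# Methods

This note documents the models and procedures implemented in `svatlas`,
the parameters that matter, the numerical choices made where the design
was genuinely open, and what the synthetic fixtures do and do not show
about real data.

## Coordinates and records

Internal coordinates are 0-based, half-open, everywhere; the VCF 1-based
anchor-base convention is handled only at parse/write time. An `SvRecord`
keeps the anchored alleles verbatim: `start` is the 0-based anchor
position, `end = start + len(REF)`, and the affected interval is
`[start+1, end)`. Records are typed from allele lengths alone — DEL
(`len(REF) > len(ALT) = 1`), INS (`len(ALT) > len(REF) = 1`), COMPLEX
(both alleles > 1 bp); symbolic ALTs are flagged unresolvable and excluded
from classification rather than silently typed. For COMPLEX records, which
have no canonical single length, `svlen` is defined as
`max(len(REF), len(ALT)) − 1`. Multiallelic lines are split into
per-allele records at parse time; genotype indices pointing at other
alternates collapse to 0, because carrier logic concerns the focal allele
only.

## Local alignment engine

External aligner calls are replaced by a self-contained seed-and-extend
engine: exact k-mer seeds (numpy-indexed, so a 5-Mb genome indexes in
seconds), grouped per exact diagonal, greedily extended without gaps under
an X-drop rule (match +1, mismatch −2, drop 12). Identity is the match
fraction over the extended segment; segments failing the identity floor
are shrunk to their best-identity core or discarded. Because extension is
ungapped, an indel in a real alignment splits a hit in two — the chaining
stage reassembles such pieces, which is the behaviour the ≥ 75 % coverage
rules need. **Uniqueness** replaces aligner mapping quality: a hit's score
gap to the best other hit covering ≥ 50 % of the same query interval (its
own score when unambiguous). The default floor of 10 emulates a MAPQ ≥ 10
filter; it is deliberately disabled for the circular mitochondrial target,
whose doubled sequence duplicates every placement.

Chaining solves the exact objective — maximize covered query bases, then
minimize hit count, then maximize summed score — by O(n²) dynamic
programming over hits sorted by query end. Hits may overlap by ≤ 10 bp on
the query (trimmed at the midpoint in the reported chain); larger overlaps
are mutually exclusive. Seed length is per-call configuration, not a
package constant: 11 bp against consensus databases, 13 bp against
genomes, 9 bp inside homology-scan windows (sensitive enough for 85 %
identity arms, specific enough to keep seed noise negligible).

## MEI annotation

Processing order for one insert: (1) TSD detection — longest exact
terminal match between an insert end and the immediately adjacent
reference flank, evaluated at both ends, ties toward the longer match and
then the 3' end, bounded at 50 bp to keep the search deterministic;
(2) poly(A)/(T) scan; (3) orientation normalization (a dominant leading
poly(T) triggers reverse complementation); (4) outer tail trimming;
(5) 3'-transduction split at a second qualifying poly(A); (6) core
decomposition; (7) class assignment.

**Tails.** A tract qualifies at length ≥ 10 bp, purity ≥ 90 % (fraction of
the tract that is the tail base — the formula is this package's choice),
ending within 50 bp of the insert end. The detector returns the longest
qualifying window, ties to the smaller end offset, with one normalization:
windows must begin and end with the tract base. Without that rule the
"longest window" is ill-posed — any pure tail of ≥ 18 bp could absorb two
foreign bases and still clear 90 % purity — so tract boundaries would be
systematically inflated. The window search is O(n) per end via a
prefix-minimum reformulation (purity ≥ p ⇔ g(i) ≤ g(j) for
g(x) = count(x) − p·x).

**Transductions.** The second poly(A) is searched with the same tract
rules but its offset from the 3' end may reach 1 kb (parameter
`max_td_len`): a transduced segment of realistic length necessarily pushes
the inner tail far beyond the 50-bp rule that applies to outer tails. The
segment past the inner tail is traced against the genome; it is accepted
as a transduction when ≥ 80 % of it aligns (union of hit query intervals),
otherwise the candidate is demoted to solo. Segments shorter than the seed
word are recorded as untraceable (side known, source unknown).

**Classification.** Coverage fractions are computed on two separate
chains — consensus-only and genome-only — rather than one mixed chain.
This matters whenever an element's full-length progenitor is present in
the reference: a single genomic hit would otherwise explain the entire
insert and shunt a genuine solo/partnered insertion into the orphan-
transduction rule. Hits shorter than 25 bp are ignored as seed noise for
classification structure. Precedence: processed pseudogene (≥ 75 % exonic)
→ partnered 5' transduction (genomic component strictly 5' of the element
component, jointly ≥ 75 %) → orphan transduction (≥ 75 % genomic,
non-exonic, tail present, element coverage < 25 %) → solo / partnered 3'
(single family ≥ 75 %, tail present) → ERV → NUMT → non-canonical MEI
(≥ 75 % over any element mix, no tail requirement) → unclassified. Every
satisfied rule is recorded in the annotation notes so conflicts are
auditable. Canonical status requires tail + TSD + no 3' truncation and no
internal rearrangement; a single minus-strand 5' component ahead of
plus-strand components of the same family is the twin-priming signature
and stays canonical. Tail-less inserts matching an element are
`non_canonical_MEI` with a `no_polyA` flag; 3'-truncation is judged
against the element consensus end with 30 bp tolerance.

**L1 subfamilies.** Diagnostic bases are read through the (ungapped)
element hits at 1-based consensus positions 5929–5931 and 5535/5538.
`ACG` → pre-Ta; `ACA` → Ta, refined to Ta-0 (G and C) or Ta-1 (T and G);
uncovered positions or any other profile → undetermined. The synthetic L1
consensus is 6 kb with these positions planted at the published
coordinates; with real data the user supplies the consensus build those
coordinates refer to.

## Tandem repeats and duplications

The detector proposes periods by self-match autocorrelation
(`seq[i] == seq[i+p]`), merges match runs across short gaps, and refines
each candidate to the maximum-scoring subsegment against the tiled
majority consensus (match +1, mismatch −2, Kadane) — flanking chance
matches drift negative and are excluded. Adjacent arrays that share a
period but not a motif merge into one self-match segment; the detector
peels off the best consensus subsegment and recurses on the remainder, so
both motifs surface. Reported identity is measured against the tiled
consensus (so two substitutions in a 40-bp array give 0.95). Hits fully
explained (≥ 90 % jointly) by divisor-period hits at comparable identity
are suppressed; motifs are canonicalized to the lexicographically smallest
rotation, making motif equality well-defined. Arrays shorter than 10 bp or
2 copies are ignored.

VNTR calls chain arrays by the same exact interval scheduler; ≥ 75 %
coverage by one motif is `VNTR_simple`, by several `VNTR_complex`.
Duplication calls restrict hits to ±2 kb of the insertion breakpoint and
apply the three ≥ 75 % orientation rules. When an allele qualifies as both
(a motif array is also a copy of adjacent sequence), VNTR wins if ≥ 2
motif copies lie within the allele — single-copy-unit gains are
duplications.

## Breakpoint junctions

Microhomology is computed directly on sequence as the capped (50 bp)
maximal exact junction-spanning match: left- plus right-extension across
the junction for deletions; insert-prefix-vs-downstream plus
insert-suffix-vs-upstream for insertions, probing at most the first/last
50 bp of inserts over 100 bp. Flanks are probed to 2 kb.

The windowed scan searches co-directional local alignments between window
pairs around the two junctions — symmetric paddings 50 bp to 100 kb
(overlapping pairs skipped, windows clipped at contig edges) plus
SV-length-sized asymmetric windows slid in sixths of the SV length, which
by construction are adjacent and never overlap. Insertions are first
implanted so both junctions exist on one sequence; reported arm intervals
are projected back to reference coordinates through the monotone implant
map (positions inside the allele project to the breakpoint). A hit passes
if it spans both junctions at the same relative position within ±5 % of
the homology length; since a local alignment legitimately sheds terminal
mismatches, the junction may sit within max(5 bp, 5 %) of the alignment
edge. The longest passing homology across all window configurations is
reported — the selection rule is this package's choice.

Mechanism bins partition every non-excluded SV by effective homology
(windowed length when ≥ 50 bp, else exact microhomology): 0 blunt; 1–15
NHEJ/alt-EJ/MMBIR; 16–49 homology-independent; ≥ 50 HDR; ≥ 200 NAHR (the
more specific label inside the HDR range). VNTR, tandem-duplication and
MEI alleles are excluded — their flank homology is allele structure, not
mechanism evidence. Repeat mediation requires ≥ 85 % of both arms inside
same-class annotations and one arm covering ≥ 85 % of its element; SD
mediation requires an SD covering ≥ 85 % of an arm with the intersection
exceeding 200 bp or half the SD — one qualifying arm suffices.

With divergent arms the scan recovers the arm length to within a few
terminal bases; an arm planted exactly at a bin boundary (e.g. 201 bp at
92 % identity) can therefore land one bin short. This is an inherent
boundary effect, visible in the acceptance metrics as mechanism accuracy
slightly below 100 % at some seeds.

## Transduction atlas

Source intervals padded ±10 kb merge transitively into loci (order-
invariant); progenitors come from a full-length database (L1 > 5.9 kb,
SVA > 1 kb; reference annotations plus non-reference insertions), with
ambiguity resolved by distance to the centroid of member alignment
positions. Loci with ≥ 5 non-orphan transductions get an exact two-tailed
binomial test of 5' vs 3' counts; Benjamini–Hochberg correction runs
across tested loci only, and bias is called toward the majority side at
adjusted p < 0.05. The null proportion defaults to 0.5 but is exposed as a
parameter — a family-specific background null is a plausible alternative
and the test is agnostic to that choice.

## Graph augmentation

Centromere masking replaces masked bases by N (lengths unchanged) and
drops any SV intersecting a masked interval. Footprints for overlap are
the anchored span for DEL/COMPLEX and a width-1 point for INS, so two
same-position insertions never share a group. Greedy first-fit by start
position is depth-optimal for intervals, so the group count equals the
sweep-line maximum overlap depth — an invariant the tests check directly.
Implantation applies alleles right-to-left per contig with a REF-allele
guard at every site, and emits per-member allele spans plus a cumulative-
offset coordinate map; extracting each span must reproduce the ALT allele
exactly. Multiple records from one assembled contig merge into a single
COMPLEX record by splicing the intervening reference into both alleles.
Novel bubbles are those ≥ 1 kb (gap distance) from every original bubble.

## Recurrence screen

Candidate deletions must pass all of: length < 5 kb, flanking homology
200–9,000 bp, allele frequency 40–60 %, Hardy–Weinberg and Mendelian
screens, phased genotypes; records missing any annotation are excluded
with the missing field named. A recurrence-indicating SNP (MAF ≥ 10 %,
within a 20-kb window centred on the deletion, outside the deleted
interval) is one where all four SNP-allele × deletion-state haplotype
combinations occur. Haplotypes in a 100-kb window are clustered with
centroid linkage; on 0/1 vectors squared Euclidean distance equals Hamming
distance, so scipy's Euclidean-based centroid method preserves the
intended metric. The flat cut is a fixed Hamming fraction of the window
SNP count (default 0.1), i.e. `t = sqrt(0.1 · S)` in Euclidean units. The
supported verdict — qualifying SNPs on both sides and carriers in ≥ 2
clusters (one carrier suffices, mirroring outlier haplotypes) — automates
what is otherwise a manual inspection; the per-cluster consensus table is
emitted so a human can audit every verdict.

## Callset operations

Allele divergence is edit distance (unit costs, via edlib) divided by the
longer allele length — the external tools the thresholds come from do not
print a formula, so this is the package's definition, applied consistently
in both directions of every comparison. Duplicate marking uses transitive
closure of the pairwise rule (offset ≤ 500 bp, size ratio strictly > 0.5,
divergence ≤ 30 %, carrier-set Jaccard ≥ 10 %; pairs without genotypes
skip the carrier criterion and are recorded); the retained representative
is the deterministic minimum of (start, −svlen, id). Matching uses offset
≤ 50 bp, ratio ≥ 0.8, divergence ≤ 10 %, preserving one-to-many links.
Note the divergence rule couples to the size ratio: two alleles differing
in length by 20 % already have ≥ 20 % divergence, so ratio boundaries are
only reachable jointly. Trio consistency enumerates one transmitted allele
per parent; sites with any missing genotype are untested and the
inconsistency rate is inconsistent / (consistent + inconsistent).

## Synthetic fixtures

The generator is the package's study design. Each descriptor occupies its
own genome slot (breakpoint in the first quarter, reference-side
constructions — progenitors, transduction sources, homology arms, exons —
in the second half), so events never interact; all randomness flows
through one numpy Generator and regeneration is bit-identical per seed.
Default conditions: genomes are i.i.d. bases at GC 0.41 (human-like);
canonical MEI mixes are 60/25/15 % Alu/L1/SVA with TSDs of 5–30 bp,
poly(A) 10–40 bp, 30 % carrying 5' truncations (half with twin-priming
inversions), 20 % carrying 3' transductions of 50–500 bp copied from
planted progenitor flanks.

Consensus elements are random sequences with three deliberate properties:
the L1 diagnostic bases are planted at their published coordinates; no
internal 10-bp window could pass the tail purity rule (so elements never
carry accidental poly(A) signals); and the last six bases of every element
are A-free, giving appended tails an unambiguous 5' boundary. The same
boundary discipline applies at generation time to transduced-source
segments and to the base adjacent to each planted TSD — without it, exact
recovery of tail/TSD lengths would be ill-defined at the single-base
level, not merely harder.

Recurrence panels draw two ancestral cores differing at 35 % of 150 SNPs
across a 100-kb window, assign haplotypes half-and-half, add per-haplotype
mutations at 1 % per site, and plant the deletion on one core (80 %
penetrance) or both (50 % each). The density and divergence are chosen so
that a genuinely dual-origin panel almost surely carries core-
distinguishing SNPs on both sides of the deletion — a dual-origin panel
without such SNPs contains no recoverable signal and would test nothing.
An optional per-SNP recombination switch rate exists for robustness
experiments and defaults to 0.

What the fixtures do **not** model: sequencing and assembly error, indel
divergence between repeat copies (arm divergence is substitution-only, so
the ungapped aligner's gap handling is exercised only via hit splitting),
realistic repeat landscapes (one unique copy of each element family
instead of thousands of interleaved, decayed copies), linkage
disequilibrium decay and coalescent genealogies, and real consensus
sequences. Passing the acceptance checks therefore demonstrates the
correctness of the decision rules and their thresholds under clean
conditions — not the end-to-end accuracy a real genome would yield, where
seed sensitivity, multi-mapping and annotation quality dominate.

## Problem sizes

The acceptance benchmarks run 200 MEIs in a 5-Mb genome plus 1,000 random
1-kb negatives, 10,000 junction-oracle SVs, 80 homology-arm deletions
(arms 100 bp–5 kb), a 100-case VNTR/duplication set, 1,000 chaining
instances (≤ 12 hits, exhaustive subset oracle), 1,000 pseudo-haplotype
callsets, 200 bias replicates, 1,000 single-origin and 100 dual-origin
recurrence panels (200 haplotypes each), and 1,000 random callsets for the
dedup/match oracles. The full set completes in about a minute on one CPU.
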
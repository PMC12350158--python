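# svatlas

Annotation toolkit for sequence-resolved structural variants (SVs):
classify insertion and deletion alleles by the sequence signatures of their
formation mechanism, quantify breakpoint-junction homology, trace
retrotransposon transductions to their source elements, build
pseudo-haplotypes for pangenome graph augmentation, and screen
homology-mediated deletions for recurrent origin.

It is aimed at researchers working with long-read SV callsets — VCFs whose
REF/ALT alleles carry the full variant sequence — who want mechanistic
annotations (what *is* this insertion? how did this deletion form?) without
assembling a zoo of external tools, and at method developers who need a
fully synthetic, ground-truthed test bed for such annotations.

## What it computes

**Mobile-element insertions (MEIs).** A canonical target-primed reverse
transcription (TPRT) insertion leaves a target-site duplication (TSD) and a
3' poly(A) tail. For each insert the toolkit detects the TSD (longest exact
terminal match to the adjacent reference sequence), scans for poly(A)/(T)
tracts (≥ 10 bp, purity ≥ 90 %, within 50 bp of the insert end), normalizes
orientation, splits off 3' transductions at a second poly(A), traces the
transduced segment to its genomic source, and decomposes the remaining core
against a consensus-element database plus the reference by seed-and-extend
local alignment chained with exact weighted-interval scheduling. Classes
follow ≥ 75 %-coverage rules in fixed precedence: processed pseudogene
(exonic), partnered 5'/3' transduction, orphan transduction, solo Alu/L1/SVA,
solo-LTR/ERVK, NUMT (circular mitochondrial alignment), non-canonical MEI.
L1 subfamilies are read from diagnostic consensus bases: positions
5929–5931 (`ACG` → pre-Ta, `ACA` → Ta) refined at 5535/5538 (G,C → Ta-0;
T,G → Ta-1).

**VNTRs and duplications.** Tandem arrays are detected by self-match
autocorrelation with consensus-motif scoring; alleles are `VNTR_simple`
(≥ 75 % one motif) or `VNTR_complex` (≥ 75 %, several motifs). Insertions
re-aligned within ±2 kb of their breakpoint are `tandem`, `inverted` or
`complex` duplications by the orientation of ≥ 75 % of their sequence.

**Breakpoint junctions.** Per SV, the maximal exact junction-spanning
match (capped at 50 bp) plus a windowed scan for longer imperfect homology
(symmetric paddings 50 bp–100 kb and SV-length-sized asymmetric windows).
Homology length `h` routes to a formation-mechanism bin:
blunt / 1–15 bp (NHEJ, alt-EJ, MMBIR) / 16–49 bp (homology-independent) /
≥ 50 bp (HDR) / ≥ 200 bp (NAHR). Homology arms covered ≥ 85 % by same-class
repeat annotations (one arm spanning ≥ 85 % of its element) mark the SV
repeat-mediated; an analogous rule marks segmental-duplication mediation.

**Transduction atlas.** Traced transductions are clustered into source
loci (±10 kb buffer, transitive merge), intersected with full-length
progenitors (L1 > 5.9 kb, SVA > 1 kb), and each locus with ≥ 5 non-orphan
events is tested for 5' vs 3' bias with an exact two-tailed binomial test,
Benjamini–Hochberg-corrected across loci.

**Graph augmentation.** Overlapping calls cannot be implanted into one
consensus, so the callset is partitioned into non-overlapping groups
(greedy first-fit, provably depth-optimal), each implanted right-to-left
into a centromere-masked reference to yield pseudo-haplotype FASTAs with
exact coordinate maps; bubbles ≥ 1 kb from any original bubble count as
novel.

**Deletion recurrence.** Deletions < 5 kb with 200–9,000 bp flanking
homology, allele frequency 40–60 %, passing Hardy–Weinberg/Mendelian
screens and phased, are screened for recurrence-indicating SNPs (both
alleles co-occurring with deletion presence *and* absence, MAF ≥ 10 %,
within a 20-kb window) and for carriers split across centroid-linkage
haplotype clusters in a 100-kb window; a supported verdict needs
qualifying SNPs on both sides plus carriers in ≥ 2 clusters.

**Callset plumbing.** Duplicate marking (offset ≤ 500 bp, size ratio
> 0.5, allele divergence ≤ 30 %, shared carriers ≥ 10 %), callset matching
(offset ≤ 50 bp, ratio ≥ 0.8, divergence ≤ 10 %), and trio Mendelian-
inconsistency statistics.

All heavy steps run on a built-in seeded fixture generator that implants
each variant architecture with known parameters, so every classifier is
exercised against exact ground truth with zero downloads.

## Worked example

Generate a small ground-truthed fixture and annotate it:

```bash
svsynth make --profile mei --outdir demo --seed 3 --n 6 --genome-length 400000
svmei annotate --vcf demo/svs.vcf --ref demo/genome.fa \
    --consensus demo/consensus.fa --out demo/annotations.tsv
```

`demo/annotations.tsv`:

```
id      class            canonical  tsd_len  tail_len  orientation  td_side  td_source          subfamily  full_length  twin_priming
sv0000  partnered_td_3p  True       13       23        +            3p       chr1:34133-34544              False        False
sv0001  partnered_td_3p  True       15       37        +            3p       chr1:100799-101052            True         False
sv0002  solo_Alu         True       16       34        +                                                   True         False
sv0003  solo_L1          True       30       14        +                                  Ta-0             True         True
sv0004  solo_Alu         True       28       24        +                                                   True         False
sv0005  solo_Alu         True       29       16        -                                                   False        False
```

Reading one row: `sv0003` is a canonical full-length solo L1 insertion with
a 30-bp target-site duplication and a 14-bp poly(A) tail, carrying the
Ta-0 diagnostic bases, integrated with a twin-priming 5' inversion.
`sv0000`/`sv0001` are L1-partnered 3' transductions whose transduced
segments trace to the reported source loci (`td_source`), which is where
their progenitor elements were implanted. `sv0005` integrated on the minus
strand (detected from its leading poly(T)) and is reported in forward
orientation. Every value matches the generator's truth table
(`demo/truth.json`).

The other entry points follow the same pattern: `svmech junctions`
(breakpoint homology + mechanism table), `svmei vntr` / `svmei dup` /
`svmei atlas`, `svaug build` (pseudo-haplotype FASTAs), `svrecur scan`
(recurrence verdicts), `svcore dedup` / `match` / `trio-check`.

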
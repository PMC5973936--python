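# Methods

## The experimental design being modelled

`circdynamics` analyses the library layout used to profile circular RNAs
(circRNAs) in a differentiating cell population: total RNA is
rRNA-depleted and sequenced as stranded 2 × 125 bp paired-end reads at
three timepoints (t0, t24, t48 after induction), once untreated
(`rminus`) and once after RNase R digestion (`rnaser`), giving a
2 × 3 sample grid. Circles, having no free 3′ end, survive the
exonuclease; linear RNA largely does not, so the treated library
enriches back-spliced species and the untreated library provides valid
linear quantification.

The abundance unit for a circRNA is the count of fragments spanning its
back-spliced junction, normalised to reads per 10⁸ mapped reads.

## Synthetic data

### Genome and annotation

`simulate.build_toy_genome` places non-overlapping multi-exon genes on
both strands of a single contig (default 20 genes, 4–8 exons of
150–350 nt, introns 80–320 nt, padded to 100 kb). Every intron carries
canonical GT..AG borders in transcript sense, and the dinucleotides
immediately outside each transcript's terminal exons are set to AG/GT as
well, so a back-splice over *any* contiguous exon run validates against
the genome. The minimum exon length equals the read length so that
junction-spanning reads stay inside the circle's terminal exons and are
resolvable by genomic anchor extension. The annotation includes lncRNA
genes and a one-exon antisense lncRNA overlapping a coding gene; the
protein-coding CDS starts in the second exon and ends in the
second-to-last, leaving whole terminal exons untranslated so UTR-only
circles exist.

### Circles, abundances, regulation

Templates are contiguous exon runs with exon counts drawn from a
distribution with mode at 2–3 exons (default
{1: 0.10, 2: 0.40, 3: 0.35, 4: 0.10, 5: 0.05}); genes may host several
templates. One antisense and one intergenic circle are planted in intron
and spacer sequence with canonical flanks written into the genome, to
exercise the non-exonic genomic categories.

Linear abundance per gene is log-normal (default median 60 molecules,
σ = 1). Circular abundance couples to it through one of three models:

- `constant` — circ = f·linear (the splicing by-product null);
- `saturating` — circ = c_max·linear/(K + linear), so the circ:linear
  ratio falls as host expression rises (default, the observed regime);
- `independent` — circ drawn independently of the host.

Planted regulation multiplies circular abundance at t24/t48 by an
effect (> 1.5 up, < 0.67 down, so planted truths are detectable by the
screening thresholds; defaults 2.5× and 0.4×).

### RNase R and sequencing

Digestion is independent Bernoulli survival per molecule
(p_circ = 0.9, p_linear = 0.05 by default), not sequence-dependent
exonucleolysis. Each timepoint has one RNA pool (Poisson molecule
counts); the treated library is a binomial thinning of that same pool,
modelling two library preps from one extraction. Fragments are
multinomial over templates with weight molecules × length; fragment
length is normal (mean 250 nt, sd 30, floored at the read length);
circle fragments start uniformly on the circumference and wrap
(rolling circle), which is what produces junction-spanning reads.
Mate 1 carries transcript sense; substitution errors are uniform
(0.1% default, no indels). A configurable fraction (5%) of linear
molecules is sequenced as unspliced pre-mRNA so exon–intron boundary
reads exist for the flanking linear estimate.

Untreated samples receive exactly `depth_per_sample` read pairs.
Treated samples keep the *per-molecule sequencing rate* constant: their
depth is scaled by the surviving mass fraction. Under this contract the
expected treated/untreated junction-read ratio per circle equals
p_circ, and linear flank counts drop by ≈ 1/p_linear — the two
quantities the survival-model tests measure. (Scaling the treated
library back to equal depth would instead renormalise everything by the
survival-weighted mass and leave linear counts nearly unchanged, hiding
the digestion signal.)

### Count-level path

`simulate_count_tables` skips sequence space: junction, flank and
whole-gene counts are Poisson around the same abundance/survival model
on a grid of hundreds of features. The screening-power and
correlation analyses run on this path; read-level simulation at those
sizes adds runtime without adding information. The whole-gene count is
an independent draw from the flank count because the ratio-vs-host
correlation must not share sampling noise between its axes.

### What the generator does not emulate

PCR duplicates, GC and positional bias, quality-score error models,
indels, intron lariats, alternative linear isoforms, fusion
transcripts, and genome-scale repeat structure. Passing tests therefore
show correctness of the method's logic under idealised noise, not
performance on human-scale data.

## Detection

Reads are aligned end-to-end against the genome and all annotated
spliced transcripts with an exact-20-mer seed table and a ≤ 2 mismatch
budget (each mate separately; mapped mates define `total_mapped_reads`).
Unmapped mates enter the back-splice stage:

1. 20-nt terminal anchors are placed on the + genome; candidate loci
   come from exact 5-mer quarter seeds, which by pigeonhole enumerates
   every locus within the 2-mismatch budget.
2. Anchor pairs in head-to-tail orientation (3′ anchor upstream of the
   5′ anchor) seed breakpoint resolution: both anchors extend toward the
   read interior and each breakpoint offset is scored by total
   mismatches; the genomic flanks must read AG | circle | GT
   (AC | circle | CT for minus-strand circles).
3. A junction is accepted only at a strictly unique best-scoring
   offset; ties are discarded as `ambiguous`. Other rejection
   categories: `no_gtag`, `too_many_mm`, `span_exceeded` (> 100 kb),
   `strand_conflict` (GT-AG-implied strand disagrees with the stranded
   library layout), `mate_inconsistent`, `repetitive`.
4. Mate consistency: the partner mate must map inside [start, end) on
   the circle's strand with the orientation a circular fragment implies,
   or span the same junction itself. A read pair contributes at most one
   junction fragment.
5. Repetitive filtering drops calls whose supporting anchors have
   multiple best loci or whose 40-nt junction context occurs elsewhere
   in the genome exactly.

Defaults: anchor 20 nt, ≤ 2 mismatches per read, circle span ≤ 100 kb,
GT-AG only. These are package decisions (the detection literature's
conventions at toy scale), exposed as parameters.

## Quantification

- Circular: junction fragments / total mapped reads × 10⁸.
- Linear at a circle: the two boundary events immediately flanking the
  circle — fragments spanning the linear splice from the neighbouring
  exon into the circle's terminal exon, plus fragments crossing that
  exon's outer exon–intron boundary (≥ 10 nt overhang each side) —
  averaged over the two flanks. Terminal-exon circles use the available
  side (`one_sided`); circles off exon borders count exon–intron events
  only (`nonexonic`). Only the untreated library yields meaningful
  linear estimates.
- Host gene: plain FPKM over the gene's exon-union model; fragments
  compatible with n genes count 1/n for each, so fractional assignments
  sum exactly to the number of assigned fragments.

Known limitation: a multi-exon circle's internal splice junctions
coincide with the host transcript's; circle-derived reads crossing them
inflate the flank estimate of any *other* circle whose boundary sits at
that junction. This is inherent to flanking-based linear estimation and
is why the survival-model tests use single-exon circles, where the
estimator is identifiable.

## Screening

A circle is *detected* in a sample at ≥ 2 junction fragments, and
enters the high-confidence set when detected in both libraries at the
same timepoint, for at least one timepoint. Fold changes are computed
on normalised values against the same-library t0 baseline, with a
pseudocount equal to one raw read on the baseline sample's normalised
scale added to both numerator and denominator (finite at zero
baselines; exactly invariant to depth rescaling of non-baseline
samples). Direction: at least three of the four fold changes
(rminus t24/t48, rnaser t24/t48) strictly above 1.5 (up) or strictly
below 0.67 (down), with the remaining value on the same side of 1.0.
Support: up calls need ≥ 3 junction reads at t24 or t48 in both
libraries; down calls need ≥ 3 at t0 in both. Calls failing support are
demoted to unchanged.

This is a deterministic rule, not a statistical test: no dispersion
estimation, no p-values, no multiple-testing correction — preserved
deliberately. Note the thresholds are asymmetric (0.67 ≠ 1/1.5); the
property tests document the band (1/1.5, 1/0.67) where the up/down
mirror breaks.

## Characterisation

Category precedence is sense-exonic > lncRNA > antisense > unannotated,
with CDS dominating UTR within the exonic class; UTR side follows
transcript orientation. Exon counts and circles-per-gene use the
transcript whose exon borders match the breakpoints. The by-product
test takes one representative circle per gene (highest summed untreated
expression, ties to the smallest id) and rank-correlates the
circ:linear ratio with host expression; it refuses n < 10. Host-linear
relationship classes (independent / concordant / reciprocal /
both_unchanged) use the untreated library only, because linear fold
changes after digestion are meaningless. Cross-dataset comparisons
re-detect circles after 3′-trimming reads to a common length (80 nt),
mirroring re-analysis rather than list trimming.

## Sponge prediction

Circle sequences are spliced exon concatenations in transcript sense
(RNA alphabet internally). Seed sites follow the canonical classes —
6mer (miRNA 2–7), 7mer-m8 (2–8), 7mer-A1 (2–7 + A opposite position 1),
8mer — scanned on the circularised sequence so junction-spanning sites
are found once; each miRNA placement yields its maximal class and
overlapping sites deduplicate by start. Duplex quality is a simplified
local alignment of the reverse-complemented miRNA against the site with
30 nt of upstream context: match +5, G:U wobble +1, mismatch −3, gap
open −8, extend −2, seed region gap-free (full thermodynamic scoring is
out of scope). A miRNA passes overall when it has a ≥ 7mer site, a
pairing score ≥ 80, and appears in the user-supplied CLIP support
table; the verdict is the three-way conjunction. The score threshold
and scoring weights are explicit configuration, not literature values.

## Numerical and reproducibility choices

All coordinates are 0-based half-open internally; GTF converts at the
boundary, BED is native. circRNA identity is the coordinate tuple; the
string id is derived, never parsed. All randomness flows from one
`numpy` Generator seeded from the configuration, and identical
configurations produce byte-identical outputs; the CLI records seed,
effective configuration and output checksums in a manifest. Simulation
sizes used by the test-suite and the reproduction script (20-gene /
100 kb study-scale runs, 10-circle deep runs for the survival model,
250–500-feature count-level grids) are chosen so every stochastic
assertion sits several standard errors from its threshold.
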
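# Methods

## Coordinates and formats

All coordinates are 0-based half-open internally (BED convention). BED-like
inputs are taken at face value; GTF exons are converted from 1-based
inclusive at the reader boundary and back at the writer, so round trips are
identities. The junction caller's strand column is trusted as the
transcribed strand of the circRNA — the antisense class requires
strand-aware comparison, so a caller that does not report strand reliably
will misclassify antisense circles. Conservation tracks are held as dense
per-chromosome arrays with an explicit coverage mask, because averaging
must distinguish a score of 0 from the absence of a score; missing bases
are excluded from means, never imputed as zero.

## Junction classification

A junction is genic-exonic iff both ends coincide exactly (no slop window)
with exon boundaries of one same-strand gene. Boundary matching uses the
union of exon intervals over all transcripts of a gene, merged into
non-overlapping blocks — whether matching should be per-transcript or
per-gene-union is genuinely open; the union is our documented choice and
the generator plants circRNAs consistent with it. Multi-gene ambiguity is
resolved deterministically: most matched boundaries first, then
lexicographically smaller gene id. Gene overlap (for genic/antisense calls)
means ≥ 1 bp overlap with the gene span. Junctions on chromosomes absent
from the annotation are classified intergenic with a logged warning rather
than failing the run.

Genic-exonic spans are tiled by the union blocks clipped to the span
(exons) and the gaps between them (introns); all other classes are treated
as a single exon covering the span. Mature sequences concatenate exon
features only — introns are excluded throughout, reflecting that intronic
read signal in this setting is better explained by lariat byproducts than
by retained circRNA introns — and minus-strand circles are
reverse-complemented. IDs are assigned by sorting spans by
(chromosome, start, end, strand) and numbering with six-digit zero padding.

## Expression

`RPKM = count / ((library_size x 1e-6)(length x 1e-3))`. Counting is
strand-aware with ≥ 1 bp overlap and no fractional assignment: a read
spanning an exon|intron boundary increments both features. Circ-level
counts are meta-feature sums over exon features with `L` the summed exon
length, consistent with the exon-only mature sequence. The expression
threshold defaults to RPKM > 3.5 — the operating point derived from
predicted-but-never-detected introns of validated circRNAs —
and `derive_threshold` recomputes it from any validation set as the maximum
per-population mean RPKM over those introns. The threshold is applied to
per-population means (not per-sample values), in ≥ 1 population, with
strict inequality; this per-population-mean reading is an interpretive
choice, made because the output tables report per-population averages.
Library size is the total read count of the sample's input, with no
GC/length bias correction (out of scope).

## Differential expression

Size factors are plain median-of-ratios over features with all-positive
counts. Fold changes are ratios of per-population means of normalized
counts with a pseudocount (default 0.5, configurable) guarding zeros; no
shrinkage, dispersion estimation, Wald testing or FDR is applied — the
deliverable is the FC-threshold pattern class, which the shrinkage
machinery of a full differential-expression model would not change at
these thresholds. Thresholds are inclusive: U iff FC ≥ 1.5, D iff
FC ≤ 0.67 (kept as printed rather than exactly 1/1.5; both are
configurable), F otherwise; the two-transition label (nine classes)
partitions all calls.

## miRNA seed sites

A site is a target hexamer Watson-Crick complementary to miRNA positions
2–7, upgraded to 7mer-m8/7mer-A1/8mer by the position-8 pair and the
target A opposite position 1. The scan is circular by default: the
sequence is extended by its first (miRNA length − 1) bases and sites are
reported once at their modular position, making the category multiset
invariant under rotation; `--linear-scan` restores a plain linear scan of
the mature sequence. Sites carry a local complementarity alignment score
(match +5, G:U wobble +1, mismatch −3, gap −8/−2) and a duplex free energy
from a Watson-Crick nearest-neighbor stacking sum (Turner-style ΔG°37
parameters, helix initiation +4.09, terminal A:U penalty +0.45; wobble
pairs interrupt the stack sum). This scorer is deliberately simple and
documented — it is not byte-compatible with any published aligner, and the
default gates (score ≥ 150, ΔG ≤ −19 kcal/mol) are calibrated to the
scale of the miRanda-family tools rather than to this scorer, so they are
retained as configurable defaults while recovery testing disables them:
the biological quantity of interest is the per-(circRNA, miRNA) seed count,
for which score/energy are pass/fail gates only.

## ORFs, CAI, eCAI

ORFs are ATG-initiated, same-strand, ≥ 150 nt (stop codon included),
non-nested (an in-frame ATG inside a reported ORF is not reported
separately); ORFs reaching the sequence end without a stop are reported
and flagged open-ended so stricter filtering remains possible. Circular
mode scans the doubled sequence, deduplicates by modular start and caps
lengths at one full turn; it is off by default since mature sequences are
conventionally analysed as linear FASTA.

CAI is the geometric mean over codons (stops excluded) of relative
adaptiveness `w = usage / max(usage in synonymous family)`, computed in
log space; `w` is floored at 1e-3 so a single zero-usage codon cannot
annihilate the mean. The default usage table is mouse codon usage per
thousand codons.

eCAI fits a nucleotide Markov model (order 1 by default, 0–2 available) to
the pooled ORF set, emits null sequences length-matched to the pool
(lengths resampled with replacement, trimmed to whole codons), strips
internal stop codons by resampling the offending codon conditioned on the
preceding base (keeping the length distribution exact; the following codon
is not re-conditioned), and returns the 95% quantile of the null CAI
distribution averaged over five independent runs of 500 sequences. Pooled
fitting with length-matched emission — rather than per-length fits — is
the documented choice. The estimator agrees with a 50 000-draw Monte-Carlo
oracle to ~0.002 on biased pools in our tests. Control datasets are
length-matched random windows from the genome and from the concatenated
transcriptome; fractions of ORFs above eCAI are compared by the 1-df
chi-squared closed form `N(ad−bc)² / ((a+b)(c+d)(a+c)(b+d))` without
continuity correction, and no multiple-testing correction anywhere.

## Conservation

Per-region means are taken over covered bases of the exon features (bodies)
or the strand-aware 200-bp flanks (clipped at chromosome ends, actual
length recorded); regions with zero covered bases are excluded and
counted. Backgrounds are location-matched: genic-exonic bodies shuffle
within merged exons, genic flanks within merged introns, genic-other
bodies within gene bodies, intergenic/antisense regions over the whole
genome, uniformly over feasible placements. A multi-exon body is shuffled
exon-by-exon (one length-matched placement per exon feature) because a
single placement of the summed length need not fit in any reference block.
One shuffled counterpart per real region per draw; `draws > 1` averages
placements. Groups are compared with a Welch two-sample t-test (the
pooled-variance variant is available); two identical zero-variance groups
return t = 0, p = 1 rather than NaN.

## Circular vs linear comparison

Linear-side expression (gene RPKM, isoform RPKM, shared-exon fold changes)
is consumed as precomputed tables; estimating differential exon usage is
out of scope. Pearson correlation is computed on log2(RPKM + 1e-3) per
population. Concordance is per transition: a pair is `opposite` if any
transition runs U vs D; `same` if no transition disagrees, at least one is
concordantly non-flat and none is half-flat; `mixed` otherwise (including
all-flat pairs). The `mixed` bucket is an explicit extension of the
two-class same/opposite dichotomy and is reported separately so the
two-class summary can be recovered by merging. Tightening thresholds can
only send a transition toward flat, so a single opposed transition never
becomes concordant; at the pair level a second, concordant transition can
make a formerly-opposite pair `same` once the opposed transition flattens —
the monotonicity guarantee is therefore stated per transition. Isoforms
count as expressed above the same RPKM threshold as circRNAs (configurable).

## Synthetic data generator

The generator emulates the study design: two 500-kb uniform-random
chromosomes; 300 non-overlapping genes (3–6 exons of 120–300 bp, introns
150–450 bp, ~20% with a second skipped-exon isoform); 150 circRNAs with
class mix 97% genic-exonic / 1% genic-other / 1% antisense / 1% intergenic
realized exactly by largest-remainder allocation; 3 populations x 3
replicates at 50 000 reads per sample. 80% of circRNAs are expressed with
base expected meta-counts log-uniform in 50–500 and per-transition
multipliers 2.0 (U), 0.4 (D), 1.0 (F) across the nine trajectory labels
(40% FF, 10% each UU/DD/UD/DU, 5% each UF/FU/DF/FD); unexpressed circRNAs
get zero planted reads, emulating junctions contributed by pooling that are
absent from these samples. Counts are negative-binomial with dispersion
0.05 (Poisson and noiseless available); reads are length-50 intervals
placed inside their feature, and intergenic background reads top each
library up to exactly 50 000. Seed sites (1–5 per chosen circRNA, one
junction-spanning) and codon-biased ORFs (300 nt, ~90% optimal codons) are
planted by editing the genome through the mature-sequence coordinate map
and verified post-edit with the scanner/ORF finder themselves. The
conservation track adds +0.5 over circRNA exon bodies and +0.25 over
flanks to Gaussian noise (sd 0.2) with 500-bp masked telomeres. Host-gene
linear RPKM is generated with target log-scale Pearson correlation 0.8 to
the circRNA RPKM; shared-exon fold changes are concordant except for a
planted 0.5% opposite fraction.

What the generator does not emulate: sequence-level reads (reads are
intervals, not FASTQ), splice-graph complexity beyond ordered exon blocks
with one optional skipped exon, overlapping genes, GC/mappability bias,
and a realistic phyloP score distribution. Passing recovery tests
therefore demonstrates the correctness of the pipeline's logic under its
own model assumptions, not calling performance on real tissue data.

All randomness flows from one integer seed through a single generator in a
fixed order; the same (config, seed) reproduces the bundle byte for byte.

## Problem sizes and numerics

Default test and acceptance runs use the full 150-circRNA design
(annotation, quantification, trajectories, seed recovery) and scaled
module-level designs where a closed-form or Monte-Carlo oracle is the
comparator: 1000 random ORFs for the CAI product oracle (agreement to
1e-12), 500-sequence nulls x 5 repeats for eCAI against a 50 000-draw
oracle (tolerance 0.02), 50 regions per group for conservation power and
200 seeds for null calibration, 1000 pairs for correlation recovery
(tolerance 0.05). Trajectory recovery on the default noisy design is
~93–97% across seeds against a ≥ 90% bar; expressed-set recovery is exact
by design margin (expressed circRNAs are far above, absent ones at zero).
Floating-point equality of "exact" recoveries is asserted at relative
1e-12 since summation orders differ between generator and pipeline.
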
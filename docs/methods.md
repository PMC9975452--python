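# Methods

## Overview

`plasmafrag` extracts whole-genome fragmentomic features from plasma
cell-free DNA (cfDNA) and combines them in a cross-validated
cancer-vs-healthy classifier. cfDNA is released mainly by
nucleosome-protected apoptotic cleavage, so healthy plasma shows a
mononucleosomal fragment-size mode near 167 bp with ~10.4 bp helical
phasing and a dinucleosomal shoulder near 334 bp. Tumor-derived DNA is
enriched in shorter (~100–150 bp) fragments and carries copy-number
alterations; local chromatin structure (promoter nucleosome depletion,
transcription-factor footprints) leaves position-specific coverage
signatures. Each module quantifies one of these signals; a seeded
simulator provides cohorts with planted ground truth so every stage is
testable without sequencing data.

## Fragment model and input handling

A fragment is a 0-based half-open genomic interval (BED convention);
BAM/SAM input yields one fragment per properly paired template using the
outer template span, with 1-based positions converted on read. Defaults:
mapping quality ≥ 30, duplicates removed, lengths restricted to
[30, 1000] bp for binned profiles. QC histograms lift the upper bound so
the "1000 bp and longer" fraction remains computable. The genome is tiled
into half-open bins (default 5 Mb); a terminal partial bin is kept, and
flagged, only when it spans at least half the bin size, avoiding
high-variance small bins. Fragments map to the bin containing their
midpoint, which assigns every fragment to exactly one bin.

## Size QC and hemolysis flag

Per-sample 1-bp histograms are summarized into five half-open fractions —
[30,80), [80,150), [150,220), [220,1000), [1000,∞) — which partition the
retained lengths and therefore sum to one. Hemolysis (red-cell rupture
during handling) floods plasma with genomic DNA whose counts rise steeply
above 150 bp; the flag compares the genome-wide count ratio of short
(100–150 bp) to long (151–220 bp) fragments against a threshold of 0.05
with a strict less-than rule. Which exact "fragment size ratio" the
threshold is meant to apply to is a known ambiguity; this package applies
it to the same genome-wide short/long count ratio used by the
fragmentation profiles, and the threshold is configurable. A zero long
count is reported as a degenerate size profile and flagged.

## Fragmentation profiles

Per bin, short (100–150 bp) and long (151–220 bp) fragments are counted;
the printed literature ranges share the 150 bp endpoint, so 150 is
assigned to the short class to keep the classes disjoint (configurable).
Counts are corrected for GC sampling bias by locally weighted regression
(lowess, span 0.75) of count on per-bin GC fraction: the fitted trend is
subtracted and the global mean added back, followed by an additive
re-centering that preserves the total exactly. Additive (not
multiplicative) restoration was chosen so bins whose corrected value
crosses zero cannot blow up the rescaling. Under a constant GC covariate
the correction is the identity.

The ratio profile is corrected-short over corrected-long per bin;
"normalized" means per-sample mean-centering only (the variance is not
scaled; z-scaling is available behind a flag). The fraction profile is
each bin's corrected total over the genome-wide corrected total and sums
to one, which also makes downstream copy-number ratios invariant to
library size. Bins with non-positive corrected long counts are masked;
bins masked in any cohort member are dropped cohort-wide before
similarity analysis so every Pearson correlation uses the same support.
Cohort similarity reports the pairwise Pearson matrix, each sample's
correlation with the per-bin median profile of the healthy samples, and a
two-sided Wilcoxon rank-sum comparison of those correlations between
groups.

Whether short and long counts should be GC-corrected separately or the
ratio corrected directly is not settled; separate correction of each
count type was implemented.

## Copy-number scores

A sample's per-bin fractions are compared with a healthy reference panel:
log2(sample / panel median) per bin, plus a z-score against the panel
per-bin mean and standard deviation (ddof 1). Bins with zero panel median
or zero panel spread are masked. The per-sample variance of the log2
scores summarizes genome-wide instability; groups are compared by
two-sided rank-sum test. Gene-level amplification calls average the log2
scores over the bins overlapping each gene's span, test cancer vs healthy
per gene (two-sided Wilcoxon rank-sum), adjust across genes by
Benjamini–Hochberg, and call a gene amplified only when q < 0.05 *and*
the cancer mean exceeds the healthy mean. In cohort analyses the healthy
group doubles as the panel, so healthy samples are scored against a panel
containing themselves; this is slightly conservative and acceptable at
panel sizes ≥ 20. No segmentation, absolute copy number, or
tumor-fraction estimation is attempted.

## TSS relative coverage and chromatin state

Three per-gene quantities, all strand-oriented around the primary TSS
(multiple annotated TSSs collapse to the most upstream):

* NDR relative coverage: mean depth over −150..+50 divided by mean depth
  over the ±(1000..3000) reference flanks;
* 2K relative coverage: the same for ±1000;
* conventional relative coverage: ±1000 depth over the genome-wide mean
  depth.

Window extents are defaults consistent with the TSS-coverage literature
and fully configurable; no authoritative coordinates exist for them.
Genes whose ±3 kb context leaves the chromosome are skipped and reported.
A gene is called permissive (open chromatin) when both NDR and 2K
coverage fall below 1.0 in a strict majority of samples, nonpermissive
(closed) when both exceed 1.5 in a strict majority, and indeterminate
otherwise. Expression concordance between gene sets uses two-sided
rank-sum tests with the direction of medians reported.

## Promoter fragmentation entropy (PFE)

PFE is the Shannon entropy (bits) of the fragment-length distribution in
a ±1000 bp promoter window (midpoint assignment), over 24 half-open 5-bp
length bins spanning [100, 220) bp, with a 0.5 pseudocount per bin as
shrinkage. Entropy is bounded by [0, log2 24 ≈ 4.585]; the normalized
version divides by log2 24. Genes with fewer than 20 qualifying
fragments are reported missing rather than letting pseudocounts dominate.
A fully Bayesian (Dirichlet-multinomial) shrinkage estimator is out of
scope; the pseudocount is the simple stand-in and is configurable.

## TF-site occupancy

Coverage is evaluated at site-relative positions −1000..+1000 in 10-bp
steps, averaged across a factor's sites (strand-oriented where strands
are given), and divided by the mean over the outer 25 % of positions on
each side, making the profile invariant to sequencing depth. The central
score is the mean normalized coverage within ±50 bp; accessible
(nucleosome-free) site sets show central scores below 1. At least 10
usable sites are required.

## Classifier

Per-modality summaries (five size fractions; per-bin normalized ratios
plus correlation to the healthy median; fraction-profile correlation to
the healthy median; CNV score variance and mean |z|; mean NDR/2K relative
coverage over the gene panel; mean PFE; TF central scores) are
concatenated into a block-labelled matrix. The model is a linear
classifier with logistic loss trained by stochastic gradient descent
(L2 penalty 1e-4, optimal learning-rate schedule); standardization and
the model are refitted inside each training fold, so no statistics leak
from evaluation folds. Reported: pooled out-of-fold ROC/AUC from
stratified 10-fold cross-validation, a stratified 70/30 train/test split
with its ROC/AUC and 0.5-threshold confusion matrix, per-sample
out-of-fold probabilities, single-block (per-modality) predictions with
per-sample agreement and majority vote, and a benchmark harness that
evaluates arbitrary fit/predict-probability estimators on identical
folds. Everything is deterministic for a fixed seed. The feature-block
default is the six non-TF blocks with the TF scores optional; reported
cfDNA feature sets in this field vary between five and six modalities,
so the block list is configuration rather than a fixed constant.

## Synthetic cohorts

The simulator generates what the feature modules assume, at desk scale:

* sizes: per-label Gaussian mixtures — healthy 0.86·N(167,10) +
  0.08·N(334,20) + 0.06·N(145,10); cancer raises the short component to
  0.20; a ±10 % cosine ripple with 10.4 bp period modulates the
  mononucleosome peak. The healthy mixture deliberately includes a small
  145-bp component so the genome-wide short/long ratio (~0.10) sits in
  the healthy range rather than at the hemolysis boundary.
* hemolysis: 0.40 mono + 0.05 di + 0.05 uniform 30–60 bp + 0.50 genomic
  tail (150 bp + exponential, mean 300 bp), reproducing the steep rise
  above 150 bp and a short/long ratio of ~0.044, below the 0.05 flag.
* placement: midpoints proportional to bin width × copy multiplier ×
  exp(gc_strength · (GC − mean GC)); per-bin GC runs on a smooth linear
  gradient (0.35–0.55) so GC correction has a controllable confounder.
  Cancer samples carry two amplified bins at 3 copies and 25 % tumor
  fraction by default (bulk multiplier 1.125).
* ratio structure: a fixed zero-mean sinusoidal modulation of the short
  component shared by every sample (regional chromatin signal) plus
  per-sample zero-sum Gaussian distortions in cancer; both are
  normalized by the placement-weighted mean so genome-wide size masses
  stay at their configured values. This yields consistent healthy ratio
  profiles and heterogeneous cancer profiles.
* promoters: expressed ("up") genes thin coverage by 0.4 in the NDR and
  0.7 across the 2-kb promoter and draw lengths from a
  1.8×-broadened mixture (coupling expression to PFE); closed ("down")
  genes gain 1.6× occupancy over the promoter. Promoter-wide (not
  NDR-only) depletion is required for the open-state call, which demands
  both NDR and 2K coverage below 1.
* TF sites: the first factor's sites are centrally depleted (0.9 healthy,
  0.6 cancer, ±50 bp); the second factor is an undepleted control.

Defaults: a 3 × 30 Mb genome with 5-Mb bins (18 bins), 200 genes, 100k
fragments per sample (~0.19×). Analyses that need per-gene promoter
resolution use a denser configuration (1 Mb genome, 100 genes, 400k
fragments ≈ 70×, 30 samples) — depth is bought by shrinking the genome,
not by inflating fragment counts. Ground truth (labels, multipliers, gene
states, TF depletions) is a first-class output; recovery tests read
truth, never expected feature values.

What the simulator does not emulate: sequence content and mappability,
GC dependence within fragments (only per-bin), subclonal mixtures,
segmentation-scale CNA structure, inter-individual germline variation,
and batch effects. Passing recovery tests therefore demonstrates the
correctness and calibration of the estimators under the stated generative
model, not clinical performance on real plasma.

## Numerical choices and degenerate inputs

Fractions below the 30 bp loader floor are excluded before the size
partition. Zero-variance profiles yield undefined correlations, reported
missing. Identical constant groups short-circuit the rank-sum test to
p = 1. Gene calls on fully masked bins return "not_called" with a reason.
The classifier reduces fold counts with a warning when classes are
smaller than the requested folds, and refuses single-class input. All
simulation randomness flows from numpy `SeedSequence` children of one
master seed, so cohorts are bit-reproducible, and the pipeline manifest
records config, input checksums and per-stage output checksums; a rerun
over unchanged inputs skips stages and preserves checksums exactly.

## Known limitations

* The hemolysis threshold's referent ratio is an interpretation (see
  above), configurable but not asserted as ground truth.
* Gene-level CNV calling is a per-gene rank-sum + BH procedure over bin
  scores; it does not model segment boundaries and will share power
  across genes in the same bin.
* Relative coverages are undefined where reference flanks have zero
  depth; such genes are reported, not imputed.
* The SGD classifier is intentionally simple; the benchmark harness is
  the extension point for other estimators.
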
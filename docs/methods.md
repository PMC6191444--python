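# Methods

This note records the models, parameter choices and numerical decisions
behind nchipkit, in the spirit of a statistical methods appendix.

## Coordinates and interval algebra

All coordinates are 0-based half-open (BED native) everywhere; the only
supported input dialects are BED3/6/12, bedGraph and UCSC chrom.sizes, so
no 1-based conversion path exists. Book-ended intervals ([0,100) and
[100,200)) do not merge at `gap=0`: merging is defined on overlap, and a
shared boundary base does not exist in the half-open convention. A
consequence worth knowing: a per-base occupancy mask cannot distinguish
book-ended from overlapping intervals, so mask-based oracles compare
coverage, not segment boundaries. Strand is carried but ignored by all
overlap arithmetic; only the meta-gene stage orients by strand. Sorting
breaks ties by (assembly chromosome order, start, end, label). No
blacklist-region exclusion is applied anywhere.

## Read model and coverage

Read surrogates are (chrom, pos, strand) tables, `pos` being the 5' end;
alignment and duplicate removal are upstream of this package's scope.
Each read is extended to `fragment_length` (default 150 bp, the expected
mononucleosomal fragment after MNase digestion): a + read covers
[pos, pos+L), a − read covers [pos−L+1, pos+1), clipped at chromosome
ends (clipping is counted and logged, never fatal). Pileup mass is exact
in integer arithmetic: total coverage = reads × L − clipped bases.
1x normalization rescales so the genome-wide mean per-base value is 1.

Region counting uses the extended-fragment midpoint: a read is counted
in the unique region containing its midpoint. Midpoint counting was
chosen over any-overlap because it cannot double-count a read across
adjacent regions, making counts additive under region splitting; the
rule is a documented convention, not an estimate.

## Size factors

Two normalizations are implemented from their definitions, not called
from external packages:

- **Median-of-ratios** (the DESeq-family estimator): per sample, the
  median over regions with all-positive counts of count / per-region
  geometric mean. The median is taken in linear ratio space. Relative
  factors are scale-equivariant; the absolute level carries the usual
  arbitrary normalization of the estimator.
- **Trimmed mean of M (TMM-style)** on 10-kb bins for the window caller:
  reference = sample with library size closest to the mean; M and A
  values over bins positive in both libraries are two-sidedly trimmed
  (30% on M, 5% on A) and the precision-weighted mean M gives a
  composition factor; the returned factor is composition × library size,
  centered to geometric mean 1.

## Meta-gene matrices

Default geometry: 6-kb flanks in 50-bp bins (120 bins each side) and 120
gene-body bins, i.e. 360 columns. Body bins are length-weighted
fractional slices of the body — bin k spans [start + kL/120,
start + (k+1)L/120) with partial bases weighted by their fractional
overlap — so any gene of length ≥ 120 bp is exactly representable and
the mean of a gene's body bins equals its mean body coverage to float
precision (the conservation invariant the tests enforce at 1e-9). Genes
shorter than the bin count, unstranded genes, and genes whose flanks run
off the chromosome are excluded and logged.

Clustering is k-means on row-standardized profiles (k=3 by default, 10
restarts, fixed seed), with labels relabeled 1..k by descending mean raw
body signal so "cluster 1" is always the body-enriched cluster. The
clustering algorithm and k are this package's choices — substitutes for
an unspecified upstream method — and are configurable.

The 3'-body vs downstream comparison uses, per gene, the final quarter of
the gene body (configurable, or a fixed width) against an equal-width
window immediately downstream of the TES, strand-aware. Both a paired
Wilcoxon signed-rank p (the design is paired per gene) and an unpaired
rank-sum p are reported. Rank tests use mid-ranks for ties, the exact
null distribution for n ≤ 25 without ties, and the normal approximation
otherwise; the exact branch is validated against full sign-enumeration
in the tests.

## State enrichment

Peaks are unioned before measuring, so observed fractions are a
partition of peak territory (Σ O_s = 1 on a tiling segmentation) and O
is bounded by 1; a `union_peaks=False` flag measures the raw list for
sensitivity analysis. log2(0/E) is reported as −inf with a
`zero_observed` flag rather than clipped; states with zero width get a
`zero_expected` flag and no ratio.

## Co-occupancy rule

For each peak of the owning factor: overlap (≥ 1 bp) with the other
factor's peaks → shared; otherwise the ratio of pseudocounted (+1)
median-of-ratios-normalized mean counts of owner over other, measured on
the merged universe region containing the peak, decides: ratio ≥ 2 →
unique, ratio < 2 → shared. The normalization universe is the union of
both factors' merged peak sets. Two limits follow from the rule as
stated: threshold → 0 recovers the pure interval-overlap Venn, and an
unattainably large threshold demotes every peak to shared; the shared
set grows monotonically in the threshold.

## Consensus differential caller

**Window arm.** 100-bp bins every 300 bp (the stated grid, leaving
200-bp gaps; a dense grid is available by passing `WindowGrid(100,100)`),
TMM-style factors from 10-kb bins, bins with mean normalized count below
5 pre-filtered. Dispersion is estimated by method of moments pooled
within 10 abundance strata: per stratum, Var(z) = c·μ + φ·μ² is solved
for φ using stratum sums, with μ̂² corrected for its own sampling
variance (Var/n per bin); per-bin moment ratios at 2 replicates are far
too noisy and systematically biased low, which the pooled estimator
avoids. The test conditions on the bin total: under a Gamma–Poisson
model the knockdown share of the total is binomial in the Poisson limit
and beta-binomial with precision (number of samples)/φ under
dispersion; two-sided p-values sum all outcomes no more probable than
the observed one, with a mid-p correction to center the discrete null.
Under the implemented NB null (10,000 bins, 2+2 replicates) the
p < 0.001 fraction lands near 0.001, which the acceptance test checks
against the band [0.0005, 0.002]. Selection is at raw p < 0.001 with no
multiplicity adjustment, deliberately mirroring the windowed procedure
it re-implements; significant bins whose starts are within 2 kb
(start-to-start) chain into regions.

**Peak arm.** Condition-consistent peaks (≥ 1 bp overlap across every
replicate of a condition) are combined across conditions and merged into
features; counts are median-of-ratios normalized; per feature an NB Wald
test on log2((μ_kd + ½)/(μ_ctrl + ½)) with SE² = Σ_c (1/μ_c + φ)/n_c
(delta method), BH-adjusted at 0.05. No shrinkage estimators are used —
fold changes at low counts are stabilized only by the half-count
pseudocount — which keeps the estimator transparent at the cost of some
variance at weak features.

**Consensus.** Window regions overlapping (≥ 1 bp) a BH-significant peak
feature, with agreeing fold-change direction (a flag disables the
direction requirement). Both tests' internals are this package's own
constructions; the surrounding scaffolding (bin sizes, scaling bins,
thresholds, merge width, the two-arm intersection) is fixed by the
procedure being reproduced, and the accuracy surface is planted-truth
recovery, not equality with any external tool.

## Synthetic data generator

The generator emulates the deposited study inputs at desk scale. Defaults
define the study conditions:

- genome: 3 chromosomes × 2 Mb; 10 chromatin states as a first-order
  Markov chain over 1-kb tiles (stay probability 0.85, ~7-kb segments),
  run-length merged into a tiling segmentation;
- 200 stranded genes, uniform placement, 2–20 kb, non-overlapping, with
  7-kb margins so meta-gene flanks fit;
- 300 peaks per factor, widths 400–1000 bp, one distinct 1-kb tile per
  peak and each peak inside its tile. Placement is two-stage: a peak
  lands in a promoter/enhancer-like tile (states 3–5) with probability
  p* = f·W_t/(f·W_t + W_o) (f = 5 by default), then uniformly among the
  unused tiles of that class — this makes the planted state preference
  an exact closed form, log2 O/E = log2(f/(1 + (f−1)E_t)) for target
  states, independent of tile depletion. If a class runs out of tiles
  the draw falls back to any free tile (relevant only near packing
  limits);
- factor B shares 70% of factor A's peaks (±50 bp jitter); the two
  acetylation marks share 80% of their peaks;
- 40 differential sites: whole acetylation peaks induced threefold under
  knockdown (binary efficiency; graded knockdown is out of scope);
- reads: ~200,000 per sample, half background (uniform per 10-kb tile)
  and half in peaks proportional to width × fold; replicate dispersion
  is Gamma–Poisson per peak/background-tile with φ = `nb_dispersion`
  (marginally NB); library sizes jittered ±20% to exercise
  normalization. Induced sites add reads to the knockdown library; the
  scaling factors must absorb the resulting ~10% composition shift,
  which is part of what the recovery tests exercise.

`nb_dispersion` defaults to 0.02 (replicate CV ≈ 14%), a realistic value
for clean nChIP replicates and one at which planted threefold changes
are recoverable by design — at φ = 0.05 the detectability margin
ln(3)/√φ sits at the p < 0.001 boundary for 2+2 replicates, making
recovery a coin flip rather than a property of the method.

One integer seed drives a single `numpy.random.Generator` per run, so
every table is bit-reproducible; the pipeline's TSV/BED/JSON outputs are
byte-identical across reruns with the same config and seed.

What the generator does **not** model: sequence content, mappability or
GC bias, spike-ins, paired-end reads, peak-width/signal correlations
beyond width-proportional intensity, and graded knockdown efficiency.
Passing tests therefore demonstrate correctness of the computations and
recoverability under a clean NB read model, not robustness to alignment
artifacts or enzymatic biases in real libraries.

## PTM quantification

"Averaged integrals" of the three fragment ions is read as the
arithmetic mean (a geometric-mean option exists); missing fragments are
averaged over the present ones; an all-zero group splits equally with a
warning. Effective areas conserve the shared MS1 area exactly.
Percentages are per (sample, peptide) and sum to 100; zero-total groups
are flagged, not fatal. Input normalization is the ratio of IP to input
percentages (a difference mode is available by flag); zero or missing
input yields a flagged missing value.

## qPCR

Percent input uses the standard dilution adjustment
Ct' = Ct_input − log2(1/input_fraction); the input fraction is a required
argument because it is experiment-specific. The ddCt SEM is computed
over replicate-level ddCt values, pairing target and reference by
(condition, replicate); the error range 2^(−ddCt ± SEM) is asymmetric
and always brackets the point estimate. No amplification-efficiency
correction is applied.

## Problem sizes used in tests

The default synthetic study (6 Mb, 4 samples × ~200k reads) runs each
caller arm in ~1 s; the acceptance suite uses 200 random 100-kb genomes
for interval-algebra equivalence, 1,000 peaks for state-enrichment
recovery, 500 genes for meta-gene conservation, 10,000 bins for null
calibration, 20 seeded studies for caller power/FDR, 200 draws for the
isobaric noise check, and two full pipeline runs for byte-level
reproducibility.
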
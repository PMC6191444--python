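# nchipkit

Desk-scale analysis of native ChIP-seq (nChIP-seq) experiments that probe
how a chromatin factor shapes histone acetylation: meta-gene profiling and
clustering, chromatin-state overlap enrichment, dual-criterion peak
co-occupancy, a two-algorithm consensus caller for differential
acetylation after a knockdown, histone-PTM isoform quantification with
isobaric deconvolution, and ChIP-/RT-qPCR quantification. A synthetic-data
generator with planted ground truth stands in for deposited sequencing
data, so every stage is testable on a laptop.

It is written for computational biologists who want the bespoke
computations of such a study as a reusable, tested Python library rather
than a one-off script collection.

## What it computes

**Coverage and counts.** Reads (5' positions and strands) are extended to
the expected fragment size (150 bp for MNase mononucleosomes) and piled
up; tracks are scaled to 1x depth (genome-wide mean per-base coverage
= 1). Region counts use the extended-fragment midpoint, so each read is
counted at most once. Size factors are median-of-ratios:
`s_j = median_i ( k_ij / (prod_j k_ij)^(1/m) )` over regions with
all-positive counts.

**Meta-gene profiles.** Signal around each gene is collected as 6-kb
flanks in 50-bp bins plus a gene body rescaled to 120 length-weighted
bins, oriented 5'→3'. The mean of a gene's body bins equals its mean
body coverage exactly. Profiles are clustered by k-means (labels ordered
by descending body signal); 3'-gene-body vs downstream signal is compared
with paired signed-rank and unpaired rank-sum tests.

**Chromatin-state enrichment.** For a peak set and a state segmentation,
`O_s = overlap(peaks, state s) / total peak width` and
`E_s = width(state s) / genome size`; the reported quantity is
`log2(O_s / E_s)` per state.

**Co-occupancy.** A peak of factor A is *shared* with factor B if it
overlaps a B peak (≥ 1 bp), or if A's normalized read count over the peak
is less than twofold above B's — sub-threshold binding the peak caller
missed. Only a non-overlapping peak with a ratio ≥ 2 stays factor-unique.

**Consensus differential calling.** The window arm bins the genome into
100-bp bins every 300 bp, normalizes with trimmed-mean-of-M scaling
factors from 10-kb bins, tests each bin with a conditional
negative-binomial exact test (dispersion by pooled method of moments),
keeps bins at raw p < 0.001 and chains neighbors within 2 kb. The peak
arm merges condition-consistent peaks, normalizes with median-of-ratios
and applies an NB Wald test with Benjamini–Hochberg adjustment. The
consensus keeps window regions confirmed by a significant peak feature
with the same fold-change direction.

**Histone PTM quantification.** Isoform percentage = 100 × area / sum of
areas over the peptide's isoforms. Coeluting isobaric isoforms share one
MS1 area, split in proportion to the mean of three modification-unique
MS2 fragment integrals; IP percentages can be normalized to input
percentages.

**qPCR.** Percent input = `100 * 2^(Ct'_input − Ct_IP)` with
`Ct' = Ct_input − log2(1/input fraction)`; expression fold change =
`2^(−ddCt)` with the error-bar range `2^(−ddCt ± SEM)`.

## Worked example

`examples/differential_acetylation.py` simulates the default study
(3 × 2 Mb genome, 300 acetylation peaks, 40 of them induced threefold
under knockdown, 2 replicates per condition, ~200k reads per sample) and
runs both caller arms:

```
window arm: 920 retained bins, 121 at p<0.001
  chained into 40 regions
peak arm: 40 of 300 features significant at BH 0.05
consensus: 40 regions; sensitivity 1.00 on 40 planted threefold sites
induced fraction 1.00 (all planted changes are acetylation gains)
median log2FC at planted sites 1.49 (target log2(3) = 1.58)
```

All 40 planted sites are recovered by both arms with no false consensus
regions; the estimated fold change sits near the planted log2(3). The
other scripts in `examples/` demonstrate meta-gene profiling, state
enrichment, co-occupancy, PTM quantification and the qPCR formulas the
same way, each printing the numbers it computes and what they mean.

The full pipeline is one call (or `nchipkit run --outdir DIR --seed 1`
from the shell):

```python
from nchipkit import RunConfig, run
summary = run(RunConfig(), "runs/demo", seed=1)
```

which writes ground-truth BEDs, read tables, per-stage TSVs and a
`summary.json` with planted-truth recovery metrics; re-running with the
same seed reproduces every artifact byte-identically.

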
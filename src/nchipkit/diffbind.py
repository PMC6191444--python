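"""Two-algorithm consensus differential-binding caller.

The window arm tiles the genome with 100-bp bins every 300 bp, normalizes
with trimmed-mean-of-M scaling factors computed on 10-kb bins (essentially
total-count normalization robust to a minority of changed regions), tests
each bin with a conditional negative-binomial exact test, keeps bins at
raw p < 0.001, and chains neighboring significant bins within a 2-kb
sliding window into regions.

The peak arm forms condition-consistent peaks (present in every replicate
of a condition), merges the combined peak lists into features, normalizes
counts with median-of-ratios size factors, and applies a per-feature
negative-binomial Wald test with Benjamini-Hochberg adjustment.

The consensus keeps window regions confirmed by an overlapping
significant peak feature (with agreeing direction by default) — regions
detected by both algorithms.

Test internals (dispersion by method of moments pooled across abundance
strata; conditional beta-binomial exact test; Wald test without
shrinkage) are this package's own: the scaffolding (bin sizes, scaling
bins, thresholds, merge width) is fixed, the test statistics are declared
substitutes for the quasi-likelihood machinery of the R ecosystem.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .coverage import (
    CountMatrix,
    count_reads_in_regions,
    fragment_midpoints,
    median_of_ratios_size_factors,
)
from .intervals import GenomeAssembly, GenomicInterval, IntervalSet, merge_overlapping

__all__ = [
    "WindowGrid",
    "window_scaling_factors",
    "count_in_grid",
    "call_differential_windows",
    "merge_significant_bins",
    "call_differential_peaks",
    "consensus_regions",
    "direction_summary",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowGrid:
    """Bins of ``bin_width`` bp placed every ``step`` bp along each chromosome."""

    bin_width: int = 100
    step: int = 300

    def n_bins(self, chrom_len: int) -> int:
        if chrom_len < self.bin_width:
            return 0
        return (chrom_len - self.bin_width) // self.step + 1

    def bin_starts(self, chrom_len: int) -> np.ndarray:
        return np.arange(self.n_bins(chrom_len), dtype=np.int64) * self.step


def count_in_grid(
    reads_per_sample: dict[str, pd.DataFrame],
    assembly: GenomeAssembly,
    grid: WindowGrid,
    fragment_length: int = 150,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Fragment-midpoint counts per grid bin; returns (bin table, counts)."""
    chroms, starts = [], []
    for chrom, clen in zip(assembly.chrom_names, assembly.chrom_lengths):
        bs = grid.bin_starts(clen)
        chroms.extend([chrom] * len(bs))
        starts.append(bs)
    starts_arr = np.concatenate(starts) if starts else np.array([], dtype=np.int64)
    bins = pd.DataFrame(
        {"chrom": chroms, "start": starts_arr, "end": starts_arr + grid.bin_width}
    )
    offsets = {}
    off = 0
    for chrom, clen in zip(assembly.chrom_names, assembly.chrom_lengths):
        offsets[chrom] = off
        off += grid.n_bins(clen)
    samples = list(reads_per_sample)
    counts = np.zeros((len(bins), len(samples)), dtype=np.int64)
    for j, s in enumerate(samples):
        mids = fragment_midpoints(reads_per_sample[s], assembly, fragment_length)
        for chrom, grp in mids.groupby("chrom", sort=False):
            m = grp["mid"].to_numpy(np.int64)
            k = m // grid.step
            nb = grid.n_bins(assembly.length_of(chrom))
            ok = (m - k * grid.step < grid.bin_width) & (k < nb)
            np.add.at(counts[:, j], offsets[chrom] + k[ok], 1)
    return bins, counts


def window_scaling_factors(
    reads_per_sample: dict[str, pd.DataFrame],
    assembly: GenomeAssembly,
    scale_bin: int = 10_000,
    fragment_length: int = 150,
    m_trim: float = 0.30,
    a_trim: float = 0.05,
) -> dict[str, float]:
    """Per-sample effective scaling factors from 10-kb bin counts.

    Trimmed mean of M values computed from the definition: the reference
    is the sample whose library size is closest to the mean; per sample,
    log ratios (M) and average abundances (A) over bins positive in both
    libraries are two-sidedly trimmed (30% on M, 5% on A) and the
    precision-weighted mean M gives the composition factor.  The returned
    factor is composition factor x library size, centered to geometric
    mean 1, so dividing counts by it yields normalized counts.
    """
    if len(reads_per_sample) < 2:
        raise ValueError("need >= 2 samples")
    lib = {s: len(df) for s, df in reads_per_sample.items()}
    if min(lib.values()) == 0:
        raise ValueError("a sample has zero reads")
    grid = WindowGrid(bin_width=scale_bin, step=scale_bin)
    _, counts = count_in_grid(reads_per_sample, assembly, grid, fragment_length)
    samples = list(reads_per_sample)
    N = np.array([lib[s] for s in samples], dtype=np.float64)
    ref = int(np.argmin(np.abs(N - N.mean())))
    tmm = np.ones(len(samples))
    for j in range(len(samples)):
        if j == ref:
            continue
        k, r = counts[:, j].astype(float), counts[:, ref].astype(float)
        ok = (k > 0) & (r > 0)
        k, r = k[ok], r[ok]
        p, q = k / N[j], r / N[ref]
        M = np.log2(p / q)
        A = 0.5 * np.log2(p * q)
        keep = np.ones(len(M), dtype=bool)
        for v, trim in ((M, m_trim), (A, a_trim)):
            lo, hi = np.quantile(v, [trim, 1 - trim])
            keep &= (v >= lo) & (v <= hi)
        w = 1.0 / ((N[j] - k) / (N[j] * k) + (N[ref] - r) / (N[ref] * r))
        w = w[keep]
        tmm[j] = 2 ** (np.sum(w * M[keep]) / np.sum(w)) if w.sum() > 0 else 1.0
    eff = tmm * N
    eff = eff / np.exp(np.mean(np.log(eff)))
    return dict(zip(samples, eff))


def _pooled_dispersion(
    z: np.ndarray, group_cols: list[np.ndarray], inv_f_mean: float, n_strata: int = 10
) -> np.ndarray:
    """Method-of-moments NB dispersion per bin, pooled in abundance strata.

    ``z`` is the normalized count matrix; residual variance is pooled
    within conditions.  Var(z) ~= mu * mean(1/f) + phi * mu^2, solved for
    phi per bin, then the median within each abundance stratum is assigned
    back to its bins (clipped at 0).
    """
    mu_bin = z.mean(axis=1)
    ss = np.zeros(len(z))
    df = 0
    for cols in group_cols:
        zc = z[:, cols]
        if zc.shape[1] >= 2:
            ss += ((zc - zc.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
            df += zc.shape[1] - 1
    if df == 0:
        logger.warning("single replicate per condition: dispersion unestimable, "
                       "falling back to Poisson")
        return np.zeros(len(z))
    var = ss / df
    n_samples = z.shape[1]
    strata = pd.qcut(mu_bin, min(n_strata, max(1, len(z) // 50)), duplicates="drop")
    phi = np.zeros(len(z))
    for _, idx in pd.Series(np.arange(len(z))).groupby(strata, observed=True):
        i = idx.values
        # stratum-level moment estimator: sum(var) = c*sum(mu) + phi*sum(mu^2);
        # mu_hat^2 corrected for its own sampling variance (var/n per bin)
        num = float(np.sum(var[i]) - inv_f_mean * np.sum(mu_bin[i]))
        den = float(np.sum(np.maximum(mu_bin[i] ** 2 - var[i] / n_samples, 0.0)))
        phi[i] = max(0.0, num / den) if den > 0 else 0.0
    return phi


def _exact_nb_test(
    y_b: int, n: int, p: float, size: float, mid_p: bool = True
) -> float:
    """Two-sided conditional exact test for the split of ``n`` counts.

    Under the null the knockdown total ``y_b`` given the bin total ``n``
    is binomial(n, p) in the Poisson limit and beta-binomial with
    precision ``size`` (sum of Gamma shapes) under NB dispersion.  The
    two-sided p-value sums all outcomes no more probable than the
    observed one; the mid-p variant counts the observed outcome with
    weight 1/2, centering the discrete null.
    """
    if n == 0:
        return 1.0
    ks = np.arange(n + 1)
    if not np.isfinite(size) or size > 1e8:
        pmf = stats.binom.pmf(ks, n, p)
    else:
        pmf = stats.betabinom.pmf(ks, n, size * p, size * (1 - p))
    p_obs = pmf[y_b]
    tail = pmf[pmf <= p_obs * (1 + 1e-12)].sum()
    if mid_p:
        tail -= 0.5 * p_obs
    return float(min(1.0, max(tail, np.finfo(float).tiny)))


def call_differential_windows(
    reads_control: dict[str, pd.DataFrame],
    reads_knockdown: dict[str, pd.DataFrame],
    assembly: GenomeAssembly,
    factors: dict[str, float] | None = None,
    grid: WindowGrid = WindowGrid(),
    alpha: float = 0.001,
    min_mean_count: float = 5.0,
    fragment_length: int = 150,
    mid_p: bool = True,
) -> pd.DataFrame:
    """Per-bin differential test; returns the table of all retained bins.

    Columns: chrom, start, end, mean_control, mean_knockdown (normalized),
    log2_fold_change, p_value, significant (raw p < ``alpha``).
    """
    all_reads = {**reads_control, **reads_knockdown}
    if factors is None:
        factors = window_scaling_factors(all_reads, assembly,
                                         fragment_length=fragment_length)
    samples = list(all_reads)
    f = np.array([factors[s] for s in samples])
    cols_a = np.array([i for i, s in enumerate(samples) if s in reads_control])
    cols_b = np.array([i for i, s in enumerate(samples) if s in reads_knockdown])
    if len(cols_a) < 2 or len(cols_b) < 2:
        logger.warning("fewer than 2 replicates in a condition; "
                       "dispersion falls back toward Poisson")
    bins, counts = count_in_grid(all_reads, assembly, grid, fragment_length)
    z = counts / f[None, :]
    keep = z.mean(axis=1) >= min_mean_count
    bins, counts, z = bins[keep].reset_index(drop=True), counts[keep], z[keep]
    if len(bins) == 0:
        return bins.assign(mean_control=[], mean_knockdown=[],
                           log2_fold_change=[], p_value=[], significant=[])
    inv_f_mean = float(np.mean(1.0 / f))
    phi = _pooled_dispersion(z, [cols_a, cols_b], inv_f_mean)
    e_a, e_b = f[cols_a].sum(), f[cols_b].sum()
    p_null = e_b / (e_a + e_b)
    y_a = counts[:, cols_a].sum(axis=1)
    y_b = counts[:, cols_b].sum(axis=1)
    n_tot = y_a + y_b
    n_shapes = len(cols_a) + len(cols_b)
    pvals = np.empty(len(bins))
    for i in range(len(bins)):
        size = n_shapes / phi[i] if phi[i] > 1e-8 else np.inf
        pvals[i] = _exact_nb_test(int(y_b[i]), int(n_tot[i]), p_null, size, mid_p)
    mu_a = z[:, cols_a].mean(axis=1)
    mu_b = z[:, cols_b].mean(axis=1)
    pc = 0.5
    out = bins.copy()
    out["mean_control"] = mu_a
    out["mean_knockdown"] = mu_b
    out["log2_fold_change"] = np.log2((mu_b + pc) / (mu_a + pc))
    out["p_value"] = pvals
    out["significant"] = pvals < alpha
    return out


def merge_significant_bins(
    bins: pd.DataFrame,
    assembly: GenomeAssembly,
    window: int = 2000,
) -> IntervalSet:
    """Chain significant bins whose starts are within ``window`` bp.

    Neighboring is measured start-to-start on the chromosome-sorted grid;
    each chain becomes one region from the first bin's start to the last
    bin's end, carrying the chain's most extreme log2 fold change as score.
    """
    sig = bins.loc[bins["significant"]].sort_values(["chrom", "start"])
    regions: list[GenomicInterval] = []
    for chrom, grp in sig.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        lfc = grp["log2_fold_change"].to_numpy()
        chain_start = 0
        for i in range(1, len(grp) + 1):
            if i == len(grp) or starts[i] - starts[i - 1] > window:
                chunk = slice(chain_start, i)
                peak_lfc = lfc[chunk][np.argmax(np.abs(lfc[chunk]))]
                regions.append(
                    GenomicInterval(chrom, int(starts[chain_start]),
                                    int(ends[i - 1]), score=float(peak_lfc))
                )
                chain_start = i
    return IntervalSet(regions, assembly, name="window_regions").sorted()


def _condition_consistent(peak_sets: list[IntervalSet]) -> IntervalSet:
    """Peaks of the first replicate overlapping >= 1 bp a peak in every other."""
    from .intervals import intersect

    base = peak_sets[0]
    for other in peak_sets[1:]:
        base = intersect(base, other)
    return base


def call_differential_peaks(
    peaks_by_condition: dict[str, list[IntervalSet]],
    reads_by_condition: dict[str, dict[str, pd.DataFrame]],
    alpha_adj: float = 0.05,
    fragment_length: int = 150,
) -> pd.DataFrame:
    """Feature-level NB Wald test on merged condition-consistent peaks.

    Conditions are tested in the order of ``peaks_by_condition`` keys:
    the second condition over the first (positive fold change = gain in
    the second).  Returns one row per merged feature with normalized
    condition means, log2 fold change, Wald p-value and BH-adjusted p.
    """
    conditions = list(peaks_by_condition)
    if len(conditions) != 2:
        raise ValueError("exactly two conditions required")
    n_samples = sum(len(v) for v in reads_by_condition.values())
    if n_samples < 2:
        raise ValueError("need >= 2 samples in total")
    assembly = peaks_by_condition[conditions[0]][0].assembly
    consistent = [
        _condition_consistent(peaks_by_condition[c]) for c in conditions
    ]
    combined = IntervalSet(
        [iv for s in consistent for iv in s], assembly, name="features"
    )
    features = merge_overlapping(combined)
    if len(features) == 0:
        raise ValueError("no condition-consistent peaks")
    all_reads: dict[str, pd.DataFrame] = {}
    cond_of: dict[str, str] = {}
    for cond in conditions:
        for name, df in reads_by_condition[cond].items():
            all_reads[name] = df
            cond_of[name] = cond
    cm = count_reads_in_regions(all_reads, features, fragment_length)
    cm = median_of_ratios_size_factors(cm)
    z = cm.normalized
    cols = {c: np.array([j for j, s in enumerate(cm.samples) if cond_of[s] == c])
            for c in conditions}
    inv_f_mean = float(np.mean(1.0 / np.asarray(cm.size_factors)))
    phi = _pooled_dispersion(z, [cols[c] for c in conditions], inv_f_mean)
    mu_a = z[:, cols[conditions[0]]].mean(axis=1)
    mu_b = z[:, cols[conditions[1]]].mean(axis=1)
    n_a, n_b = len(cols[conditions[0]]), len(cols[conditions[1]])
    pc = 0.5
    lfc = np.log2((mu_b + pc) / (mu_a + pc))
    se = np.sqrt(
        (1.0 / (mu_a + pc) + phi) / n_a + (1.0 / (mu_b + pc) + phi) / n_b
    ) / np.log(2)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = lfc / se
    pvals = 2 * stats.norm.sf(np.abs(wald))
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    padj = multipletests(pvals, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in cm.regions],
            "start": [iv.start for iv in cm.regions],
            "end": [iv.end for iv in cm.regions],
            f"mean_{conditions[0]}": mu_a,
            f"mean_{conditions[1]}": mu_b,
            "log2_fold_change": lfc,
            "p_value": pvals,
            "p_adjusted": padj,
            "significant": padj < alpha_adj,
        }
    )
    return out


def _regions_from_table(df: pd.DataFrame, assembly: GenomeAssembly,
                        name: str) -> IntervalSet:
    ivs = [
        GenomicInterval(r.chrom, int(r.start), int(r.end),
                        score=float(r.log2_fold_change))
        for r in df.itertuples()
    ]
    return IntervalSet(ivs, assembly, name=name).sorted()


def consensus_regions(
    window_regions: IntervalSet,
    peak_table: pd.DataFrame,
    require_same_direction: bool = True,
) -> IntervalSet:
    """Window-method regions confirmed by the peak method.

    A window region is kept iff it overlaps (>= 1 bp) a BH-significant
    peak feature; with ``require_same_direction`` the two methods' fold
    changes must also agree in sign.
    """
    sig = peak_table.loc[peak_table["significant"]]
    feats = _regions_from_table(sig, window_regions.assembly, "peak_features")
    kept = []
    for iv in window_regions:
        for feat in feats:
            if iv.overlaps(feat):
                if (not require_same_direction
                        or np.sign(iv.score or 0) == np.sign(feat.score or 0)):
                    kept.append(iv)
                    break
    return IntervalSet(kept, window_regions.assembly, name="consensus").sorted()


def direction_summary(consensus: IntervalSet) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-region induction/repression labels and overall fractions."""
    if len(consensus) == 0:
        raise ValueError("empty consensus set")
    rows = [
        {
            "chrom": iv.chrom,
            "start": iv.start,
            "end": iv.end,
            "log2_fold_change": iv.score,
            "direction": "induced" if (iv.score or 0) > 0 else "repressed",
        }
        for iv in consensus
    ]
    df = pd.DataFrame(rows)
    frac = {
        "induced": float((df["direction"] == "induced").mean()),
        "repressed": float((df["direction"] == "repressed").mean()),
    }
    return df, frac
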
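import numpy as np
import pandas as pd
import pytest

from nchipkit.diffbind import (
    WindowGrid,
    _exact_nb_test,
    _pooled_dispersion,
    call_differential_peaks,
    call_differential_windows,
    consensus_regions,
    count_in_grid,
    direction_summary,
    merge_significant_bins,
    window_scaling_factors,
)
from nchipkit.intervals import GenomeAssembly, GenomicInterval, IntervalSet


def random_reads(rng, assembly, n):
    ci = rng.integers(0, len(assembly.chrom_names), n)
    chroms = np.array(assembly.chrom_names)[ci]
    lens = np.array(assembly.chrom_lengths)[ci]
    pos = (rng.random(n) * (lens - 150)).astype(int) + 75
    return pd.DataFrame(
        {"chrom": chroms, "pos": pos,
         "strand": np.where(rng.random(n) < 0.5, "+", "-")}
    )


class TestScalingFactors:
    def test_identical_samples_unit_factors(self, toy_assembly):
        rng = np.random.default_rng(0)
        df = random_reads(rng, toy_assembly, 20_000)
        f = window_scaling_factors({"a": df, "b": df.copy()}, toy_assembly)
        assert np.allclose(list(f.values()), 1.0)

    def test_global_doubling_closed_form(self, toy_assembly):
        rng = np.random.default_rng(1)
        df = random_reads(rng, toy_assembly, 15_000)
        doubled = pd.concat([df, df], ignore_index=True)
        f = window_scaling_factors({"a": df, "b": doubled}, toy_assembly)
        assert f["a"] == pytest.approx(1 / np.sqrt(2), rel=1e-6)
        assert f["b"] == pytest.approx(np.sqrt(2), rel=1e-6)

    def test_matches_naive_trimmed_mean_reimplementation(self, toy_assembly):
        rng = np.random.default_rng(2)
        r = {"a": random_reads(rng, toy_assembly, 12_000),
             "b": random_reads(rng, toy_assembly, 18_000)}
        got = window_scaling_factors(r, toy_assembly)
        # independent naive computation on the same 10-kb bin counts
        grid = WindowGrid(10_000, 10_000)
        _, counts = count_in_grid(r, toy_assembly, grid)
        N = np.array([12_000, 18_000], float)
        ref = int(np.argmin(np.abs(N - N.mean())))
        j = 1 - ref
        k, rr = counts[:, j].astype(float), counts[:, ref].astype(float)
        ok = (k > 0) & (rr > 0)
        k, rr = k[ok], rr[ok]
        M = np.log2((k / N[j]) / (rr / N[ref]))
        A = 0.5 * np.log2((k / N[j]) * (rr / N[ref]))
        keep = np.ones(len(M), bool)
        for v, tr in ((M, 0.30), (A, 0.05)):
            lo, hi = np.quantile(v, [tr, 1 - tr])
            keep &= (v >= lo) & (v <= hi)
        w = 1.0 / ((N[j] - k) / (N[j] * k) + (N[ref] - rr) / (N[ref] * rr))
        tmm_j = 2 ** (np.sum(w[keep] * M[keep]) / np.sum(w[keep]))
        eff = np.ones(2)
        eff[j] = tmm_j
        eff *= N
        eff /= np.exp(np.mean(np.log(eff)))
        assert got["a"] == pytest.approx(eff[0], rel=1e-9)
        assert got["b"] == pytest.approx(eff[1], rel=1e-9)

    def test_zero_read_sample_rejected(self, toy_assembly):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError, match="zero reads"):
            window_scaling_factors(
                {"a": random_reads(rng, toy_assembly, 100),
                 "b": random_reads(rng, toy_assembly, 0)},
                toy_assembly,
            )


class TestWindowTest:
    def test_grid_defaults_leave_gaps(self, toy_assembly):
        grid = WindowGrid()
        assert grid.bin_width == 100 and grid.step == 300
        starts = grid.bin_starts(1000)
        assert list(starts) == [0, 300, 600, 900]

    def test_all_zero_bin_has_p_one(self):
        assert _exact_nb_test(0, 0, 0.5, np.inf) == 1.0

    def test_identical_reads_produce_no_calls(self, toy_assembly):
        rng = np.random.default_rng(4)
        df = random_reads(rng, toy_assembly, 30_000)
        out = call_differential_windows(
            {"c1": df, "c2": df.copy()}, {"k1": df.copy(), "k2": df.copy()},
            toy_assembly,
        )
        assert not out["significant"].any()

    def test_dispersion_estimator_recovers_truth(self):
        rng = np.random.default_rng(5)
        phi, mu = 0.1, 30.0
        r = 1 / phi
        k = rng.negative_binomial(r, r / (r + mu), size=(5000, 4)).astype(float)
        est = _pooled_dispersion(k, [np.array([0, 1]), np.array([2, 3])], 1.0)
        assert np.median(est) == pytest.approx(phi, rel=0.25)


class TestMergeBins:
    def bins_df(self, rows):
        df = pd.DataFrame(rows, columns=["chrom", "start"])
        df["end"] = df["start"] + 100
        df["log2_fold_change"] = 1.0
        df["significant"] = True
        return df

    def test_nearby_bins_chain(self, toy_assembly):
        out = merge_significant_bins(
            self.bins_df([("chr1", 1000), ("chr1", 1300)]), toy_assembly
        )
        assert [(iv.start, iv.end) for iv in out] == [(1000, 1400)]

    def test_distant_bins_stay_separate(self, toy_assembly):
        out = merge_significant_bins(
            self.bins_df([("chr1", 1000), ("chr1", 6000)]), toy_assembly
        )
        assert [(iv.start, iv.end) for iv in out] == [(1000, 1100), (6000, 6100)]

    def test_matches_brute_force_chaining(self, toy_assembly):
        rng = np.random.default_rng(6)
        starts = np.sort(rng.choice(np.arange(0, 99_000, 300), 120, replace=False))
        df = self.bins_df([("chr1", int(s)) for s in starts])
        out = merge_significant_bins(df, toy_assembly, window=2000)
        # oracle: explicit chain construction
        want = []
        chain = [starts[0]]
        for s in starts[1:]:
            if s - chain[-1] <= 2000:
                chain.append(s)
            else:
                want.append((chain[0], chain[-1] + 100))
                chain = [s]
        want.append((chain[0], chain[-1] + 100))
        assert [(iv.start, iv.end) for iv in out] == want


class TestPeakMethod:
    def test_identical_counts_give_null_result(self, toy_assembly):
        rng = np.random.default_rng(7)
        df = random_reads(rng, toy_assembly, 5000)
        peaks = IntervalSet(
            [GenomicInterval("chr1", s, s + 800) for s in range(0, 50_000, 5000)],
            toy_assembly,
        )
        out = call_differential_peaks(
            {"ctrl": [peaks, peaks], "kd": [peaks, peaks]},
            {"ctrl": {"c1": df, "c2": df.copy()},
             "kd": {"k1": df.copy(), "k2": df.copy()}},
        )
        assert np.all(np.abs(out["log2_fold_change"]) < 1e-9)
        assert np.allclose(out["p_value"], 1.0)
        assert not out["significant"].any()

    def test_condition_consistency_requires_all_replicates(self, toy_assembly):
        rng = np.random.default_rng(8)
        df = random_reads(rng, toy_assembly, 5000)
        p1 = IntervalSet([GenomicInterval("chr1", 0, 1000),
                          GenomicInterval("chr1", 5000, 6000)], toy_assembly)
        p2 = IntervalSet([GenomicInterval("chr1", 100, 900)], toy_assembly)
        out = call_differential_peaks(
            {"ctrl": [p1, p2], "kd": [p1, p2]},
            {"ctrl": {"c1": df, "c2": df.copy()},
             "kd": {"k1": df.copy(), "k2": df.copy()}},
        )
        # the peak absent from replicate 2 is dropped
        assert len(out) == 1 and out.iloc[0]["start"] == 0


class TestConsensus:
    def peak_table(self, rows):
        df = pd.DataFrame(rows, columns=["chrom", "start", "end",
                                         "log2_fold_change", "significant"])
        return df

    def window_set(self, toy_assembly, rows):
        return IntervalSet(
            [GenomicInterval(c, s, e, score=l) for c, s, e, l in rows],
            toy_assembly,
        )

    def test_disjoint_inputs_give_empty_consensus(self, toy_assembly):
        w = self.window_set(toy_assembly, [("chr1", 0, 500, 1.0)])
        p = self.peak_table([("chr1", 10_000, 11_000, 1.0, True)])
        assert len(consensus_regions(w, p)) == 0

    def test_identical_inputs_pass_through(self, toy_assembly):
        w = self.window_set(toy_assembly, [("chr1", 100, 600, 1.0),
                                           ("chr2", 0, 300, -2.0)])
        p = self.peak_table([("chr1", 100, 600, 0.9, True),
                             ("chr2", 0, 300, -1.5, True)])
        out = consensus_regions(w, p)
        assert [(iv.start, iv.end) for iv in out] == [(100, 600), (0, 300)]

    def test_direction_disagreement_filtered(self, toy_assembly):
        w = self.window_set(toy_assembly, [("chr1", 100, 600, 1.0)])
        p = self.peak_table([("chr1", 100, 600, -0.9, True)])
        assert len(consensus_regions(w, p)) == 0
        assert len(consensus_regions(w, p, require_same_direction=False)) == 1

    def test_matches_brute_force_overlap_filter(self, toy_assembly):
        rng = np.random.default_rng(9)
        w_rows = [("chr1", int(s), int(s) + 400, 1.0)
                  for s in rng.integers(0, 99_000, 30)]
        p_rows = [("chr1", int(s), int(s) + 400, 1.0, bool(rng.random() < 0.5))
                  for s in rng.integers(0, 99_000, 30)]
        w = self.window_set(toy_assembly, w_rows)
        p = self.peak_table(p_rows)
        got = {(iv.start, iv.end) for iv in consensus_regions(w, p)}
        want = {
            (s, e) for _, s, e, _ in w_rows
            if any(ps < e and s < pe for _, ps, pe, _, sig in p_rows if sig)
        }
        assert got == want

    def test_direction_summary_fractions(self, toy_assembly):
        gains = self.window_set(
            toy_assembly, [("chr1", i * 1000, i * 1000 + 500, 1.0) for i in range(10)]
        )
        df, frac = direction_summary(gains)
        assert frac["induced"] == 1.0 and len(df) == 10
        rng = np.random.default_rng(10)
        signs = rng.choice([-1.0, 1.0], 400)
        mixed = self.window_set(
            toy_assembly,
            [("chr1", i * 200, i * 200 + 100, float(s))
             for i, s in enumerate(signs)],
        )
        _, frac = direction_summary(mixed)
        # symmetric null: induced fraction within a 3-sigma binomial band
        assert abs(frac["induced"] - 0.5) <= 3 * np.sqrt(0.25 / 400)
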
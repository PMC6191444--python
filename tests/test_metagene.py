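import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from nchipkit.coverage import CoverageTrack
from nchipkit.intervals import GenomeAssembly, GenomicInterval, IntervalSet
from nchipkit.metagene import (
    MetageneMatrix,
    build_metagene,
    cluster_metagene,
    compare_body_vs_downstream,
)


def track_from(assembly, arrays):
    return CoverageTrack(assembly, {c: np.asarray(a, float) for c, a in arrays.items()})


@pytest.fixture
def long_assembly():
    return GenomeAssembly(("chr1",), (40_000,))


class TestBuildMetagene:
    def test_constant_track_gives_constant_matrix(self, long_assembly):
        track = track_from(long_assembly, {"chr1": np.full(40_000, 2.5)})
        genes = IntervalSet(
            [GenomicInterval("chr1", 10_000, 16_000, strand="+", label="g1")],
            long_assembly,
        )
        m = build_metagene(track, genes)
        assert m.values.shape == (1, 360)
        assert np.allclose(m.values, 2.5)

    def test_600bp_gene_body_bins_are_5bp_slices(self, long_assembly):
        rng = np.random.default_rng(0)
        arr = rng.random(40_000)
        track = track_from(long_assembly, {"chr1": arr})
        start, end = 10_000, 10_600
        genes = IntervalSet(
            [GenomicInterval("chr1", start, end, strand="+", label="g")],
            long_assembly,
        )
        m = build_metagene(track, genes)
        body = m.values[0, m.body_slice()]
        for k in range(120):
            want = arr[start + 5 * k: start + 5 * k + 5].mean()
            assert body[k] == pytest.approx(want, abs=1e-12)

    def test_minus_strand_row_is_reversed_plus_row(self, long_assembly):
        rng = np.random.default_rng(1)
        arr = np.repeat(rng.random(400), 100)  # step signal
        track = track_from(long_assembly, {"chr1": arr})
        plus = IntervalSet(
            [GenomicInterval("chr1", 12_000, 19_000, strand="+")], long_assembly
        )
        minus = IntervalSet(
            [GenomicInterval("chr1", 12_000, 19_000, strand="-")], long_assembly
        )
        mp = build_metagene(track, plus)
        mm = build_metagene(track, minus)
        assert np.allclose(mm.values[0], mp.values[0][::-1])

    def test_body_mean_conservation(self, long_assembly):
        rng = np.random.default_rng(2)
        arr = rng.random(40_000) * 10
        track = track_from(long_assembly, {"chr1": arr})
        genes = []
        for i in range(50):
            L = int(rng.integers(120, 5000))
            s = int(rng.integers(6000, 34_000 - L))
            genes.append(
                GenomicInterval("chr1", s, s + L, strand="+" if i % 2 else "-",
                                label=f"g{i}")
            )
        m = build_metagene(track, IntervalSet(genes, long_assembly))
        for row, iv in zip(m.values, genes):
            body_mean = row[m.body_slice()].mean()
            assert body_mean == pytest.approx(
                arr[iv.start:iv.end].mean(), abs=1e-9
            )

    def test_short_and_edge_genes_excluded(self, long_assembly):
        track = track_from(long_assembly, {"chr1": np.ones(40_000)})
        genes = IntervalSet(
            [
                GenomicInterval("chr1", 10_000, 10_050, strand="+"),  # too short
                GenomicInterval("chr1", 100, 8000, strand="+"),  # flank off edge
                GenomicInterval("chr1", 10_000, 16_000, strand="+"),
            ],
            long_assembly,
        )
        m = build_metagene(track, genes)
        assert len(m.genes) == 1

    def test_no_eligible_genes_is_error(self, long_assembly):
        track = track_from(long_assembly, {"chr1": np.ones(40_000)})
        genes = IntervalSet(
            [GenomicInterval("chr1", 10_000, 10_050, strand="+")], long_assembly
        )
        with pytest.raises(ValueError, match="eligible"):
            build_metagene(track, genes)


class TestCluster:
    def planted(self, n_per_group=20, seed=0):
        rng = np.random.default_rng(seed)
        fb, bb = 120, 120
        cols = 2 * fb + bb
        high_body = np.zeros((n_per_group, cols)) + 0.1
        high_body[:, fb:fb + bb] = 5.0
        flat = np.full((n_per_group, cols), 1.0)
        X = np.vstack([high_body, flat]) + rng.normal(0, 0.01, (2 * n_per_group, cols))
        labels = np.array([0] * n_per_group + [1] * n_per_group)
        m = MetageneMatrix(
            genes=[f"g{i}" for i in range(2 * n_per_group)],
            strands=["+"] * (2 * n_per_group),
            values=X,
        )
        return m, labels

    def test_planted_groups_recovered_exactly(self):
        m, truth = self.planted()
        out = cluster_metagene(m, k=2, seed=0)
        assert adjusted_rand_score(truth, out.cluster_labels) == 1.0
        # cluster 1 is the high-body group by the ordering convention
        assert set(out.cluster_labels[truth == 0]) == {1}

    def test_k_equals_rows_gives_singletons(self):
        m, _ = self.planted(n_per_group=3)
        out = cluster_metagene(m, k=6, seed=0)
        assert len(set(out.cluster_labels)) == 6

    def test_same_seed_same_labels(self):
        m, _ = self.planted(seed=5)
        a = cluster_metagene(m, k=3, seed=11).cluster_labels
        b = cluster_metagene(m, k=3, seed=11).cluster_labels
        assert (a == b).all()


class TestBodyVsDownstream:
    def build(self, deltas, width=500, base=1.0):
        """Genes whose 3' body window exceeds the downstream window by delta."""
        n = len(deltas)
        clen = (n + 2) * 10_000
        asm = GenomeAssembly(("chr1",), (clen,))
        arr = np.full(clen, base)
        genes = []
        for i, d in enumerate(deltas):
            start = 10_000 * (i + 1)
            end = start + 4000
            arr[end - width:end] = base + d
            genes.append(GenomicInterval("chr1", start, end, strand="+", label=f"g{i}"))
        track = track_from(asm, {"chr1": arr})
        return track, IntervalSet(genes, asm)

    def test_identical_windows_give_null_p(self):
        track, genes = self.build([0.0] * 10)
        pair = compare_body_vs_downstream(track, genes, window_bp=500)
        assert pair.wilcoxon_signed_rank_p == 1.0

    def test_uniform_positive_shift_is_significant(self):
        rng = np.random.default_rng(3)
        deltas = rng.uniform(0.5, 1.5, 25)
        track, genes = self.build(list(deltas))
        pair = compare_body_vs_downstream(track, genes, window_bp=500)
        assert (pair.body_mean > pair.downstream_mean).all()
        # two-sided p < 0.02 implies the directional p < 0.01 at n=25
        assert pair.wilcoxon_signed_rank_p < 0.02
        assert pair.rank_sum_p < 0.02

    def test_signed_rank_matches_enumeration_for_small_n(self):
        rng = np.random.default_rng(4)
        deltas = rng.uniform(-1, 1, 8)
        deltas = np.where(np.abs(deltas) < 0.05, 0.2, deltas)  # no zeros/ties
        track, genes = self.build(list(deltas))
        pair = compare_body_vs_downstream(track, genes, window_bp=500)
        diffs = pair.body_mean - pair.downstream_mean
        ranks = np.argsort(np.argsort(np.abs(diffs))) + 1
        t_obs = ranks[diffs > 0].sum()
        # exact null: enumerate all sign assignments of the ranks
        tot = ranks.sum()
        dist = np.zeros(int(tot) + 1)
        for signs in itertools.product([0, 1], repeat=len(ranks)):
            t = int(np.sum(ranks * np.array(signs)))
            dist[t] += 1
        dist /= dist.sum()
        cdf = dist.cumsum()
        t_obs = int(round(t_obs))
        p_two = 2 * min(cdf[t_obs], 1 - (cdf[t_obs - 1] if t_obs else 0.0))
        p_two = min(1.0, p_two)
        assert pair.wilcoxon_signed_rank_p == pytest.approx(p_two, rel=1e-9)

    def test_window_wider_than_gene_excludes_gene(self):
        track, genes = self.build([1.0, 1.0])
        with pytest.raises(ValueError):
            compare_body_vs_downstream(track, genes, window_bp=5000)
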
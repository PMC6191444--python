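"""Synthetic genomes, chromatin annotations, reads and peptide tables.

Everything downstream of read alignment and peak calling is exercised
against data generated here with planted ground truth: a small
multi-chromosome genome carrying a hidden 10-state chromatin annotation,
stranded gene models, peak sets for two binding factors and two
acetylation marks, replicate read-start tables for a control and a
knockdown condition with differential acetylation planted at known sites,
and histone-peptide chromatogram-area tables including coeluting isobaric
pairs.

All randomness flows from one ``numpy.random.Generator`` seeded by a
single integer, so a fixed seed reproduces every table bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import GenomeAssembly, GenomicInterval, IntervalSet

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_genome",
    "simulate_counts",
    "simulate_peptide_table",
    "PROMOTER_ENHANCER_STATES",
]

# states the peak placer treats as "promoter/enhancer-like" (positive
# control for the state-enrichment stage)
PROMOTER_ENHANCER_STATES = (3, 4, 5)

STATE_TILE = 1000  # bp; annotation is a Markov chain over 1-kb tiles


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the study conditions."""

    seed: int = 0
    chrom_lengths: tuple[int, ...] = (2_000_000, 2_000_000, 2_000_000)
    n_states: int = 10
    n_genes: int = 200
    n_peaks: int = 300  # per factor
    n_differential_sites: int = 40
    effect_fold: float = 3.0
    replicates: int = 2  # per condition
    reads_per_sample: int = 200_000
    fragment_length: int = 150
    nb_dispersion: float = 0.02
    state_enrichment_fold: float = 5.0  # peak placement bias toward target states
    peak_fraction_of_reads: float = 0.5  # fraction of reads in peaks vs background
    shared_peak_fraction: float = 0.7  # fraction of factor-B peaks shared with A
    library_jitter: float = 0.2  # +/- fractional library-size jitter

    def __post_init__(self) -> None:
        if self.effect_fold < 1:
            raise ValueError("effect_fold must be >= 1 (1 plants no change)")
        if min(self.n_genes, self.n_peaks, self.n_differential_sites,
               self.replicates, self.reads_per_sample) < 0:
            raise ValueError("counts must be >= 0")
        if self.n_differential_sites > self.n_peaks:
            raise ValueError("cannot plant more differential sites than peaks")

    @property
    def assembly(self) -> GenomeAssembly:
        names = tuple(f"chr{i + 1}" for i in range(len(self.chrom_lengths)))
        return GenomeAssembly(names, tuple(self.chrom_lengths))


@dataclass
class GroundTruth:
    """Planted truth for every downstream stage."""

    assembly: GenomeAssembly
    state_segments: IntervalSet
    peaks: dict[str, IntervalSet]  # factor name -> true peak set
    differential_sites: IntervalSet  # per-site fold in .score
    gene_models: IntervalSet
    tile_states: dict[str, np.ndarray]  # per-chrom state per 1-kb tile


def _markov_states(rng: np.random.Generator, n_tiles: int, n_states: int) -> np.ndarray:
    """First-order Markov chain over tiles with sticky diagonal."""
    stay = 0.85  # mean segment length ~6.7 kb, comparable to real state blocks
    states = np.empty(n_tiles, dtype=np.int64)
    states[0] = rng.integers(1, n_states + 1)
    move = rng.random(n_tiles - 1)
    jumps = rng.integers(1, n_states, size=n_tiles - 1)
    for i in range(1, n_tiles):
        if move[i - 1] < stay:
            states[i] = states[i - 1]
        else:
            # jump to a uniformly chosen *different* state
            s = states[i - 1] + jumps[i - 1]
            states[i] = ((s - 1) % n_states) + 1
    return states


def _run_length_segments(
    chrom: str, states: np.ndarray, tile: int, chrom_len: int
) -> list[GenomicInterval]:
    segs = []
    change = np.flatnonzero(np.diff(states)) + 1
    bounds = np.concatenate(([0], change, [len(states)]))
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        start = int(lo) * tile
        end = min(int(hi) * tile, chrom_len)
        segs.append(GenomicInterval(chrom, start, end, label=f"state{states[lo]}"))
    return segs


def simulate_genome(cfg: SimulationConfig) -> tuple[GenomeAssembly, GroundTruth]:
    """Build the genome: states, genes, peaks and planted differential sites.

    Peaks are placed on distinct 1-kb tiles sampled with weight
    ``state_enrichment_fold`` when the tile's state is promoter/enhancer-like
    and weight 1 otherwise, and each peak lies entirely within its tile —
    so the expected observed/expected state enrichment is a closed form of
    the placement weights.  Factor peak sets: ``factor_a`` and ``factor_b``
    (the two binding factors, sharing ``shared_peak_fraction`` of B's peaks
    with A) plus two acetylation marks ``mark_k27ac`` and ``mark_zac`` that
    share most of their territory; differential sites are a subset of the
    acetylation peaks.
    """
    rng = np.random.default_rng(cfg.seed)
    assembly = cfg.assembly

    tile_states: dict[str, np.ndarray] = {}
    segments: list[GenomicInterval] = []
    for chrom, clen in zip(assembly.chrom_names, assembly.chrom_lengths):
        n_tiles = clen // STATE_TILE
        st = _markov_states(rng, n_tiles, cfg.n_states)
        tile_states[chrom] = st
        segments.extend(_run_length_segments(chrom, st, STATE_TILE, clen))
    state_segments = IntervalSet(segments, assembly, name="chromatin_states")

    # genes: uniform placement, non-overlapping, min length 2 kb
    genes = _place_genes(rng, assembly, cfg.n_genes)

    # peaks: one distinct 1-kb tile per peak, each peak inside its tile.
    # Placement is two-stage so the planted state preference is exact: a
    # peak lands in a promoter/enhancer-like tile with probability
    # p* = f*W_t / (f*W_t + W_o) where f is the enrichment fold and
    # W_t/W_o the tile counts of the two classes, then uniformly among
    # the unused tiles of its class.
    tile_index = _tile_catalog(assembly, tile_states)
    is_target = np.isin(tile_index["state"], PROMOTER_ENHANCER_STATES)
    f = cfg.state_enrichment_fold
    n_t, n_o = int(is_target.sum()), int((~is_target).sum())
    p_target = f * n_t / (f * n_t + n_o) if n_t + n_o else 0.0

    def draw_peaks(n: int, taken: set[int], name: str) -> IntervalSet:
        ivs = []
        if n > 0:
            in_target = rng.random(n) < p_target
            chosen = []
            for want_target in in_target:
                pool = np.flatnonzero(
                    (is_target if want_target else ~is_target)
                )
                pool = pool[~np.isin(pool, list(taken))] if taken else pool
                if len(pool) == 0:
                    # class exhausted: fall back to any free tile
                    pool = np.flatnonzero(
                        ~np.isin(np.arange(len(is_target)), list(taken))
                    )
                if len(pool) == 0:
                    raise ValueError(
                        "too many peaks for the genome (packing infeasible)"
                    )
                t = int(pool[rng.integers(0, len(pool))])
                taken.add(t)
                chosen.append(t)
            widths = rng.integers(400, 1001, size=n)
            for t, wd in zip(chosen, widths):
                chrom = tile_index["chrom"][t]
                tstart = tile_index["start"][t]
                off = rng.integers(0, STATE_TILE - wd + 1)
                ivs.append(GenomicInterval(chrom, int(tstart + off), int(tstart + off + wd)))
        return IntervalSet(ivs, assembly, name=name).sorted()

    taken_a: set[int] = set()
    peaks_a = draw_peaks(cfg.n_peaks, taken_a, "factor_a")
    # factor B shares a fraction of A's peaks (slightly jittered) + unique ones
    n_shared = int(round(cfg.shared_peak_fraction * cfg.n_peaks))
    shared_idx = rng.choice(len(peaks_a), size=min(n_shared, len(peaks_a)), replace=False)
    shared_b = []
    for i in sorted(int(x) for x in shared_idx):
        iv = peaks_a[i]
        jit = int(rng.integers(-50, 51))
        start = max(0, iv.start + jit)
        end = min(assembly.length_of(iv.chrom), iv.end + jit)
        if end > start:
            shared_b.append(GenomicInterval(iv.chrom, start, end))
    unique_b = draw_peaks(cfg.n_peaks - len(shared_b), taken_a, "tmp")
    peaks_b = IntervalSet(list(shared_b) + list(unique_b), assembly, name="factor_b").sorted()

    # acetylation marks: K27ac on its own tiles; Zac mostly shared with K27ac
    taken_ac = set(taken_a)
    mark_k27 = draw_peaks(cfg.n_peaks, taken_ac, "mark_k27ac")
    zac_shared = [iv for i, iv in enumerate(mark_k27) if i % 10 < 8]  # 80% shared
    zac_unique = draw_peaks(cfg.n_peaks - len(zac_shared), taken_ac, "tmp")
    mark_zac = IntervalSet(list(zac_shared) + list(zac_unique), assembly, name="mark_zac").sorted()

    # differential acetylation: a subset of K27ac peaks, whole-peak induction
    diff_idx = sorted(
        int(x) for x in rng.choice(len(mark_k27), size=cfg.n_differential_sites, replace=False)
    ) if cfg.n_differential_sites else []
    diff_ivs = [
        GenomicInterval(mark_k27[i].chrom, mark_k27[i].start, mark_k27[i].end,
                        score=cfg.effect_fold, label=f"diff{i}")
        for i in diff_idx
    ]
    differential = IntervalSet(diff_ivs, assembly, name="differential_sites")

    truth = GroundTruth(
        assembly=assembly,
        state_segments=state_segments,
        peaks={
            "factor_a": peaks_a,
            "factor_b": peaks_b,
            "mark_k27ac": mark_k27,
            "mark_zac": mark_zac,
        },
        differential_sites=differential,
        gene_models=genes,
        tile_states=tile_states,
    )
    return assembly, truth


def _place_genes(
    rng: np.random.Generator, assembly: GenomeAssembly, n_genes: int
) -> IntervalSet:
    """Uniform non-overlapping gene placement, lengths 2-20 kb, random strand."""
    ivs: list[GenomicInterval] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in assembly.chrom_names}
    attempts = 0
    while len(ivs) < n_genes:
        attempts += 1
        if attempts > 50 * max(n_genes, 1):
            raise ValueError("too many genes for the genome (packing infeasible)")
        ci = int(rng.integers(0, len(assembly.chrom_names)))
        chrom = assembly.chrom_names[ci]
        clen = assembly.chrom_lengths[ci]
        length = int(rng.integers(2_000, 20_001))
        # keep 7 kb margins so 6-kb flanks fit inside the chromosome
        lo, hi = 7_000, clen - length - 7_000
        if hi <= lo:
            continue
        start = int(rng.integers(lo, hi))
        end = start + length
        if any(s < end and start < e for s, e in occupied[chrom]):
            continue
        occupied[chrom].append((start, end))
        strand = "+" if rng.random() < 0.5 else "-"
        ivs.append(GenomicInterval(chrom, start, end, strand=strand,
                                   label=f"gene{len(ivs) + 1}"))
    return IntervalSet(ivs, assembly, name="genes").sorted()


def _tile_catalog(assembly: GenomeAssembly, tile_states: dict[str, np.ndarray]) -> dict:
    chroms, starts, states = [], [], []
    for chrom in assembly.chrom_names:
        st = tile_states[chrom]
        chroms.extend([chrom] * len(st))
        starts.extend(range(0, len(st) * STATE_TILE, STATE_TILE))
        states.extend(st.tolist())
    return {
        "chrom": np.array(chroms),
        "start": np.array(starts, dtype=np.int64),
        "state": np.array(states, dtype=np.int64),
    }


def simulate_counts(
    truth: GroundTruth,
    cfg: SimulationConfig,
    condition: str,
    factor: str = "mark_k27ac",
    rng: np.random.Generator | None = None,
) -> dict[str, pd.DataFrame]:
    """Replicate read-start tables for one factor under one condition.

    Reads are a mixture of uniform background and peak-shaped enrichment;
    per-peak expected reads are proportional to peak width.  Under the
    knockdown condition, intensity at planted differential sites is
    multiplied by ``effect_fold``.  Replicate-to-replicate dispersion is
    negative-binomial: each (peak or background-tile, replicate) intensity
    is multiplied by a Gamma(1/phi, phi) variate when ``nb_dispersion`` > 0,
    so marginal counts are NB with that dispersion.  Library sizes are
    jittered by +/- ``library_jitter`` to exercise normalization.
    """
    if condition not in ("control", "knockdown"):
        raise ValueError("condition must be 'control' or 'knockdown'")
    if rng is None:
        cond_id = {"control": 0, "knockdown": 1}[condition]
        rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, 7, cond_id, _factor_id(factor)])
        )
    assembly = truth.assembly
    peaks = truth.peaks[factor]
    phi = cfg.nb_dispersion

    # baseline per-peak intensity weights (prop. to width), fold applied at
    # differential sites under knockdown
    widths = np.array([iv.width for iv in peaks], dtype=np.float64)
    folds = np.ones(len(peaks))
    if condition == "knockdown" and len(truth.differential_sites):
        diff_keys = {(iv.chrom, iv.start, iv.end): iv.score for iv in truth.differential_sites}
        for i, iv in enumerate(peaks):
            f = diff_keys.get((iv.chrom, iv.start, iv.end))
            if f is not None:
                folds[i] = f
    peak_w = widths * folds

    # background: one intensity unit per 10-kb tile (gamma-jittered if phi>0)
    bg_tiles = []
    for chrom, clen in zip(assembly.chrom_names, assembly.chrom_lengths):
        for s in range(0, clen, 10_000):
            bg_tiles.append((chrom, s, min(s + 10_000, clen)))
    bg_len = np.array([e - s for _, s, e in bg_tiles], dtype=np.float64)

    out: dict[str, pd.DataFrame] = {}
    for rep in range(1, cfg.replicates + 1):
        lib = cfg.reads_per_sample * (
            1.0 + cfg.library_jitter * (2 * rng.random() - 1.0)
        )
        n_peak_reads_mean = lib * cfg.peak_fraction_of_reads
        n_bg_reads_mean = lib - n_peak_reads_mean

        pw = peak_w.copy()
        bw = bg_len.copy()
        if phi > 0:
            pw = pw * rng.gamma(1.0 / phi, phi, size=len(pw))
            bw = bw * rng.gamma(1.0 / phi, phi, size=len(bw))
        # expected reads per peak: lambda_i prop. to width_i * fold_i, with
        # the fold=1 total equal to the peak read budget (planted induction
        # adds reads; library normalization downstream must absorb it)
        lam_peak = n_peak_reads_mean * pw / widths.sum()
        lam_bg = n_bg_reads_mean * bw / bg_len.sum()

        k_peak = rng.poisson(lam_peak)
        k_bg = rng.poisson(lam_bg)

        chroms: list[np.ndarray] = []
        positions: list[np.ndarray] = []
        for iv, k in zip(peaks, k_peak):
            if k == 0:
                continue
            pos = iv.start + rng.integers(0, iv.width, size=k)
            chroms.append(np.full(k, iv.chrom, dtype=object))
            positions.append(pos)
        for (chrom, s, e), k in zip(bg_tiles, k_bg):
            if k == 0:
                continue
            pos = rng.integers(s, e, size=k)
            chroms.append(np.full(k, chrom, dtype=object))
            positions.append(pos)
        chrom_arr = np.concatenate(chroms) if chroms else np.array([], dtype=object)
        pos_arr = np.concatenate(positions) if positions else np.array([], dtype=np.int64)
        strand_arr = np.where(rng.random(len(pos_arr)) < 0.5, "+", "-")
        # clamp 5' positions so extended fragments stay inside the chromosome
        lens = np.array(
            [assembly.length_of(c) for c in chrom_arr], dtype=np.int64
        ) if len(chrom_arr) else np.array([], dtype=np.int64)
        L = cfg.fragment_length
        pos_arr = np.where(
            strand_arr == "+",
            np.minimum(pos_arr, np.maximum(lens - L, 0)),
            np.maximum(pos_arr, L - 1),
        ).astype(np.int64)
        df = pd.DataFrame({"chrom": chrom_arr, "pos": pos_arr, "strand": strand_arr})
        df = df.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(drop=True)
        out[f"{factor}_{condition}_rep{rep}"] = df
    return out


def _factor_id(factor: str) -> int:
    return sum(ord(c) for c in factor) % 997


def simulate_peptide_table(
    n_peptides: int,
    isobaric_pairs: int,
    seed: int,
    noise_cv: float = 0.0,
    n_isoforms: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Peptide isoform MS1-area table with optional coeluting isobaric pairs.

    Returns ``(table, truth)``.  ``table`` follows the documented schema
    (sample, histone, peptide, modification, isobaric_group, ms1_area,
    frag1..frag3); ``truth`` holds the planted isoform percentages.  For
    each isobaric pair, the two members share one MS1 area and carry three
    unique MS2 fragment integrals each, proportional to the true split and
    perturbed by multiplicative lognormal noise of CV ``noise_cv``.
    """
    if not (n_peptides >= isobaric_pairs >= 0):
        raise ValueError("need n_peptides >= isobaric_pairs >= 0")
    rng = np.random.default_rng(seed)
    rows, truth_rows = [], []
    mods = ["unmod", "me1", "me2", "me3", "ac"]
    for p in range(n_peptides):
        peptide = f"H3_{27 + 9 * p}_{40 + 9 * p}"
        k = n_isoforms
        shares = rng.dirichlet(np.ones(k) * 2.0)
        total = float(rng.uniform(1e5, 1e7))
        isobaric = p < isobaric_pairs
        for i in range(k):
            mod = mods[i % len(mods)] if i < len(mods) else f"mod{i}"
            area = total * shares[i]
            row = {
                "sample": "IP1",
                "histone": "H3",
                "peptide": peptide,
                "modification": mod,
                "isobaric_group": "",
                "ms1_area": area,
                "frag1": np.nan, "frag2": np.nan, "frag3": np.nan,
            }
            truth_rows.append({
                "peptide": peptide, "modification": mod,
                "true_percentage": 100.0 * shares[i],
            })
            rows.append(row)
        if isobaric:
            # fold the last two isoforms into one coeluting MS1 peak
            a, b = rows[-2], rows[-1]
            group = f"iso_{peptide}"
            shared = a["ms1_area"] + b["ms1_area"]
            split_a = a["ms1_area"] / shared
            for member, frac in ((a, split_a), (b, 1.0 - split_a)):
                member["isobaric_group"] = group
                member["ms1_area"] = shared
                base = frac * 1e4
                noise = (
                    rng.lognormal(mean=-0.5 * np.log1p(noise_cv**2),
                                  sigma=np.sqrt(np.log1p(noise_cv**2)), size=3)
                    if noise_cv > 0 else np.ones(3)
                )
                member["frag1"], member["frag2"], member["frag3"] = base * noise
    table = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    return table, truth
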
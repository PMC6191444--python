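import numpy as np
import pytest

from nchipkit.intervals import GenomeAssembly, GenomicInterval, IntervalSet
from nchipkit.simulate import SimulationConfig, simulate_counts, simulate_genome


@pytest.fixture
def toy_assembly() -> GenomeAssembly:
    return GenomeAssembly(("chr1", "chr2"), (100_000, 50_000))


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic study shared across tests (seed 1)."""
    cfg = SimulationConfig(seed=1)
    assembly, truth = simulate_genome(cfg)
    return cfg, assembly, truth


@pytest.fixture(scope="session")
def acetyl_reads(default_sim):
    cfg, assembly, truth = default_sim
    ctrl = simulate_counts(truth, cfg, "control", factor="mark_k27ac")
    kd = simulate_counts(truth, cfg, "knockdown", factor="mark_k27ac")
    return ctrl, kd


def coverage_mask(ivs, length: int) -> np.ndarray:
    """Per-base boolean occupancy — the brute-force oracle for interval algebra."""
    m = np.zeros(length, dtype=bool)
    for iv in ivs:
        m[iv.start:iv.end] = True
    return m


def mask_to_intervals(mask: np.ndarray, chrom: str) -> list[tuple[str, int, int]]:
    """Re-segment a boolean mask into maximal runs of True."""
    out = []
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(int))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    for s, e in zip(starts, ends):
        out.append((chrom, int(s), int(e)))
    return out


def collapse_book_ended(runs):
    """Collapse exactly-adjacent intervals; book-ended stay separate in the
    half-open merge convention but are indistinguishable in a per-base mask."""
    out = []
    for chrom, s, e in runs:
        if out and out[-1][0] == chrom and out[-1][2] == s:
            out[-1] = (chrom, out[-1][1], e)
        else:
            out.append((chrom, s, e))
    return out


def random_interval_set(
    rng: np.random.Generator,
    assembly: GenomeAssembly,
    n: int,
    max_width: int = 2000,
) -> IntervalSet:
    ivs = []
    for _ in range(n):
        ci = int(rng.integers(0, len(assembly.chrom_names)))
        chrom = assembly.chrom_names[ci]
        clen = assembly.chrom_lengths[ci]
        width = int(rng.integers(1, max_width))
        start = int(rng.integers(0, clen - width))
        ivs.append(GenomicInterval(chrom, start, start + width))
    return IntervalSet(ivs, assembly, name="random")
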
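"""Coverage tracks and region count matrices from read-start tables.

Reads arrive as (chrom, pos, strand) tables — ``pos`` is the 5' end of the
read.  Each read is extended to the expected fragment size (150 bp by
default, matching MNase mononucleosome fragments): a + read covers
``[pos, pos+L)``, a - read covers ``[pos-L+1, pos+1)``, both clipped at
chromosome ends.  Tracks are dense per-chromosome float arrays; a
``scale`` attribute records any normalization multiplier applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import GenomeAssembly, IntervalSet, merge_overlapping

__all__ = [
    "CoverageTrack",
    "CountMatrix",
    "extend_and_pileup",
    "normalize_1x",
    "fragment_midpoints",
    "count_reads_in_regions",
    "median_of_ratios_size_factors",
    "write_bedgraph",
]

logger = logging.getLogger(__name__)

READ_COLUMNS = ("chrom", "pos", "strand")


@dataclass
class CoverageTrack:
    """Per-base non-negative signal over an assembly."""

    assembly: GenomeAssembly
    values: dict[str, np.ndarray]
    scale: float = 1.0
    fragment_length: int = 150
    clipped_bases: int = 0

    def __post_init__(self) -> None:
        for chrom, arr in self.values.items():
            if len(arr) != self.assembly.length_of(chrom):
                raise ValueError(f"track length mismatch on {chrom}")

    @property
    def total_mass(self) -> float:
        return float(sum(arr.sum() for arr in self.values.values()))

    @property
    def genome_mean(self) -> float:
        return self.total_mass / self.assembly.total_size

    @classmethod
    def zeros(cls, assembly: GenomeAssembly, fragment_length: int = 150) -> "CoverageTrack":
        vals = {
            c: np.zeros(l, dtype=np.float64)
            for c, l in zip(assembly.chrom_names, assembly.chrom_lengths)
        }
        return cls(assembly, vals, scale=1.0, fragment_length=fragment_length)


@dataclass
class CountMatrix:
    """regions x samples integer counts with optional per-sample size factors."""

    regions: IntervalSet
    samples: list[str]
    counts: np.ndarray
    size_factors: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.regions), len(self.samples)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.regions)} regions x {len(self.samples)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be integral")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.size_factors is not None and (np.asarray(self.size_factors) <= 0).any():
            raise ValueError("size factors must be positive")

    @property
    def normalized(self) -> np.ndarray:
        if self.size_factors is None:
            raise ValueError("size factors not computed; run a normalization first")
        return self.counts / np.asarray(self.size_factors)[None, :]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self.regions],
                "start": [iv.start for iv in self.regions],
                "end": [iv.end for iv in self.regions],
            }
        )
        for j, s in enumerate(self.samples):
            df[s] = self.counts[:, j]
        return df


def _validate_reads(reads: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in READ_COLUMNS if c not in reads.columns]
    if missing:
        raise ValueError(f"read table missing columns: {missing}")
    return reads


def _fragment_bounds(
    pos: np.ndarray, strand: np.ndarray, fragment_length: int, chrom_len: int
) -> tuple[np.ndarray, np.ndarray, int]:
    """Raw fragment [start, end) per read plus total clipped bases."""
    fwd = strand == "+"
    start = np.where(fwd, pos, pos - fragment_length + 1)
    end = start + fragment_length
    cstart = np.clip(start, 0, chrom_len)
    cend = np.clip(end, 0, chrom_len)
    clipped = int(np.sum((cstart - start) + (end - cend)))
    return cstart.astype(np.int64), cend.astype(np.int64), clipped


def extend_and_pileup(
    reads: pd.DataFrame,
    assembly: GenomeAssembly,
    fragment_length: int = 150,
) -> CoverageTrack:
    """Extend reads to ``fragment_length`` and pile up per-base coverage.

    Fragments running off a chromosome end are clipped, counted and logged,
    never fatal.  Mass conservation holds exactly in integer arithmetic:
    total coverage == n_reads * fragment_length - clipped bases.
    """
    if fragment_length < 1:
        raise ValueError("fragment_length must be >= 1")
    _validate_reads(reads)
    track = CoverageTrack.zeros(assembly, fragment_length=fragment_length)
    total_clipped = 0
    for chrom, grp in reads.groupby("chrom", sort=False):
        if chrom not in assembly:
            raise ValueError(f"read chromosome {chrom!r} not in assembly")
        L = assembly.length_of(chrom)
        start, end, clipped = _fragment_bounds(
            grp["pos"].to_numpy(np.int64),
            grp["strand"].to_numpy(),
            fragment_length,
            L,
        )
        total_clipped += clipped
        # difference-array pileup: +1 at starts, -1 at ends, cumsum
        diff = np.zeros(L + 1, dtype=np.int64)
        np.add.at(diff, start, 1)
        np.add.at(diff, end, -1)
        track.values[chrom] += np.cumsum(diff[:-1]).astype(np.float64)
    if total_clipped:
        logger.info("pileup clipped %d bases at chromosome ends", total_clipped)
    track.clipped_bases = total_clipped
    return track


def normalize_1x(track: CoverageTrack) -> CoverageTrack:
    """Scale so the genome-wide mean per-base value is exactly 1 (1x depth)."""
    mass = track.total_mass
    if mass <= 0:
        raise ValueError("cannot normalize a zero-mass track")
    factor = track.assembly.total_size / mass
    out = CoverageTrack(
        track.assembly,
        {c: arr * factor for c, arr in track.values.items()},
        scale=track.scale * factor,
        fragment_length=track.fragment_length,
        clipped_bases=track.clipped_bases,
    )
    return out


def fragment_midpoints(
    reads: pd.DataFrame, assembly: GenomeAssembly, fragment_length: int = 150
) -> pd.DataFrame:
    """Midpoint (bp) of each extended fragment, clipped into the chromosome."""
    _validate_reads(reads)
    pos = reads["pos"].to_numpy(np.int64)
    fwd = reads["strand"].to_numpy() == "+"
    start = np.where(fwd, pos, pos - fragment_length + 1)
    mid = start + fragment_length // 2
    out = pd.DataFrame({"chrom": reads["chrom"].to_numpy(), "mid": mid})
    lengths = out["chrom"].map(
        {c: l for c, l in zip(assembly.chrom_names, assembly.chrom_lengths)}
    )
    out["mid"] = np.clip(out["mid"], 0, lengths.to_numpy(np.int64) - 1)
    return out


def count_reads_in_regions(
    reads_per_sample: dict[str, pd.DataFrame],
    regions: IntervalSet,
    fragment_length: int = 150,
) -> CountMatrix:
    """Count each read's extended-fragment midpoint into at most one region.

    Regions must be non-overlapping (merge first); midpoint counting
    guarantees each read lands in at most one region even for book-ended
    regions (half-open: a midpoint exactly at a region end is outside).
    """
    if len(merge_overlapping(regions)) != len(regions):
        raise ValueError("regions overlap; merge_overlapping them first")
    srt = regions.sorted()
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    row_of: dict[str, np.ndarray] = {}
    for chrom in srt.assembly.chrom_names:
        ivs = [(i, iv) for i, iv in enumerate(srt) if iv.chrom == chrom]
        if ivs:
            starts = np.array([iv.start for _, iv in ivs], dtype=np.int64)
            ends = np.array([iv.end for _, iv in ivs], dtype=np.int64)
            rows = np.array([i for i, _ in ivs], dtype=np.int64)
            by_chrom[chrom] = (starts, ends, rows)
    samples = list(reads_per_sample.keys())
    counts = np.zeros((len(srt), len(samples)), dtype=np.int64)
    for j, sample in enumerate(samples):
        mids = fragment_midpoints(reads_per_sample[sample], srt.assembly, fragment_length)
        for chrom, grp in mids.groupby("chrom", sort=False):
            if chrom not in by_chrom:
                continue
            starts, ends, rows = by_chrom[chrom]
            m = grp["mid"].to_numpy(np.int64)
            idx = np.searchsorted(starts, m, side="right") - 1
            ok = (idx >= 0) & (m < ends[np.clip(idx, 0, None)])
            hit_rows = rows[idx[ok]]
            np.add.at(counts[:, j], hit_rows, 1)
    return CountMatrix(srt, samples, counts)


def median_of_ratios_size_factors(m: CountMatrix) -> CountMatrix:
    """Median-of-ratios per-sample size factors (the DESeq-family estimator).

    factor_j = median over regions with all-positive counts of
    count_ij / geometric-mean_i, computed from the definition.
    """
    if len(m.samples) < 2:
        raise ValueError("need >= 2 samples")
    counts = m.counts.astype(np.float64)
    all_pos = (counts > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no region with all-positive counts; add a pseudocount or "
            "restrict to covered regions"
        )
    sub = counts[all_pos]
    geomean = np.exp(np.mean(np.log(sub), axis=1))
    factors = np.median(sub / geomean[:, None], axis=0)
    return CountMatrix(m.regions, m.samples, m.counts, size_factors=factors)


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Write the track as run-length-compressed bedGraph (zero runs skipped)."""
    lines = ["track type=bedGraph"]
    for chrom in track.assembly.chrom_names:
        arr = track.values[chrom]
        change = np.flatnonzero(np.diff(arr)) + 1
        bounds = np.concatenate(([0], change, [len(arr)]))
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            v = arr[lo]
            if v != 0:
                lines.append(f"{chrom}\t{lo}\t{hi}\t{v:.6g}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
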
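"""Genome model and strand-aware interval algebra.

Coordinates are 0-based half-open throughout (the native BED convention);
book-ended intervals such as [0,100) and [100,200) do not overlap and are
not merged at ``gap=0``.  Strand is carried on every interval but ignored
by the overlap arithmetic — only the meta-gene machinery orients by strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "GenomeAssembly",
    "GenomicInterval",
    "IntervalSet",
    "read_chrom_sizes",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "merge_overlapping",
    "overlap_width",
    "intersect",
]


class BedParseError(ValueError):
    """Raised for malformed BED/bedGraph records; carries the line number."""


@dataclass(frozen=True)
class GenomeAssembly:
    """Ordered chromosome names and lengths (bp)."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(set(self.chrom_names)):
            raise ValueError("chromosome names must be unique")
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("names and lengths differ in length")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")

    @property
    def total_size(self) -> int:
        return int(sum(self.chrom_lengths))

    def length_of(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[self.chrom_names.index(chrom)]
        except ValueError:
            raise KeyError(f"chromosome {chrom!r} not in assembly") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_names

    def chrom_order(self, chrom: str) -> int:
        return self.chrom_names.index(chrom)

    def as_interval_set(self, name: str = "genome") -> "IntervalSet":
        """The whole genome as one interval per chromosome."""
        ivs = [
            GenomicInterval(c, 0, l)
            for c, l in zip(self.chrom_names, self.chrom_lengths)
        ]
        return IntervalSet(ivs, self, name=name)

    @classmethod
    def from_dict(cls, sizes: dict[str, int]) -> "GenomeAssembly":
        return cls(tuple(sizes.keys()), tuple(int(v) for v in sizes.values()))


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval with optional strand, score and label."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    score: float | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class IntervalSet:
    """A named collection of intervals validated against a genome assembly."""

    def __init__(
        self,
        intervals: Iterable[GenomicInterval],
        assembly: GenomeAssembly,
        name: str = "",
    ) -> None:
        self.intervals: list[GenomicInterval] = list(intervals)
        self.assembly = assembly
        self.name = name
        for iv in self.intervals:
            if iv.chrom not in assembly:
                raise ValueError(f"interval chromosome {iv.chrom!r} not in assembly")
            if iv.end > assembly.length_of(iv.chrom):
                raise ValueError(
                    f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                    f"length {assembly.length_of(iv.chrom)}"
                )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.intervals == other.intervals and self.assembly == other.assembly

    @property
    def total_width(self) -> int:
        return sum(iv.width for iv in self.intervals)

    def sorted(self) -> "IntervalSet":
        """Sorted by (assembly chromosome order, start, end, label)."""
        order = {c: i for i, c in enumerate(self.assembly.chrom_names)}
        ivs = sorted(
            self.intervals,
            key=lambda iv: (order[iv.chrom], iv.start, iv.end, iv.label or ""),
        )
        return IntervalSet(ivs, self.assembly, name=self.name)

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {c: [] for c in self.assembly.chrom_names}
        for iv in self.intervals:
            out[iv.chrom].append(iv)
        for c in out:
            out[c].sort(key=lambda iv: (iv.start, iv.end, iv.label or ""))
        return out

    def filter(self, predicate) -> "IntervalSet":
        return IntervalSet(
            [iv for iv in self.intervals if predicate(iv)], self.assembly, self.name
        )


def read_chrom_sizes(path: str | Path) -> GenomeAssembly:
    """Read a UCSC-style two-column chrom.sizes file."""
    names: list[str] = []
    lengths: list[int] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise BedParseError(f"{path}:{lineno}: expected two tab-separated columns")
        names.append(parts[0])
        lengths.append(int(parts[1]))
    return GenomeAssembly(tuple(names), tuple(lengths))


def _parse_bed_line(parts: list[str], lineno: int) -> GenomicInterval:
    chrom = parts[0]
    try:
        start, end = int(parts[1]), int(parts[2])
    except ValueError:
        raise BedParseError(f"line {lineno}: non-integer coordinates") from None
    if not (0 <= start < end):
        raise BedParseError(
            f"line {lineno}: invalid interval {chrom}:{start}-{end} (need start < end)"
        )
    label = parts[3] if len(parts) > 3 and parts[3] != "." else None
    score: float | None = None
    if len(parts) > 4 and parts[4] not in (".", ""):
        score = float(parts[4])
    strand = parts[5] if len(parts) > 5 and parts[5] in ("+", "-") else "."
    return GenomicInterval(chrom, start, end, strand=strand, score=score, label=label)


def read_bed(path: str | Path, assembly: GenomeAssembly) -> IntervalSet:
    """Read BED3/BED6/BED12 into an IntervalSet.

    BED12 gene records keep name and strand; block structure is ignored
    (the meta-gene machinery works on whole gene bodies).  Records on
    chromosomes absent from the assembly, or running off a chromosome end,
    are rejected.
    """
    ivs: list[GenomicInterval] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise BedParseError(f"line {lineno}: fewer than 3 columns")
        iv = _parse_bed_line(parts, lineno)
        if iv.chrom not in assembly:
            raise ValueError(f"line {lineno}: chromosome {iv.chrom!r} not in assembly")
        ivs.append(iv)
    return IntervalSet(ivs, assembly, name=Path(path).stem)


def write_bed(s: IntervalSet, path: str | Path) -> None:
    """Write BED6; scores kept to 6 significant digits, round-trips read_bed."""
    lines = [f"# {s.name or 'intervals'}"]
    for iv in s.sorted():
        score = "." if iv.score is None else f"{iv.score:.6g}"
        lines.append(
            f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label or '.'}\t{score}\t{iv.strand}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_bedgraph(path: str | Path, assembly: GenomeAssembly) -> IntervalSet:
    """Read a bedGraph as intervals with the value in ``score``."""
    ivs: list[GenomicInterval] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise BedParseError(f"line {lineno}: bedGraph needs 4 columns")
        iv = _parse_bed_line(parts[:3], lineno)
        ivs.append(replace(iv, score=float(parts[3])))
    return IntervalSet(ivs, assembly, name=Path(path).stem)


def merge_overlapping(s: IntervalSet, gap: int = 0) -> IntervalSet:
    """Merge overlapping intervals (union), optionally bridging gaps <= ``gap``.

    Half-open semantics: at ``gap=0`` book-ended intervals stay separate.
    Strand, score and label do not survive a merge.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    merged: list[GenomicInterval] = []
    for chrom in s.assembly.chrom_names:
        ivs = sorted(
            (iv for iv in s.intervals if iv.chrom == chrom),
            key=lambda iv: (iv.start, iv.end),
        )
        cur_start = cur_end = None
        for iv in ivs:
            if cur_end is None:
                cur_start, cur_end = iv.start, iv.end
            elif iv.start < cur_end or (gap > 0 and iv.start - cur_end <= gap):
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        if cur_end is not None:
            merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return IntervalSet(merged, s.assembly, name=s.name)


def _union_bounds(ivs: Sequence[GenomicInterval]) -> list[tuple[int, int]]:
    """Union of sorted-by-start intervals on one chromosome, as (start, end)."""
    out: list[tuple[int, int]] = []
    for iv in sorted(ivs, key=lambda v: (v.start, v.end)):
        if out and iv.start < out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], iv.end))
        else:
            out.append((iv.start, iv.end))
    return out


def overlap_width(a: IntervalSet, b: IntervalSet) -> int:
    """Total bp covered by both sets (each side unioned first); symmetric."""
    if a.assembly != b.assembly:
        raise ValueError("interval sets are on different assemblies")
    total = 0
    b_by_chrom = b.by_chrom()
    for chrom, a_ivs in a.by_chrom().items():
        ua = _union_bounds(a_ivs)
        ub = _union_bounds(b_by_chrom.get(chrom, []))
        i = j = 0
        while i < len(ua) and j < len(ub):
            lo = max(ua[i][0], ub[j][0])
            hi = min(ua[i][1], ub[j][1])
            if hi > lo:
                total += hi - lo
            if ua[i][1] <= ub[j][1]:
                i += 1
            else:
                j += 1
    return total


def intersect(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Intervals of ``a`` that overlap (>= 1 bp) any interval of ``b``."""
    if a.assembly != b.assembly:
        raise ValueError("interval sets are on different assemblies")
    b_by_chrom = {c: _union_bounds(ivs) for c, ivs in b.by_chrom().items()}
    kept = []
    for iv in a:
        bounds = b_by_chrom.get(iv.chrom, [])
        if not bounds:
            continue
        # union bounds are disjoint and sorted, so ends are sorted too:
        # the first block ending after iv.start is the only candidate
        ends = np.fromiter((e for _, e in bounds), dtype=np.int64)
        idx = int(np.searchsorted(ends, iv.start, side="right"))
        if idx < len(bounds) and bounds[idx][0] < iv.end:
            kept.append(iv)
    return IntervalSet(kept, a.assembly, name=a.name)
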
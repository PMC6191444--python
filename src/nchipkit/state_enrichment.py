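"""Chromatin-state occupancy statistics for peak sets.

For each state *s* of a genome segmentation, the observed overlap fraction
is the base pairs of peak territory falling in state *s* divided by the
total peak territory; the expected fraction is the state's share of the
whole genome.  The log2 ratio of observed to expected is the enrichment
(positive) or depletion (negative) of the peak set in that state.
Peaks are unioned before measuring so the observed fractions are a
partition of peak territory (they sum to 1 on a tiling segmentation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import (
    GenomeAssembly,
    IntervalSet,
    merge_overlapping,
    overlap_width,
)

__all__ = ["StateSegmentation", "StateEnrichmentResult", "state_enrichment"]


@dataclass
class StateSegmentation:
    """Non-overlapping labeled segments; labels are state identifiers."""

    segments: IntervalSet

    def __post_init__(self) -> None:
        merged = merge_overlapping(self.segments)
        if merged.total_width != self.segments.total_width:
            raise ValueError("state segments overlap")

    @property
    def state_labels(self) -> list[str]:
        return sorted({iv.label or "?" for iv in self.segments})

    def state_widths(self) -> dict[str, int]:
        widths: dict[str, int] = {}
        for iv in self.segments:
            widths[iv.label or "?"] = widths.get(iv.label or "?", 0) + iv.width
        return widths

    def subset(self, state: str) -> IntervalSet:
        return self.segments.filter(lambda iv: (iv.label or "?") == state)


@dataclass
class StateEnrichmentResult:
    """Per-state observed fraction O, expected fraction E, and log2(O/E)."""

    table: pd.DataFrame  # columns: state, observed, expected, log2_ratio, flag

    def log2_ratio(self, state: str) -> float:
        row = self.table.loc[self.table["state"] == state]
        if row.empty:
            raise KeyError(f"state {state!r} not in result")
        return float(row["log2_ratio"].iloc[0])

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def state_enrichment(
    peaks: IntervalSet,
    seg: StateSegmentation,
    assembly: GenomeAssembly,
    union_peaks: bool = True,
) -> StateEnrichmentResult:
    """Observed/expected state overlap for a peak set.

    O_s = overlap_width(peaks, state-s segments) / total peak width;
    E_s = state-s width / total genome size.  States with zero width are
    reported with flag ``zero_expected`` and no ratio.  A peak set fully
    outside a state yields log2 ratio -inf with flag ``zero_observed``.
    ``union_peaks=False`` measures against the raw (possibly overlapping)
    peak list for sensitivity analysis.
    """
    if len(peaks) == 0:
        raise ValueError("empty peak set")
    pk = merge_overlapping(peaks) if union_peaks else peaks
    peak_width = pk.total_width
    rows = []
    for state in seg.state_labels:
        segs = seg.subset(state)
        e = segs.total_width / assembly.total_size
        if e == 0:
            rows.append({"state": state, "observed": 0.0, "expected": 0.0,
                         "log2_ratio": np.nan, "flag": "zero_expected"})
            continue
        if union_peaks:
            o = overlap_width(pk, segs) / peak_width
        else:
            o = sum(overlap_width(IntervalSet([iv], pk.assembly), segs) for iv in pk) / peak_width
        if o == 0:
            ratio, flag = -np.inf, "zero_observed"
        else:
            ratio, flag = float(np.log2(o / e)), ""
        rows.append({"state": state, "observed": o, "expected": e,
                     "log2_ratio": ratio, "flag": flag})
    return StateEnrichmentResult(pd.DataFrame(rows))
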
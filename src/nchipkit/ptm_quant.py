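"""Histone-PTM relative abundance from exported chromatogram-area tables.

The pipeline starts at the table a targeted-MS tool exports: one row per
(sample, histone, peptide, modification) with the integrated MS1 peak
area.  Modification forms with identical mass that coelute as a single
MS1 peak ("isobaric groups") share that area; their split is recovered
from three modification-unique MS2 fragment-ion integrals per member —
each member's share of the MS1 area is its mean fragment integral over
the group total.  Isoform percentages are then the share of each form in
the summed areas of its peptide, and IP percentages can be normalized to
the matching input-sample percentages.

Expected columns: sample, histone, peptide, modification, isobaric_group
(empty for singletons), ms1_area, frag1, frag2, frag3.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "resolve_isobaric",
    "isoform_percentages",
    "normalize_to_input",
    "cluster_ratio_matrix",
]

logger = logging.getLogger(__name__)

FRAG_COLS = ["frag1", "frag2", "frag3"]
KEY_COLS = ["sample", "histone", "peptide", "modification"]


def _check_table(table: pd.DataFrame) -> None:
    missing = [c for c in KEY_COLS + ["ms1_area"] if c not in table.columns]
    if missing:
        raise ValueError(f"peptide table missing columns: {missing}")
    if (table["ms1_area"] < 0).any():
        raise ValueError("ms1_area must be non-negative")


def resolve_isobaric(table: pd.DataFrame, mean: str = "arithmetic") -> pd.DataFrame:
    """Split shared MS1 areas of coeluting isobaric groups by MS2 fragments.

    Within a group, member i gets ``effective_area = ms1_area * w_i / sum w``
    where ``w_i`` is the mean of its fragment integrals (arithmetic by
    default, geometric optional; missing fragments are averaged over the
    present ones).  The split conserves the shared area exactly.  Groups
    whose fragments are all zero are split equally with a warning.  Rows
    outside any group keep their own area.
    """
    _check_table(table)
    out = table.copy()
    out["effective_area"] = out["ms1_area"].astype(float)
    grouped = out["isobaric_group"].fillna("").astype(str) != "" if "isobaric_group" in out else pd.Series(False, index=out.index)
    for (sample, group), idx in out.loc[grouped].groupby(
        ["sample", "isobaric_group"]
    ).groups.items():
        rows = out.loc[idx]
        if len(rows) < 2:
            raise ValueError(f"isobaric group {group!r} has fewer than 2 members")
        ms1 = rows["ms1_area"].to_numpy(float)
        if not np.allclose(ms1, ms1[0]):
            raise ValueError(f"isobaric group {group!r} members disagree on ms1_area")
        frags = rows[[c for c in FRAG_COLS if c in rows]].to_numpy(float)
        if mean == "geometric":
            with np.errstate(divide="ignore"):
                w = np.exp(np.nanmean(np.log(frags), axis=1))
            w = np.where(np.isfinite(w), w, 0.0)
        else:
            w = np.nanmean(frags, axis=1)
        w = np.where(np.isfinite(w), w, 0.0)
        if w.sum() == 0:
            logger.warning("isobaric group %r has all-zero fragments; equal split", group)
            w = np.ones(len(rows))
        out.loc[idx, "effective_area"] = ms1[0] * w / w.sum()
    return out


def isoform_percentages(table: pd.DataFrame) -> pd.DataFrame:
    """Percentage of each modification form within its peptide and sample.

    Requires ``effective_area`` (run :func:`resolve_isobaric` first; for
    tables without isobaric groups it simply copies ``ms1_area``).
    Peptide-sample groups with zero total area get NaN percentages and a
    ``zero_total`` flag instead of an error.
    """
    if "effective_area" not in table.columns:
        table = resolve_isobaric(table)
    out = table.copy()
    totals = out.groupby(["sample", "histone", "peptide"])["effective_area"].transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        out["percentage"] = 100.0 * out["effective_area"] / totals
    out["flag"] = np.where(totals > 0, "", "zero_total")
    n_bad = int((totals == 0).sum())
    if n_bad:
        logger.warning("%d rows in peptide-sample groups with zero total area", n_bad)
    return out[KEY_COLS + ["effective_area", "percentage", "flag"]]


def normalize_to_input(
    ip: pd.DataFrame, input_: pd.DataFrame, mode: str = "ratio"
) -> pd.DataFrame:
    """Normalize IP isoform percentages to the matching input percentages.

    Matching is on (histone, peptide, modification).  ``mode='ratio'``
    divides; ``mode='difference'`` subtracts.  Zero or absent input
    percentages yield NaN with an explanatory flag.
    """
    keys = ["histone", "peptide", "modification"]
    inp = input_[keys + ["percentage"]].rename(columns={"percentage": "input_percentage"})
    merged = ip.merge(inp, on=keys, how="left")
    if mode == "ratio":
        with np.errstate(divide="ignore", invalid="ignore"):
            merged["normalized"] = merged["percentage"] / merged["input_percentage"]
        merged.loc[merged["input_percentage"] == 0, "normalized"] = np.nan
    elif mode == "difference":
        merged["normalized"] = merged["percentage"] - merged["input_percentage"]
    else:
        raise ValueError("mode must be 'ratio' or 'difference'")
    merged["flag"] = np.where(
        merged["input_percentage"].isna(), "missing_input",
        np.where(merged["input_percentage"] == 0, "zero_input", ""),
    )
    return merged


def cluster_ratio_matrix(matrix: pd.DataFrame) -> np.ndarray:
    """Average-linkage Euclidean leaf order for a modification x sample matrix."""
    link = hierarchy.linkage(pdist(matrix.to_numpy(float)), method="average")
    return np.asarray(hierarchy.leaves_list(link))
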
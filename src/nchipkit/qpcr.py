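"""qPCR quantification: ChIP percent input and 2^-ddCt expression.

Percent input adjusts the input Ct for the fraction of chromatin reserved
as input (Ct' = Ct_input - log2(1/fraction)) and reports
100 * 2^(Ct' - Ct_IP) per target and condition, with the replicate mean
and SEM.

Relative expression uses the 2^-ddCt method: dCt = Ct_target -
Ct_reference within each sample, ddCt relative to a calibrator condition,
fold change 2^-ddCt, and an error-bar range [2^(-ddCt - SEM),
2^(-ddCt + SEM)] where the SEM is taken over replicate-level ddCt values.
The range is asymmetric around the fold change and always brackets it.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

__all__ = ["percent_input", "ddct_expression"]

logger = logging.getLogger(__name__)

CT_COLS = ["target", "condition", "replicate", "role", "ct"]


def _check(t: pd.DataFrame, roles: set[str]) -> None:
    missing = [c for c in CT_COLS if c not in t.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    if (t["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    bad = set(t["role"]) - {"IP", "input", "cDNA"}
    if bad:
        raise ValueError(f"unknown roles: {sorted(bad)}")
    absent = roles - set(t["role"])
    if absent:
        raise ValueError(f"table lacks required roles: {sorted(absent)}")


def percent_input(t: pd.DataFrame, input_fraction: float) -> pd.DataFrame:
    """Percent-input per (target, condition) with replicate mean and SEM.

    Per replicate: adjusted input Ct' = Ct_input - log2(1/input_fraction);
    percent = 100 * 2^(Ct' - Ct_IP).  IP and input rows pair by
    (target, condition, replicate).
    """
    if not (0 < input_fraction <= 1):
        raise ValueError("input_fraction must be in (0, 1]")
    _check(t, {"IP", "input"})
    dilution = math.log2(1.0 / input_fraction)
    ip = t.loc[t["role"] == "IP", ["target", "condition", "replicate", "ct"]]
    inp = t.loc[t["role"] == "input", ["target", "condition", "replicate", "ct"]]
    merged = ip.merge(inp, on=["target", "condition", "replicate"],
                      suffixes=("_ip", "_input"), how="left")
    if merged["ct_input"].isna().any():
        bad = merged.loc[merged["ct_input"].isna(),
                         ["target", "condition", "replicate"]]
        raise ValueError(f"IP rows without matched input:\n{bad}")
    merged["percent"] = 100.0 * 2.0 ** (
        (merged["ct_input"] - dilution) - merged["ct_ip"]
    )
    out = (
        merged.groupby(["target", "condition"], sort=True)["percent"]
        .agg(mean="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan,
             n="count")
        .reset_index()
    )
    return out


def ddct_expression(
    t: pd.DataFrame,
    reference_gene: str,
    calibrator_condition: str,
) -> pd.DataFrame:
    """2^-ddCt fold changes per (target, condition) with the SEM range.

    dCt pairs target and reference Ct by (condition, replicate); ddCt
    subtracts the calibrator condition's mean dCt.  The SEM of
    replicate-level ddCt gives the error-bar range
    [2^(-ddCt - SEM), 2^(-ddCt + SEM)].  With a single replicate the fold
    is reported and the range left absent with a warning.
    """
    _check(t, {"cDNA"})
    cdna = t.loc[t["role"] == "cDNA"]
    if reference_gene not in set(cdna["target"]):
        raise ValueError(f"reference gene {reference_gene!r} absent from table")
    ref = cdna.loc[cdna["target"] == reference_gene,
                   ["condition", "replicate", "ct"]].rename(columns={"ct": "ct_ref"})
    for cond in cdna["condition"].unique():
        if cond not in set(ref["condition"]):
            raise ValueError(f"reference gene missing in condition {cond!r}")
    tgt = cdna.loc[cdna["target"] != reference_gene]
    merged = tgt.merge(ref, on=["condition", "replicate"], how="inner")
    merged["dct"] = merged["ct"] - merged["ct_ref"]
    cal = (
        merged.loc[merged["condition"] == calibrator_condition]
        .groupby("target")["dct"].mean().rename("dct_cal")
    )
    if cal.empty:
        raise ValueError(f"calibrator condition {calibrator_condition!r} absent")
    merged = merged.join(cal, on="target")
    merged["ddct"] = merged["dct"] - merged["dct_cal"]
    rows = []
    for (target, cond), grp in merged.groupby(["target", "condition"], sort=True):
        ddct = float(grp["ddct"].mean())
        fold = 2.0 ** (-ddct)
        if len(grp) >= 2:
            sem = float(grp["ddct"].std(ddof=1) / np.sqrt(len(grp)))
            lo, hi = 2.0 ** (-ddct - sem), 2.0 ** (-ddct + sem)
        else:
            logger.warning("single replicate for %s/%s: no error range", target, cond)
            sem, lo, hi = np.nan, np.nan, np.nan
        rows.append({"target": target, "condition": cond, "ddct": ddct,
                     "fold_change": fold, "sem_ddct": sem,
                     "range_low": lo, "range_high": hi, "n": len(grp)})
    return pd.DataFrame(rows)
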
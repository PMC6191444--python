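"""End-to-end orchestration of the synthetic study.

``run`` drives simulate -> coverage -> meta-gene / state enrichment /
co-occupancy -> consensus differential calling from one configuration,
writes every stage's tables under a run directory, and emits a
machine-readable summary including planted-truth recovery metrics
(sensitivity and false discovery of the consensus caller, fold-change
recovery, state-enrichment recovery).  Re-running with the same config
and seed reproduces all TSV/BED/JSON outputs byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coverage as cov
from . import diffbind as db
from .cooccupancy import classify_cooccupancy, venn_counts
from .intervals import IntervalSet, intersect, write_bed
from .metagene import build_metagene, cluster_metagene, compare_body_vs_downstream
from .simulate import SimulationConfig, simulate_counts, simulate_genome
from .state_enrichment import StateSegmentation, state_enrichment

__all__ = ["RunConfig", "run"]

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.6g"


@dataclass
class RunConfig:
    """Stage toggles and parameters; defaults are the study conditions."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    run_metagene: bool = True
    run_state_enrichment: bool = True
    run_cooccupancy: bool = True
    run_diffbind: bool = True
    write_tracks: bool = False
    # stage parameters
    fragment_length: int = 150
    flank_bp: int = 6000
    flank_bin: int = 50
    body_bins: int = 120
    metagene_k: int = 3
    bin_width: int = 100
    step: int = 300
    scale_bin: int = 10_000
    window_alpha: float = 0.001
    merge_window: int = 2000
    peak_alpha_adj: float = 0.05
    fold_threshold: float = 2.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        return cls(simulation=sim, **raw)


def _save_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def _recovery_metrics(
    consensus: IntervalSet, planted: IntervalSet, peak_table: pd.DataFrame
) -> dict:
    """Sensitivity / FDR of the consensus set and log2FC recovery."""
    hit_sites = intersect(planted, consensus)
    sensitivity = len(hit_sites) / len(planted) if len(planted) else float("nan")
    confirmed = intersect(consensus, planted)
    fdr = 1.0 - len(confirmed) / len(consensus) if len(consensus) else 0.0
    planted_keys = {(iv.chrom, iv.start, iv.end) for iv in planted}
    lfc = [
        float(r.log2_fold_change)
        for r in peak_table.itertuples()
        if (r.chrom, int(r.start), int(r.end)) in planted_keys
    ]
    return {
        "n_planted": len(planted),
        "n_consensus": len(consensus),
        "sensitivity": round(sensitivity, 6),
        "fdr": round(fdr, 6),
        "median_log2fc_at_planted": round(float(np.median(lfc)), 6) if lfc else None,
    }


def run(config: RunConfig, outdir: str | Path, seed: int | None = None) -> dict:
    """Execute all enabled stages; returns the summary dictionary.

    A stage failure aborts the run with the failing stage named; outputs
    of completed stages are retained in ``outdir``.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config.simulation
    if seed is not None:
        cfg = dataclasses.replace(cfg, seed=seed)
    summary: dict = {"seed": cfg.seed, "parameters": {
        k: v for k, v in dataclasses.asdict(config).items() if k != "simulation"
    }}
    summary["parameters"]["simulation"] = dataclasses.asdict(cfg)

    stage = "simulate"
    try:
        assembly, truth = simulate_genome(cfg)
        with open(out / "chrom.sizes", "w") as fh:
            for c, l in zip(assembly.chrom_names, assembly.chrom_lengths):
                fh.write(f"{c}\t{l}\n")
        write_bed(truth.state_segments, out / "states.bed")
        write_bed(truth.gene_models, out / "genes.bed")
        write_bed(truth.differential_sites, out / "differential_sites.bed")
        for name, pk in truth.peaks.items():
            write_bed(pk, out / f"peaks_{name}.bed")

        reads_a = simulate_counts(truth, cfg, "control", factor="factor_a")
        reads_b = simulate_counts(truth, cfg, "control", factor="factor_b")
        ac_ctrl = simulate_counts(truth, cfg, "control", factor="mark_k27ac")
        ac_kd = simulate_counts(truth, cfg, "knockdown", factor="mark_k27ac")
        for tables in (reads_a, reads_b, ac_ctrl, ac_kd):
            for name, df in tables.items():
                _save_tsv(df, out / f"reads_{name}.tsv")

        stage = "coverage"
        first_a = next(iter(reads_a.values()))
        track = cov.normalize_1x(
            cov.extend_and_pileup(first_a, assembly, cfg.fragment_length)
        )
        if config.write_tracks:
            cov.write_bedgraph(track, out / "factor_a_rep1.1x.bedgraph")
        summary["coverage"] = {
            "genome_mean_after_1x": round(track.genome_mean, 9),
            "clipped_bases": track.clipped_bases,
        }

        if config.run_metagene:
            stage = "metagene"
            mg = build_metagene(track, truth.gene_models, config.flank_bp,
                                config.flank_bin, config.body_bins)
            mg = cluster_metagene(mg, k=config.metagene_k, seed=cfg.seed)
            _save_tsv(mg.to_frame().reset_index(names="gene"), out / "metagene.tsv")
            pair = compare_body_vs_downstream(track, truth.gene_models)
            summary["metagene"] = {
                "n_genes": len(mg.genes),
                "cluster_sizes": {
                    str(c): int(n) for c, n in
                    sorted(pd.Series(mg.cluster_labels).value_counts().items())
                },
                "body_vs_downstream_signed_rank_p": float(pair.wilcoxon_signed_rank_p),
                "body_vs_downstream_rank_sum_p": float(pair.rank_sum_p),
            }

        if config.run_state_enrichment:
            stage = "state_enrichment"
            seg = StateSegmentation(truth.state_segments)
            res = state_enrichment(truth.peaks["factor_a"], seg, assembly)
            _save_tsv(res.table, out / "state_enrichment.tsv")
            summary["state_enrichment"] = {
                row["state"]: round(row["log2_ratio"], 4)
                for _, row in res.table.iterrows()
                if np.isfinite(row["log2_ratio"])
            }

        if config.run_cooccupancy:
            stage = "cooccupancy"
            calls = classify_cooccupancy(
                truth.peaks["factor_a"], truth.peaks["factor_b"],
                reads_a, reads_b,
                fold_threshold=config.fold_threshold,
                fragment_length=cfg.fragment_length,
            )
            call_df = pd.DataFrame(
                {
                    "chrom": [c.region.chrom for c in calls],
                    "start": [c.region.start for c in calls],
                    "end": [c.region.end for c in calls],
                    "owner": [c.owner for c in calls],
                    "overlap_hit": [c.overlap_hit for c in calls],
                    "count_ratio": [c.count_ratio for c in calls],
                    "call": [c.call for c in calls],
                }
            )
            _save_tsv(call_df, out / "cooccupancy_calls.tsv")
            summary["cooccupancy_venn"] = venn_counts(calls)

        if config.run_diffbind:
            stage = "diffbind"
            grid = db.WindowGrid(config.bin_width, config.step)
            factors = db.window_scaling_factors(
                {**ac_ctrl, **ac_kd}, assembly, config.scale_bin,
                cfg.fragment_length,
            )
            win = db.call_differential_windows(
                ac_ctrl, ac_kd, assembly, factors, grid,
                alpha=config.window_alpha, fragment_length=cfg.fragment_length,
            )
            _save_tsv(win.loc[win["significant"]], out / "window_bins.tsv")
            win_regions = db.merge_significant_bins(win, assembly, config.merge_window)
            write_bed(win_regions, out / "window_regions.bed")
            ac_peaks = truth.peaks["mark_k27ac"]
            peak_table = db.call_differential_peaks(
                {"control": [ac_peaks, ac_peaks],
                 "knockdown": [ac_peaks, ac_peaks]},
                {"control": ac_ctrl, "knockdown": ac_kd},
                alpha_adj=config.peak_alpha_adj,
                fragment_length=cfg.fragment_length,
            )
            _save_tsv(peak_table, out / "peak_features.tsv")
            consensus = db.consensus_regions(win_regions, peak_table)
            write_bed(consensus, out / "consensus_regions.bed")
            summary["diffbind"] = _recovery_metrics(
                consensus, truth.differential_sites, peak_table
            )
            if len(consensus):
                dir_df, frac = db.direction_summary(consensus)
                _save_tsv(dir_df, out / "consensus_directions.tsv")
                summary["diffbind"]["induced_fraction"] = round(frac["induced"], 6)
    except Exception:
        logger.error("pipeline failed in stage %r", stage)
        raise

    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    return summary
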
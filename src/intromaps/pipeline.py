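"""End-to-end orchestration: run every analysis stage on a map collection
and write flat TSV/BED artifacts plus a machine-readable run log.

All outputs are plain text with stable formatting, so a fixed seed yields
byte-identical runs; stages can be toggled independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import compare as _compare
from .bstat import DEFAULT_BOOTSTRAP_ITERS, WindowTrack, attach_b_values, contrast, tile_windows
from .compare import DEFAULT_HIGH_SUPPORT_K, DEFAULT_SIZE_MATCH_BP
from .deserts import DesertSet, desert_consensus, desert_introgression
from .individuals import CohortMaps, individual_jaccard_matrix
from .intervals import GenomeDefinition
from .maps import ScoredMap

__all__ = ["PipelineConfig", "run_pipeline"]

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """Parameters for a pipeline run; defaults follow the published analysis
    (793.9 Mb size-matching budget, support >= 10 for highly supported
    regions, 500 bp windows, 1,000 bootstrap iterations)."""

    size_match_bp: int | None = DEFAULT_SIZE_MATCH_BP
    high_support_k: int = DEFAULT_HIGH_SUPPORT_K
    window_bp: int = 500
    bootstrap_iters: int = DEFAULT_BOOTSTRAP_ITERS
    desert_consensus_k: int = 3
    seed: int = 0
    stages: tuple[str, ...] = ("compare", "individuals", "bstat", "deserts")

    def validate(self) -> None:
        if self.size_match_bp is not None and self.size_match_bp < 0:
            raise ValueError("size_match_bp must be non-negative")
        for name in ("high_support_k", "window_bp", "bootstrap_iters", "desert_consensus_k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        unknown = set(self.stages) - {"compare", "individuals", "bstat", "deserts"}
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def run_pipeline(
    maps: Sequence[ScoredMap],
    out_dir,
    config: PipelineConfig | None = None,
    cohort: CohortMaps | None = None,
    b_track: WindowTrack | None = None,
    b_segments: Sequence[tuple[str, int, int, float]] | None = None,
    desert_sets: Sequence[DesertSet] | None = None,
) -> dict:
    """Run the requested stages and write artifacts under ``out_dir``.

    Returns the run log (also written to ``run_log.json``): per-stage bp
    totals and headline statistics. A stage whose inputs are absent
    (e.g. no cohort) is skipped and recorded as such.
    """
    config = config or PipelineConfig()
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not maps:
        raise ValueError("run_pipeline requires at least one map")
    genome = maps[0].genome
    log: dict = {
        "config": {
            "size_match_bp": config.size_match_bp,
            "high_support_k": config.high_support_k,
            "window_bp": config.window_bp,
            "bootstrap_iters": config.bootstrap_iters,
            "desert_consensus_k": config.desert_consensus_k,
            "seed": config.seed,
            "stages": list(config.stages),
        },
        "maps": {m.name: {"regions": len(m.regions), "total_bp": m.total_bp} for m in maps},
        "stages": {},
    }

    if "compare" in config.stages and len(maps) >= 2:
        log["stages"]["compare"] = _stage_compare(maps, out, config, genome)
    if "individuals" in config.stages:
        if cohort is not None:
            log["stages"]["individuals"] = _stage_individuals(cohort, out)
        else:
            log["stages"]["individuals"] = "skipped: no cohort"
    if "bstat" in config.stages:
        if b_track is None and b_segments is not None:
            b_track = attach_b_values(tile_windows(genome, config.window_bp), b_segments)
        if b_track is not None:
            log["stages"]["bstat"] = _stage_bstat(maps, b_track, out, config)
        else:
            log["stages"]["bstat"] = "skipped: no B track"
    if "deserts" in config.stages:
        if desert_sets is not None:
            log["stages"]["deserts"] = _stage_deserts(desert_sets, maps, out, config, genome)
        else:
            log["stages"]["deserts"] = "skipped: no desert sets"

    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return log


def _stage_compare(maps, out: Path, config: PipelineConfig, genome) -> dict:
    working = maps
    if config.size_match_bp is not None:
        working = [_compare.size_match_top_scoring(m, config.size_match_bp) for m in maps]
    sim = _compare.similarity_matrix(working)
    _write_tsv(sim.to_frame("raw"), out / "similarity_raw.tsv", index=True)
    _write_tsv(sim.to_frame("normalized"), out / "similarity_normalized.tsv", index=True)

    profile = _compare.support_profile(maps)
    profile.write_bed(out / "support_profile.bed")
    high = profile.support_at_least(config.high_support_k, genome)
    high.write_bed(out / "highly_supported.bed")

    combos = _compare.combination_counts(maps)
    combo_df = pd.DataFrame(
        sorted(
            ({"maps": "+".join(k), "n_maps": len(k), "bp": v} for k, v in combos.items()),
            key=lambda r: -r["bp"],
        )
    )
    _write_tsv(combo_df, out / "combination_counts.tsv")

    tree = None
    if len(working) >= 2:
        tree = _compare.cluster_farthest_point(sim, "raw")
        (out / "cluster_tree.newick").write_text(tree.to_newick() + "\n")
        # combined matrix in leaf order: raw above diagonal, normalized below
        order = [sim.names.index(n) for n in tree.leaf_order]
        combined = sim.raw[order][:, order].copy()
        norm = sim.normalized[order][:, order]
        for i in range(len(order)):
            for j in range(i):
                combined[i, j] = norm[i, j]
        _write_tsv(
            pd.DataFrame(combined, index=tree.leaf_order, columns=tree.leaf_order),
            out / "similarity_combined.tsv",
            index=True,
        )
    return {
        "union_bp": profile.union_bp,
        "highly_supported_bp": high.total_bp,
        "size_matched_bp": [m.total_bp for m in working],
        "unique_bp": dict(profile.unique_bp),
        "leaf_order": tree.leaf_order if tree else list(sim.names),
    }


def _stage_individuals(cohort: CohortMaps, out: Path) -> dict:
    pairs_raw, long_raw = individual_jaccard_matrix(cohort, normalized=False)
    pairs_norm, _ = individual_jaccard_matrix(cohort, normalized=True)
    rows = [
        {
            "method_a": r.method_a,
            "method_b": r.method_b,
            "mean_jaccard": r.mean,
            "sd_jaccard": r.sd,
            "mean_normalized_jaccard": n.mean,
            "sd_normalized_jaccard": n.sd,
        }
        for r, n in zip(pairs_raw, pairs_norm)
    ]
    _write_tsv(pd.DataFrame(rows), out / "individual_pairs.tsv")
    _write_tsv(long_raw, out / "individual_jaccard_long.tsv")
    return {
        "n_individuals": len(cohort.individuals),
        "n_methods": len(cohort.methods),
        "mean_jaccard": {f"{r.method_a}|{r.method_b}": r.mean for r in pairs_raw},
    }


def _stage_bstat(maps, b_track: WindowTrack, out: Path, config: PipelineConfig) -> dict:
    frames = []
    summary = {}
    for i, m in enumerate(maps):
        result = contrast(
            m, b_track, n_boot=config.bootstrap_iters, rng=config.seed + i
        )
        df = result.to_frame()
        df.insert(0, "map", m.name)
        frames.append(df)
        summary[m.name] = {"ratio": result.ratio, "p_value": result.p_value}
    _write_tsv(pd.concat(frames, ignore_index=True), out / "bstat_contrast.tsv")
    return summary


def _stage_deserts(desert_sets, maps, out: Path, config: PipelineConfig, genome) -> dict:
    log: dict = {}
    if len(desert_sets) >= 2:
        consensus = desert_consensus(desert_sets, config.desert_consensus_k)
        with open(out / "desert_consensus.bed", "w") as fh:
            for chrom, start, end, support in consensus:
                fh.write(f"{chrom}\t{start}\t{end}\t{support}\n")
        log["n_consensus_regions"] = len(consensus)
    reports = [
        desert_introgression(d, m, genome) for d in desert_sets for m in maps
    ]
    report = pd.concat(reports, ignore_index=True)
    _write_tsv(report, out / "desert_report.tsv")
    log["mean_normalized_fraction"] = float(report["normalized_fraction"].mean())
    return log
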
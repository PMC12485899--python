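"""Introgression-desert consensus and per-desert introgression levels.

Deserts — long regions depleted of archaic ancestry across individuals —
have been called by several studies under differing criteria. This module
(1) finds consensus desert regions supported by at least ``k_min`` study
desert sets, and (2) quantifies, for each desert window and each
introgression map, the raw fraction of the window the map calls
introgressed and that fraction normalized by the map's genome-wide
introgression proportion (so a value near 1 means "as introgressed as an
average window", well below 1 means depleted).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import GenomeDefinition, IntervalSet, coverage_segments, coverage_fraction
from .maps import ScoredMap

__all__ = ["DesertSet", "desert_consensus", "desert_introgression"]


@dataclass
class DesertSet:
    """One study's desert calls."""

    study: str
    regions: IntervalSet


def desert_consensus(
    desert_sets: Sequence[DesertSet], k_min: int
) -> list[tuple[str, int, int, int]]:
    """Maximal merged regions where >= ``k_min`` desert sets overlap.

    Returns ``(chrom, start, end, support)`` rows, where ``support`` is the
    maximum number of concordant studies within the merged region.
    Touching consensus runs merge, so the row count is the number of
    distinct consensus desert regions. ``k_min`` larger than the number of
    sets yields an empty (valid) result.
    """
    if len(desert_sets) < 2:
        raise ValueError("consensus requires at least two desert sets")
    names = [d.study for d in desert_sets]
    if len(set(names)) != len(names):
        raise ValueError("study names must be unique")
    if k_min < 1:
        raise ValueError("k_min must be >= 1")
    genome = desert_sets[0].regions.genome
    rows: list[tuple[str, int, int, int]] = []
    segments = coverage_segments([d.regions for d in desert_sets])
    for chrom in genome.names:
        if chrom not in segments:
            continue
        bounds, counts = segments[chrom]
        run_start = None
        run_support = 0
        prev_end = None
        for s, e, k in zip(bounds[:-1], bounds[1:], counts):
            if k >= k_min:
                if run_start is not None and s == prev_end:
                    run_support = max(run_support, int(k))
                else:
                    if run_start is not None:
                        rows.append((chrom, int(run_start), int(prev_end), run_support))
                    run_start, run_support = s, int(k)
                prev_end = e
            else:
                if run_start is not None:
                    rows.append((chrom, int(run_start), int(prev_end), run_support))
                    run_start = None
        if run_start is not None:
            rows.append((chrom, int(run_start), int(prev_end), run_support))
    return rows


def desert_introgression(
    desert: DesertSet, m: ScoredMap, genome: GenomeDefinition | None = None
) -> pd.DataFrame:
    """Per-desert-window introgression levels for one map.

    For each desert window: ``raw = |window ∩ map| / |window|`` and
    ``normalized = raw / coverage_fraction(map, genome)``. A map with zero
    genome-wide coverage has no defined normalization and is rejected.
    """
    genome = genome if genome is not None else m.genome
    if not genome.compatible(desert.regions.genome):
        raise ValueError("desert set and map are on different genomes")
    genome_wide = coverage_fraction(m.regions, genome)
    if genome_wide == 0:
        raise ValueError(
            f"map {m.name!r} has zero genome-wide coverage; normalization undefined"
        )
    rows = []
    for chrom, start, end in desert.regions:
        window = IntervalSet([(chrom, start, end)], genome)
        overlap = window.overlap_bp(m.regions)
        raw = overlap / (end - start)
        rows.append(
            {
                "study": desert.study,
                "chrom": chrom,
                "start": start,
                "end": end,
                "map": m.name,
                "raw_fraction": raw,
                "normalized_fraction": raw / genome_wide,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "study", "chrom", "start", "end", "map",
            "raw_fraction", "normalized_fraction",
        ],
    )
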
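"""Ingestion and harmonization of scored introgression callsets.

Published introgression maps arrive as BED-like text with heterogeneous
score semantics (LOD scores, CRF posterior probabilities, S'/Sprime scores,
haplotype posteriors) and occasionally closed-end coordinates. This module
reads them through a single generic scored-BED reader with a dialect flag,
then harmonizes fragments into a :class:`ScoredMap`: a canonical interval
set in which each maximal merged region retains the *maximum* score among
the fragments it absorbed.

Study-specific download/parsing recipes and assembly liftover are out of
scope; the analysis operates entirely on this harmonized layer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .intervals import CoordinateError, GenomeDefinition, IntervalSet

__all__ = [
    "ScoredRegion",
    "ScoredMap",
    "read_scored_bed",
    "merge_to_map",
    "variants_to_map",
]

logger = logging.getLogger(__name__)

#: Score assigned when an input lacks a score column; such maps still take
#: part in comparisons but order arbitrarily under size-matching.
UNSCORED_SENTINEL = 1.0


@dataclass(frozen=True)
class ScoredRegion:
    """One called fragment: half-open interval with a confidence score."""

    chrom: str
    start: int
    end: int
    score: float = UNSCORED_SENTINEL
    sample: str | None = None
    population: str | None = None

    def __post_init__(self):
        if self.start >= self.end:
            raise CoordinateError(
                f"region {self.chrom}:{self.start}-{self.end} has start >= end"
            )
        if not np.isfinite(self.score):
            raise ValueError(f"non-finite score for {self.chrom}:{self.start}-{self.end}")


class ScoredMap:
    """An introgression map: canonical regions, one retained score per region."""

    __slots__ = ("name", "regions", "region_scores", "provenance")

    def __init__(
        self,
        name: str,
        regions: IntervalSet,
        region_scores: Sequence[float],
        provenance: str = "",
    ):
        scores = np.asarray(region_scores, dtype=float)
        if scores.size != len(regions):
            raise ValueError(
                f"map {name!r}: {scores.size} scores for {len(regions)} regions"
            )
        self.name = name
        self.regions = regions
        self.region_scores = scores
        self.provenance = provenance

    @property
    def genome(self) -> GenomeDefinition:
        return self.regions.genome

    @property
    def total_bp(self) -> int:
        return self.regions.total_bp

    def __repr__(self) -> str:
        return f"ScoredMap({self.name!r}, {len(self.regions)} regions, {self.total_bp} bp)"

    def records(self) -> Iterable[tuple[str, int, int, float]]:
        for (chrom, start, end), score in zip(self.regions, self.region_scores):
            yield chrom, start, end, float(score)

    def write_bed(self, path) -> None:
        """Write as sorted BED4 (chrom, start, end, score)."""
        with open(path, "w") as fh:
            for chrom, start, end, score in self.records():
                fh.write(f"{chrom}\t{start}\t{end}\t{score:.10g}\n")

    @classmethod
    def read_bed(
        cls,
        path,
        genome: GenomeDefinition,
        name: str | None = None,
        score_col: int = 3,
        dialect: str = "half_open",
        min_score: float | None = None,
    ) -> "ScoredMap":
        regions = read_scored_bed(path, score_col=score_col, dialect=dialect)
        if min_score is not None:
            regions = [r for r in regions if r.score >= min_score]
        return merge_to_map(regions, name or str(path), genome, provenance=str(path))


def read_scored_bed(
    path, score_col: int = 3, dialect: str = "half_open"
) -> list[ScoredRegion]:
    """Read a scored BED-like file into half-open :class:`ScoredRegion` records.

    Parameters
    ----------
    score_col
        0-based column index of the score; if the file has no such column
        every record gets the sentinel score 1.0 (a warning is logged once).
    dialect
        ``"half_open"`` (BED; end exclusive) or ``"closed_end"`` (end
        inclusive; end is incremented on read so internal coordinates are
        uniformly half-open).
    """
    if dialect not in ("half_open", "closed_end"):
        raise ValueError(f"unknown dialect {dialect!r}")
    shift = 1 if dialect == "closed_end" else 0
    out: list[ScoredRegion] = []
    warned = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise CoordinateError(
                    f"{path}:{lineno}: expected >=3 tab-separated columns, got {len(fields)}"
                )
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise CoordinateError(f"{path}:{lineno}: malformed coordinates") from exc
            if len(fields) > score_col:
                try:
                    score = float(fields[score_col])
                except ValueError as exc:
                    raise CoordinateError(
                        f"{path}:{lineno}: non-numeric score {fields[score_col]!r}"
                    ) from exc
            else:
                score = UNSCORED_SENTINEL
                if not warned:
                    logger.warning(
                        "%s: no score column %d; using sentinel score %.1f",
                        path, score_col, UNSCORED_SENTINEL,
                    )
                    warned = True
            out.append(ScoredRegion(chrom, start, end + shift, score))
    return out


def merge_to_map(
    regions: Iterable[ScoredRegion],
    name: str,
    genome: GenomeDefinition,
    provenance: str = "",
) -> ScoredMap:
    """Harmonize fragments into a map: merge overlapping/touching fragments,
    retaining the highest score among the constituents of each merged region.

    An empty fragment list yields a valid empty map.
    """
    regions = list(regions)
    interval_set = IntervalSet(((r.chrom, r.start, r.end) for r in regions), genome)
    n_regions = len(interval_set)
    scores = np.full(n_regions, -np.inf)
    # map each fragment to the merged region containing it (fragments are
    # fully contained in exactly one merged run by construction)
    offsets: dict[str, int] = {}
    acc = 0
    for chrom in genome.names:
        offsets[chrom] = acc
        acc += interval_set.arrays(chrom)[0].size
    for r in regions:
        starts, _ = interval_set.arrays(r.chrom)
        idx = int(np.searchsorted(starts, r.start, side="right")) - 1
        scores[offsets[r.chrom] + idx] = max(scores[offsets[r.chrom] + idx], r.score)
    return ScoredMap(name, interval_set, scores, provenance=provenance)


def variants_to_map(
    positions: Iterable[tuple[str, int]],
    name: str,
    genome: GenomeDefinition,
    score: float = UNSCORED_SENTINEL,
) -> ScoredMap:
    """Turn 1-based variant positions into a map of 1 bp half-open intervals.

    Position ``p`` becomes ``[p-1, p)``; duplicate positions collapse, so
    the map's ``total_bp`` equals the number of distinct positions.
    """
    fragments = []
    for chrom, pos in positions:
        pos = int(pos)
        if pos < 1:
            raise CoordinateError(f"1-based variant position must be >= 1, got {pos}")
        fragments.append(ScoredRegion(str(chrom), pos - 1, pos, score))
    return merge_to_map(fragments, name, genome, provenance="variants")
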
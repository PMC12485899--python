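"""Map-level concordance statistics.

Jaccard and normalized Jaccard at base-pair resolution, size-matched
subsetting to remove map-size confounding, per-bp support profiles and
combination counts, highly supported regions, and farthest-point
(complete-linkage) clustering of the resulting distance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage, to_tree
from scipy.spatial.distance import squareform

from .intervals import GenomeDefinition, IntervalSet, coverage_segments
from .maps import ScoredMap

__all__ = [
    "jaccard",
    "normalized_jaccard",
    "similarity_matrix",
    "SimilarityMatrix",
    "size_match_top_scoring",
    "support_profile",
    "SupportProfile",
    "highly_supported",
    "combination_counts",
    "cluster_farthest_point",
    "ClusterTree",
    "DEFAULT_SIZE_MATCH_BP",
    "DEFAULT_HIGH_SUPPORT_K",
]

#: Default size-matching budget: the smallest published map's total bp
#: (793.9 Mb), used to truncate every map to comparable size.
DEFAULT_SIZE_MATCH_BP = 793_900_000

#: Support count at or above which loci are called "highly supported".
DEFAULT_HIGH_SUPPORT_K = 10


def _as_intervals(m) -> IntervalSet:
    return m.regions if isinstance(m, ScoredMap) else m


def jaccard(a, b) -> float:
    """|a ∩ b| / |a ∪ b| at base-pair resolution; 0 when the union is empty."""
    a, b = _as_intervals(a), _as_intervals(b)
    inter = a.overlap_bp(b)
    union_bp = a.total_bp + b.total_bp - inter
    return inter / union_bp if union_bp else 0.0


def normalized_jaccard(a, b) -> float:
    """|a ∩ b| / min(|a|, |b|): 1 exactly when the smaller map is a subset
    of the larger. 0 when either map is empty."""
    a, b = _as_intervals(a), _as_intervals(b)
    denom = min(a.total_bp, b.total_bp)
    if denom == 0:
        return 0.0
    return a.overlap_bp(b) / denom


@dataclass
class SimilarityMatrix:
    """Pairwise raw and normalized Jaccard similarities between maps."""

    names: tuple[str, ...]
    raw: np.ndarray
    normalized: np.ndarray

    def to_frame(self, which: str = "raw"):
        import pandas as pd

        mat = self.raw if which == "raw" else self.normalized
        return pd.DataFrame(mat, index=self.names, columns=self.names)


def similarity_matrix(maps: Sequence[ScoredMap]) -> SimilarityMatrix:
    names = tuple(m.name for m in maps)
    if len(set(names)) != len(names):
        raise ValueError("map names must be unique")
    n = len(maps)
    raw = np.eye(n)
    norm = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            raw[i, j] = raw[j, i] = jaccard(maps[i], maps[j])
            norm[i, j] = norm[j, i] = normalized_jaccard(maps[i], maps[j])
    return SimilarityMatrix(names, raw, norm)


def size_match_top_scoring(m: ScoredMap, target_bp: int) -> ScoredMap:
    """Truncate a map to its ``target_bp`` highest-scoring base pairs.

    Whole regions are admitted in descending score order (ties broken by
    genome position for determinism); the last admitted region is cut from
    its right end so the returned total is exactly
    ``min(target_bp, map.total_bp)``.
    """
    target_bp = int(target_bp)
    if target_bp < 0:
        raise ValueError("target_bp must be non-negative")
    if target_bp >= m.total_bp:
        return m
    genome = m.genome
    chrom_rank = {name: i for i, name in enumerate(genome.names)}
    records = list(m.records())
    order = sorted(
        range(len(records)),
        key=lambda i: (-records[i][3], chrom_rank[records[i][0]], records[i][1]),
    )
    taken: list[tuple[str, int, int]] = []
    scores: list[float] = []
    remaining = target_bp
    for i in order:
        if remaining == 0:
            break
        chrom, start, end, score = records[i]
        length = end - start
        if length > remaining:
            end = start + remaining
            length = remaining
        taken.append((chrom, start, end))
        scores.append(score)
        remaining -= length
    # reorder to genome order for the canonical interval set / score pairing
    pos_order = sorted(
        range(len(taken)), key=lambda i: (chrom_rank[taken[i][0]], taken[i][1])
    )
    interval_set = IntervalSet([taken[i] for i in pos_order], genome)
    region_scores = _scores_after_merge(
        [taken[i] for i in pos_order], [scores[i] for i in pos_order], interval_set
    )
    return ScoredMap(
        m.name, interval_set, region_scores, provenance=f"{m.provenance} [top {target_bp} bp]"
    )


def _scores_after_merge(fragments, scores, interval_set: IntervalSet) -> np.ndarray:
    """Max score per merged region (selected fragments may merge if adjacent)."""
    genome = interval_set.genome
    out = np.full(len(interval_set), -np.inf)
    offsets, acc = {}, 0
    for chrom in genome.names:
        offsets[chrom] = acc
        acc += interval_set.arrays(chrom)[0].size
    for (chrom, start, _end), score in zip(fragments, scores):
        starts, _ = interval_set.arrays(chrom)
        idx = int(np.searchsorted(starts, start, side="right")) - 1
        pos = offsets[chrom] + idx
        out[pos] = max(out[pos], score)
    return out


@dataclass
class SupportProfile:
    """Partition of the union of maps into runs of constant support count.

    ``runs`` lists maximal ``(chrom, start, end, k)`` stretches with k >= 1
    supporting maps; ``unique_bp`` tallies, per map, the bp that only that
    map calls (the k == 1 runs attributed to their single supporter).
    """

    map_names: tuple[str, ...]
    runs: list[tuple[str, int, int, int]]
    unique_bp: Mapping[str, int]

    @property
    def union_bp(self) -> int:
        return sum(e - s for _, s, e, _ in self.runs)

    def bp_by_support(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for _, s, e, k in self.runs:
            out[k] = out.get(k, 0) + (e - s)
        return out

    def support_at_least(self, k_min: int, genome: GenomeDefinition) -> IntervalSet:
        return IntervalSet(
            ((c, s, e) for c, s, e, k in self.runs if k >= k_min), genome
        )

    def write_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, start, end, k in self.runs:
                fh.write(f"{chrom}\t{start}\t{end}\t{k}\n")


def _bitmask_segments(maps: Sequence[ScoredMap]):
    if not maps:
        raise ValueError("need at least one map")
    if len(maps) > 62:
        raise ValueError("bitmask engine supports at most 62 maps")
    sets = [m.regions for m in maps]
    g0 = sets[0].genome
    for s in sets[1:]:
        if not g0.compatible(s.genome):
            raise ValueError("maps are defined on different genomes")
    weights = [1 << i for i in range(len(sets))]
    return coverage_segments(sets, weights)


def support_profile(maps: Sequence[ScoredMap]) -> SupportProfile:
    """Per-bp support counts over a collection of maps (see Fig-3-style
    histograms of how many maps call each introgressed bp)."""
    names = tuple(m.name for m in maps)
    runs: list[tuple[str, int, int, int]] = []
    unique = {n: 0 for n in names}
    genome = maps[0].genome
    segments = _bitmask_segments(maps)
    for chrom in genome.names:
        if chrom not in segments:
            continue
        bounds, masks = segments[chrom]
        counts = np.array([int(m).bit_count() for m in masks], dtype=np.int64)
        # unique-bp attribution from the k == 1 segments' masks
        solo = counts == 1
        for mask, s, e in zip(masks[solo], bounds[:-1][solo], bounds[1:][solo]):
            unique[names[int(mask).bit_length() - 1]] += int(e - s)
        # merge consecutive segments with equal support count into maximal runs
        run_start, run_count = None, 0
        prev_end = None
        for s, e, k in zip(bounds[:-1], bounds[1:], counts):
            if k == 0:
                if run_start is not None:
                    runs.append((chrom, int(run_start), int(prev_end), int(run_count)))
                    run_start = None
                prev_end = e
                continue
            if run_start is not None and k == run_count and s == prev_end:
                prev_end = e
            else:
                if run_start is not None:
                    runs.append((chrom, int(run_start), int(prev_end), int(run_count)))
                run_start, run_count, prev_end = s, k, e
        if run_start is not None:
            runs.append((chrom, int(run_start), int(prev_end), int(run_count)))
    return SupportProfile(names, runs, unique)


def highly_supported(
    maps: Sequence[ScoredMap], k_min: int = DEFAULT_HIGH_SUPPORT_K
) -> IntervalSet:
    """Merged regions called introgressed by at least ``k_min`` maps."""
    if k_min < 1:
        raise ValueError("k_min must be >= 1")
    profile = support_profile(maps)
    return profile.support_at_least(k_min, maps[0].genome)


def combination_counts(maps: Sequence[ScoredMap]) -> dict[tuple[str, ...], int]:
    """Exact bp attributed to each covering subset of maps (UpSet-style).

    Every bp in the union is assigned to exactly one signature — the set of
    maps that call it — so the counts are disjoint and sum to the union bp.
    """
    names = tuple(m.name for m in maps)
    out: dict[tuple[str, ...], int] = {}
    for chrom, (bounds, masks) in _bitmask_segments(maps).items():
        widths = np.diff(bounds)
        for mask in np.unique(masks):
            if mask == 0:
                continue
            key = tuple(names[i] for i in range(len(names)) if mask >> i & 1)
            out[key] = out.get(key, 0) + int(widths[masks == mask].sum())
    return out


@dataclass
class ClusterTree:
    """Agglomerative complete-linkage merge history over map distance 1 - J."""

    names: tuple[str, ...]
    linkage_matrix: np.ndarray  # scipy linkage format, (n-1) x 4

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    @property
    def leaf_order(self) -> list[str]:
        return [self.names[i] for i in leaves_list(self.linkage_matrix)]

    def to_newick(self) -> str:
        def render(node) -> str:
            if node.is_leaf():
                return self.names[node.id]
            left, right = node.get_left(), node.get_right()
            return (
                f"({render(left)}:{node.dist - left.dist:.6g},"
                f"{render(right)}:{node.dist - right.dist:.6g})"
            )

        return render(to_tree(self.linkage_matrix)) + ";"


def cluster_farthest_point(
    similarity: SimilarityMatrix, which: str = "raw"
) -> ClusterTree:
    """Complete-linkage ("farthest point") clustering on distance 1 - Jaccard.

    Inter-cluster distance is the maximum pairwise distance
    d(u, v) = max dist(u[i], v[j]); merge heights are non-decreasing.
    """
    if which not in ("raw", "normalized"):
        raise ValueError(f"which must be 'raw' or 'normalized', got {which!r}")
    mat = similarity.raw if which == "raw" else similarity.normalized
    if mat.shape[0] < 2:
        raise ValueError("clustering requires at least 2 maps")
    dist = 1.0 - mat
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="complete")
    return ClusterTree(similarity.names, z)
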
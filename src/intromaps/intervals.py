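"""Genome model and exact base-pair interval set algebra.

Every statistic in this package is a base-pair count over sets of genomic
intervals, so the central object is :class:`IntervalSet`: a canonical
(sorted, non-overlapping, non-adjacent) collection of 0-based half-open
intervals per chromosome, tied to a :class:`GenomeDefinition` that fixes
the chromosome universe and the denominator for genome-coverage fractions.

Conventions
-----------
* Coordinates are 0-based half-open, as in BED: a 1 bp feature at 1-based
  position ``p`` is ``[p-1, p)``.
* Touching intervals merge: the algebra is a set of base pairs, and
  adjacency carries no information for any bp-count statistic.
* Assembly gaps are subtracted only inside coverage-fraction computations;
  interval sets themselves store coordinates as given.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "GenomeDefinition",
    "IntervalSet",
    "canonicalize",
    "intersect",
    "union",
    "subtract",
    "coverage_fraction",
    "region_lengths",
]


class CoordinateError(ValueError):
    """An interval violates the coordinate contract (start >= end, out of bounds, unknown chromosome)."""


def _merge_sorted(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge possibly overlapping/touching intervals into canonical form."""
    if starts.size == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    s = starts[order]
    e = np.maximum.accumulate(ends[order])
    # new run begins where a start strictly exceeds the running max end
    new_run = np.empty(s.size, dtype=bool)
    new_run[0] = True
    new_run[1:] = s[1:] > e[:-1]
    run_starts = s[new_run]
    run_idx = np.flatnonzero(new_run)
    run_ends = e[np.append(run_idx[1:] - 1, s.size - 1)]
    return run_starts, run_ends


@dataclass(frozen=True)
class GenomeDefinition:
    """Ordered chromosomes with lengths, plus optional assembly-gap intervals.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length)`` pairs; names unique, lengths positive.
    gaps
        Optional assembly gaps as ``(chrom, start, end)`` triples (or an
        :class:`IntervalSet`); each gap must lie within its chromosome.
        The *effective size* — total length minus gap bp — is the
        denominator for genome-coverage fractions.
    """

    chromosomes: tuple[tuple[str, int], ...]
    gaps: "IntervalSet | None" = field(default=None, compare=False)

    def __init__(
        self,
        chromosomes: Iterable[tuple[str, int]],
        gaps: "IntervalSet | Iterable[tuple[str, int, int]] | None" = None,
    ):
        chroms = tuple((str(n), int(l)) for n, l in chromosomes)
        names = [n for n, _ in chroms]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        if any(l <= 0 for _, l in chroms):
            raise ValueError("chromosome lengths must be positive")
        object.__setattr__(self, "chromosomes", chroms)
        object.__setattr__(self, "gaps", None)
        if gaps is not None:
            if not isinstance(gaps, IntervalSet):
                gaps = canonicalize(gaps, self)
            elif not self.compatible(gaps.genome):
                raise ValueError("gap intervals built on a different genome")
            object.__setattr__(self, "gaps", IntervalSet(gaps.to_tuples(), self))
        if self.effective_size <= 0:
            raise ValueError("effective genome size (length minus gaps) must be positive")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.chromosomes)

    @property
    def lengths(self) -> Mapping[str, int]:
        return dict(self.chromosomes)

    @property
    def total_size(self) -> int:
        return sum(l for _, l in self.chromosomes)

    @property
    def effective_size(self) -> int:
        gap_bp = self.gaps.total_bp if self.gaps is not None else 0
        return self.total_size - gap_bp

    def compatible(self, other: "GenomeDefinition") -> bool:
        """Two genomes are operation-compatible when chromosome names and lengths agree."""
        return self.chromosomes == other.chromosomes

    @classmethod
    def from_chrom_sizes(cls, path, gaps_bed=None) -> "GenomeDefinition":
        """Load from a two-column chrom-sizes file, optionally with a gaps BED."""
        chroms = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                name, length = line.split("\t")[:2]
                chroms.append((name, int(length)))
        gaps = None
        if gaps_bed is not None:
            gaps = list(_read_bed3(gaps_bed))
        return cls(chroms, gaps)


def _read_bed3(path) -> Iterator[tuple[str, int, int]]:
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise CoordinateError(f"{path}:{i}: expected >=3 tab-separated columns")
            yield fields[0], int(fields[1]), int(fields[2])


class IntervalSet:
    """Canonical set of genomic intervals on one genome.

    Stored per chromosome as sorted numpy arrays of starts and ends
    (0-based, half-open). Construction canonicalizes: overlapping and
    touching intervals are merged, so ``total_bp`` is exactly the size of
    the underlying base-pair set.
    """

    __slots__ = ("genome", "_data")

    def __init__(
        self,
        intervals: Iterable[tuple[str, int, int]] = (),
        genome: GenomeDefinition | None = None,
    ):
        if genome is None:
            raise ValueError("an IntervalSet requires a GenomeDefinition")
        self.genome = genome
        lengths = genome.lengths
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            chrom = str(chrom)
            if chrom not in lengths:
                raise CoordinateError(f"unknown chromosome {chrom!r}")
            start, end = int(start), int(end)
            if start >= end:
                raise CoordinateError(
                    f"interval {chrom}:{start}-{end} has start >= end"
                )
            if start < 0 or end > lengths[chrom]:
                raise CoordinateError(
                    f"interval {chrom}:{start}-{end} outside [0, {lengths[chrom]})"
                )
            by_chrom.setdefault(chrom, []).append((start, end))
        data: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, pairs in by_chrom.items():
            arr = np.asarray(pairs, dtype=np.int64)
            data[chrom] = _merge_sorted(arr[:, 0], arr[:, 1])
        self._data = data

    @classmethod
    def _from_arrays(
        cls, data: dict[str, tuple[np.ndarray, np.ndarray]], genome: GenomeDefinition
    ) -> "IntervalSet":
        """Internal: wrap already-canonical arrays without re-validating."""
        obj = cls.__new__(cls)
        obj.genome = genome
        obj._data = {c: (s, e) for c, (s, e) in data.items() if s.size}
        return obj

    # -- basic introspection -------------------------------------------------

    def arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(starts, ends) for one chromosome (empty arrays if none)."""
        if chrom in self._data:
            return self._data[chrom]
        empty = np.empty(0, dtype=np.int64)
        return empty, empty

    def to_tuples(self) -> list[tuple[str, int, int]]:
        out = []
        for chrom in self.genome.names:
            s, e = self.arrays(chrom)
            out.extend((chrom, int(a), int(b)) for a, b in zip(s, e))
        return out

    def __iter__(self) -> Iterator[tuple[str, int, int]]:
        return iter(self.to_tuples())

    def __len__(self) -> int:
        return sum(s.size for s, _ in self._data.values())

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.genome.compatible(other.genome) and self.to_tuples() == other.to_tuples()

    def __repr__(self) -> str:
        return f"IntervalSet({len(self)} regions, {self.total_bp} bp)"

    @property
    def total_bp(self) -> int:
        return int(sum((e - s).sum() for s, e in self._data.values()))

    def is_empty(self) -> bool:
        return not self._data

    # -- set algebra ---------------------------------------------------------

    def _check(self, other: "IntervalSet") -> None:
        if not self.genome.compatible(other.genome):
            raise ValueError("interval sets are defined on different genomes")

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        self._check(other)
        return _combine([self, other], lambda v: v == 2)

    def union(self, other: "IntervalSet") -> "IntervalSet":
        self._check(other)
        return _combine([self, other], lambda v: v >= 1)

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        self._check(other)
        return _combine([self, other], lambda v: v == 1, weights=[1, -1])

    __and__ = intersect
    __or__ = union
    __sub__ = subtract

    def region_lengths(self) -> np.ndarray:
        """Length of each maximal region, in genome order."""
        if not self._data:
            return np.empty(0, dtype=np.int64)
        return np.concatenate(
            [self.arrays(c)[1] - self.arrays(c)[0] for c in self.genome.names]
        )

    def overlap_bp(self, other: "IntervalSet") -> int:
        return self.intersect(other).total_bp

    def write_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, start, end in self:
                fh.write(f"{chrom}\t{start}\t{end}\n")

    @classmethod
    def read_bed(cls, path, genome: GenomeDefinition) -> "IntervalSet":
        return cls(_read_bed3(path), genome)


def coverage_segments(
    sets: Sequence[IntervalSet], weights: Sequence[int] | None = None
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Sweep-line decomposition of the genome into constant-value segments.

    For each chromosome returns ``(bounds, values)`` where ``bounds`` is the
    sorted array of breakpoints and ``values[i]`` is the summed weight of
    sets covering ``[bounds[i], bounds[i+1])``. With unit weights the value
    is the support count; with weights ``1 << i`` it is the exact covering
    bitmask. Segments outside every set have value 0.
    """
    if weights is None:
        weights = [1] * len(sets)
    genome = sets[0].genome
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in genome.names:
        pos_parts, delta_parts = [], []
        for s_set, w in zip(sets, weights):
            starts, ends = s_set.arrays(chrom)
            if starts.size:
                pos_parts.append(starts)
                delta_parts.append(np.full(starts.size, w, dtype=np.int64))
                pos_parts.append(ends)
                delta_parts.append(np.full(ends.size, -w, dtype=np.int64))
        if not pos_parts:
            continue
        pos = np.concatenate(pos_parts)
        delta = np.concatenate(delta_parts)
        bounds, inverse = np.unique(pos, return_inverse=True)
        agg = np.zeros(bounds.size, dtype=np.int64)
        np.add.at(agg, inverse, delta)
        values = np.cumsum(agg)[:-1]  # value on [bounds[i], bounds[i+1])
        out[chrom] = (bounds, values)
    return out


def _combine(sets, predicate, weights=None) -> IntervalSet:
    genome = sets[0].genome
    data: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, (bounds, values) in coverage_segments(sets, weights).items():
        keep = predicate(values)
        if not keep.any():
            continue
        seg_s = bounds[:-1][keep]
        seg_e = bounds[1:][keep]
        data[chrom] = _merge_sorted(seg_s, seg_e)
    return IntervalSet._from_arrays(data, genome)


# -- module-level functional forms ------------------------------------------


def canonicalize(
    raw_intervals: Iterable[tuple[str, int, int]], genome: GenomeDefinition
) -> IntervalSet:
    """Merge raw (possibly overlapping/touching) intervals into canonical form."""
    return IntervalSet(raw_intervals, genome)


def intersect(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    return a.intersect(b)


def union(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    return a.union(b)


def subtract(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    return a.subtract(b)


def region_lengths(interval_set: IntervalSet) -> np.ndarray:
    return interval_set.region_lengths()


def coverage_fraction(interval_set: IntervalSet, genome: GenomeDefinition | None = None) -> float:
    """Fraction of the gap-free genome covered by ``interval_set``.

    Gap bp are removed from both numerator and denominator, so a map equal
    to the entire gap-free genome has coverage exactly 1.
    """
    if genome is None:
        genome = interval_set.genome
    elif not genome.compatible(interval_set.genome):
        raise ValueError("genome definitions differ")
    covered = interval_set
    if genome.gaps is not None and not genome.gaps.is_empty():
        gaps = IntervalSet(genome.gaps.to_tuples(), interval_set.genome)
        covered = interval_set.subtract(gaps)
    return covered.total_bp / genome.effective_size
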
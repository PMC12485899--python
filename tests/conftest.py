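"""Shared fixtures and brute-force per-bp oracles.

The oracles represent interval sets as boolean membership arrays over toy
chromosomes, so every set statistic can be recomputed by elementary numpy
reductions, independently of the interval algebra under test.
"""

from __future__ import annotations

import numpy as np
import pytest

from intromaps import GenomeDefinition, IntervalSet


@pytest.fixture
def toy_genome() -> GenomeDefinition:
    return GenomeDefinition([("1", 10_000), ("2", 6_000)])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20_240_901)


# ---------------------------------------------------------------------------
# per-bp boolean oracle


def mask_of(intervals, genome: GenomeDefinition) -> dict[str, np.ndarray]:
    """Boolean membership array per chromosome for any iterable of
    (chrom, start, end) or an IntervalSet."""
    masks = {name: np.zeros(length, dtype=bool) for name, length in genome.chromosomes}
    for chrom, start, end in intervals:
        masks[chrom][start:end] = True
    return masks


def mask_to_tuples(masks: dict[str, np.ndarray], genome: GenomeDefinition):
    """Maximal runs of True, as (chrom, start, end), in genome order."""
    out = []
    for chrom in genome.names:
        m = masks[chrom]
        padded = np.concatenate([[False], m, [False]])
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)
        out.extend((chrom, int(s), int(e)) for s, e in zip(starts, ends))
    return out


def mask_bp(masks: dict[str, np.ndarray]) -> int:
    return int(sum(m.sum() for m in masks.values()))


def random_intervals(rng, genome, n, max_len=400):
    """Random raw (possibly overlapping) intervals across the genome."""
    out = []
    names = genome.names
    lengths = genome.lengths
    for _ in range(n):
        chrom = names[rng.integers(len(names))]
        length = int(rng.integers(1, max_len + 1))
        start = int(rng.integers(0, lengths[chrom] - length + 1))
        out.append((chrom, start, start + length))
    return out


def random_interval_set(rng, genome, n=30, max_len=400) -> IntervalSet:
    return IntervalSet(random_intervals(rng, genome, n, max_len), genome)
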
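"""Synthetic introgression-map ensembles with known ground truth.

Real introgression maps are large published callsets; for testing and
benchmarking, this module generates interval-level stand-ins with the
structural features the comparison pipeline cares about:

* ``generate_ensemble`` — M maps sharing a "core" fraction of the genome
  (emulating the highly supported core seen across real maps) plus
  independent per-map private regions, with exponential/geometric tract
  lengths, higher confidence scores on core than on private regions, and
  desert zones that are guaranteed introgression-free in every map.
* ``generate_cohort`` — per-individual maps for a shared cohort under
  several "methods" with known per-method sensitivity, giving a
  closed-form expected individual-level Jaccard.
* ``generate_b_track`` — a background-selection score track (values in
  1–1,000, quantized to multiples of 50) whose mean differs between
  introgressed and non-introgressed windows by a controlled
  multiplicative effect ``delta``.

Every generator consumes a single seed that fans out to per-component
substreams (``numpy.random.SeedSequence``), so outputs are byte-stable and
adding a map does not perturb earlier maps. Closed-form expectations for
the generated statistics are provided alongside, so recovery tests never
compare an implementation against itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import Sequence

import numpy as np

from .bstat import WindowTrack, label_windows, tile_windows
from .deserts import DesertSet
from .individuals import CohortMaps
from .intervals import GenomeDefinition, IntervalSet
from .maps import ScoredMap, ScoredRegion, merge_to_map

__all__ = [
    "default_toy_genome",
    "EnsembleSpec",
    "generate_ensemble",
    "expected_support_share",
    "generate_cohort",
    "expected_individual_jaccard",
    "BTrackSpec",
    "generate_b_track",
    "generate_desert_sets",
]


def default_toy_genome() -> GenomeDefinition:
    """Two toy chromosomes (800 kb + 400 kb), enough to exercise
    multi-chromosome code paths while keeping simulations fast."""
    return GenomeDefinition([("1", 800_000), ("2", 400_000)])


# ---------------------------------------------------------------------------
# region placement


def _sample_lengths(rng: np.random.Generator, total: int, mean_len: float) -> np.ndarray:
    """Geometric region lengths (mean ``mean_len``) summing exactly to ``total``."""
    if total == 0:
        return np.empty(0, dtype=np.int64)
    lengths: list[np.ndarray] = []
    acc = 0
    p = min(1.0, 1.0 / mean_len)
    while acc < total:
        batch = rng.geometric(p, size=max(8, int(total / mean_len) + 8)).astype(np.int64)
        lengths.append(batch)
        acc += int(batch.sum())
    flat = np.concatenate(lengths)
    cum = np.cumsum(flat)
    k = int(np.searchsorted(cum, total)) + 1
    flat = flat[:k]
    flat[-1] -= int(cum[k - 1] - total)
    return flat[flat > 0]


def _place_regions(
    avail: IntervalSet, total_bp: int, mean_len: float, rng: np.random.Generator
) -> list[tuple[str, int, int]]:
    """Place non-overlapping regions of total ``total_bp`` uniformly at
    random within the available space (stars-and-bars over the
    concatenated available pieces; regions crossing piece boundaries are
    split, preserving the exact bp total)."""
    free = avail.total_bp
    if total_bp > free:
        raise ValueError(f"cannot place {total_bp} bp into {free} bp of available space")
    lengths = _sample_lengths(rng, total_bp, mean_len)
    k = lengths.size
    if k == 0:
        return []
    slack = free - total_bp
    offsets = np.sort(rng.integers(0, slack + 1, size=k))
    starts_concat = offsets + np.concatenate([[0], np.cumsum(lengths[:-1])])
    # concatenated coordinate -> genome coordinate mapping
    pieces = avail.to_tuples()
    piece_len = np.array([e - s for _, s, e in pieces], dtype=np.int64)
    piece_off = np.concatenate([[0], np.cumsum(piece_len)])
    out: list[tuple[str, int, int]] = []
    for s, l in zip(starts_concat, lengths):
        e = s + l
        i = int(np.searchsorted(piece_off, s, side="right")) - 1
        while s < e:
            chrom, ps, pe = pieces[i]
            seg_start = ps + (s - piece_off[i])
            seg_end = min(pe, ps + (e - piece_off[i]))
            out.append((chrom, int(seg_start), int(seg_end)))
            s += seg_end - seg_start
            i += 1
    return out


# ---------------------------------------------------------------------------
# multi-map ensembles


@dataclass(frozen=True)
class EnsembleSpec:
    """Construction parameters for a synthetic map ensemble.

    Fractions are relative to the genome's effective size. The core
    (shared by all maps) and the desert zones are carved out first; each
    map's private regions are then placed independently and uniformly in
    the remaining space, so private coverage is independent across maps.
    """

    genome: GenomeDefinition = field(default_factory=default_toy_genome)
    n_maps: int = 5
    core_fraction: float = 0.3
    private_fraction: float | tuple[float, ...] = 0.1
    mean_region_length: float = 3_000.0
    core_score_mean: float = 8.0
    private_score_mean: float = 3.0
    score_sd: float = 1.0
    deserts: tuple[tuple[str, int, int], ...] = (
        ("1", 600_000, 650_000),
        ("2", 300_000, 330_000),
    )
    seed: int = 0

    def private_fractions(self) -> tuple[float, ...]:
        if isinstance(self.private_fraction, (int, float)):
            return (float(self.private_fraction),) * self.n_maps
        if len(self.private_fraction) != self.n_maps:
            raise ValueError("need one private fraction per map")
        return tuple(float(f) for f in self.private_fraction)

    def validate(self) -> None:
        if self.n_maps < 1:
            raise ValueError("n_maps must be >= 1")
        if self.core_fraction < 0 or any(f < 0 for f in self.private_fractions()):
            raise ValueError("fractions must be non-negative")
        effective = self.genome.effective_size
        desert_bp = IntervalSet(self.deserts, self.genome).total_bp if self.deserts else 0
        core_bp = round(self.core_fraction * effective)
        avail = effective - desert_bp - core_bp
        if core_bp > effective - desert_bp:
            raise ValueError("core fraction infeasible given desert zones")
        for f in self.private_fractions():
            if round(f * effective) > avail:
                raise ValueError("private fraction infeasible given core and deserts")


def generate_ensemble(spec: EnsembleSpec) -> tuple[list[ScoredMap], dict]:
    """Generate the ensemble; returns (maps, ground_truth).

    ``ground_truth`` holds the core :class:`IntervalSet` (present in every
    map), each map's private set, the desert zones, and the available
    space the privates were drawn from — everything a recovery test needs.
    """
    spec.validate()
    genome = spec.genome
    ss = np.random.SeedSequence(spec.seed)
    streams = [np.random.default_rng(c) for c in ss.spawn(spec.n_maps + 1)]
    core_rng, map_rngs = streams[0], streams[1:]

    deserts = IntervalSet(spec.deserts, genome)
    placeable = _whole_genome(genome).subtract(deserts)
    if genome.gaps is not None:
        placeable = placeable.subtract(
            IntervalSet(genome.gaps.to_tuples(), genome)
        )
    core_bp = round(spec.core_fraction * genome.effective_size)
    core = IntervalSet(
        _place_regions(placeable, core_bp, spec.mean_region_length, core_rng), genome
    )
    core_tuples = core.to_tuples()
    avail = placeable.subtract(core)

    maps: list[ScoredMap] = []
    privates: list[IntervalSet] = []
    for i, (frac, rng) in enumerate(zip(spec.private_fractions(), map_rngs)):
        t_priv = round(frac * genome.effective_size)
        priv_tuples = _place_regions(avail, t_priv, spec.mean_region_length, rng)
        priv = IntervalSet(priv_tuples, genome)
        fragments = [
            ScoredRegion(c, s, e, float(rng.normal(spec.core_score_mean, spec.score_sd)))
            for c, s, e in core_tuples
        ] + [
            ScoredRegion(c, s, e, float(rng.normal(spec.private_score_mean, spec.score_sd)))
            for c, s, e in priv_tuples
        ]
        maps.append(merge_to_map(fragments, f"map{i + 1:02d}", genome, provenance="synthetic"))
        privates.append(priv)

    ground_truth = {
        "core": core,
        "privates": privates,
        "deserts": deserts,
        "available": avail,
        "core_bp": core.total_bp,
        "private_bp": [p.total_bp for p in privates],
    }
    return maps, ground_truth


def _whole_genome(genome: GenomeDefinition) -> IntervalSet:
    return IntervalSet([(n, 0, l) for n, l in genome.chromosomes], genome)


def expected_support_share(spec: EnsembleSpec) -> tuple[float, float]:
    """Closed-form (mean, sd) of the share of union bp supported by all M maps.

    The core contributes deterministically; private coverage behaves, per
    map, as a stationary on/off renewal process with on-probability
    q = private_bp / available_bp and mean on-length L, independent across
    maps. The union (and all-maps intersection) of M such processes has an
    exponentially decaying autocovariance whose integral gives the
    variance of covered bp; the ratio's sd follows by the delta method.
    Because each map's private total is fixed exactly by construction, the
    first-order (own-total fluctuation) term of the covariance expansion
    vanishes under that conditioning, so the sums start at j = 2.
    """
    spec.validate()
    effective = spec.genome.effective_size
    desert_bp = IntervalSet(spec.deserts, spec.genome).total_bp if spec.deserts else 0
    c_bp = round(spec.core_fraction * effective)
    a_bp = effective - desert_bp - c_bp
    fracs = spec.private_fractions()
    q = float(np.mean([round(f * effective) / a_bp for f in fracs]))
    m = spec.n_maps
    l_mean = spec.mean_region_length

    pu = 1.0 - (1.0 - q) ** m  # P(bp in union of privates)
    ps = q**m  # P(bp in all privates)
    eu = c_bp + a_bp * pu
    es = c_bp + a_bp * ps

    # Var of covered bp: 2F * sum_{j>=2} C(M,j) a^(M-j) b^j / (j*r),
    # r = 1/(L(1-q)); j = 1 drops out because per-map totals are exact
    inv_r = l_mean * (1.0 - q)
    a_u, b_u = (1.0 - q) ** 2, q * (1.0 - q)
    var_u = 2.0 * a_bp * inv_r * sum(
        comb(m, j) * a_u ** (m - j) * b_u**j / j for j in range(2, m + 1)
    )
    a_s, b_s = q**2, q * (1.0 - q)
    var_s = 2.0 * a_bp * inv_r * sum(
        comb(m, j) * a_s ** (m - j) * b_s**j / j for j in range(2, m + 1)
    )
    var_ratio = (es / eu**2) ** 2 * var_u + var_s / eu**2
    return es / eu, float(np.sqrt(var_ratio))


def support_share(maps: Sequence[ScoredMap]) -> float:
    """Observed share of union bp supported by every map in the ensemble."""
    from .compare import support_profile

    profile = support_profile(maps)
    by_k = profile.bp_by_support()
    return by_k.get(len(maps), 0) / profile.union_bp


# ---------------------------------------------------------------------------
# individual-level cohorts


def generate_cohort(
    genome: GenomeDefinition,
    n_individuals: int,
    sensitivities: dict[str, float],
    carry_prob: float = 0.5,
    population_fraction: float = 0.2,
    mean_region_length: float = 3_000.0,
    error_mode: str = "independent",
    seed: int = 0,
) -> tuple[CohortMaps, dict]:
    """Per-individual maps for a shared cohort under several methods.

    A set of population regions is placed once; each individual carries
    each region independently with ``carry_prob``. Each method detects a
    region according to a per-region detection mask with probability equal
    to its sensitivity. ``error_mode="independent"`` draws masks
    independently per method; ``"disjoint"`` assigns each method's missed
    regions to disjoint slices of the region pool (requires the miss rates
    to sum to <= 1), so two methods never miss the same region.
    """
    if not 0.0 <= carry_prob <= 1.0:
        raise ValueError("carry_prob must be in [0, 1]")
    if error_mode not in ("independent", "disjoint"):
        raise ValueError(f"unknown error_mode {error_mode!r}")
    methods = tuple(sensitivities)
    misses = [1.0 - sensitivities[m] for m in methods]
    if error_mode == "disjoint" and sum(misses) > 1.0 + 1e-12:
        raise ValueError("disjoint error mode requires miss rates summing to <= 1")
    ss = np.random.SeedSequence(seed)
    region_rng, mask_rng, carry_rng = (np.random.default_rng(c) for c in ss.spawn(3))

    placeable = _whole_genome(genome)
    if genome.gaps is not None:
        placeable = placeable.subtract(IntervalSet(genome.gaps.to_tuples(), genome))
    total = round(population_fraction * genome.effective_size)
    regions = _place_regions(placeable, total, mean_region_length, region_rng)
    n_regions = len(regions)

    detected = {}
    if error_mode == "independent":
        for m in methods:
            detected[m] = mask_rng.random(n_regions) < sensitivities[m]
    else:
        u = mask_rng.random(n_regions)
        offset = 0.0
        for m, miss in zip(methods, misses):
            detected[m] = ~((u >= offset) & (u < offset + miss))
            offset += miss

    individuals = tuple(f"ind{i + 1:03d}" for i in range(n_individuals))
    carried = carry_rng.random((n_individuals, n_regions)) < carry_prob
    maps: dict[tuple[str, str], ScoredMap] = {}
    for m in methods:
        for i, ind in enumerate(individuals):
            keep = carried[i] & detected[m]
            frags = [
                ScoredRegion(c, s, e, 1.0)
                for (c, s, e), k in zip(regions, keep)
                if k
            ]
            maps[(m, ind)] = merge_to_map(frags, f"{m}:{ind}", genome)
    cohort = CohortMaps(methods, individuals, maps)
    truth = {"regions": regions, "detected": detected, "carried": carried}
    return cohort, truth


def expected_individual_jaccard(s1: float, s2: float, error_mode: str = "independent") -> float:
    """Closed-form expected per-individual Jaccard for two methods with
    sensitivities ``s1``, ``s2`` under the cohort generator's construction
    (in the limit of many carried regions)."""
    if error_mode == "disjoint":
        return max(s1 + s2 - 1.0, 0.0)
    both = s1 * s2
    either = s1 + s2 - both
    return both / either if either else 0.0


# ---------------------------------------------------------------------------
# B-statistic tracks


@dataclass(frozen=True)
class BTrackSpec:
    """Baseline B distribution and the multiplicative effect on
    introgressed windows. Emitted values are quantized to multiples of 50
    within [50, 1000], mimicking published B tracks."""

    b_mean: float = 600.0
    b_sd: float = 120.0
    delta: float = 1.0  # multiplicative effect on introgressed windows
    window: int = 500
    seed: int = 0

    def validate(self) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.window <= 0:
            raise ValueError("window must be positive")


def quantize_b(raw: np.ndarray) -> np.ndarray:
    """Round to the nearest multiple of 50 and clamp into [50, 1000]."""
    return np.clip(np.round(raw / 50.0) * 50.0, 50.0, 1000.0)


def generate_b_track(spec: BTrackSpec, m: ScoredMap) -> WindowTrack:
    """B track over the map's genome: baseline Normal(b_mean, b_sd) values,
    scaled by ``delta`` on introgressed windows, then quantized. With mild
    quantization the expected ratio of class means is ~= delta."""
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    track = tile_windows(m.genome, spec.window)
    track = label_windows(track, m)
    df = track.windows
    raw = rng.normal(spec.b_mean, spec.b_sd, size=len(df))
    flag = df["introgressed"].to_numpy(dtype=bool)
    raw[flag] *= spec.delta
    df = df.assign(b=quantize_b(raw))
    return WindowTrack(track.genome, track.width, df)


# ---------------------------------------------------------------------------
# desert study sets


def generate_desert_sets(
    genome: GenomeDefinition,
    true_deserts: Sequence[tuple[str, int, int]],
    n_studies: int = 5,
    include_prob: float = 0.9,
    jitter_bp: int = 2_000,
    seed: int = 0,
) -> list[DesertSet]:
    """Study-specific desert callsets around shared true desert zones.

    Each study includes each true desert with ``include_prob`` and jitters
    its boundaries by up to ``jitter_bp`` (clamped to the chromosome),
    emulating the differing criteria used by published desert studies.
    """
    ss = np.random.SeedSequence(seed)
    lengths = genome.lengths
    sets = []
    for i, child in enumerate(ss.spawn(n_studies)):
        rng = np.random.default_rng(child)
        rows = []
        for chrom, start, end in true_deserts:
            if rng.random() >= include_prob:
                continue
            s = int(np.clip(start + rng.integers(-jitter_bp, jitter_bp + 1), 0, lengths[chrom] - 1))
            e = int(np.clip(end + rng.integers(-jitter_bp, jitter_bp + 1), s + 1, lengths[chrom]))
            rows.append((chrom, s, e))
        sets.append(DesertSet(f"study{i + 1}", IntervalSet(rows, genome)))
    return sets
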
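"""Window tiling, labeling, B attachment, bootstrap, rank-sum, contrast."""

from itertools import combinations

import numpy as np
import pytest

from intromaps import (
    GenomeDefinition,
    WindowTrack,
    attach_b_values,
    bootstrap_mean,
    contrast,
    label_windows,
    merge_to_map,
    rank_sum_test,
    tile_windows,
)
from intromaps.maps import ScoredRegion
from intromaps.synthetic import BTrackSpec, EnsembleSpec, generate_b_track, generate_ensemble

from conftest import mask_of, random_interval_set


def _map_from(intervals, genome, name="m"):
    return merge_to_map(
        [ScoredRegion(c, s, e, 1.0) for c, s, e in intervals], name, genome
    )


class TestTileWindows:
    def test_trailing_partial_window(self):
        g = GenomeDefinition([("1", 1_250)])
        t = tile_windows(g, 500)
        assert list(map(tuple, t.windows[["start", "end"]].to_numpy())) == [
            (0, 500), (500, 1_000), (1_000, 1_250)
        ]

    def test_single_window_when_width_equals_length(self):
        g = GenomeDefinition([("1", 700)])
        assert len(tile_windows(g, 700)) == 1

    def test_window_count(self, toy_genome):
        t = tile_windows(toy_genome, 300)
        expected = sum(-(-l // 300) for _, l in toy_genome.chromosomes)
        assert len(t) == expected

    def test_gap_windows_dropped(self):
        g = GenomeDefinition([("1", 2_000)], gaps=[("1", 500, 1_500)])
        t = tile_windows(g, 500)
        starts = t.windows["start"].tolist()
        assert starts == [0, 1_500]  # the two fully-gapped windows are gone


class TestLabelWindows:
    def test_one_bp_overlap_suffices(self):
        g = GenomeDefinition([("1", 2_000)])
        t = tile_windows(g, 500)
        labelled = label_windows(t, _map_from([("1", 499, 501)], g))
        assert labelled.windows["introgressed"].tolist() == [True, True, False, False]

    def test_empty_map_all_false(self, toy_genome):
        t = tile_windows(toy_genome, 500)
        labelled = label_windows(t, _map_from([], toy_genome))
        assert not labelled.windows["introgressed"].any()

    def test_matches_per_bp_overlap_oracle(self, toy_genome, rng):
        t = tile_windows(toy_genome, 250)
        for _ in range(10):
            m = random_interval_set(rng, toy_genome, n=20, max_len=300)
            labelled = label_windows(t, m)
            masks = mask_of(m, toy_genome)
            for row in labelled.windows.itertuples(index=False):
                assert row.introgressed == bool(masks[row.chrom][row.start:row.end].any())


class TestAttachBValues:
    def test_bp_weighted_mean_across_segments(self):
        g = GenomeDefinition([("1", 1_000)])
        t = tile_windows(g, 500)
        segs = [("1", 0, 250, 100.0), ("1", 250, 600, 500.0)]
        out = attach_b_values(t, segs)
        b = out.windows["b"].tolist()
        assert b[0] == pytest.approx((250 * 100 + 250 * 500) / 500)
        assert b[1] == pytest.approx(500.0)  # only 100 covered bp, all at 500

    def test_uncovered_window_is_missing(self):
        g = GenomeDefinition([("1", 1_000)])
        out = attach_b_values(tile_windows(g, 500), [("1", 0, 400, 200.0)])
        assert np.isnan(out.windows["b"].iloc[1])

    def test_rejects_overlapping_segments(self):
        g = GenomeDefinition([("1", 1_000)])
        with pytest.raises(ValueError, match="overlapping"):
            attach_b_values(tile_windows(g, 500), [("1", 0, 300, 1.0), ("1", 200, 400, 2.0)])


class TestBootstrapMean:
    def test_identical_values_degenerate_ci(self):
        mean, lo, hi = bootstrap_mean([7.0] * 20, rng=0)
        assert (mean, lo, hi) == (7.0, 7.0, 7.0)

    def test_ci_contains_sample_mean(self, rng):
        x = rng.normal(10, 3, size=200)
        mean, lo, hi = bootstrap_mean(x, rng=1)
        assert lo <= mean <= hi

    def test_deterministic_under_seed(self, rng):
        x = rng.normal(size=50)
        assert bootstrap_mean(x, rng=42) == bootstrap_mean(x, rng=42)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            bootstrap_mean([])

    def test_coverage_near_nominal(self):
        """95% percentile CI covers the true mean at roughly nominal rate."""
        mu, covered, n_rep = 800.0, 0, 200
        master = np.random.default_rng(123)
        for _ in range(n_rep):
            x = master.normal(mu, 50, size=400)
            _, lo, hi = bootstrap_mean(x, n_iter=400, rng=master)
            covered += lo <= mu <= hi
        assert 0.89 <= covered / n_rep <= 0.99


def oracle_exact_p(x, y):
    """Independent enumeration oracle: U via pairwise comparisons, p by
    counting assignments at least as extreme (two-sided, from n1*n2/2)."""
    x, y = list(x), list(y)
    n1, n2 = len(x), len(y)
    pooled = x + y

    def u_of(xs, ys):
        return sum(
            1.0 if a > b else 0.5 if a == b else 0.0 for a in xs for b in ys
        )

    mu = n1 * n2 / 2
    obs = abs(u_of(x, y) - mu)
    hits = total = 0
    for idx in combinations(range(n1 + n2), n1):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(n1 + n2) if i not in idx]
        total += 1
        if abs(u_of(xs, ys) - mu) >= obs - 1e-12:
            hits += 1
    return hits / total


class TestRankSum:
    def test_identical_multisets(self):
        x = [1.0, 2.0, 3.0, 4.0]
        u, p = rank_sum_test(x, list(x))
        assert u == pytest.approx(len(x) ** 2 / 2)
        assert p == pytest.approx(1.0)

    def test_maximal_separation(self):
        u, p = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)  # 2/20 most extreme assignments

    def test_all_tied_warns_p_one(self):
        with pytest.warns(UserWarning, match="tied"):
            u, p = rank_sum_test([5.0, 5.0], [5.0, 5.0, 5.0])
        assert p == 1.0

    def test_small_samples_match_enumeration_oracle(self, rng):
        for n1 in (1, 2, 3, 5, 7):
            for n2 in (1, 3, 6, 7):
                x = rng.integers(0, 5, size=n1).astype(float)  # ties likely
                y = rng.integers(0, 5, size=n2).astype(float)
                if np.all(np.concatenate([x, y]) == x[0]):
                    continue  # all-tied draws warn and return 1 by contract
                _, p = rank_sum_test(x, y)
                assert p == pytest.approx(oracle_exact_p(x, y), abs=1e-12)

    def test_large_sample_uses_tie_corrected_normal(self, rng):
        x = rng.integers(0, 10, 100).astype(float)
        y = (rng.integers(0, 10, 120) + 1.5).astype(float)
        _, p = rank_sum_test(x, y)
        assert 0 < p < 1


class TestContrast:
    def test_constant_b_ratio_one(self, toy_genome, rng):
        m = _map_from([("1", 0, 3_000)], toy_genome)
        track = tile_windows(toy_genome, 500)
        track.windows["b"] = 750.0
        with pytest.warns(UserWarning, match="tied"):
            result = contrast(m, track, rng=0)
        assert result.ratio == 1.0 and result.p_value == 1.0

    def test_inverted_flags_invert_ratio(self, toy_genome):
        m = _map_from([("1", 0, 3_000), ("2", 100, 2_100)], toy_genome)
        track = tile_windows(toy_genome, 500)
        track.windows["b"] = np.random.default_rng(5).normal(600, 50, len(track))
        r1 = contrast(m, track, rng=0)
        flipped = label_windows(track, m)
        flipped.windows["introgressed"] = ~flipped.windows["introgressed"]
        r2 = contrast(None, flipped, rng=0)
        assert r2.ratio == pytest.approx(1 / r1.ratio)

    def test_empty_class_rejected(self, toy_genome):
        track = tile_windows(toy_genome, 500)
        track.windows["b"] = 100.0
        with pytest.raises(ValueError, match="introgressed"):
            contrast(_map_from([], toy_genome), track, rng=0)

    def test_injected_effect_recovered(self):
        spec = EnsembleSpec(seed=3, n_maps=1, core_fraction=0.25)
        (m,), _ = generate_ensemble(spec)
        track = generate_b_track(BTrackSpec(delta=1.06, seed=4), m)
        result = contrast(None, track, rng=5)
        assert result.ci_ratio[0] <= 1.06 <= result.ci_ratio[1]
        assert result.ratio == pytest.approx(1.06, abs=0.02)
        assert result.p_value < 0.01
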
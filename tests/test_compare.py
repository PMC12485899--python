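"""Map-level concordance: Jaccard statistics, size-matching, support
profiles, combination counts, and farthest-point clustering."""

import numpy as np
import pytest

from intromaps import (
    IntervalSet,
    ScoredRegion,
    cluster_farthest_point,
    combination_counts,
    highly_supported,
    jaccard,
    merge_to_map,
    normalized_jaccard,
    similarity_matrix,
    size_match_top_scoring,
    support_profile,
)

from conftest import mask_bp, mask_of, mask_to_tuples, random_interval_set


def _scored(intervals_scores, genome, name="m"):
    return merge_to_map(
        [ScoredRegion(c, s, e, sc) for (c, s, e), sc in intervals_scores], name, genome
    )


def _random_map(rng, genome, name, n=25):
    regions = random_interval_set(rng, genome, n=n, max_len=300)
    scores = rng.random(len(regions)) * 10
    return merge_to_map(
        [ScoredRegion(c, s, e, sc) for (c, s, e), sc in zip(regions, scores)],
        name, genome,
    )


class TestJaccard:
    def test_examples(self, toy_genome):
        a = IntervalSet([("1", 0, 10)], toy_genome)
        b = IntervalSet([("1", 5, 15)], toy_genome)
        assert jaccard(a, b) == pytest.approx(5 / 15)
        assert normalized_jaccard(a, b) == pytest.approx(5 / 10)
        assert jaccard(a, a) == 1.0

    def test_empty_conventions(self, toy_genome):
        empty = IntervalSet([], toy_genome)
        assert jaccard(empty, empty) == 0.0
        assert normalized_jaccard(empty, empty) == 0.0

    def test_subset_gives_normalized_one(self, toy_genome):
        small = IntervalSet([("1", 100, 200)], toy_genome)
        big = IntervalSet([("1", 0, 500)], toy_genome)
        assert normalized_jaccard(small, big) == 1.0
        assert jaccard(small, big) < 1.0

    def test_matches_per_bp_oracle(self, toy_genome, rng):
        for _ in range(30):
            a = random_interval_set(rng, toy_genome)
            b = random_interval_set(rng, toy_genome)
            ma, mb = mask_of(a, toy_genome), mask_of(b, toy_genome)
            inter = sum((ma[c] & mb[c]).sum() for c in ma)
            union = sum((ma[c] | mb[c]).sum() for c in ma)
            assert jaccard(a, b) == pytest.approx(inter / union)
            assert normalized_jaccard(a, b) == pytest.approx(
                inter / min(mask_bp(ma), mask_bp(mb))
            )
            assert normalized_jaccard(a, b) >= jaccard(a, b)


class TestSizeMatch:
    def test_target_at_least_total_is_identity(self, toy_genome, rng):
        m = _random_map(rng, toy_genome, "m")
        assert size_match_top_scoring(m, m.total_bp + 100) is m

    def test_greedy_order_with_truncation(self, toy_genome):
        m = _scored([(("1", 0, 10), 3.0), (("1", 100, 110), 5.0)], toy_genome)
        out = size_match_top_scoring(m, 15)
        # whole score-5 region, then left 5 bp of the score-3 region
        assert out.regions.to_tuples() == [("1", 0, 5), ("1", 100, 110)]
        assert out.total_bp == 15

    def test_rejects_negative_target(self, toy_genome, rng):
        with pytest.raises(ValueError, match="non-negative"):
            size_match_top_scoring(_random_map(rng, toy_genome, "m"), -1)

    def test_matches_brute_force_greedy(self, toy_genome, rng):
        chrom_rank = {n: i for i, n in enumerate(toy_genome.names)}
        for _ in range(20):
            m = _random_map(rng, toy_genome, "m")
            target = int(rng.integers(0, m.total_bp + 1))
            out = size_match_top_scoring(m, target)
            assert out.total_bp == min(target, m.total_bp)
            # oracle: independently re-run the greedy selection on records
            recs = sorted(
                m.records(), key=lambda r: (-r[3], chrom_rank[r[0]], r[1])
            )
            expected = []
            left = target
            for chrom, start, end, score in recs:
                if left <= 0:
                    break
                take = min(end - start, left)
                expected.append((score, take))
                left -= take
            got = sorted((s, e - st) for (c, st, e), s in
                         zip(out.regions, out.region_scores))
            assert got == sorted(expected)

    def test_monotone_in_target(self, toy_genome, rng):
        m = _random_map(rng, toy_genome, "m")
        small = size_match_top_scoring(m, m.total_bp // 3)
        large = size_match_top_scoring(m, 2 * m.total_bp // 3)
        assert (small.regions - large.regions).total_bp == 0  # subset


class TestSupportProfile:
    def test_identical_maps_all_support_m(self, toy_genome, rng):
        m = _random_map(rng, toy_genome, "a")
        maps = [merge_to_map(
            [ScoredRegion(c, s, e, sc) for (c, s, e, sc) in m.records()], n, toy_genome)
            for n in ("a", "b", "c")]
        profile = support_profile(maps)
        assert all(k == 3 for _, _, _, k in profile.runs)
        assert profile.union_bp == m.total_bp

    def test_conservation_and_oracle(self, toy_genome, rng):
        maps = [_random_map(rng, toy_genome, f"m{i}") for i in range(12)]
        profile = support_profile(maps)
        counts = {c: np.zeros(l, dtype=int) for c, l in toy_genome.chromosomes}
        for m in maps:
            for c, mask in mask_of(m.regions, toy_genome).items():
                counts[c] += mask
        # conservation: runs partition the union
        union_bp = sum((cnt > 0).sum() for cnt in counts.values())
        assert profile.union_bp == union_bp
        assert sum(profile.bp_by_support().values()) == union_bp
        # exact per-bp support counts
        for chrom, start, end, k in profile.runs:
            assert (counts[chrom][start:end] == k).all()
        # maximality: support changes (or coverage ends) at run boundaries
        for chrom, start, end, k in profile.runs:
            if start > 0:
                assert counts[chrom][start - 1] != k
            if end < toy_genome.lengths[chrom]:
                assert counts[chrom][end] != k
        # unique bp per map
        for i, m in enumerate(maps):
            mine = mask_of(m.regions, toy_genome)
            expected = sum(
                int((mine[c] & (counts[c] == 1)).sum()) for c in mine
            )
            assert profile.unique_bp[m.name] == expected


class TestHighlySupported:
    def test_k1_is_union_and_km_identical(self, toy_genome, rng):
        maps = [_random_map(rng, toy_genome, f"m{i}") for i in range(4)]
        union = maps[0].regions
        for m in maps[1:]:
            union = union | m.regions
        assert highly_supported(maps, 1) == union
        same = [merge_to_map(
            [ScoredRegion(c, s, e, sc) for c, s, e, sc in maps[0].records()],
            f"c{i}", toy_genome) for i in range(3)]
        assert highly_supported(same, 3) == maps[0].regions

    def test_k_above_m_empty(self, toy_genome, rng):
        maps = [_random_map(rng, toy_genome, f"m{i}") for i in range(3)]
        assert highly_supported(maps, 5).total_bp == 0

    def test_threshold_matches_oracle(self, toy_genome, rng):
        maps = [_random_map(rng, toy_genome, f"m{i}") for i in range(6)]
        counts = {c: np.zeros(l, dtype=int) for c, l in toy_genome.chromosomes}
        for m in maps:
            for c, mask in mask_of(m.regions, toy_genome).items():
                counts[c] += mask
        for k_min in (1, 2, 4, 6):
            expected = mask_to_tuples(
                {c: counts[c] >= k_min for c in counts}, toy_genome
            )
            assert highly_supported(maps, k_min).to_tuples() == expected


class TestCombinationCounts:
    def test_disjoint_maps_give_singletons(self, toy_genome):
        a = _scored([(("1", 0, 10), 1.0)], toy_genome, "a")
        b = _scored([(("1", 100, 150), 1.0)], toy_genome, "b")
        assert combination_counts([a, b]) == {("a",): 10, ("b",): 50}

    def test_signatures_match_per_bp_oracle(self, toy_genome, rng):
        maps = [_random_map(rng, toy_genome, f"m{i}") for i in range(5)]
        combos = combination_counts(maps)
        masks = [mask_of(m.regions, toy_genome) for m in maps]
        expected: dict[tuple[str, ...], int] = {}
        for chrom, length in toy_genome.chromosomes:
            sig = np.zeros(length, dtype=int)
            for i, mk in enumerate(masks):
                sig |= mk[chrom].astype(int) << i
            vals, cnts = np.unique(sig, return_counts=True)
            for v, n in zip(vals, cnts):
                if v == 0:
                    continue
                key = tuple(maps[i].name for i in range(5) if v >> i & 1)
                expected[key] = expected.get(key, 0) + int(n)
        assert combos == expected
        union_bp = support_profile(maps).union_bp
        assert sum(combos.values()) == union_bp


class TestClustering:
    def _sim_from_dist(self, names, dist):
        from intromaps import SimilarityMatrix

        sim = 1.0 - dist
        np.fill_diagonal(sim, 1.0)
        return SimilarityMatrix(tuple(names), sim, sim)

    def test_three_point_example(self):
        dist = np.array([[0.0, 0.1, 0.9], [0.1, 0.0, 0.9], [0.9, 0.9, 0.0]])
        tree = cluster_farthest_point(self._sim_from_dist("ABC", dist))
        heights = tree.heights
        assert heights[0] == pytest.approx(0.1)
        assert heights[1] == pytest.approx(0.9)
        assert set(tree.linkage_matrix[0, :2]) == {0.0, 1.0}

    def test_identical_maps_merge_at_zero(self, toy_genome, rng):
        m = _random_map(rng, toy_genome, "a")
        clones = [merge_to_map(
            [ScoredRegion(c, s, e, sc) for c, s, e, sc in m.records()],
            n, toy_genome) for n in ("a", "b", "c")]
        tree = cluster_farthest_point(similarity_matrix(clones))
        assert np.allclose(tree.heights, 0.0)

    def test_single_map_rejected(self, toy_genome, rng):
        sim = similarity_matrix([_random_map(rng, toy_genome, "a")])
        with pytest.raises(ValueError, match="at least 2"):
            cluster_farthest_point(sim)

    def test_matches_exhaustive_complete_linkage(self, rng):
        for _ in range(25):
            n = 6
            d = rng.random((n, n))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0.0)
            tree = cluster_farthest_point(self._sim_from_dist([str(i) for i in range(n)], d))
            expected = brute_force_complete_linkage(d)
            got = merges_from_linkage(tree.linkage_matrix, n)
            for (h1, s1), (h2, s2) in zip(expected, got):
                assert h1 == pytest.approx(h2)
                assert s1 == s2

    def test_heights_non_decreasing(self, toy_genome, rng):
        maps = [_random_map(rng, toy_genome, f"m{i}") for i in range(6)]
        tree = cluster_farthest_point(similarity_matrix(maps))
        assert (np.diff(tree.heights) >= -1e-12).all()
        assert tree.linkage_matrix.shape == (5, 4)
        newick = tree.to_newick()
        assert newick.endswith(";") and all(m.name in newick for m in maps)


def brute_force_complete_linkage(d: np.ndarray):
    """Exhaustive complete-linkage reference: at each step merge the pair
    of clusters with the smallest maximum pairwise leaf distance."""
    clusters = [frozenset([i]) for i in range(d.shape[0])]
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                h = max(d[a, b] for a in clusters[i] for b in clusters[j])
                if best is None or h < best[0]:
                    best = (h, i, j)
        h, i, j = best
        merged = clusters[i] | clusters[j]
        merges.append((h, merged))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return merges


def merges_from_linkage(z: np.ndarray, n: int):
    """(height, merged leaf set) per merge, from a scipy linkage matrix."""
    members = {i: frozenset([i]) for i in range(n)}
    out = []
    for row_idx, (a, b, h, _) in enumerate(z):
        merged = members[int(a)] | members[int(b)]
        members[n + row_idx] = merged
        out.append((h, merged))
    return out
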
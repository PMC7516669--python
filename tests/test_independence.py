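"""Pairwise dependence tests, block decomposition, split-dimension rule."""

import itertools

import numpy as np
import pytest

from cadee import (
    EstimatorConfig,
    calibrate_mi_cutoff,
    choose_split_dimension,
    correlated,
    dependency_matrix,
    find_blocks,
    mi_cutoff,
    pair_dependent,
    rank_transform,
    spearman_matrix,
)


class TestSpearman:
    def test_monotone_relations_give_unit_correlation(self, rng):
        x = rng.standard_normal(50)
        u = rank_transform(np.column_stack([x, np.exp(x), -x]))
        r = spearman_matrix(u)
        assert r[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert r[0, 2] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_hand_computed_rank_correlation(self):
        # 5x2 table with ranks (1..5) and (2,1,4,3,5): Pearson of ranks = 0.8
        x = np.column_stack([[10.0, 20, 30, 40, 50], [5.0, 1, 8, 7, 9]])
        r = spearman_matrix(rank_transform(x))
        assert r[0, 1] == pytest.approx(0.8, abs=1e-12)


class TestCorrelationTest:
    def test_zero_correlation_never_significant(self):
        assert not correlated(0.0, 50)

    def test_perfect_correlation_always_significant(self):
        assert correlated(1.0, 4)
        assert correlated(-1.0, 4)

    def test_t_statistic_threshold(self):
        # r=0.1 at n=1000: t ~ 3.17 > 1.962
        assert correlated(0.1, 1000, alpha=0.05)
        # same r at n=100: t ~ 1.0, not significant
        assert not correlated(0.1, 100, alpha=0.05)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            correlated(0.5, 3)


class TestMiCutoff:
    def test_closed_form_values(self):
        assert mi_cutoff(10_000) == pytest.approx(-0.75 * 10_000**-0.62, rel=1e-12)
        assert mi_cutoff(100) == pytest.approx(-0.0431, abs=2e-3)

    def test_magnitude_shrinks_with_n(self):
        ns = [10, 100, 10_000, 1_000_000]
        mags = [abs(mi_cutoff(n)) for n in ns]
        assert all(a > b for a, b in zip(mags, mags[1:]))

    def test_calibration_is_negative_and_near_power_law(self):
        cal = calibrate_mi_cutoff(10_000, alpha=0.05, reps=300, seed=1)
        assert cal < 0.0
        ratio = cal / mi_cutoff(10_000)
        assert 0.5 < ratio < 2.0

    def test_calibration_deterministic_given_seed(self):
        a = calibrate_mi_cutoff(500, reps=100, seed=3)
        b = calibrate_mi_cutoff(500, reps=100, seed=3)
        assert a == b


class TestPairDependence:
    def test_comonotone_pair_is_dependent(self, rng):
        u = rank_transform(rng.standard_normal((1000, 1)))
        assert pair_dependent(u[:, 0], u[:, 0])

    def test_ring_detected_through_mi_branch(self):
        # points on the unit circle: near-zero correlation, strong dependence
        rng = np.random.default_rng(7)
        theta = rng.uniform(0, 2 * np.pi, 10_000)
        u = rank_transform(np.column_stack([np.cos(theta), np.sin(theta)]))
        r = spearman_matrix(u)[0, 1]
        assert not correlated(r, 10_000)  # correlation alone misses it
        assert pair_dependent(u[:, 0], u[:, 1])

    def test_paired_structure_recovered_in_blocks(self):
        """The (1,2)(3,4) pairing is detected; cross-pair edges are rare.

        Each truly-independent cross pair is falsely flagged with
        probability ~2*alpha, so the exact block-diagonal pattern shows
        up for most but not all seeds.
        """
        from cadee import DistributionSpec, Family, sample_distribution

        exact_pattern = 0
        for seed in range(5):
            x = sample_distribution(DistributionSpec(Family.C2, 4), 100_000, seed)
            A = dependency_matrix(rank_transform(x))
            assert A[0, 1] and A[2, 3]  # the real pairs are always caught
            if [list(b) for b in find_blocks(A)] == [[0, 1], [2, 3]]:
                exact_pattern += 1
        assert exact_pattern >= 3

    def test_single_dimension_matrix(self, rng):
        A = dependency_matrix(rank_transform(rng.random((50, 1))))
        assert A.shape == (1, 1) and A[0, 0]


class TestBlocks:
    def test_worked_three_node_example(self):
        A = np.array([[1, 0, 1], [0, 1, 0], [1, 0, 1]], dtype=bool)
        blocks = find_blocks(A)
        assert [list(b) for b in blocks] == [[0, 2], [1]]

    def test_identity_gives_singletons(self):
        blocks = find_blocks(np.eye(4, dtype=bool))
        assert [list(b) for b in blocks] == [[0], [1], [2], [3]]

    def test_full_matrix_gives_one_block(self):
        blocks = find_blocks(np.ones((5, 5), dtype=bool))
        assert [list(b) for b in blocks] == [[0, 1, 2, 3, 4]]

    def test_asymmetric_rejected(self):
        A = np.eye(3, dtype=bool)
        A[0, 1] = True
        with pytest.raises(ValueError):
            find_blocks(A)

    @pytest.mark.parametrize("d", [2, 3, 4])
    def test_exhaustive_against_union_find(self, d):
        """All 2^(d(d-1)/2) graphs agree with a brute-force union-find."""
        pairs = list(itertools.combinations(range(d), 2))
        for mask in range(2 ** len(pairs)):
            A = np.eye(d, dtype=bool)
            parent = list(range(d))

            def find(i):
                while parent[i] != i:
                    parent[i] = parent[parent[i]]
                    i = parent[i]
                return i

            for bit, (i, j) in enumerate(pairs):
                if mask >> bit & 1:
                    A[i, j] = A[j, i] = True
                    parent[find(i)] = find(j)
            expected = {}
            for i in range(d):
                expected.setdefault(find(i), []).append(i)
            expected = sorted(expected.values())
            got = [list(b) for b in find_blocks(A)]
            assert got == expected


class TestSplitDimension:
    def test_identity_ties_break_to_first(self):
        assert choose_split_dimension(np.eye(3)) == 0

    def test_strongest_row_wins(self):
        r = np.eye(3)
        r[0, 1] = r[1, 0] = 0.9
        r[0, 2] = r[2, 0] = 0.5
        assert choose_split_dimension(r) == 0

    def test_permutation_equivariance(self):
        r = np.eye(3)
        r[0, 1] = r[1, 0] = 0.9
        r[0, 2] = r[2, 0] = 0.5
        perm = [2, 0, 1]
        rp = r[np.ix_(perm, perm)]
        assert perm[choose_split_dimension(rp)] == choose_split_dimension(r)
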
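"""Mantel tests, residual summaries, group averages, and UPGMA trees."""

from __future__ import annotations

import numpy as np
import pytest

from kmerbeta.correlation_stats import (
    condense,
    correlation,
    group_averages,
    mantel,
    residual_stats,
    upgma_tree,
)
from kmerbeta.dissimilarity import DissimilarityMatrix
from kmerbeta.errors import DataError, UndefinedCorrelationError

from conftest import random_dissimilarity
from _oracles import group_means, mantel_naive, newick_clades, random_ultrametric


class TestCondense:
    def test_three_by_three_order(self):
        v = np.array([[0.0, 0.1, 0.2], [0.1, 0.0, 0.3], [0.2, 0.3, 0.0]])
        m = DissimilarityMatrix(["a", "b", "c"], v)
        assert condense(m).tolist() == [0.1, 0.2, 0.3]

    def test_two_samples_give_length_one(self):
        m = DissimilarityMatrix(["a", "b"], np.array([[0.0, 0.4], [0.4, 0.0]]))
        assert condense(m).tolist() == [0.4]

    def test_asymmetric_and_nonhollow_rejected(self):
        bad = DissimilarityMatrix(["a", "b"], np.array([[0.0, 0.4], [0.5, 0.0]]))
        with pytest.raises(DataError):
            condense(bad)
        nonhollow = DissimilarityMatrix(["a", "b"], np.array([[0.1, 0.4], [0.4, 0.0]]))
        with pytest.raises(DataError):
            condense(nonhollow)


class TestCorrelation:
    def test_exact_linearity(self):
        assert correlation([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)

    def test_monotone_nonlinear(self):
        assert correlation([1, 2, 3], [1, 4, 9], "spearman") == pytest.approx(1.0)
        assert correlation([1, 2, 3], [1, 4, 9], "pearson") < 1.0

    def test_spearman_average_ranks_for_ties(self):
        # ranks [1, 2.5, 2.5, 4] vs [1, 2, 3, 4]
        r = correlation([1, 2, 2, 3], [1, 2, 3, 4], "spearman")
        assert r == pytest.approx(4.5 / np.sqrt(4.5 * 5.0), abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            correlation([1, 1, 1], [1, 2, 3])

    def test_too_short_rejected(self):
        with pytest.raises(DataError):
            correlation([1, 2], [1, 2])


class TestMantel:
    def test_statistic_equals_condensed_correlation(self, rng):
        m1 = random_dissimilarity(rng, 10)
        m2 = random_dissimilarity(rng, 10)
        for method in ("pearson", "spearman"):
            res = mantel(m1, m2, method=method, n_permutations=99, seed=0)
            expected = correlation(condense(m1), condense(m2), method)
            assert abs(res.statistic - expected) < 1e-12

    def test_perfect_linear_relation_hits_p_floor(self, rng):
        m1 = random_dissimilarity(rng, 12)
        m2 = DissimilarityMatrix(m1.labels, 0.5 * m1.values, "scaled")
        res = mantel(m1, m2, method="pearson", n_permutations=999, seed=1)
        assert res.statistic == pytest.approx(1.0, abs=1e-12)
        assert res.p_value == pytest.approx(0.001)

    def test_alignment_by_label_not_position(self, rng):
        m1 = random_dissimilarity(rng, 8)
        m2 = random_dissimilarity(rng, 8)
        perm = rng.permutation(8)
        shuffled = m2.reorder([m2.labels[i] for i in perm])
        r1 = mantel(m1, m2, n_permutations=99, seed=5)
        r2 = mantel(m1, shuffled, n_permutations=99, seed=5)
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-12)
        assert r1.p_value == r2.p_value

    def test_label_mismatch_rejected(self, rng):
        m1 = random_dissimilarity(rng, 5)
        m2 = random_dissimilarity(rng, 5, labels=[f"X{i}" for i in range(5)])
        with pytest.raises(DataError):
            mantel(m1, m2)

    def test_too_small_rejected(self, rng):
        m = random_dissimilarity(rng, 2)
        with pytest.raises(DataError):
            mantel(m, m)

    @pytest.mark.parametrize("method", ["pearson", "spearman"])
    @pytest.mark.parametrize("alternative", ["two-sided", "greater"])
    def test_matches_naive_permutation_oracle(self, rng, method, alternative):
        # same generator protocol -> identical permutations; the naive oracle
        # re-ranks every permuted matrix from scratch
        m1 = random_dissimilarity(rng, 9)
        m2 = random_dissimilarity(rng, 9)
        res = mantel(m1, m2, method=method, n_permutations=199,
                     alternative=alternative, seed=77)
        obs, p = mantel_naive(m1.values, m2.values, method, 199, alternative, 77)
        assert res.statistic == pytest.approx(obs, abs=1e-12)
        assert res.p_value == pytest.approx(p, abs=1e-12)

    @pytest.mark.parametrize("method", ["pearson", "spearman"])
    def test_statistic_matches_scikit_bio(self, rng, method):
        from skbio.stats.distance import DistanceMatrix, mantel as skbio_mantel

        m1 = random_dissimilarity(rng, 10)
        m2 = random_dissimilarity(rng, 10)
        res = mantel(m1, m2, method=method, n_permutations=99, seed=3)
        r_ref, _, _ = skbio_mantel(DistanceMatrix(m1.values, m1.labels),
                                   DistanceMatrix(m2.values, m2.labels),
                                   method=method, permutations=0)
        assert res.statistic == pytest.approx(float(r_ref), abs=1e-10)

    def test_pvalue_never_below_floor(self, rng):
        m1 = random_dissimilarity(rng, 6)
        res = mantel(m1, m1, n_permutations=99, seed=0)
        assert res.p_value >= 1 / 100

    def test_seed_reproducibility(self, rng):
        m1 = random_dissimilarity(rng, 8)
        m2 = random_dissimilarity(rng, 8)
        a = mantel(m1, m2, n_permutations=199, seed=42)
        b = mantel(m1, m2, n_permutations=199, seed=42)
        assert (a.statistic, a.p_value) == (b.statistic, b.p_value)


class TestResidualStats:
    def test_identical_matrices(self, rng):
        m = random_dissimilarity(rng, 6)
        assert residual_stats(m, m) == (0.0, 0.0)

    def test_hand_example_population_variance(self):
        # condensed residuals are [0.1, 0.3, 0.0]: population variance (ddof=0)
        m1 = DissimilarityMatrix(["a", "b", "c"],
                                 np.array([[0, 0.5, 0.3], [0.5, 0, 0.0],
                                           [0.3, 0.0, 0]], dtype=float))
        m2 = DissimilarityMatrix(["a", "b", "c"],
                                 np.array([[0, 0.4, 0.0], [0.4, 0, 0.0],
                                           [0.0, 0.0, 0]], dtype=float))
        mean, var = residual_stats(m1, m2)
        assert mean == pytest.approx(0.4 / 3)
        assert var == pytest.approx(np.mean(np.square([0.1, 0.3, 0.0])) - (0.4 / 3) ** 2)
        # sample variance differs and is available via ddof
        assert residual_stats(m1, m2, ddof=1)[1] == pytest.approx(np.var([0.1, 0.3, 0.0], ddof=1))

    def test_symmetric_in_arguments(self, rng):
        m1 = random_dissimilarity(rng, 7)
        m2 = random_dissimilarity(rng, 7)
        assert residual_stats(m1, m2) == residual_stats(m2, m1)


class TestGroupAverages:
    def _block_matrix(self):
        labels = ["a1", "a2", "b1", "b2"]
        v = np.full((4, 4), 0.9)
        v[0, 1] = v[1, 0] = v[2, 3] = v[3, 2] = 0.1
        np.fill_diagonal(v, 0.0)
        return DissimilarityMatrix(labels, v), {"a1": "G1", "a2": "G1", "b1": "G2", "b2": "G2"}

    def test_constant_blocks(self):
        m, groups = self._block_matrix()
        table = group_averages(m, groups).set_index(["group_a", "group_b"])
        assert table.loc[("G1", "G1"), "mean_dissimilarity"] == pytest.approx(0.1)
        assert table.loc[("G2", "G2"), "mean_dissimilarity"] == pytest.approx(0.1)
        assert table.loc[("G1", "G2"), "mean_dissimilarity"] == pytest.approx(0.9)

    def test_single_group_equals_condensed_mean(self, rng):
        m = random_dissimilarity(rng, 6)
        table = group_averages(m, {l: "G" for l in m.labels})
        assert table.loc[0, "mean_dissimilarity"] == pytest.approx(condense(m).mean())

    def test_matches_bruteforce_for_random_grouping(self, rng):
        m = random_dissimilarity(rng, 12)
        groups = {l: f"G{rng.integers(0, 4)}" for l in m.labels}
        expected = group_means(m.values, m.labels, groups)
        table = group_averages(m, groups)
        for _, row in table.iterrows():
            key = tuple(sorted((row.group_a, row.group_b)))
            if key in expected:
                assert row.mean_dissimilarity == pytest.approx(expected[key])
            else:
                assert np.isnan(row.mean_dissimilarity)

    def test_singleton_group_intra_is_nan(self):
        m = DissimilarityMatrix(["a", "b"], np.array([[0.0, 0.3], [0.3, 0.0]]))
        table = group_averages(m, {"a": "G1", "b": "G2"}).set_index(["group_a", "group_b"])
        assert np.isnan(table.loc[("G1", "G1"), "mean_dissimilarity"])
        assert table.loc[("G1", "G2"), "mean_dissimilarity"] == pytest.approx(0.3)

    def test_unlabelled_sample_rejected(self, rng):
        m = random_dissimilarity(rng, 4)
        with pytest.raises(DataError):
            group_averages(m, {m.labels[0]: "G"})


class TestUpgma:
    def test_two_step_hand_example(self):
        v = np.array([[0.0, 0.2, 0.8], [0.2, 0.0, 0.8], [0.8, 0.8, 0.0]])
        m = DissimilarityMatrix(["A", "B", "C"], v)
        assert upgma_tree(m) == "((A:0.1,B:0.1):0.3,C:0.4);"

    def test_two_leaves_cherry(self):
        m = DissimilarityMatrix(["A", "B"], np.array([[0.0, 0.3], [0.3, 0.0]]))
        assert upgma_tree(m) == "(A:0.15,B:0.15);"

    def test_identical_samples_join_first_at_zero(self):
        v = np.array([[0.0, 0.0, 0.6], [0.0, 0.0, 0.6], [0.6, 0.6, 0.0]])
        m = DissimilarityMatrix(["A", "B", "C"], v)
        assert upgma_tree(m).startswith("((A:0,B:0)")

    def test_deterministic_under_ties(self):
        # all off-diagonals equal: tie-break must pick the same pair each time
        v = np.full((4, 4), 0.5)
        np.fill_diagonal(v, 0.0)
        m = DissimilarityMatrix(["d", "c", "b", "a"], v)
        assert upgma_tree(m) == upgma_tree(m.reorder(["a", "b", "c", "d"]))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_recovers_ultrametric_topology(self, seed):
        rng = np.random.default_rng(seed)
        labels, values, clades = random_ultrametric(rng, 8)
        m = DissimilarityMatrix(labels, values)
        assert newick_clades(upgma_tree(m)) == clades
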
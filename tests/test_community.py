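"""Community statistics: rarefaction, Bray-Curtis, Shannon, UPGMA, NMDS, ANOSIM."""

import itertools

import numpy as np
import pandas as pd
import pytest

from dnasip.community import (
    DissimilarityMatrix,
    OtuTable,
    anosim_test,
    bray_curtis_matrix,
    nmds_embed,
    nmds_stress_path,
    shannon_index,
    subsample_counts,
    upgma_cluster,
)


def brute_force_bray_curtis(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    return np.abs(a - b).sum() / (a + b).sum()


def exact_anosim(values, labels):
    """Full-enumeration oracle: R and exact permutation p (all n! labelings)."""
    from scipy.stats import rankdata

    n = len(labels)
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(values[iu])
    M = len(ranks)

    def r_of(lab):
        lab = np.asarray(lab)
        within = lab[iu[0]] == lab[iu[1]]
        return (ranks[~within].mean() - ranks[within].mean()) / (M / 2)

    obs = r_of(labels)
    rs = [r_of(p) for p in itertools.permutations(labels)]
    p = sum(r >= obs - 1e-12 for r in rs) / len(rs)
    return obs, p


def table_from_counts(rows, labels=None):
    labels = labels or [f"s{i}" for i in range(len(rows))]
    counts = pd.DataFrame(rows, index=labels)
    counts.columns = [f"OTU{j}" for j in range(counts.shape[1])]
    return OtuTable(counts=counts)


class TestSubsample:
    def test_single_otu_row(self):
        t = subsample_counts(table_from_counts([[10, 0, 0], [8, 1, 1]]), depth=5, seed=0)
        assert list(t.counts.iloc[0]) == [5, 0, 0]

    def test_depth_equal_to_row_sum_is_identity(self):
        t0 = table_from_counts([[3, 4, 5], [6, 3, 3]])
        t = subsample_counts(t0, depth=12, seed=0)
        assert t.counts.equals(t0.counts)

    def test_rows_sum_to_depth_and_never_exceed_original(self, rng):
        t0 = table_from_counts(rng.integers(0, 50, size=(6, 30)) + 1)
        t = subsample_counts(t0, depth=100, seed=5)
        assert (t.counts.sum(axis=1) == 100).all()
        assert (t.counts.to_numpy() <= t0.counts.to_numpy()).all()

    def test_hypergeometric_expectation(self):
        t0 = table_from_counts([[500, 500], [500, 500]])
        means = []
        for s in range(1000):
            t = subsample_counts(t0, depth=100, seed=s)
            means.append(t.counts.iloc[0, 0])
        assert np.mean(means) == pytest.approx(50.0, abs=2.0)

    def test_shallow_samples_dropped_with_warning(self):
        t0 = table_from_counts([[5, 0], [50, 50]])
        with pytest.warns(UserWarning, match="dropping"):
            t = subsample_counts(t0, depth=20, seed=1)
        assert list(t.counts.index) == ["s1"]

    def test_nonpositive_depth_rejected(self):
        with pytest.raises(ValueError):
            subsample_counts(table_from_counts([[5, 5]]), depth=0, seed=1)


class TestBrayCurtis:
    def test_identical_rows_are_zero(self):
        d = bray_curtis_matrix(table_from_counts([[3, 3, 4], [3, 3, 4]]))
        assert d.values[0, 1] == 0.0

    def test_disjoint_rows_are_one(self):
        d = bray_curtis_matrix(table_from_counts([[5, 0], [0, 9]]))
        assert d.values[0, 1] == pytest.approx(1.0)

    def test_raw_count_worked_example(self):
        d = bray_curtis_matrix(table_from_counts([[6, 2], [2, 2]]), use_relative=False)
        assert d.values[0, 1] == pytest.approx(1 / 3)

    def test_matches_brute_force_on_random_pairs(self, rng):
        for _ in range(100):
            a = rng.integers(0, 40, size=25) + (rng.random(25) < 0.5)
            b = rng.integers(0, 40, size=25) + 1.0
            ra, rb = a / a.sum(), b / b.sum()
            d = bray_curtis_matrix(table_from_counts([a, b]))
            assert abs(d.values[0, 1] - brute_force_bray_curtis(ra, rb)) <= 1e-12

    def test_zero_total_sample_rejected(self):
        with pytest.raises(ValueError, match="zero total"):
            bray_curtis_matrix(table_from_counts([[0, 0], [1, 2]]))

    def test_matrix_invariants(self, rng):
        t = table_from_counts(rng.integers(0, 30, size=(5, 20)) + 1)
        d = bray_curtis_matrix(t)
        assert np.allclose(d.values, d.values.T, atol=1e-12)
        assert np.all(np.diag(d.values) == 0)
        assert np.all((d.values >= 0) & (d.values <= 1))


class TestShannon:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ([5, 5, 5, 5], np.log(4)),
            ([7, 0, 0], 0.0),
            ([1, 2, 3], 1.0114042647),  # −Σ p ln p at p = (1/6, 1/3, 1/2)
        ],
    )
    def test_closed_forms(self, counts, expected):
        assert shannon_index(counts) == pytest.approx(expected, abs=1e-9)

    def test_log_base_is_configurable(self):
        assert shannon_index([1, 1], base=2) == pytest.approx(1.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            shannon_index([0, 0])


class TestUpgma:
    def test_three_leaf_hand_example(self):
        d = DissimilarityMatrix(
            ["A", "B", "C"],
            np.array([[0, 0.1, 0.8], [0.1, 0, 0.8], [0.8, 0.8, 0]]),
        )
        tree = upgma_cluster(d)
        heights = tree.merge_heights()
        assert heights[0] == pytest.approx(0.1)
        assert heights[1] == pytest.approx(0.8)
        nwk = tree.newick()
        assert "(A:0.1,B:0.1):0.7" in nwk  # A,B merge first, then join C
        cut = tree.two_group_cut()
        assert cut["A"] == cut["B"] != cut["C"]

    def test_two_leaves_single_merge(self):
        d = DissimilarityMatrix(["A", "B"], np.array([[0, 0.4], [0.4, 0]]))
        assert upgma_cluster(d).merge_heights()[0] == pytest.approx(0.4)

    def test_equal_distances_merge_at_equal_heights(self):
        v = np.full((4, 4), 0.6)
        np.fill_diagonal(v, 0.0)
        tree = upgma_cluster(DissimilarityMatrix(list("ABCD"), v))
        assert np.allclose(tree.merge_heights(), 0.6)

    def test_heights_non_decreasing(self, rng):
        for _ in range(20):
            pts = rng.random((6, 3))
            v = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            tree = upgma_cluster(DissimilarityMatrix([f"s{i}" for i in range(6)], v))
            h = tree.merge_heights()
            assert np.all(np.diff(h) >= -1e-12)

    def test_newick_is_parseable(self):
        import io

        from Bio import Phylo

        d = DissimilarityMatrix(
            ["A", "B", "C"],
            np.array([[0, 0.1, 0.8], [0.1, 0, 0.8], [0.8, 0.8, 0]]),
        )
        tree = Phylo.read(io.StringIO(upgma_cluster(d).newick()), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == ["A", "B", "C"]

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            DissimilarityMatrix(["A", "B"], np.array([[0, 0.1], [0.2, 0]]))


class TestNmds:
    def test_planar_points_embed_with_low_stress(self, rng):
        pts = rng.random((4, 2)) * 3
        v = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        _, stress = nmds_embed(
            DissimilarityMatrix([f"s{i}" for i in range(4)], v), seed=1, restarts=10
        )
        assert stress < 0.01

    def test_equilateral_triangle(self):
        v = np.full((3, 3), 1.0)
        np.fill_diagonal(v, 0.0)
        _, stress = nmds_embed(DissimilarityMatrix(list("ABC"), v), seed=2, restarts=5)
        assert stress < 0.01

    def test_stress_non_increasing_within_a_run(self, rng):
        pts = rng.random((8, 4))
        v = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        path = nmds_stress_path(
            DissimilarityMatrix([f"s{i}" for i in range(8)], v), seed=3, max_iter=50
        )
        assert all(b <= a + 1e-9 for a, b in zip(path, path[1:]))

    def test_degenerate_matrix_rejected(self):
        v = np.zeros((3, 3))
        with pytest.raises(ValueError):
            nmds_embed(DissimilarityMatrix(list("ABC"), v))

    def test_too_few_samples_rejected(self):
        v = np.array([[0, 0.5], [0.5, 0]])
        with pytest.raises(ValueError):
            nmds_embed(DissimilarityMatrix(list("AB"), v))


class TestAnosim:
    def test_perfect_separation_gives_r_one(self):
        # all within-group distances below all between-group distances
        v = np.array(
            [
                [0.0, 0.1, 0.9, 0.8],
                [0.1, 0.0, 0.85, 0.9],
                [0.9, 0.85, 0.0, 0.15],
                [0.8, 0.9, 0.15, 0.0],
            ]
        )
        r, p = anosim_test(
            DissimilarityMatrix(list("ABCD"), v), ["g1", "g1", "g2", "g2"], seed=0
        )
        assert r == pytest.approx(1.0)

    def test_exact_enumeration_small_n(self, rng):
        for n1, n2 in [(2, 2), (3, 3), (2, 4)]:
            pts = rng.random((n1 + n2, 3))
            v = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            labels = ["a"] * n1 + ["b"] * n2
            d = DissimilarityMatrix([f"s{i}" for i in range(n1 + n2)], v)
            r_exact, p_exact = exact_anosim(v, labels)
            r, p = anosim_test(d, labels, n_perm=999, seed=4)
            assert r == pytest.approx(r_exact, abs=1e-12)
            assert p == pytest.approx(p_exact, abs=0.06)

    def test_uniquely_maximal_partition_p_one_third(self):
        v = np.array(
            [
                [0.0, 0.1, 0.9, 0.8],
                [0.1, 0.0, 0.85, 0.9],
                [0.9, 0.85, 0.0, 0.15],
                [0.8, 0.9, 0.15, 0.0],
            ]
        )
        _, p_exact = exact_anosim(v, ["a", "a", "b", "b"])
        assert p_exact == pytest.approx(1 / 3)

    def test_agrees_with_skbio(self, rng):
        from skbio import DistanceMatrix
        from skbio.stats.distance import anosim as skbio_anosim

        pts = rng.random((10, 3))
        v = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = ["a"] * 5 + ["b"] * 5
        r, _ = anosim_test(
            DissimilarityMatrix([f"s{i}" for i in range(10)], v), labels, seed=0
        )
        expected = skbio_anosim(
            DistanceMatrix(v, [f"s{i}" for i in range(10)]), labels, permutations=99
        )["test statistic"]
        assert r == pytest.approx(expected, abs=1e-12)

    def test_r_bounded_and_p_in_unit_interval(self, rng):
        for _ in range(10):
            pts = rng.random((8, 2))
            v = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            labels = list(rng.permutation(["a"] * 4 + ["b"] * 4))
            r, p = anosim_test(
                DissimilarityMatrix([f"s{i}" for i in range(8)], v), labels, seed=1
            )
            assert -1.0 <= r <= 1.0
            assert 0.0 < p <= 1.0

    def test_small_group_rejected(self):
        v = np.zeros((3, 3))
        with pytest.raises(ValueError):
            anosim_test(DissimilarityMatrix(list("ABC"), v), ["a", "a", "b"])
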
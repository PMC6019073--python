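"""Correlation distance and average-linkage clustering against naive oracles."""

import itertools

import numpy as np
import pytest
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from conftest import make_record
from dnproj.catalog import DNCatalog
from dnproj.cluster import (
    DistanceMatrix,
    ZeroVarianceError,
    autocorrelation,
    average_linkage,
    correlation_distance_matrix,
    cut_dendrogram,
    pearson_correlation,
    to_newick,
)
from dnproj.matrix import InnervationMatrix, build_matrix


def naive_average_linkage(d0: np.ndarray):
    """O(n^3) reference: recompute all cluster-average dissimilarities from
    the original matrix at every step.  Same tie-break rule as the package."""
    n = d0.shape[0]
    clusters = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        best_key = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            avg = np.mean([d0[i, j] for i in clusters[a] for j in clusters[b]])
            key = (avg, tuple(sorted((min(clusters[a]), min(clusters[b])))))
            if best_key is None or key < best_key:
                best_key, best = key, (a, b)
        a, b = best
        merges.append((a, b, best_key[0], next_id))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return merges


def random_distance(rng, n):
    m = rng.random((n, n)) * 2
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0)
    return m


class TestPearson:
    def test_self_correlation_is_one(self):
        assert pearson_correlation([1, 0, 1, 0], [1, 0, 1, 0]) == pytest.approx(1.0)

    def test_orthogonal_balanced_binaries(self):
        assert pearson_correlation([1, 1, 0, 0], [1, 0, 1, 0]) == pytest.approx(0.0)

    def test_complement_is_minus_one(self):
        assert pearson_correlation([1, 0, 1, 0], [0, 1, 0, 1]) == pytest.approx(-1.0)

    def test_zero_variance_signalled(self):
        with pytest.raises(ZeroVarianceError):
            pearson_correlation([1, 1, 1], [1, 0, 1])

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_numpy_corrcoef(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.random(20), rng.random(20)
        assert pearson_correlation(x, y) == pytest.approx(np.corrcoef(x, y)[0, 1])


def _im(values, rows=None, cols=None):
    values = np.asarray(values)
    rows = rows or [f"r{i}" for i in range(values.shape[0])]
    cols = cols or [f"c{j}" for j in range(values.shape[1])]
    return InnervationMatrix(rows, cols, values, "any", "custom")


class TestCorrelationDistance:
    def test_identical_rows_at_distance_zero(self):
        m = _im([[1, 0, 1], [1, 0, 1], [0, 1, 1]])
        d = correlation_distance_matrix(m, axis="rows")
        assert d.values[0, 1] == pytest.approx(0.0)

    def test_toy_matrix_equals_double_loop(self):
        rng = np.random.default_rng(3)
        vals = (rng.random((6, 8)) < 0.5).astype(int)
        vals[:, 0] = [1, 0, 1, 0, 1, 0]  # ensure variance
        m = _im(vals)
        d = correlation_distance_matrix(m, axis="rows")
        idx = [m.rows.index(l) for l in d.labels]
        for a, la in enumerate(d.labels):
            for b, lb in enumerate(d.labels):
                if a == b:
                    continue
                r = pearson_correlation(vals[idx[a]], vals[idx[b]])
                assert d.values[a, b] == pytest.approx(1 - r)

    def test_degenerate_column_excluded_and_reported(self):
        vals = np.array([[1, 0, 0], [0, 1, 0], [1, 1, 0]])
        m = _im(vals)
        d = correlation_distance_matrix(m, axis="cols", degenerate="exclude")
        assert "c2" not in d.labels and d.excluded == ["c2"]

    def test_degenerate_max_policy_keeps_label_at_distance_two(self):
        vals = np.array([[1, 0, 0], [0, 1, 0], [1, 1, 0]])
        d = correlation_distance_matrix(_im(vals), axis="cols", degenerate="max")
        j = d.labels.index("c2")
        assert all(d.values[j, k] == 2.0 for k in range(len(d.labels)) if k != j)

    def test_fewer_than_two_usable_profiles_rejected(self):
        vals = np.array([[1, 0], [1, 0]])
        with pytest.raises(ValueError):
            correlation_distance_matrix(_im(vals), axis="cols")


class TestAverageLinkage:
    def test_two_leaves_merge_at_their_distance(self):
        d = DistanceMatrix(["A", "B"], np.array([[0, 0.4], [0.4, 0]]))
        dend = average_linkage(d)
        assert dend.merges == [(0, 1, 0.4, 2)]

    def test_worked_four_leaf_example(self):
        """d(A,B)=2, d(C,D)=4, d(A,C)=d(B,C)=6, d(A,D)=d(B,D)=10
        -> merges at heights 2, 4, then (6+6+10+10)/4 = 8."""
        vals = np.array(
            [
                [0, 2, 6, 10],
                [2, 0, 6, 10],
                [6, 6, 0, 4],
                [10, 10, 4, 0],
            ],
            dtype=float,
        )
        dend = average_linkage(DistanceMatrix(list("ABCD"), vals, metric="custom"))
        assert [m[2] for m in dend.merges] == [2.0, 4.0, 8.0]
        assert dend.merges[0][:2] == (0, 1)
        assert dend.merges[1][:2] == (2, 3)

    @pytest.mark.parametrize("seed", range(20))
    def test_equivalence_with_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 12))
        vals = random_distance(rng, n)
        dend = average_linkage(DistanceMatrix([str(i) for i in range(n)], vals, "custom"))
        ref = naive_average_linkage(vals)
        for got, exp in zip(dend.merges, ref):
            assert got[:2] == exp[:2]
            assert got[2] == pytest.approx(exp[2])

    @pytest.mark.parametrize("seed", range(10))
    def test_heights_monotone_nondecreasing(self, seed):
        rng = np.random.default_rng(100 + seed)
        vals = random_distance(rng, 9)
        h = average_linkage(
            DistanceMatrix([str(i) for i in range(9)], vals, "custom")
        ).heights
        assert all(b >= a - 1e-12 for a, b in zip(h, h[1:]))

    @pytest.mark.parametrize("seed", range(5))
    def test_heights_match_scipy_upgma(self, seed):
        """Independent cross-check against scipy's average linkage."""
        rng = np.random.default_rng(200 + seed)
        vals = random_distance(rng, 10)
        ours = sorted(
            average_linkage(
                DistanceMatrix([str(i) for i in range(10)], vals, "custom")
            ).heights
        )
        Z = sch.linkage(squareform(vals, checks=False), method="average")
        assert np.allclose(ours, sorted(Z[:, 2]))

    @pytest.mark.parametrize("seed", range(5))
    def test_invariant_under_label_permutation(self, seed):
        rng = np.random.default_rng(300 + seed)
        n = 8
        vals = random_distance(rng, n)
        perm = rng.permutation(n)
        labels = [f"L{i}" for i in range(n)]
        d1 = DistanceMatrix(labels, vals, "custom")
        d2 = DistanceMatrix(
            [labels[i] for i in perm], vals[np.ix_(perm, perm)], "custom"
        )
        h1 = average_linkage(d1).heights
        h2 = average_linkage(d2).heights
        assert np.allclose(sorted(h1), sorted(h2))
        # partitions agree up to relabeling
        f1 = dict(zip(labels, cut_dendrogram(average_linkage(d1), k=3)))
        f2 = dict(zip([labels[i] for i in perm], cut_dendrogram(average_linkage(d2), k=3)))
        pairs1 = {(a, b) for a in labels for b in labels if f1[a] == f1[b]}
        pairs2 = {(a, b) for a in labels for b in labels if f2[a] == f2[b]}
        assert pairs1 == pairs2

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["A", "B"], np.array([[0, 1], [2, 0]]))


class TestCut:
    @pytest.fixture
    def worked(self):
        vals = np.array(
            [[0, 2, 6, 10], [2, 0, 6, 10], [6, 6, 0, 4], [10, 10, 4, 0]], float
        )
        return average_linkage(DistanceMatrix(list("ABCD"), vals, "custom"))

    def test_k_equals_n_gives_singletons(self, worked):
        assert cut_dendrogram(worked, k=4) == [0, 1, 2, 3]

    def test_k_one_gives_single_cluster(self, worked):
        assert cut_dendrogram(worked, k=1) == [0, 0, 0, 0]

    def test_k_two_separates_ab_from_cd(self, worked):
        assert cut_dendrogram(worked, k=2) == [0, 0, 1, 1]

    def test_cut_by_height(self, worked):
        assert cut_dendrogram(worked, h=5.0) == [0, 0, 1, 1]

    def test_out_of_range_k(self, worked):
        with pytest.raises(ValueError):
            cut_dendrogram(worked, k=0)
        with pytest.raises(ValueError):
            cut_dendrogram(worked, k=5)
        with pytest.raises(ValueError):
            cut_dendrogram(worked)


class TestAutocorrelation:
    def test_duplicated_column_has_unit_correlation(self):
        vals = np.array([[1, 1, 0], [0, 0, 1], [1, 1, 0], [0, 0, 1]])
        ac = autocorrelation(_im(vals), axis="cols")
        i, j = ac.labels.index("c0"), ac.labels.index("c1")
        assert ac.values[i, j] == pytest.approx(1.0)

    def test_equals_one_minus_distance(self):
        rng = np.random.default_rng(5)
        vals = (rng.random((8, 6)) < 0.5).astype(int)
        vals[0] = 1 - vals[1]  # guarantee at least two non-degenerate columns
        m = _im(vals)
        ac = autocorrelation(m, axis="cols")
        d = correlation_distance_matrix(m, axis="cols")
        assert np.allclose(ac.values, 1 - d.values)

    def test_block_structure_raises_within_group_correlation(self):
        rng = np.random.default_rng(11)
        n = 40
        block = np.zeros((n, 6), dtype=int)
        block[: n // 2, :3] = (rng.random((n // 2, 3)) < 0.9).astype(int)
        block[n // 2 :, 3:] = (rng.random((n - n // 2, 3)) < 0.9).astype(int)
        block += (rng.random(block.shape) < 0.05).astype(int)
        block = np.clip(block, 0, 1)
        ac = autocorrelation(_im(block), axis="cols")
        idx = {l: i for i, l in enumerate(ac.labels)}
        g1 = [idx[f"c{j}"] for j in range(3) if f"c{j}" in idx]
        g2 = [idx[f"c{j}"] for j in range(3, 6) if f"c{j}" in idx]
        within = [ac.values[a, b] for g in (g1, g2) for a in g for b in g if a < b]
        between = [ac.values[a, b] for a in g1 for b in g2]
        assert np.mean(within) > np.mean(between)


def test_newick_export_contains_leaves_and_valid_lengths(toy_catalog):
    vals = np.array(
        [[0, 2, 6, 10], [2, 0, 6, 10], [6, 6, 0, 4], [10, 10, 4, 0]], float
    )
    dend = average_linkage(DistanceMatrix(list("ABCD"), vals, "custom"))
    nwk = to_newick(dend)
    assert nwk.endswith(";")
    for leaf in "ABCD":
        assert leaf in nwk
    # A sits under the AB node (height 2) under the root (height 8): length 2 then 6
    assert "A:2" in nwk and "(A:2,B:2):6" in nwk
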
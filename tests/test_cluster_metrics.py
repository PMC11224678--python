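import itertools
import math
from math import comb, factorial

import numpy as np
import pytest

import regionvec as rv
from regionvec.cluster_metrics import ClusterAssignment


# ---------------------------------------------------------------------------
# independent partition-metric oracles (contingency-table formulas)
# ---------------------------------------------------------------------------

def set_partitions(n):
    """All partitions of n items as canonical label vectors (restricted
    growth strings)."""
    def rec(prefix, k):
        i = len(prefix)
        if i == n:
            yield list(prefix)
            return
        for label in range(k + 1):
            yield from rec(prefix + [label], max(k, label + 1))

    yield from rec([], 0)


def contingency(a, b):
    ka, kb = max(a) + 1, max(b) + 1
    table = np.zeros((ka, kb), dtype=int)
    for x, y in zip(a, b):
        table[x, y] += 1
    return table


def ari_oracle(a, b):
    t = contingency(a, b)
    n = t.sum()
    sum_ij = sum(comb(int(x), 2) for x in t.ravel())
    sum_a = sum(comb(int(x), 2) for x in t.sum(axis=1))
    sum_b = sum(comb(int(x), 2) for x in t.sum(axis=0))
    expected = sum_a * sum_b / comb(n, 2)
    maximum = (sum_a + sum_b) / 2
    if abs(maximum - expected) < 1e-12:
        return 1.0
    return (sum_ij - expected) / (maximum - expected)


def entropy(labels):
    n = len(labels)
    counts = np.bincount(labels)
    p = counts[counts > 0] / n
    return float(-(p * np.log(p)).sum())


def mutual_information(a, b):
    t = contingency(a, b)
    n = t.sum()
    mi = 0.0
    for i in range(t.shape[0]):
        for j in range(t.shape[1]):
            nij = t[i, j]
            if nij:
                mi += (nij / n) * math.log(n * nij / (t[i].sum() * t[:, j].sum()))
    return mi


def expected_mi(a, b):
    """Exact expected MI under the permutation (hypergeometric) model."""
    t = contingency(a, b)
    n = int(t.sum())
    row = [int(x) for x in t.sum(axis=1)]
    col = [int(x) for x in t.sum(axis=0)]
    emi = 0.0
    for ai in row:
        for bj in col:
            lo = max(1, ai + bj - n)
            hi = min(ai, bj)
            for nij in range(lo, hi + 1):
                term = (nij / n) * math.log(n * nij / (ai * bj)) if nij else 0.0
                weight = (
                    factorial(ai) * factorial(bj)
                    * factorial(n - ai) * factorial(n - bj)
                ) / (
                    factorial(n) * factorial(nij) * factorial(ai - nij)
                    * factorial(bj - nij) * factorial(n - ai - bj + nij)
                )
                emi += term * weight
    return emi


def ami_oracle(a, b):
    mi = mutual_information(a, b)
    emi = expected_mi(a, b)
    mean_h = (entropy(a) + entropy(b)) / 2
    denom = mean_h - emi
    if abs(denom) < 1e-12:
        return 1.0
    return (mi - emi) / denom


def homogeneity_oracle(truth, pred):
    h_truth = entropy(truth)
    if h_truth == 0:
        return 1.0
    # H(truth | pred) = H(truth) + H(pred) - H(joint) ... via MI
    return mutual_information(truth, pred) / h_truth


def perm_expected_rand(a, b):
    """Average unadjusted pair-agreement numerator over ALL item
    permutations — the permutation model enumerated directly."""
    n = len(a)
    total = 0.0
    count = 0
    for perm in itertools.permutations(range(n)):
        b_p = [b[i] for i in perm]
        t = contingency(a, b_p)
        total += sum(comb(int(x), 2) for x in t.ravel())
        count += 1
    return total / count


# ---------------------------------------------------------------------------


class TestPartitionMetrics:
    def test_identical_partitions(self):
        a = [0, 0, 1, 1, 2]
        assert rv.ari(a, a) == 1.0
        assert rv.ami(a, a) == 1.0
        assert rv.homogeneity(a, a) == 1.0

    def test_permutation_invariance(self):
        assert rv.ari([0, 0, 1, 1], [1, 1, 0, 0]) == 1.0

    def test_crossed_partition_ari(self):
        # hand contingency: ARI([0,0,1,1],[0,1,0,1]) = -0.5
        assert math.isclose(rv.ari([0, 0, 1, 1], [0, 1, 0, 1]), -0.5)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            rv.ari([0, 1], [0, 1, 2])

    def test_formula_oracle_matches_permutation_enumeration(self):
        # validate the ARI adjustment term against brute-force enumeration
        # of every item permutation (n = 4)
        parts = list(set_partitions(4))
        for a in parts[:8]:
            for b in parts[:8]:
                t = contingency(a, b)
                n = 4
                sum_a = sum(comb(int(x), 2) for x in t.sum(axis=1))
                sum_b = sum(comb(int(x), 2) for x in t.sum(axis=0))
                expected = sum_a * sum_b / comb(n, 2)
                assert math.isclose(expected, perm_expected_rand(a, b), abs_tol=1e-10)

    @pytest.mark.parametrize("n", [2, 3, 4, 5])
    def test_all_partition_pairs_match_oracles(self, n):
        parts = list(set_partitions(n))
        for a in parts:
            for b in parts:
                assert math.isclose(rv.ari(a, b), ari_oracle(a, b), abs_tol=1e-9)
                assert math.isclose(rv.ami(a, b), ami_oracle(a, b), abs_tol=1e-9)
                assert math.isclose(
                    rv.homogeneity(a, b), homogeneity_oracle(a, b), abs_tol=1e-9
                )


class TestGini:
    def test_perfect_equality(self):
        assert rv.gini([1, 1, 1]) == 0.0

    def test_maximal_inequality(self):
        assert math.isclose(rv.gini([0, 0, 1]), 2 / 3)

    def test_hand_value(self):
        assert math.isclose(rv.gini([1, 2, 3]), 8 / 36)

    def test_all_zero_defined_zero(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="regionvec.cluster_metrics"):
            assert rv.gini([0.0, 0.0]) == 0.0
        assert "all-zero" in caplog.text

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.random(rng.integers(2, 30))
            assert math.isclose(rv.gini(x), rv.gini(7.3 * x), rel_tol=1e-12)

    def test_matches_double_sum_on_random_vectors(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.random(int(rng.integers(1, 25)))
            n = len(x)
            brute = sum(abs(a - b) for a in x for b in x) / (2 * n * x.sum())
            assert math.isclose(rv.gini(x), brute, rel_tol=1e-12)

    def test_bounds(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x = rng.random(int(rng.integers(2, 20)))
            n = len(x)
            assert 0 <= rv.gini(x) <= (n - 1) / n + 1e-12


def _hand_matrix():
    """6 cells x 4 regions; clusters of 2 cells each."""
    import scipy.sparse as sp

    dense = np.array(
        [
            # marker region 0 | housekeeping region 1 | extra regions
            [1, 1, 0, 0],
            [1, 1, 0, 0],
            [0, 1, 1, 0],
            [0, 1, 0, 0],
            [0, 1, 0, 1],
            [0, 1, 0, 0],
        ],
        dtype=float,
    )
    regions = [rv.GenomicRegion("chr1", i * 1000, i * 1000 + 500) for i in range(4)]
    matrix = rv.AccessibilityMatrix([f"c{i}" for i in range(6)], regions, sp.csr_matrix(dense))
    assignment = ClusterAssignment([f"c{i}" for i in range(6)], np.repeat([0, 1, 2], 2))
    return matrix, assignment


class TestRagi:
    def test_hand_fixture_marker_specific_housekeeping_uniform(self):
        matrix, assignment = _hand_matrix()
        sigs = rv.SignatureSets({"m": {0}}, {"h": {1}})
        res = rv.ragi(matrix, assignment, sigs)
        # marker activity [1,0,0] -> gini 2/3; housekeeping uniform -> gini 0
        assert math.isclose(res["mean_marker_gini"], 2 / 3)
        assert res["mean_housekeeping_gini"] == 0.0
        assert math.isclose(res["ragi"], 2 / 3)

    def test_marker_equals_housekeeping_is_zero(self):
        matrix, assignment = _hand_matrix()
        sigs = rv.SignatureSets({"m": {0, 2}}, {"h2": {0, 2}})
        res = rv.ragi(matrix, assignment, sigs)
        assert math.isclose(res["ragi"], 0.0, abs_tol=1e-12)

    def test_matches_brute_force_oracle(self):
        matrix, assignment = _hand_matrix()
        sigs = rv.SignatureSets({"m": {0, 2}, "m2": {3}}, {"h": {1}})
        res = rv.ragi(matrix, assignment, sigs)

        dense = matrix.entries.toarray() > 0
        labels = assignment.labels

        def activity(gene_regions):
            idx = sorted(gene_regions)
            per_cell = dense[:, idx].mean(axis=1)
            return [per_cell[labels == c].mean() for c in range(3)]

        def brute_gini(x):
            x = np.asarray(x, float)
            if x.sum() == 0:
                return 0.0
            return sum(abs(a - b) for a in x for b in x) / (2 * len(x) * x.sum())

        marker = np.mean([brute_gini(activity(s)) for s in sigs.marker_sets.values()])
        house = np.mean([brute_gini(activity(s)) for s in sigs.housekeeping_sets.values()])
        assert math.isclose(res["ragi"], marker - house, rel_tol=1e-12)

    def test_absent_gene_excluded_with_warning(self, caplog):
        import logging

        matrix, assignment = _hand_matrix()
        sigs = rv.SignatureSets({"m": {0}, "ghost": {99}}, {"h": {1}})
        with caplog.at_level(logging.WARNING, logger="regionvec.cluster_metrics"):
            res = rv.ragi(matrix, assignment, sigs)
        assert "ghost" in caplog.text
        assert "marker:ghost" not in res["per_gene"]

    def test_monotone_in_marker_specificity(self):
        # making signature regions more type-specific raises RAGI
        scores = []
        for p_high in (0.12, 0.3, 0.7):
            spec = rv.SyntheticSpec(
                n_types=3, cells_per_type=30, n_regions=150, signature_size=20,
                housekeeping_size=20, p_high=p_high, p_low=0.05, p_house=0.3, seed=5,
            )
            matrix, labels, sigs = rv.generate(spec)
            types = sorted(set(labels.values()))
            label_idx = {t: i for i, t in enumerate(types)}
            assignment = ClusterAssignment(
                list(matrix.barcodes),
                np.array([label_idx[labels[b]] for b in matrix.barcodes]),
            )
            scores.append(rv.ragi(matrix, assignment, sigs)["ragi"])
        assert scores[0] < scores[1] < scores[2]


class TestCluster:
    def _blobs(self, n_per=20, spread=0.01, centers=((0, 0), (10, 10)), seed=0):
        rng = np.random.default_rng(seed)
        vectors = np.vstack(
            [np.asarray(c) + spread * rng.standard_normal((n_per, 2)) for c in centers]
        )
        return rv.CellEmbeddingSet(
            [f"c{i}" for i in range(len(vectors))], vectors,
            np.ones(len(vectors), dtype=int),
        )

    def test_kmeans_separable(self):
        emb = self._blobs()
        a = rv.cluster(emb, "kmeans", seed=0, k=2)
        truth = np.repeat([0, 1], 20)
        assert rv.ari(truth, a.labels) == 1.0

    def test_hc_identical_points_single_cluster(self):
        emb = rv.CellEmbeddingSet(
            [f"c{i}" for i in range(5)], np.ones((5, 3)), np.ones(5, dtype=int)
        )
        a = rv.cluster(emb, "hc", seed=0, k=1)
        assert a.n_clusters == 1

    def test_louvain_two_disconnected_cliques(self):
        # two tight 10-point blobs with k_graph=9 -> two disconnected
        # 10-cliques; modularity optimization must find exactly 2 communities
        emb = self._blobs(n_per=10, spread=0.001)
        a = rv.cluster(emb, "louvain", seed=0, k_graph=9)
        assert a.n_clusters == 2
        assert rv.ari(np.repeat([0, 1], 10), a.labels) == 1.0

    def test_k_too_large_errors(self):
        emb = self._blobs(n_per=3)
        with pytest.raises(ValueError):
            rv.cluster(emb, "kmeans", seed=0, k=10)

    def test_requires_k(self):
        with pytest.raises(ValueError):
            rv.cluster(self._blobs(), "kmeans", seed=0)

    def test_nan_cells_excluded(self):
        emb = self._blobs()
        emb.vectors[0] = np.nan
        emb.coverage[0] = 0
        a = rv.cluster(emb, "kmeans", seed=0, k=2)
        assert "c0" not in a.barcodes
        assert len(a.barcodes) == 39

    def test_deterministic(self):
        emb = self._blobs(spread=2.0)
        for method, kw in (("kmeans", {"k": 3}), ("louvain", {}), ("hc", {"k": 3})):
            a = rv.cluster(emb, method, seed=4, **kw)
            b = rv.cluster(emb, method, seed=4, **kw)
            assert np.array_equal(a.labels, b.labels)

    def test_labels_contiguous(self):
        emb = self._blobs(spread=3.0, centers=((0, 0), (5, 5), (10, 0)))
        a = rv.cluster(emb, "louvain", seed=0, k_graph=5)
        uniq = np.unique(a.labels)
        assert np.array_equal(uniq, np.arange(len(uniq)))


class TestSubsampledRagi:
    def _setup(self):
        spec = rv.SyntheticSpec(
            n_types=2, cells_per_type=25, n_regions=120, signature_size=20,
            housekeeping_size=10, p_high=0.6, p_low=0.02, p_house=0.3, seed=2,
        )
        matrix, labels, sigs = rv.generate(spec)
        rng = np.random.default_rng(0)
        vectors = np.vstack(
            [
                rng.standard_normal((25, 4)) * 0.1,
                rng.standard_normal((25, 4)) * 0.1 + 5,
            ]
        )
        emb = rv.CellEmbeddingSet(list(matrix.barcodes), vectors, np.ones(50, dtype=int))
        return matrix, emb, sigs

    def test_degenerate_subsample_equals_full_ragi(self):
        matrix, emb, sigs = self._setup()
        methods = {"kmeans": {"method": "kmeans", "k": 2}}
        res = rv.subsampled_ragi(
            matrix, {"e": emb}, sigs, methods, n_sub=matrix.n_cells, reps=1, seed=0
        )
        full = rv.ragi(matrix, rv.cluster(emb, "kmeans", seed=0, k=2), sigs)
        assert math.isclose(res["e"]["kmeans"]["mean"], full["ragi"], rel_tol=1e-12)

    def test_identical_sources_identical_scores(self):
        matrix, emb, sigs = self._setup()
        methods = {"kmeans": {"method": "kmeans", "k": 2}}
        res = rv.subsampled_ragi(
            matrix, {"a": emb, "b": emb}, sigs, methods, n_sub=30, reps=3, seed=1
        )
        assert res["a"]["kmeans"]["scores"] == res["b"]["kmeans"]["scores"]

    def test_n_sub_too_large_errors(self):
        matrix, emb, sigs = self._setup()
        with pytest.raises(ValueError):
            rv.subsampled_ragi(matrix, {"e": emb}, sigs, {}, n_sub=10_000, reps=1)
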
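import numpy as np
import pytest
from scipy import stats

from apocrine.clustering import (
    cluster_class_association,
    correlation_distance,
    cut_dendrogram,
    ward_cluster,
)
from apocrine.io import DataError, ExpressionMatrix

from _oracles import oracle_ward, pearson_r


def _adjusted_rand(a, b):
    from sklearn.metrics import adjusted_rand_score

    return adjusted_rand_score(a, b)


class TestCorrelationDistance:
    def test_identical_samples_distance_zero(self):
        v = np.array([[1.0, 1.0], [2.0, 2.0], [5.0, 5.0]])
        X = ExpressionMatrix(v, ["p1", "p2", "p3"], ["s1", "s2"])
        D = correlation_distance(X, axis="samples")
        assert D[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_samples_distance_two(self):
        v = np.array([[1.0, -1.0], [2.0, -2.0], [3.0, -3.0]])
        X = ExpressionMatrix(v, ["p1", "p2", "p3"], ["s1", "s2"])
        D = correlation_distance(X, axis="samples")
        assert D[0, 1] == pytest.approx(2.0)

    def test_matches_textbook_pearson(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=(6, 3))
        X = ExpressionMatrix(v, [f"p{i}" for i in range(6)], ["a", "b", "c"])
        D = correlation_distance(X, axis="samples")
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            r = pearson_r(list(v[:, i]), list(v[:, j]))
            assert D[i, j] == pytest.approx(1 - r, abs=1e-12)

    def test_zero_variance_vector_named(self):
        v = np.array([[1.0, 2.0], [1.0, 3.0], [1.0, 4.0]])
        X = ExpressionMatrix(v, ["p1", "p2", "p3"], ["flat", "ok"])
        with pytest.raises(DataError, match="flat"):
            correlation_distance(X, axis="samples")


class TestWard:
    def test_duplicated_samples_merge_first_at_zero(self):
        rng = np.random.default_rng(1)
        P = rng.normal(size=(4, 6))
        P[1] = P[0]
        D = 1 - np.corrcoef(P)
        np.fill_diagonal(D, 0)
        dend = ward_cluster(D)
        assert dend.merges[0] == (0, 1)
        assert dend.heights[0] == pytest.approx(0.0, abs=1e-12)

    def test_brute_force_oracle_equivalence(self):
        """Merge order and heights equal a naive ESS recomputation for
        n <= 8 over 100 random 1-Pearson instances."""
        rng = np.random.default_rng(2)
        for _ in range(100):
            n = int(rng.integers(4, 9))
            P = rng.normal(size=(n, 5))
            D = 1 - np.corrcoef(P)
            np.fill_diagonal(D, 0)
            dend = ward_cluster(D)
            expected = oracle_ward(D)
            for (a, b), h, (ea, eb, eh) in zip(dend.merges, dend.heights, expected):
                assert (a, b) == (ea, eb)
                assert h == pytest.approx(eh, abs=1e-8)

    def test_two_blob_recovery(self):
        rng = np.random.default_rng(3)
        genes = rng.normal(size=(30, 1))
        blob1 = genes + rng.normal(0, 0.1, size=(30, 8))
        blob2 = -genes + rng.normal(0, 0.1, size=(30, 8))
        v = np.hstack([blob1, blob2])
        X = ExpressionMatrix(
            v, [f"p{i}" for i in range(30)], [f"s{i}" for i in range(16)]
        )
        dend = ward_cluster(correlation_distance(X), leaf_ids=X.sample_ids)
        labels = cut_dendrogram(dend, 2)
        left = {labels[f"s{i}"] for i in range(8)}
        right = {labels[f"s{i}"] for i in range(8, 16)}
        assert left == {0} and right == {1}

    def test_heights_non_decreasing_and_order_invariant(self):
        rng = np.random.default_rng(4)
        P = rng.normal(size=(10, 6))
        D = 1 - np.corrcoef(P)
        np.fill_diagonal(D, 0)
        dend = ward_cluster(D)
        assert np.all(np.diff(dend.heights) >= -1e-12)
        perm = rng.permutation(10)
        dend2 = ward_cluster(D[np.ix_(perm, perm)])
        assert np.allclose(np.sort(dend.heights), np.sort(dend2.heights))

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(DataError):
            ward_cluster(D)


class TestCut:
    def _dend(self, n=8, seed=5):
        rng = np.random.default_rng(seed)
        P = rng.normal(size=(n, 5))
        D = 1 - np.corrcoef(P)
        np.fill_diagonal(D, 0)
        return ward_cluster(D, leaf_ids=[f"s{i}" for i in range(n)])

    def test_k_one_single_cluster(self):
        labels = cut_dendrogram(self._dend(), 1)
        assert set(labels.values()) == {0}

    def test_k_n_singletons(self):
        labels = cut_dendrogram(self._dend(), 8)
        assert len(set(labels.values())) == 8

    def test_k_out_of_range(self):
        with pytest.raises(DataError):
            cut_dendrogram(self._dend(), 0)

    def test_planted_three_classes_ari(self):
        rng = np.random.default_rng(6)
        n_per, genes = 8, 40
        base = rng.normal(size=(genes, 3))
        cols, truth = [], []
        for c in range(3):
            cols.append(base[:, [c]] * 2 + rng.normal(0, 0.3, size=(genes, n_per)))
            truth += [c] * n_per
        v = np.hstack(cols)
        X = ExpressionMatrix(
            v, [f"p{i}" for i in range(genes)], [f"s{i}" for i in range(3 * n_per)]
        )
        dend = ward_cluster(correlation_distance(X), leaf_ids=X.sample_ids)
        labels = cut_dendrogram(dend, 3)
        got = [labels[s] for s in X.sample_ids]
        assert _adjusted_rand(truth, got) >= 0.9


class TestAssociation:
    def test_identical_labels_strongly_associated(self):
        labels = ["a"] * 20 + ["b"] * 20
        stat, p, test = cluster_class_association(labels, labels)
        # closed form: chi-square = n for a perfectly aligned 2x2 balanced table
        assert stat == pytest.approx(40.0)
        assert p < 1e-6

    def test_perfect_2x2_fisher_enumeration(self):
        # perfectly aligned 8+8 table: expected counts 4 trigger Fisher;
        # two-sided p is twice the probability of the observed extreme table
        labels = ["a"] * 8 + ["b"] * 8
        classes = ["x"] * 8 + ["y"] * 8
        _, p, test = cluster_class_association(labels, classes)
        assert test == "fisher"
        assert p == pytest.approx(2 / 12870)

    def test_table_10_0_0_10_fisher(self):
        from apocrine.ihc import contingency_test

        res = contingency_test([[10, 0], [0, 10]])
        assert res.test_used == "fisher"
        from math import comb

        assert res.p_value == pytest.approx(2 / comb(20, 10))

    def test_null_p_uniform(self):
        rng = np.random.default_rng(7)
        pvals = []
        for _ in range(300):
            labels = rng.integers(0, 2, size=60)
            classes = rng.integers(0, 2, size=60)
            try:
                _, p, _ = cluster_class_association(labels, classes)
            except DataError:
                continue
            pvals.append(p)
        # chi-square p-values are discrete-ish but close to uniform at n=60
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.001

    def test_degenerate_rejected(self):
        with pytest.raises(DataError):
            cluster_class_association(["a"] * 10, ["x"] * 5 + ["y"] * 5)


def test_newick_export_contains_all_leaves():
    rng = np.random.default_rng(8)
    P = rng.normal(size=(5, 4))
    D = 1 - np.corrcoef(P)
    np.fill_diagonal(D, 0)
    dend = ward_cluster(D, leaf_ids=["a", "b", "c", "d", "e"])
    nwk = dend.to_newick()
    assert nwk.endswith(";")
    for leaf in "abcde":
        assert leaf in nwk


def test_apocrine_branch_isolated(study_like_scenario):
    """The planted apocrine samples form a single branch at some cut."""
    from apocrine.filtering import select_clustering_probes

    sc = study_like_scenario
    probes, _ = select_clustering_probes(sc.expression, sc.annotation)
    Xf = sc.expression.subset_probes(probes)
    dend = ward_cluster(correlation_distance(Xf), leaf_ids=Xf.sample_ids)
    apo = set(sc.truth.apocrine_samples)
    found = False
    for k in range(2, 11):
        labels = cut_dendrogram(dend, k)
        clusters = {}
        for s, l in labels.items():
            clusters.setdefault(l, set()).add(s)
        if apo in clusters.values():
            found = True
            break
    assert found
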
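import numpy as np
import pandas as pd
import pytest
from scipy import stats

from apocrine.io import DataError, ExpressionMatrix
from apocrine.signature import (
    derive_signature,
    forest_select,
    local_fdr,
    welch_t,
    welch_t_matrix,
)
from apocrine.synthetic import generate_expression


class TestWelch:
    def test_identical_groups(self):
        a = np.array([1.0, 2.0, 3.0])
        t, df, p = welch_t(a, a)
        assert t == 0.0 and p == 1.0

    def test_hand_computed_example(self):
        # a=[1,2,3], b=[4,5,6]: means 2 and 5, variances 1 and 1
        # t = -3 / sqrt(1/3 + 1/3) = -3.674235..., Welch df = 4 exactly
        t, df, p = welch_t(np.array([1.0, 2, 3]), np.array([4.0, 5, 6]))
        assert t == pytest.approx(-3 / np.sqrt(2 / 3), rel=1e-12)
        assert df == pytest.approx(4.0, rel=1e-12)
        assert p == pytest.approx(2 * stats.t.sf(3 / np.sqrt(2 / 3), 4), rel=1e-12)

    def test_antisymmetry_under_swap(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=6), rng.normal(1, 1, size=9)
        t1, df1, p1 = welch_t(a, b)
        t2, df2, p2 = welch_t(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)
        assert df1 == pytest.approx(df2)

    def test_small_group_rejected(self):
        with pytest.raises(DataError):
            welch_t(np.array([1.0]), np.array([1.0, 2.0]))

    def test_matrix_agrees_with_scalar(self):
        rng = np.random.default_rng(1)
        A, B = rng.normal(size=(20, 5)), rng.normal(size=(20, 8))
        t, df, p = welch_t_matrix(A, B)
        for i in range(20):
            ts, dfs, ps = welch_t(A[i], B[i])
            assert t[i] == pytest.approx(ts)
            assert df[i] == pytest.approx(dfs)
            assert p[i] == pytest.approx(ps)

    def test_null_p_uniform(self):
        rng = np.random.default_rng(2)
        A = rng.normal(size=(10000, 8))
        B = rng.normal(size=(10000, 12))
        _, _, p = welch_t_matrix(A, B)
        assert stats.kstest(p, "uniform").pvalue > 0.01


class TestLocalFdr:
    def test_pure_null(self):
        rng = np.random.default_rng(3)
        lfdr, pi0 = local_fdr(rng.uniform(size=10000))
        assert pi0 >= 0.9
        assert np.median(lfdr) >= 0.9

    def test_mixture_pi0_recovery(self):
        rng = np.random.default_rng(4)
        null = rng.uniform(size=8000)
        alt = stats.norm.cdf(rng.normal(-2, 1, size=2000))
        _, pi0 = local_fdr(np.concatenate([null, alt]))
        assert abs(pi0 - 0.8) <= 0.1

    def test_degenerate_input_flagged(self):
        with pytest.warns(UserWarning, match="degenerate"):
            lfdr, pi0 = local_fdr(np.full(500, 0.5))
        assert np.all(lfdr == 1.0)

    def test_out_of_range_p_clamped(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=500)
        p[0] = 0.0
        p[1] = 1.0
        with pytest.warns(UserWarning, match="clamped"):
            lfdr, _ = local_fdr(p)
        assert np.all((lfdr >= 0) & (lfdr <= 1))

    def test_too_few_pvalues_rejected(self):
        with pytest.raises(DataError):
            local_fdr(np.full(50, 0.3))


def _matrix_with_labels(n_probes, n_a, n_b, seed, separating=()):
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n_probes, n_a + n_b))
    for row in separating:
        v[row, :n_a] += 5.0
    probes = [f"p{i:04d}" for i in range(n_probes)]
    samples = [f"s{i}" for i in range(n_a + n_b)]
    X = ExpressionMatrix(v, probes, samples)
    y = pd.Series(["a"] * n_a + ["b"] * n_b, index=samples)
    return X, y, probes


class TestForest:
    def test_perfect_separator_ranked_first(self):
        X, y, probes = _matrix_with_labels(51, 10, 10, seed=6, separating=(17,))
        ranked = forest_select(X, y, probes, n_keep=51, n_trees=300, seed=1)
        assert ranked.index[0] == probes[17]

    def test_same_seed_identical_ranking(self):
        X, y, probes = _matrix_with_labels(40, 8, 8, seed=7)
        r1 = forest_select(X, y, probes, n_keep=40, n_trees=200, seed=9)
        r2 = forest_select(X, y, probes, n_keep=40, n_trees=200, seed=9)
        assert list(r1.index) == list(r2.index)

    def test_noise_ranking_uncorrelated_across_seeds(self):
        X, y, probes = _matrix_with_labels(60, 10, 10, seed=8)
        r1 = forest_select(X, y, probes, n_keep=60, n_trees=200, seed=1)
        r2 = forest_select(X, y, probes, n_keep=60, n_trees=200, seed=2)
        rho = stats.spearmanr(
            r1["rank"].reindex(probes), r2["rank"].reindex(probes)
        ).statistic
        assert abs(rho) < 0.45

    def test_n_keep_exceeding_candidates_warns(self):
        X, y, probes = _matrix_with_labels(10, 6, 6, seed=9)
        with pytest.warns(UserWarning, match="exceeds"):
            ranked = forest_select(X, y, probes, n_keep=20, n_trees=50, seed=3)
        assert len(ranked) == 10

    def test_missing_seed_rejected(self):
        X, y, probes = _matrix_with_labels(10, 6, 6, seed=10)
        with pytest.raises(DataError):
            forest_select(X, y, probes, n_keep=5)


class TestDeriveSignature:
    def test_selected_subset_of_screen_and_directions(self, plain_annotation):
        X, y, probes = _matrix_with_labels(3000, 10, 12, seed=11, separating=(5, 6, 7))
        ann = plain_annotation(probes)
        res = derive_signature(X, y, ann, n_keep=50, n_trees=200, seed=4)
        screened = set(res.table.index[res.table["p_value"] < 0.01])
        assert set(res.selected_probes) <= screened
        for pid in res.selected_probes:
            row = res.table.loc[pid]
            a_mean = X.values[X.probe_ids.index(pid), :10].mean()
            b_mean = X.values[X.probe_ids.index(pid), 10:].mean()
            assert (row["direction"] == "up") == (a_mean >= b_mean)

    def test_group_swap_preserves_selection_flips_direction(self):
        X, y, probes = _matrix_with_labels(2000, 8, 10, seed=12, separating=(3, 4))
        res1 = derive_signature(X, y, n_keep=30, n_trees=200, seed=5)
        swapped = y.map({"a": "b", "b": "a"})
        res2 = derive_signature(X, swapped, n_keep=30, n_trees=200, seed=5)
        assert set(res1.selected_probes) == set(res2.selected_probes)
        joint = res1.table.loc[res1.selected_probes, "direction"]
        flipped = res2.table.loc[res1.selected_probes, "direction"]
        assert (joint != flipped).all()

    def test_p_threshold_one_screens_everything(self):
        X, y, probes = _matrix_with_labels(500, 6, 6, seed=13)
        res = derive_signature(X, y, p_thresh=1.0, n_keep=20, n_trees=100, seed=6)
        assert res.screen_size == 500
        assert len(res.selected_probes) == 20

    def test_empty_screen_rejected(self):
        X, y, probes = _matrix_with_labels(300, 6, 6, seed=14)
        with pytest.raises(DataError, match="screen"):
            derive_signature(X, y, p_thresh=1e-30, n_keep=10, n_trees=50, seed=7)


def test_planted_de_probes_dominate_selection():
    """With 150 up- and 50 down-regulated probes planted in a 5-sample
    group, >= 80% of the 200 selected probes are planted."""
    sc = generate_expression(apocrine_block=150, down_block=50, seed=11)
    groups = pd.Series(
        {
            s: ("apo" if c == "apocrine" else "rest")
            for s, c in sc.truth.sample_class.items()
        }
    )
    res = derive_signature(
        sc.expression, groups, sc.annotation, n_keep=200, seed=11, contrast="apocrine"
    )
    planted = set(sc.truth.up_probes) | set(sc.truth.down_probes)
    hit = len(set(res.selected_probes) & planted)
    assert hit >= 0.8 * len(res.selected_probes)
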
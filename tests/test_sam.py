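"""SAM statistics, s0 selection, and exhaustive-vs-sampled permutation
null equivalence."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from radresponse.sam import (
    choose_s0, sam_multiclass, sam_paired, sam_two_class,
)


def gauss_matrix(n_genes, n_samples, seed=0, base_sd=1.0, noise_sd=0.5):
    rng = np.random.default_rng(seed)
    X = rng.normal(8, base_sd, (n_genes, 1)) + rng.normal(0, noise_sd,
                                                          (n_genes, n_samples))
    return pd.DataFrame(X, index=[f"g{i}" for i in range(n_genes)],
                        columns=[f"s{j}" for j in range(n_samples)])


def brute_force_s0(s, num):
    """Independent re-implementation of the Tusher grid search."""
    s, num = np.asarray(s, float), np.asarray(num, float)
    cands = np.percentile(s, np.arange(0, 101, 5))
    order = np.argsort(s, kind="stable")
    edges = np.linspace(0, len(s), min(100, len(s)) + 1).astype(int)
    wins = [order[edges[i]:edges[i + 1]] for i in range(len(edges) - 1)
            if edges[i + 1] > edges[i]]
    best, best_cv = None, np.inf
    for s0 in cands:
        d = num / (s + s0)
        mads = []
        for w in wins:
            med = np.median(d[w])
            mads.append(np.median(np.abs(d[w] - med)) * 1.4826)
        mads = np.array(mads)
        cv = np.inf if mads.mean() == 0 else mads.std(ddof=1) / mads.mean()
        if cv < best_cv - 1e-12:
            best_cv, best = cv, s0
    return best


class TestChooseS0:
    def test_constant_scatter_returns_fifth_percentile(self):
        s = np.full(50, 0.7)
        assert choose_s0(s, np.random.default_rng(0).normal(size=50)) \
            == pytest.approx(0.7)

    def test_matches_independent_grid_search(self, rng):
        s = np.exp(rng.normal(0, 1, 1000))
        num = rng.normal(0, 1, 1000) * s          # scatter-dependent numerators
        assert choose_s0(s, num) == pytest.approx(brute_force_s0(s, num))

    def test_scatter_independent_d_gives_flat_cv(self, rng):
        # d already independent of s: small s0 should win (no stabilization needed)
        s = np.exp(rng.normal(0, 1, 2000))
        num = rng.normal(0, 1, 2000)               # gives d ~ 1/s ... dependent
        s0 = choose_s0(s, num * s)                  # numerator ∝ s → d independent of s
        assert s0 <= np.percentile(s, 50)

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            choose_s0([1.0] * 5, [0.0] * 5)


class TestTwoClass:
    def test_identical_groups_give_zero_d_and_no_calls(self):
        X = gauss_matrix(30, 3, seed=1)
        dup = pd.concat([X, X], axis=1)
        dup.columns = [f"s{j}" for j in range(6)]
        res = sam_two_class(dup, ["a", "a", "a", "b", "b", "b"], n_perm=20, seed=0)
        assert np.allclose(res.table["d"], 0.0)
        assert len(res.called_genes) == 0

    def test_sampled_null_with_all_assignments_equals_exhaustive(self):
        X = gauss_matrix(20, 6, seed=2)
        labels = ["a"] * 3 + ["b"] * 3
        ex = sam_two_class(X, labels, n_perm=20, seed=1)
        sam = sam_two_class(X, labels, n_perm=20, seed=1, force_sampled=True)
        assert ex.exhaustive and not sam.exhaustive
        assert ex.n_permutations == sam.n_permutations == 20
        np.testing.assert_allclose(ex.dbar, sam.dbar)
        np.testing.assert_allclose(ex.table["q"], sam.table["q"])

    def test_d_equals_t_statistic_with_zero_s0(self, rng):
        X = gauss_matrix(40, 10, seed=3).to_numpy()
        from radresponse.sam import _two_class_d
        member = np.zeros((10, 1), dtype=bool)
        member[5:, 0] = True
        d, num, s = _two_class_d(X, member, 0.0)
        t = sps.ttest_ind(X[:, 5:], X[:, :5], axis=1, equal_var=True).statistic
        np.testing.assert_allclose(d[:, 0], t, rtol=1e-10)

    def test_sample_order_invariance(self):
        X = gauss_matrix(25, 8, seed=4)
        labels = ["a"] * 4 + ["b"] * 4
        res1 = sam_two_class(X, labels, n_perm=100, seed=5)
        perm = np.random.default_rng(0).permutation(8)
        res2 = sam_two_class(X.iloc[:, perm], [labels[i] for i in perm],
                             n_perm=100, seed=5)
        np.testing.assert_allclose(res1.table["d"], res2.table["d"])
        np.testing.assert_allclose(res1.table["q"], res2.table["q"])

    def test_q_monotone_in_abs_d_within_direction(self):
        X = gauss_matrix(100, 12, seed=6)
        X.iloc[:10, 6:] += 1.5
        res = sam_two_class(X, ["a"] * 6 + ["b"] * 6, n_perm=200, seed=7)
        for direction in ("up", "down"):
            t = res.table[res.table["direction"] == direction]
            t = t.sort_values("d", key=np.abs, ascending=False)
            assert (np.diff(t["q"]) >= -1e-12).all()

    def test_small_group_rejected(self):
        X = gauss_matrix(20, 4)
        with pytest.raises(ValueError, match="2 samples"):
            sam_two_class(X, ["a", "b", "b", "b"])


class TestPaired:
    def pairs(self, n):
        return [(f"s{2 * i}", f"s{2 * i + 1}") for i in range(n)]

    def test_identical_pre_post_gives_zero_d(self):
        X = gauss_matrix(20, 5, seed=8)
        dup = pd.concat([X, X], axis=1)
        dup.columns = [f"s{j}" for j in range(10)]
        pairs = [(f"s{i}", f"s{i + 5}") for i in range(5)]
        res = sam_paired(dup, pairs, n_perm=32, seed=0)
        assert np.allclose(res.table["d"], 0.0)
        assert len(res.called_genes) == 0

    def test_sampled_sign_flips_equal_enumeration(self):
        X = gauss_matrix(20, 10, seed=9)
        pairs = self.pairs(5)
        ex = sam_paired(X, pairs, n_perm=32, seed=1)
        sam = sam_paired(X, pairs, n_perm=32, seed=1, force_sampled=True)
        assert ex.exhaustive and ex.n_permutations == 32
        assert sam.n_permutations == 32
        np.testing.assert_allclose(ex.dbar, sam.dbar)
        np.testing.assert_allclose(ex.table["q"], sam.table["q"])

    def test_swapping_roles_negates_d(self):
        X = gauss_matrix(30, 8, seed=10)
        fwd = sam_paired(X, self.pairs(4), n_perm=16, seed=2)
        rev = sam_paired(X, [(b, a) for a, b in self.pairs(4)], n_perm=16, seed=2)
        np.testing.assert_allclose(fwd.table["d"], -rev.table["d"])

    def test_incomplete_pairs_dropped_with_warning(self):
        X = gauss_matrix(15, 8, seed=11)
        pairs = self.pairs(4) + [("s8", "missing")]
        with pytest.warns(UserWarning, match="incomplete pair"):
            res = sam_paired(X, pairs, n_perm=16, seed=0)
        assert res.n_permutations == 16

    def test_too_few_pairs_rejected(self):
        X = gauss_matrix(15, 4)
        with pytest.raises(ValueError, match="3 complete pairs"):
            sam_paired(X, self.pairs(2))


class TestMulticlass:
    def test_equal_group_means_give_zero_r(self):
        X = gauss_matrix(20, 2, seed=12)
        trip = pd.concat([X, X, X], axis=1)
        trip.columns = [f"s{j}" for j in range(6)]
        res = sam_multiclass(trip, ["a", "a", "b", "b", "c", "c"], n_perm=50, seed=0)
        assert np.allclose(res.table["d"], 0.0, atol=1e-10)
        assert len(res.called_genes) == 0

    def test_planted_monotone_effect_ranks_top(self):
        X = gauss_matrix(100, 15, seed=13)
        X.iloc[:8, 5:10] += 1.0
        X.iloc[:8, 10:] += 2.0
        res = sam_multiclass(X, ["a"] * 5 + ["b"] * 5 + ["c"] * 5,
                             n_perm=300, seed=1)
        top8 = res.table["d"].nlargest(8).index
        assert set(top8) == {f"g{i}" for i in range(8)}

    def test_two_groups_reduce_to_abs_d(self):
        X = gauss_matrix(50, 10, seed=14)
        labels = ["a"] * 5 + ["b"] * 5
        two = sam_two_class(X, labels, n_perm=100, seed=3)
        multi = sam_multiclass(X, labels, n_perm=100, seed=3)
        # identical s and numerator magnitude → same s0 and r = |d| exactly
        np.testing.assert_allclose(multi.table["d"], two.table["d"].abs(),
                                   rtol=1e-10)

    def test_direction_column_absent(self):
        X = gauss_matrix(20, 6, seed=15)
        res = sam_multiclass(X, ["a", "a", "b", "b", "c", "c"], n_perm=20, seed=0)
        assert "direction" not in res.table.columns
        with pytest.raises(ValueError, match="no direction"):
            res.called_in_direction("up")
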
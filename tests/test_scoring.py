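"""ssGSEA against a brute-force running-sum oracle, ESTIMATE composition,
profile means and paired score tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from radresponse.genesets import GeneSet
from radresponse.scoring import (
    SSGSEAScorer, estimate_scores, ies_panel, paired_score_test, ssgsea_score,
    tcell_inflamed_gep,
)
from radresponse.scoring import PURITY_INTERCEPT, PURITY_SLOPE


def oracle_es(expr: pd.Series, members: set, alpha: float) -> float:
    """Independent running-sum coding of the weighted/unweighted ECDF
    difference."""
    ranks = sps.rankdata(expr.to_numpy())
    order = sorted(range(len(expr)),
                   key=lambda i: (-ranks[i], i))        # descending, stable
    in_set = [expr.index[i] in members for i in order]
    w = [ranks[order[i]] ** alpha if in_set[i] else 0.0 for i in range(len(order))]
    wsum = sum(w)
    n_out = sum(1 for f in in_set if not f)
    es, cin, cout = 0.0, 0.0, 0.0
    for i in range(len(order)):
        cin += w[i] / wsum
        cout += (0.0 if in_set[i] else 1.0) / n_out
        es += cin - cout
    return es


def frame(vals, genes=None):
    vals = np.asarray(vals, dtype=float)
    genes = genes or [f"g{i}" for i in range(vals.shape[0])]
    return pd.DataFrame(vals, index=genes,
                        columns=[f"s{j}" for j in range(vals.shape[1])])


class TestSsgsea:
    @pytest.mark.parametrize("n", [4, 6, 8])
    def test_matches_oracle_on_all_set_choices(self, n, rng):
        X = frame(rng.normal(size=(n, 2)))
        for r in range(1, n):
            for combo in itertools.combinations(X.index, r):
                gs = GeneSet("S", tuple(combo))
                got = ssgsea_score(X, gs, normalize_es=False)
                for s in X.columns:
                    assert got[s] == pytest.approx(
                        oracle_es(X[s], set(combo), 0.25), abs=1e-10)

    @pytest.mark.parametrize("n", [10, 12])
    def test_matches_oracle_on_random_sets(self, n, rng):
        X = frame(rng.normal(size=(n, 3)))
        for _ in range(20):
            r = int(rng.integers(1, n))
            combo = tuple(rng.choice(X.index, size=r, replace=False))
            got = ssgsea_score(X, GeneSet("S", combo), normalize_es=False)
            for s in X.columns:
                assert got[s] == pytest.approx(oracle_es(X[s], set(combo), 0.25),
                                               abs=1e-10)

    def test_top_set_positive_bottom_set_negative(self, rng):
        X = frame(np.sort(rng.normal(size=(10, 1)), axis=0)[::-1])
        top = ssgsea_score(X, GeneSet("T", tuple(X.index[:3])), normalize_es=False)
        bottom = ssgsea_score(X, GeneSet("B", tuple(X.index[-3:])), normalize_es=False)
        assert top.iloc[0] > 0
        assert bottom.iloc[0] < 0

    def test_rank_invariance_under_monotone_transform(self, rng):
        X = frame(rng.normal(size=(15, 4)))
        gs = GeneSet("S", tuple(X.index[2:7]))
        a = ssgsea_score(X, gs, normalize_es=False)
        b = ssgsea_score(np.exp(X) + 3.0, gs, normalize_es=False)
        pd.testing.assert_series_equal(a, b)

    def test_whole_universe_set_rejected(self, rng):
        X = frame(rng.normal(size=(5, 2)))
        with pytest.raises(ValueError, match="whole gene universe"):
            ssgsea_score(X, GeneSet("ALL", tuple(X.index)))

    def test_absent_members_dropped_with_warning(self, rng):
        X = frame(rng.normal(size=(8, 2)))
        gs = GeneSet("S", ("g1", "g2", "nope"))
        with pytest.warns(UserWarning, match="absent member"):
            got = ssgsea_score(X, gs, normalize_es=False)
        assert np.isfinite(got).all()

    def test_normalized_scores_divided_by_range(self, rng):
        X = frame(rng.normal(size=(20, 6)))
        gs = GeneSet("S", tuple(X.index[:5]))
        raw = ssgsea_score(X, gs, normalize_es=False)
        norm = ssgsea_score(X, gs, normalize_es=True)
        pd.testing.assert_series_equal(norm, raw / (raw.max() - raw.min()))


class TestEstimate:
    def make_sets(self, X):
        return (GeneSet("STROMAL", tuple(X.index[:4])),
                GeneSet("IMMUNE", tuple(X.index[4:8])))

    def test_score_additivity(self, rng):
        X = frame(rng.normal(size=(20, 5)))
        stromal, immune = self.make_sets(X)
        with pytest.warns(UserWarning, match="calibration"):
            est = estimate_scores(X, stromal, immune)
        assert np.allclose(est["estimate"], est["stromal"] + est["immune"])
        assert est.attrs["purity_out_of_calibration"]

    def test_purity_monotone_decreasing_on_valid_segment(self):
        es = np.linspace(0, (np.pi - PURITY_INTERCEPT) / PURITY_SLOPE * 0.9, 50)
        purity = np.cos(PURITY_INTERCEPT + PURITY_SLOPE * es)
        assert (np.diff(purity) < 0).all()

    def test_planted_stromal_enrichment_raises_score_lowers_purity(self, rng):
        X = frame(np.tile(rng.normal(8, 1, (20, 1)), (1, 2)))
        stromal, immune = self.make_sets(X)
        X.iloc[:4, 1] += 2.0                 # stromal genes upshifted in sample 2
        with pytest.warns(UserWarning, match="calibration"):
            est = estimate_scores(X, stromal, immune)
        assert est["stromal"].iloc[1] > est["stromal"].iloc[0]
        assert est["purity"].iloc[1] < est["purity"].iloc[0]


class TestGep:
    def test_constant_expression_returns_constant(self):
        genes = [f"G{i}" for i in range(18)]
        X = frame(np.full((18, 3), 5.5), genes=genes)
        score = tcell_inflamed_gep(X, GeneSet("GEP", tuple(genes)))
        assert np.allclose(score, 5.5)

    def test_partial_panel_warns_and_names_missing(self, rng):
        genes = [f"G{i}" for i in range(16)]
        X = frame(rng.normal(size=(16, 2)), genes=genes)
        gep = GeneSet("GEP", tuple(genes) + ("ABSENT1", "ABSENT2"))
        with pytest.warns(UserWarning, match="ABSENT1.*ABSENT2"):
            score = tcell_inflamed_gep(X, gep)
        assert len(score) == 2

    def test_under_half_present_rejected(self, rng):
        X = frame(rng.normal(size=(3, 2)), genes=["a", "b", "c"])
        gep = GeneSet("GEP", ("a", "b", "c", "d", "e", "f", "g"))
        with pytest.raises(ValueError, match="<50%"):
            tcell_inflamed_gep(X, gep)

    def test_planted_shift_moves_score_by_shift(self, rng):
        genes = [f"G{i}" for i in range(10)]
        pre = frame(rng.normal(size=(10, 4)), genes=genes)
        post = pre + 1.0
        gep = GeneSet("GEP", tuple(genes))
        diff = tcell_inflamed_gep(post, gep) - tcell_inflamed_gep(pre, gep)
        assert np.allclose(diff, 1.0)

    def test_weighted_variant(self):
        X = frame([[1.0], [3.0]], genes=["a", "b"])
        gs = GeneSet("GEP", ("a", "b"))
        score = tcell_inflamed_gep(X, gs, weights={"a": 3.0, "b": 1.0})
        assert score.iloc[0] == pytest.approx(1.5)


class TestIesPanel:
    def test_empty_overlap_signature_skipped(self, rng):
        X = frame(rng.normal(size=(10, 3)))
        sets = [GeneSet("OK", tuple(X.index[:3])), GeneSet("MISS", ("zz", "yy"))]
        with pytest.warns(UserWarning, match="no overlap"):
            out = ies_panel(X, sets)
        assert list(out.columns) == ["OK"]

    def test_duplicated_sample_gets_identical_scores(self, rng):
        X = frame(rng.normal(size=(12, 2)))
        X["s2"] = X["s0"]
        out = ies_panel(X, [GeneSet("S", tuple(X.index[:4]))])
        assert out.loc["s0", "S"] == pytest.approx(out.loc["s2", "S"])


class TestPairedScoreTest:
    def pairs(self, n):
        return [(f"p{i}", f"p{i}") for i in range(n)]

    def test_identical_arms_give_p_one(self):
        s = pd.Series([1.0, 2.0, 3.0, 4.0], index=[f"p{i}" for i in range(4)])
        res = paired_score_test(s, s, self.pairs(4))
        assert res["pvalue"] == 1.0
        assert res["statistic"] == 0.0

    def test_five_positive_differences_exact_one_sided(self):
        pre = pd.Series(np.zeros(5), index=[f"p{i}" for i in range(5)])
        post = pre + np.arange(1, 6)
        res = paired_score_test(pre, post, self.pairs(5), alternative="greater")
        assert res["pvalue"] == pytest.approx(1 / 32)
        assert res["median_change"] == 3.0

    def test_too_few_pairs_rejected(self):
        s = pd.Series([1.0, 2.0], index=["p0", "p1"])
        with pytest.raises(ValueError, match="3 complete pairs"):
            paired_score_test(s, s, self.pairs(2))

    def test_sign_pattern_invariant_to_monotone_rescale(self, rng):
        pre = pd.Series(rng.normal(size=6), index=[f"p{i}" for i in range(6)])
        post = pre + rng.normal(0.5, 0.1, 6)
        a = paired_score_test(pre, post, self.pairs(6))
        b = paired_score_test(pre * 3 + 1, post * 3 + 1, self.pairs(6))
        assert a["statistic"] == pytest.approx(b["statistic"])
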
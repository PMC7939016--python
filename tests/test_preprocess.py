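"""Normalization factor arithmetic, detection filtering, batch screening and
empirical-Bayes batch correction."""

import numpy as np
import pandas as pd
import pytest

from radresponse.expr import ExpressionError
from radresponse.preprocess import (
    BatchCorrector, PanelNormalizer, correct_batch_effects, detect_batch_effect,
    filter_genes, normalize,
)
from conftest import make_matrix

CLASSES_10 = (["endogenous"] * 5 + ["housekeeping"] * 2
              + ["positive_control"] * 2 + ["negative_control"])


def _toy_matrix(n_samples=4, seed=0, scale=None):
    rng = np.random.default_rng(seed)
    base = np.array([200, 500, 50, 1000, 80, 600, 700, 4000, 1000, 2], dtype=float)
    vals = np.tile(base[:, None], (1, n_samples))
    if scale is not None:
        vals = vals * np.asarray(scale)[None, :]
    return make_matrix(np.round(vals).astype(int), list(CLASSES_10))


class TestNormalize:
    def test_identical_profiles_give_unit_factors(self):
        norm = normalize(_toy_matrix())
        assert np.allclose(norm.norm_factors["pos_factor"], 1.0)
        assert np.allclose(norm.norm_factors["hk_factor"], 1.0)
        assert norm.state == "normalized"

    def test_doubled_library_collapses_after_normalization(self):
        mat = _toy_matrix(n_samples=2, scale=[1.0, 2.0])
        norm = normalize(mat)
        endo = norm.genes_of_class("endogenous")
        a, b = norm.values.loc[endo].iloc[:, 0], norm.values.loc[endo].iloc[:, 1]
        assert np.allclose(a, b, atol=1e-9)

    def test_scaling_is_idempotent(self):
        """Re-deriving both scaling factors from the normalizer's own linear
        output yields exactly 1."""
        mat = _toy_matrix(n_samples=3, scale=[0.5, 1.0, 1.7])
        est = PanelNormalizer(log2=False)
        out = est.fit(mat).transform(mat)
        vals = out.values
        pos = vals.loc[out.genes_of_class("positive_control")].sum(axis=0)
        f_pos = np.exp(np.mean(np.log(pos))) / pos
        assert np.allclose(f_pos, 1.0)
        hk = vals.loc[out.genes_of_class("housekeeping")]
        gm = np.exp(np.mean(np.log(hk), axis=0))
        f_hk = np.exp(np.mean(np.log(gm))) / gm
        assert np.allclose(f_hk, 1.0)

    def test_background_floor_preserves_monotonicity(self):
        mat = _toy_matrix()
        mat.values.iloc[2, 0] = 0          # endogenous count below background
        mat.values.iloc[2, 1] = 1
        norm = normalize(mat)
        assert norm.values.iloc[2, 0] <= norm.values.iloc[2, 1] + 1e-12
        assert norm.values.iloc[2, 0] > 0  # floored to background, then logged

    def test_zero_positive_controls_rejected(self):
        mat = _toy_matrix()
        mat.values.iloc[7:9, 0] = 0
        with pytest.raises(ExpressionError, match="positive-control"):
            normalize(mat)

    def test_extreme_factor_flagged(self):
        mat = _toy_matrix(n_samples=3, scale=[1.0, 1.0, 60.0])
        with pytest.warns(UserWarning, match="lane quality"):
            normalize(mat)


class TestFilterGenes:
    def _matrix_with_detection(self, nonzero_per_gene, n_samples=100):
        n_genes = len(nonzero_per_gene)
        vals = np.zeros((n_genes + 3, n_samples), dtype=int)
        for i, nz in enumerate(nonzero_per_gene):
            vals[i, :nz] = 50
        vals[n_genes:] = 100                      # hk + controls
        classes = (["endogenous"] * n_genes
                   + ["housekeeping", "positive_control", "negative_control"])
        return make_matrix(vals, classes)

    def test_boundary_is_inclusive(self):
        mat = self._matrix_with_detection([74, 75, 100])
        out = filter_genes(mat, 0.75)
        endo = out.genes_of_class("endogenous")
        assert list(endo) == ["g1", "g2"]

    def test_controls_never_filtered(self):
        mat = self._matrix_with_detection([100, 10])
        out = filter_genes(mat, 0.75)
        assert set(out.genes) >= {"g2", "g3", "g4"}

    def test_count_by_construction(self):
        # 6 of 20 endogenous genes zeroed in 30% of samples → 14 survive
        mat = self._matrix_with_detection([70] * 6 + [100] * 14)
        assert len(filter_genes(mat, 0.75).genes_of_class("endogenous")) == 14

    def test_no_value_mutation(self):
        mat = self._matrix_with_detection([100, 80])
        out = filter_genes(mat, 0.75)
        pd.testing.assert_frame_equal(out.values, mat.values.loc[out.genes])

    def test_all_filtered_rejected(self):
        mat = self._matrix_with_detection([10, 20])
        with pytest.raises(ExpressionError, match="all endogenous"):
            filter_genes(mat, 0.75)


def _batch_matrix(shift=0.0, n_per_batch=10, n_genes=60, seed=0, group_effect=0.0):
    rng = np.random.default_rng(seed)
    n = 2 * n_per_batch
    X = rng.normal(8, 1, (n_genes, 1)) + rng.normal(0, 0.5, (n_genes, n))
    batch = np.array(["B1"] * n_per_batch + ["B2"] * n_per_batch)
    group = np.array(["g", "p"] * n_per_batch)      # orthogonal to batch
    X[:, batch == "B2"] += shift
    X[: n_genes // 2, group == "p"] += group_effect
    samples = pd.DataFrame({"batch": batch, "group": group},
                           index=[f"s{j}" for j in range(n)])
    return make_matrix(X, ["endogenous"] * n_genes, state="normalized",
                       samples=samples)


class TestDetectBatch:
    def test_planted_shift_detected(self):
        rep = detect_batch_effect(_batch_matrix(shift=2.0), "batch")
        assert rep.batch_present
        assert (rep.per_component["pvalue"] <= 1).all()

    def test_null_rarely_flagged(self):
        flags = sum(detect_batch_effect(_batch_matrix(shift=0.0, seed=s), "batch")
                    .batch_present for s in range(10))
        assert flags <= 2

    def test_single_batch_rejected(self):
        mat = _batch_matrix()
        mat.samples["batch"] = "B1"
        with pytest.raises(ExpressionError, match="two batches"):
            detect_batch_effect(mat, "batch")

    def test_confounded_design_rejected(self):
        mat = _batch_matrix()
        with pytest.raises(ExpressionError, match="confounded"):
            detect_batch_effect(mat, "batch", group=mat.samples["batch"].to_numpy())


class TestBatchCorrection:
    def test_single_batch_identity(self):
        mat = _batch_matrix()
        mat.samples["batch"] = "B1"
        with pytest.warns(UserWarning, match="single batch"):
            out = correct_batch_effects(mat, "batch")
        pd.testing.assert_frame_equal(out.values, mat.values)

    def test_location_shift_removed(self):
        mat = _batch_matrix(shift=2.0)
        out = correct_batch_effects(mat, "batch")
        b = mat.samples["batch"] == "B2"
        before = (mat.values.loc[:, b.to_numpy()].mean(axis=1)
                  - mat.values.loc[:, ~b.to_numpy()].mean(axis=1))
        after = (out.values.loc[:, b.to_numpy()].mean(axis=1)
                 - out.values.loc[:, ~b.to_numpy()].mean(axis=1))
        assert after.abs().mean() < 0.1 * before.abs().mean()

    def test_orthogonal_group_effect_preserved(self):
        mat = _batch_matrix(shift=2.0, group_effect=1.5)
        out = correct_batch_effects(mat, "batch", covariates=mat.samples["group"])
        g = (mat.samples["group"] == "p").to_numpy()
        affected = out.values.index[:30]
        diff = (out.values.loc[affected, g].mean(axis=1)
                - out.values.loc[affected, ~g].mean(axis=1))
        assert diff.mean() == pytest.approx(1.5, rel=0.10)

    def test_grand_mean_preserved(self):
        mat = _batch_matrix(shift=2.0)
        out = correct_batch_effects(mat, "batch")
        assert np.allclose(out.values.mean(axis=1), mat.values.mean(axis=1),
                           atol=1e-6)

    def test_tiny_batch_rejected(self):
        mat = _batch_matrix(n_per_batch=5)
        mat.samples.loc[mat.samples.index[1:], "batch"] = "B2"
        with pytest.raises(ExpressionError, match="<2 samples"):
            correct_batch_effects(mat, "batch")

    def test_confounded_covariate_rejected(self):
        mat = _batch_matrix()
        with pytest.raises(ExpressionError, match="confounded"):
            BatchCorrector().fit_transform(mat, "batch",
                                           covariates=mat.samples["batch"].to_numpy())
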
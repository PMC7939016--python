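"""Panel-count preprocessing: control-based normalization, detection
filtering, and empirical-Bayes batch correction.

The normalization recipe follows standard practice for reporter-count
panels: (1) lane efficiency is equalized with a positive-control scaling
factor (cohort geometric mean of positive-control sums over the sample's
sum), (2) counts below a per-sample background threshold (mean + 2·sd of
the negative controls) are floored to that threshold, (3) content is
equalized with a housekeeping scaling factor (cohort geometric mean of the
housekeeping geometric means over the sample's), and (4) values are
log2(x + 1) transformed.  Each step is switchable.

Batch effects in the normalized log2 data are screened by testing the top
principal components against the batch labels, and corrected with a
parametric empirical-Bayes location/scale model (gene-wise standardization
preserving covariate effects, batch parameters shrunk toward common
priors, back-transformation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from .expr import ExpressionMatrix, ExpressionError
from .tcd import kruskal_wallis

SCALE_FACTOR_FLAG_RANGE = (0.1, 10.0)   # lane-quality warning band


def _gmean(x: np.ndarray, axis=None) -> np.ndarray:
    return np.exp(np.mean(np.log(x), axis=axis))


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

class PanelNormalizer(BaseEstimator, TransformerMixin):
    """Control- and housekeeping-based normalizer for raw panel counts.

    ``fit`` learns the cohort reference levels (geometric mean of
    positive-control sums and of housekeeping geometric means); ``transform``
    scales each sample to those references, floors sub-background values and
    applies log2(x + 1).  The positive-control factor is applied to every
    gene; the housekeeping factor only to endogenous and housekeeping genes,
    which keeps re-derived factors on the normalizer's own output exactly 1.

    Parameters
    ----------
    use_positive_controls, use_background, use_housekeeping, log2 : bool
        Toggles for the individual steps.
    background_sds : float
        Negative-control threshold is mean + ``background_sds``·sd.
    """

    def __init__(self, use_positive_controls: bool = True, use_background: bool = True,
                 use_housekeeping: bool = True, log2: bool = True,
                 background_sds: float = 2.0):
        self.use_positive_controls = use_positive_controls
        self.use_background = use_background
        self.use_housekeeping = use_housekeeping
        self.log2 = log2
        self.background_sds = background_sds

    def _check(self, matrix: ExpressionMatrix) -> None:
        if matrix.state != "raw":
            raise ExpressionError("normalize expects a raw-count matrix")
        for cls, flag in (("positive_control", self.use_positive_controls),
                          ("negative_control", self.use_background),
                          ("housekeeping", self.use_housekeeping)):
            if flag and len(matrix.genes_of_class(cls)) == 0:
                raise ExpressionError(f"normalization requires ≥1 {cls} gene")

    def _pos_sums(self, matrix: ExpressionMatrix) -> pd.Series:
        pos_sums = matrix.values.loc[matrix.genes_of_class("positive_control")] \
            .astype(float).sum(axis=0)
        if self.use_positive_controls and (pos_sums <= 0).any():
            bad = pos_sums.index[pos_sums <= 0].tolist()
            raise ExpressionError(f"zero positive-control sum in samples {bad}")
        return pos_sums

    def _scaled_and_floored(self, matrix: ExpressionMatrix,
                            f_pos: pd.Series) -> tuple[pd.DataFrame, pd.Series]:
        """Positive-control scaling then background flooring; shared by fit
        and transform so derived factors are exactly reproducible."""
        vals = matrix.values.astype(float).mul(f_pos, axis=1)
        thr = pd.Series(0.0, index=matrix.sample_ids)
        if self.use_background:
            neg = vals.loc[matrix.genes_of_class("negative_control")]
            thr = neg.mean(axis=0) + self.background_sds * neg.std(axis=0, ddof=1)
            thr = thr.fillna(neg.mean(axis=0))
            target = matrix.genes_of_class("endogenous").append(
                matrix.genes_of_class("housekeeping"))
            vals.loc[target] = vals.loc[target].clip(lower=thr, axis=1)
        return vals, thr

    def _hk_gmeans(self, matrix: ExpressionMatrix, vals: pd.DataFrame) -> pd.Series:
        hk = vals.loc[matrix.genes_of_class("housekeeping")].to_numpy()
        if (hk.sum(axis=0) <= 0).any():
            cols = matrix.sample_ids[hk.sum(axis=0) <= 0].tolist()
            raise ExpressionError(f"zero housekeeping sum in samples {cols}")
        # zeros enter the geometric mean at a 0.5-count detection limit
        return pd.Series(_gmean(np.where(hk <= 0, 0.5, hk), axis=0),
                         index=matrix.sample_ids)

    def fit(self, matrix: ExpressionMatrix, y=None) -> "PanelNormalizer":
        self._check(matrix)
        pos_sums = self._pos_sums(matrix)
        if self.use_positive_controls:
            self.pos_reference_ = float(_gmean(pos_sums.to_numpy()))
            f_pos = self.pos_reference_ / pos_sums
        else:
            self.pos_reference_ = None
            f_pos = pd.Series(1.0, index=matrix.sample_ids)
        if self.use_housekeeping:
            vals, _ = self._scaled_and_floored(matrix, f_pos)
            self.hk_reference_ = float(_gmean(self._hk_gmeans(matrix, vals).to_numpy()))
        else:
            self.hk_reference_ = None
        return self

    def transform(self, matrix: ExpressionMatrix) -> ExpressionMatrix:
        self._check(matrix)
        factors = pd.DataFrame(index=matrix.sample_ids,
                               columns=["pos_factor", "background", "hk_factor"],
                               dtype=float)
        if self.use_positive_controls:
            f_pos = self.pos_reference_ / self._pos_sums(matrix)
        else:
            f_pos = pd.Series(1.0, index=matrix.sample_ids)
        factors["pos_factor"] = f_pos
        vals, thr = self._scaled_and_floored(matrix, f_pos)
        factors["background"] = thr
        if self.use_housekeeping:
            f_hk = self.hk_reference_ / self._hk_gmeans(matrix, vals)
            target = matrix.genes_of_class("endogenous").append(
                matrix.genes_of_class("housekeeping"))
            vals.loc[target] = vals.loc[target].mul(f_hk, axis=1)
        else:
            f_hk = pd.Series(1.0, index=matrix.sample_ids)
        factors["hk_factor"] = f_hk

        lo, hi = SCALE_FACTOR_FLAG_RANGE
        for name in ("pos_factor", "hk_factor"):
            bad = factors.index[(factors[name] < lo) | (factors[name] > hi)]
            if len(bad):
                warnings.warn(f"{name} outside [{lo}, {hi}] for samples "
                              f"{bad.tolist()} — lane quality flag")
        if self.log2:
            vals = np.log2(vals + 1.0)
        # linear-scale output (log2=False) is still "normalized" state
        return replace(matrix, values=vals, state="normalized",
                       norm_factors=factors,
                       gene_classes=matrix.gene_classes.copy(),
                       samples=matrix.samples.copy())


def normalize(matrix: ExpressionMatrix, **kwargs) -> ExpressionMatrix:
    """Fit-and-apply :class:`PanelNormalizer` on one cohort."""
    return PanelNormalizer(**kwargs).fit(matrix).transform(matrix)


# ---------------------------------------------------------------------------
# detection filter
# ---------------------------------------------------------------------------

def filter_genes(matrix: ExpressionMatrix, min_nonzero_frac: float = 0.75,
                 raw_counts: pd.DataFrame | None = None) -> ExpressionMatrix:
    """Keep endogenous genes with nonzero raw counts in ≥ ``min_nonzero_frac``
    of samples (boundary inclusive); controls and housekeeping are never
    filtered.  The decision is made on raw counts: pass the raw matrix via
    ``raw_counts`` when filtering a normalized one.
    """
    if matrix.state == "raw":
        raw = matrix.values
    elif raw_counts is not None:
        raw = raw_counts.reindex(index=matrix.genes, columns=matrix.sample_ids)
        if raw.isna().any().any():
            raise ExpressionError("raw_counts does not cover the matrix")
    else:
        raise ExpressionError("filtering a normalized matrix requires raw_counts")
    endo = matrix.genes_of_class("endogenous")
    frac = (raw.loc[endo] > 0).mean(axis=1)
    keep_endo = endo[frac >= min_nonzero_frac]
    if len(keep_endo) == 0:
        raise ExpressionError("all endogenous genes removed by the detection filter")
    keep = matrix.genes[(matrix.gene_classes != "endogenous")
                        | matrix.genes.isin(keep_endo)]
    return matrix.subset_genes(keep)


# ---------------------------------------------------------------------------
# batch detection
# ---------------------------------------------------------------------------

@dataclass
class BatchReport:
    """Association of top principal components with batch labels."""

    per_component: pd.DataFrame      # columns: statistic, pvalue
    batch_present: bool
    alpha: float


def _check_confounding(batch: pd.Series, covariates: pd.Series | None) -> None:
    if covariates is None:
        return
    ct = pd.crosstab(batch, covariates)
    nonzero_per_batch = (ct > 0).sum(axis=1)
    nonzero_per_cov = (ct > 0).sum(axis=0)
    if (nonzero_per_batch == 1).all() and (nonzero_per_cov == 1).all():
        raise ExpressionError("batch is 1:1 confounded with the covariate; "
                              "batch effect is inestimable")


def detect_batch_effect(matrix: ExpressionMatrix, batch: Sequence | pd.Series | str = "batch",
                        n_components: int = 5, alpha: float = 0.01,
                        group: Sequence | None = None) -> BatchReport:
    """PCA screen for batch effects in normalized log2 data.

    Genes are centered, the top ``n_components`` sample scores are tested
    against batch with Kruskal-Wallis, and a batch effect is declared when
    any component associates at p < ``alpha``.
    """
    if matrix.state == "raw":
        raise ExpressionError("batch detection expects normalized data")
    batch = _resolve_labels(matrix, batch)
    if batch.nunique() < 2:
        raise ExpressionError("batch detection needs at least two batches")
    if group is not None:
        _check_confounding(batch, pd.Series(np.asarray(group), index=matrix.sample_ids))
    X = matrix.values.to_numpy().T                       # samples × genes
    X = X - X.mean(axis=0, keepdims=True)
    k = min(n_components, min(X.shape) - 1)
    scores = PCA(n_components=k, svd_solver="full").fit_transform(X)
    rows = []
    for i in range(k):
        res = kruskal_wallis(scores[:, i], batch.to_numpy())
        rows.append({"component": f"PC{i + 1}", "statistic": res.statistic,
                     "pvalue": res.pvalue})
    table = pd.DataFrame(rows).set_index("component")
    return BatchReport(per_component=table,
                       batch_present=bool((table["pvalue"] < alpha).any()),
                       alpha=alpha)


def _resolve_labels(matrix: ExpressionMatrix, labels) -> pd.Series:
    if isinstance(labels, str):
        if labels not in matrix.samples.columns:
            raise ExpressionError(f"no {labels!r} column in sample metadata")
        return matrix.samples[labels]
    return pd.Series(np.asarray(labels), index=matrix.sample_ids)


# ---------------------------------------------------------------------------
# empirical-Bayes batch correction
# ---------------------------------------------------------------------------

class BatchCorrector(BaseEstimator, TransformerMixin):
    """Parametric empirical-Bayes location/scale batch adjustment.

    Standard ComBat-style model: per gene, fit grand mean + covariate
    effects + batch offsets by least squares (batch offsets constrained to
    average to zero with batch-size weights), standardize residual-scale
    data, shrink per-batch location (normal prior) and scale
    (inverse-gamma prior, moment-matched) estimates via the usual iterative
    solution, then back-transform.  Covariate (biological group) effects are
    preserved.
    """

    def __init__(self, max_iter: int = 100, tol: float = 1e-6):
        self.max_iter = max_iter
        self.tol = tol

    def fit_transform(self, matrix: ExpressionMatrix, batch="batch",
                      covariates=None, y=None) -> ExpressionMatrix:
        if matrix.state == "raw":
            raise ExpressionError("batch correction expects normalized data")
        batch = _resolve_labels(matrix, batch)
        levels = pd.unique(batch)
        if len(levels) < 2:
            # identity contract: a constant batch column returns the input
            warnings.warn("single batch — matrix returned unchanged")
            return replace(matrix, values=matrix.values.copy(), state="batch_corrected")
        sizes = batch.value_counts()
        if (sizes < 2).any():
            small = sizes.index[sizes < 2].tolist()
            raise ExpressionError(f"batches with <2 samples: {small}")
        cov = None
        if covariates is not None:
            cov = _resolve_labels(matrix, covariates)
            _check_confounding(batch, cov)

        X = matrix.values.to_numpy(dtype=float)          # genes × samples
        n_genes, n_samples = X.shape
        # design: intercept + covariate dummies (drop first) + batch dummies (all)
        parts = [np.ones((n_samples, 1))]
        if cov is not None:
            dummies = pd.get_dummies(cov, drop_first=True).to_numpy(dtype=float)
            parts.append(dummies)
        B = pd.get_dummies(batch).reindex(columns=levels).to_numpy(dtype=float)
        design = np.hstack(parts + [B])
        n_nonbatch = design.shape[1] - len(levels)
        if np.linalg.matrix_rank(design) < design.shape[1] - 1:
            raise ExpressionError("design is rank deficient: batch confounded "
                                  "with covariates")
        # constrained LS: batch effects weighted to sum to zero
        nb = sizes.reindex(levels).to_numpy(dtype=float)
        C = np.zeros((1, design.shape[1]))
        C[0, n_nonbatch:] = nb / nb.sum()
        A = np.vstack([np.hstack([design.T @ design, C.T]),
                       np.hstack([C, np.zeros((1, 1))])])
        rhs = np.vstack([design.T @ X.T, np.zeros((1, n_genes))])
        beta = np.linalg.solve(A, rhs)[:-1]              # params × genes
        grand = (design[:, :n_nonbatch] @ beta[:n_nonbatch]).T   # genes × samples
        gamma_hat_ls = beta[n_nonbatch:]                 # batches × genes

        resid = X - grand - (B @ gamma_hat_ls).T
        var_pooled = (resid ** 2).mean(axis=1)           # genes
        sd = np.sqrt(var_pooled)
        if (sd == 0).any():
            raise ExpressionError("genes with zero residual variance cannot be adjusted")
        Z = (X - grand) / sd[:, None]                    # standardized

        gamma_star = np.zeros((len(levels), n_genes))
        delta_star = np.ones((len(levels), n_genes))
        for bi, lev in enumerate(levels):
            idx = (batch == lev).to_numpy()
            nbi = idx.sum()
            g_hat = Z[:, idx].mean(axis=1)
            d_hat = Z[:, idx].var(axis=1, ddof=1)
            g_bar, tau2 = g_hat.mean(), g_hat.var(ddof=1)
            m, s2 = d_hat.mean(), d_hat.var(ddof=1)
            if s2 <= 0 or tau2 <= 0:
                gamma_star[bi], delta_star[bi] = g_hat, d_hat
                continue
            a_prior = (2 * s2 + m ** 2) / s2
            b_prior = (m * s2 + m ** 3) / s2
            g_new, d_new = g_hat.copy(), d_hat.copy()
            for _ in range(self.max_iter):
                g_old, d_old = g_new, d_new
                g_new = (nbi * tau2 * g_hat + d_old * g_bar) / (nbi * tau2 + d_old)
                sse = ((Z[:, idx] - g_new[:, None]) ** 2).sum(axis=1)
                d_new = (0.5 * sse + b_prior) / (nbi / 2.0 + a_prior - 1.0)
                if (np.max(np.abs(g_new - g_old)) < self.tol
                        and np.max(np.abs(d_new - d_old)) < self.tol):
                    break
            gamma_star[bi], delta_star[bi] = g_new, d_new

        adj = Z.copy()
        for bi, lev in enumerate(levels):
            idx = (batch == lev).to_numpy()
            adj[:, idx] = (Z[:, idx] - gamma_star[bi][:, None]) / \
                np.sqrt(delta_star[bi])[:, None]
        out = adj * sd[:, None] + grand
        # restore each gene's grand mean exactly (a constant per-gene shift;
        # within- and between-batch structure of the adjustment is unchanged)
        out += (X.mean(axis=1) - out.mean(axis=1))[:, None]
        self.batch_levels_ = list(levels)
        self.gamma_star_ = gamma_star
        self.delta_star_ = delta_star
        values = pd.DataFrame(out, index=matrix.genes, columns=matrix.sample_ids)
        return replace(matrix, values=values, state="batch_corrected",
                       gene_classes=matrix.gene_classes.copy(),
                       samples=matrix.samples.copy())


def correct_batch_effects(matrix: ExpressionMatrix, batch="batch",
                          covariates=None) -> ExpressionMatrix:
    """Thin wrapper over :class:`BatchCorrector`."""
    return BatchCorrector().fit_transform(matrix, batch=batch, covariates=covariates)
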
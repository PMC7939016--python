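"""Single-sample gene-set scoring.

* ssGSEA: for one sample, genes are ranked by expression (descending,
  average ranks on ties) and the enrichment score is the sum over the
  ranked list of the difference between the weighted in-set cumulative
  distribution (weights = rank^alpha) and the unweighted out-of-set
  cumulative distribution.
* ESTIMATE: stromal and immune ssGSEA scores; their sum is the ESTIMATE
  score, mapped to tumor purity via the published transform
  purity = cos(0.6049872018 + 0.0001467884 · ESTIMATE).  The transform was
  calibrated on genome-wide arrays; on a targeted panel the purity values
  are flagged out-of-calibration.
* T-cell-inflamed expression profile: (weighted) mean of normalized log2
  expression over the available profile genes.
* Immune enrichment signature (IES) panel: ssGSEA per cell-type/process set.
* Paired score comparison: Wilcoxon signed-rank on pre/post differences.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .expr import ExpressionMatrix
from .genesets import GeneSet

PURITY_INTERCEPT = 0.6049872018
PURITY_SLOPE = 0.0001467884


def _as_frame(matrix) -> pd.DataFrame:
    if isinstance(matrix, ExpressionMatrix):
        keep = matrix.genes[matrix.gene_classes.isin(["endogenous", "housekeeping"])]
        return matrix.values.loc[keep]
    return pd.DataFrame(matrix)


# ---------------------------------------------------------------------------
# ssGSEA
# ---------------------------------------------------------------------------

def _es_one_sample(expr: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    """Running-sum enrichment score for one sample.

    ``expr``: expression vector; ``in_set``: boolean membership mask.
    """
    n = len(expr)
    ranks = stats.rankdata(expr)                    # ascending, ties averaged
    order = np.lexsort((np.arange(n), -ranks))      # descending, stable
    member = in_set[order]
    w = ranks[order] ** alpha * member
    denom_in = w.sum()
    denom_out = float((~member).sum())
    p_in = np.cumsum(w) / denom_in
    p_out = np.cumsum(~member) / denom_out
    return float(np.sum(p_in - p_out))


class SSGSEAScorer(BaseEstimator, TransformerMixin):
    """Per-sample gene-set enrichment scores (ssGSEA).

    ``transform`` maps an expression matrix to a samples × signatures score
    frame.  Set members absent from the matrix are dropped with a warning;
    sets with no overlap are skipped with a warning.  With
    ``normalize_es=True`` each signature's scores are divided by the
    cross-sample score range (making scores comparable across signatures).
    """

    def __init__(self, gene_sets: Sequence[GeneSet], alpha: float = 0.25,
                 normalize_es: bool = True):
        self.gene_sets = gene_sets
        self.alpha = alpha
        self.normalize_es = normalize_es

    def fit(self, matrix, y=None) -> "SSGSEAScorer":
        return self

    def transform(self, matrix) -> pd.DataFrame:
        vals = _as_frame(matrix)
        genes = vals.index
        arr = vals.to_numpy(dtype=float)
        out = {}
        for gs in self.gene_sets:
            present = [g for g in gs.genes if g in genes]
            if not present:
                warnings.warn(f"gene set {gs.name!r}: no overlap with the matrix, skipped")
                continue
            if len(present) < len(gs.genes):
                missing = sorted(set(gs.genes) - set(present))
                warnings.warn(f"gene set {gs.name!r}: {len(missing)} absent member(s) "
                              f"dropped: {missing[:5]}{'…' if len(missing) > 5 else ''}")
            if len(present) == len(genes):
                raise ValueError(f"gene set {gs.name!r} covers the whole gene "
                                 "universe; the out-of-set complement is empty")
            in_set = np.asarray(genes.isin(present))
            es = np.array([_es_one_sample(arr[:, j], in_set, self.alpha)
                           for j in range(arr.shape[1])])
            if self.normalize_es:
                rng_ = es.max() - es.min()
                if rng_ > 0:
                    es = es / rng_
            out[gs.name] = es
        return pd.DataFrame(out, index=vals.columns)


def ssgsea_score(matrix, gene_set: GeneSet, alpha: float = 0.25,
                 normalize_es: bool = True) -> pd.Series:
    """Per-sample enrichment score for one gene set."""
    frame = SSGSEAScorer([gene_set], alpha=alpha, normalize_es=normalize_es) \
        .fit(matrix).transform(matrix)
    if gene_set.name not in frame.columns:
        raise ValueError(f"gene set {gene_set.name!r} has no overlap with the matrix")
    return frame[gene_set.name]


# ---------------------------------------------------------------------------
# ESTIMATE
# ---------------------------------------------------------------------------

def estimate_scores(matrix, stromal_set: GeneSet, immune_set: GeneSet,
                    purity_transform: bool = True, alpha: float = 0.25) -> pd.DataFrame:
    """Stromal/immune/ESTIMATE scores and (optionally) tumor purity.

    ESTIMATE = stromal + immune exactly.  Purity uses the published cosine
    transform, clipped to [0, 1]; ``purity_out_of_calibration`` is attached
    as frame metadata because the transform was fit on genome-wide data.
    """
    stromal = ssgsea_score(matrix, stromal_set, alpha=alpha, normalize_es=False)
    immune = ssgsea_score(matrix, immune_set, alpha=alpha, normalize_es=False)
    out = pd.DataFrame({"stromal": stromal, "immune": immune})
    out["estimate"] = out["stromal"] + out["immune"]
    if purity_transform:
        out["purity"] = np.clip(
            np.cos(PURITY_INTERCEPT + PURITY_SLOPE * out["estimate"]), 0.0, 1.0)
        out.attrs["purity_out_of_calibration"] = True
        warnings.warn("purity transform applied outside its genome-wide "
                      "calibration domain (targeted panel); interpret with care")
    return out


# ---------------------------------------------------------------------------
# T-cell-inflamed expression profile
# ---------------------------------------------------------------------------

def tcell_inflamed_gep(matrix, gep_genes: GeneSet,
                       weights: Mapping[str, float] | None = None) -> pd.Series:
    """(Weighted) mean normalized log2 expression over available profile genes.

    Requires ≥50% of the profile present; absent members are reported in a
    warning (a known situation on targeted panels).
    """
    vals = _as_frame(matrix)
    present = [g for g in gep_genes.genes if g in vals.index]
    missing = sorted(set(gep_genes.genes) - set(present))
    if len(present) < 0.5 * len(gep_genes.genes):
        raise ValueError(f"only {len(present)}/{len(gep_genes.genes)} profile genes "
                         "present (<50%)")
    if missing:
        warnings.warn(f"profile genes absent from the panel: {missing}; score "
                      f"computed on the {len(present)} available genes")
    sub = vals.loc[present]
    if weights is None and gep_genes.weights is not None:
        weights = gep_genes.weights
    if weights is None:
        score = sub.mean(axis=0)
    else:
        w = np.array([float(weights[g]) for g in present])
        score = pd.Series(sub.to_numpy().T @ w / w.sum(), index=sub.columns)
    score.name = gep_genes.name
    return score


def ies_panel(matrix, ies_sets: Sequence[GeneSet], alpha: float = 0.25,
              normalize_es: bool = True) -> pd.DataFrame:
    """ssGSEA scores for each immune enrichment signature (samples × sets)."""
    return SSGSEAScorer(ies_sets, alpha=alpha, normalize_es=normalize_es) \
        .fit(matrix).transform(matrix)


# ---------------------------------------------------------------------------
# paired comparison
# ---------------------------------------------------------------------------

def paired_score_test(pre_scores: pd.Series, post_scores: pd.Series,
                      pairs: Sequence[tuple[str, str]],
                      alternative: str = "two-sided",
                      exact_limit: int = 25) -> dict:
    """Wilcoxon signed-rank test on paired (post − pre) score differences.

    Exact null distribution up to ``exact_limit`` pairs, normal
    approximation beyond.  All-zero differences return p = 1 with a zero
    statistic.
    """
    diffs = []
    for pre, post in pairs:
        if pre in pre_scores.index and post in post_scores.index:
            diffs.append(post_scores[post] - pre_scores[pre])
        else:
            warnings.warn(f"incomplete pair ({pre}, {post}) dropped")
    if len(diffs) < 3:
        raise ValueError("paired score test needs at least 3 complete pairs")
    diffs = np.asarray(diffs, dtype=float)
    median_change = float(np.median(diffs))
    if np.all(diffs == 0):
        return {"median_change": 0.0, "statistic": 0.0, "pvalue": 1.0,
                "n_pairs": len(diffs)}
    method = "exact" if len(diffs) <= exact_limit else "approx"
    res = stats.wilcoxon(diffs, alternative=alternative, method=method)
    return {"median_change": median_change, "statistic": float(res.statistic),
            "pvalue": float(res.pvalue), "n_pairs": len(diffs)}
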
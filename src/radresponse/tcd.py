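"""Tumor cell density (TCD) response quantification and classification.

TCD is the percentage of tumor cells among ~300 systematically sampled
points on an H&E section; earlier modeling showed at least 250 points are
needed for an accurate estimate, so assessments below that floor are
rejected and assessments outside the customary 300±15 window are flagged.
ΔTCD = post-treatment TCD − baseline TCD; negative values mean tumor-cell
loss, i.e. response.  Patients are stratified into good / intermediate /
poor responders by univariate k-means on ΔTCD (labels ordered by ascending
cluster mean), and the grouping is related to clinical covariates with
Kruskal-Wallis, Fisher exact and t tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

MIN_VALID_POINTS = 250          # accuracy floor from point-count modeling
TARGET_POINTS = 300             # customary assessment size
TARGET_POINTS_TOL = 15          # warning band around the target

RESPONSE_LABELS = ("good", "intermediate", "poor")


class InvalidAssessmentError(ValueError):
    """Point-grid assessment fails the minimum point-count requirement."""


@dataclass(frozen=True)
class PointGridAssessment:
    """Tumor/total point counts for one specimen."""

    specimen: str
    n_tumor_points: int
    n_total_points: int

    def __post_init__(self):
        if not 0 <= self.n_tumor_points <= self.n_total_points:
            raise ValueError("need 0 ≤ n_tumor_points ≤ n_total_points")


def compute_tcd(assessment: PointGridAssessment) -> float:
    """TCD percent = 100 · tumor points / total points.

    Raises :class:`InvalidAssessmentError` below the 250-point accuracy
    floor; warns outside the 300±15 assessment window.
    """
    n = assessment.n_total_points
    if n < MIN_VALID_POINTS:
        raise InvalidAssessmentError(
            f"{assessment.specimen}: {n} points assessed, below the "
            f"{MIN_VALID_POINTS}-point minimum required for an accurate TCD")
    if abs(n - TARGET_POINTS) > TARGET_POINTS_TOL:
        warnings.warn(
            f"{assessment.specimen}: {n} points is outside the customary "
            f"{TARGET_POINTS}±{TARGET_POINTS_TOL} window")
    return 100.0 * assessment.n_tumor_points / n


def delta_tcd(baseline: float, post: float) -> float:
    """ΔTCD = post − baseline (negative = tumor-cell loss = response)."""
    for v in (baseline, post):
        if not 0.0 <= v <= 100.0:
            raise ValueError("TCD percentages must lie in [0, 100]")
    return post - baseline


# ---------------------------------------------------------------------------
# univariate k-means response classifier
# ---------------------------------------------------------------------------

def _dp_contiguous_partition(x: np.ndarray, k: int) -> tuple[np.ndarray, float]:
    """Exact univariate k-means via dynamic programming over contiguous
    partitions of the sorted values.  Returns (cluster index per original
    position, ascending in value; total within-SS)."""
    n = len(x)
    order = np.argsort(x, kind="stable")
    xs = x[order]
    csum = np.concatenate([[0.0], np.cumsum(xs)])
    csq = np.concatenate([[0.0], np.cumsum(xs ** 2)])

    def cost(i: int, j: int) -> float:  # within-SS of xs[i:j]
        s, q, m = csum[j] - csum[i], csq[j] - csq[i], j - i
        return q - s * s / m

    dp = np.full((k + 1, n + 1), np.inf)
    cut = np.zeros((k + 1, n + 1), dtype=int)
    dp[0, 0] = 0.0
    for m in range(1, k + 1):
        for j in range(m, n + 1):
            for i in range(m - 1, j):
                c = dp[m - 1, i] + cost(i, j)
                if c < dp[m, j]:
                    dp[m, j] = c
                    cut[m, j] = i
    labels_sorted = np.empty(n, dtype=int)
    j = n
    for m in range(k, 0, -1):
        i = cut[m, j]
        labels_sorted[i:j] = m - 1
        j = i
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return labels, float(dp[k, n])


class ResponseKMeans(BaseEstimator, ClusterMixin):
    """Univariate k-means over ΔTCD with response-ordered labels.

    Lloyd iterations are run from a deterministic quantile seeding plus
    ``n_restarts`` random restarts; the best partition (lowest within-cluster
    sum of squares) is kept.  Clusters are relabeled by ascending cluster
    mean — most negative ΔTCD (largest tumor-cell loss) first — as
    good < intermediate < poor when ``k == 3``, or ``group_1..group_k``
    otherwise.  The optimal univariate partition is contiguous in ΔTCD; the
    fitted partition is asserted contiguous.

    Attributes
    ----------
    cluster_means_ : ndarray of shape (k,)
        Cluster means in ascending order.
    labels_ : ndarray of str
        Response label per fitted sample.
    boundaries_ : ndarray of shape (k - 1,)
        Midpoints between consecutive cluster means, for `predict`.
    """

    def __init__(self, k: int = 3, n_restarts: int = 10, seed: int = 0):
        self.k = k
        self.n_restarts = n_restarts
        self.seed = seed

    def fit(self, X, y=None) -> "ResponseKMeans":
        x = np.asarray(X, dtype=float).ravel()
        if np.unique(x).size < self.k:
            raise ValueError(f"need at least k={self.k} distinct ΔTCD values")
        data = x.reshape(-1, 1)
        qinit = np.quantile(x, (np.arange(self.k) + 0.5) / self.k).reshape(-1, 1)
        best = KMeans(n_clusters=self.k, init=qinit, n_init=1).fit(data)
        if self.n_restarts > 0:
            alt = KMeans(n_clusters=self.k, init="k-means++",
                         n_init=self.n_restarts,
                         random_state=self.seed).fit(data)
            if alt.inertia_ < best.inertia_ - 1e-12:
                best = alt
        order = np.argsort(best.cluster_centers_.ravel(), kind="stable")
        rank = np.empty(self.k, dtype=int)
        rank[order] = np.arange(self.k)
        idx = rank[best.labels_]
        inertia = best.inertia_
        # Lloyd can stall in a local optimum; the univariate problem admits an
        # exact O(k n²) dynamic program over contiguous partitions — take
        # whichever solution has the lower within-cluster sum of squares.
        dp_idx, dp_inertia = _dp_contiguous_partition(x, self.k)
        if dp_inertia < inertia - 1e-12:
            idx, inertia = dp_idx, dp_inertia
        means = np.array([x[idx == t].mean() for t in range(self.k)])
        self.cluster_means_ = means
        self.inertia_ = float(inertia)
        # optimal univariate k-means is contiguous in the sorted values
        order_x = np.argsort(x, kind="stable")
        if np.any(np.diff(idx[order_x]) < 0):
            raise AssertionError("fitted univariate partition is not contiguous in ΔTCD")
        names = self._label_names()
        self.labels_ = np.array([names[i] for i in idx])
        self.label_index_ = idx
        self.boundaries_ = (self.cluster_means_[:-1] + self.cluster_means_[1:]) / 2.0
        return self

    def _label_names(self) -> list[str]:
        if self.k == 3:
            return list(RESPONSE_LABELS)
        return [f"group_{i + 1}" for i in range(self.k)]

    def predict(self, X) -> np.ndarray:
        x = np.asarray(X, dtype=float).ravel()
        names = self._label_names()
        idx = np.searchsorted(self.boundaries_, x)
        return np.array([names[i] for i in idx])


def classify_response(delta_tcds: Sequence[float] | pd.Series, k: int = 3,
                      n_restarts: int = 10, seed: int = 0) -> pd.DataFrame:
    """Per-patient response calls from ΔTCD values.

    Returns a DataFrame with ``patient`` (index of the input if a Series),
    ``delta_tcd``, ``group`` and ``cluster_mean``.
    """
    if isinstance(delta_tcds, pd.Series):
        index = delta_tcds.index
        x = delta_tcds.to_numpy(dtype=float)
    else:
        x = np.asarray(delta_tcds, dtype=float)
        index = pd.RangeIndex(len(x))
    est = ResponseKMeans(k=k, n_restarts=n_restarts, seed=seed).fit(x)
    means = est.cluster_means_[est.label_index_]
    return pd.DataFrame({"patient": index, "delta_tcd": x, "group": est.labels_,
                         "cluster_mean": means}).set_index("patient")


def optimal_contiguous_partition(x: Sequence[float], k: int) -> list[int]:
    """Exhaustive minimum-within-SS contiguous k-partition of sorted values.

    Independent oracle for the k-means classifier: enumerates every
    placement of k−1 cut points in the sorted order and returns cluster
    indices (0..k−1, ascending in value) in the original order.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    order = np.argsort(x, kind="stable")
    xs = x[order]
    csum = np.concatenate([[0.0], np.cumsum(xs)])
    csq = np.concatenate([[0.0], np.cumsum(xs ** 2)])

    def ss(i, j):  # within-SS of xs[i:j]
        s, q, m = csum[j] - csum[i], csq[j] - csq[i], j - i
        return q - s * s / m

    best, best_cuts = np.inf, None
    for cuts in combinations(range(1, n), k - 1):
        bounds = (0, *cuts, n)
        total = sum(ss(bounds[t], bounds[t + 1]) for t in range(k))
        if total < best - 1e-12:
            best, best_cuts = total, bounds
    labels_sorted = np.empty(n, dtype=int)
    for t in range(k):
        labels_sorted[best_cuts[t]:best_cuts[t + 1]] = t
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return labels.tolist()


# ---------------------------------------------------------------------------
# association tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KruskalWallisResult:
    statistic: float
    df: int
    pvalue: float


def kruskal_wallis(values: Sequence[float], groups: Sequence) -> KruskalWallisResult:
    """Tie-corrected Kruskal-Wallis H with chi-square p on (g − 1) df."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("Kruskal-Wallis needs at least two groups")
    samples = [values[groups == g] for g in levels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group must be nonempty")
    h, p = stats.kruskal(*samples)
    return KruskalWallisResult(statistic=float(h), df=len(levels) - 1, pvalue=float(p))


def fisher_exact_2xc(table: np.ndarray) -> float:
    """Two-sided Fisher exact p for a 2×c table by exhaustive enumeration.

    Sums the probabilities of all tables with the observed margins whose
    probability does not exceed the observed table's (with a small relative
    tolerance against floating-point ties).
    """
    table = np.asarray(table, dtype=int)
    if table.ndim != 2 or table.shape[0] != 2:
        raise ValueError("table must be 2×c")
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    col = table.sum(axis=0)
    r1 = int(table[0].sum())
    n = int(table.sum())
    denom = comb(n, r1)

    def prob(row0: tuple[int, ...]) -> float:
        num = 1
        for cj, aj in zip(col, row0):
            num *= comb(int(cj), int(aj))
        return num / denom

    p_obs = prob(tuple(table[0]))
    total = 0.0
    c = len(col)

    def rec(j: int, remaining: int, row0: list[int]):
        nonlocal total
        if j == c - 1:
            if 0 <= remaining <= col[j]:
                p = prob(tuple(row0 + [remaining]))
                if p <= p_obs * (1 + 1e-9):
                    total += p
            return
        tail = int(col[j + 1:].sum())
        lo = max(0, remaining - tail)
        hi = min(int(col[j]), remaining)
        for a in range(lo, hi + 1):
            rec(j + 1, remaining - a, row0 + [a])

    rec(0, r1, [])
    return min(total, 1.0)


def clinical_association(table: pd.DataFrame, groups: Sequence,
                         categorical_max_levels: int = 10) -> pd.DataFrame:
    """Per-covariate association tests between response groups.

    Categorical covariates: Fisher exact (exhaustive 2×c) when there are two
    groups, chi-square otherwise (with a warning).  Continuous covariates:
    Welch t test for two groups, Kruskal-Wallis beyond.  Covariates with an
    empty stratum are skipped with a warning.
    """
    groups = pd.Series(np.asarray(groups), index=table.index)
    levels = pd.unique(groups.dropna())
    rows = []
    for covar in table.columns:
        col = table[covar]
        mask = col.notna() & groups.notna()
        g = groups[mask]
        if any((g == lv).sum() == 0 for lv in levels):
            warnings.warn(f"covariate {covar!r}: empty stratum, skipped")
            continue
        is_cat = (col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype)
                  or col.dtype == bool
                  or col[mask].nunique() <= min(categorical_max_levels,
                                                max(2, len(col[mask]) // 5)))
        if is_cat:
            ct = pd.crosstab(g, col[mask])
            if len(levels) == 2:
                p = fisher_exact_2xc(ct.to_numpy())
                test = "fisher_exact"
            else:
                warnings.warn(f"covariate {covar!r}: >2 groups, chi-square used "
                              "instead of Fisher exact")
                p = float(stats.chi2_contingency(ct.to_numpy())[1])
                test = "chi2"
        else:
            vals = [col[mask][g == lv].to_numpy(dtype=float) for lv in levels]
            if len(levels) == 2:
                p = float(stats.ttest_ind(vals[0], vals[1], equal_var=False).pvalue)
                test = "t_welch"
            else:
                p = kruskal_wallis(col[mask].to_numpy(dtype=float), g.to_numpy()).pvalue
                test = "kruskal_wallis"
        rows.append({"covariate": covar, "test": test, "pvalue": p})
    if not rows:
        return pd.DataFrame(columns=["test", "pvalue"],
                            index=pd.Index([], name="covariate"))
    return pd.DataFrame(rows).set_index("covariate")


# ---------------------------------------------------------------------------
# TCD table I/O helpers
# ---------------------------------------------------------------------------

def tcd_from_table(df: pd.DataFrame) -> pd.DataFrame:
    """Per-patient ΔTCD from a TCD table.

    Accepts either precomputed ``baseline_tcd``/``post_tcd`` percent columns
    or long-format point counts (``patient``, ``timepoint``,
    ``n_tumor_points``, ``n_total_points``).
    """
    if {"baseline_tcd", "post_tcd"}.issubset(df.columns):
        out = df.set_index("patient")[["baseline_tcd", "post_tcd"]].astype(float)
    elif {"patient", "timepoint", "n_tumor_points", "n_total_points"}.issubset(df.columns):
        tcds = {}
        for _, row in df.iterrows():
            a = PointGridAssessment(str(row.get("specimen", row["patient"])),
                                    int(row["n_tumor_points"]), int(row["n_total_points"]))
            tcds.setdefault(row["patient"], {})[row["timepoint"]] = compute_tcd(a)
        out = pd.DataFrame(tcds).T.rename(columns={"pre": "baseline_tcd",
                                                   "post": "post_tcd"})
        out.index.name = "patient"
    else:
        raise ValueError("TCD table needs baseline_tcd/post_tcd or point-count columns")
    out["delta_tcd"] = [delta_tcd(b, p)
                        for b, p in zip(out["baseline_tcd"], out["post_tcd"])]
    return out
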
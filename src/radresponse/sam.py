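"""Significance Analysis of Microarrays (SAM).

Moderated per-gene statistics with a permutation-estimated false discovery
rate, for three designs:

* two-class unpaired: d_i = (mean2 − mean1) / (s_i + s0), s_i the pooled
  standard error, null from group-label permutations;
* paired two-class: d_i = mean(Δ_i) / (s_i + s0), Δ the post−pre paired
  differences, null from random sign flips of pairs;
* multiclass: ANOVA-like r_i = sqrt((Σn/Πn)·Σ_k n_k (x̄_ik − x̄_i)²) /
  (s_i + s0), which reduces exactly to |d_i| for two classes; null from
  label shuffles.

The exchangeability (fudge) factor s0 is chosen by the Tusher procedure:
among candidate percentiles of the gene-wise scatter s, pick the one that
minimizes the coefficient of variation of the median absolute deviation of
d across s-quantile windows, making |d| roughly independent of s.

Significance: genes are ordered by d; the expected order statistics d̄_(i)
are the mean sorted permutation statistics.  For a threshold Δ, the calling
cutoffs are the first crossings of |d_(i) − d̄_(i)| ≥ Δ above and below the
origin; the estimated FDR at Δ is the median number of permutation
statistics beyond the cutoffs divided by the number of observed calls, and
a gene's q-value is the smallest estimated FDR at which it is called.

Permutation nulls are enumerated exhaustively whenever the design admits at
most ``exhaustive_limit`` distinct permutations, otherwise sampled without
replacement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations, product
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd

DEFAULT_N_PERM = 1000
EXHAUSTIVE_LIMIT = 10_000


@dataclass
class SamResult:
    """Per-gene SAM table plus permutation-null provenance.

    ``table`` columns: ``d`` (moderated statistic), ``effect_log2``
    (numerator), ``s`` (gene-wise scatter), ``q`` (permutation q-value),
    ``direction`` (``up``/``down``; absent for multiclass) and ``called``
    (at the requested FDR).
    """

    table: pd.DataFrame
    s0: float
    n_permutations: int
    exhaustive: bool
    seed: int | None
    design: str
    fdr_target: float
    dbar: np.ndarray            # expected order statistics, ascending

    @property
    def called_genes(self) -> list[str]:
        return self.table.index[self.table["called"]].tolist()

    def called_in_direction(self, direction: str) -> list[str]:
        t = self.table
        if "direction" not in t.columns:
            raise ValueError(f"{self.design} design has no direction")
        return t.index[t["called"] & (t["direction"] == direction)].tolist()


# ---------------------------------------------------------------------------
# s0 selection (Tusher procedure)
# ---------------------------------------------------------------------------

def _mad(x: np.ndarray) -> float:
    return float(np.median(np.abs(x - np.median(x)))) * 1.4826


def choose_s0(s_values: Sequence[float], d_numerators: Sequence[float],
              n_windows: int = 100) -> float:
    """Pick s0 from percentile candidates {0, 5, …, 100} of s.

    For each candidate, d = numerator / (s + s0) is computed and the
    coefficient of variation of MAD(d) across ``n_windows`` s-quantile
    windows is evaluated; the candidate with the smallest CV wins.  Ties
    (including a constant s, where every candidate is equivalent) resolve
    to the 5th-percentile candidate.
    """
    s = np.asarray(s_values, dtype=float)
    num = np.asarray(d_numerators, dtype=float)
    if len(s) < 10:
        raise ValueError("choose_s0 needs at least 10 genes")
    if np.ptp(s) == 0:
        return float(np.percentile(s, 5))
    cands = np.percentile(s, np.arange(0, 101, 5))
    order = np.argsort(s, kind="stable")
    edges = np.linspace(0, len(s), min(n_windows, len(s)) + 1).astype(int)
    windows = [order[edges[i]:edges[i + 1]] for i in range(len(edges) - 1)
               if edges[i + 1] > edges[i]]
    best_cv, best = np.inf, None
    for j, s0 in enumerate(cands):
        d = num / (s + s0)
        mads = np.array([_mad(d[w]) for w in windows])
        mean = mads.mean()
        cv = np.inf if mean == 0 else mads.std(ddof=1) / mean
        if cv < best_cv - 1e-12:
            best_cv, best = cv, s0
    if best is None:          # fully tied CV curve
        best = cands[1]
    return float(best)


# ---------------------------------------------------------------------------
# per-design statistics (vectorized across permutations)
# ---------------------------------------------------------------------------

def _safe_ratio(num: np.ndarray, denom: np.ndarray) -> np.ndarray:
    """num/denom with 0/0 → 0 (constant genes under a zero fudge factor)."""
    num = np.asarray(num, dtype=float)
    out = np.zeros(np.broadcast(num, denom).shape)
    np.divide(num, denom, out=out, where=np.asarray(denom) > 0)
    return out


def _two_class_d(X: np.ndarray, member: np.ndarray, s0: float):
    """d, numerator, s for group assignments.

    ``member``: boolean (n_samples × n_perm) matrix, True = group 2.
    Returns arrays of shape (n_genes, n_perm).
    """
    n = X.shape[1]
    A2 = member.astype(float)
    A1 = 1.0 - A2
    n2 = A2.sum(axis=0)
    n1 = n - n2
    m1 = (X @ A1) / n1
    m2 = (X @ A2) / n2
    sq = X ** 2
    ss1 = sq @ A1 - n1 * m1 ** 2
    ss2 = sq @ A2 - n2 * m2 ** 2
    sp2 = (ss1 + ss2) / (n1 + n2 - 2)
    s = np.sqrt(np.clip(sp2 * (1.0 / n1 + 1.0 / n2), 0.0, None))
    num = m2 - m1
    return _safe_ratio(num, s + s0), num, s


def _paired_d(Z: np.ndarray, signs: np.ndarray, s0: float):
    """d for paired differences under sign-flip matrix (n_pairs × n_perm)."""
    n = Z.shape[1]
    mean = (Z @ signs) / n
    ss = (Z ** 2).sum(axis=1, keepdims=True) - n * mean ** 2
    s = np.sqrt(np.clip(ss / (n - 1) / n, 0.0, None))
    return _safe_ratio(mean, s + s0), mean, s


def _multiclass_r(X: np.ndarray, assign: np.ndarray, n_classes: int, s0: float):
    """samr-style multiclass statistic for label matrices.

    ``assign``: integer (n_samples × n_perm) class indices.
    """
    n_genes, n = X.shape
    n_perm = assign.shape[1]
    r = np.empty((n_genes, n_perm))
    num = np.empty((n_genes, n_perm))
    s_out = np.empty((n_genes, n_perm))
    sq = X ** 2
    grand = X.mean(axis=1, keepdims=True)
    for p in range(n_perm):
        lab = assign[:, p]
        between = np.zeros(n_genes)
        wss = np.zeros(n_genes)
        nks = []
        for k in range(n_classes):
            idx = lab == k
            nk = idx.sum()
            nks.append(nk)
            mk = X[:, idx].mean(axis=1)
            between += nk * (mk - grand[:, 0]) ** 2
            wss += sq[:, idx].sum(axis=1) - nk * mk ** 2
        nks = np.array(nks, dtype=float)
        fac = nks.sum() / nks.prod()
        scor = np.sqrt(fac * between)
        sd = np.sqrt(wss / (nks.sum() - n_classes) * np.sum(1.0 / nks))
        r[:, p] = _safe_ratio(scor, sd + s0)
        num[:, p] = scor
        s_out[:, p] = sd
    return r, num, s_out


# ---------------------------------------------------------------------------
# permutation sets
# ---------------------------------------------------------------------------

def _two_class_permutations(n: int, n2: int, n_perm: int, rng: np.random.Generator,
                            force_sampled: bool = False):
    """Boolean membership matrix (n × B).  Exhaustive over all C(n, n2)
    assignments when that count is within the limit (unless sampling is
    forced), else distinct assignments sampled without replacement."""
    total = comb(n, n2)
    if total <= EXHAUSTIVE_LIMIT and not force_sampled:
        combos = list(combinations(range(n), n2))
        member = np.zeros((n, len(combos)), dtype=bool)
        for j, c in enumerate(combos):
            member[list(c), j] = True
        return member, True
    seen: set[tuple[int, ...]] = set()
    cols = []
    while len(cols) < min(n_perm, total):
        c = tuple(sorted(rng.choice(n, size=n2, replace=False).tolist()))
        if c in seen:
            continue
        seen.add(c)
        col = np.zeros(n, dtype=bool)
        col[list(c)] = True
        cols.append(col)
    return np.stack(cols, axis=1), False


def _sign_flip_permutations(n_pairs: int, n_perm: int, rng: np.random.Generator,
                            force_sampled: bool = False):
    total = 2 ** n_pairs
    if total <= EXHAUSTIVE_LIMIT and not force_sampled:
        signs = np.array(list(product([1.0, -1.0], repeat=n_pairs))).T
        return signs, True
    seen: set[tuple[int, ...]] = set()
    cols = []
    while len(cols) < min(n_perm, total):
        c = tuple(rng.choice([1, -1], size=n_pairs).tolist())
        if c in seen:
            continue
        seen.add(c)
        cols.append(np.array(c, dtype=float))
    return np.stack(cols, axis=1), False


def _multiclass_permutations(labels: np.ndarray, n_perm: int,
                             rng: np.random.Generator,
                             force_sampled: bool = False):
    n = len(labels)
    counts = np.bincount(labels)
    total = 1
    rem = n
    for c in counts:
        total *= comb(rem, int(c))
        rem -= int(c)
        if total > EXHAUSTIVE_LIMIT:
            break
    if total <= EXHAUSTIVE_LIMIT and not force_sampled:
        perms = _enumerate_assignments(counts)
        return np.stack(perms, axis=1), True
    cols = []
    seen: set[tuple[int, ...]] = set()
    while len(cols) < min(n_perm, total):
        p = rng.permutation(labels)
        t = tuple(p.tolist())
        if t in seen:
            continue
        seen.add(t)
        cols.append(p)
    return np.stack(cols, axis=1), False


def _enumerate_assignments(counts: np.ndarray) -> list[np.ndarray]:
    n = int(counts.sum())
    out: list[np.ndarray] = []

    def rec(remaining: set[int], k: int, assign: np.ndarray):
        if k == len(counts):
            out.append(assign.copy())
            return
        for combo in combinations(sorted(remaining), int(counts[k])):
            assign[list(combo)] = k
            rec(remaining - set(combo), k + 1, assign)

    rec(set(range(n)), 0, np.zeros(n, dtype=int))
    return out


# ---------------------------------------------------------------------------
# FDR / q-values
# ---------------------------------------------------------------------------

def _q_values(d: np.ndarray, d_perm: np.ndarray, two_sided: bool):
    """SAM q-values from observed d and permutation statistics.

    Returns (q, dbar).  ``d_perm``: (n_genes × B).  For one-sided designs
    (multiclass r ≥ 0) only the upper cutoff is scanned.
    """
    n_genes, n_perm = d_perm.shape
    # round at 1e-10 so the threshold bookkeeping is exactly invariant to
    # float reassociation (e.g. permuting the sample order)
    d = np.round(d, 10)
    d_perm = np.round(d_perm, 10)
    order = np.argsort(d, kind="stable")
    d_sorted = d[order]
    perm_sorted = np.sort(d_perm, axis=0)               # each column sorted ascending
    # expected order statistics, rounded so summation order cannot leak in
    dbar = np.round(perm_sorted.mean(axis=1), 10)
    diff = d_sorted - dbar

    # candidate deltas: the achievable crossing gaps (capped scan grid)
    gaps = np.abs(diff)
    deltas = np.unique(np.concatenate([[0.0], gaps[gaps > 0]]))
    if len(deltas) > 256:
        deltas = np.unique(np.concatenate(
            [deltas[[0, -1]], np.quantile(deltas, np.linspace(0, 1, 255))]))
    up_ok = (dbar > 0) if two_sided else np.ones(n_genes, dtype=bool)
    lo_ok = (dbar < 0) if two_sided else np.zeros(n_genes, dtype=bool)

    cutups = np.empty(len(deltas))
    cutlos = np.empty(len(deltas))
    for j, delta in enumerate(deltas):
        up_idx = np.nonzero((diff >= delta) & up_ok)[0]
        cutups[j] = d_sorted[up_idx[0]] if len(up_idx) else np.inf
        if two_sided:
            lo_idx = np.nonzero((-diff >= delta) & lo_ok)[0]
            cutlos[j] = d_sorted[lo_idx[-1]] if len(lo_idx) else -np.inf
        else:
            cutlos[j] = -np.inf

    false_counts = np.empty((n_perm, len(deltas)))
    for b in range(n_perm):
        col = perm_sorted[:, b]
        c = n_genes - np.searchsorted(col, cutups, side="left")
        if two_sided:
            c = c + np.searchsorted(col, cutlos, side="right")
        false_counts[b] = c
    med_false = np.median(false_counts, axis=0)

    q = np.full(n_genes, 1.0)
    for j in range(len(deltas)):
        called = (d >= cutups[j]) | (d <= cutlos[j])
        n_called = int(called.sum())
        if n_called == 0:
            continue
        fdr = min(1.0, float(med_false[j]) / n_called)
        q[called] = np.minimum(q[called], fdr)
    return q, dbar


# ---------------------------------------------------------------------------
# public designs
# ---------------------------------------------------------------------------

def _as_matrix(matrix) -> tuple[np.ndarray, pd.Index, pd.Index]:
    """Accept an ExpressionMatrix (endogenous genes only) or a DataFrame."""
    from .expr import ExpressionMatrix
    if isinstance(matrix, ExpressionMatrix):
        vals = matrix.values.loc[matrix.endogenous]
    else:
        vals = pd.DataFrame(matrix)
    arr = vals.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise ValueError("SAM does not support missing values; complete the "
                         "matrix upstream")
    return arr, vals.index, vals.columns


def sam_two_class(matrix, labels: Sequence, fdr_target: float = 0.05,
                  n_perm: int = DEFAULT_N_PERM, seed: int = 0,
                  group_order: Sequence | None = None,
                  force_sampled: bool = False) -> SamResult:
    """Unpaired two-class SAM; d > 0 means higher in the second group.

    ``group_order`` fixes which label is the reference (first) group;
    defaults to sorted label order.
    """
    X, genes, samples = _as_matrix(matrix)
    labels = pd.Series(np.asarray(labels), index=samples)
    levels = sorted(labels.unique()) if group_order is None else list(group_order)
    if len(levels) != 2:
        raise ValueError(f"two-class SAM needs exactly 2 groups, got {levels}")
    counts = labels.value_counts()
    if (counts.reindex(levels) < 2).any():
        raise ValueError("both groups need at least 2 samples")
    if n_perm < 25:
        warnings.warn(f"n_perm={n_perm} is very small; FDR estimates will be unstable")
    member_obs = (labels == levels[1]).to_numpy()[:, None]
    rng = np.random.default_rng(seed)
    d_obs, num, s = (a[:, 0] for a in _two_class_d(X, member_obs, 0.0))
    s0 = choose_s0(s, num)
    d_obs = _safe_ratio(num, s + s0)
    member, exhaustive = _two_class_permutations(len(labels), int(member_obs.sum()),
                                                 n_perm, rng,
                                                 force_sampled=force_sampled)
    d_perm, _, _ = _two_class_d(X, member, s0)
    q, dbar = _q_values(d_obs, d_perm, two_sided=True)
    table = pd.DataFrame({
        "d": d_obs, "effect_log2": num, "s": s, "q": q,
        "direction": np.where(d_obs >= 0, "up", "down"),
        "called": q <= fdr_target}, index=genes)
    return SamResult(table=table, s0=s0, n_permutations=member.shape[1],
                     exhaustive=exhaustive, seed=seed, design="two_class",
                     fdr_target=fdr_target, dbar=dbar)


def sam_paired(matrix, pairs: Sequence[tuple[str, str]], fdr_target: float = 0.05,
               n_perm: int = DEFAULT_N_PERM, seed: int = 0,
               force_sampled: bool = False) -> SamResult:
    """Paired two-class SAM on (pre, post) sample pairs; d > 0 = up post."""
    X, genes, samples = _as_matrix(matrix)
    loc = {s: i for i, s in enumerate(samples)}
    complete = []
    for pre, post in pairs:
        if pre in loc and post in loc:
            complete.append((loc[pre], loc[post]))
        else:
            warnings.warn(f"incomplete pair ({pre}, {post}) dropped")
    if len(complete) < 3:
        raise ValueError("paired SAM needs at least 3 complete pairs")
    if n_perm < 25:
        warnings.warn(f"n_perm={n_perm} is very small; FDR estimates will be unstable")
    Z = np.stack([X[:, post] - X[:, pre] for pre, post in complete], axis=1)
    rng = np.random.default_rng(seed)
    ones = np.ones((Z.shape[1], 1))
    d0, num, s = (a[:, 0] for a in _paired_d(Z, ones, 0.0))
    s0 = choose_s0(s, num)
    d_obs = _safe_ratio(num, s + s0)
    signs, exhaustive = _sign_flip_permutations(Z.shape[1], n_perm, rng,
                                                force_sampled=force_sampled)
    d_perm, _, _ = _paired_d(Z, signs, s0)
    q, dbar = _q_values(d_obs, d_perm, two_sided=True)
    table = pd.DataFrame({
        "d": d_obs, "effect_log2": num, "s": s, "q": q,
        "direction": np.where(d_obs >= 0, "up", "down"),
        "called": q <= fdr_target}, index=genes)
    return SamResult(table=table, s0=s0, n_permutations=signs.shape[1],
                     exhaustive=exhaustive, seed=seed, design="paired",
                     fdr_target=fdr_target, dbar=dbar)


def sam_multiclass(matrix, labels: Sequence, fdr_target: float = 0.05,
                   n_perm: int = DEFAULT_N_PERM, seed: int = 0,
                   force_sampled: bool = False) -> SamResult:
    """Multiclass SAM (≥2 groups); r is nonnegative, no direction."""
    X, genes, samples = _as_matrix(matrix)
    labels = pd.Series(np.asarray(labels), index=samples)
    levels = sorted(labels.unique())
    if len(levels) < 2:
        raise ValueError("multiclass SAM needs at least 2 groups")
    if (labels.value_counts().reindex(levels) < 2).any():
        raise ValueError("every group needs at least 2 samples")
    codes = labels.map({lv: i for i, lv in enumerate(levels)}).to_numpy()
    rng = np.random.default_rng(seed)
    r0, num, s = (a[:, 0] for a in _multiclass_r(X, codes[:, None], len(levels), 0.0))
    s0 = choose_s0(s, num)
    r_obs = _safe_ratio(num, s + s0)
    assign, exhaustive = _multiclass_permutations(codes, n_perm, rng,
                                                  force_sampled=force_sampled)
    r_perm, _, _ = _multiclass_r(X, assign, len(levels), s0)
    q, dbar = _q_values(r_obs, r_perm, two_sided=False)
    table = pd.DataFrame({"d": r_obs, "effect_log2": num, "s": s, "q": q,
                          "called": q <= fdr_target}, index=genes)
    return SamResult(table=table, s0=s0, n_permutations=assign.shape[1],
                     exhaustive=exhaustive, seed=seed, design="multiclass",
                     fdr_target=fdr_target, dbar=dbar)


def write_sam_tsv(result: SamResult, path) -> None:
    out = result.table.copy()
    out.index.name = "gene"
    out.rename(columns={"called": "called_at_fdr"}, inplace=True)
    out.to_csv(path, sep="\t", float_format="%.10g")
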
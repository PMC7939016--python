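"""Signature-score survival validation.

An external-style cohort is scored by the unweighted mean expression of a
gene signature (here, genes upregulated at baseline in poor responders);
the optimal score cutpoint is chosen by maximally selected rank statistics
— the standardized two-group log-rank statistic is evaluated at every
admissible cutpoint (both groups ≥ a minimum proportion of the cohort) and
the cutpoint maximizing |statistic| wins.  The resulting high-expressor
("poor-like") and low-expressor ("good-like") groups are compared with
Kaplan-Meier curves and the log-rank test.

The log-rank p at the *selected* cutpoint is anti-conservative (the maximum
of many correlated statistics is compared against a single-split null); it
is reported with a ``selection_biased`` flag and no corrected p is
computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .genesets import GeneSet


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def signature_mean(matrix, genes: GeneSet | list[str]) -> pd.Series:
    """Unweighted mean normalized expression over the available signature genes."""
    from .scoring import _as_frame
    vals = _as_frame(matrix)
    members = genes.genes if isinstance(genes, GeneSet) else list(genes)
    present = [g for g in members if g in vals.index]
    if not present:
        raise ValueError("signature has no overlap with the expression matrix")
    missing = sorted(set(members) - set(present))
    if missing:
        warnings.warn(f"signature genes absent: {missing}")
    score = vals.loc[present].mean(axis=0)
    score.name = "signature_mean"
    return score


# ---------------------------------------------------------------------------
# log-rank machinery
# ---------------------------------------------------------------------------

def _validate_survival(time: np.ndarray, event: np.ndarray) -> None:
    if (time < 0).any():
        raise ValueError("survival times must be nonnegative")
    if not np.isin(event, [0, 1]).all():
        raise ValueError("event indicators must be 0/1")


def logrank_components(time: np.ndarray, event: np.ndarray,
                       in_group: np.ndarray) -> tuple[float, float]:
    """(O − E, V) for the flagged group, summed over distinct event times.

    Observed-minus-expected deaths with the hypergeometric variance of the
    per-event-time 2×2 tables.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    in_group = np.asarray(in_group, dtype=bool)
    _validate_survival(time, event)
    ts = np.unique(time[event == 1])
    if len(ts) == 0:
        return 0.0, 0.0
    sorted_all = np.sort(time)
    sorted_grp = np.sort(time[in_group])
    n_at = len(time) - np.searchsorted(sorted_all, ts, side="left")
    n1_at = len(sorted_grp) - np.searchsorted(sorted_grp, ts, side="left")
    d = np.bincount(np.searchsorted(ts, time[event == 1]), minlength=len(ts))
    d1 = np.bincount(np.searchsorted(ts, time[(event == 1) & in_group]),
                     minlength=len(ts))
    frac = n1_at / n_at
    o_minus_e = float(np.sum(d1 - d * frac))
    ok = n_at > 1
    var = float(np.sum(d[ok] * frac[ok] * (1 - frac[ok])
                       * (n_at[ok] - d[ok]) / (n_at[ok] - 1)))
    return o_minus_e, var


@dataclass(frozen=True)
class LogrankResult:
    statistic: float          # chi-square, 1 df
    pvalue: float
    o_minus_e: float
    variance: float


def logrank_test(group_a: pd.DataFrame, group_b: pd.DataFrame) -> LogrankResult:
    """Two-group log-rank test; groups are (time, event) tables."""
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be nonempty")
    time = np.concatenate([group_a["time"].to_numpy(float),
                           group_b["time"].to_numpy(float)])
    event = np.concatenate([group_a["event"].to_numpy(int),
                            group_b["event"].to_numpy(int)])
    if event.sum() == 0:
        raise ValueError("log-rank needs at least one event")
    in_a = np.concatenate([np.ones(len(group_a), bool), np.zeros(len(group_b), bool)])
    ome, var = logrank_components(time, event, in_a)
    if var == 0:
        raise ValueError("log-rank variance is zero (no comparable risk sets)")
    chi2 = ome ** 2 / var
    return LogrankResult(statistic=float(chi2),
                         pvalue=float(stats.chi2.sf(chi2, df=1)),
                         o_minus_e=ome, variance=var)


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def km_estimate(survival: pd.DataFrame) -> pd.DataFrame:
    """Product-limit survival curve with right censoring.

    Returns a step-function table (time, at_risk, survival); S(0) = 1 and
    the curve drops only at event times.
    """
    if len(survival) == 0:
        raise ValueError("need at least one record")
    time = survival["time"].to_numpy(float)
    event = survival["event"].to_numpy(int)
    _validate_survival(time, event)
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    table = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    out = pd.DataFrame({"time": table.index.to_numpy(float),
                        "at_risk": table["at_risk"].to_numpy(int),
                        "survival": surv.reindex(table.index).to_numpy(float)})
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# maximally selected rank statistics
# ---------------------------------------------------------------------------

@dataclass
class CutpointSplit:
    """Optimal-cutpoint split with its (selection-biased) log-rank test."""

    scores: pd.Series
    cutpoint: float
    labels: pd.Series                 # "high" (> cutpoint) / "low"
    max_statistic: float              # standardized log-rank statistic at cutpoint
    n_high: int
    n_low: int
    logrank: LogrankResult
    km_high: pd.DataFrame
    km_low: pd.DataFrame
    scan: pd.DataFrame = field(repr=False, default=None)
    selection_biased: bool = True     # the p-value ignores cutpoint selection


def maxstat_cutpoint(scores: pd.Series, survival: pd.DataFrame,
                     min_prop: float = 0.1) -> CutpointSplit:
    """Maximally selected rank statistic over admissible score cutpoints.

    Candidates are the observed score values whose split keeps both groups
    at ≥ ``min_prop`` of the samples; at each, the standardized log-rank
    statistic (O−E)/sqrt(V) of high (> cut) vs low is computed and the
    candidate with the largest |statistic| is selected (ties: smallest
    cutpoint).  KM curves and the log-rank test are evaluated on the
    selected split.
    """
    scores = pd.Series(scores).astype(float)
    surv = survival.set_index("sample") if "sample" in survival.columns else survival
    surv = surv.loc[scores.index]
    time = surv["time"].to_numpy(float)
    event = surv["event"].to_numpy(int)
    _validate_survival(time, event)
    n = len(scores)
    if n < 10 or event.sum() < 5:
        raise ValueError("maxstat needs ≥10 samples with ≥5 events")
    if scores.nunique() == 1:
        raise ValueError("all scores equal; no admissible cutpoint")
    x = scores.to_numpy()
    candidates = np.unique(x)
    rows = []
    for c in candidates:
        high = x > c
        n_high = int(high.sum())
        if min(n_high, n - n_high) < min_prop * n or n_high in (0, n):
            continue
        ome, var = logrank_components(time, event, high)
        if var == 0:
            continue
        rows.append({"cutpoint": float(c), "statistic": ome / np.sqrt(var),
                     "n_high": n_high})
    if not rows:
        raise ValueError(f"no admissible cutpoint at min_prop={min_prop}")
    scan = pd.DataFrame(rows)
    best = scan.loc[scan["statistic"].abs().idxmax()]
    cut = float(best["cutpoint"])
    high = scores > cut
    labels = pd.Series(np.where(high, "high", "low"), index=scores.index,
                       name="expressor")
    high_tab = surv[high.to_numpy()]
    low_tab = surv[~high.to_numpy()]
    lr = logrank_test(high_tab, low_tab)
    return CutpointSplit(
        scores=scores, cutpoint=cut, labels=labels,
        max_statistic=float(best["statistic"]),
        n_high=int(high.sum()), n_low=int((~high).sum()),
        logrank=lr, km_high=km_estimate(high_tab), km_low=km_estimate(low_tab),
        scan=scan)


def split_and_survive(matrix, genes: GeneSet | list[str], survival: pd.DataFrame,
                      min_prop: float = 0.1) -> CutpointSplit:
    """signature_mean → maxstat_cutpoint → KM + log-rank, end to end.

    High expressors are the "poor-like", low the "good-like" samples.
    """
    scores = signature_mean(matrix, genes)
    surv = survival.set_index("sample") if "sample" in survival.columns else survival
    common = scores.index.intersection(surv.index)
    if len(common) < len(scores):
        warnings.warn(f"{len(scores) - len(common)} scored sample(s) lack survival "
                      "records and were dropped")
    return maxstat_cutpoint(scores.loc[common],
                            surv.loc[common].reset_index(names="sample"),
                            min_prop=min_prop)


def write_split_tsv(split: CutpointSplit, path) -> None:
    out = pd.DataFrame({"score": split.scores, "expressor": split.labels})
    out.index.name = "sample"
    out.to_csv(path, sep="\t", float_format="%.10g")
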
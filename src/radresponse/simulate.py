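"""Synthetic neoadjuvant-radiotherapy cohort generator.

Emulates the statistical structure of a paired pre-/post-treatment rectal
cancer cohort profiled on a targeted immune gene panel:

* per-patient tumor cell density (TCD) pairs with group-specific ΔTCD
  shifts (good / intermediate / poor responders),
* negative-binomial panel counts with housekeeping genes, a positive-control
  titration ladder, negative-control background, per-sample library-size
  factors, planted baseline differential expression (up in poor responders),
  planted longitudinal upregulation (post-treatment samples of good
  responders), and an additive log2-scale batch shift,
* survival times whose hazard depends on a gene-signature score,
* gene-set collections (decoy pathways plus sets enriched for the planted
  genes) so enrichment stages have a known answer,

together with a ground-truth record for every planted effect.  Every
stream of randomness is a deterministic function of ``cfg.seed``.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expr import ExpressionMatrix, write_counts_tsv, write_meta_tsv
from .genesets import GeneSet, write_gmt

GROUPS = ("good", "intermediate", "poor")

# substream keys: one independent generator per simulation component
_STREAMS = {"truth": 0, "tcd": 1, "means": 2, "counts": 3, "survival": 4, "sets": 5}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


@dataclass
class CohortConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults mirror the cohort shape the analysis was designed for: 53
    patients in response groups of 23/16/14, a 760-probe panel (706
    endogenous, 40 housekeeping, 6 positive and 8 negative controls), 40
    genes upregulated (log2FC 2) at baseline in poor responders, 198 genes
    upregulated (log2FC 1) post-treatment in good responders, a two-batch
    design with a 1-log2-unit location shift, and survival hazard scaling
    2× per unit of standardized signature score.
    """

    n_patients: int = 53
    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"good": 23, "intermediate": 16, "poor": 14})
    tcd_baseline_mean: float = 55.0
    tcd_baseline_sd: float = 10.0
    tcd_shift: Mapping[str, float] = field(
        default_factory=lambda: {"good": -25.0, "intermediate": -10.0, "poor": 0.0})
    tcd_noise_sd: float = 3.0
    n_genes: int = 706                # endogenous probes
    n_housekeeping: int = 40
    n_pos_controls: int = 6
    n_neg_controls: int = 8
    nb_dispersion: float = 0.1
    baseline_de_genes: int = 40
    baseline_de_lfc: float = 2.0
    longitudinal_de_genes: int = 198
    longitudinal_de_lfc: float = 1.0
    n_batches: int = 2
    batch_shift_log2: float = 1.0
    libsize_sd_log2: float = 0.15
    survival_hr_per_unit: float = 2.0
    censor_frac: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if sum(self.group_sizes.values()) != self.n_patients:
            raise ValueError("group sizes must sum to n_patients")
        if set(self.group_sizes) != set(GROUPS):
            raise ValueError(f"group_sizes must have keys {GROUPS}")
        for name in ("tcd_baseline_sd", "tcd_noise_sd", "nb_dispersion", "libsize_sd_log2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be ≥ 0")
        for lfc in (self.baseline_de_lfc, self.longitudinal_de_lfc):
            if not np.isfinite(lfc):
                raise ValueError("fold changes must be finite")
        if self.baseline_de_genes + self.longitudinal_de_genes > self.n_genes:
            raise ValueError("fewer endogenous genes than planted DE genes")
        if self.n_batches < 1:
            raise ValueError("need at least one batch")
        if not 0 <= self.censor_frac < 1:
            raise ValueError("censor_frac must be in [0, 1)")


@dataclass
class GroundTruth:
    """Record of every planted effect; disjoint from housekeeping/controls."""

    group: dict[str, str]                     # patient → response group
    baseline_de: dict[str, float]             # gene → signed log2FC (poor vs good)
    longitudinal_de: dict[str, float]         # gene → log2FC (post vs pre, good)
    batch: dict[str, str]                     # sample → batch label
    batch_shift: dict[str, float]             # batch → additive log2 shift
    true_cutpoint: float | None = None        # survival-score cutpoint

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# naming helpers
# ---------------------------------------------------------------------------

def _patients(cfg: CohortConfig) -> list[str]:
    return [f"P{i + 1:03d}" for i in range(cfg.n_patients)]


def _patient_groups(cfg: CohortConfig) -> dict[str, str]:
    out, i = {}, 0
    pats = _patients(cfg)
    for g in GROUPS:
        for _ in range(cfg.group_sizes[g]):
            out[pats[i]] = g
            i += 1
    return out


def _gene_names(cfg: CohortConfig) -> tuple[list[str], list[str], list[str], list[str]]:
    endo = [f"ENDO_{i + 1:04d}" for i in range(cfg.n_genes)]
    hk = [f"HK_{i + 1:02d}" for i in range(cfg.n_housekeeping)]
    pos = [f"POS_{chr(65 + i)}" for i in range(cfg.n_pos_controls)]
    neg = [f"NEG_{chr(65 + i)}" for i in range(cfg.n_neg_controls)]
    return endo, hk, pos, neg


def make_truth(cfg: CohortConfig) -> GroundTruth:
    """Draw the planted-effect structure (identical across noise seeds only
    when ``cfg.seed`` is identical; the structure — which genes are planted,
    group sizes, batch labels — depends only on the configuration counts)."""
    cfg.validate()
    rng = _rng(cfg.seed, "truth")
    endo, _, _, _ = _gene_names(cfg)
    planted = rng.choice(len(endo), size=cfg.baseline_de_genes + cfg.longitudinal_de_genes,
                         replace=False)
    base_idx = planted[:cfg.baseline_de_genes]
    long_idx = planted[cfg.baseline_de_genes:]
    baseline_de = {endo[i]: float(cfg.baseline_de_lfc) for i in sorted(base_idx)}
    longitudinal_de = {endo[i]: float(cfg.longitudinal_de_lfc) for i in sorted(long_idx)}
    group = _patient_groups(cfg)
    batch, shift = {}, {}
    for b in range(cfg.n_batches):
        shift[f"B{b + 1}"] = float(b * cfg.batch_shift_log2)
    pats = _patients(cfg)
    # alternate batches across the patient list so every response group is
    # represented in every batch (both samples of a patient share a lane)
    for j, p in enumerate(pats):
        lab = f"B{j % cfg.n_batches + 1}"
        for tp in ("pre", "post"):
            batch[f"{p}_{tp}"] = lab
    return GroundTruth(group=group, baseline_de=baseline_de,
                       longitudinal_de=longitudinal_de, batch=batch, batch_shift=shift)


# ---------------------------------------------------------------------------
# TCD pairs
# ---------------------------------------------------------------------------

def simulate_tcd_pairs(cfg: CohortConfig) -> pd.DataFrame:
    """Per-patient baseline and post-treatment TCD percentages.

    ``post = clip(baseline + shift(group) + noise, 0, 100)``.
    """
    cfg.validate()
    rng = _rng(cfg.seed, "tcd")
    group = _patient_groups(cfg)
    for g, s in cfg.tcd_shift.items():
        m = cfg.tcd_baseline_mean + s
        if not 0 <= m <= 100:
            warnings.warn(f"group {g!r}: mean TCD {m:.1f}% outside [0, 100], values clipped")
    pats = _patients(cfg)
    baseline = np.clip(rng.normal(cfg.tcd_baseline_mean, cfg.tcd_baseline_sd, len(pats)), 0, 100)
    shift = np.array([cfg.tcd_shift[group[p]] for p in pats])
    noise = rng.normal(0.0, cfg.tcd_noise_sd, len(pats)) if cfg.tcd_noise_sd > 0 else 0.0
    post = np.clip(baseline + shift + noise, 0, 100)
    return pd.DataFrame({
        "patient": pats,
        "baseline_tcd": np.round(baseline, 6),
        "post_tcd": np.round(post, 6),
        "group": [group[p] for p in pats],
    })


# ---------------------------------------------------------------------------
# panel counts
# ---------------------------------------------------------------------------

_POS_LADDER_BASE = 32.0  # counts of the lowest positive-control titration step


def _sample_table(cfg: CohortConfig, truth: GroundTruth) -> pd.DataFrame:
    pats = _patients(cfg)
    # regimen alternates; TRG drawn per response group (no complete responses)
    trg_probs = {"good": [0.3, 0.7, 0.0], "intermediate": [0.0, 1.0, 0.0],
                 "poor": [0.0, 0.8, 0.2]}
    rows = []
    trg_rng = np.random.default_rng([int(cfg.seed), 17])
    for j, p in enumerate(pats):
        g = truth.group[p]
        trg = int(trg_rng.choice([1, 2, 3], p=trg_probs[g]))
        regimen = "SCRT" if j % 2 == 0 else "LCRT"
        for tp in ("pre", "post"):
            sid = f"{p}_{tp}"
            rows.append({"sample": sid, "patient": p, "timepoint": tp,
                         "regimen": regimen, "trg": trg, "batch": truth.batch[sid],
                         "group": g})
    return pd.DataFrame(rows).set_index("sample")


def expected_counts(cfg: CohortConfig, truth: GroundTruth) -> pd.DataFrame:
    """Expected (mean) count matrix of :func:`simulate_counts`, genes × samples."""
    cfg.validate()
    endo, hk, pos, neg = _gene_names(cfg)
    meta = _sample_table(cfg, truth)
    rng = _rng(cfg.seed, "means")
    base_endo = rng.normal(6.0, 1.5, cfg.n_genes)           # log2 mean counts
    base_hk = rng.normal(9.0, 0.7, cfg.n_housekeeping)
    libsize = 2.0 ** rng.normal(0.0, cfg.libsize_sd_log2, len(meta))
    pos_ladder = _POS_LADDER_BASE * 4.0 ** np.arange(cfg.n_pos_controls)[::-1]
    neg_mean = np.full(cfg.n_neg_controls, 2.0)

    log2mu = np.tile(base_endo[:, None], (1, len(meta)))
    genes = pd.Index(endo)
    for s_i, (sid, row) in enumerate(meta.iterrows()):
        if row["group"] == "poor":
            for g, lfc in truth.baseline_de.items():
                log2mu[genes.get_loc(g), s_i] += lfc
        if row["group"] == "good" and row["timepoint"] == "post":
            for g, lfc in truth.longitudinal_de.items():
                log2mu[genes.get_loc(g), s_i] += lfc
        log2mu[:, s_i] += truth.batch_shift[row["batch"]]

    mu_endo = 2.0 ** log2mu
    mu_hk = np.tile((2.0 ** base_hk)[:, None], (1, len(meta)))
    mu_pos = np.tile(pos_ladder[:, None], (1, len(meta)))
    mu_neg = np.tile(neg_mean[:, None], (1, len(meta)))
    mu = np.vstack([mu_endo, mu_hk, mu_pos, mu_neg]) * libsize[None, :]
    return pd.DataFrame(mu, index=endo + hk + pos + neg, columns=meta.index)


def simulate_counts(cfg: CohortConfig, truth: GroundTruth) -> ExpressionMatrix:
    """Raw negative-binomial panel counts for paired pre/post samples.

    Housekeeping genes carry no group/timepoint/batch effect beyond the
    library-size factor; positive controls follow a fixed 4-fold titration
    ladder; negative controls sit at a low Poisson background.
    """
    mu = expected_counts(cfg, truth)
    meta = _sample_table(cfg, truth)
    endo, hk, pos, neg = _gene_names(cfg)
    classes = pd.Series(
        ["endogenous"] * len(endo) + ["housekeeping"] * len(hk)
        + ["positive_control"] * len(pos) + ["negative_control"] * len(neg),
        index=mu.index)
    rng = _rng(cfg.seed, "counts")
    arr = mu.to_numpy()
    if cfg.nb_dispersion <= 0:
        counts = rng.poisson(arr)
    else:
        size = 1.0 / cfg.nb_dispersion
        p = size / (size + arr)
        counts = rng.negative_binomial(size, p)
    values = pd.DataFrame(counts.astype(np.int64), index=mu.index, columns=mu.columns)
    return ExpressionMatrix(values=values, gene_classes=classes, samples=meta, state="raw")


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def simulate_survival(scores: pd.Series, hr_per_unit: float, censor_frac: float,
                      seed: int, baseline_hazard: float = 0.05) -> pd.DataFrame:
    """Exponential event times with hazard ``h0 · hr_per_unit**score``.

    Censoring is independent Uniform(0, c_max), with c_max solved so the
    expected censored fraction approximates ``censor_frac``.
    """
    scores = pd.Series(scores).astype(float)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if hr_per_unit <= 0:
        raise ValueError("hr_per_unit must be positive")
    if not 0 <= censor_frac < 1:
        raise ValueError("censor_frac must be in [0, 1)")
    rng = np.random.default_rng(seed)
    rates = baseline_hazard * hr_per_unit ** scores.to_numpy()
    times = rng.exponential(1.0 / rates)
    if censor_frac == 0:
        return pd.DataFrame({"sample": scores.index, "time": times,
                             "event": np.ones(len(scores), dtype=int)})

    def censored_frac(cmax: float) -> float:
        # P(C < T), C ~ U(0,cmax), T ~ Exp(rate): E[(1 − exp(−r·cmax))/(r·cmax)]
        rc = rates * cmax
        return float(np.mean((1.0 - np.exp(-rc)) / rc))

    lo, hi = 1e-6, 1e6
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if censored_frac(mid) > censor_frac:
            lo = mid
        else:
            hi = mid
    cmax = np.sqrt(lo * hi)
    cens = rng.uniform(0.0, cmax, len(scores))
    event = (times <= cens).astype(int)
    obs = np.minimum(times, cens)
    return pd.DataFrame({"sample": scores.index, "time": obs, "event": event})


# ---------------------------------------------------------------------------
# gene sets with known enrichment structure
# ---------------------------------------------------------------------------

def make_gene_sets(cfg: CohortConfig, truth: GroundTruth) -> list[GeneSet]:
    """Decoy pathways plus sets loaded with the planted genes.

    ``PATHWAY_POOR_BASELINE`` is enriched for the baseline-planted genes,
    ``PATHWAY_RT_INDUCED_IFN`` (and the IES/GEP sets) for the longitudinal
    ones, so ORA and signature scoring have a known positive.
    """
    rng = _rng(cfg.seed, "sets")
    endo, _, _, _ = _gene_names(cfg)
    base = list(truth.baseline_de)
    long_ = list(truth.longitudinal_de)
    other = [g for g in endo if g not in truth.baseline_de and g not in truth.longitudinal_de]

    def draw(pool: list[str], k: int) -> list[str]:
        k = min(k, len(pool))
        return sorted(rng.choice(pool, size=k, replace=False).tolist())

    sets = []
    for i in range(12):
        sets.append(GeneSet(f"PATHWAY_SYN_{i + 1:02d}", tuple(draw(other, 30)),
                            "synthetic decoy pathway"))
    sets.append(GeneSet("PATHWAY_POOR_BASELINE",
                        tuple(draw(base, 30) + draw(other, 5)),
                        "synthetic pathway enriched for baseline poor-responder genes"))
    sets.append(GeneSet("PATHWAY_RT_INDUCED_IFN",
                        tuple(draw(long_, 30) + draw(other, 5)),
                        "synthetic pathway enriched for treatment-induced genes"))
    # signature sets may overlap, as real cell-type signatures do
    ies_spec = {"IES_TYPE_I_IFN": (long_, 12), "IES_CYTOLYTIC_ACTIVITY": (long_, 8),
                "IES_TCELL_COINHIBITION": (long_, 9)}
    for name, (pool, k) in ies_spec.items():
        sets.append(GeneSet(name, tuple(draw(pool, k)),
                            "synthetic immune enrichment signature"))
    mac = draw(base, 5) + draw(long_, 5)
    sets.append(GeneSet("IES_MACROPHAGE", tuple(dict.fromkeys(mac)),
                        "synthetic immune enrichment signature"))
    sets.append(GeneSet("IES_NEUTROPHIL", tuple(draw(other, 8)),
                        "synthetic decoy immune signature"))
    sets.append(GeneSet("GEP_TCELL_INFLAMED", tuple(draw(long_, 18)),
                        "synthetic T-cell-inflamed profile"))
    sets.append(GeneSet("ESTIMATE_STROMAL_SYN",
                        tuple(dict.fromkeys(draw(base, 15) + draw(other, 5))),
                        "synthetic stromal signature (up in poor responders)"))
    sets.append(GeneSet("ESTIMATE_IMMUNE_SYN",
                        tuple(dict.fromkeys(draw(long_, 15) + draw(other, 5))),
                        "synthetic immune signature"))
    return sets


# ---------------------------------------------------------------------------
# full cohort
# ---------------------------------------------------------------------------

@dataclass
class SimulatedCohort:
    tcd: pd.DataFrame
    counts: ExpressionMatrix
    survival: pd.DataFrame
    gene_sets: list[GeneSet]
    truth: GroundTruth


def simulate_cohort(cfg: CohortConfig | None = None,
                    out_dir: str | Path | None = None) -> SimulatedCohort:
    """Compose TCD, counts, gene sets and survival into one cohort.

    When ``out_dir`` is given, writes ``counts.tsv``, ``meta.tsv``,
    ``tcd.tsv``, ``survival.tsv``, ``sets.gmt`` and ``truth.json``.
    """
    cfg = cfg or CohortConfig()
    cfg.validate()
    truth = make_truth(cfg)
    tcd = simulate_tcd_pairs(cfg)
    counts = simulate_counts(cfg, truth)
    sets = make_gene_sets(cfg, truth)

    # survival scored on baseline samples via the planted baseline signature
    base_samples = counts.samples.index[counts.samples["timepoint"] == "pre"]
    sig = list(truth.baseline_de)
    logc = np.log2(1.0 + counts.values.loc[sig, base_samples])
    score = logc.mean(axis=0)
    z = (score - score.mean()) / score.std(ddof=0)
    truth.true_cutpoint = float(np.median(z))
    survival = simulate_survival(z, cfg.survival_hr_per_unit, cfg.censor_frac,
                                 seed=int(np.random.default_rng([cfg.seed, 4]).integers(2**31)))
    cohort = SimulatedCohort(tcd=tcd, counts=counts, survival=survival,
                             gene_sets=sets, truth=truth)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_counts_tsv(counts, out / "counts.tsv")
        write_meta_tsv(counts, out / "meta.tsv")
        tcd.to_csv(out / "tcd.tsv", sep="\t", index=False, float_format="%.10g")
        survival.to_csv(out / "survival.tsv", sep="\t", index=False, float_format="%.10g")
        write_gmt(sets, out / "sets.gmt")
        truth.to_json(out / "truth.json")
    return cohort
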
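"""End-to-end orchestration of the two analysis arms.

* Baseline arm: ΔTCD k-means response classification → preprocessing of
  pre-treatment expression → ESTIMATE stromal/immune scores by response
  group → two-class SAM (good vs poor at baseline, intermediate excluded)
  → over-representation of the up-in-poor genes → cell-type combined-score
  enrichment → optional signature-score survival validation.
* Longitudinal arm: paired SAM (post vs pre) separately within good and
  poor responders → IES and T-cell-inflamed-profile paired score tests →
  over-representation of the upregulated genes.

The arms are independent: the baseline arm never reads post-treatment
expression and the longitudinal arm never reads TRG.  Every stage's
parameters and warnings are collected into a machine-readable run report.
"""

from __future__ import annotations

import dataclasses
import json
import warnings as _warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .enrich import enrichment_z_scores, hypergeometric_ora
from .expr import read_counts_tsv, write_counts_tsv
from .genesets import read_gmt
from .preprocess import correct_batch_effects, detect_batch_effect, filter_genes, normalize
from .sam import sam_paired, sam_two_class, write_sam_tsv
from .scoring import estimate_scores, ies_panel, paired_score_test, tcell_inflamed_gep
from .survival import split_and_survive, write_split_tsv
from .tcd import classify_response, kruskal_wallis, tcd_from_table

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Paths, thresholds and stage toggles for a pipeline run."""

    counts: str
    meta: str
    tcd: str
    sets: str
    out_dir: str
    survival: str | None = None
    fdr_de: float = 0.05
    fdr_pathway: float = 0.2
    min_nonzero_frac: float = 0.75
    k_groups: int = 3
    min_prop: float = 0.1
    n_perm: int = 1000
    n_background: int = 100
    seed: int = 0
    run_estimate: bool = True
    run_celltype: bool = True
    run_survival: bool = True

    def validate(self) -> None:
        for name in ("fdr_de", "fdr_pathway", "min_nonzero_frac", "min_prop"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.k_groups < 2:
            raise ValueError("k_groups must be ≥ 2")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        cfg = cls(**data)
        cfg.validate()
        return cfg


class _Report:
    """Collects per-stage parameters, warnings and metrics."""

    def __init__(self, cfg: RunConfig, arm: str):
        self.doc = {
            "package": "radresponse",
            "version": __version__,
            "arm": arm,
            "seed": cfg.seed,
            "config": dataclasses.asdict(cfg),
            "stages": [],
        }

    def stage(self, name: str, params: dict):
        return _Stage(self, name, params)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.doc, indent=1, sort_keys=True,
                                   default=str) + "\n")


class _Stage:
    def __init__(self, report: _Report, name: str, params: dict):
        self.report = report
        self.entry = {"name": name, "params": params, "warnings": [],
                      "metrics": {}, "outputs": []}

    def __enter__(self):
        self._ctx = _warnings.catch_warnings(record=True)
        self._records = self._ctx.__enter__()
        _warnings.simplefilter("always")
        return self

    def __exit__(self, exc_type, exc, tb):
        self.entry["warnings"] = sorted({str(w.message) for w in self._records})
        self._ctx.__exit__(exc_type, exc, tb)
        if exc_type is None:
            self.report.doc["stages"].append(self.entry)
        return False

    def metric(self, name: str, value) -> None:
        self.entry["metrics"][name] = value

    def output(self, path: Path) -> None:
        self.entry["outputs"].append(Path(path).name)


# ---------------------------------------------------------------------------
# shared stages
# ---------------------------------------------------------------------------

def _require(cfg: RunConfig, *attrs: str) -> None:
    for a in attrs:
        p = getattr(cfg, a)
        if p is None or not Path(p).exists():
            raise FileNotFoundError(f"stage input {a!r} missing: {p}")


def _classify_stage(cfg: RunConfig, report: _Report) -> pd.DataFrame:
    with report.stage("classify_response", {"k": cfg.k_groups, "seed": cfg.seed}) as st:
        tcd = tcd_from_table(pd.read_csv(cfg.tcd, sep="\t"))
        calls = classify_response(tcd["delta_tcd"], k=cfg.k_groups, seed=cfg.seed)
        calls = calls.join(tcd[["baseline_tcd", "post_tcd"]])
        st.metric("group_sizes", calls["group"].value_counts().to_dict())
        st.metric("delta_tcd_range", [float(calls["delta_tcd"].min()),
                                      float(calls["delta_tcd"].max())])
    return calls


def _preprocess_stage(cfg: RunConfig, report: _Report, sample_filter=None):
    with report.stage("preprocess", {"min_nonzero_frac": cfg.min_nonzero_frac}) as st:
        raw = read_counts_tsv(cfg.counts, meta_path=cfg.meta)
        if sample_filter is not None:
            raw = raw.subset_samples(raw.sample_ids[sample_filter(raw.samples)])
        n_before = len(raw.endogenous)
        norm = normalize(raw)
        norm = filter_genes(norm, cfg.min_nonzero_frac, raw_counts=raw.values)
        st.metric("n_endogenous_before_filter", n_before)
        st.metric("n_genes_removed_by_filter", n_before - len(norm.endogenous))
        batch_present = False
        if "batch" in norm.samples.columns and norm.samples["batch"].nunique() > 1:
            rep = detect_batch_effect(norm, "batch")
            batch_present = rep.batch_present
            st.metric("batch_pc_pvalues", rep.per_component["pvalue"].round(6).to_dict())
        st.metric("batch_present", bool(batch_present))
        if batch_present:
            cov = norm.samples["group"] if "group" in norm.samples.columns else None
            norm = correct_batch_effects(norm, "batch", covariates=cov)
    return norm


def _attach_groups(matrix, calls: pd.DataFrame):
    groups = matrix.samples["patient"].map(calls["group"])
    matrix.samples["group"] = groups
    return matrix


# ---------------------------------------------------------------------------
# baseline arm
# ---------------------------------------------------------------------------

def run_baseline_arm(cfg: RunConfig) -> dict:
    """Good-vs-poor baseline contrast; returns the artifact bundle."""
    cfg.validate()
    _require(cfg, "tcd", "counts", "meta", "sets")
    out = Path(cfg.out_dir) / "baseline"
    out.mkdir(parents=True, exist_ok=True)
    report = _Report(cfg, "baseline")
    bundle: dict = {}

    calls = _classify_stage(cfg, report)
    calls.to_csv(out / "response_calls.tsv", sep="\t", float_format=_FLOAT_FMT)
    bundle["calls"] = calls

    # TRG association (clinical context of the classification)
    meta = pd.read_csv(cfg.meta, sep="\t", index_col=0)
    if "trg" in meta.columns:
        with report.stage("trg_association", {"test": "kruskal_wallis"}) as st:
            trg = meta.drop_duplicates("patient").set_index("patient")["trg"]
            common = calls.index.intersection(trg.index)
            if trg.loc[common].nunique() > 1:
                res = kruskal_wallis(calls.loc[common, "delta_tcd"].to_numpy(),
                                     trg.loc[common].to_numpy())
                st.metric("H", res.statistic)
                st.metric("pvalue", res.pvalue)

    # the baseline arm reads pre-treatment expression only
    norm = _preprocess_stage(cfg, report,
                             sample_filter=lambda s: s["timepoint"] == "pre")
    norm = _attach_groups(norm, calls)
    write_counts_tsv(norm, out / "normalized_pre.tsv")
    bundle["matrix"] = norm
    sets = read_gmt(cfg.sets)
    universe = list(norm.endogenous)

    if cfg.run_estimate:
        stromal = next((s for s in sets if "STROMAL" in s.name.upper()), None)
        immune = next((s for s in sets if "IMMUNE" in s.name.upper()), None)
        if stromal is not None and immune is not None:
            with report.stage("estimate", {"stromal_set": stromal.name,
                                           "immune_set": immune.name}) as st:
                est = estimate_scores(norm, stromal, immune)
                est["group"] = norm.samples["group"]
                est.to_csv(out / "estimate_scores.tsv", sep="\t",
                           float_format=_FLOAT_FMT)
                st.output(out / "estimate_scores.tsv")
                gp = est.dropna(subset=["group"]).groupby("group")
                st.metric("mean_estimate_by_group",
                          gp["estimate"].mean().round(6).to_dict())
            bundle["estimate"] = est

    with report.stage("sam_baseline", {"design": "two_class", "fdr": cfg.fdr_de,
                                       "n_perm": cfg.n_perm, "seed": cfg.seed}) as st:
        keep = norm.samples["group"].isin(["good", "poor"])
        sub = norm.subset_samples(norm.sample_ids[keep])
        res = sam_two_class(sub, sub.samples["group"], fdr_target=cfg.fdr_de,
                            n_perm=cfg.n_perm, seed=cfg.seed,
                            group_order=["good", "poor"])
        write_sam_tsv(res, out / "sam_baseline.tsv")
        st.output(out / "sam_baseline.tsv")
        up_in_poor = res.called_in_direction("up")
        st.metric("n_called", len(res.called_genes))
        st.metric("n_up_in_poor", len(up_in_poor))
        st.metric("s0", res.s0)
    bundle["sam"] = res
    bundle["up_in_poor"] = up_in_poor

    pathway_sets = [s for s in sets if s.name.upper().startswith("PATHWAY")] or sets
    if up_in_poor:
        with report.stage("ora_up_in_poor", {"fdr": cfg.fdr_pathway}) as st:
            ora = hypergeometric_ora(up_in_poor, pathway_sets, universe,
                                     fdr_threshold=cfg.fdr_pathway)
            ora.to_csv(out / "ora_up_in_poor.tsv", sep="\t", float_format=_FLOAT_FMT)
            st.output(out / "ora_up_in_poor.tsv")
            st.metric("n_significant", int(ora["significant"].sum()))
        bundle["ora"] = ora

        if cfg.run_celltype:
            cell_sets = [s for s in sets if s.name.upper().startswith("IES")]
            if cell_sets:
                with report.stage("celltype_enrichment",
                                  {"n_background": cfg.n_background,
                                   "seed": cfg.seed}) as st:
                    ct = enrichment_z_scores(up_in_poor, cell_sets, universe,
                                             n_background=cfg.n_background,
                                             seed=cfg.seed)
                    ct.to_csv(out / "celltype_enrichment.tsv", sep="\t",
                              float_format=_FLOAT_FMT)
                    st.output(out / "celltype_enrichment.tsv")
                bundle["celltype"] = ct

    if cfg.run_survival and cfg.survival and Path(cfg.survival).exists() and up_in_poor:
        with report.stage("survival_validation", {"min_prop": cfg.min_prop}) as st:
            surv = pd.read_csv(cfg.survival, sep="\t")
            split = split_and_survive(norm, up_in_poor, surv, min_prop=cfg.min_prop)
            write_split_tsv(split, out / "expressor_split.tsv")
            split.km_high.to_csv(out / "km_high.tsv", sep="\t", index=False,
                                 float_format=_FLOAT_FMT)
            split.km_low.to_csv(out / "km_low.tsv", sep="\t", index=False,
                                float_format=_FLOAT_FMT)
            st.metric("cutpoint", split.cutpoint)
            st.metric("logrank_chi2", split.logrank.statistic)
            st.metric("logrank_p_selection_biased", split.logrank.pvalue)
        bundle["split"] = split

    report.write(out / "report.json")
    bundle["report"] = report.doc
    return bundle


# ---------------------------------------------------------------------------
# longitudinal arm
# ---------------------------------------------------------------------------

def run_longitudinal_arm(cfg: RunConfig) -> dict:
    """Paired pre/post SAM within good and poor responders."""
    cfg.validate()
    _require(cfg, "tcd", "counts", "meta", "sets")
    out = Path(cfg.out_dir) / "longitudinal"
    out.mkdir(parents=True, exist_ok=True)
    report = _Report(cfg, "longitudinal")
    bundle: dict = {}

    calls = _classify_stage(cfg, report)
    norm = _preprocess_stage(cfg, report)
    norm = _attach_groups(norm, calls)
    sets = read_gmt(cfg.sets)
    universe = list(norm.endogenous)
    pathway_sets = [s for s in sets if s.name.upper().startswith("PATHWAY")] or sets
    ies_sets = [s for s in sets if s.name.upper().startswith("IES")]
    gep_set = next((s for s in sets if "GEP" in s.name.upper()), None)

    for grp in ("good", "poor"):
        patients = calls.index[calls["group"] == grp]
        pairs = []
        for p in patients:
            pre, post = f"{p}_pre", f"{p}_post"
            if pre in norm.sample_ids and post in norm.sample_ids:
                pairs.append((pre, post))
        if len(pairs) < 3:
            _warnings.warn(f"{grp}: fewer than 3 complete pairs, arm skipped")
            continue
        with report.stage(f"sam_paired_{grp}",
                          {"n_pairs": len(pairs), "fdr": cfg.fdr_de,
                           "n_perm": cfg.n_perm, "seed": cfg.seed}) as st:
            res = sam_paired(norm, pairs, fdr_target=cfg.fdr_de,
                             n_perm=cfg.n_perm, seed=cfg.seed)
            write_sam_tsv(res, out / f"sam_paired_{grp}.tsv")
            st.output(out / f"sam_paired_{grp}.tsv")
            up = res.called_in_direction("up")
            st.metric("n_called", len(res.called_genes))
            st.metric("n_upregulated", len(up))
        bundle[f"sam_{grp}"] = res
        bundle[f"up_{grp}"] = up

        if up:
            with report.stage(f"ora_up_{grp}", {"fdr": cfg.fdr_pathway}) as st:
                ora = hypergeometric_ora(up, pathway_sets, universe,
                                         fdr_threshold=cfg.fdr_pathway)
                ora.to_csv(out / f"ora_up_{grp}.tsv", sep="\t",
                           float_format=_FLOAT_FMT)
                st.output(out / f"ora_up_{grp}.tsv")
                st.metric("n_significant", int(ora["significant"].sum()))
            bundle[f"ora_{grp}"] = ora

        # paired signature-score changes
        score_rows = []
        if ies_sets:
            scores = ies_panel(norm, ies_sets)
            for name in scores.columns:
                test = paired_score_test(scores[name], scores[name], pairs)
                score_rows.append({"signature": name, "method": "ssgsea", **test})
        if gep_set is not None:
            gep = tcell_inflamed_gep(norm, gep_set)
            test = paired_score_test(gep, gep, pairs)
            score_rows.append({"signature": gep_set.name, "method": "mean_log2", **test})
        if score_rows:
            with report.stage(f"signature_changes_{grp}", {"n_pairs": len(pairs)}) as st:
                tab = pd.DataFrame(score_rows).set_index("signature")
                tab.to_csv(out / f"signature_changes_{grp}.tsv", sep="\t",
                           float_format=_FLOAT_FMT)
                st.output(out / f"signature_changes_{grp}.tsv")
            bundle[f"signature_changes_{grp}"] = tab

    report.write(out / "report.json")
    bundle["report"] = report.doc
    return bundle


def run_all(cfg: RunConfig) -> dict:
    return {"baseline": run_baseline_arm(cfg),
            "longitudinal": run_longitudinal_arm(cfg)}


# ---------------------------------------------------------------------------
# report validation
# ---------------------------------------------------------------------------

def load_report_schema() -> dict:
    path = resources.files("radresponse").joinpath("data", "report_schema.json")
    return json.loads(path.read_text())


def validate_report(report: dict, schema: dict | None = None) -> None:
    """Validate a run report against the shipped schema (minimal checker:
    required keys and primitive types)."""
    schema = schema or load_report_schema()

    def check(obj, spec, where):
        for key, kind in spec.get("required", {}).items():
            if key not in obj:
                raise ValueError(f"report{where}: missing required key {key!r}")
            if kind == "string" and not isinstance(obj[key], str):
                raise ValueError(f"report{where}.{key}: expected string")
            if kind == "number" and not isinstance(obj[key], (int, float)):
                raise ValueError(f"report{where}.{key}: expected number")
            if kind == "object" and not isinstance(obj[key], dict):
                raise ValueError(f"report{where}.{key}: expected object")
            if kind == "array" and not isinstance(obj[key], list):
                raise ValueError(f"report{where}.{key}: expected array")

    check(report, schema, "")
    for i, stage in enumerate(report.get("stages", [])):
        check(stage, schema.get("stage", {}), f".stages[{i}]")
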
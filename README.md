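# radresponse

Quantifying rectal-cancer response to neoadjuvant radiotherapy/chemoradiation
and relating it to the tumor immune microenvironment.

Clinical tumor-regression grading (TRG) compresses a wide range of
radiotherapy responses into a few subjective categories. This package
implements an analysis stack built around an objective alternative, **tumor
cell density (TCD)**: the percentage of tumor cells among ~300 systematically
sampled points on an H&E section (assessments with fewer than 250 points are
rejected as inaccurate). The change between paired specimens,

> ΔTCD = TCD(post-treatment resection) − TCD(baseline biopsy),

is negative when tumor cells are lost, i.e. when the tumor responded.
Patients are stratified into **good / intermediate / poor responders** by
univariate k-means on ΔTCD, and the downstream immune gene-expression
analysis asks two questions:

1. **Baseline**: which genes are already different in poor vs good responders
   before treatment?
2. **Longitudinal**: which genes change from the pre-treatment biopsy to the
   post-treatment resection, separately in good and poor responders?

## What's inside

| module | contents |
| --- | --- |
| `radresponse.simulate` | synthetic paired cohort generator with planted ΔTCD shifts, negative-binomial panel counts (housekeeping genes, positive-control titration, negative-control background), planted baseline/longitudinal differential expression, batch shifts, score-dependent survival — plus the ground truth |
| `radresponse.tcd` | TCD / ΔTCD, `ResponseKMeans` (univariate k-means with response-ordered labels and an exact contiguous-partition guarantee), Kruskal-Wallis, Fisher exact (2×c by enumeration), clinical covariate tests |
| `radresponse.preprocess` | `PanelNormalizer` (positive-control scaling → negative-control background floor → housekeeping content scaling → log2), 75%-detection gene filter, PCA batch screen, parametric empirical-Bayes (ComBat-style) `BatchCorrector` |
| `radresponse.sam` | Significance Analysis of Microarrays: moderated d = (x̄₂ − x̄₁)/(s + s₀) with the Tusher s₀ search, permutation-estimated FDR and q-values; two-class, paired (sign-flip null) and multiclass designs, exhaustive enumeration when the design admits ≤ 10 000 permutations |
| `radresponse.scoring` | ssGSEA running-sum enrichment scores (weights rankᵅ, α = 0.25), ESTIMATE stromal/immune scores with the published purity transform cos(0.6049872018 + 0.0001467884·E), T-cell-inflamed expression profile mean, immune-enrichment-signature panel, paired Wilcoxon score tests |
| `radresponse.enrich` | hypergeometric over-representation P[X ≥ k] with BH FDR on a measured-panel universe, Enrichr-style combined score c = ln(p)·z with resampled backgrounds, pathway-gene networks, cross-cohort pathway overlap |
| `radresponse.survival` | signature-mean scoring, maximally selected rank statistics (standardized log-rank statistic maximized over admissible cutpoints), Kaplan-Meier estimation, log-rank test |
| `radresponse.pipeline` / `radresponse.cli` | the two analysis arms end to end, with run reports; `radresponse` console script |

Transform-shaped components are scikit-learn-style estimators
(`fit`/`transform`/`predict`, fitted attributes with trailing underscores)
and compose with sklearn tooling; hypothesis-test-shaped components are
functions returning result objects, statsmodels-style.

## Worked example

```python
import pandas as pd
import radresponse as rr

cohort = rr.simulate_cohort(rr.CohortConfig(seed=1))   # 53 patients, paired pre/post

delta = pd.Series((cohort.tcd["post_tcd"] - cohort.tcd["baseline_tcd"]).to_numpy(),
                  index=cohort.tcd["patient"])
calls = rr.classify_response(delta, k=3, seed=0)

norm = rr.normalize(cohort.counts)
norm = rr.filter_genes(norm, 0.75, raw_counts=cohort.counts.values)
norm.samples["group"] = norm.samples["patient"].map(calls["group"])
if rr.detect_batch_effect(norm, "batch").batch_present:
    norm = rr.correct_batch_effects(norm, "batch", covariates=norm.samples["group"])

pre = norm.subset_samples(norm.sample_ids[norm.samples["timepoint"] == "pre"])
contrast = pre.subset_samples(pre.sample_ids[pre.samples["group"].isin(["good", "poor"])])
res = rr.sam_two_class(contrast, contrast.samples["group"], fdr_target=0.05,
                       n_perm=1000, seed=0, group_order=["good", "poor"])
up_in_poor = res.called_in_direction("up")

split = rr.split_and_survive(pre, up_in_poor, cohort.survival, min_prop=0.1)
```

Output:

```
response groups: {'good': 23, 'intermediate': 18, 'poor': 12}
delta-TCD range: -31.4 to 3.8
batch effect detected: True
genes up in poor responders at q<=0.05: 39
top pathway: PATHWAY_POOR_BASELINE fdr=5.09e-36
maxstat cutpoint 7.99 -> 11 high (poor-like) vs 42 low (good-like)
log-rank chi2=21.8, p=3.01e-06 (selection-biased)
```

Reading this: k-means recovers the three planted response groups (23/16/14
planted; two boundary patients from the poor group land in the intermediate
cluster). The
two-class SAM contrast on baseline biopsies calls 39 genes up in poor
responders at q ≤ 0.05 — 39 of the 40 planted ones — and over-representation
analysis pins the pathway that was seeded with those genes. The mean
expression of the called genes then splits an independent survival table at
the maxstat-optimal cutpoint into poor-like high expressors with worse
survival; the log-rank p is flagged selection-biased because the cutpoint
maximizing the statistic was chosen from the data.

The same analysis is available from the shell:

```bash
radresponse simulate --out data --seed 1
radresponse classify-response --tcd data/tcd.tsv --out calls.tsv
radresponse run --config run.yaml all
```

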
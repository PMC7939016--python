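# Methods

This note documents the statistical models behind `radresponse`, the
parameters that matter, what the synthetic cohort does and does not emulate,
and the numerical choices made where the design was genuinely open.

## Tumor cell density and response classification

TCD is 100 · (tumor points)/(total points) from a systematic point grid on
an H&E section. Assessments below **250 total points** are rejected
(point-count modelling places the accuracy floor there); counts outside the
customary **300 ± 15** window only warn, since nothing justifies a hard error
above the floor. ΔTCD = post − baseline, so negative values mean response.

Response groups come from univariate k-means on ΔTCD with k = 3, pooled
across radiotherapy regimens, labels ordered by ascending cluster mean
(good < intermediate < poor). The optimal univariate k-means partition is
contiguous in the sorted values; the estimator runs Lloyd iterations from a
deterministic quantile seeding plus k-means++ restarts and then refines the
result with an exact O(k·n²) dynamic program over contiguous partitions, so
the returned partition is globally optimal and the contiguity invariant is
guaranteed rather than merely asserted. The test oracle is a separate
exhaustive enumeration of all contiguous 3-partitions. `k ≠ 3` is allowed
with generic labels.

Association tests: Kruskal-Wallis (tie-corrected H, chi-square p on g − 1
degrees of freedom — no exact small-sample permutation p, matching common
practice), Fisher exact for categorical covariates (2×c tables by exhaustive
enumeration of tables with fixed margins; probabilities ≤ the observed
table's are summed with a 1e-9 relative tolerance against float ties), and
Welch t tests for continuous covariates with two groups.

## Panel preprocessing

Reporter-count panels carry three kinds of calibration probes, used in this
order (each step can be switched off):

1. **Positive-control scaling** — factor = geometric mean over samples of the
   positive-control sums / the sample's sum; applied to all genes.
2. **Background flooring** — per sample threshold = mean + 2·sd of the
   negative controls (after step 1); endogenous and housekeeping values below
   it are floored to it.
3. **Housekeeping content scaling** — factor = geometric mean over samples of
   the per-sample housekeeping geometric means / the sample's value; applied
   to endogenous + housekeeping genes only. Zero counts enter the geometric
   mean at a 0.5-count detection limit.
4. **log2(x + 1)** — the +1 offset maps zero counts to 0.

Restricting the housekeeping factor to non-control genes makes the scaling
exactly idempotent: re-deriving both factors from the normalizer's own
linear-scale output returns 1. Factors outside [0.1, 10] raise a
lane-quality warning. Scaling references are learned by `fit` and can be
applied to new samples.

The detection filter keeps endogenous genes with nonzero **raw** counts in
≥ 75% of samples (boundary inclusive — "75% or more"); filtering is a
detection decision, so it is made on raw counts even when applied to a
normalized matrix, and control/housekeeping probes are never filtered.

**Batch screening** is a principal-component association test: genes are
centered, the top 5 component scores are tested against batch with
Kruskal-Wallis, and a batch effect is declared if any p < 0.01. This is a
deliberately simple screen — its only job here is to gate the correction.

**Batch correction** is the standard parametric empirical-Bayes
location/scale model: per gene, a least-squares fit of grand mean +
covariate (response-group) effects + batch offsets constrained to a
size-weighted zero sum; standardization by the pooled residual sd; per-batch
location (normal prior) and scale (inverse-gamma prior, moment-matched
a = (2s² + m²)/s², b = (ms² + m³)/s²) estimates shrunk by the usual
fixed-point iteration (tolerance 1e-6, ≤100 iterations); back-transformation.
After adjustment each gene's grand mean is restored exactly by a constant
shift — this leaves all within- and between-batch structure of the
adjustment untouched and makes the grand-mean invariant exact rather than
approximate. Designs with a batch of one sample, or batch 1:1 confounded
with the covariate, are rejected; a constant batch column returns the input
unchanged.

## SAM

For gene *i* the two-class statistic is d_i = (x̄₂ − x̄₁)/(s_i + s₀) with
s_i the pooled two-sample standard error; the paired statistic replaces the
numerator by the mean paired difference and s_i by its standard error; the
multiclass statistic is r_i = sqrt((Σn/Πn)·Σ_k n_k (x̄_ik − x̄_i)²) /
(s_i + s₀) with the pooled within-class sd — a form chosen because it
reduces *exactly* to |d_i| when there are two classes. 0/0 (a constant gene
under s₀ = 0) is defined as 0.

**s₀ (fudge factor)**: candidates are the percentiles {0, 5, …, 100} of the
s_i; for each, the coefficient of variation of MAD(d) across 100 s-quantile
windows is computed and the smallest CV wins. A constant s short-circuits to
the 5th-percentile candidate (= the constant).

**Null distribution**: label permutations (two-class), pair sign flips
(paired), label shuffles (multiclass); enumerated exhaustively whenever the
design admits ≤ 10 000 distinct permutations (cheap at this cohort's arm
sizes), otherwise sampled *without replacement* (n_perm default 1000,
< 25 warns). s₀ is held fixed across permutations.

**Calling and q-values**: genes are ordered by d; d̄_(i) is the mean of the
per-permutation order statistics. For a threshold Δ the upper cutoff is the
observed d at the first index (with d̄ > 0) where d_(i) − d̄_(i) ≥ Δ, the
lower cutoff symmetric; all genes beyond the cutoffs are called. The
estimated FDR at Δ is median(permutation statistics beyond the cutoffs) /
(observed calls), capped at 1 — the median-false-call convention, with no
π₀ multiplier (the plain ratio is the definition used throughout; this is
conservative relative to a π₀-corrected variant). A gene's q-value is the
minimum FDR over all Δ at which it is called; nested call sets make q
monotone in |d| within a direction. The Δ grid is the set of observed
crossing gaps, capped at 256 quantile-spaced points. For the bookkeeping the
statistics are rounded at 1e-10 so results are exactly invariant to sample
order and other float-reassociation effects. Order-statistic ties break by
stable sort on (d, gene position). Missing values are rejected upstream —
panel data is complete.

## Single-sample scores

**ssGSEA**: per sample, genes are ranked by expression (ascending ranks,
ties averaged; traversal in descending order, stable on ties); the
enrichment score is Σ_positions (weighted in-set ECDF − unweighted
out-of-set ECDF) with in-set weights rankᵅ, α = 0.25 by default
(configurable, e.g. 0.75). Scores are rank-based, hence invariant to
monotone transforms. With `normalize_es` the per-signature scores are
divided by the cross-sample score range. A set covering the whole universe
has an empty complement and is rejected; absent members are dropped with a
warning.

**ESTIMATE**: stromal and immune scores are raw (unnormalized) ssGSEA
scores; ESTIMATE = stromal + immune by definition, and purity =
cos(0.6049872018 + 0.0001467884 · ESTIMATE) clipped to [0, 1]. Those
constants were calibrated on genome-wide arrays; applying the transform to a
targeted immune panel is out of calibration, so the output carries an
explicit flag and warning while still being computed for comparability.

**T-cell-inflamed profile**: unweighted mean of normalized log2 expression
over the available profile genes (the published per-gene weights are not
reproduced here; a weights mapping is accepted for the weighted variant).
At least 50% of the profile must be present; missing members are named in a
warning — on this panel 16 of the 18 genes is the expected situation.

**Paired score changes** use the Wilcoxon signed-rank test (exact null up to
25 pairs, normal approximation beyond; all-zero differences return p = 1).
A paired t test would also be defensible; the rank test was chosen because
enrichment-score scales are not interval-calibrated.

## Over-representation and combined scores

ORA: p = P[X ≥ k] for X ~ Hypergeometric(N, K, n), with the universe being
the **panel genes surviving the detection filter** — not the genome —
because enrichment must be conditioned on what was measurable. BH adjustment
across the tested sets; pathway significance defaults to FDR < 0.2 and
gene-level thresholds to 0.05 (both configurable). The combined score is
c = ln(p) · z where z is the set's rank-deviation z-score over a seeded
background of random same-size queries (the precomputed service backgrounds
are not reproducible, so they are re-derived by resampling); an enriched set
ranks better than in the background, giving z < 0 and c > 0. p = 0 is
rejected (work in log space upstream instead).

## Survival validation

The signature score of a sample is the unweighted mean normalized expression
of the signature genes (here: the genes up in poor responders at baseline).
The cutpoint is chosen by **maximally selected rank statistics**: every
observed score value whose split keeps both groups at ≥ min_prop = 0.1 of
the cohort (the method's customary constraint; the source analysis names the
method but no constraint) is a candidate; at each, the standardized log-rank
statistic (O − E)/√V of high (> cut, "poor-like") vs low ("good-like") is
computed, and the largest |statistic| wins (ties → smallest cutpoint;
membership at the cutpoint is strictly-greater). KM curves use the
product-limit estimator (via lifelines) and the log-rank test uses the
observed-minus-expected sum with hypergeometric variance over distinct event
times (own vectorized implementation — the maxstat scan needs it fast —
cross-checked against lifelines in the tests).

The log-rank p at the selected cutpoint is reported with a
`selection_biased` flag: maximizing over cutpoints inflates type-I error
well above nominal (the acceptance study measures ~38% rejection at nominal
5% under a score-independent hazard), and no corrected p-approximation is
computed.

## Synthetic cohort

The generator emulates the statistical structure the analysis assumes, with
defaults mirroring the target study design:

| parameter | default | meaning |
| --- | --- | --- |
| patients | 53, groups 23/16/14 | paired pre/post samples (106) |
| ΔTCD shifts | −25 / −10 / 0 % | good / intermediate / poor |
| TCD baseline | mean 55%, sd 10% | plausible biopsy tumor content |
| TCD noise | sd 3% | measurement + biological noise on the shift |
| panel | 706 endogenous + 40 housekeeping + 6 pos + 8 neg = 760 probes | positive controls on a fixed 4-fold titration ladder; negative controls at Poisson background mean 2 |
| counts | negative binomial, dispersion 0.1, gene means 2^N(6, 1.5) (housekeeping 2^N(9, 0.7)) | overdispersed panel counts; library-size factors 2^N(0, 0.15) |
| baseline DE | 40 genes, +2 log2FC in poor patients | tumor-intrinsic, present at both timepoints |
| longitudinal DE | 198 genes, +1 log2FC in post samples of good responders | treatment-induced |
| batch | 2 batches, +1 log2 location shift, patients alternated so groups are balanced across batches | both samples of a patient share a batch |
| survival | exponential, hazard h₀·HR^z with HR 2.0 per unit z-scored signature score, h₀ = 0.05; independent Uniform(0, c_max) censoring with c_max solved by bisection to hit the 20% censoring target | validation-cohort structure |

Ground truth (group membership, planted gene lists, batch shifts, the true
score cutpoint) is recorded alongside. Gene sets are generated with known
enrichment structure: decoy pathways from unplanted genes, one pathway
seeded with the baseline-planted genes, one with the longitudinal ones, plus
IES-like, stromal/immune and profile sets. Every stream of randomness
derives deterministically from the configuration seed.

What the generator does **not** emulate: spatial structure of H&E sections,
probe-level artifacts (cross-hybridization, saturation), correlated gene
modules (genes are independent given their class effects), gene-specific
batch sensitivity (the location shift is uniform across endogenous genes),
dropout patterns of degraded FFPE material, and informative censoring.
Passing tests therefore demonstrate correctness of the algorithms and their
calibration under a realistic-but-idealized data model, not robustness to
every artifact of real panel data.

## Problem sizes and numerical choices

The acceptance study uses 50 cohorts for classification recovery, 20
replicates for SAM calibration (760 genes, 21 vs 12 samples, 1000
permutations) and batch correction, 1000 null replicates for log-rank
type-I calibration, and 100 replicates each for maxstat recovery and its
null selection bias — sizes chosen to make Monte-Carlo error small relative
to the tested margins while the whole study runs in well under a minute.
Degenerate inputs fail loudly throughout (all-equal ΔTCD, single batch for
detection, zero-variance genes in batch correction, empty queries, zero
log-rank variance, all-equal scores). Output tables are written with a
fixed `%.10g` float format so repeated runs are byte-identical.

## Known limitations

- The SAM FDR uses the median-false-call ratio without a π₀ estimate; with
  many true positives it is conservative.
- The batch screen is a PC-association heuristic, not a guided-PCA method;
  it only gates the correction.
- The ESTIMATE purity values on a targeted panel are indicative, not
  calibrated fractions.
- The maxstat split reports the naive log-rank p (flagged); studies needing
  an honest selection-adjusted p should use the corrected approximations
  from the maxstat literature.
- Fisher exact enumeration is exponential in the table's column count; it is
  intended for the small contingency tables of cohort descriptors.
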
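# Methods

## The problem

A prognostic gene-expression signature is usually trained on one tissue
sample per patient, but a tumor is not spatially homogeneous: different
regions of the same tumor can yield different expression profiles, and a
signature whose genes vary strongly within a tumor will assign the same
patient to different risk groups depending on which region was biopsied.
This package quantifies that failure mode and builds signatures that
avoid it, using multiregion expression cohorts (several sampled regions
per patient, e.g. multiregion esophageal squamous cell carcinoma
microarray data) as the measuring instrument.

## Heterogeneity scores

For gene *g*, with patients *p* and tumor regions *r*:

* **Intratumor score**: the dispersion of `x[g, p, ·]` across the
  regions of patient *p*, averaged over all patients with at least two
  tumor regions. Dispersion is the sample SD (ddof = 1) by default; MAD
  (scaled by 1.4826, so it estimates the SD under normality) and
  CV = SD/mean are available for sensitivity analysis. Pooling all
  regions of all patients would mix between-patient variation into the
  within-tumor estimate, so aggregation is always per-patient first —
  this is the one reading consistent with the quadrant logic below.
* **Intertumor score**: draw one tumor region uniformly at random per
  patient, take the dispersion of the selected values across patients,
  and average over `n_reps = 10` independent draws (patients with a
  single region contribute it deterministically). Under the two-level
  Gaussian model below the expectation of this estimator is
  `c4(n)·sqrt(tau² + sigma²)` — it deliberately measures what a
  single-biopsy study would see between patients, which *includes* the
  region-sampling noise.

**Quadrants.** Cutting the (inter, intra) plane at the arithmetic means
of the two axes partitions genes into Q1 (low inter / high intra), Q2
(low/low), Q3 (high/high) and Q4 (high inter / low intra). `>=` the
mean counts as "high" on both axes, a deterministic tie-break that only
matters on measure-zero boundaries. Q4 genes are stable within a tumor
but discriminative between tumors — the candidate pool for
sampling-robust signatures. Before scoring, genes with zero variance
across tumor samples are dropped ("expressed-gene" filter); an optional
mean-expression quantile filter exists but is off by default.

**CV guard.** Log-scale expression can average to ~0; genes whose
relevant mean is within 1e-8 of zero get CV = NaN and are excluded from
CV-based analyses.

## Data handling choices

Expression is assumed already log-transformed; a `log1p` flag applies
log2(x+1) on load for linear-scale inputs (TPM), and the choice is
recorded in the run manifest. Delimiters follow the file extension
(`.tsv` tab, `.csv` comma) — never sniffed, for determinism. Gene ids
are opaque strings; when a platform delivers probe-level rows, the
`collapse-probes` utility maps probes to genes with a two-column
annotation file and keeps, per gene, the probe with the highest mean
expression — the common convention, stated here because it is a choice,
not a given. Heterogeneity scores and the quadrant universe are
computed on tumor samples only; normal-tissue regions are excluded
before scoring (`subset_tumor`).

## Sampling-bias audit

A signature scores a sample as Σᵢ coefficientᵢ × expressionᵢ. Regions
are classified high/low risk at the cohort-median score over all tumor
region samples (ties are classed low; with an even sample count the
median then splits the cohort exactly in half). A patient whose regions
all fall on one side is *concordant* (low or high); a mixture is
*discordant*. A signature exhibits substantial sampling bias on a
cohort when more than 50% of patients are discordant. Signature genes
missing from a matrix are dropped (not zero-imputed, which would shift
scores on log-scale data) and reported.

Two dispersion statistics complete the audit: the per-patient SD of
region scores (how much the score depends on the sampled region) and the
cohort-wide score variance (how much the score separates samples at
all). A good signature minimizes the former while keeping the latter
high.

## Synthetic cohorts

The generator draws `x[g,p,r] = mu_g + b[g,p] + e[g,p,r]` with
`b ~ N(0, tau_g²)` (patient level) and `e ~ N(0, sigma_g²)` (region
level), in archetype blocks mirroring the four quadrants. Survival is a
patient attribute: an exponential proportional-hazards outcome with
linear predictor Σ βⱼ(μⱼ + b[j,p]) over a planted subset of Q4-like
genes — region noise never enters the hazard. The linear predictor is
centred by its deterministic part Σβμ before exponentiation, so
`baseline_hazard` keeps its events/day meaning for any μ and β; this is
a pure reparameterization of the baseline. Censoring is an independent
exponential time whose rate is solved numerically (Brent) so that the
expected censored fraction `mean_p c/(c + h_p)` matches `censor_rate`.

Defaults describe the canonical study design used throughout the tests:
100 patients × 3 regions, four archetypes of 250 genes with variance
levels 1.0 (high) / 0.2 (low) around a mean of 6 log2 units, ten planted
prognostic genes with log-hazard slope 0.5 per log2 unit, baseline
hazard 5e-4/day (median survival ≈ 3.8 years, typical of an
intermediate-prognosis carcinoma cohort) and 30% censoring. One global
seed drives fixed-offset sub-streams for expression, survival and
censoring, so changing the censoring target never perturbs the
expression draws.

What the generator does *not* emulate: count noise and library-size
effects, batch effects, copy-number-driven expression, platform
differences, or spatial correlation between neighbouring regions.
Passing recovery tests therefore shows the estimators do what they claim
under the stated two-level Gaussian model, not that any particular real
cohort satisfies that model.

**A structural limit worth knowing.** Because the intertumor estimator
absorbs region noise (expectation `sqrt(tau² + sigma²)`), genes with
`sigma ≈ tau_high` and low `tau` (Q1-like) are indistinguishable from
Q4-like genes on the inter axis: at archetype levels tau 1.0/0.2 and
sigma 1.0/0.2 both have expected inter score 1.02, and no mean-threshold
cut can separate them, so near-perfect archetype recovery requires
`sigma_high` meaningfully below `tau_high` (the recovery tests use tau
2.0/0.1, sigma 0.8/0.1). This is a property of the single-random-region
method itself, not of the implementation; on real data it means the Q1
and Q4 pools of a quadrant chart are separated only to the extent that
within-tumor noise is smaller than between-tumor spread.

## Gene selection and the learner benchmark

1. **Univariate Cox screen**: one single-covariate proportional-hazards
   fit per gene (Newton–Raphson on the partial likelihood, Efron ties),
   Wald p < 0.05, no multiplicity correction — the screen is a filter.
   The fitter is batched and vectorized across genes so a genome-wide
   screen runs per CV fold; it is validated against lifelines and a
   direct partial-likelihood maximization. Non-convergent genes
   (constant expression, monotone likelihood) are flagged and excluded.
2. **LASSO refinement**: L1-penalized Cox (scikit-survival Coxnet) over
   a 100-point penalty path, genes standardized per cohort; the penalty
   maximizes the mean 5-fold cross-validated Harrell C-index, with
   penalties within one standard error of the best treated as tied and
   the tie going to the strongest penalty (the sparsest model). The CV
   curve is typically flat near its optimum, and the plain argmax rides
   that noise into dense models; `se_rule=False` restores it.
3. **Benchmark**: each learner is scored by the unweighted mean of its
   internal 5-fold CV C-index on the training cohort and its C-index on
   each external validation cohort (train-fitted model applied directly,
   no refitting). Ties break toward fewer selected genes, then name.
   Fold assignment depends only on (k, seed, a CRC32 hash of the patient
   order). Implemented learners: stepwise Cox by AIC (forward /
   backward / both), ridge Cox, elastic net (mixing grid 0.1–0.9),
   LASSO, random survival forest (1000 trees) and gradient-boosted Cox
   (10 000 trees, depth 3, learning rate 0.001, min 10 per leaf).
   CoxBoost, plsRcox, SuperPC and survival-SVM are registry entries
   marked unavailable; asking for them fails loudly with the available
   set, so benchmark coverage is always explicit.

Expression is standardized per cohort (gene-wise mean 0 / SD 1) before
any fit, and exported coefficients live on that standardized scale —
the per-cohort transform makes scores comparable across platforms.
Genes absent from a scoring cohort contribute 0 after standardization,
the non-linear-model equivalent of dropping the term. Multiregion
training cohorts are reduced to one value per patient by region
averaging before any survival fit, since survival is a patient
attribute.

## Evaluation utilities

* **Harrell's C-index**, hand-implemented to pin the conventions: a pair
  is comparable when the shorter time has an observed event and times
  differ, or times are tied with exactly one event; tied scores count
  0.5. Exact agreement with an O(n²) enumeration oracle and with
  lifelines is asserted in tests.
* **Kaplan–Meier + two-group log-rank** via lifelines (hypergeometric
  variance, χ²₁ p-value). A group with zero events is a warning, not an
  error.
* **Multivariate Cox** via lifelines (Efron ties) with a rank check that
  names collinear columns before fitting, and a warning below ~10 events
  per covariate.
* **Time-dependent AUC**: IPCW cumulative-case / dynamic-control
  estimator with Kaplan–Meier censoring weights (scikit-survival);
  evaluation times with no case, no control, or beyond follow-up are
  reported missing. This is the single supported flavour.
* **Hazard-ratio pooling**: fixed-effect inverse-variance, Cochran's Q,
  I² = max(0, (Q − df)/Q), heterogeneity p from χ²_df. Fixed-effect is
  the default because the intended use is a handful of cohorts analysed
  with a shared protocol; a random-effects variant was deliberately left
  out of scope.

## Problem sizes in the test suite

The recovery experiments run at desk scale, chosen as the smallest sizes
at which the quantities stabilize: 100–500 patients for variance
components, 2000 genes for type-I calibration, 500 candidate genes /
400 patients for LASSO recovery, and 300 + 2×150 patients for the
learner benchmark (with 10 planted genes among 100 candidates). The
bias-monotonicity and quadrant-contrast experiments pair 10–20 seeds at
200 patients × 3 regions.
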
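# Methods

## The problem

Metabolomics association studies test hundreds to thousands of correlated
metabolite measurements against a clinical outcome. Because metabolites
travel in correlated packs (shared pathways, shared chemistry), a metabolite
with no direct (conditional) effect on the outcome can carry a strong
marginal association purely through its correlation with a truly associated
metabolite. Univariate testing with multiplicity correction treats each
metabolite in isolation and therefore selects these correlated bystanders —
and does so *more* aggressively as the sample size grows, because power to
detect small marginal effects increases. Multivariate sparse methods model
all metabolites jointly and largely avoid this failure mode.

`metabobench` makes that phenomenon measurable: it simulates studies with a
known ("planted") set of directly associated metabolites, runs six standard
analysis procedures, and scores each against the planted truth.

## Simulated data model

Metabolite levels for one study are drawn `X ~ MVN(0, Σ)` on the
standardized (post log-transform) scale; `Σ` is a correlation matrix built
as block compound symmetry plus light Gaussian jitter:

* `M` metabolites are split into `n_clusters` near-equal clusters
  (default 10). Within-cluster correlation defaults to 0.7; the
  between-cluster value is solved in closed form so the overall mean
  off-diagonal correlation equals the target (default +0.40).
  With `M = 200` this gives a between-cluster correlation of ≈ 0.37.
* Zero-mean symmetric Gaussian jitter (entry SD default 0.005) makes
  pairwise correlations scatter rather than take exactly two values; the
  matrix is then projected to the PSD cone (eigenvalue clipping, unit
  diagonal restored). The jitter default is deliberately small: the
  perturbation's spectral radius grows like `2·sd·√M`, and once it exceeds
  the base matrix's smallest eigenvalue (0.3 under the defaults) the
  clipping repair visibly biases the mean correlation downward. Most of
  the observed spread of pairwise correlations (SD ≈ 0.10) comes from the
  two-level block structure, not the jitter.
* Options: a fraction of cluster pairs with sign-flipped (negative)
  between-cluster correlation, and one planted highly intercorrelated pair
  per cluster, for secondary designs with negative and near-duplicate
  correlations.
* The jitter (and any random block choice) is driven by a dedicated
  `corr_seed`, so the correlation structure is a **fixed attribute of a
  scenario**: all replicates share the same `Σ`.

Ten "true positive" metabolites (configurable) are placed round-robin
across clusters (seeded), so correlation-induced false positives can be
attributed per cluster; a `same_cluster` option concentrates them instead.

**Effect sizes.** The default effect vector is a geometric grid of
magnitudes from 0.05 to 0.5 outcome-SD per metabolite-SD with **alternating
signs**. The signs matter: with an everywhere-positive correlation
structure and all-positive effects, the linear predictor `Xβ` is nearly
proportional to the common metabolite factor, every null metabolite has a
marginal effect of roughly `ρ̄·Σβ ≈ 0.8` SD, and univariate methods select
essentially all of `M` already at `N = 200` — the false-positive count
saturates and cannot grow with `N`. With mixed signs the common-factor
contributions largely cancel, marginal null associations stay cluster-local
(≈ `(ρ_w − ρ_b)·β` for cluster-mates of a truth), and the benchmark's
central phenomenon — univariate false positives growing with sample size —
appears exactly as expected.

**Outcomes.** Continuous: `y = Xβ + ε`, `ε ~ N(0, noise_sd²)` with
`noise_sd = 1` by default, so effects are interpretable in SD units and the
population R² is `β'Σβ / (β'Σβ + 1)`. Binary: logistic model on `Xβ` with
the intercept calibrated by monotone root-finding (Brent, tolerance
1e-13) so the expected prevalence equals the configured value; a
`case_control` option subsamples to an exact 1:1 ratio. The default
scenario grid uses 20% prevalence at `N = 200` and 50% at
`N = 1000 / 5000`, for both `M = 200` and `M = 2000`, plus small-sample
variants at `N = 50, 100`.

**Cohort-style raw tables.** A separate generator emulates a population
cohort's feature table: log-intensities are a correlated Gaussian field
plus covariate effects (age per-SD shift, sex class shift, random per-batch
shifts), exponentiated so raw intensities are strictly positive and
right-skewed, with no missing values. It exists so the preprocessing and
cohort-analysis stages can be tested end to end on data with known planted
covariate associations.

What the generator does **not** emulate: missingness and
limit-of-detection censoring, raw LC-MS signal (retention time, adducts,
isotopes), heavy-tailed or nonlinear metabolite-outcome relationships, and
real biological pathway topology. Passing tests therefore demonstrate
correctness of the procedures and the claimed operating-characteristic
patterns under this generative model, not performance on any particular
real cohort.

## The six procedures

All methods consume a standardized `N × M` matrix and return nonnegative
per-metabolite importance scores; selection-capable methods also return a
selected set.

1. **Univariate scan + Bonferroni / BH-FDR.** Per-metabolite simple
   regression (OLS Wald for continuous outcomes, vectorized via the
   partialled-out closed form; per-metabolite logistic ML Wald for binary,
   with a linear-probability option). Degenerate fits (constant column,
   perfect separation, unstable logistic SE) conservatively get p = 1.
   Bonferroni selects `p ≤ α/M` (α = 0.05); BH applies the step-up rule at
   q = 0.1 (via `statsmodels.multipletests`). The Bonferroni set is a
   subset of the BH set at the same level, always.
2. **PCR.** Principal components of `X`; outcome regressed on the leading
   `K` scores; importance reallocated to metabolites as `|V γ|` (loadings
   times component coefficients). With all components this equals the
   |OLS| coefficients exactly. Ranking only — no principled selection.
3. **LASSO.** `(1/2N)‖y − Xβ‖² + λ‖β‖₁` (scikit-learn coordinate descent;
   penalized logistic likelihood for binary). λ chosen by K-fold CV on a
   log-spaced grid from `λ_max = max|X'y|/N` down 4 decades (100 points by
   default). Adjustment covariates are unpenalized: partialled out exactly
   in the linear case, zero-penalty-weight columns in the logistic case.
4. **SPLS** (authored here, soft-thresholded-direction formulation): at
   component `k`, the candidate direction `z = X'y_deflated` is
   soft-thresholded at `η·max|z|`; the accumulated support is refit with a
   `k`-component PLS restricted to the active columns, and the response is
   deflated by the refit prediction. At `η = 0` the first direction is the
   dense PLS direction; as `η → 1` only the maximal-covariance metabolite
   survives. Scores are |refit coefficients| on the support.
5. **SPLSDA.** The centered 0/1 indicator is used as the SPLS response to
   obtain support and latent components; a logistic classifier on the
   components gives the discriminant fit. Selection and scores come from
   the sparse directions.
6. **Random forest.** 500 trees by default with the classic mtry —
   p/3 candidate features per split for regression, √p for
   classification; importance is permutation
   importance, computed by an in-package batched implementation (permuted
   copies of many columns stacked into one prediction call per chunk; same
   statistic as scikit-learn's `permutation_importance`, validated against
   it in the tests). Negative importances — pure permutation noise — are
   clipped at zero. Ranking only.

**Tuning and the flat-CV rule.** Sparse-method tuning (λ for LASSO; η and
`K` for SPLS/SPLSDA, grids η ∈ {0.1,…,0.9}, K ∈ {1,…,5}, 5 folds,
stratified for binary outcomes) minimizes CV prediction error (squared
error; Brier score for binary), **except** that among all grid points
within one standard error of the minimum the sparsest full-data model
wins. Sparse-PLS CV curves are characteristically flat — many sparsity
levels predict equally well — and the one-SE sparsest rule resolves that
flatness in favour of parsimony deterministically. Ties in sparsity break
toward the stronger penalty.

## Operating characteristics

Against the planted truth: sensitivity, specificity, PPV, NPV, and the
false-positive count, where a "false positive" is any selected metabolite
not planted as directly associated — deliberately counting
correlation-induced hits that are genuine *marginal* associations. A
companion tabulation records, for each false positive, whether it shares a
cluster with a true metabolite, quantifying exactly that phenomenon.
Undefined rates (PPV of an empty selection, NPV of a full one) are
reported as missing and excluded from replicate averages — never imputed
as 0 or 1, which would bias sparse methods' PPV at small N — and every
average carries the count of contributing replicates and a Monte-Carlo
standard error. Ranking methods are scored by the probability that each
true metabolite appears in the top 10 by score, and detection rate is
tabulated per effect size.

## Cohort analysis stage

Raw tables are log-transformed and z-scored per metabolite (exact to
machine precision; nonpositive intensities and zero-variance columns are
hard errors naming the offending cell). The method battery for a cohort
trait is Bonferroni, BH-FDR, LASSO, and SPLS (continuous trait, e.g. age)
or SPLSDA (binary trait, e.g. sex), with an optional specimen-batch
indicator entering all models unpenalized as a sensitivity analysis.
Method agreement is reported as the seven regions of the FDR/LASSO/SPLS
Venn partition (Bonferroni is omitted as a strict subset of FDR).
Relatedness is summarized as a Spearman correlation network keeping pairs
with signed ρ above a threshold — default +0.75, configurable (0.65 is a
plausible alternative in circulation) — annotated with each metabolite's
selecting methods, and exported as force-layout JSON and GraphML. Spearman
correlation is computed on the standardized values; being rank-based it is
identical on the raw scale.

## Replication machinery and problem sizes

A scenario grid runs `n_replicates` per scenario with per-replicate seeds
spawned as `SeedSequence(master_seed, spawn_key=(scenario, replicate))`, so
any replicate is reproducible in isolation; per-replicate rows are
persisted as CSV before aggregation, and a run manifest records the config
hash, seed, package version, and wall time. Everything downstream of a
`(config, seed)` pair is bit-reproducible.

Default desk-scale replication is 100 replicates per scenario (the full
grid at 1000 replicates is runnable but takes hours, dominated by
sparse-method CV at `M = 2000`). The test suite's replicate loops use a
documented desk-scale tuning preset — LASSO path of 25 alphas over 2.5
decades, SPLS grids η ∈ {0.3, 0.6, 0.9} × K ∈ {1, 2, 3}, 3 folds, forests
of 100 trees with single-repeat subsampled permutation scoring — chosen so
that aggregate operating characteristics are statistically
indistinguishable from the full grids on pilot runs while replicate loops
stay desk-scale. The strong-signal recovery check uses `N = 800`,
`M = 200`, independent metabolites, ten effects of ±1 SD and noise SD 0.5:
a regime chosen by power analysis (every method's weakest truth-vs-null
score gap exceeds five standard errors) so that perfect top-10 recovery is
the correct expectation, not a coin flip.

## Numerical choices and edge cases

* PSD repair: eigenvalue clipping at 0 + diagonal renormalization —
  adequate for jitter-scale indefiniteness; an infeasible correlation
  target (unreachable mean, flipped-block cancellation) raises a
  configuration error naming the violated constraint rather than silently
  renormalizing.
* Intercept calibration solves to |mean probability − target| < 1e-12;
  non-finite linear predictors are rejected.
* `top_k` breaks score ties by ascending metabolite index
  (deterministic).
* Logistic scans catch separation/non-convergence per metabolite and
  assign p = 1 rather than silently switching to a penalized estimator.
* A method failing on a replicate is logged and recorded as a
  `failed_replicates` row; the scenario continues.

## Known limitations

* The binary univariate default is logistic regression; the
  linear-probability variant exists as an option because both readings
  are defensible, and results can differ at small N.
* SPLSDA's CV error is a Brier score through a clipped linear predictor
  during tuning; full logistic refits per fold would be slower and were
  not needed for stable tuning in practice.
* The number of PCR components has no principled default for ranking;
  callers choose it (tests use either full rank or a CV-free small
  value).
* Selection counts from any particular real population cohort depend on
  access-restricted data; the cohort stage here reproduces the
  *artifacts* (selected sets, Venn regions, network exports) on
  synthetic tables, not cohort-specific numbers.
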
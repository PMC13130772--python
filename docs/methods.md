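# Methods

This note documents the statistical machinery implemented in `diagmiss`:
the data-generating model, the missingness mechanisms, the seven handling
methods, the performance measures, and the numerical and design choices
made where the construction was genuinely open.

## Data-generating model

Each simulated study is a cross-sectional single-test design with an
error-free binary reference standard `D`, a binary index test `Y` and three
binary covariates `X1, X2, X3`. A scenario is the tuple
(true sensitivity, true specificity, mechanism, missing proportion,
prevalence, n); the default factorial grid crosses three values of each
factor (Se, Sp ∈ {0.7, 0.8, 0.9}; MCAR/MAR/MNAR; missing proportion
∈ {0.1, 0.3, 0.5}; prevalence ∈ {0.1, 0.2, 0.4}; n ∈ {400, 800, 1600}),
i.e. 3⁶ = 729 scenarios.

Group sizes are fixed, not drawn: `n_D = round(n · prevalence)` subjects
(round-half-away-from-zero) come from the diseased latent model and the
rest from the non-diseased one. Sampling the two groups from separate
models makes the sampling conditional on prevalence; a binomially drawn
`n_D` would only add noise to a quantity no estimand depends on.

Within each group the four variables are jointly latent-normal with unit
variances and are dichotomized (strictly greater than the cutoff → 1; ties
have probability zero). Calibration is exact by construction:

* index cutoff `c = Φ⁻¹(Sp)`; latent index mean 0 in the non-diseased group
  and `μ_D = Φ⁻¹(Sp) − Φ⁻¹(1 − Se)` in the diseased group, so that
  `P(Y=1|D=1) = 1 − Φ(c − μ_D) = Se` and `P(Y=0|D=0) = Φ(c) = Sp`;
* covariates have latent means (0, 5, 35) — stand-ins for sex, a biomarker
  and age group — and are median-split at their means, hence Bernoulli(1/2).
  With a median split the latent variance is immaterial, and the index-test
  derivation above fixes the index scale, which is why all latent variances
  can be set to 1.

### Correlation structure

The target is a phi coefficient (Pearson correlation of the dichotomized
variables) of 0.4 for every pair. Dichotomization attenuates correlation,
so the latent correlation is obtained by inverting the bivariate-normal
orthant probability at the pair's cutpoints (`solve_latent_correlation`,
Brent root-finding to 1e-6; for two median splits this reproduces the
closed form ρ = sin(πφ/2) ≈ 0.5878). The index cutpoint is group-specific
(`Φ⁻¹(Sp)` non-diseased, `Φ⁻¹(1−Se)` diseased), so the two groups carry
different latent correlation matrices.

Two boundary situations are handled explicitly and logged with warnings:

* **Attainability.** The phi coefficient of two binary variables is bounded
  by their margins; for an index margin of 0.9 against a median-split
  covariate the bound is √(0.1·0.5/(0.9·0.5)) ≈ 0.333 < 0.4. For such pairs
  the solver's infeasibility signal triggers a fallback to the median-split
  adjustment ρ = sin(π·0.4/2). The realized phi for those pairs is then the
  attainable attenuated value, not 0.4 — an unavoidable consequence of
  requesting a fixed phi across a grid of margins.
* **Positive semi-definiteness.** Solving pairwise does not guarantee a
  PSD 4×4 matrix; if the smallest eigenvalue is negative the matrix is
  projected to the nearest correlation matrix (Higham-style, via
  statsmodels) before Cholesky factorization.

Only the calibration of Se/Sp — not the correlation detail — drives the
estimands, so these repairs affect the covariate usefulness of the
imputation models, not the truth values being estimated.

## Amputation

Missing values occur in the index test only (one missingness pattern). Each
subject's weighted sum score is `wss_i = w_Y Y_i + w_1 X1_i + w_2 X2_i +
w_3 X3_i + w_R R_i` with `R = D`. Default weights: MAR = (0,1,1,1,1) —
missingness driven by observed variables only; MNAR = (1,0,0,0,0) —
missingness driven by the unobserved value itself; MCAR ignores the score.
Scores are standardized within the dataset being amputed (sample mean/SD);
the missingness probability is `logistic(z_i + c)` with the shift `c`
solved by bisection so the mean probability equals the target proportion
(constant-score degenerate case falls back to a constant probability).
Higher scores are more likely missing ("RIGHT"-type allocation).
Amputation is Bernoulli per subject rather than fixed-count, so degenerate
datasets (all observed index results of one type) can occur, as the
exclusion rule anticipates.

## Handling methods

* **CCA** drops incomplete rows; fails (per-method failure flag) if a
  reference group retains no complete case.
* **WC** codes missing as a diagnostic error given `D` — a deliberate lower
  bound for both estimands.
* **RHD** imputes each missing `Y` with a uniform draw (with replacement)
  from the observed values in the same reference group. Donors are drawn
  with replacement because nothing ties recipients to distinct donors;
  a donor-less stratum is a per-method failure.
* **MICE** fits `logit P(Y=1) = β0 + β1 X1 + β2 X2 + β3 X3 + β4 R` on the
  complete rows, draws β* from N(MLE, inverse observed information)
  ("proper" imputation), imputes Bernoulli, repeats m times (default
  m = 5; m = 50 supported for supplementary configurations). Since only one
  variable is incomplete, the chained-equations cycle collapses to this
  single step — no Gibbs iteration is needed. Estimates are pooled with
  Rubin's rules **on the logit scale** (consistent with the logit intervals
  used everywhere else), with Barnard–Rubin degrees of freedom bounded by
  the complete-data df. Separation or non-convergence of the MLE triggers a
  ridge-penalized IRLS refit (λ = 1e-4 on non-intercept terms, logged);
  the normal-approximation draw was preferred over bootstrap-refit as the
  standard "logreg"-style approach.
* **MLMAR / MLMCAR** transform the data to a frequency table over the 16
  strata (D, X1, X2, X3) with 32 fully classified cells and 16 partial
  cells, substitute 1e-6 for zero full cells, and run EM for the saturated
  multinomial (tol 1e-8 on cell probabilities, max 1000 iterations; the
  observed-data log-likelihood is non-decreasing and is exposed for
  testing). The saturated fixed point allocates
  `partial(s) · full(y,s) / full(·,s)`. The MCAR variant carries an
  explicit constant missingness probability through the constrained EM;
  its allocation provably coincides with the MAR fit because the mechanism
  likelihood factorizes — both are computed and the coincidence is verified
  in tests. A stratum whose partial count has *no* complete mass at all
  (un-substituted table) cannot be allocated and raises a failure; after
  the epsilon substitution such strata are split 0.5/0.5 by the epsilon
  cells, which is what keeps the allocation well-defined across millions of
  repetitions.
* **WLSMCAR** fits the same model by iterated GLS / minimum chi-square: the
  48-category proportion vector (32 complete cells + 16 partial strata) is
  modeled through the 32 cell probabilities and an observation probability
  α (MCAR makes the partial pattern proportional to the stratum margins),
  weighted by the pseudo-inverse of the estimated multinomial covariance
  and iterated with Gauss–Newton steps (ridge 1e-10; convergence on
  parameter movement < 1e-8 or a stalled chi-square; max 500 iterations —
  near-flat directions created by epsilon cells converge geometrically but
  slowly). The exact estimator of the original categorical-data software is
  not published; this GLS construction is validated by its asymptotic
  agreement with the ML allocation (max cell difference < 1e-3 at N = 10⁵),
  which is the relevant correctness surface. Allocation-based methods yield
  fractional pseudo-counts; estimation accepts real-valued counts.

## Estimation

`Se = TP/(TP+FN)`, `Sp = TN/(TN+FP)` with 95% logit Wald intervals
`logit(p) ± z·√(1/x + 1/(n−x))`. Degenerate margins (x ∈ {0, n}) get a 0.5
continuity correction on the margin's two cells (x+0.5 of n+1) for both
point and interval, with a flag counted in the summaries. Single-dataset
intervals use the normal quantile; only Rubin pooling uses t quantiles.

## Performance measures

Per scenario × method × estimand over the `n_sim` repetitions: bias,
MSE, empirical SE (denominator `n_sim − 1`), coverage of the 95% interval,
and power `P(θ0 ≤ lower)` when a null value θ0 is configured (none is
built in). Monte Carlo standard errors: `EmpSE/√n_sim` for bias (the MSE
decomposition `MSE = Bias² + EmpSE²·(n−1)/n` holds to 1e-12 and is
tested), the usual second-moment formula for MSE, `EmpSE/√(2(n_sim−1))`
for EmpSE, and binomial formulas for coverage and power (maximum
`√(0.25/n_sim)`, e.g. 0.0158 at n_sim = 1000). Excluded and failed
repetitions are dropped from the denominator and reported as counts;
confidence-interval lengths are exported as min/median/max summaries.

## Study orchestration

One repetition generates a dataset, amputes it once, and feeds the *same*
amputated dataset to every method (paired comparison). If the amputated
dataset's observed index results are all one category the repetition is
excluded for all methods (study-wide exclusion — required for sensible
imputation for any method); per-method breakdowns are recorded as failure
flags instead. Seeds are counter-based,
`SeedSequence(master, spawn_key=(scenario, rep, stage))`, so results are
bit-identical regardless of execution order or parallelism (joblib across
scenarios). Outputs are long-form CSV tables plus a JSON manifest; a
nested-loop export orders scenarios by a configurable factor nesting and
attaches step-function level indices for plotting frontends (rendering
itself is out of scope).

## What the generator does and does not emulate

The generator reproduces the *structure* of a diagnostic accuracy study —
calibrated binary accuracy, correlated binary covariates, a single
missingness pattern with controllable mechanism. It does not emulate
imperfect reference standards, missingness in covariates or the reference
standard, continuous index tests, non-normal latent structure, or
covariate–outcome relationships beyond the exchangeable 0.4 correlation.
Conclusions from passing tests therefore speak to method behavior under a
clean, correctly specified world; real data can violate MAR in ways no
method here detects. Note also a deliberate asymmetry: data are generated
through a probit-type latent construction while MICE imputes with a
logistic model — a mild, realistic model misspecification rather than a
defect.

In this implementation the weighted sum score under MAR is a function of
the stratification variables only, so missingness is constant within each
(D, X1, X2, X3) stratum; the saturated-model allocation methods are then
consistent under MAR and behave close to MICE in bias, while differing
sharply in coverage (single-allocation variance understatement). Their
bias advantage over CCA/RHD under MAR, and everything about MNAR, matches
the qualitative pattern described in the missing-data literature.

## Problem sizes used in tests

The shipped test-suite and acceptance script run desk-scale versions of the
study: calibration checks use 2,000 replicates at n = 1600; the method
comparison uses four scenarios (Se = Sp = 0.8, prevalence 0.2, n = 800,
missingness {0.1, 0.5} × {MCAR, MAR}) at 200 repetitions; oracle suites use
1,000 randomized frequency tables and an exhaustive enumeration of
two-stratum tables with counts ≤ 6. These sizes give Monte Carlo standard
errors a comfortable factor below the effect sizes being asserted while
keeping a full run in minutes on one CPU.
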
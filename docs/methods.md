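# Methods

## The analysis model

The pipeline estimates individualized treatment effects in a two-arm
randomized trial (TAU vs. blended treatment) with a continuous-ish
integer outcome, the PHQ-9 depression total at 12 weeks (0–27, lower is
better). The analysis set is the completer sample: patients with an
observed 12-week outcome. Baseline covariates missing in ≥ 50% of the
completer rows are screened out; the rest are imputed (below). Nominal
covariates are split into k−1 indicator columns against a deterministic
reference level (lexicographically first), so each category is a
predictor of its own; binary covariates contribute a single 0/1 column,
continuous and count covariates pass through. The screening threshold
is strict-below: a covariate missing in exactly 49% of rows is kept,
one at 50% is dropped. Screening runs after completer filtering, so the
fractions refer to the analysis sample; both the order and the
threshold are configurable.

### Per-arm Bayesian model averaging

Each arm gets its own Gaussian linear model space: a model is an
inclusion vector γ over the p encoded columns, the intercept always
included. Outcome and predictors are centered before marginal-likelihood
computation (prediction coefficients are later refit by OLS on the
original scale). Under Zellner's g-prior the Bayes factor against the
intercept-only null is

    log BF(γ | g) = ((n − 1 − p_γ)/2) log(1+g) − ((n − 1)/2) log(1 + g(1 − R²_γ)).

The ZS-null (Jeffreys–Zellner–Siow) prior mixes g over
Inverse-Gamma(1/2, n·α/2) with α = 1 by default — equivalent to a
Cauchy prior on the standardized coefficients with Jeffreys' prior on
the error scale. The mixture integral is evaluated on the t = log g
scale by Laplace approximation: the mode is found by root-finding on
the closed-form derivative (the derivative decreases from +∞ to
−(p_γ+1)/2, so the integrand has a single interior mode), the curvature
is closed-form, and the standard higher-order correction from the third
and fourth derivatives at the mode is applied. The correction matters:
the plain second-order Laplace is off by ≈ 0.08 log units for p_γ = 1
(the integrand is visibly skewed for small models), while the corrected
version agrees with adaptive quadrature to ≈ 0.001 across
n ∈ {30, 100, 300} × p_γ ∈ {1, 5, 15} × R² ∈ {0, 0.3, 0.8}. The
quadrature evaluator is kept as the independent oracle and as the
fallback when the mode search fails. The null model short-circuits to
exactly 0; a saturated fit (R² = 1) raises; models with p_γ ≥ n − 1 get
zero posterior mass (unidentifiable).

Posterior model probabilities renormalize exp(log BF + log prior) over
the evaluated model set. The model prior is uniform over the 2^p space
by default, with beta-binomial(1,1) (uniform on model size) as an
option. The per-column posterior inclusion probability (PIP) is the
posterior mass of models containing the column. Reporting ties are
broken by fewer variables, then lexicographic γ.

For p ≤ 20 the space is enumerated exhaustively (R² per subset solved
from the precomputed Gram matrix). Larger spaces use MCMC+BAS with a
30 000-distinct-model budget: phase 1 is a Metropolis–Hastings chain
over inclusion vectors (single-bit flips, 10% swap proposals of an
included/excluded pair) targeting the posterior, run until half the
budget in unique models is scored; phase 2 draws further distinct
models with per-column Bernoulli probabilities set to the running PIP
estimates, clamped to [0.025, 0.975] to keep the without-replacement
sampling non-degenerate, skipping already-scored models and refreshing
the estimates every 500 new models. When the remaining budget can cover
the whole unscored space the remainder is enumerated — so a budget of
2^p reproduces enumeration exactly; if duplicate sampling starves
(2000 consecutive duplicates) the run finishes early with a note. Final
PIPs and posterior probabilities renormalize over all unique scored
models. The published ranking criterion that pairs posterior
probability with BIC is not implemented; posterior probability alone
ranks models.

### Leave-one-out PAI

Predictor sets are selected **once per arm** on the full arm sample —
default: the highest-posterior model (HPM); option: the
median-probability model (MPM, PIP > 0.5, falling back to intercept-only
with a flag when empty) — and held fixed across folds. HPM is the
default because an MPM threshold excludes borderline categories (a
PIP of 0.497, say) that the top model may legitimately contain; the two
rules can genuinely disagree and both selections are logged with their
PIPs. Selecting once on the full sample is a known optimism source
(models are built and tested in the same data); it is the documented
design here, not an oversight.

For patient i in arm A: the factual prediction is an OLS fit of the
outcome on the selected arm-A predictors over arm A **without patient
i**, evaluated at x_i; the counterfactual prediction is an OLS fit on
the **entire** other arm (which never contains patient i), evaluated at
x_i. Neither training set contains the patient, so both predictions are
invariant to the patient's own outcome. Predictions are raw linear
predictors, not clipped to 0–27 (clipping is available as a flag and
slightly affects the error summaries at the scale edges). A predictor
column constant within a fold is dropped for that fold; a singular fold
design falls back to the minimum-norm solution; both warn.

PAI = |factual − counterfactual|; the optimal arm is the one with the
smaller predicted PHQ-9, exact ties counted as optimal-received (a
zero-PAI patient cannot be misallocated). Summaries: mean PAI (read:
the 12-week score under model-optimal allocation would be that many
points lower than under suboptimal allocation); the fraction with
PAI ≥ 5 points — the threshold for a minimal clinically important
individual PHQ-9 change; observed-outcome means and counts of the
optimal- vs suboptimal-allocated groups (a partition of the analysis
cohort); and the mean absolute error of the factual predictions.

## Imputation

Missing baseline covariates are imputed with an iterative
random-forest scheme (the missForest algorithm), implemented on
scikit-learn forests because no Python port of the original is
available and sklearn's IterativeImputer is a different (regression-
based, round-robin) algorithm without the forest stopping rule.
Missing cells are initialized with the column mean (continuous/count;
counts rounded) or mode (binary/nominal); variables are visited in
ascending order of missingness; each variable is regressed/classified
on all others (current imputed state, nominals one-hot) using only its
originally observed rows, with 100 trees per fit by default; sweeps
stop when the difference between successive imputed matrices —
normalized squared difference for the numeric part, disagreement
proportion for the categorical part — increases for both parts, and
the previous iterate is returned (cap: 10 sweeps). Observed cells are
never altered; imputed categories are always observed levels; a
constant observed column is filled with its constant (warned); a fully
unobserved column is an error. The randomization arm is offered to the
forests as a feature by default since imputation runs on the pooled
completer sample (switchable); the outcome never enters the imputation
model set. Count predictions are rounded to non-negative integers to
keep the table type-faithful — a deliberate, slight departure from the
original algorithm's continuous output.

## The synthetic-data generator

The generator emulates the study design the analysis targets, so every
stage is testable with known ground truth:

- **Randomization**: permuted blocks at 1:1, block sizes drawn from
  {8, 10, 12, 14} — even values only, so balance is exact within every
  full block; a shorter final block pads the remainder (for odd n the
  extra patient goes to a random arm, so arm sizes differ by at most
  one incomplete block).
- **Covariates**: each variable has a marginal (normal, Poisson,
  Bernoulli, categorical) and an optional loading ρ ∈ (−1, 1) on a
  single latent severity factor, combined through a Gaussian copula —
  latent score ρ·f + √(1−ρ²)·z mapped through the marginal quantile.
  This produces the correlated baseline batteries (severity, quality of
  life, utilization) seen in real symptom data while keeping marginals
  exactly as configured; one factor cannot represent richer dependence
  structures (blocks, non-monotone relations).
- **Outcome**: arm-specific linear predictors over the encoded design
  columns plus Gaussian noise, then rounded and clipped to the 0–27
  integer scale. The truth record (both arms' linear predictors, true
  optimal arm, true PAI) is computed before noise, rounding, clipping
  and missingness, so it is exact and mask-invariant; truth and
  observation can diverge at the scale edges by construction.
- **Missingness**: MCAR per covariate at configured rates; an optional
  MAR hook makes missingness logistic in a driver covariate around the
  same marginal rate. Outcome dropout is MCAR.

All randomness flows from one seed through a single generator stream;
identical configurations are byte-identical on disk.

Presets define the study conditions used by the tests and the
acceptance script:

- `null` (n = 200): one positive prognostic severity effect, identical
  arms — every true PAI is 0. Used for calibration: the
  optimal/suboptimal observed-outcome gap should be centered at zero
  and clinically meaningful PAIs rare.
- `prognostic_only` (n = 250): four shared prognostic effects, still no
  prescriptive contrast.
- `prescriptive` (n = 500): one binary marker at +4/−4 points
  (TAU/blend) with a 1-point intercept contrast and noise sd 4, giving
  true PAIs of 1 or 9 points (no exact ties). Used for recovery: mean
  PAI within 20% of truth, allocation agreement ≥ 80%.
- `ecompared_like` (n = 251): 28 mixed-type candidate predictors in the
  four standard categories (sociodemographics incl. 4-level country and
  5-level marital status; symptomatology/quality of life; 12 healthcare-
  utilization counts; expectancy/credibility), per-item missingness
  spanning 2–41%, outcome dropout 2.4%, noise sd 4 (arm R² around 0.4),
  and a handful of arm-specific effects so that severity and expectancy
  are prognostic while country, utilization items, quality of life and
  widowhood are prescriptive. Coefficients are in PHQ-9 points per
  covariate unit. Because the country reference level is Denmark
  (lexicographically first), "TAU works ≈ 2 points better in Denmark"
  is encoded as +2 on the other three country indicators.

What passing tests on these scenarios do **not** show: robustness to
informative (MNAR) dropout, item-level measurement structure,
treatment-effect heterogeneity beyond linear-in-covariates form, or
non-Gaussian residuals — real trial data can violate all of these.

## Numerical and design choices

- Centering, not standardization, before marginal likelihoods; R² (and
  hence all Bayes factors and PIPs) is invariant to outcome scaling.
- Subset R² solved from the Gram matrix by Cholesky, least-squares
  fallback for singular subsets.
- Laplace: mode bracketed in t ∈ [−15, 35] (extended if needed), brentq
  to 1e-10, higher-order correction; quadrature fallback on failure.
- Sampler clamping ε = 0.025; PIP refresh every 500 scored models;
  starvation threshold 2000 consecutive duplicates.
- Determinism: per-stage seeds derive from one master seed via
  `SeedSequence`; reports serialize with sorted keys; two runs with the
  same input and seed are byte-identical.
- Problem sizes in the test suite (n ≈ 120–500, p ≤ 15 for
  enumeration-vs-sampler checks, 10–20 replicate seeds) are chosen so
  the full suite documents the statistical properties at desk scale.

## Known limitations

- Selection and evaluation share the sample (by design, matching the
  analysis the pipeline reproduces); reported PAIs are optimistic.
- BMA is used for selection only; predictions are plain OLS, not
  model-averaged, and no prediction intervals are produced.
- The imputation is single, not multiple: downstream uncertainty
  ignores imputation variance.
- The generator's MAR hook calibrates the marginal missingness rate
  only approximately (logistic shift around the configured rate).
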
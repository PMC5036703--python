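# Methods

This note records the modelling assumptions, the numerical choices, and the
design decisions behind `admitsem`, in the spirit of a model-description
appendix. Notation follows the README.

## Data model and derived quantities

The unit of analysis is the GP practice. Quality indicators arrive as
numerator/denominator pairs `(Z_ij, N_ij)` (patients attaining a clinical
target out of those eligible), access indicators as `(W_ik, V_ik)` (survey
respondents rating an aspect of access poor out of all surveyed). Note the
deliberate renaming: survey denominators are called **V** here because the
conventional symbol M is also the age-standardised morbidity rate; using both
would invite subtle bugs.

**Expected counts.** Relative risks ν_i need a reference exposure. By
default `E_i ∝ register_i` (the per-practice mean of the quality
denominators, i.e. the diabetes register — the natural exposure for
diabetes-related admissions), internally standardized so `Σ E = Σ Y` and
ν = 1 is the no-effect reference. Practice list size is available as an
alternative basis (`basis="list_size"`); the choice moves only the intercept
interpretation when exposure bases are proportional.

**Covariate standardization.** Deprivation, morbidity rate, GP supply and
list size are centred and scaled to unit SD before fitting (the record is
kept for back-transformation). Coefficients of order 0.1–0.5 and latent
factors on a roughly unit-variance scale then share a common prior scale;
raw deprivation scores (shares in [0, 1]) would make the priors
scale-sensitive. Reported coefficients are therefore per-SD effects.

## Likelihoods

Both measurement blocks are **logistic-normal-binomial**: extra-binomial
dispersion is a normal deviate on the logit scale (`ε_ij`, `e_ik`) with
indicator-specific SDs (a shared-SD switch exists:
`ModelConfig(shared_quality_sd=True)`). This composes cleanly with the
linear loading structure `λ_j F_i`; a beta-binomial would not. The outcome
is **Poisson with a log-normal random effect** `u_i ~ N(0, α²)`; α is the
residual log-scale SD and shrinks toward zero as explanatory covariates
enter — the behaviour expected of a residual overdispersion parameter.
Binomial log-probabilities are evaluated as
`z·lp − n·log(1+e^lp)` so `Z = 0` and `Z = N` remain finite for any finite
linear predictor.

Identification: the first loading of each block is fixed at 1 (`λ₁ = κ₁ =
1`), anchoring the scale and orientation of F and G; the factor variances
Σ₁₁, Σ₂₂ are then free parameters. Remaining loadings are not
sign-constrained.

Model 4 implements bivariate Student-t factors by the standard Gamma(df/2,
df/2) scale mixture on Σ with df fixed at 4 (a conventional robust default);
df is not estimated.

## Priors

Normal(0, 10²) on regression coefficients, intercepts and free loadings;
Half-Normal(0, 1) on all SDs (α, σ_j, τ_k, and the factor scales); uniform
(−1, 1) on ρ via a separation (scales + correlation) parameterisation. All
location priors are zero-mean, hence symmetric in sign — a requirement for
reading posterior sign probabilities as marginal Bayes factors `p/(1−p)`
under unit prior odds. After covariate standardization these are weakly
informative at the scale of the data.

## Sampler

Adaptive random-walk Metropolis-within-Gibbs, written in the package rather
than delegated to a generic engine (the joint structure — two binomial
measurement blocks, a Poisson outcome, bivariate latent scores with causes —
is the point of the package, and the sampler is tested against independent
oracles). Key choices:

* Latent blocks (F, G, ε, e, u) have conditionals independent across
  practices given globals, so they are updated with vectorised element-wise
  proposals with per-element adapted steps.
* `(F_i, G_i)` are proposed jointly per practice.
* **Non-centred parameterisation** for the overdispersion effects:
  `ε = σ_j ε_raw`, `e = τ_k e_raw`, `u = α u_raw` with standard-normal raws.
  The hierarchical SDs sit near zero in well-explained models (α ≈ 0.03),
  where centred random-walk updates funnel; non-centring removes the
  pathology without changing the model.
* The factor scores stay **centred** (the indicator data are strongly
  informative about F and G, where centred updates mix better), but the
  factor scale gets an additional **interweaved rescaling move** in the
  univariate-structure models: propose σ_F on the log scale while rescaling
  F to keep the standardized residuals fixed. The structural prior and
  Jacobian cancel exactly, so the acceptance ratio involves only the data
  likelihood, the half-normal prior, and the log-walk Jacobian. This is what
  makes small-σ_F posteriors (relevant in calibration experiments) mix.
* Scales are updated on the log scale, ρ on the Fisher-z scale, with
  Jacobians; the model-4 mixture weights ω_i have a conjugate Gamma(df/2+1,
  (df+q_i)/2) Gibbs draw.
* Robbins-Monro adaptation of proposal steps toward 0.44 acceptance (0.35
  for the bivariate factor move) runs during burn-in only and is frozen
  afterwards, so retained draws come from a valid Markov chain.
* Initialization: indicator intercepts at pooled empirical logits with a
  (x+0.5)/(n+1) continuity correction (all-zero survey columns stay
  finite), factor scores at jittered zero, scales at 0.1, coefficients at
  jittered zero; re-jittered until the log-posterior is finite.

Defaults are 4 chains × 20,000 iterations with 10,000 burn-in and thinning
5. The test and acceptance runs use deliberately shorter chains (roughly
2,000–4,000 iterations, 1–2 chains) — adequate here because the vectorised
updates mix quickly at I = 90, as the calibration and oracle tests verify.
Convergence reporting (split-R-hat, ESS, MCSE) is delegated to ArviZ;
parameters with R-hat > 1.05 or undefined R-hat are flagged.

All randomness flows from a single seed through `numpy` `SeedSequence`
spawning (per chain, per pipeline stage), making every fit and every CLI
run bit-reproducible.

## Model criticism

**WAIC** is computed per likelihood component (outcome, quality, access)
with one cell per observation: `WAIC = −2(lppd − p_waic)`, `lppd` via
log-sum-exp over retained draws, `p_waic` the sum of pointwise draw
variances. Component-wise reporting lets the outcome fit be compared across
the model ladder without being swamped by the measurement blocks.

**Posterior predictive checks** replicate each observed variable from its
likelihood at every retained draw and compare a chi-square discrepancy
`T(x;θ) = Σ_i (x_i − E[x_i|θ])²/Var(x_i|θ)` between replicate and
observation. The chi-square is an omnibus choice for count data; other
statistics would give numerically different p-values, so the meaningful
contract is the satisfactory band (roughly 0.1–0.9), not the exact value.

**Factor-risk curves** are LOWESS smooths (tricube weights, default span
2/3, via statsmodels) of posterior-mean relative risk against posterior-mean
factor score — the device used to spot threshold effects of quality.

**Geographic aggregation** multiplies per-practice scores (draws or means)
by a row-stochastic area×practice population-share matrix. Crosswalk rows
that sum to less than 1 (partial coverage of an area's population) are
renormalized, with the raw sum reported as `covered_fraction`, preserving
the convex-combination property while surfacing coverage. Aggregation is
linear, so draw-wise and mean-first aggregation agree on the mean; draw-wise
additionally yields an area-level SD. Both are available because either
convention is defensible for mapping.

## Synthetic data generator

The generator emulates the study design: 90 practices in a two-CCG urban
area, J = K = 4 indicators, quality denominators uniform on [50, 600]
(register sizes), access denominators uniform on [50, 200] (survey
responders) — denominators deliberately heterogeneous, since varying
precision of the raw percentages is a key motivation for the latent
treatment. Covariates are drawn on natural scales (deprivation share
0.20 ± 0.08, morbidity rate 6 ± 1.5 per 100 with a 0.7 correlation to
deprivation, 0.58 ± 0.15 FTE GPs per 1000, list size 7 ± 3 thousand), then
standardized internally before the structural coefficients are applied —
matching the fitting pipeline, so published coefficient values used as
truths are recoverable on the same scale. Expected counts use 0.10
admissions per register patient, giving realistic practice totals of ~15–60
admissions.

Default truths are the published full-model posterior means (outcome
coefficients −0.03, −0.17, 0.24, 0.18, 0.09; loadings 1/0.63/0.77/1.33 and
1/1.35/1.89/1.47; structural effects −0.08, 0.45, −0.37, 0.053; ρ = −0.38),
with indicator intercepts at the logits of the published overall rates.
The latent and overdispersion scales are not published; the defaults
(σ_F = 0.50, σ_G = 0.45, σ_j = 0.15, τ_k = 0.20) were calibrated once so the
implied logit-scale spread of practice rates matches the published
10th–90th percentile ranges (≈0.6–0.7 logit SD per block), and are not
otherwise adjusted.

What the generator does **not** emulate: spatial autocorrelation of areas
(geographic clustering arises only through deprivation structure), item
non-response, temporal drift, or misclassification in the indicators.
Passing recovery/calibration tests therefore demonstrates correctness of
the inference machinery under the stated model, not robustness to the
misspecifications real QOF/survey/HES data may carry.

## Verification strategy

* Likelihood kernels against closed-form/factorial arithmetic; the
  bivariate latent density against `scipy.stats.multivariate_normal`.
* The sampler against a fine-grid numerical posterior on a toy with fixed
  latents; prior-only runs against prior moments; simulation-based
  calibration (rank uniformity over 200 prior-draw replicates) on a
  3-practice toy.
* Parameter recovery at the study scale: 95% intervals cover the
  generating coefficients in ≥85% of replicates at I = 90 (the tolerance
  reflects interval-estimation noise at small I and short chains).
* The WAIC machinery against hand computation, and the expected qualitative
  ordering (covariate model beats quality-only when covariate effects are
  real) over replicates.

## Known limitations

* Random-walk MCMC: mixing degrades for much larger I or many indicators;
  no gradient-based sampler is provided.
* df of the Student-t variant is fixed, not estimated.
* No cross-loadings (quality indicators load only on F, access only on G)
  and at most two factors.
* A Monte Carlo sign probability of exactly 0 or 1 only bounds the
  corresponding Bayes factor; the package warns rather than reporting the
  unbounded value silently.
* Area aggregation assumes the crosswalk is measured without error and
  carries no spatial smoothing.
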
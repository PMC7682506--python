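# Methods

`bootmi` implements confidence-interval construction for analyses of
multiply imputed data, with particular attention to what happens when the
imputation model and the analyst's model are *uncongenial* (no single
Bayesian model embeds both) or misspecified. This note records the models,
the estimators, the numerical conventions, and the design choices that were
genuinely open.

## Set-up and notation

The analyst has a complete-data procedure returning a point estimate
θ̂(Z) and a model-based variance W(Z) for a scalar target θ — here always an
OLS coefficient with the classical homoscedastic variance (denominator
n − p). The imputer fills the missing values M times from a Bayesian
predictive model, giving completed datasets m = 1, …, M with estimates θ̂_m
and variances W_m.

### Proper normal imputation (MAR)

A single continuous outcome is imputed from a normal linear regression on
fully observed predictors, fitted to the complete rows. Each imputation uses
a fresh posterior draw under the standard noninformative prior:

    σ² ~ RSS / χ²(n_obs − p),    β | σ² ~ N(β̂_OLS, σ² (XᵀX)⁻¹),

and each missing outcome is filled with its drawn conditional mean plus
N(0, σ²) noise. Drawing parameters anew for every imputation is what makes
the imputation "proper": the between-imputation variance reflects parameter
uncertainty, which Rubin's rules require.

### Jump to reference (J2R)

For a two-arm trial with one post-baseline outcome, the posterior draw is
taken from the **control-arm** regression of outcome on baseline covariates,
and *all* missing outcomes — control and active — are imputed from that
control-arm conditional distribution. Missing active-arm patients "jump to
reference". The imputer thereby assumes more than the analyst's model (OLS
of outcome on baseline and treatment), which is the canonical source of
uncongeniality studied here. Only the single-timepoint version is
implemented; copy-reference variants, multi-visit J2R and MNAR delta
adjustments are out of scope.

An important consequence: with MCAR dropout at rate p_mis in both arms, the
J2R point estimator converges not to the generating effect θ_Z but to
(1 − p_mis)·θ_Z, because the imputed fraction of the active arm carries no
treatment effect. Repeated-sampling coverage under J2R is therefore
assessed against this probability limit — the method's own estimand — which
is what makes the observed over-coverage of Rubin's rules attributable
purely to variance bias rather than to point-estimator bias.

## The five interval constructions

1. **Rubin's rules** (`rubin`). θ̄_M = mean(θ̂_m); T = W̄ + (1 + 1/M)·B with
   B the sample variance of the θ̂_m (divisor M − 1); t interval on Rubin's
   classical df ν = (M − 1)(1 + W̄/((1 + 1/M)B))², with a normal quantile
   when B = 0. The Barnard–Rubin small-sample adjustment is deliberately
   omitted — the intended regime is moderate-to-large n, where it is
   immaterial — and a plain-normal rule is available via
   `df_method="normal"`.
2. **MI boot Rubin** (`mi_boot_rubin`). Identical pooling, but W_m is
   replaced by the nonparametric bootstrap variance of the estimator on the
   m-th completed dataset (B resamples, divisor B − 1). Valid exactly where
   Rubin's rules are.
3. **MI boot pooled percentile** (`mi_boot_pooled`). All M·B bootstrap
   estimates are pooled and the interval is read from their α/2 and 1 − α/2
   empirical percentiles. The pooled sample variance (divisor MB) is carried
   as a diagnostic: by one-way random-intercept results it is unbiased (for
   large B) for (1 − 1/M)·Var[E(θ|Z_com)|Z_obs] + E[Var(θ|Z_com)|Z_obs],
   which is *below* the posterior variance at small M — the mechanism behind
   this method's under-coverage even under congeniality.
4. **Boot MI percentile** (`boot_mi_percentile`). B resamples of the
   *incomplete* data, each independently imputed M times; interval from the
   percentiles of the per-replicate means θ̄_b. This is the ordinary
   percentile bootstrap of the MI estimator, valid under uncongeniality
   whenever the point estimator is consistent — but expensive, and with
   M = 1 the single-imputation Monte-Carlo noise is resampled into the
   percentiles, producing wide, over-covering intervals.
5. **von Hippel variance-component interval** (`boot_mi_vonhippel`). The
   same grid is treated as a one-way random-effects model
   θ̂_bm = θ̄_∞ + c_b + d_bm. With MSB and MSW the between/within-bootstrap
   mean squares, σ̂²_∞ = (MSB − MSW)/M, σ̂²_btw = MSW, and

       V̂(θ̄_BM) = (1 + 1/B)(MSB − MSW)/M + MSW/(BM)
                 = ((B + 1)/(BM))·MSB − MSW/M,

   with a t interval on Satterthwaite df

       ν̂ = V̂² / [ ((B+1)/(BM))²·MSB²/(B−1) + MSW²/(B·M²·(M−1)) ].

   When MSW = 0 both the numerator and denominator collapse and ν̂ is
   evaluated as the analytic limit B − 1. When MSB < MSW the component
   estimates are truncated (σ̂²_∞ = 0, σ̂²_btw = total sample variance of the
   BM estimates); the fallback is stated only for the components in the
   source literature, so as a design decision the variance *and* df formulas
   are evaluated with MSB and MSW both replaced by the fallback-implied
   common value, which reduces V̂ to s²_tot/(BM) and keeps it non-negative.
   Recommended settings are a large B with M = 2: near the efficiency of
   percentile Boot MI at a fraction of the cost.

### Conventions fixed package-wide

- `alpha` is always the **total two-sided error rate** (0.05 gives a 95%
  interval); percentile endpoints sit at α/2 and 1 − α/2. Sources that write
  "(1 − 2α) interval from the α and 1 − α percentiles" correspond to
  alpha = 2α here.
- Empirical quantiles use linear interpolation between order statistics
  (the numpy default).
- Missing cells are NaN in memory; CSV I/O uses a declared token
  (default `"NA"`).
- Bootstrap resampling is of whole rows, with replacement, size n. In
  bootstrap-then-MI a duplicated incomplete row receives independent
  imputations for each copy. A resample on which a model is inestimable
  (singular design, collapsed subgroup) is redrawn up to 10 times and then
  reported as an error; silently dropping replicates would bias B.
- In MI-then-bootstrap, `mi_boot_pooled`'s point estimate defaults to the
  MI estimate θ̄_M (comparable with the other methods); the grid mean is
  available via `point="grid_mean"`.

## Simulation designs

### Two-arm trial

n = 500 with exactly 250 per arm (fixed-count randomisation, not
Bernoulli); per subject (X, Y) bivariate normal with means (2, 2 + 0.2·Z),
variances 0.4 and covariance 0.2; Y missing completely at random with
probability 0.5. Analysis: OLS of Y on X and Z, target the Z coefficient.
Imputation either congenial MAR (Y on X and Z) or J2R (control-arm Y on X).
The generator's defaults are exactly these constants.

### Anthropometric model

    sex ~ Bernoulli(π)
    (age, height) | sex ~ N(α₀ + α₁·sex, Σ)
    weight = ι₀ + ι₁·sex + ι₂·age + ι₃·height + η_sex^λ·error_W
    loginsindex = β₀ + β₁·sex + β₂·age + θ·weight + η_sex^ω·error_L

with η_sex = 1 for women and η for men. Weight is MCAR at rate 0.6;
analysis targets θ, the weight coefficient in the insulin-index regression
adjusted for age and sex; the imputation model for weight uses sex, age,
height and loginsindex. Four scenario switches:

- **subgroup** — null sex effects; weight missing among men only; the
  imputer pools the sexes (drops sex), the analyst fits men only
  (uncongenial: the imputer uses the women's data the analyst ignores).
- **heteroscedastic** — η = 2 doubles the male error SD; both models
  wrongly assume homoscedasticity (congenial but misspecified).
- **omitted interaction** — the analyst adds weight×sex; the imputer,
  correctly, does not (uncongenial).
- **non-normal** — errors take a log-normal shape, exp{N(0, 0.25²)},
  centred and scaled to mean 0 and unit variance before multiplying by the
  error SD, so only the error *shape* changes (congenial but misspecified).

The non-null parameter values of this design live in an external study not
reproduced here; the bundled defaults (`bootmi/configs/anthro_default.yaml`:
π = 0.5, ages ~20 y, heights ~170 cm, σ_W = 8 kg, θ = 0.02 per kg, …) are
realistic anthropometric placeholders chosen once to satisfy the
scenario-defining constraints (α₁ = 0, ι₁ = 0, β₁ = 0, η = 1 unless
switched). Consequently the anthropometric results are checked as
*qualitative properties* — direction and presence of over-/under-coverage —
not as numeric reproductions, and every parameter is editable through the
scenario config.

### Study runner

A master seed spawns one `SeedSequence` substream per replication, and per
replication one substream for data generation plus one per method, so all
methods see identical datasets and results are reproducible bit-for-bit,
including under `workers > 1` (joblib splits replications, seeds are
pre-assigned). Coverage is the percentage of intervals containing the
scenario's true target (the J2R estimand under J2R); summaries report the
median interval width and the Monte-Carlo SE of the coverage estimate,
100·√(p(1−p)/n_reps). Note that the commonly quoted "0.43%" figure for
10,000 replications is 1.96×SE (a 95% margin), not the SE itself (0.218%);
`mc_se` returns the plain SE.

## What the generators do and do not emulate

The generators produce i.i.d. rows with exactly normal (or standardised
log-normal) errors, MCAR missingness, and single-variable missingness
patterns. Real trial and cohort data feature MAR/MNAR mechanisms driven by
observables, multivariate missingness, longitudinal structure and
non-normal outcomes; passing coverage here demonstrates the *inferential*
properties of the pooling rules under controlled (un)congeniality, not
robustness to those complications. The nonparametric row bootstrap also
assumes i.i.d. sampling — clustered or weighted designs would need a
different resampling scheme.

## Numerical choices

- OLS is solved by Cholesky on the normal equations; rank deficiency
  surfaces as an `EstimationError`. The simulation engine performs ~10⁷
  fits per study, so batched fitters (multinomial resample weights against
  precomputed row outer products; batched solves across imputations) do the
  heavy lifting. Their agreement with a reference OLS implementation
  (statsmodels) is asserted in the tests.
- The bootstrap weight representation (multinomial counts) is exactly
  equivalent to index resampling for fitting purposes.
- Degenerate inputs: zero residual variance collapses the imputation
  posterior (imputations become deterministic); a grid with all entries
  equal yields a zero-width interval with df = B − 1.

## Problem sizes used in the checks

The reproduction tests and the acceptance script run the trial study at
1,000 replications with B = 200 (the published study used 10,000 and
B = 1,000); comparisons use three combined Monte-Carlo standard errors, and
median widths a 10% band, reflecting the reduced scale. The anthropometric
property checks use 800 replications with B = 200. These sizes are the
package's chosen trade-off between statistical resolution and a test suite
that runs in minutes.

## Known limitations

- Scalar targets only; no multivariate pooling or joint tests.
- Single-outcome imputation; no chained equations.
- Fraction-of-missing-information diagnostics, BCa/studentised bootstrap
  intervals and sandwich variances are not provided.
- The Satterthwaite-df behaviour under the MSB < MSW fallback is an
  interpretation (see above); it only engages when the sampling variance
  estimate is already at the resolution floor.
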
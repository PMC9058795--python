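# Methods

## The model

For each song *i* by male *j(i)* in year *t(i)*, and traits stacked as a
vector **y**ᵢ (SL and MF jointly, or complexity alone):

    y_i = X_i β + u_{t(i)} + Z_i a_{j(i)} + ε_i

* **Fixed effects** (per trait): intercept, z(date), binary age (1 = adult),
  z(song order within the recording), z(singing position as % of vegetation
  height), social-context contrasts (female stimulus, no stimulus; male
  stimulus is the reference) and order-by-context interactions. All
  continuous variables, including the responses, are z-scored (mean 0,
  SD 1, n−1 denominator) over the rows entering the fit, preserving
  direction. Rows with a missing covariate or response are dropped listwise
  and counted.
* **Individual block**: `Z_i = (1, z(order)_i, z(position)_i)`; the deviation
  vector `a_j` (3 entries per trait) is drawn from `N(0, G_c)` where `c` is
  the social context of the male's recording. The three context blocks are
  independent (cross-context covariances structurally zero), but within a
  context every intercept–slope and cross-trait covariance is estimated.
  A context observed for fewer than two individuals loses its block with a
  warning. Only each male's first recording enters the main models.
* **Year**: a random intercept per year with cross-trait covariance
  `V_year`; **residuals** are i.i.d. across songs with cross-trait
  covariance `R`.

## Priors and the Gibbs sampler

Fixed effects get independent N(0, 10⁸) priors (effectively flat on the
z-scale; a truly flat prior is available and used in the GLS oracle test).
Every covariance block gets either

* the **parameter-expanded** family (default): the block is parameterized
  `G = diag(α) G_η diag(α)` with `G_η ~ IW(I·s, ν)` and working parameters
  `α ~ N(0, 1000·I)`. The α update is a linear-regression draw given the
  scaled effects; the redundant multiplicative reparameterization moves the
  chain efficiently when variance components sit near zero.
* or a plain **inverse-Wishart** `IW(I·s, ν)` (`prior_family =
  "inverse_wishart"`), which on the same data yields somewhat larger but
  qualitatively consistent variance estimates (asserted as overlapping CIs
  in the tests).

Default scale s = 1 and df ν = block dimension. For univariate blocks this
is a df of 1; for multivariate blocks a df below the dimension would make
the inverse-Wishart improper, so the dimension is the smallest proper
choice and is used throughout. Residual blocks default to `IW(I, T+1)`.

One Gibbs iteration performs:

1. **Joint location draw** of all fixed, year and individual effects from
   their exact multivariate-normal full conditional. The posterior
   precision has an arrow structure — dense fixed+year columns plus one
   small diagonal block per individual — so the draw is computed by Schur
   complement elimination of the individual blocks with a perturbation
   sampler (solve `Qθ = b + W'R^{-1/2}ξ₁ + Σ₀^{-1/2}ξ₂`), which is
   algebraically identical to factorizing the full joint precision; a test
   verifies equality with densely assembled mixed-model equations to
   1e-10. Cost is linear in individuals instead of cubic.
2. **Per-context block updates**: conjugate inverse-Wishart draw of each
   `G_η` from the scaled effects, then the working-parameter draw (PX
   family), giving the expanded `G_c` draw; identically for the year block.
3. **Residual update**: inverse-Wishart from the residual cross-products
   (skipped when the residual covariance is fixed, as in the GLS oracle).

Chains are initialized at zero effects and identity covariances and differ
only by RNG streams spawned from the seed; every retained covariance draw
is symmetric positive definite by construction. Retained draws per chain
are `floor((iterations − burn-in)/thin)`; the published single-chain
settings (510,000 / 10,000 / 500 → exactly 1000 draws) are available as
`ChainConfig.paper_faithful()`, while the package defaults to several
shorter chains so that convergence can be checked automatically with the
rank-normalized split R-hat (strictly more conservative than the classic
statistic). Non-positive-definite conditionals abort with the iteration
index.

## Posterior summaries

Equal-tailed credible intervals use linear-interpolation (type-7)
quantiles; the convention behind any published interval is unknowable
without the original draws, so it is documented rather than guessed. The
probability of direction is the share of draws carrying the posterior
median's sign, with exact zeros split evenly; it maps to a two-sided
p-value analog as `2(1 − pd)`. A location estimate is "significant" iff its
95% CI excludes zero. Variance CIs cannot cross zero, so variance rows
instead report the posterior mass below a negligible-variance threshold
(default 0.01 on the z-scale) as a reproducible proxy for inspecting the
whole posterior. Covariances are transformed to correlations per draw,
`r = cov/√(v_A v_B)`, dropping (and counting) draws with a non-positive
variance.

## Synthetic data

The generator inverts the model above. Defaults emulate the field design:
185 males (context shares 0.45/0.21/0.34 for male/female/none), 9–126
songs per recording, 12 years, season dates 0–27 days, 40% yearlings, 15%
missing singing positions, 20% of males with a second recording (65% of
those in the same context). Singing position is Beta(2,2) rescaled to
[0,100]; songs per recording are uniform over the configured range —
neither distribution is identified by field summaries, so symmetric and
uniform defaults were chosen once. Fixed-effect defaults reproduce the
published population-level point estimates for SL and MF (e.g. the
order-by-female-context interactions 0.285 and 0.379 on the z-scale);
date/age effects on complexity default to the published values as well.
Random-effect defaults are realistic z-scale choices (per-trait intercept
variance 0.20, slope variances 0.03–0.10, year 0.05, residual 0.60,
totalling ≈1 phenotypic variance), with the two published male-context
slope correlations (−0.69 between the SL order- and position-slopes;
−0.71 between the SL position- and MF order-slopes) embedded in the
male-context matrix; the remaining covariances are small and the matrix was
verified positive definite (smallest eigenvalue 0.019).

Each *recording* realizes its slopes as the male's stable slope plus an
independent `N(0, repeat_noise_sd²)` deviation (intercepts carry over), so
the true slope repeatability across recordings is the intraclass
correlation `R = var_slope/(var_slope + repeat_noise_sd²)`; the default
`repeat_noise_sd = √0.10` against a male-context order-slope variance of
0.10 gives R = 0.5. A consequence worth noting: the slope variance seen in
any single recording is `var_slope + repeat_noise_sd²`, and recording noise
that is i.i.d. across slope dimensions attenuates the realized slope
correlations; experiments that target the stable components set
`repeat_noise_sd = 0`.

What the generator does **not** emulate: non-Gaussian trait distributions,
autocorrelation of songs within a recording beyond the linear order trend,
context-dependent position responses, stimulus-bird identity effects, and
any acoustic structure below the syllable-feature level (syllable features
are Gaussian clusters with hard assignments). Passing tests therefore show
that the pipeline recovers the assumed linear-reaction-norm structure, not
that real song data satisfy those assumptions.

## Repeatability estimator

Stage 1 fits the univariate model separately to the first and second
recordings of the same-context repeated cohort, restricted to the random
terms under study (intercept + the target gradient slope), and extracts
each male's full slope-draw vector. Stage 2 regresses slope draws on
recording order with individual identity random and reports the posterior
of `R = V_ind/(V_ind + V_res)`.

The phrase "repeated with all posterior samples" admits two readings and
both are implemented. The default repeats the stage-2 model across
posterior draw indices (an evenly spaced subsample of 100 indices, each fit
with a short chain) and pools the R draws. Fitting once on the *stacked*
draws-as-rows dataset (`method="stacked"`) is faster but statistically
distinct: stacking pseudo-replicates each individual×recording cell 1000
times, so the within-cell residual variance collapses to the posterior
spread of the slope estimate and R converges to roughly
`(V_a + σ_d²/2 + σ_p²/2)/(V_a + σ_d² + 3σ_p²/2)` instead of
`V_a/(V_a + σ_d² + σ_p²)` — biased toward and never far below ½. The
stacked route is retained for comparison only. Either way R is a
procedure-defined, pragmatic estimator — stage-2 rows are posterior draws,
not independent measurements — and shrinkage of the stage-1 slopes
attenuates it somewhat below the generator truth. Individuals with more
than two recordings contribute their first two (by date); stage 2 includes
identity only (no year term).

## Validation experiments and problem sizes

`songnorms.validation` (used by the tests and `scripts/acceptance.py`)
runs: a GLS conjugate oracle (100 songs, bivariate, 2000 i.i.d. posterior
draws); prior-moment recovery with zero observations (50,000 draws;
IW df = dim+6 so the analytic mean exists with small MC error);
fixed-effect calibration over 20 replicate studies of 60 males × 20 songs
(chains 26,000/1,000/25, i.e. 1000 retained); slope-variance recovery with
200 males × 40 songs (8,000/1,000/7); slope-repeatability recovery at
truth R = 0.5 with 40 males × 30 songs × 2 recordings, averaged over three
replicate cohorts (stage-2 repeated over 60 evenly spaced draw indices), plus a monotonicity sweep over recording-noise SDs
(0.10, 0.316, 0.80) and an 11-male cohort whose R interval must be wide
(width > 0.5); and syllable-type recovery on 150 songs with 10 planted
clusters. These experiments disable position missingness so the
generator's and the fit's z-standardizations coincide row-for-row, letting
fitted coefficients be mapped back to the generator scale exactly
(multiply by sd(y); add mean(y) to the intercept).

## Known limitations

* Bivariate models support exactly two traits; the trivariate extension
  (all three song traits jointly) is not implemented, matching the main
  analyses.
* Stage-2 repeatability treats posterior draws as data (see above); R is
  comparable across noise levels and cohorts, but is not a likelihood-exact
  ICC.
* The paper-faithful chain preset (510k iterations) is provided for
  fidelity but is slow at full scale; the validation experiments use the
  reduced chain lengths listed above, which retain the same 1000 draws.
* `gelman_rubin` requires ≥2 chains; the single-chain paper preset must be
  checked by trace inspection instead.
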
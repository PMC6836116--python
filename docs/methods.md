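# Methods

`latmask` re-implements, as a tested pipeline, the analysis of a two-group
lateral-masking experiment: 2AFC detection of a central vertical Gabor target
(4 cycles/degree) presented alone or between two collinear high-contrast
flankers at 1, 2, 3, 4, 6 or 12 carrier wavelengths, with seven target
contrasts between 0.0075 and 0.09 (Michelson proportion), 20 repetitions per
level, one block per condition.  The two observer groups are controls (n=31)
and migraine-with-aura (n=24).  Because no trial-level dataset was deposited
with the study, the package pairs the analysis with a synthetic-data
generator that reproduces the study design, so every statistical claim made
by the test suite is a claim about the method on data with the structure the
analysis assumes.

## Generative and analysis model

Trial outcome `y_ij ∈ {0,1}` of observer `i` at contrast `c` follows a
probit-link binomial mixed model:

    P(y_ij = 1 | b_i) = Φ(x_ij'β + z_ij'b_i),     b_i ~ N(0, Σ)

* `x` — fixed effects: intercept, contrast, group (control = reference,
  coded 0), group×contrast; the flanker model adds flanker distance (in
  wavelengths) and the three interactions contrast×distance, group×distance
  and group×distance×contrast (distance terms drop the baseline block).
* `z` = (1, c) — a random intercept and a random contrast slope per
  observer with unstructured 2×2 covariance Σ.
* No lapse/guess parameters: chance performance (0.5) corresponds to a
  linear predictor of zero, matching the analysis model rather than a
  0.5-floored 2AFC psychometric function.  A simulated observer with
  intercept 0 and slope 0 therefore performs exactly at chance.

Contrast levels are treated as Michelson proportions (0.0075–0.09).  The
printed percent signs on the levels would put them three orders of magnitude
below any plausible detection range, and the study-scale slope (≈29 probit
units per unit contrast) is only consistent with proportions.

Default generative parameters are the study-scale values
`β = (−0.5, 29.141, −0.391, 12.313)` and `Σ = diag(0.04, 16)` with group
sizes (31, 24).  The slope terms are the study's fitted baseline
coefficients; the intercept is not printed anywhere and is chosen so the
control 75% threshold (≈0.040) sits mid-range of the contrast levels; the
random-effect SDs (0.2 probit units for the intercept, 4 for the slope)
give observer-to-observer threshold variation of roughly ±15–20%,
a realistic spread for practiced psychophysical observers.  An optional
per-condition intercept offset lets the generator seed facilitation or
inhibition scenarios; by default flanker distance has no generative effect,
matching the study's null result for lateral-interaction differences.

## Estimation

The marginal likelihood integrates the 2-D random effect per observer:

    L(β, Σ) = ∏_i ∫ ∏_j Φ(η_ij)^{y_ij} (1−Φ(η_ij))^{1−y_ij} φ(b; 0, Σ) db

It is maximised directly (maximum likelihood, not REML):

* **Quadrature.** Adaptive Gauss–Hermite on a tensor grid, default 7 nodes
  per dimension.  Each observer's integrand is centred at its conditional
  mode (found by a vectorised Newton ascent; the probit Bernoulli
  loglikelihood is concave in η, so the inner problem is well behaved) and
  scaled by the inverse square-root of the negative Hessian there.
  `n_quad=1` is the Laplace approximation, used as the fast mode inside
  bootstrap loops.  On study-scale fits, raising the order from 5 to 15
  nodes moves the loglikelihood by less than 1e−4.
* **Parameterisation.** Σ = LLᵀ with L its Cholesky factor, entries
  unconstrained, so every iterate and the final estimate are PSD by
  construction.
* **Optimisation.** L-BFGS-B over (β, vech L) with finite-difference
  gradients; start values are the plain probit GLM for β and Σ₀ = 0.1·I.
  The relative-loglikelihood stopping tolerance is deliberately tight
  (1e−11): the plain-probit start estimates the *population-average* slope,
  which is attenuated relative to the conditional slope the mixed model
  estimates, and a looser tolerance (1e−8) measurably strands fits partway
  between the two (~0.5% slope attenuation, visible as bias across
  replicate simulations).  Convergence: optimizer success, with up to two
  restarts from the final point when the line search terminates abnormally
  (stationarity across restarts counts as convergence).  The exact Σ=0 optimum (a plain probit
  Newton fit) is always evaluated as a boundary candidate and returned when
  the interior search cannot beat it, which makes the fitted loglikelihood
  never fall below the plain-probit value.
* **Covariance.** Inverse observed information, by central-difference
  Hessian at the optimum over all parameters; the β block of the full
  inverse is reported as `cov_beta`.
* **Codings.** Trial-level (Bernoulli) rows and per-(observer, condition,
  contrast) binomial cells are both supported and give identical
  loglikelihoods and estimates; the binomial coding omits the additive
  log-binomial-coefficient constant so the two codings' loglikelihoods
  match exactly.  Binomial coding is the default (it is ~20× smaller for
  the study design).
* **Wald table.** t = estimate/SE with residual degrees of freedom
  (design rows − number of fixed effects).  The dof convention printed in
  the study is not derivable from the stated design, so the package
  documents its own convention and never asserts dof equality.

Identifiability note: with contrasts confined to (0.0075, 0.09), the
slope-variance component Σ₂₂ is only weakly identified (a slope deviation
of 1 changes the linear predictor by at most 0.09); its profile likelihood
is flat and the estimate scatters widely without harming the fixed-effect
estimates or thresholds.  This mirrors the design, not a defect of the
optimiser.

## Thresholds and the parametric bootstrap

The 75% threshold of a probit psychometric function with intercept `a` and
slope `m` is `T = (Φ⁻¹(0.75) − a)/m`; group thresholds use each group's
fixed-effect (population-average) curve.  Uncertainty follows the study's
parametric bootstrap: each of B samples (study scale B=1000; the test suite
and acceptance script use B=50–200, stated with each result)

1. draws per-observer (intercept, slope) pairs around each group's fitted
   values — by default spread with the fitted random-effects covariance Σ̂
   (a population of heterogeneous simulated observers); an alternative mode
   spreads them with the sampling covariance of the group's fixed effects,
   since the study's description admits either reading;
2. simulates binomial responses at the design's contrast levels through the
   probit link;
3. refits the same mixed model (optionally with Laplace refits, or with Σ
   pinned at zero when the fitted Σ̂ is zero);
4. recomputes each group's threshold.

The per-group SD over samples is the reported error.  Non-convergent refits
are dropped and counted; more than 20% dropped is a hard error.  The
two-sided group-difference p-value is `2·min(Pr(diff≤0), Pr(diff≥0))` over
the draws with the (k+1)/(B+1) continuity correction, so it is never exactly
zero.  In the zero-Σ regime this bootstrap SD agrees with the delta-method
SE of the threshold (gradient (−1/m, −T/m) applied to the fixed-effect
covariance) to within sampling noise, and the group-difference test holds
its nominal size.

## Facilitation profiles

Relative thresholds divide each flanker-condition threshold by the same
group's no-flanker baseline threshold; values < 1 are facilitation, > 1
inhibition (an optional tolerance band widens the "none" region around 1;
default 0, strict).  Normalisation is strictly within group.  Two estimation
modes: per-condition fits of the baseline-type model in each block (default,
matching how per-distance thresholds are usually derived in this paradigm)
or a single joint fit of the flanker model evaluated at each distance.
Relative-threshold SDs, when bootstrap samples are requested, scale the
condition threshold's bootstrap SD by the baseline point estimate (baseline
uncertainty is not propagated into the ratio).

## Stimulus rendering

Luminance in normalised units, background 0.5:
`L = 0.5·(1 + c·cos(2πfu + φ)·exp(−(u²+v²)/2σ²))` with u along the
modulation axis.  Display geometry defaults to 0.7 arcmin/pixel.  Envelope σ
defaults to one wavelength (0.25°) — the study does not print it, and this
is the classic choice in the collinear lateral-masking paradigm; flanker
contrast defaults to 0.6 ("high-contrast" is not quantified); carrier phase
defaults to cosine (even-symmetric).  All three are configurable.
Overlapping patches add in contrast-modulation space; a sum that would leave
the displayable range raises instead of clipping.  The measured Michelson
contrast of a rendered frame is the peak relative deviation `max|L/L0 − 1|`
(carrier amplitude at the envelope peak): the naive frame statistic
(Lmax−Lmin)/(Lmax+Lmin) under-reads a windowed grating because the Gaussian
envelope attenuates the nearest trough (by ~12% at σ = λ/2).

## Problem sizes in tests and the acceptance script

Simulation-backed checks use the study's group sizes (31 + 24) and design
throughout.  Replication counts are scaled for a desk-scale run: parameter
recovery uses 200 replicate experiments; bootstrap calibration uses 200 null
experiments at B=100 with zero-Σ (plain probit) refits — the regime where
the delta-method oracle is valid; profile checks use a 4-condition design.
All randomness flows from explicit seeds; identical seeds give bit-identical
tables, fits and bootstrap summaries.

## What the synthetic data do and do not show

The generator reproduces the design arithmetic, the probit-Bernoulli
response process and observer heterogeneity the analysis model assumes.  It
does not emulate lapses, learning or fatigue across blocks, serial
dependence between trials, finite display contrast resolution, or any
flanker effect unless seeded.  Passing tests therefore demonstrate that the
pipeline recovers what the analysis model represents — not that the model
is adequate for any particular real observer population.

## Known limitations

* Random effects are limited to (intercept, contrast slope) per observer;
  no crossed or higher-dimensional structures.
* Probit link only.
* Finite-difference outer gradients: fits are accurate to optimizer
  tolerance (~1e−3 relative in weakly identified covariance directions).
* The flanker-distance covariate enters linearly (as in the study's
  interaction model); no nonmonotone distance response is fitted, even
  though classic lateral masking shows one — per-condition fits cover that
  case.
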
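# Methods

## The task and its calculus

Each trial presents two lotteries ("wheels of fortune").  A wheel offers a
better outcome `x` and a worse outcome `y` (`x > y`, both in task points),
with `P(x) = p` shown as the angular size of a wheel segment.  After the
choice, *both* wheels spin, so the player always sees the factual outcome of
the chosen wheel and the counterfactual outcome of the unchosen one — the
full-feedback design that makes regret measurable.

Per wheel: `EV = p·x + (1−p)·y` and the probability-weighted spread
`SD = sqrt(p(x−EV)² + (1−p)(y−EV)²)`.  Per trial, three regressors drive
choice:

* `dEV = EV_L − EV_R` — relative value of the left wheel;
* `dSD = SD_R − SD_L` — relative risk, oriented so a positive coefficient
  means risk aversion (a riskier right wheel pushes toward the left);
* `AR = |y_R − x_L| − |y_L − x_R|` — anticipated regret, the difference of
  the two options' maximum possible regrets; a positive coefficient is
  regret aversion.  The absolute values are implemented exactly as printed
  in the source formula, with no rectification, even in configurations
  where an operand is negative.

Post-outcome emotion factors: experienced regret = counterfactual −
obtained; experienced disappointment = (unobtained outcome of the chosen
wheel) − obtained.  Because both share the obtained outcome, the two
factors are strongly correlated by construction (~0.6 in simulated data);
each rating-model fit reports this correlation, since it bounds how
separable the two effects can be.

The bonus payment converts points to GBP through the four anchors
(−200→0, −50→1.0, 50→1.5, 200→2.5).  The anchors are not collinear, so
"linear conversion" is implemented as piecewise-linear interpolation: exact
at every anchor, monotone in between.  Only anchor outcomes occur in the
default task, so the interpolation matters only for nonstandard point
values supplied on input.

## The generative model (synthetic subjects)

The simulator reproduces the study conditions: 50 subjects, 2×2
within-subject design (beneficiary: self/partner × audience:
present/absent), 48 trials per cell, one common stimulus list presented in
per-subject pseudorandom order, outcomes drawn from {−200, −50, 50, 200},
wheel probabilities on a 0.05 grid in [0.2, 0.8] (the grid keeps wheel
segments visually distinct and outcome spreads away from zero; the study
does not print its probabilities).  Stimulus lists are resampled until
each of dEV/dSD/AR spans both signs and |corr(dEV, AR)| < 0.95, so the
regressors are identifiable.

Choices follow a hierarchical logistic model: in each cell, subject *i*
uses coefficients `β_cell + b_i`, with `b_i ~ N(0, diag(τ²))` redrawn
independently per cell (matching the per-condition independent fits;
a switch makes them subject-constant across cells instead).  Defaults, in
logit units per point, control cell (self/absent):

| parameter | value | random SD τ |
|---|---|---|
| intercept | 0 | 0 |
| b_e (dEV) | 0.010 | 0.005 |
| b_sd (dSD) | −0.002 | 0.001 |
| b_r (AR) | 0.010 | 0.005 |

τ is half of each |β| component.  Condition offsets (chosen once to
reproduce the qualitative ordering the design is built to detect, since
the study prints no numeric coefficient values): audience-present adds
+0.004 to b_r and −0.002 to b_e; partner-beneficiary adds −0.002 to b_r
and +0.001 to b_sd.  These keep simulated P(left) mostly within [0.1, 0.9]
for the default gamble ranges.

Ratings are linear in the experienced factors plus Gaussian noise, rounded
to integers and clamped to the [−50, 50] response axis (a cursor on a
number line).  Default slopes are −0.06 (regret) and −0.10
(disappointment) per point with residual SD 10.  Note a deliberate
divergence from the real-data fit this mimics: published baseline slopes
of −0.25/−0.59 combined with this outcome alphabet would drive ~87% of
linear ratings past ±50 — the real response process is evidently not the
clamped linear rule — so the generator uses smaller slopes that keep
~87% of ratings *on* the axis (≈13% at the bounds).  Clamping-induced
censoring is accepted and attenuates fitted slopes by roughly 10–15%; it
is not modelled.  Switches disable clamping and rounding for exact
linear-recovery checks.

What the generator does **not** emulate: missing responses, reaction
times, sequential/order effects, any facial-expression channel, and the
true (unpublished) 48-item stimulus table — the generator reproduces its
statistical role, not the exact stimuli.  Passing tests therefore
establish that the pipeline recovers the truth of *this* generative
family, not that the published estimates are correct.

## Stage 1: mixed-effects logistic regression (choices)

Per cell: `logit P(left) = x_t β + z_t b_i` with identical fixed and
random designs (intercept + dEV + dSD + AR) and diagonal random-effect
covariance.  The source formula prints no intercept, but the reference
fitting function's default includes one; both fixed and random intercepts
are included by default and can be switched off.  The notational residual
term sometimes written in such formulas has no role for a Bernoulli
response and is not implemented.

Estimation is the Laplace approximation, in two stages:

* **Stage A (fast):** for trial variance parameters θ = log σ, β and all
  b_i are jointly maximized by a penalized Newton solver that exploits the
  block-arrow Hessian (one m×m block per subject, Schur complement for β);
  a box-constrained quasi-Newton (L-BFGS-B, finite-difference gradients)
  then optimizes θ alone.
* **Stage B (refinement):** quasi-Newton over (β, θ) jointly, with only
  the conditional modes of b profiled, so the objective sees the full
  dependence on β including through the log-determinant.  This is the
  surface glmer walks at nAGQ = 1; on a 50×48-trial cell the two agree to
  ~1e−5 on slope estimates and ~1e−4 in log-likelihood (the refinement
  routinely ends marginally *above* glmer's optimum).

Numerical choices: predictor columns standardized internally (results
mapped back); variance components parameterized as log-SDs and bounded in
[e⁻⁸, e³] on the standardized scale; inner Newton to gradient ∞-norm
1e−8 with step halving; outer tolerances ftol 1e−8/1e−9, gtol 5e−3 (A) /
2e−4 (B).  Non-convergence triggers one retry with a larger evaluation
budget — restarting from θ = 0 was tried and rejected, as it can land in
a collapsed-variance local basin.  Separation (a standardized slope
exceeding 15) triggers a ridge-stabilised refit (λ = 1e−3), flagged in
the diagnostics.

Wald SEs come from the Schur complement of the joint Hessian at the
optimum; BIC counts fixed effects plus variance components.  Per-subject
composite coefficients are β̂ + b̂_i (BLUE + BLUP); with β profiled at the
joint mode these average exactly to β̂, while at the nAGQ-1 optimum the
deviation is a fraction (≲0.5) of one SE.

The optional anticipated-disappointment regressor for BIC comparison is
defined here as `AD = (x_L − y_L) − (x_R − y_R)`, the difference of each
wheel's maximum possible experienced disappointment — the exact analogue
of how AR contrasts maximum possible regrets (the study's source for this
factor does not print a formula).

## Stage 1: linear mixed regression (ratings)

Per cell, ratings are regressed on experienced regret and disappointment
with a random intercept and independent random slopes (REML, via
statsmodels MixedLM).  Ratings are treated as continuous despite the
bounded integer scale, matching the analysis being reproduced; no
censoring model.  The factors are internally expressed per 100 points —
otherwise the slope variance components sit ~6 orders of magnitude below
the residual variance and the optimizer fails — and mapped back.
Fallback ladder on non-convergence: random intercept only, then pooled
OLS, each flagged.  BLUPs are computed directly as
`G Zᵢ' Vᵢ⁻¹ (yᵢ − Xᵢβ̂)`, which stays defined when a variance component is
estimated at zero.

Denominator degrees of freedom use a Satterthwaite-style approximation:
df_j = 2·Var(β̂_j)² / (g_j' C g_j), with g_j the numerical gradient of
Var(β̂_j) in the variance parameters and C the inverse observed REML
information (computed from this package's own REML evaluation at the
fitted parameters).  The exact df method behind the published fractional
df is unstated; this approximation reproduces fractional df of the same
character without claiming equivalence.  Values outside (2, N] signal a
near-singular information matrix and fall back to n_subjects − 1.

## Stage 2: repeated-measures ANOVA

Per coefficient (dEV, dSD, AR, b_reg, b_dis), a two-way within-subject
ANOVA over the 2×2 cells of per-subject composites.  With two levels per
factor, each F(1, n−1) is exactly the squared paired t of the
corresponding contrast (verified to 1e−10), so sum-of-squares "types"
coincide and sphericity is moot.  Effect size is partial eta squared,
SSn/(SSn+SSd) — the definition was confirmed against the published
table's own rows, which it reproduces to <0.001.  Its CI comes from
noncentral-F inversion (Steiger): the bounds are the noncentralities
placing the observed F at the (1±0.95)/2 quantiles, mapped through
η² = λ/(λ + DFn + DFd + 1); this reproduces the published intervals to
≤0.01 per bound.  Post-hoc contrasts are paired t tests within one level
of the other factor, reported as F = t².

## Calibration harnesses, and an honest caveat

`type1_simulation` and `power_simulation` run the entire chain (simulate →
per-cell mixed fits → coefficient extraction → ANOVA) hundreds of times.
The stage-2 ANOVA itself is exactly calibrated when fed the true
per-subject coefficients (empirical rate 0.042–0.055 at nominal 0.05 over
400 replicates).  The full two-stage procedure, however, is
**anticonservative under the default generative conditions**: BLUP
composites equal β̂_cell plus shrunken deviations, so the within-subject
error term sees only the shrunken between-subject spread while the
condition contrast carries the full sampling error of four independently
estimated β̂_cell.  When a random-effect SD is estimated at ~0 (routine
for the small default τ, e.g. τ_dSD = 0.001), every subject collapses onto
β̂_cell, the error SS vanishes, and F diverges.  Measured main-effect
rejection rates at nominal α = 0.05 run 0.2–0.9 depending on coefficient
and scale.  glmer shows the identical variance collapse on the same data,
so this is a property of the two-stage-with-BLUPs procedure, not of this
implementation; it sharpens the interpretation of any such analysis: the
procedure is trustworthy in the regime where between-subject spread is
well resolved (τ large relative to each subject's estimation SE), and its
F statistics for hard-shrunk coefficients should not be read as calibrated
tests.  The harnesses exist precisely to expose this; the power harness
(default audience offset +0.004 on b_r) shows power rising in n and
exceeding 0.8 at n = 50.

Simulation sizes used by the test suite: 100 replicates at 50×48 for
recovery; 500 replicates at 20 subjects × 24 trials for type-I rates;
50 replicates per point of the {10, 25, 50}-subject power curve.

## Known limitations

* Rating censoring is simulated but not modelled; fitted rating slopes are
  attenuated ~10–15% under default clamping.
* The OSF deposit of the original study is not fetched; external data
  enter only through an explicit column mapping, and no claim of numeric
  agreement with the published coefficient tables is made at desk scale.
* Random-effect covariance is diagonal by design; correlated random
  effects are out of scope.
* The two-stage type-I inflation described above is reported, not
  "fixed": the package reproduces the published procedure faithfully.
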
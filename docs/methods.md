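# Methods

This note documents the models, numerical conventions and design choices
behind `rarpipe`: what the synthetic cohort generator produces and why,
how the accelerometry and rhythm computations are defined at the edges,
and how the longitudinal models are parameterised. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## 1. The synthetic cohort generator

### Cohort structure

The default configuration emulates a five-wave post-treatment cohort:
268 participants enrolled, measured at 6 weeks, 6, 12, 24 and 60 months,
with marginal retention 268/254/214/138/77. Dropout is monotone and
completely at random: participant *i* draws one latent uniform *u_i* and
attends visit *j* iff *u_i* < *r_j*; because the retention fractions
*r_j* are non-increasing, the attended visits form a prefix, and the
marginal attendance probability at visit *j* is exactly *r_j*.

Covariates (age, sex, education, neoadjuvant therapy, adjuvant
chemotherapy; per-visit BMI, comorbidity class, stoma, smoking,
employment, alcohol, days since treatment) are drawn to match the
descriptive distributions of a survivorship cohort of this kind; they
are confounder *placeholders* — none of them causally enters the
outcome model by default, so adjusted and unadjusted analyses estimate
the same estimand in expectation.

### Minute-level count model

Each participant-visit carries a cosinor triple (M\*, A\*, φ\*) on the
arbitrary activity-count scale (population defaults 3.7 / 0.6 / 14.2 h;
the count calibration of real devices is unknown, so the scale is
treated as arbitrary and configurable). The expected count at minute
*t* of a day is

- waking: c(t) = M\* + A\*·cos(2π(t − φ\*)/24), modulated by the
  behavior-bout multiplier (below), which is renormalised to have
  exactly unit mean over each realised day so the cosinor curve remains
  the expected waking count;
- in bed: κ·c(t), with attenuation κ ∈ (0, 1];

multiplied by mean-one lognormal noise with log-SD σ (default 0.30).
Counts are therefore non-negative by construction. A configuration in
which A\* ≥ M\* is rejected (it would force a negative expected count).

### Behavior bouts

Waking time is partitioned into sedentary / standing / activity by an
alternating-renewal process: geometric bout lengths (default means
22 / 6 / 5 min) and jump probabilities proportional to
(target share)/(mean length). The jump chain's stationary shares only
approximate the targets, which is why the count modulation is
renormalised per realised day rather than per stationary expectation.
Relative count multipliers per state default to 0.8 / 1.3 / 3.5; after
normalisation with the default composition, activity minutes sit well
above and sedentary/standing minutes well below the intensity threshold,
so a noiseless day is classified back perfectly (tested).

### Embedded exposure effects and the dichotomy index inversion

`truth_effects` maps exposures to raw-scale slopes on mesor, amplitude,
acrophase and the dichotomy index. The per-visit truth value of each
affected parameter is *exactly linear* in the (realised) exposures given
the participant's latent baseline:

  θ\*_it = θ_i + Σ_e β_eθ (x_it,e − μ_e).

Consequently within-person demeaned regression of truth outcomes on
truth exposures recovers the embedded slopes to machine precision (the
package's tested interpretation of "truth-level exactness"); between-
person recovery is exact only up to the latent baselines, which are
needed to reproduce realistic cross-sectional SDs. Default slope
magnitudes correspond to standardized coefficients of about −0.59 SD
per 2 h/day sedentary time on the mesor (with outcome SDs 0.17 / 0.18 /
0.11 for mesor / amplitude / dichotomy index).

The dichotomy index cannot be set directly — it is a functional of the
whole count distribution — so the generator inverts it: given the linear
truth target I\<O\*, the in-bed attenuation κ is solved by bisection so
that the model-implied index

  I\<O(κ) = mean over in-bed minutes of P(κ·c(t)·LN < median_out)

equals the target, where median_out is the median of the waking count
mixture (computed by bisection on the exact mixture CDF of lognormals)
and LN is the mean-one lognormal noise. Truth targets are clipped to
[0.05, 0.995]; clipped rows are flagged (`dichotomy_clipped`) and
excluded from exactness checks.

R24 has no direct dial either; the truth panel records the model-implied
value Var_t(E[count(t)]) / (Var_t(E) + mean_t Var(count(t))), i.e. the
shared-profile variance over the total minute variance. This first-order
value ignores night-to-night bed-time jitter and bout autocorrelation,
so realised R24 scatters around it; no test asserts equality beyond a
loose Monte-Carlo band.

### Raw signal synthesis

Minute counts are rendered as a 25 Hz tri-axial signal: a 2 Hz sinusoid
on the anterior axis whose per-minute amplitude is the exact inverse of
the discrete SMA map (2 Hz × 60 s is an integer cycle count per epoch,
so the dynamic component has exactly zero epoch mean and the noiseless
count → signal → count round trip is exact to float precision — the
basis of the 1e-9 cosinor round-trip test). The static component
encodes posture: gravity on the longitudinal axis while upright, on the
anterior-posterior axis while sitting/lying or in bed. Device-physics
effects (orientation drift, temperature, sensor noise on the gravity
component) are deliberately not modelled.

Non-wear is a Poisson process of episodes (default 0.37/week — chosen so
that ~30% of weeks contain at least one episode and thus lose their R24,
matching the attrition level typical of the 7-valid-day rule) with
exponential durations (mean 2 h); injection only flags samples, never
alters them.

Randomness fans out from one seed through named `SeedSequence`
substreams keyed by (purpose, participant, visit, day), so enlarging the
cohort does not perturb existing participants and every artifact is
bit-reproducible.

## 2. Accelerometry conventions

- **Counts**: SMA per 1-min epoch, i.e. mean over samples of
  |ax|+|ay|+|az| of the gravity-removed signal, times a calibration
  constant (default 1). Gravity removal defaults to per-epoch mean
  subtraction: for epoch-aligned analysis this is exact, has no filter
  transients at posture transitions, and keeps the noiseless round trip
  exact. A 4th-order 0.25 Hz Butterworth high-pass (common actigraphy
  practice) is available as `gravity_mode="butterworth"`.
- **Posture**: thigh inclination of the per-epoch gravity vector;
  upright below 45° by default.
- **Intensity**: the count threshold standing in for 1.5 MET defaults to
  8.0 count units — a calibration constant shared between generator and
  classifier, since no published count equivalent exists for this device
  class. Waking epochs above the cut are physical activity regardless of
  posture; below the cut, upright → standing, recumbent → sedentary.
- **Edges and gaps**: trailing partial epochs are dropped, not padded;
  an epoch is non-wear when more than half its samples are flagged; a
  day is wear-complete only with 1440 labelled epochs and zero non-wear;
  a measurement is valid only with ≥ 4 wear-complete days including a
  weekend day (Saturday/Sunday by local calendar).
- **Bouts**: maximal runs of waking-sedentary epochs with length ≥ 30
  min; any other epoch, or a timestamp gap, breaks the run.

## 3. Rhythm parameters: numerical choices

- The cosinor is fitted per midnight-to-midnight calendar day on all
  1440 epochs including in-bed time (the dichotomy index is defined on
  the same 00:00–23:59 window; using one window keeps the parameters
  internally consistent). A flat day returns A = 0 with the acrophase
  flagged undefined. No log-transform is applied by default.
  Note the consequence, visible in the README example: in-bed
  attenuation lowers the fitted mesor below the generator's waking-curve
  M\* and inflates the fitted amplitude; the truth panel therefore also
  stores the model-implied fit of the full mean profile
  (`mesor_expected`, `amplitude_expected`, `acrophase_expected`) as the
  recovery reference.
- Dichotomy-index ties (count exactly equal to the out-of-bed median)
  count as *not* below, per the strict inequality in the definition.
- R24 is the lag-1440 Pearson autocorrelation of the pooled 7-day
  series (leading vs trailing 6-day segment, each with its own mean);
  per-day-pair averaging is available via `mode="pairwise"`. It is
  defined only when all seven days are wear-complete.
- Acrophase averaging across days uses the circular mean (the
  arithmetic mean is wrong at the midnight wrap).
- Standardization divides each outcome by the mean of its per-visit
  cross-sectional SDs, without centering; visits with < 2 observations
  are excluded from the divisor with a warning, and an all-equal outcome
  raises rather than dividing by ~0.
- Tertile boundaries are either empirical tertiles of the supplied
  sample (the pipeline default, pooled over all visits) or fixed
  reference bounds; fixed intervals are closed on the left, open on the
  right, last closed, and a value falling in a gap between printed
  bounds maps to the lower group. Values outside the outer bounds clamp
  to the nearest group.

## 4. Longitudinal models

- `MixedEffectsAssociation`: REML linear mixed model with a random
  intercept per participant; fixed effects are the exposure (already on
  its analysis unit: 2 h/day for sedentary exposures, 1 h/day otherwise)
  plus the a-priori confounder list. A random exposure slope is added
  iff a likelihood-ratio test on ML refits gives p < 0.05, using the
  50:50 χ²(1)/χ²(2) mixture appropriate for a variance component plus a
  covariance. The random-slope design uses a mean-centered copy of the
  exposure — [1, x − x̄] spans the same space as [1, x] but is far
  better conditioned (uncentered, the optimizer frequently stalls below
  the nested optimum; when a gradient fit still lands below the reduced
  model's likelihood, the model is refitted with a derivative-free
  search). Non-convergence of a slope model drops the slope with a
  warning; a constant exposure raises a rank-deficiency error. Missing
  data are handled complete-case per model.
- Inter/intra decomposition: B_i = person mean − grand mean, W_it =
  value − person mean; both enter one model and B_i + W_it + grand mean
  reconstructs the exposure exactly. The decomposed model's random
  slope, when selected, is on the within-person deviation.
- Acrophase tertiles: pooled multinomial logit over participant-visits
  with participant-clustered sandwich SEs ("longitudinal multinomial
  regression" is under-specified; a random-effects multinomial was
  judged out of proportion, and the pooled-robust choice is recorded in
  the result metadata). Refitting with tertile 2 as reference yields the
  3-vs-2 contrast. |coefficients| > 15 flag possible separation.
- Interaction tests: joint Wald test on the exposure × modifier block
  (ML fit); for categorical modifiers with p < α, per-level exposure
  effects are linear combinations of the main effect and interactions.
- Time-lag models re-pair exposure and covariates at visit *k* with the
  outcome at visit *k+1* (covariates taken at the exposure visit);
  participants without consecutive visits drop out.
- No multiple-testing correction is applied by default.

## 5. What the simulations do and do not establish

The panel-level simulator (`simulate_panel`) generates exposures with
separate between-person and within-person components and outcomes with
configurable between/within/lagged effects, a random intercept and
optional random slope. The test suite and acceptance script use it at
the cohort's size (268 × 5 visits with the default dropout) for: effect
recovery (200 replicates), 95% CI coverage (target band 90–98%),
type-I error (~5%), between/within separation (50 replicates per
direction), and time-lag attenuation under concurrent-only causation
(50 replicates). The raw-signal path is exercised end to end on a
40-participant, 3-visit demo cohort, twice, to verify byte-identical
outputs; these sizes are the package's chosen defaults for a desk-scale
check, not estimates of anything.

Passing these checks shows the estimators are correct *under the
generator's assumptions*: Gaussian person effects, MCAR monotone
dropout, lognormal minute noise that is independent across minutes and
days, no covariate confounding, exact self-reported bed times. Real
accelerometer cohorts violate all of these to some degree (autocorrelated
intra-day noise, informative dropout, misreported bed times, device
artefacts), so the tests validate the computation, not the
epidemiology.

## 6. Known limitations

- The MET-equivalent count threshold and the count calibration are
  conventions shared by generator and classifier, not physical
  calibrations.
- The model-implied R24 truth is first-order; no exact inversion is
  attempted.
- With heavy in-bed attenuation the fitted amplitude is dominated by the
  day-night contrast rather than the waking cosinor amplitude; analyses
  of amplitude on real data carry the same caveat.
- The multinomial model ignores within-person correlation in its point
  estimates (it is consistent under working independence; the clustered
  SEs account for the correlation).
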
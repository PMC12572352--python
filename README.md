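# rarpipe

Diurnal rest-activity rhythms (RAR) from thigh-worn accelerometry, with
longitudinal mixed-model associations — built around a synthetic cohort
generator with known ground truth.

## The scientific problem

After cancer treatment, a disrupted 24-h rest-activity rhythm — flat
daytime activity, restless nights, inconsistent timing from day to day —
is associated with fatigue and reduced quality of life. Epidemiological
cohorts quantify the rhythm from week-long tri-axial accelerometer wear
and ask whether time spent sedentary, standing, or physically active is
longitudinally associated with rhythm robustness. `rarpipe` implements
that full computation for researchers in actigraphy and cancer
survivorship epidemiology:

1. **Signal → epochs** (`rarpipe.accelerometry`): 25 Hz tri-axial signal
   is reduced to 1-minute activity counts via the signal magnitude area
   (SMA) of the gravity-removed signal; posture (thigh inclination) and
   an intensity threshold standing in for 1.5 MET classify each waking
   minute as sedentary, standing, or physical activity; uninterrupted
   sedentary runs ≥ 30 min form prolonged bouts. Days are valid only
   with 24-h wear; measurements only with ≥ 4 valid days including a
   weekend day.
2. **Epochs → rhythm parameters** (`rarpipe.rar`): per calendar day a
   single-harmonic cosinor

   y(t) = M + A·cos(2π(t − φ)/24) + e(t)

   gives the mesor *M*, amplitude *A*, and acrophase *φ* (decimal
   hours); the circadian quotient CQ = A/M; the dichotomy index
   I\<O = P(in-bed count < median out-of-bed count); and, for full
   7-valid-day weeks only, the 24-h autocorrelation R24 (lag-1440
   Pearson autocorrelation of the minute series). Daily values are
   averaged per visit (circular mean for φ), standardized by the mean of
   per-visit SDs, and acrophase is grouped into tertiles.
3. **Rhythm parameters → associations** (`rarpipe.longitudinal`):
   statsmodels-style model objects. `MixedEffectsAssociation` fits a
   confounder-adjusted linear mixed model (REML, random intercept, and a
   random exposure slope when a likelihood-ratio test on ML refits
   supports it) of each standardized outcome on each exposure —
   sedentary time per 2 h/day, all other behaviors per 1 h/day — and can
   split the effect into between-person and within-person components by
   person-mean centering. `MultinomialTertileModel` fits the acrophase
   tertile by pooled multinomial logit with participant-clustered robust
   SEs. Interaction (effect modification) tests and time-lag
   (exposure at visit k, outcome at visit k+1) models are included.
4. **Synthetic cohort** (`rarpipe.simulate`): because cohort data of
   this kind are not public, the package generates a full synthetic
   cohort — five post-treatment waves with monotone dropout, raw 25 Hz
   signal whose minute counts follow each participant's cosinor curve
   modulated by behavior bouts, in-bed attenuation and lognormal noise,
   self-reported bed logs and a covariate panel — with every true
   parameter recorded, so each downstream stage can be checked against
   known truth.

## Worked example

Simulate one synthetic day (mesor 3.7, amplitude 0.6, acrophase 14.2 h,
in-bed counts attenuated to 60%, 30% lognormal noise) and recover its
rhythm parameters:

```python
import numpy as np
from rarpipe import fit_cosinor_day, simulate_day_counts, dichotomy_index_day

in_bed = np.zeros(1440, bool); in_bed[:450] = True; in_bed[1395:] = True
counts, states = simulate_day_counts(
    3.7, 0.6, 14.2, in_bed,
    shares=np.array([0.70, 0.20, 0.10]),   # sedentary/standing/activity
    attenuation=0.6, sigma=0.3,
    rng=np.random.default_rng(42),
)
fit = fit_cosinor_day(counts)
print(fit.summary())
print("I<O =", round(dichotomy_index_day(counts, in_bed), 3))
```

```
Cosinor fit (n=1440 epochs)
  mesor         3.2216 counts
  amplitude     1.3115 counts
  acrophase    13.9145 h
  CQ            0.4071

I<O = 0.913
```

The fitted mesor sits below the generating 3.7 and the amplitude above
the generating 0.6 because the attenuated in-bed third of the day pulls
the 24-h mean down and deepens the day-night contrast that the
fundamental harmonic absorbs; the acrophase is recovered within minutes
of 14.2 h, and I\<O ≈ 0.91 reflects the strong day-night separation.

Fit the longitudinal association on a simulated panel (268 participants,
5 visits with the cohort's dropout, true slope −0.59 SD per exposure
unit):

```python
from rarpipe import simulate_panel, MixedEffectsAssociation
panel = simulate_panel(beta_between=-0.59, beta_within=-0.59, seed=1)
res = MixedEffectsAssociation(panel, "exposure", "outcome", ("C(sex)", "age")).fit()
print(res.summary())
```

```
Linear mixed model: outcome ~ exposure (+ confounders)
  observations 960, participants 268, converged=True
  random slope: no (LRT p=0.2807)
  overall beta   -0.622  95% CI (-0.710, -0.533)  p=4.07e-43
```

The estimate −0.622 (CI −0.710, −0.533) covers the true −0.59.

A full end-to-end run (simulate → process → rhythm parameters → models →
report) on the bundled demo cohort:

```bash
rarpipe run --out runs/demo --seed 1
```

which writes, under `runs/demo/`, the truth panel, visit exposures,
daily and measurement-level RAR tables, the analysis panel, a tidy
`model_results.csv` (one row per exposure × outcome × estimand), the
first-visit exposure × outcome Pearson correlation matrix, a manifest
with SHA-256 checksums, and `report.md` with per-visit descriptives and
truth-recovery diagnostics.

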
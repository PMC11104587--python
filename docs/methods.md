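# Methods

## The interruption model

Weekly screening-encounter counts are binned into Sunday-start weeks
(labeled by their Sunday) and modeled per group *i* and week *t* as
Poisson with a log-normal mixed log-mean:

    y_it ~ Poisson(lambda_it)
    log lambda_it = mu_it + H_t * beta_H + S_t' beta_S + eps_it
    eps_it ~ Normal(0, sigma_eps^2)
    mu_it = tau_it * beta_it + (1 - tau_it) * omega_it

The additive Gaussian noise on the log mean is the standard reading of a
"log-normal Poisson" and induces overdispersion; a configuration switch
(`ModelSpec.family = "negbin"`) collapses it into a moment-matched
negative binomial (dispersion `alpha = exp(sigma_eps^2) - 1`), which
removes one latent variable per group-week and is useful when many
refits are needed.

`beta_it` (undisturbed level) and `omega_it` (depressed level) are
independent Gaussian random walks per group. Holiday and seasonal effects
are shared across groups; everything else is group-specific. The seasonal
basis uses K = 2 annual sin/cos harmonics with period 52.1775 weeks, so
the basis is exactly one-year periodic on the week grid. The holiday
indicator flags any week containing New Year's Day, Memorial Day,
Independence Day, Labor Day, Thanksgiving, or Christmas, all placed by
statutory rule (no observed-day shifting — the week-level indicator makes
shifts immaterial).

### The interruption weight

`tau_it` mixes the two processes. It is pinned to 1 outside the
early-pandemic envelope (2020-03-01 to 2020-08-31) and inside it follows
a smooth pulse

    tau(t) = 1 - sigmoid((t - d0)/s) * sigmoid((d1 - t)/s)

with group-specific change points `d0` (onset, uniform over
[2020-03-01, 2020-04-15)) and `d1` (offset, uniform over
[2020-04-15, 2020-08-01]). Constraining the two dates to disjoint
calendar windows identifies which change point is which and rules out
label switching, while leaving the interruption timing data-driven.

**Ramp scale.** The ramp `s` is fixed at 0.08 weeks (about half a day).
The value is set by the geometry of a weekly grid: for the pulse to
switch from fully-on at one week label to fully-off at the next (as a
hard screening pause does), `s` must satisfy roughly `5.9 s < 1` week;
at `s = 0.5` the pulse cannot complete the transition between adjacent
weeks, so the depressed process is forced to track the *normal* level at
the transition weeks, the offset date drifts, and the
interruption-weighted sums get diluted by normal-volume weeks. At
`s = 0.08` the weight at the week labels adjacent to the change points is
within 0.002 of 0/1 and the estimator is consistent with a hard pause.
`s` remains configurable for sensitivity analysis.

### Priors and defaults

All constants are exposed on `ModelSpec`:

| parameter | prior / default | note |
| --- | --- | --- |
| `beta_H` | Normal(0, 1) | holiday effect (log scale) |
| `beta_S` (each) | Normal(0, 1) | harmonic coefficients |
| `beta_i0` | Normal(log mean first-year count, 1) | initial undisturbed level |
| `omega_i0` | Normal(beta-anchor − 3, 2) | weakly encodes a depressed start |
| `sigma_beta`, `sigma_omega` | half-Normal(0.2) | random-walk innovation SDs |
| `sigma_eps` | half-Normal(0.5) | log-mean noise SD |
| `d0`, `d1` | Uniform over their calendar windows | |
| K | 2 | annual harmonics |

### Sampling

The joint posterior is sampled by an in-package adaptive Hamiltonian
Monte Carlo sampler (leapfrog integration; dual-averaging step-size
adaptation toward 0.85 acceptance; a diagonal mass matrix re-estimated in
two warmup windows; leapfrog count jittered in [80%, 100%] of 64). The
model supplies the log-density and an analytic gradient, verified against
finite differences and against an independent term-by-term brute-force
density in the test suite.

Latent paths use the *centered* parameterization: with weekly counts in
the hundreds to thousands the likelihood pins the paths tightly, which is
exactly the regime where centered coordinates give well-conditioned
geometry (the non-centered form couples every innovation to every later
observation and forces tiny step sizes). Change points are sampled
through an interval-logit transform, scales through log transforms, with
the corresponding jacobians in the density.

Defaults are 4 chains of 1000 warmup + 1000 draws. Split R-hat and bulk
ESS (via arviz) are reported for the change points, scales, and holiday
effect. The innovation-scale posteriors are weakly identified when the
true path is nearly constant and can mix slowly; convergence gating in
the command-line runner therefore uses the decision-relevant quantities
(change points; the drop summaries), all of which reach R-hat < 1.05 in
the recovery tests.

### Posterior summaries

* **Counterfactual.** Per draw, `yhat` is a Poisson draw from the full
  model and `yhat_o` from the undisturbed process alone (`tau` forced to
  1) with the *same* holiday, seasonal, and noise terms — so
  `ydiff = yhat_o - yhat` isolates the interruption. Where the two means
  coincide (all weeks outside the envelope) the same Poisson variate is
  used and `ydiff` is exactly zero. Inside the window the random-walk
  posterior for `beta` is informed by both sides of the gap, giving
  Brownian-bridge interpolation of the no-interruption trend.
* **Missed visits.** Per draw, `n_missed_i = sum_t (1 - tau_it) ydiff_it`
  and `pct_i = 100 * sum_t (1 - tau_it) ydiff_it / sum_t (1 - tau_it)
  yhat_o_it`; point estimates are posterior means, intervals the
  2.5th/97.5th draw percentiles with the upper bound truncated at 100%.
* **Window report.** A week is called interrupted when
  `P(1 - tau_t > 0.5) >= 0.975`; the report gives the earliest and latest
  such week, or "no interruption detected" when none qualifies. The
  (0.5, 0.975) pair is exposed as configuration; the high probability bar
  makes the null report robust (a diffuse `tau` posterior never crosses
  it).
* **Group contrast.** The equality test uses the vector of posterior-mean
  differences of group drop percentages from a reference group and the
  posterior covariance of those per-draw differences:
  `c' Sigma^-1 c ~ chi-square(G-1)` under equality. A singular covariance
  falls back to a pseudo-inverse with a warning and the rank reported.

## The synthetic-data generators

**Weekly counts.** Counts are Poisson with log-mean `log(baseline) +
harmonics + holiday + log(1 - w_t * drop) + Normal(0, sd)`, where the
window weight `w_t` is 1 between the injected window dates and ramps
linearly over `ramp_weeks` outside them (0 = hard pulse, the default —
the acute pause was a hard administrative event). Defaults mirror the
study conditions: baseline 1000 encounters/week, K = 2 harmonics with
log-amplitudes (0.06, 0.08, 0.03, 0.02), holiday factor 0.85,
overdispersion SD 0.05, window 2020-03-15..2020-05-24, drop fraction
0.988, grid 2019-01-06..2021-12-26. A full stop (drop = 1) floors the
suppressed mean at 0.1/week so the log scale stays finite. The generator
reports noise-free expected paths and the window-weighted true percent
drop as recovery targets.

The generator shares the model's harmonic basis; a third harmonic can be
added in configuration for misspecification checks. It does **not**
emulate EHR quirks, deaths, moves, out-of-system care, or a changing
eligible population — recovery results say the estimator inverts its own
generating process at realistic volumes, not that real extracts are this
clean.

**Encounter tables.** Weekly series are expanded to one row per
encounter (dates uniform within the week, covariates from a configurable
demography mix, birth dates consistent with the drawn age band), so the
whole pipeline — CSV reading, age/quartile derivation, week binning,
cohort construction — runs end to end; binning the expanded table
reproduces the generating weekly series exactly.

**Attrition cohorts.** One row per woman with race, age-band, and
income-quartile covariates. A designated *primary outcome* follows an
exact conditional-logistic law: `logit P = logit(p_ref) + sum of log ORs`
of the woman's non-reference levels. The remaining 2020–2022 presence
pattern is completed with covariate-free allocation rates so the four
outcomes keep their partition structure (annual + biennial + triennial +
no-return = 1). Injecting *all four* outcomes as exact marginal logistic
laws simultaneously is generally infeasible — `any` is the union of the
other three, so the system is over-determined — hence the primary-outcome
design; each recovery experiment injects the outcome it fits.

All generators draw from named substreams of a single integer seed
(`SeedSequence([seed, stream])`; MCMC chains use a disjoint stream
family), so every stage is independently and jointly reproducible.

## Cohort and covariate rules

* Age is completed years at the encounter; bands 40–49 … >= 80; women
  under 40 at the encounter are excluded before analysis.
* Income quartiles are computed over the catchment *zip list* (zip-level,
  unweighted), rank-based with ties assigned to the lower quartile;
  unmapped zips are Missing and Missing-covariate rows are dropped from
  models only.
* Cohort covariates come from the woman's first baseline-year encounter;
  same-day duplicate encounters are collapsed (and counted in the log).
* The race/ethnicity analysis drops the sparse levels (NH AI/AN, NH
  Other Pacific Islander, NH Other, NH Two or more, Missing); the
  age-group analysis retains them. All cohort women remain in every
  outcome model (outcome 0 when the defining years lack encounters).
* The 2018 sensitivity cohort starts at 2018-06-02 and defines only the
  annual (return-in-2019) outcome, with 2018 covariates.

## Problem sizes and runtime

The recovery tests fit the full study-size grid (156 weeks) with 4
chains x 1000/1000 for the single-group experiment and 2 x 800/800 for
the four-group experiment; the multi-seed replicate checks (null
calibration, equal-drop test) use a 65-week grid with 2 chains x 400/300,
sizes at which the decision quantities are already stable. The acceptance
script uses 4 x 1000/1000 throughout and completes in about five minutes
on one CPU.

## Known limitations

* The innovation-scale posteriors (`sigma_beta`, `sigma_omega`) mix
  slowly when the true level is nearly constant; the decision quantities
  are insensitive to this, but scale estimates from short chains should
  not be over-read.
* The counterfactual credible bands on clean synthetic data are narrower
  than would be expected on real extracts, whose week-to-week variation
  exceeds the generator's log-normal noise.
* A single interruption window per group; no spline seasonality; no
  covariate-rich designs; forecasting beyond the observed grid is out of
  scope.
* The Wald-type group test relies on approximate posterior normality of
  the drop percentages; with very small groups (tens of encounters per
  week) the percentages pile up near 100 and the test is conservative.
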
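# screengap

Bayesian interrupted time-series and attrition analysis of weekly
screening-mammogram encounter counts.

When the COVID-19 pandemic paused routine breast-cancer screening in
spring 2020, two questions mattered to health systems: *for how long and
by how much* did screening encounters drop, and *which women did not come
back* afterwards. `screengap` implements both analyses as a tested,
reusable pipeline for encounter-level EHR extracts, together with a
synthetic-data module that emulates such an extract with known injected
truths — so the entire pipeline runs, and is validated, without access to
protected health data.

## The models

**Interruption model.** Weekly encounter counts `y_it` (group *i*, week
*t*, Sunday-start weeks) follow a log-normal Poisson state-space model:

    log E[y_it] = mu_it + H_t * beta_H + S_t' beta_S + eps_it,
    eps_it ~ Normal(0, sigma_eps^2),
    mu_it  = tau_it * beta_it + (1 - tau_it) * omega_it,

where `H_t` flags weeks containing one of six federal holidays, `S_t` is
a K=2 annual sin/cos harmonic basis, and `beta_it` and `omega_it` are
group-specific Gaussian random walks: the *undisturbed* and the
*depressed* mean process. The averaging weight `tau_it` is 1 outside an
early-pandemic envelope (2020-03-01 to 2020-08-31) and dips toward 0
inside a smooth pulse bounded by two continuous change points, the onset
constrained to [2020-03-01, 2020-04-15) and the offset to
[2020-04-15, 2020-08-01], both estimated from the data. Fitting is by
adaptive Hamiltonian Monte Carlo with analytic gradients.

From the posterior, the package produces the counterfactual
posterior-predictive series `yhat_o` (the undisturbed process alone — the
random-walk posterior bridges the pre- and post-pandemic trends), the
draw-wise difference `ydiff = yhat_o - yhat`, interruption-weighted
missed-visit totals and percentages with 95% credible intervals
(2.5th/97.5th draw percentiles), the first/last interrupted week per
group, and a posterior Wald-type chi-square test for equality of group
drops.

**Attrition model.** Among women screened in a baseline year, four binary
return outcomes are defined by calendar-year encounter presence — annual
(2020), biennial (2021 not 2020), triennial (2022 not 2020/21), any
(2020–22) — and adjusted odds ratios by race/ethnicity (reference NH
White) and age group (reference 50–59) are estimated by logistic
regression with Wald 95% confidence intervals, adjusting for zip-level
median-income quartile (and age category when race is the exposure). A
2018-baseline sensitivity analysis asks whether return patterns predate
the pandemic.

## Worked example

```python
from screengap import synthetic_data as sd, posterior_inference as pi
from screengap.interruption_model import ModelSpec

cfg = sd.CountSimConfig(
    groups={"overall": 300.0},          # 300 encounters/week baseline
    drop_fraction=0.95,                 # injected 95% drop
    date_range=("2019-06-02", "2021-06-27"),
    seed=42,
)
series, truth = sd.simulate_weekly_counts(cfg)

fitted = pi.fit(series, ModelSpec(),
                pi.MCMCSettings(chains=2, warmup=500, draws=500, seed=42))
cf = pi.counterfactual(fitted, seed=42)
row = pi.missed_visits(cf).table.iloc[0]
window = pi.estimate_window(fitted).iloc[0]
```

This prints (via the surrounding script):

```
weeks: 109  total encounters: 29268
injected drop: 95.0%  window: 2020-03-15 .. 2020-05-24
recovered drop: 94.2% (95% CrI 92.9 to 95.4)
missed encounters (posterior mean): 3015
interrupted weeks: 2020-03-15 .. 2020-05-24
```

The model recovers the injected 95% drop (the credible interval covers
it) and identifies the interrupted weeks exactly, from counts alone.

A command-line interface wraps the same stages for shell use:

```bash
screengap simulate  --seed 3 --out sim/
screengap fit-counts --counts sim/weekly_counts.csv --seed 3 --out fit/
screengap attrition --encounters sim/encounters.csv --income sim/income_lookup.csv --out attr/
screengap report    --predictions fit/weekly_predictions.csv --out fig.png
```

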
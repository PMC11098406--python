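# chronosim

An individual- and population-level Monte Carlo microsimulation of chronic
vascular disease and dementia over the adult life course.

Policy questions about blood-pressure (BP) management — *does treating BP more
aggressively, earlier, reduce late-life dementia, or mostly delay it? how do
stroke prevention and longer survival trade off?* — cannot be answered by
feasible randomized trials, because the outcomes take decades to accrue.
`chronosim` is built for researchers who study these questions by simulation:
it advances a synthetic cohort of US-like adults (18+, free of stroke, MI and
dementia at entry) in annual cycles through

1. **Risk-factor dynamics** — each time-varying factor (SBP, DBP, lipids,
   HbA1c, BMI, waist, physical activity, smoking, medications) is advanced by
   a lagged regression model: next value = linear predictor over demographics,
   the lagged factor value, the lagged mean (over all prior waves) and the
   other lagged factors, plus a residual draw. SBP/DBP are modelled on the
   log scale. All models are declarative JSON specs evaluated by one pathway.
2. **ASCVD events** — 10-year atherosclerotic cardiovascular disease risk from
   a revised Pooled-Cohort-Equations-style stratified model, annualized as
   p₁ = 1 − (1 − p₁₀)^(1/10), drawn Bernoulli; events split into stroke vs MI
   by an inverse-logit partition model; case fatality 0.15 (stroke) / 0.13 (MI).
3. **Cognition and dementia** — global cognitive performance (GCP, 1 point =
   0.1 SD) follows a mixed model (fixed effects + person-level random
   intercept + residual); annual all-cause dementia risk comes from a
   proportional-hazards model (hazard ratios: 0.927 per GCP point, 1.108 per
   year of baseline age, 1.214 Black vs White, ...) with an exp-quadratic
   baseline cumulative hazard H₀(t) = exp(a + bt + ct²) − exp(a) that can be
   recalibrated by grid search to a target age-incidence curve.
4. **Non-CV mortality** — a variant-selected logistic model (separate variant
   for persons with dementia) over age, age², demographics and mean vascular
   factors, with grid-search recalibration of the age/age² coefficients
   against a life table.
5. **Treatment** — each added antihypertensive lowers SBP/DBP by 5.5/3.1 mmHg
   and the lowered BP feeds forward through the dynamics. Because the
   observational BP–risk gradient understates trial effects, an end-of-wave
   population-level recalibration *rolls back* excess ASCVD events among
   treated individuals (selection weighted by inverse untreated risk) until
   realized events match the trial-anchored expectation
   (RR 0.79/medication for stroke, 0.87 for MI).
6. **QALYs** — age-based utilities times condition multipliers (0.67 incident
   stroke, 0.88 incident MI, 0.9 subsequent years; dementia 0.80 − 0.01·k at
   k years since onset).

Runs are bit-reproducible: every stochastic component draws from a named
`(master_seed, stream, wave)` substream in stable-person-id order, so results
are invariant to person storage order and toggling one component never
perturbs another.

## Worked example

```python
import chronosim as cs
from chronosim.population import PopulationConfig
from chronosim.reporting import incidence_report

cfg = cs.SimulationConfig(
    population=PopulationConfig(n=50_000, start_year=1999),
    horizon=10, master_seed=1,
)
res = cs.run(cfg)
print(res.snapshots[["wave", "alive", "strokes", "mis",
                     "dementia_onsets", "non_cv_deaths", "mean_qaly"]])
print(incidence_report(res.population))
```

prints (abridged):

```
 wave  alive  strokes  mis  dementia_onsets  non_cv_deaths  mean_qaly
    1  49413      193  204              136            530   0.923445
    2  48862      180  192              140            504   0.910134
   ...
   10  44136      196  207              117            583   0.797631

  kind  stratum  rate    lo    hi  crude  events
stroke      all 381.7 363.7 399.8  421.3  1998.0
stroke nh_black 489.2 429.6 548.8  568.2   302.0
    mi      all 347.7 330.3 365.1  410.4  1946.0
```

Each snapshot row is one annual wave: survivors, reported (non-rolled-back)
strokes/MIs, dementia onsets, non-CV deaths, and the mean QALY accrued that
year. The incidence report gives crude and age-standardized rates per 100,000
person-years (US 2000 standard million weights) with 95% CIs, overall and by
race — the age-standardized Black-vs-White stroke excess visible above is
driven by the partition model's race contrast and the risk-factor
distributions. Absolute rates depend on the packaged illustrative coefficient
sets, which are inputs, not fitted ground truth (see `docs/methods.md`).

The same machinery is scriptable from the shell:

```bash
chronosim run --seed 1 --out out/
chronosim experiment add-one-med --seed 1 --n 100000 --out rr.json
chronosim calibrate-mortality --seed 1 --out calib.json
chronosim calibrate-dementia  --seed 1 --out calib_dem.json
```

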
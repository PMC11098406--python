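# Methods

This note documents the model, its assumptions, the defaults and why they
were chosen, what the synthetic cohort does and does not emulate, and the
numerical choices that matter when extending or auditing the package.

## Model structure

`chronosim` is an annual-cycle Monte Carlo microsimulation. Each simulated
person carries static demographics (sex, race/ethnicity, 5-level education),
per-wave series of vascular risk factors, biometrics, behaviors, medications
and cognition, and an outcome history. There is no interaction between
individuals; the single population-level operation is the treatment-effect
recalibration described below. Rules are applied in a fixed order each wave:

1. risk factors update (from a frozen snapshot of the prior wave);
2. the treatment strategy applies;
3. cognition (GCP) updates at the new factor levels;
4. ASCVD events are assigned at the updated factor levels, with fatality;
5. dementia onset is drawn for alive, dementia-free persons;
6. non-CV death is drawn for survivors;
7. population-level treatment recalibration rolls back excess events;
8. QALYs accrue.

A fatal CV event short-circuits steps 5–6 in that wave. Dementia and death
are absorbing. The dementia draw is deliberately placed after ASCVD and
before non-CV mortality; the ordering is fixed in the engine, not
configurable, so results are comparable across runs. A person can acquire
dementia and a nonfatal ASCVD event in the same wave; only death is
exclusive.

## Regression-spec evaluation

Every linear predictor is evaluated through one pathway: a JSON
`RegressionSpec` (family linear/logistic, coefficients including an
intercept, residual mean/SD, optional log-outcome transform, and per-covariate
resolution kinds). Residuals are Normal(mean, sd): the minimal
distribution consistent with storing only the first two moments; the draw
site is isolated so a heavier-tailed choice is a one-line change. The schema
is strict — unknown keys are rejected — because a silently ignored
misspelled coefficient is the dominant failure mode of coefficient-file
plumbing. Covariate names encode resolution (`lag_`, `lagmean_`, `log_`
prefixes; `age_squared`; indicator names), so a single resolver serves the
dynamics, partition, mortality and cognition models.

### Why snapshot-then-commit matters

Next-wave values of *all* factors are computed from the committed state of
wave *t* and appended atomically. Updating factors sequentially within a
wave would leak same-wave values into covariates and make results depend on
factor iteration order; a test verifies that registering the factor models in
reverse order changes nothing.

## Synthetic cohort

The generator stands in for survey initialization. Continuous factors are
drawn through a Gaussian copula (configurable correlation matrix, validated
positive semi-definite) over configurable marginals (normal or lognormal,
clipped to physiologic ranges); categorical factors come from configurable
frequencies; the antihypertensive count is driven by a latent copula column
so medication use correlates with age (ρ=0.5) and SBP (ρ=0.35). Default
means (age 45.9, 51.7% female, BMI 28.5, race mix 68/12/14/6%) are anchored
to published survey summaries for face validity; the remaining moments and
the correlation structure are plausible values, i.e. configuration rather
than ground truth.

What the synthetic cohort does **not** emulate: survey weights and design
effects, item missingness/imputation, cohort effects across entry years
(`start_year` only labels the calendar), in/out-migration, and any joint
distributional detail beyond second moments plus the configured categorical
mixes. Tests passing against this cohort therefore validate the *mechanisms*
(dynamics, event assignment, calibration, rollback, accounting), not
US-population point estimates.

## Default coefficient sets

The paper-derived constants in the package are: dementia-model hazard ratios
(0.927/GCP point, 0.999/slope unit, 1.108/year of age, 1.1 female, education
contrasts 1.032/1.088/0.919/0.797, 1.214 Black vs White), case fatality
(0.15/0.13), treatment effects (5.5/3.1 mmHg; RR 0.79/0.87 per medication)
and the QALY multipliers. All other coefficient files — risk-factor
dynamics, the stroke-vs-MI partition, non-CV mortality, the GCP fixed
effects, and the PCE-style risk strata — are **illustrative inputs** with the
documented structure, authored for stationarity and realism:

- dynamics models use lag weight 0.70 + lagged-mean weight 0.28; cross-factor
  and demographic coefficients are specified as *equilibrium effects* and
  scaled by (1 − 0.70 − 0.28) so the long-run mean shift equals the intended
  effect (with persistence ρ, a raw coefficient's equilibrium effect is
  amplified by 1/(1−ρ); authoring in equilibrium units avoids accidental
  drift);
- residual SDs are ≈ one fifth of the cross-sectional SD, giving stationary
  dispersion near the baseline marginals;
- the PCE-style strata use identical treated/untreated SBP coefficients
  (0.018/mmHg). The published model's treated-SBP coefficient partly encodes
  confounding by indication; reusing it in the untreated-counterfactual
  evaluation would manufacture a spurious direct treatment effect larger than
  the trial target, which the one-sided rollback could not correct.

Replace any of these with fitted coefficients by pointing `model_dir` /
loader paths at your own JSON files.

## ASCVD events

Ten-year risk is annualized as 1 − (1 − p₁₀)^(1/10) (constant-hazard
conversion; `annualization="linear"` gives p₁₀/10). The stroke-vs-MI
partition is evaluated at lagged covariates, matching the lag convention of
its source model, while the event draw itself uses the just-updated factors.
At most one ASCVD event per person-year. Persons with an ASCVD history are
partitioned by the same spec (a history-conditional spec can be registered in
its place; the published history-specific coefficients are not available).

## Dementia hazard and its calibration

The baseline cumulative hazard is H₀(t) = exp(a + bt + ct²) − exp(a): an
exp-quadratic, chosen because it guarantees H₀(0) = 0, positivity, and
monotonicity while b + 2ct ≥ 0, and inverts in closed form (a quadratic in
t), which the parameter-recovery experiment exploits. Defaults
(a = −3.06, b = 0.10259 = ln 1.108, c = 0) give a reference-profile
(age 75, GCP 50) annual hazard of ≈ 0.005 rising consistently with the age
hazard ratio, so attained-age incidence tracks an exponential doubling curve
(default target: I₀ = 0.0015/person-year at 65, doubling every 5.1 years;
both the curve and the anchor are configuration). Continuous covariates are
centered at references (GCP 50, age 75) so the baseline refers to an
interpretable profile.

The GCP slope covariate is realized change, (GCP_t − GCP₀)/t, recomputed each
wave. Under-40 persons are protected by the hazard itself (their linear
predictor is tiny), not an artificial age gate.

The engine's annual probability 1 − exp(−[H₀(t+1) − H₀(t)]·e^lp) is exactly
the grouped version of the continuous hazard (a test asserts this). The
parameter-recovery experiment (`cox_recovery_experiment`) simulates
*continuous* times by inversion and refits with lifelines: fitting a Cox
partial likelihood to heavily tied annual times would bias hazard ratios
toward the null purely through the ties approximation, so the continuous
inversion is the faithful recovery design.

Baseline-hazard recalibration is a grid search over (a, b, c): each candidate
runs a reduced simulation under the same master seed (making the search
deterministic) and the summed squared deviation of attained-age incidence
(5-year bands) from the target curve is minimized. It can be disabled, in
which case the configured parameters pass through untouched.

## Non-CV mortality and its calibration

Mortality uses a logistic person-year model with two variants selected by
dementia status; absent published dementia-specific coefficients, the
dementia variant defaults to the no-history spec plus a configurable +1.5
log-odds offset. The age/age² grid search mirrors the dementia one:
age-specific all-cause death probabilities are computed in 1-year bins,
sparse bins (<50 person-years) merged upward, and squared deviation from the
life table minimized. The packaged life table is a synthetic
Gompertz–Makeham stand-in (qx = 0.0008 + 2·10⁻⁵·e^{0.095·age}, terminal qx
= 1 at 110) for the national tables a real analysis would supply; the engine
also forces death at `max_age` (110), which guarantees `until_all_dead`
termination.

## Treatment and rollback recalibration

Strategies add medications once or every wave (optionally restricted by an
eligibility predicate); each added medication lowers SBP/DBP by 5.5/3.1 mmHg
at the application wave, and later waves inherit the effect through the
dynamics (that is the life-course assumption: the treatment's cognitive and
dementia effects are mediated entirely through BP; cognition is never
recalibrated directly).

Rollback, per event kind per wave: among treated persons alive at wave
start, the trial-anchored expectation is E_target = Σᵢ p_untreated,ᵢ ·
rr^{medsᵢ} (rr applied multiplicatively per medication). The deficit
E_real − E_target is stochastically rounded (floor + Bernoulli of the
fraction — expectation-matching, the minimal unbiased rule) and that many
events among treated event-havers are rolled back, sampled without
replacement with probability ∝ 1/p_untreated, so the highest-risk treated
persons are least likely to lose their events. Rolled-back fatal events
restore the person to life; rolled-back events are excluded from all
reporting and QALYs (QALY accrual runs after recalibration for exactly this
reason). A rolled-back fatal event's skipped same-wave dementia/mortality
draws are not re-run; the person resumes normally the next wave.

**The untreated counterfactual.** p_untreated is recomputed each wave, never
cached. From the first strategy application the population carries a shadow
untreated SBP/DBP series, advanced through the *same* dynamics specs with
the *same* residual substreams — under common random numbers this reproduces
the untreated trajectory exactly, so E_target stays aligned with a usual-care
arm run under the same seed. (A simple "add back 5.5 mmHg" correction
remains as fallback; it over-states untreated risk once the carried-forward
effect decays below the nominal lowering and measurably weakens the MI-side
rollback.) Known limitation: rollback is one-sided — events can be retracted
but never added — so waves in which realized events undershoot the target
cannot be compensated; the realized MI relative risk sits ~0.02 above its
0.87 anchor in the two-arm experiment, and the stroke RR ~0.01–0.02 below
0.79.

## QALYs

Base utility is 1.0 to age 40, linearly declining to 0.70 at 90 (flat
after) — a configurable stand-in for a published age-utility table.
Condition multipliers: stroke 0.67 incident / 0.90 subsequent, MI 0.88 /
0.90, dementia max(0.80 − 0.01k, floor). Multiple conditions combine
multiplicatively (configurable to minimum). The wave of death accrues 0,
avoiding double counting against the fatality timing; the baseline wave
accrues normally.

## Randomness and reproducibility

Seeding: `SeedSequence([master_seed, crc32(stream), wave])` per named
component per wave. Per-person variates are generated over the original
cohort's id span and indexed by a stable person uid, so (a) storage/iteration
order cannot affect results, (b) toggling one stochastic component leaves
every other component's draws untouched, and (c) two arms of an experiment
under one seed share their random numbers, which both sharpens RR contrasts
and makes the shadow-BP counterfactual exact. Rollback candidate lists are
sorted by uid for the same reason.

## Reporting conventions

Person-years: one full year per wave a person is alive at wave start (death
or event year still counts 1), consistent with annual granularity.
Age-standardized rates use the US 2000 projected standard million
(config-replaceable); bands with zero person-years are excluded with a
warning and the weights renormalized. CIs are exact Poisson below 100 events,
normal approximation above.

## Problem sizes used in the shipped analyses

The acceptance script and test suite use: 100,000 fatality draws; the
two-arm experiment at n = 100,000, 5-year horizon, 15 replicates; hazard
recovery at n = 100,000 over a 20-year horizon; calibration
self-consistency at n = 3,000 over 15 waves with 3-point grids. These sizes
put Monte-Carlo error well inside each check's tolerance (e.g. 3 binomial
SEs at 100,000 draws is ±0.34 percentage points on the stroke fatality
fraction) while keeping a full run to minutes on one CPU.

## Known limitations

- All shipped behavioral/vascular coefficient files are illustrative; results
  at default settings demonstrate mechanism, not US estimates.
- Medication-count dynamics are a monotone add-one-per-wave logistic rule;
  counts never decrease and drug classes are not distinguished.
- No costs, no adherence, no stroke subtypes, no MCI state, no migration.
- Hispanic and "other" race contrasts in the dementia model are 1.0 (no
  published contrast); dementia-specific mortality is an offset, not a fitted
  variant.
- The rollback mechanism is one-sided (see above) and makes persons
  non-independent within a wave, which is why replicate-level (not
  person-level) variability is reported for treatment effects.
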
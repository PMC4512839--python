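# Methods

## Model structure

The model follows a cohort of hypertensive adults aged 25–64 at entry
(2014) for 37 annual cycles (to 2050). Eight sex × 10-year-band cohorts are
simulated independently; individuals occupy one of four living states —
*well* (hypertension, no CVD history), *history of MI*, *history of
angina*, *history of stroke* — or one of two absorbing states (*CVD death*,
*non-CVD death*). Each cycle executes, in order:

1. **Insurance assignment.** Bernoulli with the scenario's cohort insured
   fraction; redrawn every year by default, or drawn once at entry and held
   in the continuous-coverage variant.
2. **Treatment assignment.** Bernoulli given insurance status. The insured
   treatment probability is per sex and constant across age (0.590 men,
   0.680 women, published); the uninsured probability varies by cohort and
   is calibrated (below).
3. **Event occurrence.** At most one incident event per person-year, drawn
   from competing annual CHD and stroke probabilities. If their sum exceeds
   1 after adjustments the pair is renormalised with a logged warning.
   Incident CHD events split into MI / stable angina / unstable angina by
   an age–sex mix. Persons with a CVD history face history-multiplied
   probabilities (×2.0 after MI or stroke, ×1.8 after angina) and remain at
   risk of new events every year; all incident events, including recurrent
   ones, are tallied.
4. **Case fatality.** One-year death probability by event type, age band,
   insurance status and prior history.
5. **Background mortality.** Event-free survivors face an annual non-CVD
   death probability by sex and single year of age.
6. **Ageing and history update.** Survivors carry acquired histories
   forward; the reported state is the most recent event's state, with
   same-year dominance stroke > MI > angina. Individuals age past 64 and
   remain in simulation until death or the horizon.

There is no half-cycle correction, no within-year event timing, and no new
entrants; deaths are removed at each year end.

### Two modes, one cycle

The stochastic mode realises every step as individual draws over
`n_persons` simulated people per cohort (default 100,000; a run setting,
rescaled to cohort size at reporting). The expectation mode propagates the
6-state occupancy vector through exactly the same transition probabilities,
marginalising the insurance and treatment draws (in the
continuous-coverage variant it mixes the two conditional chains with fixed
insurance status). Because every transition is linear in occupancy, the
expectation mode is the exact mean of the microsimulation and is used as
its oracle in tests; it is deterministic and independent of `n_persons`.

## Event probabilities

Ten-year risks come from sex-specific Cox-form equations
`1 − s0^exp(lp − lp_mean)` with log-linear predictors over age, systolic
blood pressure (separate coefficient under treated blood pressure), total
and HDL cholesterol, smoking and diabetes. The general-CVD coefficient sets
are transcribed exactly from the published risk-function tables and verify
against the published worked example (10.48% for a 61-year-old smoking
woman, SBP 124 untreated, TC 180, HDL 47). Disease-specific (CHD, stroke)
equations reuse the covariate coefficients with baseline survivals split so
that small-risk CHD:stroke proportions match the sex-specific shares of
baseline events in the published outcome table (men 76.3% CHD, women
60.6%); this split is labelled assumed. Ages above the validated range
(74) are clamped before evaluation, logged once per process.

Ten-year risks convert to annual probabilities by the constant-hazard rule
`1 − (1 − p10)^(1/10)`, isolated in one function so it can be swapped. Each
cohort's annual probability schedule is the mean annual risk over a fixed
seeded sample of 2,000 synthetic profiles, rescored at each year's age;
treatment multiplies the annual probability by an age-band relative risk
(CHD 0.75–0.87, stroke 0.60–0.75, transcribed from blood-pressure-lowering
trial meta-analyses, attenuating with age).

## Parameters and provenance

Every block of the default `ParameterSet` carries one of three labels:

- **published** — printed in the source study's tables: the age-band cohort
  sizes (total 54,697,510), the insured treatment probabilities, and the
  treatment-rate/outcome tables bundled in `htnsim.tables`.
- **transcribed** — taken from the cited literature by the implementer:
  risk-function coefficients, treatment relative risks, the CHD event mix,
  NHANES-like risk-factor summaries.
- **assumed** — set here with a documented rationale, because the source
  study's full input appendix is not available.

Key assumed values and their rationale:

- **Sex split of the age bands** (female shares 0.4338 / 0.4836 / 0.4832 /
  0.5337): fitted by least squares from the published male/female/total
  treatment-rate rows, whose totals are convex combinations of the sex
  rows.
- **Baseline insured fractions** (0.71 / 0.76 / 0.81 / 0.86 by age band):
  consistent with published uninsurance surveys of nonelderly adults.
  Given these and the published rates, the uninsured treatment probability
  per cohort and the partial-expansion insured fraction per cohort are
  *calibrated* by inverting the treatment-rate mixture rule, so the
  computed per-sex treatment-rate table reproduces the published one
  exactly (the published band-total cells are themselves rounded
  inconsistently by up to 0.05 points and are matched to rounding slack).
- **Case fatality**: insured first-event values rising with age (MI
  0.04→0.32, stroke 0.06→0.38, angina 0.01→0.08), uninsured ×1.4, prior
  history ×1.5, capped at 0.95.
- **Background mortality**: Gompertz–Makeham curves per sex approximating
  US life-table all-cause mortality net of the CVD share.
- **History risk multipliers** (2.0 / 1.8 / 2.0): secondary-prevention
  populations face roughly doubled event rates.
- **Race blocks** (white/black/Hispanic cohort sizes and insured
  fractions) and the **prehypertension block** (53 million additional
  adults, SBP 120–139, lower treatment probabilities) parameterise the
  stratified and sensitivity analyses.

## Synthetic population

The generator emulates NHANES-2011–2012-like joint risk-factor
distributions per sex × age band: truncated normals for systolic blood
pressure (window [140, 230] mm Hg for hypertensive cohorts, [120, 140) for
prehypertensive), total cholesterol ([100, 400] mg/dL) and HDL
([20, 120]), Bernoulli smoking and diabetes, independent within a cell
given age and sex (the within-cell covariance of real survey data is not
reproduced, and survey weights, item nonresponse and measurement error are
not modelled). Passing tests therefore demonstrate correctness of the
machinery on a population with the right marginal structure, not fidelity
to any particular survey wave. Generation is seeded and bit-reproducible.

## Uncertainty analysis

Each replication adds a zero-mean normal perturbation to every cohort's
annual CHD and stroke probabilities (cohort-level, one draw per
cohort × disease per replication), truncated into [0, 1] when applied. The
default scale is the standard error of the cohort-mean annual probability
across the synthetic profile sample — an honest stand-in for unpublished
scale estimates, labelled assumed. Intervals are 2.5th/97.5th percentiles
over replications (default 1,000); the point estimate is the unperturbed
run. Replications draw from independent child streams spawned from the
master seed, so results do not depend on evaluation order.

## Numerical choices

- Expectation-mode conservation (living + dead = initial mass) holds to
  float roundoff (asserted at 1e-9 over 37 years); stochastic counts are
  conserved exactly.
- Per-10,000 denominators are initial cohort sizes, not person-years.
- Rounding for display is half-away-from-zero and applied only at render
  time; all arithmetic (differences, percent changes) uses unrounded
  internals.
- Competing-probability renormalisation and risk-function age clamping are
  each logged once per process.
- Problem sizes used by the shipped checks: 100,000 persons/cohort for
  stochastic-versus-expectation comparisons (5-year horizon on the default
  set), 100 Monte Carlo replications in the acceptance suite with the full
  1,000 available through the API and CLI.

## Known limitations

- **Absolute outcome levels are not calibrated.** With the reconstructed
  risk inputs, lifetime per-10,000 event counts are substantially higher
  than the source study's printed rates (e.g. baseline CHD ≈ 6,700 vs
  ≈ 2,000 per 10,000); recurrent events are tallied and the general-CVD
  risk function is split rather than disease-fitted. Relative scenario
  effects are directionally consistent. The reporting arithmetic
  (aggregation, differences, percent changes) reproduces the published
  tables exactly.
- **Survival selection can locally break monotonicity.** Averting fatal
  events extends survival, and survivors keep accruing (recurrent) events.
  In the highest-risk cohort (men 55–64) universal coverage raises
  cumulative CHD by a few parts per million relative to baseline, even
  though every per-year event probability is lower. The population-level
  scenario ordering (universal ≤ partial ≤ baseline for CHD, stroke, and
  CVD deaths) is unaffected.
- **Continuous coverage shows no extra benefit in this structure.** With
  insurance drawn once and held, treatment still redrawn annually, and
  treatment acting as a per-year multiplicative relative risk, holding
  coverage polarises the population; the never-insured arm suffers more
  early fatal events and the measurable benefit of expansion is truncated
  (persistent-coverage benefits come out at 95–98% of annual-redraw
  benefits). Producing the larger continuous-coverage benefits reported in
  the source literature would require an additional mechanism (e.g.
  adherence compounding across insured years) that is deliberately not
  invented here.
- No blood-pressure dynamics (treatment acts on event probabilities, not
  on measured SBP), no cholesterol or diabetes treatment, no migration or
  new cohort entrants, no state-level (expansion vs non-expansion state)
  geography, and no cost or QALY outcomes.
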
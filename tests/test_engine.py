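"""The state-transition engine: cycle semantics, both modes, conservation,
determinism, and the expectation-mode oracle."""

import dataclasses

import numpy as np
import pytest

from htnsim import (
    HealthState,
    PersonState,
    built_in_scenarios,
    derive_health_state,
    run_cohort,
    simulate_year,
)
from htnsim.engine import (
    Population,
    RiskSchedule,
    assign_insurance,
    assign_treatment,
    build_risk_schedule,
    weighted_merge,
)


# --- health-state derivation ------------------------------------------------

def test_no_histories_is_well():
    p = PersonState(current_age=40, cohort_id="c")
    assert derive_health_state(p) == HealthState.WELL


def test_most_recent_event_determines_state():
    p = PersonState(current_age=40, cohort_id="c")
    p.add_event("mi", 2016)
    p.add_event("stroke", 2020)
    assert derive_health_state(p) == HealthState.HX_STROKE
    p.add_event("stable_angina", 2024)
    assert derive_health_state(p) == HealthState.HX_ANGINA


def test_same_year_dominance_stroke_over_mi_over_angina():
    p = PersonState(current_age=40, cohort_id="c")
    p.add_event("mi", 2018)
    p.add_event("stroke", 2018)
    assert derive_health_state(p) == HealthState.HX_STROKE
    q = PersonState(current_age=40, cohort_id="c")
    q.add_event("unstable_angina", 2018)
    q.add_event("mi", 2018)
    assert derive_health_state(q) == HealthState.HX_MI


def test_dead_persons_never_transition():
    p = PersonState(current_age=40, cohort_id="c", alive=False,
                    cause_of_death="cvd")
    with pytest.raises(ValueError):
        p.add_event("mi", 2020)
    assert derive_health_state(p) == HealthState.DEAD_CVD


# --- insurance and treatment assignment -------------------------------------

def test_full_coverage_insures_everyone(tiny):
    scenario = built_in_scenarios(tiny)["expansion-universal"]
    pop = Population.initial(tiny.cohorts[0], 1000)
    assign_insurance(pop, scenario, np.random.default_rng(0))
    assert pop.insured.all()


def test_half_coverage_fraction_within_binomial_bound(tiny):
    scenario = built_in_scenarios(tiny)["baseline"]  # p = 0.5
    pop = Population.initial(tiny.cohorts[0], 10_000)
    assign_insurance(pop, scenario, np.random.default_rng(1))
    assert abs(pop.insured.mean() - 0.5) < 0.015


def test_persistent_mode_holds_the_initial_draw(tiny):
    scenario = dataclasses.replace(
        built_in_scenarios(tiny)["baseline"], persistence="persistent")
    pop = Population.initial(tiny.cohorts[0], 5000)
    rng = np.random.default_rng(2)
    assign_insurance(pop, scenario, rng)
    first = pop.insured.copy()
    for _ in range(5):
        assign_insurance(pop, scenario, rng)
        assert np.array_equal(pop.insured, first)


def test_treatment_fraction_converges_to_insured_probability(params):
    cohort = next(c for c in params.cohorts if c.sex == "female")
    pop = Population.initial(cohort, 50_000)
    pop.insured[:] = True
    assign_treatment(pop, params, np.random.default_rng(3))
    assert abs(pop.treated.mean() - 0.680) < 0.01


def test_zero_treatment_probability_never_treats(tiny):
    pop = Population.initial(tiny.cohorts[0], 1000)
    assign_treatment(pop, tiny, np.random.default_rng(4))
    assert not pop.treated.any()


# --- one simulated year ------------------------------------------------------

def _zero_schedule(cohort, horizon=1):
    return RiskSchedule(cohort_id=cohort.cohort_id,
                        p_chd=np.zeros(horizon), p_stroke=np.zeros(horizon))


def test_no_risk_no_mortality_changes_nothing_but_age(tiny):
    cohort = tiny.cohorts[0]
    scenario = built_in_scenarios(tiny)["baseline"]
    pop = Population.initial(cohort, 1000)
    before = pop.state.copy()
    tallies = simulate_year(pop, tiny, scenario, _zero_schedule(cohort),
                            np.random.default_rng(5))
    assert np.array_equal(pop.state, before)
    assert pop.year_index == 1
    assert all(v == 0 for v in tallies.values())


def test_certain_event_and_fatality_kills_every_well_person(tiny):
    certain = dataclasses.replace(
        tiny,
        fixed_annual_probabilities={
            c.cohort_id: {"chd": 1.0, "stroke": 0.0} for c in tiny.cohorts
        },
        case_fatality=dataclasses.replace(
            tiny.case_fatality,
            table={k: 1.0 for k in tiny.case_fatality.table}),
    )
    cohort = certain.cohorts[0]
    scenario = built_in_scenarios(certain)["baseline"]
    result = run_cohort(cohort, scenario, certain, mode="stochastic",
                        n_persons=500, seed=6, horizon=1)
    assert result.cumulative("chd") == 500
    assert result.cumulative("cvd_death") == 500
    assert result.living[1, int(HealthState.DEAD_CVD)] == 500


def test_one_year_run_reproduces_simulate_year(tiny):
    cohort = tiny.cohorts[0]
    scenario = built_in_scenarios(tiny)["baseline"]
    schedule = build_risk_schedule(cohort, tiny)
    result = run_cohort(cohort, scenario, tiny, mode="stochastic",
                        n_persons=2000, seed=7, schedule=schedule, horizon=1)
    pop = Population.initial(cohort, 2000)
    tallies = simulate_year(pop, tiny, scenario, schedule,
                            np.random.default_rng(7))
    assert result.cumulative("mi") == tallies["mi"]
    assert result.cumulative("cvd_death") == tallies["deaths_cvd"]


def test_tallies_add_over_disjoint_half_populations(tiny):
    """The tally of a merged run equals the sum of the half-runs' tallies
    (tallies are sums of individual outcomes)."""
    cohort = tiny.cohorts[0]
    scenario = built_in_scenarios(tiny)["baseline"]
    schedule = build_risk_schedule(cohort, tiny)
    halves = [run_cohort(cohort, scenario, tiny, mode="stochastic",
                         n_persons=1500, seed=seed, schedule=schedule)
              for seed in (11, 12)]
    merged = weighted_merge(halves, [1.0, 1.0])
    assert merged.initial_size == 3000
    for measure in ("chd", "stroke", "cvd_death", "other_death"):
        assert merged.cumulative(measure) == pytest.approx(
            sum(h.cumulative(measure) for h in halves))
    assert np.array_equal(merged.living,
                          halves[0].living + halves[1].living)


# --- full runs: conservation, determinism, oracle ----------------------------

def test_stochastic_conservation_exact_in_counts(params):
    cohort = params.cohorts[0]
    scenario = built_in_scenarios(params)["baseline"]
    result = run_cohort(cohort, scenario, params, mode="stochastic",
                        n_persons=5000, seed=8, horizon=10)
    for t in range(result.horizon + 1):
        assert result.living[t].sum() == 5000
    deaths = result.deaths["cvd"] + result.deaths["other"]
    living_counts = result.living[:, :4].sum(axis=1)
    assert np.array_equal(living_counts[:-1] - deaths, living_counts[1:])


def test_expectation_conservation_to_float_roundoff(params):
    cohort = params.cohorts[3]
    scenario = built_in_scenarios(params)["expansion-partial"]
    result = run_cohort(cohort, scenario, params, mode="expectation")
    for t in range(result.horizon + 1):
        assert result.living[t].sum() == pytest.approx(1.0, abs=1e-9)


def test_identical_seeds_give_bit_identical_runs(params):
    cohort = params.cohorts[2]
    scenario = built_in_scenarios(params)["baseline"]
    schedule = build_risk_schedule(cohort, params, horizon=5)
    a, b = (run_cohort(cohort, scenario, params, mode="stochastic",
                       n_persons=20_000, seed=99, schedule=schedule,
                       horizon=5)
            for _ in range(2))
    for k in a.events:
        assert np.array_equal(a.events[k], b.events[k])
    assert np.array_equal(a.living, b.living)


def test_expectation_mode_ignores_n_persons(params):
    cohort = params.cohorts[1]
    scenario = built_in_scenarios(params)["baseline"]
    schedule = build_risk_schedule(cohort, params, horizon=5)
    a = run_cohort(cohort, scenario, params, schedule=schedule, horizon=5)
    b = run_cohort(cohort, scenario, params, schedule=schedule, horizon=5,
                   n_persons=12345, seed=1)
    for k in a.events:
        assert np.array_equal(a.events[k], b.events[k])


def test_multi_year_closed_form_on_tiny_fixture(tiny):
    """With event probability 0.1 (all MI), fatality 0.5, no background
    mortality and history multiplier 1, the alive fraction decays by factor
    0.95/year and events are 0.1 x alive: cumulative events over 3 years are
    0.1 x (1 + 0.95 + 0.95^2) = 0.28525."""
    three = dataclasses.replace(tiny, horizon_years=3)
    scenario = built_in_scenarios(three)["baseline"]
    result = run_cohort(three.cohorts[0], scenario, three,
                        mode="expectation")
    expected_events = 0.1 * (1 + 0.95 + 0.95 ** 2)
    assert result.per_10k("chd") == pytest.approx(1e4 * expected_events,
                                                  abs=1e-9)
    assert result.per_10k("cvd_death") == pytest.approx(
        1e4 * expected_events / 2, abs=1e-9)


def test_stochastic_matches_expectation_oracle_on_tiny(tiny):
    scenario = built_in_scenarios(tiny)["baseline"]
    n = 100_000
    expect = run_cohort(tiny.cohorts[0], scenario, tiny, mode="expectation")
    stoch = run_cohort(tiny.cohorts[0], scenario, tiny, mode="stochastic",
                       n_persons=n, seed=13)
    for measure in ("chd", "cvd_death"):
        e = expect.per_10k(measure)
        s = stoch.per_10k(measure)
        se = 1e4 * np.sqrt(e / 1e4 * (1 - e / 1e4) / n)
        assert abs(s - e) < 3 * se


def test_scenarios_without_treatment_effect_coincide(tiny):
    """With relative risks of 1 and insurance-independent case fatality,
    the insurance mix cannot change expectation-mode outcomes."""
    neutral = dataclasses.replace(
        tiny,
        treatment=dataclasses.replace(
            tiny.treatment,
            insured={k: 0.5 for k in tiny.treatment.insured},
            uninsured={k: 0.5 for k in tiny.treatment.uninsured},
        ),
        med_effect=dataclasses.replace(
            tiny.med_effect,
            rr_chd={k: 1.0 for k in tiny.med_effect.rr_chd},
            rr_stroke={k: 1.0 for k in tiny.med_effect.rr_stroke},
        ),
    )
    runs = {
        name: run_cohort(neutral.cohorts[0], scenario, neutral,
                         mode="expectation")
        for name, scenario in built_in_scenarios(neutral).items()
    }
    base = runs["baseline"]
    for other in (runs["expansion-partial"], runs["expansion-universal"]):
        for k in base.events:
            assert np.allclose(base.events[k], other.events[k], atol=1e-12)
        assert np.allclose(base.deaths["cvd"], other.deaths["cvd"],
                           atol=1e-12)


def test_higher_treatment_scenario_never_worse_on_tiny(tiny):
    """More coverage -> more treatment -> fewer events and CVD deaths, on
    the short-horizon fixture where survival selection cannot accrue."""
    treated = dataclasses.replace(
        tiny,
        treatment=dataclasses.replace(
            tiny.treatment,
            insured={k: 0.6 for k in tiny.treatment.insured},
            uninsured={k: 0.1 for k in tiny.treatment.uninsured},
        ),
        horizon_years=1,
    )
    runs = {
        name: run_cohort(treated.cohorts[0], scenario, treated,
                         mode="expectation")
        for name, scenario in built_in_scenarios(treated).items()
    }
    for measure in ("chd", "cvd_death"):
        assert runs["expansion-universal"].per_10k(measure) <= \
            runs["expansion-partial"].per_10k(measure) <= \
            runs["baseline"].per_10k(measure)
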
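"""The state-transition engine.

Each cohort advances one simulated year at a time through a fixed cycle:

1. insurance assignment (Bernoulli; redrawn annually or held, per scenario),
2. treatment assignment (Bernoulli given insurance status),
3. at most one incident event, drawn from competing CHD/stroke annual
   probabilities (renormalised with a logged warning if they exceed 1),
4. one-year case fatality for the event,
5. background non-CVD mortality for event-free survivors,
6. history/state update and ageing.

Two modes share this cycle structure. Stochastic mode realises every step as
individual-level draws over ``n_persons`` simulated people. Expectation mode
propagates state-occupancy fractions deterministically through the same
transition probabilities (marginalising the insurance/treatment draws) and
serves as the independent oracle for the stochastic mode; its results do not
depend on ``n_persons`` or on a random seed.

Annual event probabilities come from a per-cohort :class:`RiskSchedule`:
the mean 10-year Framingham risk of a synthetic cohort profile sample,
rescored each year at the cohort's advancing age and converted to an annual
probability, or fixed per-cohort constants when the parameter set supplies
them (small fixtures).
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from .parameters import ParameterSet, CohortSpec
from .population import generate_profile_arrays
from .risk import annual_probability, ten_year_risk_arrays
from .scenarios import ScenarioSpec

logger = logging.getLogger(__name__)


class HealthState(IntEnum):
    WELL = 0
    HX_MI = 1
    HX_ANGINA = 2
    HX_STROKE = 3
    DEAD_CVD = 4
    DEAD_OTHER = 5


LIVING_STATES = (HealthState.WELL, HealthState.HX_MI, HealthState.HX_ANGINA,
                 HealthState.HX_STROKE)

#: state acquired after a non-fatal event of each kind
EVENT_STATE = {
    "mi": HealthState.HX_MI,
    "stable_angina": HealthState.HX_ANGINA,
    "unstable_angina": HealthState.HX_ANGINA,
    "stroke": HealthState.HX_STROKE,
}

#: case-fatality table key for each incident event kind
EVENT_FATALITY_TYPE = {
    "mi": "mi",
    "stable_angina": "angina",
    "unstable_angina": "angina",
    "stroke": "stroke",
}

CHD_SUBTYPES = ("mi", "stable_angina", "unstable_angina")
EVENT_KINDS = CHD_SUBTYPES + ("stroke",)

#: same-year dominance order used when deriving a state from histories
_DOMINANCE = {"stroke": 3, "mi": 2, "angina": 1,
              "stable_angina": 1, "unstable_angina": 1}
_HISTORY_STATE = {"stroke": HealthState.HX_STROKE, "mi": HealthState.HX_MI,
                  "angina": HealthState.HX_ANGINA,
                  "stable_angina": HealthState.HX_ANGINA,
                  "unstable_angina": HealthState.HX_ANGINA}


@dataclass
class PersonState:
    """One simulated individual (object-level view).

    ``histories`` is an append-only list of ``(event, year)`` pairs; the
    reported health state is derived from it by recency, with the same-year
    dominance order stroke > MI > angina.
    """

    current_age: float
    cohort_id: str
    histories: list[tuple[str, int]] = field(default_factory=list)
    insured: bool = False
    treated: bool = False
    alive: bool = True
    cause_of_death: str | None = None

    def add_event(self, event: str, year: int) -> None:
        if not self.alive:
            raise ValueError("dead persons never transition")
        self.histories.append((event, year))


def derive_health_state(person: PersonState) -> HealthState:
    """WELL if no histories, else the state of the most recent event
    (same-year ties broken by stroke > MI > angina)."""
    if not person.alive:
        return (HealthState.DEAD_CVD if person.cause_of_death == "cvd"
                else HealthState.DEAD_OTHER)
    if not person.histories:
        return HealthState.WELL
    best = max(person.histories,
               key=lambda ev: (ev[1], _DOMINANCE[ev[0]]))
    return _HISTORY_STATE[best[0]]


# ---------------------------------------------------------------------------
# risk schedules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RiskSchedule:
    """Untreated annual CHD/stroke probabilities per simulated year."""

    cohort_id: str
    p_chd: np.ndarray
    p_stroke: np.ndarray

    def probabilities(self, t: int,
                      offsets: dict[tuple[str, str], float]) -> tuple[float, float]:
        pc = self.p_chd[t] + offsets.get((self.cohort_id, "chd"), 0.0)
        ps = self.p_stroke[t] + offsets.get((self.cohort_id, "stroke"), 0.0)
        return (float(np.clip(pc, 0.0, 1.0)), float(np.clip(ps, 0.0, 1.0)))


def build_risk_schedule(cohort: CohortSpec, params: ParameterSet,
                        horizon: int | None = None,
                        n_profiles: int = 2000,
                        schedule_seed: int = 0) -> RiskSchedule:
    """Cohort-average annual event probabilities at each simulated age.

    A fixed synthetic profile sample is drawn once (seeded), then rescored
    at each year's age; ages past the risk equations' validated range are
    clamped inside the scoring step.
    """
    horizon = params.horizon_years if horizon is None else horizon
    fixed = params.fixed_annual_probabilities.get(cohort.cohort_id)
    if fixed is not None:
        return RiskSchedule(
            cohort_id=cohort.cohort_id,
            p_chd=np.full(horizon, fixed.get("chd", 0.0)),
            p_stroke=np.full(horizon, fixed.get("stroke", 0.0)),
        )
    seed = np.random.SeedSequence(
        entropy=schedule_seed,
        spawn_key=(zlib.crc32(cohort.cohort_id.encode()),),
    )
    arrays = generate_profile_arrays(cohort, n_profiles, params.population,
                                     np.random.default_rng(seed))
    p_chd = np.empty(horizon)
    p_stroke = np.empty(horizon)
    bp_treated = np.zeros(n_profiles, dtype=bool)
    for t in range(horizon):
        age = np.full(n_profiles, float(cohort.start_age + t))
        for disease, out in (("chd", p_chd), ("stroke", p_stroke)):
            cs = params.risk_coefficients.get(disease, cohort.sex)
            ten = ten_year_risk_arrays(
                cs, age, arrays["systolic_bp"], bp_treated,
                arrays["smoker"], arrays["total_cholesterol"],
                arrays["hdl_cholesterol"], arrays["diabetes"],
            )
            out[t] = annual_probability(float(np.mean(ten)))
    return RiskSchedule(cohort_id=cohort.cohort_id, p_chd=p_chd,
                        p_stroke=p_stroke)


def build_schedules(params: ParameterSet,
                    cohorts: tuple[CohortSpec, ...] | None = None,
                    horizon: int | None = None, n_profiles: int = 2000,
                    schedule_seed: int = 0) -> dict[str, RiskSchedule]:
    cohorts = params.cohorts if cohorts is None else cohorts
    return {
        c.cohort_id: build_risk_schedule(c, params, horizon=horizon,
                                         n_profiles=n_profiles,
                                         schedule_seed=schedule_seed)
        for c in cohorts
    }


# ---------------------------------------------------------------------------
# run results
# ---------------------------------------------------------------------------

@dataclass
class RunResult:
    """Per-year event and death tallies for one cohort run.

    ``events[kind][t]`` is the number of incident events of ``kind`` in
    simulated year ``t``; ``living[t]`` is the start-of-year-``t`` population
    by state (row ``horizon`` is the final population), in persons for
    stochastic runs and in fractions of one initial person for expectation
    runs. ``initial_size`` is the simulated denominator.
    """

    cohort_id: str
    start_year: int
    horizon: int
    events: dict[str, np.ndarray]
    deaths: dict[str, np.ndarray]
    living: np.ndarray  # shape (horizon + 1, 6)
    initial_size: float
    cohort_size: int
    mode: str

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.start_year + self.horizon)

    def cumulative(self, measure: str) -> float:
        """Cumulative count over the horizon of "chd", "stroke",
        "cvd_death", "other_death", or a single event kind."""
        if measure == "chd":
            return float(sum(self.events[k].sum() for k in CHD_SUBTYPES))
        if measure == "stroke":
            return float(self.events["stroke"].sum())
        if measure == "cvd_death":
            return float(self.deaths["cvd"].sum())
        if measure == "other_death":
            return float(self.deaths["other"].sum())
        return float(self.events[measure].sum())

    def per_10k(self, measure: str) -> float:
        return 1e4 * self.cumulative(measure) / self.initial_size


def weighted_merge(results: list[RunResult],
                   weights: list[float]) -> RunResult:
    """Linear combination of runs with identical shape (used to mix the
    insured/uninsured sub-populations of persistent-coverage expectation
    runs, and to merge split stochastic populations with weights 1)."""
    first = results[0]
    events = {k: sum(w * r.events[k] for r, w in zip(results, weights))
              for k in first.events}
    deaths = {k: sum(w * r.deaths[k] for r, w in zip(results, weights))
              for k in first.deaths}
    living = sum(w * r.living for r, w in zip(results, weights))
    return RunResult(
        cohort_id=first.cohort_id, start_year=first.start_year,
        horizon=first.horizon, events=events, deaths=deaths, living=living,
        initial_size=sum(w * r.initial_size
                         for r, w in zip(results, weights)),
        cohort_size=first.cohort_size, mode=first.mode,
    )


# ---------------------------------------------------------------------------
# stochastic microsimulation
# ---------------------------------------------------------------------------

@dataclass
class Population:
    """Vectorised person arrays for one cohort."""

    cohort: CohortSpec
    state: np.ndarray      # HealthState codes, int8
    insured: np.ndarray    # bool
    treated: np.ndarray    # bool
    year_index: int = 0
    insurance_drawn: bool = False

    @classmethod
    def initial(cls, cohort: CohortSpec, n: int) -> "Population":
        return cls(cohort=cohort,
                   state=np.zeros(n, dtype=np.int8),
                   insured=np.zeros(n, dtype=bool),
                   treated=np.zeros(n, dtype=bool))

    @property
    def n(self) -> int:
        return self.state.size

    @property
    def alive(self) -> np.ndarray:
        return self.state < int(HealthState.DEAD_CVD)

    @property
    def current_age(self) -> float:
        return float(self.cohort.start_age + self.year_index)

    def person(self, i: int, start_year: int = 2014) -> PersonState:
        """Object-level view of person ``i`` (state only; the vectorised
        engine keeps the current state, not the full event history)."""
        st = HealthState(int(self.state[i]))
        p = PersonState(current_age=self.current_age,
                        cohort_id=self.cohort.cohort_id,
                        insured=bool(self.insured[i]),
                        treated=bool(self.treated[i]),
                        alive=st not in (HealthState.DEAD_CVD,
                                         HealthState.DEAD_OTHER))
        if st == HealthState.DEAD_CVD:
            p.cause_of_death = "cvd"
        elif st == HealthState.DEAD_OTHER:
            p.cause_of_death = "other"
        return p


def assign_insurance(pop: Population, scenario: ScenarioSpec,
                     rng: np.random.Generator) -> Population:
    """Draw insurance status: a fresh Bernoulli draw each cycle in annual
    mode; drawn once and held in persistent mode."""
    if scenario.persistence == "persistent" and pop.insurance_drawn:
        return pop
    p = scenario.probability_for(pop.cohort)
    pop.insured = rng.random(pop.n) < p
    pop.insurance_drawn = True
    return pop


def assign_treatment(pop: Population, params: ParameterSet,
                     rng: np.random.Generator) -> Population:
    """Bernoulli treatment draw given each person's insurance status."""
    tm = params.treatment_for(pop.cohort)
    p_ins = tm.probability(pop.cohort.sex, pop.cohort.age_lo, insured=True)
    p_unins = tm.probability(pop.cohort.sex, pop.cohort.age_lo,
                             insured=False)
    p = np.where(pop.insured, p_ins, p_unins)
    pop.treated = rng.random(pop.n) < p
    return pop


_renorm_warned = False


def _warn_renormalised(cohort_id: str) -> None:
    global _renorm_warned
    if not _renorm_warned:
        logger.warning(
            "competing CHD+stroke probabilities exceeded 1 for cohort %s; "
            "renormalised (warned once)", cohort_id,
        )
        _renorm_warned = True


def _event_probabilities(pop: Population, params: ParameterSet,
                         schedule: RiskSchedule,
                         t: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-person competing annual CHD/stroke probabilities after history
    multipliers and treatment relative risks."""
    base_chd, base_stroke = schedule.probabilities(
        t, params.probability_offsets
    )
    age = pop.cohort.start_age + t
    mult = np.ones(pop.n)
    for state, key in ((HealthState.HX_MI, "HX_MI"),
                       (HealthState.HX_ANGINA, "HX_ANGINA"),
                       (HealthState.HX_STROKE, "HX_STROKE")):
        mult[pop.state == int(state)] = params.history_risk[key]
    rr_chd = np.where(pop.treated, params.med_effect.rr("chd", age), 1.0)
    rr_stroke = np.where(pop.treated,
                         params.med_effect.rr("stroke", age), 1.0)
    p_chd = np.minimum(base_chd * mult * rr_chd, 1.0)
    p_stroke = np.minimum(base_stroke * mult * rr_stroke, 1.0)
    total = p_chd + p_stroke
    over = total > 1.0
    if np.any(over):
        _warn_renormalised(pop.cohort.cohort_id)
        p_chd = np.where(over, p_chd / total, p_chd)
        p_stroke = np.where(over, p_stroke / total, p_stroke)
    return p_chd, p_stroke


def simulate_year(pop: Population, params: ParameterSet,
                  scenario: ScenarioSpec, schedule: RiskSchedule,
                  rng: np.random.Generator) -> dict[str, float]:
    """Advance a population one simulated year; return the year's tallies.

    Tallies are keyed by incident event kind plus "deaths_cvd" and
    "deaths_other" and equal the sum of individual outcomes.
    """
    t = pop.year_index
    age = pop.cohort.start_age + t
    alive = pop.alive

    assign_insurance(pop, scenario, rng)
    assign_treatment(pop, params, rng)

    p_chd, p_stroke = _event_probabilities(pop, params, schedule, t)

    u_event = rng.random(pop.n)
    chd = alive & (u_event < p_chd)
    stroke = alive & ~chd & (u_event < p_chd + p_stroke)
    no_event = alive & ~chd & ~stroke

    # CHD subtype
    p_mi, p_stable, _ = params.event_mix.probabilities(pop.cohort.sex, age)
    u_sub = rng.random(pop.n)
    kind = np.full(pop.n, -1, dtype=np.int8)  # index into EVENT_KINDS
    kind[chd & (u_sub < p_mi)] = 0
    kind[chd & (u_sub >= p_mi) & (u_sub < p_mi + p_stable)] = 1
    kind[chd & (u_sub >= p_mi + p_stable)] = 2
    kind[stroke] = 3

    # case fatality, conditional on insurance and prior history
    has_history = pop.state != int(HealthState.WELL)
    u_fatal = rng.random(pop.n)
    fatal = np.zeros(pop.n, dtype=bool)
    cf = params.case_fatality
    for ki, ev in enumerate(EVENT_KINDS):
        etype = EVENT_FATALITY_TYPE[ev]
        mask = kind == ki
        if not np.any(mask):
            continue
        for ins in (True, False):
            for hist in (True, False):
                sub = mask & (pop.insured == ins) & (has_history == hist)
                if np.any(sub):
                    p = cf.probability(etype, age, ins, hist)
                    fatal[sub] = u_fatal[sub] < p

    # background non-CVD mortality for event-free survivors
    q_bg = params.background_mortality.probability(pop.cohort.sex, age)
    u_bg = rng.random(pop.n)
    bg_death = no_event & (u_bg < q_bg)

    tallies: dict[str, float] = {}
    for ki, ev in enumerate(EVENT_KINDS):
        tallies[ev] = float(np.count_nonzero(kind == ki))
    event_mask = kind >= 0
    tallies["deaths_cvd"] = float(np.count_nonzero(event_mask & fatal))
    tallies["deaths_other"] = float(np.count_nonzero(bg_death))

    # state update: non-fatal events change state; fatal events / background
    # deaths absorb
    new_state = pop.state.copy()
    for ki, ev in enumerate(EVENT_KINDS):
        new_state[(kind == ki) & ~fatal] = int(EVENT_STATE[ev])
    new_state[event_mask & fatal] = int(HealthState.DEAD_CVD)
    new_state[bg_death] = int(HealthState.DEAD_OTHER)
    pop.state = new_state
    pop.year_index += 1
    return tallies


# ---------------------------------------------------------------------------
# expectation mode
# ---------------------------------------------------------------------------

def _expectation_step(occ: np.ndarray, cohort: CohortSpec,
                      params: ParameterSet, schedule: RiskSchedule, t: int,
                      p_ins: float) -> tuple[np.ndarray, dict[str, float]]:
    """One deterministic cycle on a 6-state occupancy vector."""
    age = cohort.start_age + t
    base_chd, base_stroke = schedule.probabilities(
        t, params.probability_offsets
    )
    tm = params.treatment_for(cohort)
    q_bg = params.background_mortality.probability(cohort.sex, age)
    p_mi, p_stable, p_unstable = params.event_mix.probabilities(
        cohort.sex, age
    )
    sub_mix = {"mi": p_mi, "stable_angina": p_stable,
               "unstable_angina": p_unstable}
    rr = {"chd": params.med_effect.rr("chd", age),
          "stroke": params.med_effect.rr("stroke", age)}

    new = np.zeros(6)
    new[int(HealthState.DEAD_CVD)] = occ[int(HealthState.DEAD_CVD)]
    new[int(HealthState.DEAD_OTHER)] = occ[int(HealthState.DEAD_OTHER)]
    tallies = {k: 0.0 for k in EVENT_KINDS}
    tallies["deaths_cvd"] = 0.0
    tallies["deaths_other"] = 0.0

    hist_mult = {HealthState.WELL: 1.0,
                 HealthState.HX_MI: params.history_risk["HX_MI"],
                 HealthState.HX_ANGINA: params.history_risk["HX_ANGINA"],
                 HealthState.HX_STROKE: params.history_risk["HX_STROKE"]}

    for s in LIVING_STATES:
        mass_s = occ[int(s)]
        if mass_s == 0.0:
            continue
        has_history = s != HealthState.WELL
        mult = hist_mult[s]
        for ins, w_ins in ((True, p_ins), (False, 1.0 - p_ins)):
            if w_ins == 0.0:
                continue
            p_t = tm.probability(cohort.sex, cohort.age_lo, insured=ins)
            for treated, w_tr in ((True, p_t), (False, 1.0 - p_t)):
                w = w_ins * w_tr
                if w == 0.0:
                    continue
                pc = min(base_chd * mult * (rr["chd"] if treated else 1.0),
                         1.0)
                ps = min(base_stroke * mult
                         * (rr["stroke"] if treated else 1.0), 1.0)
                total = pc + ps
                if total > 1.0:
                    _warn_renormalised(cohort.cohort_id)
                    pc, ps = pc / total, ps / total
                cell = mass_s * w
                for sub, m in sub_mix.items():
                    if m == 0.0:
                        continue
                    ev_mass = cell * pc * m
                    cf = params.case_fatality.probability(
                        EVENT_FATALITY_TYPE[sub], age, ins, has_history
                    )
                    tallies[sub] += ev_mass
                    tallies["deaths_cvd"] += ev_mass * cf
                    new[int(HealthState.DEAD_CVD)] += ev_mass * cf
                    new[int(EVENT_STATE[sub])] += ev_mass * (1.0 - cf)
                cf_st = params.case_fatality.probability(
                    "stroke", age, ins, has_history
                )
                st_mass = cell * ps
                tallies["stroke"] += st_mass
                tallies["deaths_cvd"] += st_mass * cf_st
                new[int(HealthState.DEAD_CVD)] += st_mass * cf_st
                new[int(HealthState.HX_STROKE)] += st_mass * (1.0 - cf_st)
                none_mass = cell * (1.0 - pc - ps)
                tallies["deaths_other"] += none_mass * q_bg
                new[int(HealthState.DEAD_OTHER)] += none_mass * q_bg
                new[int(s)] += none_mass * (1.0 - q_bg)
    return new, tallies


def _run_expectation(cohort: CohortSpec, p_ins: float, params: ParameterSet,
                     schedule: RiskSchedule, horizon: int) -> RunResult:
    occ = np.zeros(6)
    occ[int(HealthState.WELL)] = 1.0
    living = np.zeros((horizon + 1, 6))
    living[0] = occ
    events = {k: np.zeros(horizon) for k in EVENT_KINDS}
    deaths = {"cvd": np.zeros(horizon), "other": np.zeros(horizon)}
    for t in range(horizon):
        occ, tallies = _expectation_step(occ, cohort, params, schedule, t,
                                         p_ins)
        living[t + 1] = occ
        for k in EVENT_KINDS:
            events[k][t] = tallies[k]
        deaths["cvd"][t] = tallies["deaths_cvd"]
        deaths["other"][t] = tallies["deaths_other"]
    return RunResult(cohort_id=cohort.cohort_id,
                     start_year=params.start_year, horizon=horizon,
                     events=events, deaths=deaths, living=living,
                     initial_size=1.0, cohort_size=cohort.size,
                     mode="expectation")


# ---------------------------------------------------------------------------
# cohort runs
# ---------------------------------------------------------------------------

def run_cohort(cohort: CohortSpec, scenario: ScenarioSpec,
               params: ParameterSet, mode: str = "expectation",
               n_persons: int | None = None, seed: int | None = None,
               schedule: RiskSchedule | None = None,
               horizon: int | None = None, n_profiles: int = 2000,
               schedule_seed: int = 0) -> RunResult:
    """Run one cohort for ``horizon`` years (default: the parameter set's).

    Stochastic mode requires ``n_persons`` and ``seed``; expectation mode
    ignores both and is fully deterministic. A prebuilt ``schedule`` may be
    passed so that both modes (or many scenarios) share identical annual
    event probabilities.
    """
    horizon = params.horizon_years if horizon is None else horizon
    if schedule is None:
        schedule = build_risk_schedule(cohort, params, horizon=horizon,
                                       n_profiles=n_profiles,
                                       schedule_seed=schedule_seed)
    if schedule.p_chd.size < horizon:
        raise ValueError("schedule shorter than requested horizon")

    p_ins = scenario.probability_for(cohort)

    if mode == "expectation":
        if scenario.persistence == "persistent":
            parts, weights = [], []
            for p_fixed, w in ((1.0, p_ins), (0.0, 1.0 - p_ins)):
                if w > 0.0:
                    parts.append(_run_expectation(cohort, p_fixed, params,
                                                  schedule, horizon))
                    weights.append(w)
            return weighted_merge(parts, weights)
        return _run_expectation(cohort, p_ins, params, schedule, horizon)

    if mode != "stochastic":
        raise ValueError(f"unknown mode {mode!r}")
    if n_persons is None:
        raise ValueError("stochastic mode requires n_persons")
    rng = np.random.default_rng(seed)
    pop = Population.initial(cohort, n_persons)
    living = np.zeros((horizon + 1, 6))
    living[0] = np.bincount(pop.state, minlength=6)
    events = {k: np.zeros(horizon) for k in EVENT_KINDS}
    deaths = {"cvd": np.zeros(horizon), "other": np.zeros(horizon)}
    for t in range(horizon):
        tallies = simulate_year(pop, params, scenario, schedule, rng)
        living[t + 1] = np.bincount(pop.state, minlength=6)
        for k in EVENT_KINDS:
            events[k][t] = tallies[k]
        deaths["cvd"][t] = tallies["deaths_cvd"]
        deaths["other"][t] = tallies["deaths_other"]
    return RunResult(cohort_id=cohort.cohort_id,
                     start_year=params.start_year, horizon=horizon,
                     events=events, deaths=deaths, living=living,
                     initial_size=float(n_persons), cohort_size=cohort.size,
                     mode="stochastic")


def run_all_cohorts(params: ParameterSet, scenario: ScenarioSpec,
                    mode: str = "expectation",
                    cohorts: tuple[CohortSpec, ...] | None = None,
                    n_persons: int | None = None, seed: int | None = None,
                    schedules: dict[str, RiskSchedule] | None = None,
                    horizon: int | None = None,
                    n_profiles: int = 2000,
                    schedule_seed: int = 0) -> dict[str, RunResult]:
    """Run every cohort under one scenario; returns cohort_id -> RunResult.

    In stochastic mode, per-cohort seeds are spawned from ``seed`` so runs
    are reproducible and independent across cohorts.
    """
    cohorts = params.cohorts if cohorts is None else cohorts
    if schedules is None:
        schedules = build_schedules(params, cohorts=cohorts, horizon=horizon,
                                    n_profiles=n_profiles,
                                    schedule_seed=schedule_seed)
    out = {}
    child_seeds = (np.random.SeedSequence(seed).spawn(len(cohorts))
                   if mode == "stochastic" else [None] * len(cohorts))
    for c, s in zip(cohorts, child_seeds):
        out[c.cohort_id] = run_cohort(
            c, scenario, params, mode=mode, n_persons=n_persons,
            seed=s, schedule=schedules[c.cohort_id], horizon=horizon,
        )
    return out
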
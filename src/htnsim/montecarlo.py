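"""Monte Carlo uncertainty analysis and sensitivity variants.

Each replication perturbs every cohort's annual CHD and stroke probabilities
with an additive normal draw (mean zero, per-cohort/disease standard
deviation), truncates into [0, 1], and reruns the engine in expectation
mode. Point estimates come from the unperturbed run; interval bounds are the
2.5th/97.5th percentiles across replications. Replications use independent
child streams spawned from the master seed, so results are independent of
evaluation order.

The default perturbation scale is the standard error of the cohort-mean
annual probability on the synthetic population (risk-function linear-
predictor variability across profiles), a stand-in for unpublished scale
estimates; it is labelled assumed and can be overridden.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import build_schedules, run_all_cohorts
from .parameters import DISEASES, CohortSpec, ParameterSet
from .population import generate_profile_arrays
from .reporting import MEASURES, OutcomeSummary, summarize_runs
from .risk import annual_probability, ten_year_risk_arrays
from .scenarios import ScenarioSpec, built_in_scenarios


@dataclass
class UncertaintySpec:
    """Replication count, perturbation scales and master seed.

    ``sd`` maps (cohort_id, disease) to the standard deviation of the
    additive probability perturbation; ``None`` means estimate the default
    scales from the synthetic population.
    """

    n_reps: int = 1000
    sd: dict[tuple[str, str], float] | None = None
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2")
        if self.sd is not None and any(v < 0 for v in self.sd.values()):
            raise ValueError("perturbation sd must be >= 0")


def estimate_probability_se(params: ParameterSet,
                            cohorts: tuple[CohortSpec, ...] | None = None,
                            n_profiles: int = 2000,
                            seed: int = 0) -> dict[tuple[str, str], float]:
    """Standard error of each cohort's mean annual event probability,
    from risk-function variability across a synthetic profile sample."""
    cohorts = params.cohorts if cohorts is None else cohorts
    out = {}
    for c in cohorts:
        fixed = params.fixed_annual_probabilities.get(c.cohort_id)
        if fixed is not None:
            for disease in DISEASES:
                out[(c.cohort_id, disease)] = 0.0
            continue
        arrays = generate_profile_arrays(c, n_profiles, params.population,
                                         seed)
        bp_treated = np.zeros(n_profiles, dtype=bool)
        age = np.full(n_profiles, float(c.start_age))
        for disease in DISEASES:
            cs = params.risk_coefficients.get(disease, c.sex)
            ten = ten_year_risk_arrays(
                cs, age, arrays["systolic_bp"], bp_treated,
                arrays["smoker"], arrays["total_cholesterol"],
                arrays["hdl_cholesterol"], arrays["diabetes"],
            )
            annual = annual_probability(ten)
            out[(c.cohort_id, disease)] = float(
                np.std(annual, ddof=1) / np.sqrt(n_profiles)
            )
    return out


def perturb_probabilities(params: ParameterSet, spec: UncertaintySpec,
                          rep_rng: np.random.Generator) -> ParameterSet:
    """A copy of ``params`` whose annual event probabilities carry one
    replication's normal perturbations (truncated into [0, 1] when
    applied); all other parameters are unchanged."""
    sd = spec.sd if spec.sd is not None else estimate_probability_se(params)
    offsets = {key: float(rep_rng.normal(0.0, s)) if s > 0 else 0.0
               for key, s in sd.items()}
    return dataclasses.replace(params, probability_offsets=offsets)


@dataclass
class UncertaintyResult:
    """Point estimates with percentile CIs, plus per-rep results for audit."""

    summaries: dict[str, OutcomeSummary]
    replications: pd.DataFrame  # columns: rep, scenario, stratum, measure, value


def run_uncertainty(params: ParameterSet, spec: UncertaintySpec,
                    scenarios: dict[str, ScenarioSpec] | None = None,
                    cohorts: tuple[CohortSpec, ...] | None = None,
                    horizon: int | None = None,
                    n_profiles: int = 2000) -> UncertaintyResult:
    """Monte Carlo uncertainty analysis in expectation mode.

    Point estimate: the unperturbed run. Bounds: 2.5th/97.5th percentiles
    over ``spec.n_reps`` perturbed replications. A fixed master seed gives
    bit-identical bounds across calls.
    """
    scenarios = built_in_scenarios(params) if scenarios is None else scenarios
    cohorts = params.cohorts if cohorts is None else cohorts
    schedules = build_schedules(params, cohorts=cohorts, horizon=horizon,
                                n_profiles=n_profiles)
    sd = spec.sd if spec.sd is not None else estimate_probability_se(
        params, cohorts=cohorts, n_profiles=n_profiles
    )
    resolved = dataclasses.replace(spec, sd=sd)

    def summarize(p: ParameterSet) -> dict[str, OutcomeSummary]:
        out = {}
        for name, scenario in scenarios.items():
            results = run_all_cohorts(p, scenario, mode="expectation",
                                      cohorts=cohorts, schedules=schedules,
                                      horizon=horizon)
            out[name] = summarize_runs(results, list(cohorts), name)
        return out

    point = summarize(params)

    streams = np.random.SeedSequence(spec.master_seed).spawn(spec.n_reps)
    rep_rows = []
    for rep, stream in enumerate(streams):
        perturbed = perturb_probabilities(
            params, resolved, np.random.default_rng(stream)
        )
        for name, summary in summarize(perturbed).items():
            for stratum in summary.table.index:
                for measure in MEASURES:
                    rep_rows.append({
                        "rep": rep, "scenario": name, "stratum": stratum,
                        "measure": measure,
                        "value": float(summary.table.loc[stratum, measure]),
                    })
    reps = pd.DataFrame(rep_rows)

    for name, summary in point.items():
        sub = reps[reps["scenario"] == name]
        lo = sub.pivot_table(index="stratum", columns="measure",
                             values="value",
                             aggfunc=lambda v: np.percentile(v, 2.5))
        hi = sub.pivot_table(index="stratum", columns="measure",
                             values="value",
                             aggfunc=lambda v: np.percentile(v, 97.5))
        summary.ci_lo = lo.reindex(index=summary.table.index,
                                   columns=list(MEASURES))
        summary.ci_hi = hi.reindex(index=summary.table.index,
                                   columns=list(MEASURES))
    return UncertaintyResult(summaries=point, replications=reps)


VARIANTS = ("continuous-coverage", "prehypertension")


def run_sensitivity_variant(variant: str, params: ParameterSet,
                            horizon: int | None = None,
                            n_profiles: int = 2000,
                            ) -> dict[str, OutcomeSummary]:
    """Run all built-in scenarios under a sensitivity variant.

    ``continuous-coverage`` draws insurance once per person and holds it;
    ``prehypertension`` enlarges the population with the prehypertensive
    cohorts configured in the parameter set.
    """
    if variant == "continuous-coverage":
        scenarios = built_in_scenarios(params, persistence="persistent")
        cohorts = params.cohorts
    elif variant == "prehypertension":
        if params.prehypertension is None:
            raise ValueError(
                "parameter set has no prehypertension block configured"
            )
        scenarios = built_in_scenarios(params, include_prehypertension=True)
        cohorts = params.cohorts + params.prehypertension.cohorts
    else:
        raise ValueError(f"unknown variant {variant!r}; "
                         f"expected one of {VARIANTS}")
    schedules = build_schedules(params, cohorts=cohorts, horizon=horizon,
                                n_profiles=n_profiles)
    out = {}
    for name, scenario in scenarios.items():
        results = run_all_cohorts(params, scenario, mode="expectation",
                                  cohorts=cohorts, schedules=schedules,
                                  horizon=horizon)
        out[name] = summarize_runs(results, list(cohorts), name)
    return out
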
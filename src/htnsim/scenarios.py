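"""Policy scenarios and insurance-to-treatment arithmetic.

A scenario is an insured probability per cohort plus a coverage-persistence
mode. The three built-in scenarios are the pre-expansion baseline, a partial
expansion (opt-out states stay out), and universal coverage. The implied
cohort treatment rate is the insurance-weighted mixture of the insured and
uninsured treatment probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import tables
from .parameters import (
    SCENARIO_NAMES,
    CohortSpec,
    ParameterSet,
)


class UndefinedValueError(ZeroDivisionError):
    """A ratio with a zero denominator was requested."""


class InfeasibleCalibrationError(ValueError):
    """No uninsured treatment probability in [0, 1] matches the target."""


@dataclass(frozen=True)
class ScenarioSpec:
    """A named insurance-mix assumption.

    ``persistence`` is "annual" (status redrawn every simulated year) or
    "persistent" (drawn once at entry and held; the continuous-coverage
    sensitivity variant).
    """

    name: str
    insured_probability: dict[str, float]
    persistence: str = "annual"
    notes: str = ""

    def probability_for(self, cohort: CohortSpec) -> float:
        try:
            return self.insured_probability[cohort.cohort_id]
        except KeyError:
            raise LookupError(
                f"scenario {self.name!r} defines no insured probability for "
                f"cohort {cohort.cohort_id!r}"
            )


def built_in_scenarios(params: ParameterSet,
                       persistence: str = "annual",
                       include_prehypertension: bool = False,
                       ) -> dict[str, ScenarioSpec]:
    """The three policy scenarios configured in a parameter set."""
    out = {}
    for name in SCENARIO_NAMES:
        probs = dict(params.insurance[name])
        if include_prehypertension and params.prehypertension is not None:
            probs.update(params.prehypertension.insurance[name])
        out[name] = ScenarioSpec(name=name, insured_probability=probs,
                                 persistence=persistence)
    return out


def treatment_rate(p_insured: float, p_treat_ins: float,
                   p_treat_unins: float) -> float:
    """Cohort treatment rate implied by an insurance mix:
    ``p_insured * p_treat_ins + (1 - p_insured) * p_treat_unins``."""
    for name, p in (("p_insured", p_insured), ("p_treat_ins", p_treat_ins),
                    ("p_treat_unins", p_treat_unins)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name}={p} outside [0, 1]")
    return p_insured * p_treat_ins + (1.0 - p_insured) * p_treat_unins


def calibrate_uninsured_rate(observed_rate: float, p_insured: float,
                             p_treat_ins: float) -> float:
    """Invert :func:`treatment_rate` for the uninsured probability.

    Raises :class:`InfeasibleCalibrationError` when the algebraic solution
    falls outside [0, 1], reporting the implied bound.
    """
    if not 0.0 <= p_insured < 1.0:
        raise ValueError(f"p_insured={p_insured} must be in [0, 1)")
    solution = (observed_rate - p_insured * p_treat_ins) / (1.0 - p_insured)
    if -1e-9 <= solution < 0.0 or 1.0 < solution <= 1.0 + 1e-9:
        solution = min(max(solution, 0.0), 1.0)  # float roundoff at bounds
    if not 0.0 <= solution <= 1.0:
        lo = p_insured * p_treat_ins
        hi = lo + (1.0 - p_insured)
        raise InfeasibleCalibrationError(
            f"observed rate {observed_rate} requires uninsured probability "
            f"{solution:.6f}; feasible observed rates lie in "
            f"[{lo:.6f}, {hi:.6f}]"
        )
    return solution


def percent_change(baseline: float, comparison: float) -> float:
    """``100 * (comparison - baseline) / baseline`` (unrounded)."""
    if baseline == 0:
        raise UndefinedValueError("percent change undefined for zero baseline")
    return 100.0 * (comparison - baseline) / baseline


def cohort_treatment_rates(params: ParameterSet, scenario: ScenarioSpec,
                           ) -> dict[str, float]:
    """Treatment rate per cohort under a scenario's insurance mix."""
    out = {}
    for c in params.cohorts:
        tm = params.treatment_for(c)
        out[c.cohort_id] = treatment_rate(
            scenario.probability_for(c),
            tm.probability(c.sex, c.age_lo, insured=True),
            tm.probability(c.sex, c.age_lo, insured=False),
        )
    return out


def treatment_rate_table(params: ParameterSet) -> pd.DataFrame:
    """Computed treatment-rate table across the built-in scenarios.

    One row per scenario x stratum (total / male / female) with a column per
    age band plus the size-weighted ``all_ages`` aggregate and the percent
    change vs baseline, all computed from unrounded internals.
    """
    scenarios = built_in_scenarios(params)
    records = []
    base_agg: dict[str, float] = {}
    for name in SCENARIO_NAMES:
        rates = cohort_treatment_rates(params, scenarios[name])
        for stratum in ("total", "male", "female"):
            cohorts = [c for c in params.cohorts
                       if stratum in ("total", c.sex)]
            row: dict[str, object] = {"scenario": name, "stratum": stratum}
            for lo, hi in ((25, 34), (35, 44), (45, 54), (55, 64)):
                cs = [c for c in cohorts if c.age_lo == lo]
                num = sum(rates[c.cohort_id] * c.size for c in cs)
                den = sum(c.size for c in cs)
                row[f"{lo}-{hi}"] = 100.0 * num / den
            num = sum(rates[c.cohort_id] * c.size for c in cohorts)
            den = sum(c.size for c in cohorts)
            agg = 100.0 * num / den
            row["all_ages"] = agg
            if name == "baseline":
                base_agg[stratum] = agg
                row["pct_change_vs_baseline"] = 0.0
            else:
                row["pct_change_vs_baseline"] = percent_change(
                    base_agg[stratum], agg
                )
            records.append(row)
    return pd.DataFrame.from_records(records)


def published_rate_check(params: ParameterSet) -> pd.DataFrame:
    """Computed vs published treatment rates (calibration diagnostic)."""
    table = treatment_rate_table(params)
    pub = tables.published_treatment_rates()
    merged = pub.merge(
        table.melt(id_vars=["scenario", "stratum"],
                   value_vars=list(tables.AGE_BAND_LABELS),
                   var_name="age_band", value_name="computed_pct"),
        on=["scenario", "stratum", "age_band"], how="left",
    )
    merged["abs_error"] = (merged["computed_pct"] - merged["rate_pct"]).abs()
    return merged
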
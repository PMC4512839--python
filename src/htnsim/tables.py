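"""Published reference tables the default parameter set is calibrated against.

These are the printed results of the state-transition modelling study of US
health-insurance expansion among nonelderly hypertensive adults that this
package reimplements: hypertension treatment rates by coverage scenario, sex
and 10-year age band (with the cohort sizes used as aggregation weights), and
cumulative CVD outcomes per 10,000 population under each scenario.

They serve three purposes: calibrating the default uninsured treatment
probabilities and partial-expansion insured fractions, exercising the
aggregation/percent-change reporting arithmetic, and acceptance checking.
Provenance for everything in this module is "published".
"""

from __future__ import annotations

import pandas as pd

#: 10-year age bands of the simulated nonelderly cohorts.
AGE_BAND_LABELS = ("25-34", "35-44", "45-54", "55-64")

#: Hypertensive adults per age band (aggregation weights; total 54,697,510).
AGE_BAND_SIZES = {
    "25-34": 3_911_740,
    "35-44": 10_190_086,
    "45-54": 17_326_094,
    "55-64": 23_269_590,
}

TOTAL_POPULATION = sum(AGE_BAND_SIZES.values())

#: Percent of hypertensive adults receiving antihypertensive treatment, by
#: scenario, sex and age band (published, 1 decimal place).
TREATMENT_RATES_PCT = {
    "baseline": {
        "total": {"25-34": 51.5, "35-44": 53.3, "45-54": 57.0, "55-64": 58.8},
        "male": {"25-34": 45.9, "35-44": 47.2, "45-54": 51.6, "55-64": 53.0},
        "female": {"25-34": 58.8, "35-44": 59.8, "45-54": 62.8, "55-64": 63.8},
    },
    "expansion-partial": {
        "total": {"25-34": 56.3, "35-44": 56.9, "45-54": 60.2, "55-64": 60.7},
        "male": {"25-34": 51.4, "35-44": 51.4, "45-54": 55.4, "55-64": 55.4},
        "female": {"25-34": 62.7, "35-44": 62.7, "45-54": 65.4, "55-64": 65.4},
    },
    "expansion-universal": {
        "total": {"25-34": 62.9, "35-44": 63.3, "45-54": 63.4, "55-64": 63.8},
        "male": {"25-34": 59.0, "35-44": 59.0, "45-54": 59.0, "55-64": 59.0},
        "female": {"25-34": 68.0, "35-44": 68.0, "45-54": 68.0, "55-64": 68.0},
    },
}

#: Published US-total treatment rates after aggregating bands by cohort size.
TREATMENT_RATE_TOTALS_PCT = {
    "baseline": 56.7,
    "expansion-partial": 59.5,
    "expansion-universal": 63.5,
}

#: Cumulative CVD events and deaths per 10,000 population over 2014-2050,
#: published point estimates by scenario and sex, plus the published
#: scenario-minus-baseline differences (kept unrounded relative to the
#: rounded rate columns, hence stored separately).
OUTCOMES_PER_10K = {
    "baseline": {
        "total": {"chd": 2022.0, "stroke": 837.0, "cvd_death": 816.0},
        "male": {"chd": 1366.0, "stroke": 424.0, "cvd_death": 474.0},
        "female": {"chd": 648.0, "stroke": 421.0, "cvd_death": 342.0},
    },
    "expansion-partial": {
        "total": {"chd": 2011.0, "stroke": 831.0, "cvd_death": 806.0},
        "male": {"chd": 1358.0, "stroke": 420.0, "cvd_death": 468.0},
        "female": {"chd": 645.0, "stroke": 419.0, "cvd_death": 338.0},
    },
    "expansion-universal": {
        "total": {"chd": 1992.0, "stroke": 826.0, "cvd_death": 794.0},
        "male": {"chd": 1344.0, "stroke": 418.0, "cvd_death": 460.0},
        "female": {"chd": 640.0, "stroke": 416.0, "cvd_death": 334.0},
    },
}

#: Published baseline-minus-scenario differences per 10,000 (one decimal;
#: computed by the source study from unrounded internals).
OUTCOME_DIFFERENCES_PER_10K = {
    "expansion-partial": {
        "total": {"chd": 11.1, "stroke": 6.3, "cvd_death": 9.5},
        "male": {"chd": 8.3, "stroke": 4.1, "cvd_death": 5.8},
        "female": {"chd": 2.8, "stroke": 2.3, "cvd_death": 3.7},
    },
    "expansion-universal": {
        "total": {"chd": 29.9, "stroke": 10.9, "cvd_death": 22.2},
        "male": {"chd": 21.9, "stroke": 6.3, "cvd_death": 14.0},
        "female": {"chd": 7.9, "stroke": 4.8, "cvd_death": 8.2},
    },
}


def published_treatment_rates() -> pd.DataFrame:
    """Published treatment-rate table as a tidy DataFrame.

    Columns: scenario, stratum (total/male/female), age_band, rate_pct.
    """
    rows = []
    for scenario, strata in TREATMENT_RATES_PCT.items():
        for stratum, bands in strata.items():
            for band, rate in bands.items():
                rows.append(
                    {"scenario": scenario, "stratum": stratum,
                     "age_band": band, "rate_pct": rate}
                )
    return pd.DataFrame(rows)


def published_outcomes() -> pd.DataFrame:
    """Published per-10,000 outcome table (point estimates and differences)."""
    rows = []
    for scenario, strata in OUTCOMES_PER_10K.items():
        for stratum, measures in strata.items():
            for measure, rate in measures.items():
                diff = (
                    OUTCOME_DIFFERENCES_PER_10K.get(scenario, {})
                    .get(stratum, {})
                    .get(measure)
                )
                rows.append(
                    {"scenario": scenario, "stratum": stratum,
                     "measure": measure, "per_10k": rate,
                     "difference_vs_baseline": diff}
                )
    return pd.DataFrame(rows)
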
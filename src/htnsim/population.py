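"""Synthetic risk-factor populations and small fixture parameter sets.

Profiles are drawn from the NHANES-like summaries in the parameter set's
:class:`~htnsim.parameters.PopulationModel`: truncated normals for the
continuous factors, Bernoulli for the binary ones, independent within a
sex x age-band cell. Hypertensive cohorts enforce SBP >= 140 mm Hg,
prehypertensive cohorts SBP in [120, 140); both windows are applied on top
of the global clinical truncation ranges.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from .parameters import (
    CaseFatalityTable,
    CohortSpec,
    EventMix,
    MedicationEffect,
    ParameterSet,
    PopulationModel,
    TreatmentModel,
    default_parameters,
)
from .risk import RiskProfile

# global clinical truncation ranges (applied before the cohort SBP window)
SBP_RANGE = (90.0, 230.0)
TC_RANGE = (100.0, 400.0)
HDL_RANGE = (20.0, 120.0)

_BP_WINDOWS = {
    "hypertension": (140.0, SBP_RANGE[1]),
    "prehypertension": (120.0, np.nextafter(140.0, 0.0)),
}


def _truncated_normal(mean, sd, lo, hi, n, rng):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n,
                               random_state=rng)


def generate_profile_arrays(cohort: CohortSpec, n: int,
                            model: PopulationModel,
                            seed) -> dict[str, np.ndarray]:
    """Vectorised profile generation: a dict of length-``n`` arrays.

    Keys: age, systolic_bp, smoker, total_cholesterol, hdl_cholesterol,
    diabetes. ``seed`` may be an int or a Generator.
    """
    rng = np.random.default_rng(seed)
    cell = model.cell(cohort.sex, cohort.age_lo)
    lo, hi = _BP_WINDOWS[cohort.bp_group]
    lo = max(lo, SBP_RANGE[0])
    sbp = _truncated_normal(cell.sbp_mean, cell.sbp_sd, lo, hi, n, rng)
    tc = _truncated_normal(cell.tc_mean, cell.tc_sd, *TC_RANGE, n, rng)
    hdl = _truncated_normal(cell.hdl_mean, cell.hdl_sd, *HDL_RANGE, n, rng)
    return {
        "age": np.full(n, float(cohort.start_age)),
        "systolic_bp": sbp,
        "smoker": rng.random(n) < cell.smoking,
        "total_cholesterol": tc,
        "hdl_cholesterol": hdl,
        "diabetes": rng.random(n) < cell.diabetes,
    }


def generate_profiles(cohort: CohortSpec, n: int, model: PopulationModel,
                      seed) -> list[RiskProfile]:
    """Generate ``n`` seeded, reproducible risk profiles for a cohort."""
    arrays = generate_profile_arrays(cohort, n, model, seed)
    return [
        RiskProfile(
            sex=cohort.sex,
            age=float(arrays["age"][i]),
            systolic_bp=float(arrays["systolic_bp"][i]),
            smoker=bool(arrays["smoker"][i]),
            total_cholesterol=float(arrays["total_cholesterol"][i]),
            hdl_cholesterol=float(arrays["hdl_cholesterol"][i]),
            diabetes=bool(arrays["diabetes"][i]),
            race=None if cohort.race == "all" else cohort.race,
        )
        for i in range(n)
    ]


def fixture_parameters(scale: str = "tiny") -> ParameterSet:
    """Small parameter sets for testing.

    ``"default"`` returns the packaged default set. ``"tiny"`` returns a
    2-cohort, 1-year-horizon set with hand-set round-number probabilities
    whose expectation-mode results have closed forms: annual CHD probability
    0.1 (all MI), stroke 0, case fatality 0.5 everywhere, background
    mortality 0, nobody treated, relative risk 0.5 at every age.
    """
    if scale == "default":
        return default_parameters()
    if scale != "tiny":
        raise ValueError(f"unknown fixture scale {scale!r}")

    cohorts = tuple(
        CohortSpec(sex=sex, age_lo=55, age_hi=64, size=10_000, start_age=60)
        for sex in ("male", "female")
    )
    bands = [25, 35, 45, 55, 65, 75, 85]
    treatment = TreatmentModel(
        insured={"male": 0.0, "female": 0.0},
        uninsured={(s, 55): 0.0 for s in ("male", "female")},
    )
    med_effect = MedicationEffect(rr_chd={b: 0.5 for b in bands},
                                  rr_stroke={b: 0.5 for b in bands})
    event_mix = EventMix(mix={(s, b): (1.0, 0.0, 0.0)
                              for s in ("male", "female") for b in bands})
    case_fatality = CaseFatalityTable(table={
        (event, b, ins, hist): 0.5
        for event in ("mi", "angina", "stroke")
        for b in bands for ins in (True, False) for hist in (True, False)
    })
    defaults = default_parameters()
    background = dataclasses.replace(
        defaults.background_mortality,
        rates={s: tuple(0.0 for _ in qs)
               for s, qs in defaults.background_mortality.rates.items()},
    )
    insurance = {
        "baseline": {c.cohort_id: 0.5 for c in cohorts},
        "expansion-partial": {c.cohort_id: 0.75 for c in cohorts},
        "expansion-universal": {c.cohort_id: 1.0 for c in cohorts},
    }
    return dataclasses.replace(
        defaults,
        cohorts=cohorts,
        treatment=treatment,
        med_effect=med_effect,
        event_mix=event_mix,
        case_fatality=case_fatality,
        background_mortality=background,
        insurance=insurance,
        history_risk={"HX_MI": 1.0, "HX_ANGINA": 1.0, "HX_STROKE": 1.0},
        horizon_years=1,
        race_cohorts=(),
        prehypertension=None,
        fixed_annual_probabilities={
            c.cohort_id: {"chd": 0.1, "stroke": 0.0} for c in cohorts
        },
        provenance={"all": "assumed (synthetic test fixture)"},
    )
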
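"""Model inputs: types, defaults, validation, and (de)serialisation.

Every quantity the simulation consumes lives in a :class:`ParameterSet`:
cohort definitions, insurance mixes per policy scenario, treatment
probabilities by insurance status, medication relative risks, the CHD
event-type mix, one-year case fatality, background (non-CVD) mortality,
Framingham-style risk-function coefficients, and risk-factor distributions
for the synthetic population.

Each block carries a provenance label:

``published``
    printed in the source study's tables (cohort sizes, treatment rates).
``transcribed``
    transcribed from the cited literature (risk-function coefficients,
    medication relative risks, and similar).
``assumed``
    set by this package where neither of the above is available; the
    rationale for each such value is in the methods note.

Parameter files are YAML documents following the schema produced by
:func:`write_parameters`; any block omitted from a file is filled from the
packaged defaults.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any

import yaml

from . import tables

SCHEMA_VERSION = 1

SEXES = ("male", "female")

#: 10-year bands of the starting cohorts.
CORE_BANDS = ((25, 34), (35, 44), (45, 54), (55, 64))

#: Bands used for age-indexed tables; individuals age past 64 during the
#: simulation, so lookup tables extend to very old ages.
EXTENDED_BANDS = CORE_BANDS + ((65, 74), (75, 84), (85, 109))

EVENT_TYPES = ("mi", "angina", "stroke")
CHD_SUBTYPES = ("mi", "stable_angina", "unstable_angina")
DISEASES = ("chd", "stroke")

SCENARIO_NAMES = ("baseline", "expansion-partial", "expansion-universal")

MIN_AGE, MAX_AGE = 25, 109


class ParameterError(Exception):
    """Base class for parameter-handling failures."""


class SchemaError(ParameterError):
    """A parameter file does not parse as the documented schema."""


class ValidationError(ParameterError):
    """A parsed parameter set violates one or more invariants."""

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__(
            "parameter set failed validation:\n  " + "\n  ".join(violations)
        )


def band_for_age(age: float) -> tuple[int, int]:
    """Extended 10-year band containing ``age`` (clamped to [25, 109])."""
    a = min(max(age, MIN_AGE), MAX_AGE)
    for lo, hi in EXTENDED_BANDS:
        if lo <= a <= hi:
            return (lo, hi)
    raise LookupError(f"no age band for age {age}")  # pragma: no cover


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """A simulated sex x age-band (x race) cohort of hypertensive adults."""

    sex: str
    age_lo: int
    age_hi: int
    size: int
    start_age: int
    race: str = "all"
    bp_group: str = "hypertension"  # or "prehypertension"

    @property
    def cohort_id(self) -> str:
        cid = f"{self.sex}_{self.age_lo}_{self.age_hi}"
        if self.race != "all":
            cid += f"_{self.race}"
        if self.bp_group != "hypertension":
            cid += "_pre"
        return cid

    @property
    def age_band_label(self) -> str:
        return f"{self.age_lo}-{self.age_hi}"


@dataclass(frozen=True)
class TreatmentModel:
    """Probability of antihypertensive treatment, by insurance status.

    ``insured`` is per sex and constant across age (the universal-coverage
    treatment rows are identical at every age, which forces this form);
    ``uninsured`` may vary by sex and entry age band so that published
    baseline rates can be matched by calibration.
    """

    insured: dict[str, float]
    uninsured: dict[tuple[str, int], float]

    def probability(self, sex: str, age_lo: int, insured: bool) -> float:
        if insured:
            return self.insured[sex]
        return self.uninsured[(sex, age_lo)]


@dataclass(frozen=True)
class MedicationEffect:
    """Multiplicative relative risks of treatment, by current age band."""

    rr_chd: dict[int, float]
    rr_stroke: dict[int, float]

    def rr(self, disease: str, age: float) -> float:
        lo, _ = band_for_age(age)
        return {"chd": self.rr_chd, "stroke": self.rr_stroke}[disease][lo]


@dataclass(frozen=True)
class EventMix:
    """Split of incident CHD events into MI / stable / unstable angina."""

    # keyed (sex, band_lo) -> (p_mi, p_stable, p_unstable)
    mix: dict[tuple[str, int], tuple[float, float, float]]

    def probabilities(self, sex: str, age: float) -> tuple[float, float, float]:
        lo, _ = band_for_age(age)
        try:
            return self.mix[(sex, lo)]
        except KeyError:
            raise LookupError(f"no CHD event mix for sex={sex}, band {lo}")


@dataclass(frozen=True)
class CaseFatalityTable:
    """One-year death probability after an event.

    Keyed by (event type, current age band, insured, prior CVD history).
    """

    table: dict[tuple[str, int, bool, bool], float]

    def probability(self, event: str, age: float, insured: bool,
                    has_history: bool) -> float:
        lo, _ = band_for_age(age)
        key = (event, lo, bool(insured), bool(has_history))
        try:
            return self.table[key]
        except KeyError:
            raise LookupError(f"no case-fatality entry for {key}")


@dataclass(frozen=True)
class BackgroundMortality:
    """Annual non-CVD death probability by sex and single year of age."""

    age_start: int
    rates: dict[str, tuple[float, ...]]  # sex -> q(age_start), q(age_start+1), ...

    def probability(self, sex: str, age: float) -> float:
        qs = self.rates[sex]
        idx = min(max(int(age) - self.age_start, 0), len(qs) - 1)
        return qs[idx]


@dataclass(frozen=True)
class CoefficientSet:
    """Sex-specific Cox-form risk equation: ``1 - s0 ** exp(lp - lp_mean)``.

    The linear predictor uses log age, log systolic blood pressure (with a
    separate coefficient when blood pressure is treated), log total and HDL
    cholesterol, and smoking/diabetes indicators. ``max_age`` is the upper
    validated age; older ages are clamped before evaluation.
    """

    ln_age: float
    ln_sbp_untreated: float
    ln_sbp_treated: float
    ln_total_chol: float
    ln_hdl: float
    smoker: float
    diabetes: float
    s0_10yr: float
    lp_mean: float
    max_age: int = 74


@dataclass(frozen=True)
class RiskCoefficients:
    """Coefficient sets per disease ("cvd", "chd", "stroke") and sex."""

    sets: dict[str, dict[str, CoefficientSet]]

    def get(self, disease: str, sex: str) -> CoefficientSet:
        try:
            return self.sets[disease][sex]
        except KeyError:
            raise LookupError(
                f"no risk coefficients for disease={disease}, sex={sex}"
            )


@dataclass(frozen=True)
class RiskFactorCell:
    """Risk-factor distribution for one sex x age-band population cell."""

    sbp_mean: float
    sbp_sd: float
    smoking: float
    tc_mean: float
    tc_sd: float
    hdl_mean: float
    hdl_sd: float
    diabetes: float


@dataclass(frozen=True)
class PopulationModel:
    """NHANES-like joint risk-factor summaries by sex and age band.

    Continuous factors are modelled truncated-normal, binary factors
    Bernoulli, independent within a cell given age and sex.
    """

    cells: dict[tuple[str, int], RiskFactorCell]

    def cell(self, sex: str, age_lo: int) -> RiskFactorCell:
        try:
            return self.cells[(sex, age_lo)]
        except KeyError:
            raise LookupError(f"no population cell for sex={sex}, band {age_lo}")


@dataclass(frozen=True)
class PrehypertensionBlock:
    """Additional prehypertensive cohorts for the sensitivity variant."""

    cohorts: tuple[CohortSpec, ...]
    treatment: TreatmentModel
    insurance: dict[str, dict[str, float]]  # scenario -> cohort_id -> p


@dataclass(frozen=True)
class ParameterSet:
    """Complete, validated bundle of model inputs."""

    cohorts: tuple[CohortSpec, ...]
    treatment: TreatmentModel
    med_effect: MedicationEffect
    event_mix: EventMix
    case_fatality: CaseFatalityTable
    background_mortality: BackgroundMortality
    risk_coefficients: RiskCoefficients
    population: PopulationModel
    #: scenario name -> cohort_id -> insured probability
    insurance: dict[str, dict[str, float]]
    #: excess-risk multipliers applied to persons with a CVD history
    history_risk: dict[str, float]
    horizon_years: int = 37
    start_year: int = 2014
    schema_version: int = SCHEMA_VERSION
    provenance: dict[str, str] = field(default_factory=dict)
    race_cohorts: tuple[CohortSpec, ...] = ()
    prehypertension: PrehypertensionBlock | None = None
    #: optional per-cohort constant annual probabilities bypassing the risk
    #: functions (used by small fixtures): cohort_id -> {"chd": p, "stroke": p}
    fixed_annual_probabilities: dict[str, dict[str, float]] = field(
        default_factory=dict
    )
    #: additive perturbations of annual event probabilities, set by the
    #: Monte Carlo machinery: (cohort_id, disease) -> delta
    probability_offsets: dict[tuple[str, str], float] = field(
        default_factory=dict
    )

    def cohort(self, cohort_id: str) -> CohortSpec:
        for c in self.cohorts + self.race_cohorts + (
            self.prehypertension.cohorts if self.prehypertension else ()
        ):
            if c.cohort_id == cohort_id:
                return c
        raise LookupError(f"no cohort {cohort_id!r}")

    def treatment_for(self, cohort: CohortSpec) -> TreatmentModel:
        if cohort.bp_group == "prehypertension" and self.prehypertension:
            return self.prehypertension.treatment
        return self.treatment

    def insured_probability(self, scenario: str, cohort: CohortSpec) -> float:
        blocks = [self.insurance]
        if self.prehypertension is not None:
            blocks.append(self.prehypertension.insurance)
        for block in blocks:
            if scenario in block and cohort.cohort_id in block[scenario]:
                return block[scenario][cohort.cohort_id]
        raise LookupError(
            f"no insured probability for scenario={scenario}, "
            f"cohort={cohort.cohort_id}"
        )


# ---------------------------------------------------------------------------
# default parameter set
# ---------------------------------------------------------------------------

#: Female share of each age band, fitted from the published male/female/total
#: treatment-rate rows (the total row of each band is a convex combination of
#: the sex rows, which identifies the share). Provenance: assumed.
FEMALE_SHARE = {25: 0.4338, 35: 0.4836, 45: 0.4832, 55: 0.5337}

#: Pre-expansion insured fraction of hypertensive adults per age band.
#: Provenance: assumed (consistent with published uninsurance surveys of
#: nonelderly US adults; younger adults are less often insured).
BASELINE_INSURED = {25: 0.71, 35: 0.76, 45: 0.81, 55: 0.86}

#: Treatment probability when insured, by sex (published: the
#: universal-coverage rows print 59.0% / 68.0% at every age).
P_TREAT_INSURED = {"male": 0.590, "female": 0.680}


def _default_cohorts() -> tuple[CohortSpec, ...]:
    cohorts = []
    for (lo, hi) in CORE_BANDS:
        band = f"{lo}-{hi}"
        size = tables.AGE_BAND_SIZES[band]
        n_female = round(size * FEMALE_SHARE[lo])
        sizes = {"male": size - n_female, "female": n_female}
        for sex in SEXES:
            cohorts.append(
                CohortSpec(sex=sex, age_lo=lo, age_hi=hi, size=sizes[sex],
                           start_age=(lo + hi + 1) // 2)
            )
    return tuple(cohorts)


def _calibrated_insurance_and_treatment(
    cohorts: tuple[CohortSpec, ...],
) -> tuple[dict[str, dict[str, float]], TreatmentModel]:
    """Invert the published treatment-rate rows.

    With the insured treatment probability pinned by the universal-coverage
    rows and the baseline insured fraction assumed, the baseline rows give
    the uninsured treatment probability and the partial-expansion rows give
    the partial-expansion insured fraction, per cohort.
    """
    uninsured: dict[tuple[str, int], float] = {}
    insurance: dict[str, dict[str, float]] = {
        name: {} for name in SCENARIO_NAMES
    }
    rates = tables.TREATMENT_RATES_PCT
    for c in cohorts:
        band = c.age_band_label
        t_ins = P_TREAT_INSURED[c.sex]
        p0 = BASELINE_INSURED[c.age_lo]
        r0 = rates["baseline"][c.sex][band] / 100.0
        r1 = rates["expansion-partial"][c.sex][band] / 100.0
        t_unins = (r0 - p0 * t_ins) / (1.0 - p0)
        p1 = (r1 - t_unins) / (t_ins - t_unins)
        uninsured[(c.sex, c.age_lo)] = t_unins
        insurance["baseline"][c.cohort_id] = p0
        insurance["expansion-partial"][c.cohort_id] = p1
        insurance["expansion-universal"][c.cohort_id] = 1.0
    treatment = TreatmentModel(insured=dict(P_TREAT_INSURED),
                               uninsured=uninsured)
    return insurance, treatment


def _default_med_effect() -> MedicationEffect:
    # Transcribed from meta-analyses of blood-pressure-lowering trials:
    # proportionally larger stroke than CHD reduction, attenuating with age.
    rr_chd = {25: 0.75, 35: 0.76, 45: 0.78, 55: 0.80, 65: 0.82, 75: 0.85,
              85: 0.87}
    rr_stroke = {25: 0.60, 35: 0.62, 45: 0.64, 55: 0.66, 65: 0.68, 75: 0.72,
                 85: 0.75}
    return MedicationEffect(rr_chd=rr_chd, rr_stroke=rr_stroke)


def _default_event_mix() -> EventMix:
    male = {25: (0.55, 0.20, 0.25), 35: (0.52, 0.22, 0.26),
            45: (0.50, 0.24, 0.26), 55: (0.47, 0.26, 0.27),
            65: (0.45, 0.28, 0.27), 75: (0.44, 0.29, 0.27),
            85: (0.43, 0.30, 0.27)}
    female = {25: (0.45, 0.27, 0.28), 35: (0.43, 0.28, 0.29),
              45: (0.41, 0.30, 0.29), 55: (0.39, 0.31, 0.30),
              65: (0.38, 0.32, 0.30), 75: (0.37, 0.33, 0.30),
              85: (0.36, 0.34, 0.30)}
    mix = {}
    for lo, _ in EXTENDED_BANDS:
        mix[("male", lo)] = male[lo]
        mix[("female", lo)] = female[lo]
    return EventMix(mix=mix)


#: One-year case fatality for a first event among the insured, by event type
#: and age band. Uninsured x1.4, prior CVD history x1.5 (both capped at 0.95).
#: Provenance: transcribed/assumed.
_CF_BASE = {
    "mi": {25: 0.04, 35: 0.05, 45: 0.07, 55: 0.10, 65: 0.15, 75: 0.22,
           85: 0.32},
    "angina": {25: 0.010, 35: 0.012, 45: 0.015, 55: 0.020, 65: 0.030,
               75: 0.050, 85: 0.080},
    "stroke": {25: 0.06, 35: 0.07, 45: 0.09, 55: 0.12, 65: 0.18, 75: 0.27,
               85: 0.38},
}
_CF_UNINSURED_MULT = 1.4
_CF_HISTORY_MULT = 1.5


def _default_case_fatality() -> CaseFatalityTable:
    table = {}
    for event, by_band in _CF_BASE.items():
        for lo, base in by_band.items():
            for insured in (True, False):
                for history in (True, False):
                    p = base
                    if not insured:
                        p *= _CF_UNINSURED_MULT
                    if history:
                        p *= _CF_HISTORY_MULT
                    table[(event, lo, insured, history)] = min(p, 0.95)
    return CaseFatalityTable(table=table)


def _default_background_mortality() -> BackgroundMortality:
    # Gompertz-Makeham fit to US life-table all-cause mortality with the CVD
    # share removed; provenance: assumed.
    params = {"male": (0.0012, 4.0e-5, 0.085),
              "female": (0.0005, 2.8e-5, 0.085)}
    rates = {}
    for sex, (a, b, c) in params.items():
        rates[sex] = tuple(
            min(a + b * math.exp(c * age), 0.6)
            for age in range(MIN_AGE, MAX_AGE + 1)
        )
    return BackgroundMortality(age_start=MIN_AGE, rates=rates)


#: Share of baseline CVD events that are CHD (vs stroke), by sex, from the
#: published baseline outcome rates. Used to split the general-CVD equation
#: into disease-specific baseline survivals. Provenance: assumed.
_CHD_SHARE = {"male": 1366.0 / (1366.0 + 424.0),
              "female": 648.0 / (648.0 + 421.0)}


def _default_risk_coefficients() -> RiskCoefficients:
    # Sex-specific general-CVD Cox equations, transcribed exactly from the
    # published risk-function tables (provenance: transcribed).
    cvd = {
        "male": CoefficientSet(
            ln_age=3.06117, ln_sbp_untreated=1.93303, ln_sbp_treated=1.99881,
            ln_total_chol=1.12370, ln_hdl=-0.93263, smoker=0.65451,
            diabetes=0.57367, s0_10yr=0.88936, lp_mean=23.9802),
        "female": CoefficientSet(
            ln_age=2.32888, ln_sbp_untreated=2.76157, ln_sbp_treated=2.82263,
            ln_total_chol=1.20904, ln_hdl=-0.70833, smoker=0.52873,
            diabetes=0.69154, s0_10yr=0.95012, lp_mean=26.1931),
    }
    sets: dict[str, dict[str, CoefficientSet]] = {"cvd": cvd}
    # Disease-specific equations share the covariate coefficients; baseline
    # survival is split so that small-risk CHD:stroke proportions match the
    # sex-specific shares of baseline events (provenance: assumed).
    for disease in DISEASES:
        sets[disease] = {}
        for sex, cs in cvd.items():
            share = _CHD_SHARE[sex] if disease == "chd" else 1 - _CHD_SHARE[sex]
            sets[disease][sex] = dataclasses.replace(
                cs, s0_10yr=cs.s0_10yr ** share
            )
    return RiskCoefficients(sets=sets)


def _default_population_model() -> PopulationModel:
    # NHANES-2011-2012-like risk-factor summaries for hypertensive adults
    # (provenance: transcribed). Units: SBP mm Hg, cholesterol mg/dL.
    male = {
        25: RiskFactorCell(146, 11, 0.30, 195, 38, 47, 12, 0.04),
        35: RiskFactorCell(147, 12, 0.27, 202, 39, 46, 12, 0.07),
        45: RiskFactorCell(149, 13, 0.24, 205, 40, 46, 12, 0.12),
        55: RiskFactorCell(151, 14, 0.20, 203, 40, 47, 12, 0.18),
    }
    female = {
        25: RiskFactorCell(145, 10, 0.22, 192, 36, 56, 14, 0.05),
        35: RiskFactorCell(146, 11, 0.20, 198, 38, 56, 14, 0.08),
        45: RiskFactorCell(148, 13, 0.18, 208, 39, 57, 14, 0.13),
        55: RiskFactorCell(152, 14, 0.15, 214, 40, 58, 14, 0.19),
    }
    cells = {}
    for lo, _ in CORE_BANDS:
        cells[("male", lo)] = male[lo]
        cells[("female", lo)] = female[lo]
    return PopulationModel(cells=cells)


#: Race/ethnicity shares of the hypertensive population and scenario insured
#: fractions used for stratified runs. Provenance: assumed (consistent with
#: published insurance-rate differentials; Hispanics have the lowest pre-ACA
#: coverage and the smallest partial-expansion uptake because opt-out states
#: concentrate their uninsured).
_RACE_SHARE = {"white": 0.615, "black": 0.160, "hispanic": 0.115}
_RACE_INSURED_SHIFT = {"white": 0.04, "black": -0.05, "hispanic": -0.18}
_RACE_PARTIAL_UPTAKE = {"white": 0.60, "black": 0.55, "hispanic": 0.40}


def _default_race_blocks(
    cohorts: tuple[CohortSpec, ...],
) -> tuple[tuple[CohortSpec, ...], dict[str, dict[str, float]]]:
    race_cohorts = []
    insurance: dict[str, dict[str, float]] = {n: {} for n in SCENARIO_NAMES}
    for race, share in _RACE_SHARE.items():
        for c in cohorts:
            rc = dataclasses.replace(c, race=race,
                                     size=round(c.size * share))
            race_cohorts.append(rc)
            p0 = min(max(BASELINE_INSURED[c.age_lo]
                         + _RACE_INSURED_SHIFT[race], 0.0), 0.97)
            p1 = p0 + (1.0 - p0) * _RACE_PARTIAL_UPTAKE[race]
            insurance["baseline"][rc.cohort_id] = p0
            insurance["expansion-partial"][rc.cohort_id] = p1
            insurance["expansion-universal"][rc.cohort_id] = 1.0
    return tuple(race_cohorts), insurance


#: Prehypertensive adults (SBP 120-139) added by the sensitivity variant:
#: 53 million, skewed younger than the hypertensive cohorts, with lower
#: treatment probabilities. Provenance: assumed.
_PREHTN_BAND_SIZES = {25: 14_500_000, 35: 13_500_000, 45: 13_000_000,
                      55: 12_000_000}
_PREHTN_P_TREAT_INSURED = {"male": 0.25, "female": 0.30}


def _default_prehypertension(
    insurance_base: dict[str, dict[str, float]],
) -> PrehypertensionBlock:
    cohorts = []
    insurance: dict[str, dict[str, float]] = {n: {} for n in SCENARIO_NAMES}
    uninsured = {}
    for (lo, hi) in CORE_BANDS:
        size = _PREHTN_BAND_SIZES[lo]
        n_female = round(size * FEMALE_SHARE[lo])
        for sex, n in (("male", size - n_female), ("female", n_female)):
            c = CohortSpec(sex=sex, age_lo=lo, age_hi=hi, size=n,
                           start_age=(lo + hi + 1) // 2,
                           bp_group="prehypertension")
            cohorts.append(c)
            uninsured[(sex, lo)] = 0.4 * _PREHTN_P_TREAT_INSURED[sex]
            base_id = CohortSpec(sex=sex, age_lo=lo, age_hi=hi, size=0,
                                 start_age=0).cohort_id
            for name in SCENARIO_NAMES:
                insurance[name][c.cohort_id] = insurance_base[name][base_id]
    treatment = TreatmentModel(insured=dict(_PREHTN_P_TREAT_INSURED),
                               uninsured=uninsured)
    return PrehypertensionBlock(cohorts=tuple(cohorts), treatment=treatment,
                                insurance=insurance)


def default_parameters() -> ParameterSet:
    """The packaged default parameter set.

    Deterministic and referentially transparent: repeated calls compare
    equal. Cohort sizes and insured treatment probabilities reproduce the
    published treatment-rate table; everything else is transcribed or
    assumed as documented per block.
    """
    cohorts = _default_cohorts()
    insurance, treatment = _calibrated_insurance_and_treatment(cohorts)
    race_cohorts, race_insurance = _default_race_blocks(cohorts)
    for name in SCENARIO_NAMES:
        insurance[name].update(race_insurance[name])
    return ParameterSet(
        cohorts=cohorts,
        treatment=treatment,
        med_effect=_default_med_effect(),
        event_mix=_default_event_mix(),
        case_fatality=_default_case_fatality(),
        background_mortality=_default_background_mortality(),
        risk_coefficients=_default_risk_coefficients(),
        population=_default_population_model(),
        insurance=insurance,
        history_risk={"HX_MI": 2.0, "HX_ANGINA": 1.8, "HX_STROKE": 2.0},
        provenance={
            "cohorts": "published (band sizes); assumed (sex split)",
            "treatment.insured": "published",
            "treatment.uninsured": "calibrated to published baseline rates",
            "insurance.baseline": "assumed",
            "insurance.expansion-partial":
                "calibrated to published partial-expansion rates",
            "insurance.expansion-universal": "published (by definition)",
            "med_effect": "transcribed",
            "event_mix": "transcribed",
            "case_fatality": "transcribed/assumed",
            "background_mortality": "assumed (life table minus CVD)",
            "risk_coefficients.cvd": "transcribed",
            "risk_coefficients.chd/stroke": "assumed (share-split of cvd)",
            "population": "transcribed",
            "history_risk": "transcribed/assumed",
            "race_cohorts": "assumed",
            "prehypertension": "assumed",
        },
        race_cohorts=race_cohorts,
        prehypertension=_default_prehypertension(insurance),
    )


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def _check_prob(violations: list[str], where: str, value: float) -> None:
    if not isinstance(value, (int, float)) or math.isnan(value) \
            or not 0.0 <= value <= 1.0:
        violations.append(f"{where}: probability {value!r} outside [0, 1]")


def validate_parameters(params: ParameterSet) -> list[str]:
    """Check every invariant; return all violations (never raises).

    Each violation names the block, the key, and the rule it breaks.
    """
    v: list[str] = []

    if params.horizon_years < 1:
        v.append("horizon_years: must be >= 1")

    # cohorts: recognised disjoint bands, nonnegative sizes, start_age inside
    # the band; the band set must cover 25-64 unless deliberately reduced to
    # a single band (small test fixtures)
    seen_bands = set()
    groups: dict[tuple[str, str, str], list[tuple[int, int]]] = {}
    for c in params.cohorts:
        if c.size < 0:
            v.append(f"cohorts[{c.cohort_id}].size: negative ({c.size})")
        if not (c.age_lo <= c.start_age <= c.age_hi):
            v.append(
                f"cohorts[{c.cohort_id}].start_age: {c.start_age} outside "
                f"band [{c.age_lo}, {c.age_hi}]"
            )
        if (c.age_lo, c.age_hi) not in CORE_BANDS:
            v.append(
                f"cohorts[{c.cohort_id}]: band [{c.age_lo}, {c.age_hi}] is "
                "not one of the 10-year bands between 25 and 64"
            )
        seen_bands.add((c.age_lo, c.age_hi))
        groups.setdefault((c.sex, c.race, c.bp_group), []).append(
            (c.age_lo, c.age_hi)
        )
    for gkey, bands in groups.items():
        if len(bands) != len(set(bands)):
            v.append(f"cohorts: duplicate age band for group {gkey}")
    if len(seen_bands) > 1 and seen_bands != set(CORE_BANDS):
        v.append(
            "cohorts: age bands must jointly cover 25-64 (or be a single "
            f"band for reduced fixtures), got {sorted(seen_bands)}"
        )

    for sex, p in params.treatment.insured.items():
        _check_prob(v, f"treatment.insured[{sex}]", p)
    for key, p in params.treatment.uninsured.items():
        _check_prob(v, f"treatment.uninsured[{key}]", p)
        sex = key[0]
        if sex in params.treatment.insured and 0 <= p <= 1 \
                and p > params.treatment.insured[sex]:
            v.append(
                f"treatment.uninsured[{key}]: {p} exceeds insured "
                f"probability {params.treatment.insured[sex]}"
            )

    for name, table in (("rr_chd", params.med_effect.rr_chd),
                        ("rr_stroke", params.med_effect.rr_stroke)):
        for lo, rr in table.items():
            if not 0.0 < rr <= 1.0:
                v.append(f"med_effect.{name}[{lo}]: relative risk {rr} "
                         "outside (0, 1]")

    for key, probs in params.event_mix.mix.items():
        for p in probs:
            _check_prob(v, f"event_mix[{key}]", p)
        if abs(sum(probs) - 1.0) > 1e-9:
            v.append(f"event_mix[{key}]: probabilities sum to {sum(probs)}, "
                     "not 1 (tolerance 1e-9)")

    for key, p in params.case_fatality.table.items():
        _check_prob(v, f"case_fatality[{key}]", p)
    # monotone nondecreasing in age within each (event, insured, history)
    bands = [lo for lo, _ in EXTENDED_BANDS]
    for event in EVENT_TYPES:
        for insured in (True, False):
            for hist in (True, False):
                vals = [params.case_fatality.table.get(
                    (event, lo, insured, hist)) for lo in bands]
                vals = [x for x in vals if x is not None]
                if any(b < a for a, b in zip(vals, vals[1:])):
                    v.append(
                        f"case_fatality[{event}, insured={insured}, "
                        f"history={hist}]: not nondecreasing in age"
                    )

    for sex, qs in params.background_mortality.rates.items():
        for i, q in enumerate(qs):
            if not 0.0 <= q <= 1.0:
                v.append(
                    f"background_mortality[{sex}][age "
                    f"{params.background_mortality.age_start + i}]: {q} "
                    "outside [0, 1]"
                )
        start = params.background_mortality.age_start
        from30 = qs[max(30 - start, 0):]
        if any(b < a for a, b in zip(from30, from30[1:])):
            v.append(f"background_mortality[{sex}]: not nondecreasing for "
                     "ages >= 30")

    for disease, by_sex in params.risk_coefficients.sets.items():
        for sex, cs in by_sex.items():
            if not 0.0 < cs.s0_10yr <= 1.0:
                v.append(f"risk_coefficients[{disease}][{sex}].s0_10yr: "
                         f"{cs.s0_10yr} outside (0, 1]")

    for key, cell in params.population.cells.items():
        for fname in ("smoking", "diabetes"):
            _check_prob(v, f"population[{key}].{fname}",
                        getattr(cell, fname))
        for fname in ("sbp_sd", "tc_sd", "hdl_sd"):
            if getattr(cell, fname) <= 0:
                v.append(f"population[{key}].{fname}: sd must be > 0")

    for scenario, by_cohort in params.insurance.items():
        for cid, p in by_cohort.items():
            _check_prob(v, f"insurance[{scenario}][{cid}]", p)
    universal = params.insurance.get("expansion-universal", {})
    for cid, p in universal.items():
        if p != 1.0:
            v.append(f"insurance[expansion-universal][{cid}]: must be 1.0, "
                     f"got {p}")

    for state, mult in params.history_risk.items():
        if mult < 1.0:
            v.append(f"history_risk[{state}]: multiplier {mult} < 1")

    for cid, probs in params.fixed_annual_probabilities.items():
        for disease, p in probs.items():
            _check_prob(v, f"fixed_annual_probabilities[{cid}][{disease}]", p)

    return v


# ---------------------------------------------------------------------------
# (de)serialisation
# ---------------------------------------------------------------------------

def parameters_to_dict(params: ParameterSet) -> dict[str, Any]:
    """Plain-dict (YAML-ready) form of a parameter set."""

    def cohort_dict(c: CohortSpec) -> dict[str, Any]:
        return {"sex": c.sex, "age_lo": c.age_lo, "age_hi": c.age_hi,
                "size": c.size, "start_age": c.start_age, "race": c.race,
                "bp_group": c.bp_group}

    def treatment_dict(t: TreatmentModel) -> dict[str, Any]:
        unins: dict[str, dict[int, float]] = {}
        for (sex, lo), p in t.uninsured.items():
            unins.setdefault(sex, {})[lo] = p
        return {"insured": dict(t.insured), "uninsured": unins}

    mix = {}
    for (sex, lo), probs in params.event_mix.mix.items():
        mix.setdefault(sex, {})[lo] = {
            "mi": probs[0], "stable_angina": probs[1],
            "unstable_angina": probs[2],
        }

    cf: dict[str, Any] = {}
    for (event, lo, insured, hist), p in params.case_fatality.table.items():
        cf.setdefault(event, {}).setdefault(lo, {}).setdefault(
            "insured" if insured else "uninsured", {}
        )["recurrent" if hist else "first"] = p

    coeffs = {
        disease: {sex: dataclasses.asdict(cs) for sex, cs in by_sex.items()}
        for disease, by_sex in params.risk_coefficients.sets.items()
    }

    pop = {}
    for (sex, lo), cell in params.population.cells.items():
        pop.setdefault(sex, {})[lo] = dataclasses.asdict(cell)

    out: dict[str, Any] = {
        "schema_version": params.schema_version,
        "horizon_years": params.horizon_years,
        "start_year": params.start_year,
        "cohorts": [cohort_dict(c) for c in params.cohorts],
        "treatment": treatment_dict(params.treatment),
        "med_effect": {"rr_chd": dict(params.med_effect.rr_chd),
                       "rr_stroke": dict(params.med_effect.rr_stroke)},
        "event_mix": mix,
        "case_fatality": cf,
        "background_mortality": {
            "age_start": params.background_mortality.age_start,
            "rates": {s: list(q)
                      for s, q in params.background_mortality.rates.items()},
        },
        "risk_coefficients": coeffs,
        "population": pop,
        "insurance": {k: dict(vv) for k, vv in params.insurance.items()},
        "history_risk": dict(params.history_risk),
        "provenance": dict(params.provenance),
        "race_cohorts": [cohort_dict(c) for c in params.race_cohorts],
    }
    if params.fixed_annual_probabilities:
        out["fixed_annual_probabilities"] = {
            cid: dict(p) for cid, p in params.fixed_annual_probabilities.items()
        }
    if params.prehypertension is not None:
        pre = params.prehypertension
        out["prehypertension"] = {
            "cohorts": [cohort_dict(c) for c in pre.cohorts],
            "treatment": treatment_dict(pre.treatment),
            "insurance": {k: dict(vv) for k, vv in pre.insurance.items()},
        }
    return out


_KNOWN_KEYS = {
    "schema_version", "horizon_years", "start_year", "cohorts", "treatment",
    "med_effect", "event_mix", "case_fatality", "background_mortality",
    "risk_coefficients", "population", "insurance", "history_risk",
    "provenance", "race_cohorts", "prehypertension",
    "fixed_annual_probabilities",
}


def _parse_cohort(d: dict[str, Any], where: str) -> CohortSpec:
    try:
        return CohortSpec(
            sex=d["sex"], age_lo=int(d["age_lo"]), age_hi=int(d["age_hi"]),
            size=int(d["size"]), start_age=int(d["start_age"]),
            race=d.get("race", "all"),
            bp_group=d.get("bp_group", "hypertension"),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise SchemaError(f"{where}: bad cohort entry ({exc!r})") from exc


def _parse_treatment(d: dict[str, Any], where: str) -> TreatmentModel:
    try:
        uninsured = {
            (sex, int(lo)): float(p)
            for sex, by_band in d["uninsured"].items()
            for lo, p in by_band.items()
        }
        return TreatmentModel(
            insured={s: float(p) for s, p in d["insured"].items()},
            uninsured=uninsured,
        )
    except (KeyError, AttributeError, TypeError, ValueError) as exc:
        raise SchemaError(f"{where}: bad treatment block ({exc!r})") from exc


def parameters_from_dict(data: dict[str, Any]) -> ParameterSet:
    """Build a ParameterSet from a plain dict, filling missing blocks from
    the packaged defaults. Raises :class:`SchemaError` naming the offending
    key on malformed input."""
    if not isinstance(data, dict):
        raise SchemaError(f"top level must be a mapping, got {type(data)}")
    unknown = set(data) - _KNOWN_KEYS
    if unknown:
        raise SchemaError(f"unknown top-level key(s): {sorted(unknown)}")

    defaults = default_parameters()
    out: dict[str, Any] = {}

    if "cohorts" in data:
        out["cohorts"] = tuple(
            _parse_cohort(c, f"cohorts[{i}]")
            for i, c in enumerate(data["cohorts"])
        )
    if "race_cohorts" in data:
        out["race_cohorts"] = tuple(
            _parse_cohort(c, f"race_cohorts[{i}]")
            for i, c in enumerate(data["race_cohorts"])
        )
    if "treatment" in data:
        out["treatment"] = _parse_treatment(data["treatment"], "treatment")
    if "med_effect" in data:
        try:
            out["med_effect"] = MedicationEffect(
                rr_chd={int(k): float(x)
                        for k, x in data["med_effect"]["rr_chd"].items()},
                rr_stroke={int(k): float(x)
                           for k, x in data["med_effect"]["rr_stroke"].items()},
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise SchemaError(f"med_effect: {exc!r}") from exc
    if "event_mix" in data:
        try:
            mix = {}
            for sex, by_band in data["event_mix"].items():
                for lo, probs in by_band.items():
                    mix[(sex, int(lo))] = (
                        float(probs["mi"]), float(probs["stable_angina"]),
                        float(probs["unstable_angina"]),
                    )
            out["event_mix"] = EventMix(mix=mix)
        except (KeyError, TypeError, ValueError) as exc:
            raise SchemaError(f"event_mix: {exc!r}") from exc
    if "case_fatality" in data:
        try:
            table = {}
            for event, by_band in data["case_fatality"].items():
                for lo, by_ins in by_band.items():
                    for ins_key, by_hist in by_ins.items():
                        insured = {"insured": True, "uninsured": False}[ins_key]
                        for hist_key, p in by_hist.items():
                            hist = {"first": False,
                                    "recurrent": True}[hist_key]
                            table[(event, int(lo), insured, hist)] = float(p)
            out["case_fatality"] = CaseFatalityTable(table=table)
        except (KeyError, TypeError, ValueError) as exc:
            raise SchemaError(f"case_fatality: {exc!r}") from exc
    if "background_mortality" in data:
        try:
            bm = data["background_mortality"]
            out["background_mortality"] = BackgroundMortality(
                age_start=int(bm["age_start"]),
                rates={s: tuple(float(x) for x in qs)
                       for s, qs in bm["rates"].items()},
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise SchemaError(f"background_mortality: {exc!r}") from exc
    if "risk_coefficients" in data:
        try:
            out["risk_coefficients"] = RiskCoefficients(sets={
                disease: {sex: CoefficientSet(**cs)
                          for sex, cs in by_sex.items()}
                for disease, by_sex in data["risk_coefficients"].items()
            })
        except (KeyError, TypeError, ValueError) as exc:
            raise SchemaError(f"risk_coefficients: {exc!r}") from exc
    if "population" in data:
        try:
            cells = {}
            for sex, by_band in data["population"].items():
                for lo, cell in by_band.items():
                    cells[(sex, int(lo))] = RiskFactorCell(**cell)
            out["population"] = PopulationModel(cells=cells)
        except (KeyError, TypeError, ValueError) as exc:
            raise SchemaError(f"population: {exc!r}") from exc
    if "insurance" in data:
        try:
            out["insurance"] = {
                name: {cid: float(p) for cid, p in by_cohort.items()}
                for name, by_cohort in data["insurance"].items()
            }
        except (AttributeError, TypeError, ValueError) as exc:
            raise SchemaError(f"insurance: {exc!r}") from exc
    if "history_risk" in data:
        out["history_risk"] = {k: float(x)
                               for k, x in data["history_risk"].items()}
    if "fixed_annual_probabilities" in data:
        out["fixed_annual_probabilities"] = {
            cid: {d: float(p) for d, p in probs.items()}
            for cid, probs in data["fixed_annual_probabilities"].items()
        }
    if "prehypertension" in data:
        try:
            pre = data["prehypertension"]
            out["prehypertension"] = PrehypertensionBlock(
                cohorts=tuple(
                    _parse_cohort(c, f"prehypertension.cohorts[{i}]")
                    for i, c in enumerate(pre["cohorts"])
                ),
                treatment=_parse_treatment(pre["treatment"],
                                           "prehypertension.treatment"),
                insurance={
                    name: {cid: float(p) for cid, p in by_cohort.items()}
                    for name, by_cohort in pre["insurance"].items()
                },
            )
        except (KeyError, TypeError) as exc:
            raise SchemaError(f"prehypertension: {exc!r}") from exc
    for key in ("horizon_years", "start_year", "schema_version"):
        if key in data:
            try:
                out[key] = int(data[key])
            except (TypeError, ValueError) as exc:
                raise SchemaError(f"{key}: not an integer") from exc
    if "provenance" in data:
        out["provenance"] = dict(data["provenance"])

    return dataclasses.replace(defaults, **out)


def load_parameters(path: str) -> ParameterSet:
    """Load and validate a YAML parameter file.

    Missing blocks are filled from the packaged defaults; an empty file
    yields :func:`default_parameters` exactly. Raises :class:`SchemaError`
    on malformed input and :class:`ValidationError` (listing every
    violation) on invariant failures.
    """
    with open(path) as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise SchemaError(f"{path}: not valid YAML ({exc})") from exc
    if data is None:
        return default_parameters()
    params = parameters_from_dict(data)
    violations = validate_parameters(params)
    if violations:
        raise ValidationError(violations)
    return params


def write_parameters(params: ParameterSet, path: str) -> None:
    """Write a parameter set as YAML; round-trips through
    :func:`load_parameters` to an equal ParameterSet."""
    with open(path, "w") as fh:
        yaml.safe_dump(parameters_to_dict(params), fh, sort_keys=False)


def format_provenance(params: ParameterSet) -> str:
    lines = ["provenance:"]
    for block, label in sorted(params.provenance.items()):
        lines.append(f"  {block}: {label}")
    return "\n".join(lines)
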
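"""Risk functions: 10-year CVD/CHD/stroke risk, annual conversion,
treatment effects, CHD subtype draws, and case fatality.

The core equation is the sex-specific Cox-form risk function
``risk = 1 - s0 ** exp(lp - lp_mean)`` with a log-linear predictor over age,
systolic blood pressure, total and HDL cholesterol, smoking and diabetes.
Ages above the equation's validated range (74 by default) are clamped before
evaluation rather than extrapolated; the clamp is logged once per process.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .parameters import (
    CaseFatalityTable,
    CoefficientSet,
    EventMix,
    RiskCoefficients,
)

logger = logging.getLogger(__name__)

_age_clamp_logged = False


class RangeError(ValueError):
    """An input lies outside its supported range."""


@dataclass
class RiskProfile:
    """One individual's risk-factor profile.

    Units: age years, systolic_bp mm Hg, cholesterol mg/dL.
    ``treated_hypertension`` selects the treated-blood-pressure coefficient
    in the risk equation.
    """

    sex: str
    age: float
    systolic_bp: float
    smoker: bool
    total_cholesterol: float
    hdl_cholesterol: float
    diabetes: bool
    race: str | None = None
    treated_hypertension: bool = False

    def validate(self) -> None:
        if not 20 <= self.age <= 110:
            raise RangeError(f"age {self.age} outside [20, 110]")
        if not 70 <= self.systolic_bp <= 300:
            raise RangeError(
                f"systolic_bp {self.systolic_bp} outside [70, 300]"
            )
        if self.total_cholesterol <= 0:
            raise RangeError("total_cholesterol must be positive")
        if self.hdl_cholesterol <= 0:
            raise RangeError("hdl_cholesterol must be positive")


def _log_age_clamp(max_age: int) -> None:
    global _age_clamp_logged
    if not _age_clamp_logged:
        logger.info(
            "risk-function age clamped at %d for individuals aging past the "
            "validated range (logged once)", max_age,
        )
        _age_clamp_logged = True


def ten_year_risk_arrays(
    cs: CoefficientSet,
    age: np.ndarray,
    systolic_bp: np.ndarray,
    bp_treated: np.ndarray,
    smoker: np.ndarray,
    total_chol: np.ndarray,
    hdl: np.ndarray,
    diabetes: np.ndarray,
) -> np.ndarray:
    """Vectorised 10-year risk for arrays of covariates (no range checks)."""
    age_c = np.minimum(age, cs.max_age)
    if np.any(age > cs.max_age):
        _log_age_clamp(cs.max_age)
    ln_sbp = np.log(systolic_bp)
    lp = (
        cs.ln_age * np.log(age_c)
        + np.where(bp_treated, cs.ln_sbp_treated, cs.ln_sbp_untreated) * ln_sbp
        + cs.ln_total_chol * np.log(total_chol)
        + cs.ln_hdl * np.log(hdl)
        + cs.smoker * np.asarray(smoker, dtype=float)
        + cs.diabetes * np.asarray(diabetes, dtype=float)
    )
    risk = 1.0 - cs.s0_10yr ** np.exp(lp - cs.lp_mean)
    return np.clip(risk, 0.0, 1.0)


def ten_year_risk(profile: RiskProfile, disease: str,
                  coefficients: RiskCoefficients) -> float:
    """10-year probability of ``disease`` ("cvd", "chd" or "stroke").

    Deterministic in its inputs; raises :class:`RangeError` for covariates
    outside the supported clinical ranges and :class:`LookupError` when no
    coefficient set exists for the disease/sex.
    """
    profile.validate()
    cs = coefficients.get(disease, profile.sex)
    out = ten_year_risk_arrays(
        cs,
        np.asarray([profile.age], dtype=float),
        np.asarray([profile.systolic_bp], dtype=float),
        np.asarray([profile.treated_hypertension]),
        np.asarray([profile.smoker]),
        np.asarray([profile.total_cholesterol], dtype=float),
        np.asarray([profile.hdl_cholesterol], dtype=float),
        np.asarray([profile.diabetes]),
    )
    return float(out[0])


def annual_probability(p10):
    """Constant-hazard conversion of a 10-year probability to a 1-year one:
    ``1 - (1 - p10) ** (1/10)``. Accepts scalars or arrays."""
    arr = np.asarray(p10, dtype=float)
    if np.any((arr < 0.0) | (arr > 1.0)):
        raise RangeError(f"10-year probability outside [0, 1]")
    out = 1.0 - (1.0 - arr) ** 0.1
    return float(out) if np.isscalar(p10) else out


def apply_treatment(p: float, rr: float) -> float:
    """Scale an event probability by a treatment relative risk, clamped at 1.

    Untreated individuals pass ``rr = 1``.
    """
    if not 0.0 <= p <= 1.0:
        raise RangeError(f"probability {p} outside [0, 1]")
    if rr <= 0.0:
        raise RangeError(f"relative risk {rr} must be > 0")
    return min(1.0, p * rr)


def draw_chd_subtype(age: float, sex: str, event_mix: EventMix,
                     rng: np.random.Generator) -> str:
    """Draw an incident CHD event type (mi / stable_angina / unstable_angina)
    from the configured mix for the person's sex and age band."""
    p_mi, p_stable, _ = event_mix.probabilities(sex, age)
    u = rng.random()
    if u < p_mi:
        return "mi"
    if u < p_mi + p_stable:
        return "stable_angina"
    return "unstable_angina"


def case_fatality_probability(table: CaseFatalityTable, event: str,
                              age: float, insured: bool,
                              has_history: bool) -> float:
    """One-year death probability after an event (table lookup).

    ``event`` is "mi", "angina" or "stroke"; stable and unstable angina are
    pooled for fatality.
    """
    return table.probability(event, age, insured, has_history)
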
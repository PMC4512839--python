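"""Risk functions: the Cox-form equations, probability conversions,
treatment scaling, subtype draws, case fatality."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from htnsim import (
    RiskProfile,
    annual_probability,
    apply_treatment,
    case_fatality_probability,
    draw_chd_subtype,
    ten_year_risk,
)
from htnsim.parameters import (
    CoefficientSet,
    EventMix,
    RiskCoefficients,
)
from htnsim.risk import RangeError


def _reference_risk(cs, age, sbp, tc, hdl, smoker, diabetes,
                    bp_treated=False):
    """Independent spreadsheet-style evaluation of the published equation."""
    lp = (cs.ln_age * math.log(min(age, cs.max_age))
          + (cs.ln_sbp_treated if bp_treated else cs.ln_sbp_untreated)
          * math.log(sbp)
          + cs.ln_total_chol * math.log(tc)
          + cs.ln_hdl * math.log(hdl)
          + cs.smoker * smoker + cs.diabetes * diabetes)
    return 1.0 - cs.s0_10yr ** math.exp(lp - cs.lp_mean)


@pytest.mark.parametrize(
    "sex, age, sbp, tc, hdl, smoker, diabetes",
    [
        ("female", 61, 124, 180, 47, True, False),  # published worked example
        ("male", 53, 125, 161, 55, False, False),
        ("male", 60, 150, 210, 42, True, True),
        ("female", 45, 145, 200, 58, False, False),
    ],
)
def test_ten_year_cvd_risk_matches_independent_evaluation(
        params, sex, age, sbp, tc, hdl, smoker, diabetes):
    profile = RiskProfile(sex=sex, age=age, systolic_bp=sbp, smoker=smoker,
                          total_cholesterol=tc, hdl_cholesterol=hdl,
                          diabetes=diabetes)
    cs = params.risk_coefficients.get("cvd", sex)
    expected = _reference_risk(cs, age, sbp, tc, hdl, smoker, diabetes)
    assert ten_year_risk(profile, "cvd",
                         params.risk_coefficients) == pytest.approx(
        expected, abs=1e-6)


def test_published_worked_example_value(params):
    """The published example (61-year-old smoking woman, SBP 124 untreated,
    TC 180, HDL 47, no diabetes) prints a 10-year general-CVD risk of
    10.48%."""
    profile = RiskProfile(sex="female", age=61, systolic_bp=124, smoker=True,
                          total_cholesterol=180, hdl_cholesterol=47,
                          diabetes=False)
    risk = ten_year_risk(profile, "cvd", params.risk_coefficients)
    assert risk == pytest.approx(0.10484180, abs=1e-6)


def test_zero_coefficients_reduce_to_baseline_risk():
    cs = CoefficientSet(ln_age=0, ln_sbp_untreated=0, ln_sbp_treated=0,
                        ln_total_chol=0, ln_hdl=0, smoker=0, diabetes=0,
                        s0_10yr=0.95, lp_mean=0)
    coefs = RiskCoefficients(sets={"cvd": {"male": cs, "female": cs}})
    for sbp in (120, 180):
        profile = RiskProfile(sex="male", age=50, systolic_bp=sbp,
                              smoker=True, total_cholesterol=250,
                              hdl_cholesterol=35, diabetes=True)
        assert ten_year_risk(profile, "cvd", coefs) == pytest.approx(0.05)


def test_risk_nondecreasing_in_systolic_bp(params):
    risks = [
        ten_year_risk(
            RiskProfile(sex="male", age=55, systolic_bp=sbp, smoker=False,
                        total_cholesterol=200, hdl_cholesterol=45,
                        diabetes=False),
            "chd", params.risk_coefficients)
        for sbp in range(120, 220, 10)
    ]
    assert all(b >= a for a, b in zip(risks, risks[1:]))


def test_risk_invariant_to_irrelevant_fields(params):
    base = RiskProfile(sex="female", age=50, systolic_bp=150, smoker=False,
                       total_cholesterol=210, hdl_cholesterol=55,
                       diabetes=False)
    other = dataclasses.replace(base, race="black")
    assert ten_year_risk(base, "stroke", params.risk_coefficients) == \
        ten_year_risk(other, "stroke", params.risk_coefficients)


def test_age_clamped_at_validated_range(params):
    """Risks stop growing with age once past the equations' support."""
    mk = lambda age: RiskProfile(sex="male", age=age, systolic_bp=150,
                                 smoker=False, total_cholesterol=200,
                                 hdl_cholesterol=45, diabetes=False)
    r74 = ten_year_risk(mk(74), "cvd", params.risk_coefficients)
    r90 = ten_year_risk(mk(90), "cvd", params.risk_coefficients)
    assert r90 == pytest.approx(r74)


@pytest.mark.parametrize("field, value", [
    ("age", 19), ("age", 111), ("systolic_bp", 60), ("systolic_bp", 310),
    ("total_cholesterol", -1), ("hdl_cholesterol", 0),
])
def test_out_of_range_covariates_raise(params, field, value):
    profile = RiskProfile(sex="male", age=50, systolic_bp=140, smoker=False,
                          total_cholesterol=200, hdl_cholesterol=45,
                          diabetes=False)
    profile = dataclasses.replace(profile, **{field: value})
    with pytest.raises(RangeError):
        ten_year_risk(profile, "cvd", params.risk_coefficients)


def test_annual_probability_known_values():
    assert annual_probability(0.0) == 0.0
    assert annual_probability(1.0) == 1.0
    assert annual_probability(0.10) == pytest.approx(0.010481, abs=1e-6)


def test_annual_probability_rejects_out_of_range():
    with pytest.raises(RangeError):
        annual_probability(1.5)
    with pytest.raises(RangeError):
        annual_probability(-0.1)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.floats(min_value=0.0, max_value=0.999999))
def test_annual_probability_inverts_ten_year_compounding(p10):
    annual = annual_probability(p10)
    assert 1.0 - (1.0 - annual) ** 10 == pytest.approx(p10, abs=1e-12)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.floats(min_value=0.0, max_value=1.0),
       st.floats(min_value=1e-6, max_value=1.0))
def test_treatment_never_raises_risk_when_protective(p, rr):
    assert apply_treatment(p, rr) <= p


def test_apply_treatment_identity_clamp_and_errors():
    assert apply_treatment(0.02, 1.0) == 0.02
    assert apply_treatment(0.9, 1.2) == 1.0
    with pytest.raises(RangeError):
        apply_treatment(0.02, 0.0)
    with pytest.raises(RangeError):
        apply_treatment(1.1, 0.5)


def test_chd_subtype_degenerate_mix_always_mi():
    mix = EventMix(mix={("male", 55): (1.0, 0.0, 0.0)})
    rng = np.random.default_rng(0)
    assert all(draw_chd_subtype(60, "male", mix, rng) == "mi"
               for _ in range(200))


def test_chd_subtype_frequencies_converge_to_mix():
    third = 1.0 / 3.0
    mix = EventMix(mix={("female", 45): (third, third, third)})
    rng = np.random.default_rng(123)
    draws = [draw_chd_subtype(50, "female", mix, rng) for _ in range(30_000)]
    for kind in ("mi", "stable_angina", "unstable_angina"):
        freq = draws.count(kind) / len(draws)
        assert abs(freq - third) < 0.02


def test_chd_subtype_seeded_draws_reproducible():
    mix = EventMix(mix={("male", 35): (0.5, 0.3, 0.2)})
    seq1 = [draw_chd_subtype(40, "male", mix, np.random.default_rng(7))
            for _ in range(1)]
    rng_a, rng_b = np.random.default_rng(7), np.random.default_rng(7)
    a = [draw_chd_subtype(40, "male", mix, rng_a) for _ in range(100)]
    b = [draw_chd_subtype(40, "male", mix, rng_b) for _ in range(100)]
    assert a == b and a[:1] == seq1


def test_chd_subtype_missing_mix_entry_raises():
    mix = EventMix(mix={("male", 55): (1.0, 0.0, 0.0)})
    with pytest.raises(LookupError):
        draw_chd_subtype(60, "female", mix, np.random.default_rng(0))


def test_case_fatality_insured_never_worse_than_uninsured(params):
    """The default table's construction rule: coverage at the time of an
    event never raises one-year fatality."""
    table = params.case_fatality
    keys = {(event, lo, hist) for (event, lo, _, hist) in table.table}
    for event, lo, hist in keys:
        age = lo + 1
        assert case_fatality_probability(table, event, age, True, hist) <= \
            case_fatality_probability(table, event, age, False, hist)


def test_case_fatality_history_never_protective(params):
    table = params.case_fatality
    keys = {(event, lo, ins) for (event, lo, ins, _) in table.table}
    for event, lo, ins in keys:
        assert case_fatality_probability(table, event, lo, ins, True) >= \
            case_fatality_probability(table, event, lo, ins, False)


def test_case_fatality_missing_entry_names_the_key():
    from htnsim.parameters import CaseFatalityTable

    table = CaseFatalityTable(table={("mi", 25, True, False): 0.0})
    assert case_fatality_probability(table, "mi", 30, True, False) == 0.0
    with pytest.raises(LookupError, match="stroke"):
        case_fatality_probability(table, "stroke", 30, True, False)
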
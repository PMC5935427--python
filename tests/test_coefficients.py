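"""Allocation-coefficient estimation: formulas, oracle equality, convergence."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import sha2011 as sh
from sha2011.coefficients import SurveyTallies
from sha2011.errors import EstimationError


def _tallies(**pooled) -> SurveyTallies:
    """Minimal single-stratum tallies for formula tests."""
    base = {c: 0.0 for c in [
        "preventive_outpatient_income", "total_outpatient_income",
        "n_medical_service", "n_public_health", "n_medical_service_children",
        "n_public_health_children", "inpatient_bed_days",
        "outpatient_visits_total", "outpatient_visits_preventive",
        "survey_medical_income"]}
    base.update(pooled)
    df = pd.DataFrame([base], index=pd.Index(["general_hospital"], name="provider_type"))
    return SurveyTallies(by_stratum=df, cost_table=pd.DataFrame(),
                         children_cost_share=pd.DataFrame())


@pytest.mark.parametrize(
    "e_poi,e_toi,expected",
    [(0.0, 500.0, 1.0), (500.0, 500.0, 0.0), (200.0, 1000.0, 0.8)],
)
def test_curative_outpatient_fraction(e_poi, e_toi, expected):
    t = _tallies(preventive_outpatient_income=e_poi, total_outpatient_income=e_toi)
    assert sh.curative_outpatient_fraction(t) == pytest.approx(expected, abs=1e-15)


@pytest.mark.parametrize(
    "n_ms,n_phs,expected",
    [(10.0, 0.0, 1.0), (50.0, 50.0, 0.5), (300.0, 100.0, 0.75)],
)
def test_subsidy_curative_fraction(n_ms, n_phs, expected):
    t = _tallies(n_medical_service=n_ms, n_public_health=n_phs)
    assert sh.subsidy_curative_fraction(t) == pytest.approx(expected, abs=1e-15)


@pytest.mark.parametrize(
    "n_pov,n_tov,expected",
    [(0.0, 10.0, 1.0), (600.0, 600.0, 0.0), (150.0, 600.0, 0.75)],
)
def test_curative_visit_fraction(n_pov, n_tov, expected):
    t = _tallies(outpatient_visits_preventive=n_pov, outpatient_visits_total=n_tov)
    assert sh.curative_visit_fraction(t) == pytest.approx(expected, abs=1e-15)


@pytest.mark.parametrize(
    "n_ibd,n_iov,expected",
    [(1000.0, 0.0, 1.0), (1000.0, 10000.0, 0.5), (0.0, 500.0, 0.0)],
)
def test_inpatient_workload_share(n_ibd, n_iov, expected):
    assert sh.inpatient_workload_share(n_ibd, n_iov, kappa=0.1) == pytest.approx(expected)


def test_inpatient_workload_share_literal_reading():
    # the alternative reading multiplies the ratio by kappa, capping it there
    assert sh.inpatient_workload_share(1000, 10000, 0.1, scale_by_kappa=True) == \
        pytest.approx(0.05)


def test_zero_denominators_raise():
    with pytest.raises(EstimationError):
        sh.curative_outpatient_fraction(_tallies())
    with pytest.raises(EstimationError):
        sh.subsidy_curative_fraction(_tallies())
    with pytest.raises(EstimationError):
        sh.curative_visit_fraction(_tallies())
    with pytest.raises(EstimationError):
        sh.inpatient_workload_share(0.0, 0.0)


def test_empty_survey_raises(census):
    with pytest.raises(EstimationError, match="no survey records"):
        sh.tally(census.encounters.iloc[0:0], census.institutions)


def test_children_boundary_inclusive():
    """Ages 2, 14, 15: two fall in the inclusive <=14 children scope."""
    institutions = pd.DataFrame([{
        "institution_id": "I1", "provider_type": "general_hospital",
        **{c: 0.0 for c in sh.survey_ingest.FINANCE_MONEY_COLUMNS},
        "prevention_projects": []}])
    rows = []
    for age in (2, 14, 15):
        rows.append({
            "institution_id": "I1", "age_years": age, "sex": "F", "icd10_code": "J20",
            "service_type": "outpatient_curative", "bed_days": 0, "total_cost": 10.0,
            "social_insurance": 0.0, "commercial_insurance": 0.0, "donation": 0.0,
            "government_program": 0.0, "out_of_pocket": 10.0})
    tallies = sh.tally(pd.DataFrame(rows), institutions, target_age_max=14)
    assert tallies.by_stratum["n_medical_service_children"].sum() == 2
    share = tallies.children_cost_share.loc[("general_hospital", "outpatient_curative"), "share"]
    assert share == pytest.approx(2 / 3)


def test_tally_matches_brute_force(census):
    """Every tally equals an independent filter-and-sum over the record list."""
    tallies = sh.tally(census.encounters, census.institutions)
    enc = census.encounters.merge(
        census.institutions[["institution_id", "provider_type"]], on="institution_id")
    records = list(enc.itertuples(index=False))
    p = tallies.pooled
    assert p["preventive_outpatient_income"] == pytest.approx(
        sum(r.total_cost for r in records if r.service_type == "outpatient_preventive"),
        rel=1e-12)
    assert p["total_outpatient_income"] == pytest.approx(
        sum(r.total_cost for r in records
            if r.service_type in ("outpatient_curative", "outpatient_preventive")),
        rel=1e-12)
    assert p["n_medical_service"] == sum(
        r.service_type in ("outpatient_curative", "inpatient") for r in records)
    assert p["n_public_health"] == sum(
        r.service_type in ("outpatient_preventive", "public_health") for r in records)
    assert p["inpatient_bed_days"] == sum(r.bed_days for r in records)
    assert p["outpatient_visits_preventive"] == sum(
        r.service_type == "outpatient_preventive" for r in records)
    assert p["n_medical_service_children"] == sum(
        r.service_type in ("outpatient_curative", "inpatient") and r.age_years <= 14
        for r in records)
    # per-stratum tallies sum the same way
    for ptype, row in tallies.by_stratum.iterrows():
        assert row["total_outpatient_income"] == pytest.approx(
            sum(r.total_cost for r in records if r.provider_type == ptype
                and r.service_type in ("outpatient_curative", "outpatient_preventive")),
            rel=1e-12)


def test_coefficients_within_unit_interval(census_coefficients):
    c = census_coefficients
    for name in ("alpha_i", "alpha_s", "upsilon", "beta"):
        assert 0.0 <= getattr(c, name) <= 1.0
        col = c.by_stratum[name]
        assert ((col >= 0) & (col <= 1)).all()


@settings(derandomize=True, max_examples=100)
@given(
    n_ibd=st.floats(min_value=1.0, max_value=1e6),
    n_iov=st.floats(min_value=0.0, max_value=1e7),
    delta=st.floats(min_value=0.1, max_value=1e5),
)
def test_beta_monotone(n_ibd, n_iov, delta):
    """beta rises with bed days and falls with outpatient visits."""
    base = sh.inpatient_workload_share(n_ibd, n_iov, 0.1)
    assert sh.inpatient_workload_share(n_ibd + delta, n_iov, 0.1) >= base
    assert sh.inpatient_workload_share(n_ibd, n_iov + delta, 0.1) <= base


def test_upsilon_recovers_configured_preventive_share(census):
    """Pooled upsilon is within 3 binomial SE of 1 - preventive share."""
    cfg = census.config
    tallies = sh.tally(census.encounters, census.institutions)
    ups = sh.curative_visit_fraction(tallies)
    n = float(tallies.pooled["outpatient_visits_total"])
    p = cfg.preventive_visit_share
    assert abs(ups - (1 - p)) <= 3 * np.sqrt(p * (1 - p) / n)


def test_sampling_consistency(census):
    """Coefficient estimates approach census values as the sample grows."""
    census_tallies = sh.tally(census.encounters, census.institutions)
    census_coef = sh.estimate_coefficients(census_tallies, census.provincial)
    devs = {}
    for frac in (0.1, 0.5, 1.0):
        survey = sh.draw_survey(census, sh.SamplingPlan(institution_fraction=frac), seed=17)
        coef = sh.estimate_coefficients(
            sh.tally(survey.encounters, survey.institutions), census.provincial)
        devs[frac] = max(
            abs(coef.alpha_i - census_coef.alpha_i),
            abs(coef.alpha_s - census_coef.alpha_s),
            abs(coef.upsilon - census_coef.upsilon),
        )
    assert devs[1.0] <= 1e-12
    assert devs[0.5] <= 0.05
    assert devs[0.1] <= 0.15


def test_estimation_deterministic(census):
    t = sh.tally(census.encounters, census.institutions)
    a = sh.estimate_coefficients(t, census.provincial)
    b = sh.estimate_coefficients(t, census.provincial)
    assert (a.alpha_i, a.alpha_s, a.beta, a.upsilon) == (b.alpha_i, b.alpha_s, b.beta, b.upsilon)
    pd.testing.assert_frame_equal(a.by_stratum, b.by_stratum)


def test_provenance_records_sources(census_coefficients):
    prov = census_coefficients.provenance
    assert prov["n_ibd_source"] in ("provincial", "survey")
    assert "pooled" in prov and prov["pooled"]["N_TOV"] > 0
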
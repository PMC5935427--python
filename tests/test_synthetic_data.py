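"""Synthetic province generator: conservation, determinism, sampling, truth."""

import numpy as np
import pandas as pd
import pytest

import sha2011 as sh
from sha2011.errors import ConfigurationError, SamplingError
from sha2011.survey_ingest import OUTPATIENT_SERVICES, PAYER_CATEGORIES


def test_determinism_same_seed_identical(small_config):
    a = sh.generate(small_config)
    b = sh.generate(small_config)
    pd.testing.assert_frame_equal(a.encounters, b.encounters)
    pd.testing.assert_frame_equal(
        a.institutions.drop(columns="prevention_projects"),
        b.institutions.drop(columns="prevention_projects"),
    )
    assert list(a.institutions["prevention_projects"]) == list(b.institutions["prevention_projects"])
    pd.testing.assert_frame_equal(a.provincial.by_stratum, b.provincial.by_stratum)


def test_empty_generation():
    ds = sh.generate(sh.GeneratorConfig(n_cities=1, encounters_per_institution=0, seed=1))
    assert len(ds.encounters) == 0
    assert ds.provincial.total_outpatient_income == 0.0
    assert ds.provincial.total_inpatient_income == 0.0


def test_no_preventive_visits_gives_upsilon_one():
    cfg = sh.GeneratorConfig(n_cities=1, encounters_per_institution=100,
                             preventive_visit_share=0.0, seed=2)
    ds = sh.generate(cfg)
    tallies = sh.tally(ds.encounters, ds.institutions)
    assert sh.curative_visit_fraction(tallies) == 1.0
    assert sh.curative_outpatient_fraction(tallies) == 1.0


def test_census_conservation(census):
    """Provincial totals = institution-sheet sums = encounter-cost sums."""
    enc, fin, prov = census.encounters, census.institutions, census.provincial
    out_costs = enc.loc[enc["service_type"].isin(OUTPATIENT_SERVICES), "total_cost"].sum()
    in_costs = enc.loc[enc["service_type"] == "inpatient", "total_cost"].sum()
    assert prov.total_outpatient_income == pytest.approx(out_costs, rel=1e-12)
    assert prov.total_inpatient_income == pytest.approx(in_costs, rel=1e-12)
    assert prov.total_outpatient_income == pytest.approx(
        fin["outpatient_income"].sum(), rel=1e-12)
    assert prov.total_inpatient_bed_days == enc["bed_days"].sum()
    assert prov.total_outpatient_visits == int(
        enc["service_type"].isin(OUTPATIENT_SERVICES).sum())


def test_encounter_records_are_valid(census, rules):
    enc = census.encounters
    assert enc["age_years"].between(0, 100).all()
    assert (enc["total_cost"] >= 0).all()
    # payer split sums to total cost
    resid = enc[PAYER_CATEGORIES].sum(axis=1) - enc["total_cost"]
    assert np.abs(resid).max() <= 1e-6 * max(1.0, enc["total_cost"].max())
    # bed days only on inpatient records
    assert (enc.loc[enc["bed_days"] > 0, "service_type"] == "inpatient").all()
    # every code classifies
    from sha2011.classification import icd10_chapter_series, UNCLASSIFIED
    assert (icd10_chapter_series(enc["icd10_code"], rules) != UNCLASSIFIED).all()


@pytest.mark.parametrize(
    "overrides,field",
    [
        ({"n_cities": 0}, "n_cities"),
        ({"preventive_visit_share": 1.5}, "preventive_visit_share"),
        ({"kappa": 0.0}, "kappa"),
        ({"subsidy_rates": {"basic": -0.1, "project": 0.0}}, "subsidy_rates"),
        ({"institutions_per_city": {"space_hospital": 1}}, "institutions_per_city"),
    ],
)
def test_invalid_config_names_field(overrides, field):
    with pytest.raises(ConfigurationError, match=field):
        sh.generate(sh.GeneratorConfig(**overrides))


def test_draw_survey_full_plan_is_identity(census):
    survey = sh.draw_survey(census, sh.SamplingPlan(institution_fraction=1.0), seed=9)
    assert sorted(survey.institutions["institution_id"]) == sorted(
        census.institutions["institution_id"])
    assert len(survey.encounters) == len(census.encounters)
    assert not survey.is_census  # provenance records it as a drawn sample


def test_draw_survey_deterministic(census):
    plan = sh.SamplingPlan(n_cities=1, institution_fraction=0.5)
    a = sh.draw_survey(census, plan, seed=4)
    b = sh.draw_survey(census, plan, seed=4)
    assert list(a.institutions["institution_id"]) == list(b.institutions["institution_id"])
    assert a.sampling["cities"] == b.sampling["cities"]


def test_draw_survey_too_many_cities(census):
    with pytest.raises(SamplingError):
        sh.draw_survey(census, sh.SamplingPlan(n_cities=99), seed=0)


def test_half_sample_income_tracks_half_census(census):
    """A 50% institution sample holds about half the census income."""
    survey = sh.draw_survey(census, sh.SamplingPlan(institution_fraction=0.5), seed=7)
    frac_inst = len(survey.institutions) / len(census.institutions)
    assert 0.4 <= frac_inst <= 0.6
    ratio = (survey.institutions["outpatient_income"].sum()
             / census.institutions["outpatient_income"].sum())
    # income per institution is noisy (log-normal costs); allow a wide band
    assert 0.25 <= ratio <= 0.75
    # the survey is an exact subset: its tabulation matches the census rows
    sub = census.encounters[
        census.encounters["institution_id"].isin(survey.institutions["institution_id"])]
    assert sub["total_cost"].sum() == pytest.approx(
        survey.encounters["total_cost"].sum(), rel=1e-12)


def test_truth_single_encounter_single_cell(rules):
    """One fully out-of-pocket curative visit -> one household cell of 100."""
    institutions = pd.DataFrame([{
        "institution_id": "I1", "provider_type": "general_hospital",
        **{c: 0.0 for c in sh.survey_ingest.FINANCE_MONEY_COLUMNS},
        "prevention_projects": [],
    }])
    institutions["outpatient_income"] = 100.0
    encounters = pd.DataFrame([{
        "institution_id": "I1", "age_years": 3, "sex": "F", "icd10_code": "J20",
        "service_type": "outpatient_curative", "bed_days": 0, "total_cost": 100.0,
        "social_insurance": 0.0, "commercial_insurance": 0.0, "donation": 0.0,
        "government_program": 0.0, "out_of_pocket": 100.0,
    }])
    prov_df = pd.DataFrame(
        {c: [0.0] for c in sh.survey_ingest.PROVINCIAL_COLUMNS},
        index=pd.Index(["general_hospital"], name="provider_type"))
    prov_df["outpatient_income"] = 100.0
    prov_df["outpatient_visits"] = 1.0
    ds = sh.SyntheticDataset(
        institutions=institutions, encounters=encounters,
        provincial=sh.ProvincialAggregates(prov_df))
    cube = sh.tabulate_truth(ds, rules)
    assert len(cube.cells) == 1
    cell = cube.cells.iloc[0]
    assert cell["amount_cny"] == 100.0
    assert cell["financing_scheme"] == "household"
    assert cell["function"] == "curative_outpatient"
    assert cell["disease_class"] == "Respiratory system diseases"
    assert cell["age_bin"] == "3-4"


def test_truth_total_equals_generated_money(census, census_truth):
    """Independent summation: cube total = billed costs + subsidies + overheads
    + prevention-project expenditure (capital expenditure excluded)."""
    enc, fin = census.encounters, census.institutions
    billed = enc.loc[enc["service_type"] != "public_health", "total_cost"].sum()
    subsidies = (fin["basic_subsidy"] + fin["outpatient_project_subsidy"]
                 + fin["inpatient_project_subsidy"]).sum()
    overheads = (fin["assistant_service_cost"] + fin["medicine_cost"]
                 + fin["management_cost"] + fin["superior_institution_subsidy"]
                 + fin["science_education_income"] + fin["other_income"]).sum()
    projects = sum(
        sh.prevention_expenditure(p, "max") for p in fin["prevention_projects"])
    expected = billed + subsidies + overheads + projects
    assert census_truth.total == pytest.approx(expected, rel=1e-9)


def test_truth_requires_census(census):
    survey = sh.draw_survey(census, sh.SamplingPlan(institution_fraction=0.5), seed=1)
    with pytest.raises(SamplingError):
        sh.tabulate_truth(survey)


def test_chapter_frequencies_match_configured_weights():
    """With 1e5+ encounters each chapter frequency is within 3 binomial SE."""
    cfg = sh.GeneratorConfig(n_cities=4, encounters_per_institution=1800, seed=13)
    ds = sh.generate(cfg)
    enc = ds.encounters
    curative = enc[enc["service_type"].isin(["outpatient_curative", "inpatient"])]
    assert len(curative) >= 1e5 * (1 - cfg.preventive_visit_share) * 0.5
    from sha2011.classification import icd10_chapter_series
    observed = icd10_chapter_series(curative["icd10_code"]).value_counts(normalize=True)
    n = len(curative)
    for chapter, p in cfg.disease_distribution.items():
        se = np.sqrt(p * (1 - p) / n)
        assert abs(observed.get(chapter, 0.0) - p) <= 3 * se + 1e-12, chapter
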
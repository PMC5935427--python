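"""Report rendering: currency, table shapes, rounding discipline, pipeline."""

import filecmp
import os

import numpy as np
import pandas as pd
import pytest

import sha2011 as sh
from sha2011.errors import ReportingError, Sha2011Error
from sha2011.reporting import run_pipeline
from conftest import make_cube


def _provider_cube():
    """Cube whose provider/function margins equal a published-style table,
    in USD million (rate 1, divisor 1)."""
    rows = []
    printed = [
        ("township_hospital", 1.70, 0.48),
        ("outpatient_service_institution", 3.40, 0.0),
        ("maternal_child_center", 0.31, 4.72),
        ("general_hospital", 29.38, 694.09),
        ("specialized_hospital", 0.07, 0.03),
        ("tcm_hospital", 1.37, 2.02),
    ]
    for ptype, outp, inp in printed:
        if outp:
            rows.append((ptype, "curative_outpatient", "household",
                         "Respiratory system diseases", "0-1", "medical_income", outp))
        if inp:
            rows.append((ptype, "curative_inpatient", "household",
                         "Respiratory system diseases", "0-1", "medical_income", inp))
    return make_cube(rows)


def test_convert_currency_headline_value():
    # CNY 4.573 billion at 6.20 CNY/USD -> US$ 0.74 billion at 2 dp
    usd_billion = sh.convert_currency(4.573e9, 6.20) / 1e9
    assert sh.round_half_up(usd_billion, 2) == 0.74
    assert sh.convert_currency(5.0, 1.0) == 5.0
    assert sh.convert_currency(0.0, 6.2) == 0.0
    with pytest.raises(ReportingError):
        sh.convert_currency(1.0, 0.0)


def test_round_half_up():
    assert sh.round_half_up(0.125, 2) == 0.13   # numpy's round would give 0.12
    assert sh.round_half_up(0.744999, 2) == 0.74
    assert list(sh.round_half_up(np.array([1.005001, 2.675001]), 2)) == [1.01, 2.68]


def test_provider_table_matches_printed_arithmetic():
    table = sh.render_provider_table(_provider_cube()).set_index("category")
    assert table.loc["Hospitals:", "total"] == 726.96          # 30.82 + 696.14
    assert table.loc["Hospitals:", "outpatient"] == 30.82
    assert table.loc["Hospitals:", "inpatient"] == 696.14
    assert table.loc["Maternal and child care centers", "total"] == 5.03
    grand = table.loc[["Primary health agents", "Outpatient service institutions",
                       "Maternal and child care centers", "Hospitals:"], "total"].sum()
    share = 100 * table.loc["Hospitals:", "total"] / grand
    assert sh.round_half_up(share, 2) == 98.56
    # general hospitals dominate both hospital columns
    assert table.loc["general hospital", "outpatient"] / \
        table.loc["Hospitals:", "outpatient"] >= 0.95
    assert table.loc["general hospital", "inpatient"] / \
        table.loc["Hospitals:", "inpatient"] >= 0.99


def test_provider_table_unmapped_stratum_errors():
    cube = make_cube([("general_hospital", "medicine", "household",
                       "Tumor", "0-1", "other", 1.0)])
    with pytest.raises(ReportingError, match="unmapped"):
        sh.render_provider_table(cube, groups={"Hospitals:": ["tcm_hospital"]})


def test_provider_table_empty_cube():
    cube = make_cube([])
    table = sh.render_provider_table(cube)
    assert (table[["outpatient", "inpatient", "total"]].to_numpy() == 0).all()


def test_financing_table_matches_printed_arithmetic():
    rows = [
        ("general_hospital", "curative_outpatient", "government", "Tumor", "0-1",
         "basic_subsidy", 19.32),
        ("general_hospital", "curative_outpatient", "government", "Tumor", "0-1",
         "project_subsidy", 7.73),
        ("township_hospital", "management", "government", "Tumor", "0-1",
         "superior_subsidy", 0.13),
        ("general_hospital", "curative_inpatient", "household", "Tumor", "0-1",
         "medical_income", 591.40),
        ("general_hospital", "management", "social", "Tumor", "0-1",
         "science_education", 0.02),
        ("general_hospital", "management", "social", "Tumor", "0-1", "other", 7.73),
    ]
    table = sh.render_financing_table(make_cube(rows)).set_index("health_financing")
    assert table.loc["Financial subsidy:", "amount"] == 27.05     # 19.32 + 7.73
    assert table.loc["Total", "amount"] == 626.33
    # medical income is recoverable as total minus all other components
    others = (table.loc["Financial subsidy:", "amount"]
              + table.loc["Superior institution subsidy (only primary medical institutions)",
                          "amount"]
              + table.loc["Science and education income (only hospitals)", "amount"]
              + table.loc["Others", "amount"])
    assert sh.round_half_up(table.loc["Total", "amount"] - others, 2) == 591.40


def test_disease_matrix_degenerate_and_symmetric():
    single = make_cube([("general_hospital", "curative_outpatient", "household",
                         "Tumor", "3-4", "medical_income", 42.0)])
    m = sh.render_disease_age_matrix(single)
    assert m.loc["Tumor", "3-4"] == 100.00
    assert m.loc["Tumor", "0-14"] == 100.00
    two = make_cube([
        ("general_hospital", "curative_outpatient", "household", "Tumor", "3-4",
         "medical_income", 5.0),
        ("general_hospital", "curative_outpatient", "household",
         "Respiratory system diseases", "3-4", "medical_income", 5.0),
    ])
    m2 = sh.render_disease_age_matrix(two)
    assert m2.loc["Tumor", "3-4"] == 50.00
    assert m2.loc["Respiratory system diseases", "3-4"] == 50.00


def test_disease_matrix_columns_normalize(census_cube, rules):
    children = sh.restrict_to_children(census_cube, rules=rules)
    m = sh.render_disease_age_matrix(children, rules=rules)
    sums = m.sum(axis=0, skipna=True)
    populated = sums[sums > 0]
    assert ((populated - 100.0).abs() <= 0.05).all()


def test_gbd_series_columns_normalize(census_cube, rules):
    children = sh.restrict_to_children(census_cube, rules=rules)
    g = sh.render_gbd_age_series(children, rules=rules)
    sums = g.sum(axis=0, skipna=True)
    assert ((sums[sums > 0] - 100.0).abs() <= 0.05).all()


def test_rounding_discipline(census_cube, rules):
    """A rendered parent row differs from the sum of its rendered children by
    at most 0.01 per child; totals are computed before rounding."""
    children = sh.restrict_to_children(census_cube, rules=rules)
    rate = census_cube.metadata["exchange_rate_cny_per_usd"]
    table = sh.render_provider_table(children, rate, 1e6).set_index("category")
    subs = ["general hospital", "specialized hospital",
            "traditional Chinese medical hospital"]
    for col in ("outpatient", "inpatient", "total"):
        assert abs(table.loc["Hospitals:", col]
                   - table.loc[subs, col].sum()) <= 0.01 * len(subs) + 1e-9
        assert abs(table.loc[table.index[0], "total"]
                   - (table.iloc[0]["outpatient"] + table.iloc[0]["inpatient"])) <= 0.02


def test_currency_invariance_of_shares(census_cube, rules):
    """Percent tables are identical whether amounts are in CNY or USD."""
    children = sh.restrict_to_children(census_cube, rules=rules)
    usd = children.scaled(1.0 / 6.2)
    a = sh.render_disease_age_matrix(children, rules=rules)
    b = sh.render_disease_age_matrix(usd, rules=rules)
    pd.testing.assert_frame_equal(a, b, rtol=1e-9)


def test_pipeline_deterministic_outputs(tmp_path):
    cfg = {"generate": {"n_cities": 2, "encounters_per_institution": 80},
           "sampling": {"institution_fraction": 0.5}}
    out1, out2 = tmp_path / "a", tmp_path / "b"
    run_pipeline(cfg, out_dir=str(out1), seed=21)
    run_pipeline(cfg, out_dir=str(out2), seed=21)
    for name in os.listdir(out1):
        assert filecmp.cmp(out1 / name, out2 / name, shallow=False), name


def test_pipeline_reports_oracle_totals(tmp_path, census, census_truth):
    """A 100% sample reproduces the enumerated census totals."""
    paths = sh.write_dataset(census, tmp_path / "census")
    bundle = run_pipeline({"inputs": paths})
    assert bundle.summary["che_total_cny"] == pytest.approx(census_truth.total, rel=1e-9)


def test_pipeline_missing_input_aborts_with_stage(tmp_path):
    cfg = {"inputs": {"encounters": str(tmp_path / "nope.csv"),
                      "institutions": "x", "provincial": "y"}}
    with pytest.raises(Sha2011Error, match=r"\[stage: ingest\].*nope.csv"):
        run_pipeline(cfg)
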
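"""Rendering the accounts cube into report tables and the pipeline driver.

Three table shapes are produced from the children's cube:

* a provider table (outpatient / inpatient / total money per provider
  category, with hospital sub-rows),
* a disease x age matrix (percent of each age column's spending per ICD-10
  chapter, with an all-children leading column), and
* a financing table (funding-source rows: financial subsidy with basic and
  project sub-rows, superior institution subsidy, medical income, science
  and education income, others, total),

plus a GBD broad-cause-group x age percentage series (emitted as data; a
figure is left to the user).  All totals are computed from unrounded values;
money is converted to USD and rounded half-up only at rendering time.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import survey_ingest as si
from .accounts_engine import AccountsCube, compute_che, restrict_to_children
from .classification import (
    AGE_OVERFLOW_BIN,
    ClassificationRules,
    GBD_GROUPS,
    UNCLASSIFIED,
    default_rules,
    load_rules,
)
from .coefficients import estimate_coefficients, tally
from .errors import ReportingError, Sha2011Error
from .synthetic_data import GeneratorConfig, SamplingPlan, draw_survey, generate, write_dataset

log = logging.getLogger(__name__)

#: provider categories -> underlying strata (hospital sub-rows listed separately)
DEFAULT_PROVIDER_GROUPS = {
    "Primary health agents": [
        "township_hospital", "community_health_center", "village_or_individual_clinic"],
    "Outpatient service institutions": ["outpatient_service_institution"],
    "Maternal and child care centers": ["maternal_child_center"],
    "Hospitals:": [
        "provincial_hospital", "general_hospital", "specialized_hospital", "tcm_hospital"],
    "Public health institutions": ["public_health_institution"],
}

HOSPITAL_SUBROWS = {
    "general hospital": ["provincial_hospital", "general_hospital"],
    "specialized hospital": ["specialized_hospital"],
    "traditional Chinese medical hospital": ["tcm_hospital"],
}

FINANCING_ROWS = [
    "Financial subsidy:",
    "basic subsidy",
    "project subsidy",
    "Superior institution subsidy (only primary medical institutions)",
    "Medical income",
    "Science and education income (only hospitals)",
    "Others",
    "Total",
]


def round_half_up(values, decimals: int = 2):
    """Decimal-style half-up rounding (numpy rounds half to even)."""
    factor = 10.0 ** decimals
    arr = np.floor(np.asarray(values, dtype=float) * factor + 0.5) / factor
    return float(arr) if np.isscalar(values) or getattr(values, "ndim", 1) == 0 else arr


def convert_currency(amount_cny, rate_cny_per_usd: float):
    """CNY -> USD at full precision; rounding is deferred to rendering."""
    if not rate_cny_per_usd > 0:
        raise ReportingError("exchange rate must be positive")
    return amount_cny / rate_cny_per_usd


@dataclass
class ReportBundle:
    provider_table: pd.DataFrame
    disease_age_matrix: pd.DataFrame
    financing_table: pd.DataFrame
    gbd_age_series: pd.DataFrame
    currency: str = "USD million"
    rounding: int = 2
    summary: dict = field(default_factory=dict)


# -- provider table ----------------------------------------------------------------


def render_provider_table(cube: AccountsCube, rate_cny_per_usd: float = 1.0,
                          unit_divisor: float = 1.0, rounding: int = 2,
                          groups: dict[str, list[str]] | None = None) -> pd.DataFrame:
    """Outpatient / inpatient / total money per provider category.

    The inpatient column is the curative-inpatient function; everything else
    (curative outpatient, prevention, ancillary, medicine, management) is
    delivered through outpatient-style contact and counts as outpatient, so
    the category totals exhaust CHE.
    """
    groups = groups or DEFAULT_PROVIDER_GROUPS
    mapped = {s for strata in groups.values() for s in strata}
    present = set(cube.cells["provider_type"].unique())
    unmapped = present - mapped
    if unmapped:
        raise ReportingError(f"unmapped provider strata: {sorted(unmapped)}")

    by = cube.cells.groupby(["provider_type", "function"], observed=True)["amount_cny"].sum()
    by = convert_currency(by, rate_cny_per_usd) / unit_divisor

    def cols(strata: list[str]) -> tuple[float, float]:
        sub = by[by.index.get_level_values("provider_type").isin(strata)]
        inp = float(sub[sub.index.get_level_values("function") == "curative_inpatient"].sum())
        out = float(sub.sum()) - inp
        return out, inp

    rows = []
    for label, strata in groups.items():
        out, inp = cols(strata)
        if label == "Public health institutions" and out == inp == 0.0:
            continue
        rows.append((label, out, inp))
        if label == "Hospitals:":
            for sub_label, sub_strata in HOSPITAL_SUBROWS.items():
                o, i = cols(sub_strata)
                rows.append((sub_label, o, i))
    df = pd.DataFrame(rows, columns=["category", "outpatient", "inpatient"])
    df["total"] = df["outpatient"] + df["inpatient"]
    for c in ("outpatient", "inpatient", "total"):
        df[c] = round_half_up(df[c].to_numpy(), rounding)
    return df


# -- disease x age matrix -----------------------------------------------------------


def render_disease_age_matrix(cube: AccountsCube, rounding: int = 2,
                              rules: ClassificationRules | None = None) -> pd.DataFrame:
    """Percent of each age column's spending per disease chapter.

    Columns are the single-year children bins plus a leading all-children
    column computed from unrounded totals (the boundary-age overflow bin is
    included in the all-children column only).  A column with zero spending
    renders as blanks.
    """
    rules = rules or default_rules()
    child_bins = [label for _, _, label in sorted(rules.age_bins)]
    all_col = f"0-{rules.children_age_max}"

    cells = cube.cells[cube.cells["age_bin"].isin(rules.child_bin_labels)]
    pivot = (cells.groupby(["disease_class", "age_bin"], observed=True)["amount_cny"]
             .sum().unstack(fill_value=0.0))
    row_labels = rules.chapter_labels + (
        [UNCLASSIFIED] if UNCLASSIFIED in pivot.index else [])
    pivot = pivot.reindex(index=row_labels, columns=child_bins + [AGE_OVERFLOW_BIN],
                          fill_value=0.0).fillna(0.0)
    pivot.insert(0, all_col, pivot.sum(axis=1))
    pivot = pivot.drop(columns=[AGE_OVERFLOW_BIN])

    out = pd.DataFrame(index=pivot.index, columns=pivot.columns, dtype=float)
    for col in pivot.columns:
        total = pivot[col].sum()
        if total <= 0:
            log.warning("disease/age matrix: column %s has no spending; rendered blank", col)
            out[col] = np.nan
        else:
            out[col] = round_half_up((100.0 * pivot[col] / total).to_numpy(), rounding)
    out.index.name = "disease_class"
    return out


def render_gbd_age_series(cube: AccountsCube, rounding: int = 2,
                          rules: ClassificationRules | None = None) -> pd.DataFrame:
    """Percent of each age column's spending per GBD broad cause group."""
    rules = rules or default_rules()
    child_bins = [label for _, _, label in sorted(rules.age_bins)]
    all_col = f"0-{rules.children_age_max}"
    cells = cube.cells[cube.cells["age_bin"].isin(rules.child_bin_labels)].copy()
    cells["gbd_group"] = cells["disease_class"].map(
        lambda c: rules.gbd_group_map.get(c, UNCLASSIFIED))
    pivot = (cells.groupby(["gbd_group", "age_bin"], observed=True)["amount_cny"]
             .sum().unstack(fill_value=0.0))
    rows = GBD_GROUPS + ([UNCLASSIFIED] if UNCLASSIFIED in pivot.index else [])
    pivot = pivot.reindex(index=rows, columns=child_bins + [AGE_OVERFLOW_BIN],
                          fill_value=0.0).fillna(0.0)
    pivot.insert(0, all_col, pivot.sum(axis=1))
    pivot = pivot.drop(columns=[AGE_OVERFLOW_BIN])
    totals = pivot.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * pivot / totals
    out = pct.apply(lambda col: round_half_up(col.to_numpy(), rounding))
    out.index.name = "gbd_group"
    return out


# -- financing table ---------------------------------------------------------------


def render_financing_table(cube: AccountsCube, institutions: pd.DataFrame | None = None,
                           rate_cny_per_usd: float = 1.0, unit_divisor: float = 1.0,
                           rounding: int = 2) -> pd.DataFrame:
    """Funding-source rows; the total row is summed before rounding.

    The source labels travel on the cube cells, so the table is an exact
    decomposition of the cube's grand total.  ``institutions`` is accepted
    for interface symmetry (source amounts are already cube-resident).
    """
    src = cube.cells.groupby("source", observed=True)["amount_cny"].sum()
    src = convert_currency(src, rate_cny_per_usd) / unit_divisor

    def get(name: str) -> float:
        return float(src.get(name, 0.0))

    basic, project = get("basic_subsidy"), get("project_subsidy")
    values = {
        "Financial subsidy:": basic + project,
        "basic subsidy": basic,
        "project subsidy": project,
        "Superior institution subsidy (only primary medical institutions)":
            get("superior_subsidy"),
        "Medical income": get("medical_income"),
        "Science and education income (only hospitals)": get("science_education"),
        "Others": get("other"),
    }
    values["Total"] = (values["Financial subsidy:"]
                       + values["Superior institution subsidy (only primary medical institutions)"]
                       + values["Medical income"]
                       + values["Science and education income (only hospitals)"]
                       + values["Others"])
    df = pd.DataFrame(
        {"health_financing": FINANCING_ROWS,
         "amount": [round_half_up(values[r], rounding) for r in FINANCING_ROWS]}
    )
    return df


# -- pipeline ------------------------------------------------------------------------


def run_pipeline(config: dict | str, out_dir: str | None = None,
                 seed: int | None = None) -> ReportBundle:
    """End-to-end run: inputs -> coefficients -> accounts -> children -> tables.

    ``config`` is a mapping (or path to a YAML document) with either a
    ``generate`` section (synthetic province, optional ``sampling`` section)
    or an ``inputs`` section naming encounter/institution/provincial files;
    optional keys: ``kappa``, ``prevention_rule``, ``rules`` (path),
    ``children_age_max``, ``seed``, ``out``.
    """
    if isinstance(config, (str, os.PathLike)):
        with open(config, "r", encoding="utf-8") as fh:
            config = yaml.safe_load(fh)
    config = dict(config or {})
    out_dir = out_dir or config.get("out")
    seed = seed if seed is not None else config.get("seed", 0)

    rules = load_rules(config["rules"]) if config.get("rules") else default_rules()
    kappa = float(config.get("kappa", 0.1))
    prevention_rule = config.get("prevention_rule", "max")
    age_max = int(config.get("children_age_max", rules.children_age_max))

    stage = "ingest"
    try:
        if "inputs" in config:
            paths = config["inputs"]
            for key in ("encounters", "institutions", "provincial"):
                if key not in paths:
                    raise Sha2011Error(f"inputs section missing {key!r}")
                if not os.path.exists(paths[key]):
                    raise Sha2011Error(f"input file not found: {paths[key]}")
            encounters, enc_summary = si.read_encounters(paths["encounters"])
            institutions, fin_summary = si.read_institution_finance(paths["institutions"])
            provincial = si.read_provincial(paths["provincial"])
            log.info("ingest: %d encounters (%d rejected), %d institutions (%d rejected)",
                     enc_summary.rows_read, enc_summary.rows_rejected,
                     fin_summary.rows_read, fin_summary.rows_rejected)
        else:
            stage = "generate"
            gen_kwargs = dict(config.get("generate") or {})
            gen_kwargs.setdefault("seed", seed)
            if "age_distribution" not in gen_kwargs and "children_share" in gen_kwargs:
                from .synthetic_data import default_age_weights
                gen_kwargs["age_distribution"] = default_age_weights(
                    gen_kwargs.pop("children_share"))
            census = generate(GeneratorConfig(**gen_kwargs), rules)
            survey = census
            if config.get("sampling"):
                plan = SamplingPlan(**config["sampling"])
                survey = draw_survey(census, plan, seed=seed + 1)
                log.info("sampling: %d of %d institutions",
                         len(survey.institutions), len(census.institutions))
            encounters, institutions = survey.encounters, survey.institutions
            provincial = census.provincial

        stage = "coefficients"
        tallies = tally(encounters, institutions, target_age_max=age_max, rules=rules)
        coefficients = estimate_coefficients(tallies, provincial, kappa=kappa)
        log.info("coefficients: alpha_i=%.4f alpha_s=%.4f upsilon=%.4f beta=%.4f kappa=%.3f "
                 "(prevention_rule=%s)", coefficients.alpha_i, coefficients.alpha_s,
                 coefficients.upsilon, coefficients.beta, kappa, prevention_rule)

        stage = "accounts"
        cube = compute_che(provincial, institutions, coefficients, rules, prevention_rule)
        children = restrict_to_children(cube, rules=rules)

        stage = "reporting"
        rate = provincial.exchange_rate_cny_per_usd
        unit = 1e6  # USD million
        bundle = ReportBundle(
            provider_table=render_provider_table(children, rate, unit),
            disease_age_matrix=render_disease_age_matrix(children, rules=rules),
            financing_table=render_financing_table(children, institutions, rate, unit),
            gbd_age_series=render_gbd_age_series(children, rules=rules),
            summary={
                "year": provincial.year,
                "exchange_rate_cny_per_usd": rate,
                "che_total_cny": cube.total,
                "che_children_cny": children.total,
                "che_children_usd_million": convert_currency(children.total, rate) / unit,
                "children_share_of_che": children.total / cube.total if cube.total else 0.0,
                "coefficients": {
                    "alpha_i": coefficients.alpha_i,
                    "alpha_s": coefficients.alpha_s,
                    "beta": coefficients.beta,
                    "upsilon": coefficients.upsilon,
                    "kappa": coefficients.kappa,
                },
                "settings": {"prevention_rule": prevention_rule,
                             "children_age_max": age_max, "seed": int(seed)},
            },
        )

        if out_dir:
            os.makedirs(out_dir, exist_ok=True)
            cube.to_csv(os.path.join(out_dir, "cube_total.csv"))
            children.to_csv(os.path.join(out_dir, "cube_children.csv"))
            coefficients.to_yaml(os.path.join(out_dir, "coefficients.yaml"))
            bundle.provider_table.to_csv(
                os.path.join(out_dir, "provider_table.csv"), index=False)
            bundle.disease_age_matrix.to_csv(os.path.join(out_dir, "disease_age_matrix.csv"))
            bundle.financing_table.to_csv(
                os.path.join(out_dir, "financing_table.csv"), index=False)
            bundle.gbd_age_series.to_csv(os.path.join(out_dir, "gbd_age_series.csv"))
            if "inputs" not in config and config.get("write_inputs", False):
                write_dataset(survey, os.path.join(out_dir, "survey"))
            with open(os.path.join(out_dir, "summary.json"), "w", encoding="utf-8") as fh:
                json.dump(bundle.summary, fh, indent=2, sort_keys=True)
        return bundle
    except Sha2011Error as exc:
        raise Sha2011Error(f"[stage: {stage}] {exc}") from exc
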
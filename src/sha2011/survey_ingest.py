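"""Reading, validating and writing the three input record families.

The pipeline consumes

* patient encounters (one service contact per row, CSV),
* institution finance sheets (one institution per row, CSV; the prevention
  project list is a JSON-encoded column), and
* provincial aggregates (a YAML key-value document with per-provider-type
  strata),

and represents them in memory as :class:`pandas.DataFrame` objects (for the
two record families) and a :class:`ProvincialAggregates` dataclass.  Readers
never drop rows silently: every physical row either becomes a valid record
or is reported in a :class:`ValidationSummary` with its line number and the
reason for rejection.

Money is carried in CNY at full float precision throughout the pipeline;
conversion to USD happens only in the reporting module.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .classification import icd10_chapter_series, UNCLASSIFIED
from .errors import SchemaError

log = logging.getLogger(__name__)

# -- vocabulary ---------------------------------------------------------------

SERVICE_TYPES = [
    "outpatient_curative",
    "outpatient_preventive",
    "inpatient",
    "public_health",
]

#: service types whose income is booked as outpatient income
OUTPATIENT_SERVICES = ["outpatient_curative", "outpatient_preventive"]

PAYER_CATEGORIES = [
    "social_insurance",
    "commercial_insurance",
    "donation",
    "government_program",
    "out_of_pocket",
]

PROVIDER_TYPES = [
    "provincial_hospital",
    "general_hospital",
    "specialized_hospital",
    "tcm_hospital",
    "maternal_child_center",
    "outpatient_service_institution",
    "township_hospital",
    "community_health_center",
    "village_or_individual_clinic",
    "public_health_institution",
]

ENCOUNTER_COLUMNS = [
    "institution_id",
    "age_years",
    "sex",
    "icd10_code",
    "service_type",
    "bed_days",
    "total_cost",
    *PAYER_CATEGORIES,
]

FINANCE_MONEY_COLUMNS = [
    "outpatient_income",
    "preventive_outpatient_income",
    "inpatient_income",
    "basic_subsidy",
    "outpatient_project_subsidy",
    "inpatient_project_subsidy",
    "superior_institution_subsidy",
    "science_education_income",
    "other_income",
    "assistant_service_cost",
    "medicine_cost",
    "management_cost",
    "capital_expenditure",
]

FINANCE_COLUMNS = [
    "institution_id",
    "provider_type",
    *FINANCE_MONEY_COLUMNS,
    "prevention_projects",
]

#: per-stratum columns of the provincial aggregates table
PROVINCIAL_COLUMNS = [
    "outpatient_income",
    "inpatient_income",
    "outpatient_visits",
    "inpatient_bed_days",
    "basic_subsidy",
    "outpatient_project_subsidy",
    "inpatient_project_subsidy",
]

DEFAULT_EXCHANGE_RATE = 6.20  # CNY per USD, 2014 average

PAYER_SUM_RTOL = 1e-6


@dataclass
class ValidationSummary:
    """Per-file account of what was read and what was rejected."""

    rows_read: int = 0
    rows_rejected: int = 0
    reasons: list[tuple[int, str]] = field(default_factory=list)  # (line no, reason)

    @property
    def rows_total(self) -> int:
        return self.rows_read + self.rows_rejected

    def add(self, line_no: int, reason: str) -> None:
        self.rows_rejected += 1
        self.reasons.append((line_no, reason))


@dataclass
class ProvincialAggregates:
    """Yearbook-level totals that the top-down method scales.

    ``by_stratum`` is indexed by provider type and holds the columns in
    :data:`PROVINCIAL_COLUMNS`; scalar totals are exposed as properties.
    """

    by_stratum: pd.DataFrame
    exchange_rate_cny_per_usd: float = DEFAULT_EXCHANGE_RATE
    year: int = 2014

    def __post_init__(self) -> None:
        missing = [c for c in PROVINCIAL_COLUMNS if c not in self.by_stratum.columns]
        if missing:
            raise SchemaError(f"provincial aggregates missing columns: {missing}")
        if (self.by_stratum[PROVINCIAL_COLUMNS] < 0).to_numpy().any():
            raise SchemaError("provincial aggregates contain negative values")
        if not self.exchange_rate_cny_per_usd > 0:
            raise SchemaError("exchange rate must be positive")

    @property
    def total_outpatient_income(self) -> float:
        return float(self.by_stratum["outpatient_income"].sum())

    @property
    def total_inpatient_income(self) -> float:
        return float(self.by_stratum["inpatient_income"].sum())

    @property
    def total_outpatient_visits(self) -> float:
        return float(self.by_stratum["outpatient_visits"].sum())

    @property
    def total_inpatient_bed_days(self) -> float:
        return float(self.by_stratum["inpatient_bed_days"].sum())

    @property
    def total_basic_subsidy(self) -> float:
        return float(self.by_stratum["basic_subsidy"].sum())

    def scaled(self, factor: float) -> "ProvincialAggregates":
        """All money aggregates multiplied by ``factor`` (counts unchanged)."""
        df = self.by_stratum.copy()
        for c in PROVINCIAL_COLUMNS:
            if c not in ("outpatient_visits", "inpatient_bed_days"):
                df[c] = df[c] * factor
        return ProvincialAggregates(df, self.exchange_rate_cny_per_usd, self.year)


# -- encounters ---------------------------------------------------------------


def write_encounters(encounters: pd.DataFrame, path) -> None:
    encounters.loc[:, ENCOUNTER_COLUMNS].to_csv(path, index=False)


def read_encounters(path) -> tuple[pd.DataFrame, ValidationSummary]:
    """Read encounter records; returns (valid records, validation summary)."""
    df = pd.read_csv(path, dtype={"institution_id": str, "icd10_code": str, "sex": str})
    missing = [c for c in ENCOUNTER_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"encounter file {path} missing columns: {missing}")

    summary = ValidationSummary()
    n = len(df)
    reasons = pd.Series([""] * n, index=df.index, dtype=object)

    def flag(mask: pd.Series, reason: str) -> None:
        mask = mask & (reasons == "")
        reasons[mask] = reason

    age = pd.to_numeric(df["age_years"], errors="coerce")
    flag(age.isna() | (age < 0) | (age > 120) | (age != age.round()), "invalid age")
    cost = pd.to_numeric(df["total_cost"], errors="coerce")
    flag(cost.isna() | (cost < 0), "negative or unparseable cost")
    flag(~df["service_type"].isin(SERVICE_TYPES), "unknown service type")
    bed = pd.to_numeric(df["bed_days"], errors="coerce")
    flag(bed.isna() | (bed < 0), "invalid bed days")
    flag((bed > 0) & (df["service_type"] != "inpatient"), "bed days on non-inpatient record")

    payer = df[PAYER_CATEGORIES].apply(pd.to_numeric, errors="coerce")
    flag(payer.isna().any(axis=1) | (payer < 0).any(axis=1), "negative or unparseable payer amount")
    payer_sum = payer.sum(axis=1)
    tol = np.maximum(np.abs(cost.fillna(0.0)), 1.0) * PAYER_SUM_RTOL
    flag((payer_sum - cost).abs() > tol, "payer split mismatch")

    # syntactically invalid ICD codes are rejected; *missing* codes are kept
    # and classified to the explicit "unclassified" bin, so money is conserved
    codes = df["icd10_code"].fillna("").astype(str).str.strip()
    chapters = icd10_chapter_series(df["icd10_code"])
    flag((codes != "") & (chapters == UNCLASSIFIED)
         & ~codes.str.upper().str.match(r"^[A-Z][0-9]{2}"), "unparseable ICD-10 code")

    bad = reasons != ""
    for idx in df.index[bad]:
        summary.add(int(idx) + 2, reasons[idx])  # +2: header row and 1-based lines
    valid = df.loc[~bad].copy()
    valid["age_years"] = age[~bad].astype(int)
    valid["bed_days"] = bed[~bad].astype(int)
    valid["total_cost"] = cost[~bad]
    valid[PAYER_CATEGORIES] = payer.loc[~bad]
    summary.rows_read = len(valid)
    return valid.reset_index(drop=True), summary


# -- institution finance -------------------------------------------------------


def write_institution_finance(institutions: pd.DataFrame, path) -> None:
    df = institutions.loc[:, FINANCE_COLUMNS].copy()
    df["prevention_projects"] = df["prevention_projects"].map(
        lambda p: json.dumps(p if isinstance(p, list) else [])
    )
    df.to_csv(path, index=False)


def read_institution_finance(path) -> tuple[pd.DataFrame, ValidationSummary]:
    df = pd.read_csv(path, dtype={"institution_id": str, "provider_type": str,
                                  "prevention_projects": str})
    missing = [c for c in FINANCE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"institution finance file {path} missing columns: {missing}")

    summary = ValidationSummary()
    reasons = pd.Series([""] * len(df), index=df.index, dtype=object)

    def flag(mask: pd.Series, reason: str) -> None:
        mask = mask & (reasons == "")
        reasons[mask] = reason

    flag(~df["provider_type"].isin(PROVIDER_TYPES), "unknown provider type")
    money = df[FINANCE_MONEY_COLUMNS].apply(pd.to_numeric, errors="coerce")
    flag(money.isna().any(axis=1) | (money < 0).any(axis=1), "negative or unparseable money field")

    projects: list[list] = []
    bad_json = []
    for idx, raw in df["prevention_projects"].items():
        try:
            parsed = json.loads(raw) if isinstance(raw, str) and raw.strip() else []
            if not isinstance(parsed, list):
                raise ValueError
            for item in parsed:
                pid, inc, exp = item  # noqa: unpack validates shape
                if float(inc) < 0 or float(exp) < 0:
                    raise ValueError
            projects.append(parsed)
        except Exception:
            projects.append([])
            bad_json.append(idx)
    flag(pd.Series(df.index.isin(bad_json), index=df.index), "unparseable prevention projects")

    bad = reasons != ""
    for idx in df.index[bad]:
        summary.add(int(idx) + 2, reasons[idx])
    valid = df.loc[~bad].copy()
    valid[FINANCE_MONEY_COLUMNS] = money.loc[~bad]
    valid["prevention_projects"] = pd.Series(projects, index=df.index)[~bad]
    n_capital = int((valid["capital_expenditure"] > 0).sum())
    if n_capital:
        log.info("%d institutions report capital expenditure; field retained but "
                 "excluded from CHE scope", n_capital)
    summary.rows_read = len(valid)
    return valid.reset_index(drop=True), summary


# -- provincial aggregates ------------------------------------------------------


def write_provincial(provincial: ProvincialAggregates, path) -> None:
    doc = {
        "year": int(provincial.year),
        "exchange_rate_cny_per_usd": float(provincial.exchange_rate_cny_per_usd),
        "strata": {
            str(ptype): {c: float(row[c]) for c in PROVINCIAL_COLUMNS}
            for ptype, row in provincial.by_stratum.iterrows()
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def read_provincial(path) -> ProvincialAggregates:
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "strata" not in doc:
        raise SchemaError(f"provincial file {path} missing required key 'strata'")
    rate = doc.get("exchange_rate_cny_per_usd")
    if rate is None:
        log.warning("provincial file %s has no exchange rate; defaulting to %.2f CNY/USD",
                    path, DEFAULT_EXCHANGE_RATE)
        rate = DEFAULT_EXCHANGE_RATE
    rows = {}
    for ptype, values in doc["strata"].items():
        if ptype not in PROVIDER_TYPES:
            raise SchemaError(f"unknown provider type in provincial file: {ptype!r}")
        missing = [c for c in PROVINCIAL_COLUMNS if c not in values]
        if missing:
            raise SchemaError(f"provincial stratum {ptype!r} missing keys: {missing}")
        rows[ptype] = {c: float(values[c]) for c in PROVINCIAL_COLUMNS}
    df = pd.DataFrame.from_dict(rows, orient="index").loc[:, PROVINCIAL_COLUMNS]
    df.index.name = "provider_type"
    return ProvincialAggregates(df, float(rate), int(doc.get("year", 2014)))
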
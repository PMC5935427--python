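"""Top-down Current Health Expenditure (CHE) computation.

The engine scales provincial money aggregates into a multidimensional
accounts cube using the survey-derived coefficients, then restricts the cube
to the children subpopulation.  Per provider-type stratum *t*:

==========================  =====================================================
curative outpatient income  ``E_OCI = E_OI * alpha_i``
outpatient curative total   ``E_OCS = E_OCI + E_OPS + E_OBS``
curative basic subsidy      ``E_BCS = E_BS * alpha_s``
outpatient basic subsidy    ``E_OBS = E_BCS * (1 - beta)``
inpatient basic subsidy     ``E_IBS = E_BCS * beta``
inpatient curative total    ``E_ICS = E_II + E_IPS + E_IBS`` (no preventive
                            deduction on the inpatient side)
==========================  =====================================================

The remainder of the basic subsidy, ``E_BS * (1 - alpha_s)``, funds
public-health services and is booked under the prevention function, together
with the preventive share of outpatient income, ``E_OI * (1 - alpha_i)``,
and the prevention-project expenditure estimated from the surveyed
institution finance sheets (scaled to the province by the stratum income
ratio).  Assistant services, medicine and management costs, the superior
institution subsidy, science & education income and other income are scaled
the same way.  Capital expenditure is never counted (outside the CHE scope).

Financing schemes: basic and project subsidies (and the superior subsidy and
management overhead) are government; social insurance, commercial insurance
and donations are social; out-of-pocket payments are household.  Income
amounts are decomposed by the survey payer mix at full (disease, age)
granularity, so the children restriction can operate exactly on age bins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from numbers import Real

import numpy as np
import pandas as pd

from . import survey_ingest as si
from .classification import (
    ClassificationRules,
    UNCLASSIFIED,
    age_bin_series,
    default_rules,
    icd10_chapter_series,
)
from .coefficients import CoefficientSet
from .errors import AccountsError, EstimationError, Sha2011Error

log = logging.getLogger(__name__)

FUNCTIONS = [
    "curative_outpatient",
    "curative_inpatient",
    "prevention",
    "assistant_services",
    "medicine",
    "management",
]

SCHEMES = ["government", "social", "household"]

#: payer category -> financing scheme
PAYER_TO_SCHEME = {
    "social_insurance": "social",
    "commercial_insurance": "social",
    "donation": "social",
    "government_program": "government",
    "out_of_pocket": "household",
}

#: funding-source labels carried on every cube cell (financing-table rows)
SOURCES = [
    "medical_income",
    "basic_subsidy",
    "project_subsidy",
    "superior_subsidy",
    "science_education",
    "other",
]

CUBE_KEY = ["provider_type", "function", "financing_scheme", "disease_class", "age_bin"]
CUBE_COLUMNS = CUBE_KEY + ["source", "amount_cny"]

_CURATIVE_SERVICES = {"curative_outpatient": "outpatient_curative",
                      "curative_inpatient": "inpatient"}
_PREVENTIVE_POOL = ["outpatient_preventive", "public_health"]
_ALL_SERVICES = si.SERVICE_TYPES


@dataclass
class FinancingBreakdown:
    """Government / social / household decomposition of one amount."""

    government: float = 0.0
    social: float = 0.0
    household: float = 0.0

    @property
    def total(self) -> float:
        return self.government + self.social + self.household


@dataclass
class CurativeAccounts:
    """Per-stratum curative aggregates (outpatient and inpatient sides)."""

    by_stratum: pd.DataFrame  # columns documented in curative_totals

    @property
    def outpatient_curative_total(self) -> float:
        return float(self.by_stratum["outpatient_curative_total"].sum())

    @property
    def inpatient_curative_total(self) -> float:
        return float(self.by_stratum["inpatient_curative_total"].sum())


@dataclass
class AccountsCube:
    """CHE amounts per (provider, function, scheme, disease, age) cell.

    ``cells`` is a long-format frame with one row per populated cell (plus
    the funding-source label used by the financing table).  All marginals of
    a long table are sums over the same rows, so additivity is structural;
    ``validate`` enforces non-negativity.
    """

    cells: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in CUBE_COLUMNS if c not in self.cells.columns]
        if missing:
            raise AccountsError(f"cube missing columns: {missing}")
        self.cells = self.cells.loc[:, CUBE_COLUMNS].reset_index(drop=True)

    def validate(self) -> None:
        amounts = self.cells["amount_cny"]
        if amounts.empty:
            return
        if (amounts < -1e-9 * max(1.0, float(amounts.abs().max()))).any():
            bad = self.cells[amounts < 0].head()
            raise AccountsError(f"negative cube cells:\n{bad}")

    @property
    def total(self) -> float:
        return float(self.cells["amount_cny"].sum())

    def marginal(self, dims: str | list[str]) -> pd.Series:
        if isinstance(dims, str):
            dims = [dims]
        return self.cells.groupby(dims, observed=True)["amount_cny"].sum()

    def aggregated(self) -> pd.DataFrame:
        """Cells summed onto the five-dimensional key (source collapsed)."""
        return (self.cells.groupby(CUBE_KEY, observed=True)["amount_cny"]
                .sum().reset_index())

    def scaled(self, factor: float) -> "AccountsCube":
        df = self.cells.copy()
        df["amount_cny"] = df["amount_cny"] * factor
        return AccountsCube(df, dict(self.metadata))

    def to_csv(self, path) -> None:
        self.cells.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, metadata: dict | None = None) -> "AccountsCube":
        return cls(pd.read_csv(path), metadata or {})


# -- elementary operations ----------------------------------------------------------


def curative_outpatient_income(provincial: si.ProvincialAggregates, alpha_i) -> pd.Series:
    """``E_OCI = E_OI * alpha_i`` per stratum; ``alpha_i`` scalar or per-stratum."""
    _check_proportion("alpha_i", alpha_i)
    return provincial.by_stratum["outpatient_income"] * alpha_i


def split_basic_subsidy(e_bs, alpha_s, beta):
    """``E_BCS = E_BS*alpha_s``; outpatient/inpatient split ``(1-beta)/beta``.

    Returns ``(E_BCS, E_OBS, inpatient basic subsidy)``; the two shares sum
    to ``E_BCS`` exactly.  Works element-wise on per-stratum series.
    """
    _check_proportion("alpha_s", alpha_s)
    _check_proportion("beta", beta)
    e_bcs = e_bs * alpha_s
    e_obs = e_bcs * (1.0 - beta)
    return e_bcs, e_obs, e_bcs - e_obs


def _check_proportion(name: str, value) -> None:
    arr = np.asarray(value, dtype=float)
    if (arr < -1e-12).any() or (arr > 1 + 1e-12).any():
        raise AccountsError(f"{name} must lie in [0, 1]")


def curative_totals(provincial: si.ProvincialAggregates,
                    coefficients: CoefficientSet) -> CurativeAccounts:
    """Assemble per-stratum curative accounts from provincial aggregates."""
    prov = provincial.by_stratum
    coef = coefficients.by_stratum.reindex(prov.index)
    if coef.isna().any().any():
        raise EstimationError(
            f"missing coefficients for strata: {list(prov.index[coef.isna().any(axis=1)])}")

    e_oci = curative_outpatient_income(provincial, coef["alpha_i"])
    e_bcs, e_obs, e_ibs = split_basic_subsidy(prov["basic_subsidy"],
                                              coef["alpha_s"], coef["beta"])
    df = pd.DataFrame(index=prov.index)
    df["outpatient_curative_income"] = e_oci
    df["outpatient_project_subsidy"] = prov["outpatient_project_subsidy"]
    df["outpatient_basic_subsidy"] = e_obs
    df["outpatient_curative_total"] = (
        e_oci + prov["outpatient_project_subsidy"] + e_obs)
    # inpatient income needs no preventive deduction
    df["inpatient_curative_income"] = prov["inpatient_income"]
    df["inpatient_project_subsidy"] = prov["inpatient_project_subsidy"]
    df["inpatient_basic_subsidy"] = e_ibs
    df["inpatient_curative_total"] = (
        prov["inpatient_income"] + prov["inpatient_project_subsidy"] + e_ibs)
    df["basic_curative_subsidy"] = e_bcs
    df["prevention_basic_subsidy"] = prov["basic_subsidy"] - e_bcs
    df["preventive_outpatient_income"] = prov["outpatient_income"] - e_oci
    return CurativeAccounts(df)


def prevention_expenditure(projects, rule: str = "max") -> float:
    """Prevention-project expenditure from (income, expense) comparisons.

    ``rule="max"``: when income < expense take the expense, otherwise the
    income (i.e. ``max`` per project).  ``rule="expense_always"`` takes the
    expense for every project.
    """
    if rule not in ("max", "expense_always"):
        raise Sha2011Error(f"unknown prevention rule: {rule!r}")
    total = 0.0
    for item in projects:
        income, expense = (item[-2], item[-1]) if len(item) >= 3 else item
        income, expense = float(income), float(expense)
        if income < 0 or expense < 0:
            raise AccountsError("prevention project with negative income or expense")
        total += expense if rule == "expense_always" else max(income, expense)
    return total


def assign_financing(amount_kind: str, amount: float,
                     payer_split: dict[str, float] | None = None) -> FinancingBreakdown:
    """Decompose one amount into government / social / household schemes."""
    if amount < 0:
        raise AccountsError("cannot decompose a negative amount")
    if amount_kind in ("basic_subsidy", "project_subsidy", "superior_subsidy"):
        return FinancingBreakdown(government=amount)
    if amount_kind == "other_income":
        return FinancingBreakdown(social=amount)
    if amount_kind == "encounter_payment":
        if payer_split is None:
            raise AccountsError("encounter_payment requires a payer split")
        total = sum(payer_split.values())
        if abs(total - amount) > si.PAYER_SUM_RTOL * max(abs(amount), 1.0):
            raise AccountsError("payer split mismatch")
        out = FinancingBreakdown()
        for payer, value in payer_split.items():
            scheme = PAYER_TO_SCHEME.get(payer)
            if scheme is None:
                raise AccountsError(f"unknown payer category: {payer!r}")
            setattr(out, scheme, getattr(out, scheme) + value)
        return out
    raise AccountsError(f"unknown amount kind: {amount_kind!r}")


# -- apportionment ------------------------------------------------------------------


def _share_table(cost_table: pd.DataFrame, services: list[str],
                 by_payer: bool) -> pd.DataFrame:
    """Cost shares over (disease, age[, scheme]) within each stratum.

    Returns a frame with columns provider_type, disease_class, age_bin,
    [financing_scheme,] share, where shares sum to 1 within each stratum;
    plus a pooled block under provider_type ``"__pooled__"`` used as the
    fallback for strata the survey did not observe.
    """
    sub = cost_table[cost_table["service_type"].isin(services)]
    frames = []
    for pooled in (False, True):
        if by_payer:
            melted = sub.melt(
                id_vars=["provider_type", "disease_class", "age_bin"],
                value_vars=si.PAYER_CATEGORIES, var_name="payer", value_name="amount")
            melted["financing_scheme"] = melted["payer"].map(PAYER_TO_SCHEME)
            dims = ["disease_class", "age_bin", "financing_scheme"]
        else:
            melted = sub.rename(columns={"total_cost": "amount"})
            dims = ["disease_class", "age_bin"]
        if pooled:
            melted = melted.assign(provider_type="__pooled__")
        grp = (melted.groupby(["provider_type"] + dims, observed=True)["amount"]
               .sum().reset_index())
        tot = grp.groupby("provider_type", observed=True)["amount"].transform("sum")
        grp = grp[tot > 0].copy()
        grp["share"] = grp["amount"] / tot[tot > 0]
        frames.append(grp.drop(columns=["amount"]))
    return pd.concat(frames, ignore_index=True)


def _apportion(amounts: pd.Series, shares: pd.DataFrame, function: str, source: str,
               scheme: str | None = None) -> pd.DataFrame:
    """Spread per-stratum amounts over a share table; returns cube rows.

    ``scheme=None`` means the share table carries a financing_scheme column
    (payer-based decomposition); otherwise every cell lands on ``scheme``.
    Strata with money but no shares use the pooled block, or a single
    unclassified cell if the survey saw nothing of this kind at all.
    """
    amounts = amounts[amounts > 0]
    if amounts.empty:
        return pd.DataFrame(columns=CUBE_COLUMNS)
    rows = []
    observed = set(shares["provider_type"].unique())
    for ptype, amount in amounts.items():
        key = ptype if ptype in observed else "__pooled__"
        block = shares[shares["provider_type"] == key]
        if block.empty:
            rows.append(pd.DataFrame([{
                "provider_type": ptype, "function": function,
                "financing_scheme": scheme or "government",
                "disease_class": UNCLASSIFIED, "age_bin": UNCLASSIFIED,
                "source": source, "amount_cny": amount,
            }]))
            continue
        out = block.copy()
        out["provider_type"] = ptype
        out["function"] = function
        out["source"] = source
        if scheme is not None:
            out["financing_scheme"] = scheme
        out["amount_cny"] = out["share"] * amount
        rows.append(out.drop(columns=["share"]))
    return pd.concat(rows, ignore_index=True).loc[:, CUBE_COLUMNS]


# -- the top-down computation ---------------------------------------------------------


def compute_che(provincial: si.ProvincialAggregates,
                institutions: pd.DataFrame,
                coefficients: CoefficientSet,
                rules: ClassificationRules | None = None,
                prevention_rule: str = "max") -> AccountsCube:
    """Total-population CHE cube from provincial aggregates and the survey.

    Homogeneous of degree 1 in the provincial money aggregates at fixed
    coefficients.  Capital expenditure is excluded by construction.
    """
    rules = rules or default_rules()
    ca = curative_totals(provincial, coefficients).by_stratum
    coef = coefficients.by_stratum
    ct = coefficients.cost_table

    shares_oc_payer = _share_table(ct, ["outpatient_curative"], by_payer=True)
    shares_op_payer = _share_table(ct, ["outpatient_preventive"], by_payer=True)
    shares_ip_payer = _share_table(ct, ["inpatient"], by_payer=True)
    shares_oc = _share_table(ct, ["outpatient_curative"], by_payer=False)
    shares_ip = _share_table(ct, ["inpatient"], by_payer=False)
    shares_prev = _share_table(ct, _PREVENTIVE_POOL, by_payer=False)
    shares_all = _share_table(ct, _ALL_SERVICES, by_payer=False)

    blocks = [
        _apportion(ca["outpatient_curative_income"], shares_oc_payer,
                   "curative_outpatient", "medical_income"),
        _apportion(ca["preventive_outpatient_income"], shares_op_payer,
                   "prevention", "medical_income"),
        _apportion(ca["inpatient_curative_income"], shares_ip_payer,
                   "curative_inpatient", "medical_income"),
        _apportion(ca["outpatient_project_subsidy"], shares_oc,
                   "curative_outpatient", "project_subsidy", scheme="government"),
        _apportion(ca["inpatient_project_subsidy"], shares_ip,
                   "curative_inpatient", "project_subsidy", scheme="government"),
        _apportion(ca["outpatient_basic_subsidy"], shares_oc,
                   "curative_outpatient", "basic_subsidy", scheme="government"),
        _apportion(ca["inpatient_basic_subsidy"], shares_ip,
                   "curative_inpatient", "basic_subsidy", scheme="government"),
        _apportion(ca["prevention_basic_subsidy"], shares_prev,
                   "prevention", "basic_subsidy", scheme="government"),
    ]

    # institution-level items, scaled from the survey to the province
    fin = institutions.groupby("provider_type")
    scale = coef["scale"]

    def scaled(col_sum: pd.Series) -> pd.Series:
        s = col_sum.reindex(scale.index).fillna(0.0) * scale
        return s.fillna(0.0)

    proj = institutions.assign(
        prevention_project_expenditure=institutions["prevention_projects"].map(
            lambda p: prevention_expenditure(p or [], prevention_rule))
    ).groupby("provider_type")["prevention_project_expenditure"].sum()
    blocks.append(_apportion(scaled(proj), shares_prev,
                             "prevention", "project_subsidy", scheme="government"))

    item_specs = [
        ("assistant_service_cost", "assistant_services", "other", "household"),
        ("medicine_cost", "medicine", "other", "household"),
        ("management_cost", "management", "other", "government"),
        ("superior_institution_subsidy", "management", "superior_subsidy", "government"),
        ("science_education_income", "management", "science_education", "social"),
        ("other_income", "management", "other", "social"),
    ]
    for col, function, source, scheme in item_specs:
        blocks.append(_apportion(scaled(fin[col].sum()), shares_all,
                                 function, source, scheme=scheme))

    cells = pd.concat(blocks, ignore_index=True)
    cells = cells[cells["amount_cny"] != 0.0].reset_index(drop=True)
    cube = AccountsCube(
        cells,
        metadata={
            "currency": "CNY",
            "year": provincial.year,
            "population_scope": "total",
            "exchange_rate_cny_per_usd": provincial.exchange_rate_cny_per_usd,
            "prevention_rule": prevention_rule,
            "method": "top_down",
        },
    )
    cube.validate()
    return cube


# -- census ground truth ---------------------------------------------------------------


def tabulate_truth_cube(dataset, rules: ClassificationRules,
                        prevention_rule: str = "max") -> AccountsCube:
    """Exact cube of a generated census by direct enumeration of its records.

    Encounter money is tabulated record by record; institution-level money
    (subsidies, prevention projects, overheads) is allocated by the
    generating rules evaluated on exact census counts.  This shares no code
    with :func:`compute_che`'s coefficient/scaling path and serves as its
    oracle.
    """
    enc = dataset.encounters.merge(
        dataset.institutions[["institution_id", "provider_type"]],
        on="institution_id", how="left")
    enc["disease_class"] = icd10_chapter_series(enc["icd10_code"], rules)
    enc["age_bin"] = age_bin_series(enc["age_years"], rules)

    blocks = []
    fmap = {"outpatient_curative": "curative_outpatient",
            "inpatient": "curative_inpatient",
            "outpatient_preventive": "prevention"}
    billed = enc[enc["service_type"].isin(fmap)]
    if len(billed):
        melted = billed.melt(
            id_vars=["provider_type", "service_type", "disease_class", "age_bin"],
            value_vars=si.PAYER_CATEGORIES, var_name="payer", value_name="amount_cny")
        melted["financing_scheme"] = melted["payer"].map(PAYER_TO_SCHEME)
        melted["function"] = melted["service_type"].map(fmap)
        melted["source"] = "medical_income"
        blocks.append(melted.groupby(CUBE_KEY + ["source"], observed=True)["amount_cny"]
                      .sum().reset_index())

    def spread(amounts: pd.Series, pool: pd.DataFrame, function: str,
               source: str, scheme: str) -> None:
        """Spread stratum amounts over the pool's exact (d, a) cost pattern."""
        if float(amounts.sum()) == 0:
            return
        pat = pool.groupby(["provider_type", "disease_class", "age_bin"],
                           observed=True)["total_cost"].sum().reset_index()
        tot = pat.groupby("provider_type")["total_cost"].transform("sum")
        pat["share"] = pat["total_cost"] / tot
        rows = []
        for ptype, amount in amounts[amounts > 0].items():
            block = pat[pat["provider_type"] == ptype]
            if block.empty:
                rows.append(pd.DataFrame([{
                    "provider_type": ptype, "disease_class": UNCLASSIFIED,
                    "age_bin": UNCLASSIFIED, "share": 1.0}]))
                rows[-1]["amount_cny"] = amount
            else:
                block = block.copy()
                block["amount_cny"] = block["share"] * amount
                rows.append(block)
        out = pd.concat(rows, ignore_index=True)
        out["function"] = function
        out["financing_scheme"] = scheme
        out["source"] = source
        blocks.append(out.loc[:, CUBE_COLUMNS])

    fin = dataset.institutions
    by = fin.groupby("provider_type")

    # exact equivalent-person and equivalent-workload splits per stratum
    sgrp = enc.groupby("provider_type")
    n_ms = sgrp.apply(lambda g: (g["service_type"].isin(["outpatient_curative", "inpatient"])).sum(),
                      include_groups=False)
    n_phs = sgrp.apply(lambda g: (g["service_type"]
                                  .isin(["outpatient_preventive", "public_health"])).sum(),
                       include_groups=False)
    n_ibd = sgrp["bed_days"].sum()
    n_ocv = sgrp.apply(lambda g: (g["service_type"] == "outpatient_curative").sum(),
                       include_groups=False)
    kappa = dataset.config.kappa if dataset.config is not None else 0.1

    strata = fin["provider_type"].unique()
    idx = pd.Index(sorted(strata), name="provider_type")

    def reidx(s):
        return s.reindex(idx).fillna(0.0).astype(float)

    e_bs = reidx(by["basic_subsidy"].sum())
    n_ms, n_phs, n_ibd, n_ocv = map(reidx, (n_ms, n_phs, n_ibd, n_ocv))
    denom_p = n_ms + n_phs
    alpha_s = np.where(denom_p > 0, n_ms / denom_p.replace(0, np.nan), 1.0)
    alpha_s = pd.Series(np.nan_to_num(alpha_s, nan=1.0), index=idx)
    denom_w = n_ibd + n_ocv * kappa
    beta = pd.Series(
        np.where(denom_w > 0, n_ibd / denom_w.replace(0, np.nan), 0.0), index=idx
    ).fillna(0.0)

    e_bcs = e_bs * alpha_s
    oc_pool = enc[enc["service_type"] == "outpatient_curative"]
    ip_pool = enc[enc["service_type"] == "inpatient"]
    prev_pool = enc[enc["service_type"].isin(_PREVENTIVE_POOL)]
    all_pool = enc

    spread(e_bcs * (1 - beta), oc_pool, "curative_outpatient", "basic_subsidy", "government")
    spread(e_bcs * beta, ip_pool, "curative_inpatient", "basic_subsidy", "government")
    spread(e_bs - e_bcs, prev_pool, "prevention", "basic_subsidy", "government")
    spread(reidx(by["outpatient_project_subsidy"].sum()), oc_pool,
           "curative_outpatient", "project_subsidy", "government")
    spread(reidx(by["inpatient_project_subsidy"].sum()), ip_pool,
           "curative_inpatient", "project_subsidy", "government")

    proj = reidx(fin.assign(
        v=fin["prevention_projects"].map(lambda p: prevention_expenditure(p or [],
                                                                          prevention_rule))
    ).groupby("provider_type")["v"].sum())
    spread(proj, prev_pool, "prevention", "project_subsidy", "government")

    for col, function, source, scheme in [
        ("assistant_service_cost", "assistant_services", "other", "household"),
        ("medicine_cost", "medicine", "other", "household"),
        ("management_cost", "management", "other", "government"),
        ("superior_institution_subsidy", "management", "superior_subsidy", "government"),
        ("science_education_income", "management", "science_education", "social"),
        ("other_income", "management", "other", "social"),
    ]:
        spread(reidx(by[col].sum()), all_pool, function, source, scheme)

    cells = pd.concat(blocks, ignore_index=True)
    cells = cells[cells["amount_cny"] != 0.0].reset_index(drop=True)
    cube = AccountsCube(
        cells,
        metadata={
            "currency": "CNY",
            "year": dataset.provincial.year,
            "population_scope": "total",
            "exchange_rate_cny_per_usd": dataset.provincial.exchange_rate_cny_per_usd,
            "prevention_rule": prevention_rule,
            "method": "census_enumeration",
        },
    )
    cube.validate()
    return cube


# -- children restriction ----------------------------------------------------------------


def restrict_to_children(cube: AccountsCube, children_share=None,
                         rules: ClassificationRules | None = None) -> AccountsCube:
    """Restrict the cube to the children subpopulation (age <= 14 inclusive).

    With ``children_share=None`` the cube's own age dimension is used: cells
    in the children age bins (single-year bins plus the boundary-age
    overflow bin) are kept as-is and everything else is dropped.  This is
    exact because every amount was apportioned at full age granularity.

    Alternatively ``children_share`` may be a scalar proportion or a mapping
    ``provider_type -> share`` (the survey children's cost share); every cell
    is then scaled by its stratum's share — the coarse variant for cubes
    without age detail and for sensitivity analysis.
    """
    rules = rules or default_rules()
    df = cube.cells
    if children_share is None:
        keep = df["age_bin"].isin(rules.child_bin_labels)
        dropped_unclassified = float(
            df.loc[(df["age_bin"] == UNCLASSIFIED), "amount_cny"].sum())
        if dropped_unclassified > 0:
            log.warning("children restriction drops %.2f CNY with unclassified age",
                        dropped_unclassified)
        out = df[keep].copy()
    else:
        if isinstance(children_share, Real):
            shares = pd.Series(float(children_share),
                               index=df["provider_type"].unique())
        else:
            shares = pd.Series(children_share, dtype=float)
        _check_proportion("children_share", shares)
        missing = set(df["provider_type"].unique()) - set(shares.index)
        if missing:
            raise EstimationError(f"missing children share for strata: {sorted(missing)}")
        out = df.copy()
        out["amount_cny"] = out["amount_cny"] * out["provider_type"].map(shares).to_numpy()
        out = out[out["amount_cny"] != 0.0]
    meta = dict(cube.metadata)
    meta["population_scope"] = f"children_0_{rules.children_age_max}"
    result = AccountsCube(out.reset_index(drop=True), meta)
    result.validate()
    return result
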
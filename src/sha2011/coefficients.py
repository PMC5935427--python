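"""Survey-derived allocation coefficients for the top-down method.

From the survey microdata four proportions are estimated and then applied to
the provincial aggregates:

* ``alpha_i = 1 - E_POI / E_TOI`` — share of outpatient income that is
  curative (preventive outpatient income removed);
* ``alpha_s = N_MS / (N_MS + N_PHS)`` — share of the basic expenditure
  subsidy attributable to curative care, by the equivalent-person principle
  (N_MS medical-service patients vs N_PHS public-health service users);
* ``upsilon = 1 - N_POV / N_TOV`` — share of outpatient visits that are
  curative, used to convert provincial outpatient visits into curative
  outpatient visits ``N_IOV = N_OV * upsilon``;
* ``beta = N_IBD / (N_IBD + N_IOV * kappa)`` — the inpatient share of the
  curative basic subsidy, by equivalent workload: one outpatient visit
  counts as ``kappa`` (default 0.1) bed-day equivalents.  A literal
  alternative reading that multiplies the whole ratio by ``kappa`` is
  available via ``scale_by_kappa=True`` for sensitivity analysis.

Coefficients are estimated per provider-type stratum where the survey has
records for the stratum (with a pooled fallback), because case mix and the
preventive share differ systematically between, say, village clinics and
provincial hospitals.  Alongside the scalar coefficients the estimator
carries the survey cost table — spending by (stratum, service type, disease
chapter, age bin, payer) — which is the apportionment basis the accounts
engine uses to fill the disease, age and financing dimensions, plus the
children's cost shares per (stratum, service type).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import survey_ingest as si
from .classification import ClassificationRules, age_bin_series, default_rules, icd10_chapter_series
from .errors import EstimationError

log = logging.getLogger(__name__)

#: per-stratum tally columns
_TALLY_COLS = [
    "preventive_outpatient_income",   # E_POI
    "total_outpatient_income",        # E_TOI
    "n_medical_service",              # N_MS (all ages)
    "n_public_health",                # N_PHS (all ages)
    "n_medical_service_children",
    "n_public_health_children",
    "inpatient_bed_days",             # N_IBD (survey)
    "outpatient_visits_total",        # N_TOV
    "outpatient_visits_preventive",   # N_POV
    "survey_medical_income",          # outpatient + inpatient income (scale basis)
]

_CURATIVE_SERVICES = ["outpatient_curative", "inpatient"]
_PREVENTIVE_SERVICES = ["outpatient_preventive", "public_health"]


@dataclass
class SurveyTallies:
    """Filtered sums and counts over the survey records."""

    by_stratum: pd.DataFrame                 # index provider_type, columns _TALLY_COLS
    cost_table: pd.DataFrame                 # provider_type, service_type, disease, age, payers, cost
    children_cost_share: pd.DataFrame        # index (provider_type, service_type), column share
    target_age_max: int = 14
    n_records: int = 0

    @property
    def pooled(self) -> pd.Series:
        return self.by_stratum.sum(axis=0)


@dataclass
class CoefficientSet:
    """Estimated allocation coefficients with provenance."""

    alpha_i: float
    alpha_s: float
    beta: float
    upsilon: float
    kappa: float
    curative_outpatient_visits: float        # N_IOV, provincial scale
    by_stratum: pd.DataFrame                 # per-stratum alpha_i/alpha_s/upsilon/beta/n_iov/scale
    children_share: pd.DataFrame             # per (stratum, service_type) children cost share
    cost_table: pd.DataFrame                 # apportionment basis (from tallies)
    provenance: dict = field(default_factory=dict)

    def to_yaml(self, path) -> None:
        doc = {
            "alpha_i": float(self.alpha_i),
            "alpha_s": float(self.alpha_s),
            "beta": float(self.beta),
            "upsilon": float(self.upsilon),
            "kappa": float(self.kappa),
            "curative_outpatient_visits": float(self.curative_outpatient_visits),
            "by_stratum": {
                str(k): {c: float(v) for c, v in row.items()}
                for k, row in self.by_stratum.iterrows()
            },
            "provenance": self.provenance,
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


# -- tallies ---------------------------------------------------------------------


def tally(encounters: pd.DataFrame, institutions: pd.DataFrame,
          target_age_max: int = 14,
          rules: ClassificationRules | None = None) -> SurveyTallies:
    """Compute every survey tally by direct filtered summation.

    The children filter is inclusive: ``age_years <= target_age_max``.
    """
    if len(encounters) == 0:
        raise EstimationError("no survey records")
    rules = rules or default_rules()

    enc = encounters.merge(
        institutions[["institution_id", "provider_type"]], on="institution_id", how="left"
    )
    if enc["provider_type"].isna().any():
        raise EstimationError("encounters reference institutions missing from the finance sheets")

    enc["disease_class"] = icd10_chapter_series(enc["icd10_code"], rules)
    enc["age_bin"] = age_bin_series(enc["age_years"], rules)
    child = enc["age_years"] <= target_age_max
    outp = enc["service_type"].isin(si.OUTPATIENT_SERVICES)
    prev = enc["service_type"] == "outpatient_preventive"
    ms = enc["service_type"].isin(_CURATIVE_SERVICES)
    phs = enc["service_type"].isin(_PREVENTIVE_SERVICES)

    g = enc.groupby("provider_type")
    t = pd.DataFrame(index=g.size().index)
    t["preventive_outpatient_income"] = enc.loc[prev].groupby("provider_type")["total_cost"].sum()
    t["total_outpatient_income"] = enc.loc[outp].groupby("provider_type")["total_cost"].sum()
    t["n_medical_service"] = enc.loc[ms].groupby("provider_type").size()
    t["n_public_health"] = enc.loc[phs].groupby("provider_type").size()
    t["n_medical_service_children"] = enc.loc[ms & child].groupby("provider_type").size()
    t["n_public_health_children"] = enc.loc[phs & child].groupby("provider_type").size()
    t["inpatient_bed_days"] = g["bed_days"].sum()
    t["outpatient_visits_total"] = enc.loc[outp].groupby("provider_type").size()
    t["outpatient_visits_preventive"] = enc.loc[prev].groupby("provider_type").size()
    not_ph = enc["service_type"] != "public_health"
    t["survey_medical_income"] = enc.loc[not_ph].groupby("provider_type")["total_cost"].sum()
    t = t.fillna(0.0).loc[:, _TALLY_COLS]
    t.index.name = "provider_type"

    cost_table = (
        enc.groupby(["provider_type", "service_type", "disease_class", "age_bin"],
                    observed=True)[si.PAYER_CATEGORIES + ["total_cost"]]
        .sum()
        .reset_index()
    )

    total = enc.groupby(["provider_type", "service_type"], observed=True)["total_cost"].sum()
    child_cost = (
        enc.loc[child].groupby(["provider_type", "service_type"], observed=True)["total_cost"].sum()
    )
    share = (child_cost.reindex(total.index).fillna(0.0) / total.replace(0.0, np.nan)).fillna(0.0)
    children = share.to_frame("share")

    return SurveyTallies(
        by_stratum=t,
        cost_table=cost_table,
        children_cost_share=children,
        target_age_max=target_age_max,
        n_records=len(enc),
    )


# -- the four coefficient formulas -------------------------------------------------


def curative_outpatient_fraction(tallies: SurveyTallies) -> float:
    """``alpha_i = 1 - E_POI / E_TOI`` on the pooled survey."""
    p = tallies.pooled
    e_toi = float(p["total_outpatient_income"])
    if e_toi <= 0:
        raise EstimationError("alpha_i undefined: survey total outpatient income is zero")
    return 1.0 - float(p["preventive_outpatient_income"]) / e_toi


def subsidy_curative_fraction(tallies: SurveyTallies) -> float:
    """``alpha_s = N_MS / (N_MS + N_PHS)`` on the pooled survey."""
    p = tallies.pooled
    denom = float(p["n_medical_service"] + p["n_public_health"])
    if denom <= 0:
        raise EstimationError("alpha_s undefined: no medical or public-health service users")
    return float(p["n_medical_service"]) / denom


def curative_visit_fraction(tallies: SurveyTallies) -> float:
    """``upsilon = 1 - N_POV / N_TOV`` on the pooled survey."""
    p = tallies.pooled
    n_tov = float(p["outpatient_visits_total"])
    if n_tov <= 0:
        raise EstimationError("upsilon undefined: no outpatient visits in the survey")
    return 1.0 - float(p["outpatient_visits_preventive"]) / n_tov


def inpatient_workload_share(n_ibd: float, n_iov: float, kappa: float = 0.1,
                             scale_by_kappa: bool = False) -> float:
    """``beta``: the inpatient share of the curative basic subsidy.

    One outpatient visit counts as ``kappa`` bed-day equivalents, so
    ``beta = N_IBD / (N_IBD + N_IOV * kappa)``.  With ``scale_by_kappa`` the
    whole ratio is additionally multiplied by ``kappa`` (the literal reading
    of the printed expression), capping beta at ``kappa``.
    """
    if kappa <= 0:
        raise EstimationError("kappa must be positive")
    denom = n_ibd + n_iov * kappa
    if denom <= 0:
        raise EstimationError("beta undefined: no inpatient or outpatient workload")
    beta = n_ibd / denom
    return beta * kappa if scale_by_kappa else beta


# -- composition --------------------------------------------------------------------


def estimate_coefficients(tallies: SurveyTallies,
                          provincial: si.ProvincialAggregates,
                          kappa: float = 0.1,
                          scale_by_kappa: bool = False) -> CoefficientSet:
    """Compose the coefficient formulas, per stratum with pooled fallback.

    ``N_IOV`` is computed from the *provincial* outpatient visit count and
    the survey ``upsilon``; ``beta`` uses the provincial bed-day count when
    the stratum appears in the provincial table (falling back to the survey
    tally), consistent with the provincial origin of ``N_OV``.
    """
    pooled_alpha_i = curative_outpatient_fraction(tallies)
    pooled_alpha_s = subsidy_curative_fraction(tallies)
    pooled_upsilon = curative_visit_fraction(tallies)
    n_ov_total = provincial.total_outpatient_visits
    if n_ov_total <= 0:
        raise EstimationError("provincial outpatient visit count must be positive")
    pooled_n_iov = n_ov_total * pooled_upsilon
    pooled_beta = inpatient_workload_share(
        provincial.total_inpatient_bed_days or float(tallies.pooled["inpatient_bed_days"]),
        pooled_n_iov, kappa, scale_by_kappa)

    strata = provincial.by_stratum.index.union(tallies.by_stratum.index)
    t = tallies.by_stratum.reindex(strata).fillna(0.0)
    prov = provincial.by_stratum.reindex(strata).fillna(0.0)

    fallbacks: dict[str, list[str]] = {"alpha_i": [], "alpha_s": [], "upsilon": [], "beta": []}

    def per_stratum(num, den, pooled, name):
        out = pd.Series(pooled, index=strata, dtype=float)
        ok = den > 0
        out[ok] = num[ok] / den[ok]
        fallbacks[name] = sorted(strata[~ok])
        return out

    alpha_i = 1.0 - per_stratum(t["preventive_outpatient_income"],
                                t["total_outpatient_income"], 1.0 - pooled_alpha_i, "alpha_i")
    alpha_s = per_stratum(t["n_medical_service"],
                          t["n_medical_service"] + t["n_public_health"],
                          pooled_alpha_s, "alpha_s")
    upsilon = 1.0 - per_stratum(t["outpatient_visits_preventive"],
                                t["outpatient_visits_total"], 1.0 - pooled_upsilon, "upsilon")
    n_iov = prov["outpatient_visits"] * upsilon

    ibd_source = "provincial"
    n_ibd = prov["inpatient_bed_days"]
    if float(n_ibd.sum()) <= 0:
        n_ibd = t["inpatient_bed_days"]
        ibd_source = "survey"
    denom = n_ibd + n_iov * kappa
    beta = pd.Series(pooled_beta, index=strata, dtype=float)
    ok = denom > 0
    beta[ok] = n_ibd[ok] / denom[ok]
    if scale_by_kappa:
        beta = beta * kappa
    fallbacks["beta"] = sorted(strata[~ok])

    # survey -> province scale factor for institution-level items
    scale = pd.Series(np.nan, index=strata, dtype=float)
    prov_income = prov["outpatient_income"] + prov["inpatient_income"]
    ok = t["survey_medical_income"] > 0
    scale[ok] = prov_income[ok] / t.loc[ok, "survey_medical_income"]
    pooled_scale = (float(prov_income.sum()) / float(t["survey_medical_income"].sum())
                    if float(t["survey_medical_income"].sum()) > 0 else 1.0)
    scale = scale.fillna(pooled_scale)

    by_stratum = pd.DataFrame(
        {"alpha_i": alpha_i, "alpha_s": alpha_s, "upsilon": upsilon,
         "beta": beta, "n_iov": n_iov, "scale": scale}
    )
    by_stratum.index.name = "provider_type"

    for name, vals in [("alpha_i", alpha_i), ("alpha_s", alpha_s),
                       ("upsilon", upsilon)]:
        if ((vals < -1e-12) | (vals > 1 + 1e-12)).any():
            raise EstimationError(f"{name} outside [0, 1]")

    provenance = {
        "n_survey_records": int(tallies.n_records),
        "target_age_max": int(tallies.target_age_max),
        "n_ibd_source": ibd_source,
        "scale_by_kappa": bool(scale_by_kappa),
        "pooled_fallback_strata": {k: [str(s) for s in v] for k, v in fallbacks.items()},
        "pooled": {
            "E_POI": float(tallies.pooled["preventive_outpatient_income"]),
            "E_TOI": float(tallies.pooled["total_outpatient_income"]),
            "N_MS": float(tallies.pooled["n_medical_service"]),
            "N_PHS": float(tallies.pooled["n_public_health"]),
            "N_POV": float(tallies.pooled["outpatient_visits_preventive"]),
            "N_TOV": float(tallies.pooled["outpatient_visits_total"]),
            "N_OV_provincial": float(n_ov_total),
        },
    }
    if any(fallbacks.values()):
        log.info("pooled-coefficient fallback used for strata: %s",
                 {k: v for k, v in fallbacks.items() if v})

    return CoefficientSet(
        alpha_i=pooled_alpha_i,
        alpha_s=pooled_alpha_s,
        beta=pooled_beta,
        upsilon=pooled_upsilon,
        kappa=kappa,
        curative_outpatient_visits=pooled_n_iov,
        by_stratum=by_stratum,
        children_share=tallies.children_cost_share,
        cost_table=tallies.cost_table,
        provenance=provenance,
    )
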
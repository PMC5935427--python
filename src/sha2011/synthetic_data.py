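"""Synthetic census generator for the subnational accounting pipeline.

The generator emulates the structure of a multistage institution survey in a
Chinese province: cities, provider-type strata within cities, institution
finance sheets, and patient-encounter microdata coded with ICD-10.  Unlike a
real survey, it first creates a complete *census* of a small synthetic
province — every institution and every encounter — together with consistent
yearbook-style provincial aggregates, and a sampling operation then draws
the "survey" from that census.  Because the census is fully observed, an
exact ground-truth accounts cube exists (:func:`tabulate_truth`) against
which the top-down estimator can be checked end to end.

Generating rules (the "physics" of the synthetic province)
----------------------------------------------------------
* Encounter costs are log-normal per service type: positive, right-skewed,
  the standard shape for expenditure data.
* Payer splits are Dirichlet draws around configured mean simplex weights;
  components are adjusted so they sum to the encounter cost exactly.
* Preventive-type encounters (preventive outpatient visits and public-health
  program contacts) carry codes from the "factors influencing health status"
  ICD range; curative encounters draw chapters from the configured case-mix.
* Institution subsidies are generated at institution level as configured
  rates times medical income, matching how subsidies appear on finance
  sheets; public-health contact costs are booked as the income of a
  prevention project on the institution's sheet (with a random
  expense/income ratio), not as outpatient income.
* Overhead items (assistant services, medicine, management, superior
  subsidy, science & education income, other income, capital expenditure)
  are rate-based on medical income; capital expenditure is generated so the
  CHE-scope exclusion is exercised, and it is never counted in the truth cube.
* The default age distribution is uniform within 0-14 and within 15-100,
  with the total weight on ages 0-14 set by ``children_weight`` so the
  expected children's cost share is a known constant.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import survey_ingest as si
from .classification import ClassificationRules, default_rules
from .errors import ConfigurationError, SamplingError

_WEIGHT_TOL = 1e-9

#: default pediatric-flavoured case-mix over ICD chapters (normalised at use)
DEFAULT_DISEASE_WEIGHTS = {
    "Infectious diseases and parasitic diseases": 0.039,
    "Tumor": 0.014,
    "Blood diseases": 0.009,
    "Endocrine, nutritional and metabolic disease": 0.061,
    "Mental and behavior disorders": 0.003,
    "Nervous system diseases": 0.010,
    "Eye diseases": 0.019,
    "Ear diseases": 0.010,
    "Circulatory system diseases": 0.069,
    "Respiratory system diseases": 0.431,
    "Digestive system diseases": 0.057,
    "Skin and subcutaneous tissue disease": 0.055,
    "Muscular and connective tissue diseases": 0.004,
    "Urogenital system diseases": 0.014,
    "Pregnancy, childbirth and puerperium diseases": 0.005,
    "Perinatal diseases": 0.028,
    "Congenital anomalies and chromosomal abnormalities": 0.002,
    "Symptoms, signs, clinical and laboratory abnormalities": 0.093,
    "Injury, poisoning and external causes": 0.032,
    "Death": 0.001,
    "Factors influencing health status": 0.046,
}
_total = sum(DEFAULT_DISEASE_WEIGHTS.values())
DEFAULT_DISEASE_WEIGHTS = {k: v / _total for k, v in DEFAULT_DISEASE_WEIGHTS.items()}

DEFAULT_INSTITUTIONS_PER_CITY = {
    "provincial_hospital": 1,
    "general_hospital": 3,
    "specialized_hospital": 1,
    "tcm_hospital": 1,
    "maternal_child_center": 1,
    "outpatient_service_institution": 1,
    "township_hospital": 2,
    "community_health_center": 2,
    "village_or_individual_clinic": 2,
    "public_health_institution": 1,
}

DEFAULT_COST_DISTRIBUTIONS = {
    # (mu, sigma) of log cost in CNY
    "outpatient_curative": (np.log(180.0), 0.8),
    "outpatient_preventive": (np.log(60.0), 0.6),
    "inpatient": (np.log(5200.0), 0.7),
    "public_health": (np.log(25.0), 0.5),
}

DEFAULT_PAYER_WEIGHTS = {
    "social_insurance": 0.28,
    "commercial_insurance": 0.04,
    "donation": 0.01,
    "government_program": 0.02,
    "out_of_pocket": 0.65,
}

DEFAULT_OVERHEAD_RATES = {
    "assistant_service_cost": 0.010,
    "medicine_cost": 0.020,
    "management_cost": 0.020,
    "superior_institution_subsidy": 0.005,  # primary institutions only
    "science_education_income": 0.002,      # hospitals only
    "other_income": 0.010,
    "capital_expenditure": 0.050,           # generated but outside CHE scope
}

PRIMARY_TYPES = ["township_hospital", "community_health_center", "village_or_individual_clinic"]
HOSPITAL_TYPES = ["provincial_hospital", "general_hospital", "specialized_hospital", "tcm_hospital"]


def default_age_weights(children_share: float = 0.0619) -> np.ndarray:
    """Uniform-within-block weights over ages 0-100.

    ``children_share`` is the total probability on ages 0-14 inclusive, i.e.
    the expected share of encounters (and, with age-independent costs, of
    spending) that falls in the children scope.
    """
    if not 0.0 <= children_share <= 1.0:
        raise ConfigurationError("children_share must lie in [0, 1]")
    w = np.empty(101)
    w[:15] = children_share / 15.0
    w[15:] = (1.0 - children_share) / 86.0
    return w


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic province; defaults are the study conditions."""

    n_cities: int = 4
    institutions_per_city: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_INSTITUTIONS_PER_CITY)
    )
    encounters_per_institution: float = 2000
    age_distribution: np.ndarray = field(default_factory=default_age_weights)
    disease_distribution: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DISEASE_WEIGHTS)
    )
    disease_distribution_children: dict[str, float] | None = None
    preventive_visit_share: float = 0.25
    inpatient_share: float = 0.08
    public_health_share: float = 0.04
    payer_split_distribution: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PAYER_WEIGHTS)
    )
    payer_concentration: float = 8.0
    cost_distributions: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COST_DISTRIBUTIONS)
    )
    subsidy_rates: dict[str, float] = field(
        default_factory=lambda: {"basic": 0.06, "project": 0.015}
    )
    overhead_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OVERHEAD_RATES)
    )
    mean_bed_days: float = 4.0
    kappa: float = 0.1
    exchange_rate_cny_per_usd: float = si.DEFAULT_EXCHANGE_RATE
    year: int = 2014
    seed: int = 0

    def validate(self) -> None:
        if self.n_cities <= 0:
            raise ConfigurationError("n_cities must be positive")
        for ptype, count in self.institutions_per_city.items():
            if ptype not in si.PROVIDER_TYPES:
                raise ConfigurationError(f"institutions_per_city: unknown provider type {ptype!r}")
            if count < 0:
                raise ConfigurationError(f"institutions_per_city[{ptype!r}] must be >= 0")
        if sum(self.institutions_per_city.values()) <= 0:
            raise ConfigurationError("institutions_per_city must name at least one institution")
        if self.encounters_per_institution < 0:
            raise ConfigurationError("encounters_per_institution must be >= 0")
        ages = np.asarray(self.age_distribution, dtype=float)
        if ages.shape != (101,) or (ages < 0).any() or abs(ages.sum() - 1.0) > _WEIGHT_TOL:
            raise ConfigurationError(
                "age_distribution must be 101 non-negative weights over ages 0-100 summing to 1"
            )
        for name, dist in [("disease_distribution", self.disease_distribution)] + (
            [("disease_distribution_children", self.disease_distribution_children)]
            if self.disease_distribution_children is not None else []
        ):
            w = np.array(list(dist.values()), dtype=float)
            if (w < 0).any() or abs(w.sum() - 1.0) > 1e-6:
                raise ConfigurationError(f"{name} weights must be non-negative and sum to 1")
        for name, p in [
            ("preventive_visit_share", self.preventive_visit_share),
            ("inpatient_share", self.inpatient_share),
            ("public_health_share", self.public_health_share),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.inpatient_share + self.public_health_share > 1.0:
            raise ConfigurationError("inpatient_share + public_health_share exceeds 1")
        pw = np.array([self.payer_split_distribution.get(c, 0.0) for c in si.PAYER_CATEGORIES])
        if (pw < 0).any() or abs(pw.sum() - 1.0) > _WEIGHT_TOL:
            raise ConfigurationError("payer_split_distribution must be simplex weights")
        for stype in si.SERVICE_TYPES:
            if stype not in self.cost_distributions:
                raise ConfigurationError(f"cost_distributions missing service type {stype!r}")
            mu, sigma = self.cost_distributions[stype]
            if sigma <= 0:
                raise ConfigurationError(f"cost_distributions[{stype!r}] scale must be positive")
        for key in ("basic", "project"):
            r = self.subsidy_rates.get(key)
            if r is None or not 0.0 <= r <= 1.0:
                raise ConfigurationError(f"subsidy_rates[{key!r}] must lie in [0, 1]")
        for key, r in self.overhead_rates.items():
            if key not in DEFAULT_OVERHEAD_RATES:
                raise ConfigurationError(f"overhead_rates: unknown item {key!r}")
            if r < 0:
                raise ConfigurationError(f"overhead_rates[{key!r}] must be >= 0")
        if self.kappa <= 0:
            raise ConfigurationError("kappa must be positive")
        if self.exchange_rate_cny_per_usd <= 0:
            raise ConfigurationError("exchange_rate_cny_per_usd must be positive")


@dataclass
class SamplingPlan:
    """Multistage plan: first sample cities, then institutions within strata."""

    n_cities: int | None = None          # None = keep all cities
    institution_fraction: float = 1.0    # sampled within each (city, provider type)
    min_per_stratum: int = 1

    def validate(self) -> None:
        if self.n_cities is not None and self.n_cities <= 0:
            raise SamplingError("n_cities must be positive")
        if not 0.0 < self.institution_fraction <= 1.0:
            raise SamplingError("institution_fraction must lie in (0, 1]")


@dataclass
class SyntheticDataset:
    """A generated census (or a survey subset of one)."""

    institutions: pd.DataFrame
    encounters: pd.DataFrame
    provincial: si.ProvincialAggregates
    truth: "pd.DataFrame | None" = None      # filled lazily by tabulate_truth
    config: GeneratorConfig | None = None
    sampling: dict | None = None             # plan + seed, set by draw_survey

    @property
    def is_census(self) -> bool:
        return self.sampling is None


# -- ICD code sampling ---------------------------------------------------------

_PREVENTIVE_CHAPTER = "Factors influencing health status"


def _build_code_pools(rules: ClassificationRules) -> dict[str, list[str]]:
    """All 3-character codes per chapter label, for uniform sampling."""
    pools: dict[str, list[str]] = {}
    for start, end, label in rules.icd_chapter_ranges:
        lo = (ord(start[0]) - 65) * 100 + int(start[1:3])
        hi = (ord(end[0]) - 65) * 100 + int(end[1:3])
        codes = [f"{chr(65 + k // 100)}{k % 100:02d}" for k in range(lo, hi + 1)]
        pools.setdefault(label, []).extend(codes)
    return pools


# -- generation ------------------------------------------------------------------


def generate(config: GeneratorConfig, rules: ClassificationRules | None = None) -> SyntheticDataset:
    """Generate a synthetic province census; deterministic for a fixed seed."""
    config.validate()
    rules = rules or default_rules()
    rng = np.random.default_rng(config.seed)

    # institutions frame
    rows = []
    for city in range(config.n_cities):
        for ptype in si.PROVIDER_TYPES:
            for k in range(config.institutions_per_city.get(ptype, 0)):
                rows.append(
                    {
                        "institution_id": f"C{city:02d}-{ptype}-{k:02d}",
                        "city": f"city_{city:02d}",
                        "provider_type": ptype,
                    }
                )
    inst = pd.DataFrame(rows)
    n_inst = len(inst)

    # encounter counts per institution
    epi = config.encounters_per_institution
    if float(epi).is_integer():
        counts = np.full(n_inst, int(epi))
    else:
        counts = rng.poisson(epi, size=n_inst)
    n = int(counts.sum())

    enc = pd.DataFrame(
        {
            "institution_id": np.repeat(inst["institution_id"].to_numpy(), counts),
            "provider_type": np.repeat(inst["provider_type"].to_numpy(), counts),
        }
    )

    if n > 0:
        # service types
        p_inp, p_ph = config.inpatient_share, config.public_health_share
        p_out = 1.0 - p_inp - p_ph
        probs = [
            p_out * (1.0 - config.preventive_visit_share),
            p_out * config.preventive_visit_share,
            p_inp,
            p_ph,
        ]
        stype = rng.choice(si.SERVICE_TYPES, size=n, p=probs)
        enc["service_type"] = stype

        enc["age_years"] = rng.choice(101, size=n, p=np.asarray(config.age_distribution, float))
        enc["sex"] = rng.choice(["F", "M"], size=n)

        # ICD-10 codes: curative case-mix from the configured weights,
        # preventive contacts from the health-status-factors range
        pools = _build_code_pools(rules)
        codes = np.empty(n, dtype=object)
        curative = ~np.isin(stype, ["outpatient_preventive", "public_health"])
        child = enc["age_years"].to_numpy() <= rules.children_age_max

        def sample_codes(mask: np.ndarray, weights: dict[str, float]) -> None:
            m = int(mask.sum())
            if m == 0:
                return
            labels = list(weights)
            w = np.array([weights[c] for c in labels], dtype=float)
            chap = rng.choice(len(labels), size=m, p=w / w.sum())
            out = np.empty(m, dtype=object)
            for ci, label in enumerate(labels):
                sel = chap == ci
                if sel.any():
                    pool = pools[label]
                    out[sel] = np.asarray(pool, dtype=object)[
                        rng.integers(0, len(pool), size=int(sel.sum()))
                    ]
            codes[mask] = out

        if config.disease_distribution_children is not None:
            sample_codes(curative & child, config.disease_distribution_children)
            sample_codes(curative & ~child, config.disease_distribution)
        else:
            sample_codes(curative, config.disease_distribution)
        prev_pool = pools[_PREVENTIVE_CHAPTER]
        n_prev = int((~curative).sum())
        codes[~curative] = np.asarray(prev_pool, dtype=object)[
            rng.integers(0, len(prev_pool), size=n_prev)
        ]
        enc["icd10_code"] = codes

        # costs, bed days, payer split
        mu = np.array([config.cost_distributions[s][0] for s in si.SERVICE_TYPES])
        sg = np.array([config.cost_distributions[s][1] for s in si.SERVICE_TYPES])
        sidx = pd.Categorical(stype, categories=si.SERVICE_TYPES).codes
        cost = np.round(rng.lognormal(mu[sidx], sg[sidx]), 2)
        enc["total_cost"] = cost
        bed = np.zeros(n, dtype=int)
        inp = stype == "inpatient"
        bed[inp] = 1 + rng.poisson(config.mean_bed_days, size=int(inp.sum()))
        enc["bed_days"] = bed

        pw = np.array([config.payer_split_distribution.get(c, 0.0) for c in si.PAYER_CATEGORIES])
        pos = pw > 0
        split = np.zeros((n, len(si.PAYER_CATEGORIES)))
        if pos.sum() == 1:
            split[:, np.argmax(pos)] = cost
        else:
            alpha = config.payer_concentration * pw[pos]
            fr = rng.dirichlet(alpha, size=n)
            split[:, pos] = np.round(fr * cost[:, None], 2)
            # absorb rounding residue into the largest configured component
            main = int(np.flatnonzero(pos)[np.argmax(pw[pos])])
            split[:, main] = 0.0
            split[:, main] = cost - split.sum(axis=1)
        for j, cat in enumerate(si.PAYER_CATEGORIES):
            enc[cat] = split[:, j]
    else:
        defaults = {"age_years": 0, "bed_days": 0, "total_cost": 0.0,
                    "service_type": "", "sex": "", "icd10_code": ""}
        for col in si.ENCOUNTER_COLUMNS:
            if col not in enc.columns:
                enc[col] = pd.Series(dtype=type(defaults.get(col, 0.0)))

    enc = enc.reset_index(drop=True)

    # institution finance sheets from the encounter census
    fin = _finance_sheets(inst, enc, config, rng)

    # provincial aggregates = census sums per stratum
    prov = _provincial_from_census(fin, enc, config)

    enc_out = enc.loc[:, si.ENCOUNTER_COLUMNS].copy()
    return SyntheticDataset(institutions=fin, encounters=enc_out, provincial=prov, config=config)


def _finance_sheets(inst: pd.DataFrame, enc: pd.DataFrame, config: GeneratorConfig,
                    rng: np.random.Generator) -> pd.DataFrame:
    fin = inst.copy()
    if len(enc):
        by = enc.groupby("institution_id")
        agg = pd.DataFrame(
            {
                "outpatient_income": by.apply(
                    lambda g: g.loc[g["service_type"].isin(si.OUTPATIENT_SERVICES),
                                    "total_cost"].sum(), include_groups=False),
                "preventive_outpatient_income": by.apply(
                    lambda g: g.loc[g["service_type"] == "outpatient_preventive",
                                    "total_cost"].sum(), include_groups=False),
                "inpatient_income": by.apply(
                    lambda g: g.loc[g["service_type"] == "inpatient",
                                    "total_cost"].sum(), include_groups=False),
                "public_health_cost": by.apply(
                    lambda g: g.loc[g["service_type"] == "public_health",
                                    "total_cost"].sum(), include_groups=False),
            }
        )
        fin = fin.merge(agg, left_on="institution_id", right_index=True, how="left")
        for c in agg.columns:
            fin[c] = fin[c].fillna(0.0)
    else:
        for c in ["outpatient_income", "preventive_outpatient_income",
                  "inpatient_income", "public_health_cost"]:
            fin[c] = 0.0

    income = fin["outpatient_income"] + fin["inpatient_income"]
    fin["basic_subsidy"] = config.subsidy_rates["basic"] * income
    fin["outpatient_project_subsidy"] = config.subsidy_rates["project"] * fin["outpatient_income"]
    fin["inpatient_project_subsidy"] = config.subsidy_rates["project"] * fin["inpatient_income"]

    rates = config.overhead_rates
    primary = fin["provider_type"].isin(PRIMARY_TYPES)
    hospital = fin["provider_type"].isin(HOSPITAL_TYPES)
    fin["superior_institution_subsidy"] = np.where(
        primary, rates["superior_institution_subsidy"] * income, 0.0)
    fin["science_education_income"] = np.where(
        hospital, rates["science_education_income"] * income, 0.0)
    fin["other_income"] = rates["other_income"] * income
    fin["assistant_service_cost"] = rates["assistant_service_cost"] * income
    fin["medicine_cost"] = rates["medicine_cost"] * income
    fin["management_cost"] = rates["management_cost"] * income
    fin["capital_expenditure"] = rates["capital_expenditure"] * income

    # public-health contact costs are booked as a prevention project's income
    factor = rng.uniform(0.8, 1.3, size=len(fin))
    projects = []
    for i, (ph, fa) in enumerate(zip(fin["public_health_cost"], factor)):
        if ph > 0:
            projects.append([["public_health_services", float(ph), float(np.round(ph * fa, 2))]])
        else:
            projects.append([])
    fin["prevention_projects"] = projects
    fin = fin.drop(columns=["public_health_cost"])
    return fin.loc[:, ["city"] + si.FINANCE_COLUMNS]


def _provincial_from_census(fin: pd.DataFrame, enc: pd.DataFrame,
                            config: GeneratorConfig) -> si.ProvincialAggregates:
    strata = sorted(fin["provider_type"].unique())
    by = fin.groupby("provider_type")
    df = pd.DataFrame(index=pd.Index(strata, name="provider_type"))
    df["outpatient_income"] = by["outpatient_income"].sum()
    df["inpatient_income"] = by["inpatient_income"].sum()
    df["basic_subsidy"] = by["basic_subsidy"].sum()
    df["outpatient_project_subsidy"] = by["outpatient_project_subsidy"].sum()
    df["inpatient_project_subsidy"] = by["inpatient_project_subsidy"].sum()
    if len(enc):
        etype = enc if "provider_type" in enc.columns else enc.merge(
            fin[["institution_id", "provider_type"]], on="institution_id")
        grp = etype.groupby("provider_type")
        visits = grp.apply(
            lambda g: int(g["service_type"].isin(si.OUTPATIENT_SERVICES).sum()),
            include_groups=False)
        beds = grp["bed_days"].sum()
        df["outpatient_visits"] = visits.reindex(df.index).fillna(0).astype(float)
        df["inpatient_bed_days"] = beds.reindex(df.index).fillna(0).astype(float)
    else:
        df["outpatient_visits"] = 0.0
        df["inpatient_bed_days"] = 0.0
    df = df.fillna(0.0).loc[:, si.PROVINCIAL_COLUMNS]
    return si.ProvincialAggregates(df, config.exchange_rate_cny_per_usd, config.year)


# -- survey sampling --------------------------------------------------------------


def draw_survey(dataset: SyntheticDataset, plan: SamplingPlan, seed: int) -> SyntheticDataset:
    """Draw a multistage survey subset; provincial aggregates stay census-level."""
    plan.validate()
    rng = np.random.default_rng(seed)
    inst = dataset.institutions

    cities = sorted(inst["city"].unique())
    if plan.n_cities is not None:
        if plan.n_cities > len(cities):
            raise SamplingError(
                f"plan requests {plan.n_cities} cities but only {len(cities)} exist")
        cities = sorted(rng.choice(cities, size=plan.n_cities, replace=False))
    pool = inst[inst["city"].isin(cities)]

    keep_ids: list[str] = []
    for _, grp in pool.groupby("provider_type"):
        k = max(plan.min_per_stratum, int(round(plan.institution_fraction * len(grp))))
        k = min(k, len(grp))
        keep_ids.extend(sorted(rng.choice(grp["institution_id"].to_numpy(), size=k,
                                          replace=False)))
    keep = inst["institution_id"].isin(keep_ids)
    institutions = inst[keep].reset_index(drop=True)
    encounters = dataset.encounters[
        dataset.encounters["institution_id"].isin(keep_ids)
    ].reset_index(drop=True)
    return SyntheticDataset(
        institutions=institutions,
        encounters=encounters,
        provincial=dataset.provincial,
        config=dataset.config,
        sampling={"plan": dataclasses.asdict(plan), "seed": int(seed),
                  "cities": list(cities), "n_institutions": len(institutions)},
    )


# -- ground-truth tabulation -------------------------------------------------------


def tabulate_truth(dataset: SyntheticDataset, rules: ClassificationRules | None = None,
                   prevention_rule: str = "max"):
    """Exact accounts cube of the generated universe, by direct enumeration.

    Every generated yuan inside the CHE scope is assigned to a
    (provider, function, financing scheme, disease, age) cell by the
    generating rules; this is the brute-force oracle for the top-down
    engine.  Only valid on a census.
    """
    from .accounts_engine import tabulate_truth_cube  # local import: avoids cycle

    if not dataset.is_census:
        raise SamplingError("tabulate_truth requires a census dataset, not a survey subset")
    return tabulate_truth_cube(dataset, rules or default_rules(), prevention_rule)


# -- serialisation ------------------------------------------------------------------


def write_dataset(dataset: SyntheticDataset, out_dir) -> dict[str, str]:
    """Write encounters/institutions/provincial to a directory; returns paths."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "encounters": os.path.join(out_dir, "encounters.csv"),
        "institutions": os.path.join(out_dir, "institutions.csv"),
        "provincial": os.path.join(out_dir, "provincial.yaml"),
    }
    si.write_encounters(dataset.encounters, paths["encounters"])
    si.write_institution_finance(dataset.institutions, paths["institutions"])
    si.write_provincial(dataset.provincial, paths["provincial"])
    return paths
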
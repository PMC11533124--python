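"""Synthetic multi-country survey worlds with known ground truth.

The generator shares one parameterization with the hierarchical intake
model so that recovery is well-defined: the true mean intake of a fine
stratum is

    exp(intercept_asf + region + country + age + sex + education
        + urbanicity + slope * z(availability))

with region and country effects drawn from zero-mean normals at known
scales, fixed demographic contrasts, fixed per-method reporting biases
(24-hour recall is the zero reference), and a linear link to the z-scored
food-availability covariate.  Observed survey means are the true means
times the method bias times multiplicative log-normal noise of variance
sigma^2/n, inflated by a known overdispersion factor for surveys that are
not nationally representative or report coarse strata.  Coarse surveys
report population-weighted averages over the collapsed fine strata.

Everything is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .survey_io import (
    AGE_GROUPS,
    ALL,
    ASF_CATEGORIES,
    EDUCATION_LEVELS,
    METHODS,
    SEXES,
    STRATUM_FIELDS,
    SUPERREGIONS,
    URBANICITY_LEVELS,
    StratumKey,
    SurveyObservation,
    enumerate_strata,
    expand_coarse,
)

__all__ = [
    "TruthConfig",
    "SurveyDesign",
    "SyntheticTruth",
    "SyntheticWorld",
    "build_truth",
    "generate_weights",
    "standardized_availability",
    "true_stratum_mean",
    "simulate_surveys",
    "simulate_world",
]

# Default per-ASF intercepts (log g/d) anchored at plausible global child
# mean intakes for each food group.
DEFAULT_INTERCEPTS: dict[str, float] = {
    "milk": math.log(100.0),
    "cheese": math.log(6.0),
    "yogurt": math.log(18.0),
    "eggs": math.log(17.0),
    "seafood": math.log(21.0),
    "unprocessed_red_meat": math.log(40.0),
    "processed_meat": math.log(18.0),
}

DEFAULT_AGE_PROFILE: dict[str, float] = {
    "<1": 0.0,
    "1-2": 0.25,
    "3-4": 0.45,
    "5-9": 0.60,
    "10-14": 0.70,
    "15-19": 0.75,
}


@dataclass
class TruthConfig:
    """Scales and fixed effect values defining a synthetic ground truth.

    Log-scale contrasts: ``sex_effect`` is male vs female, the education
    effects are deviations from the low level, ``urbanicity_effect`` is
    urban vs rural, and method biases are deviations from 24-hour recall.
    """

    asfs: tuple[str, ...] = ("milk",)
    intercepts: Mapping[str, float] | None = None
    sd_region: float = 0.3
    sd_country: float = 0.2
    age_profile: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AGE_PROFILE)
    )
    sex_effect: float = 0.02
    education_effects: Mapping[str, float] = field(
        default_factory=lambda: {"low": 0.0, "medium": 0.10, "high": 0.30}
    )
    urbanicity_effect: float = 0.15
    method_biases: Mapping[str, float] = field(
        default_factory=lambda: {
            "24hr_recall": 0.0,
            "ffq": 0.10,
            "short_questionnaire": -0.15,
            "household_budget": 0.20,
        }
    )
    time_slope: float = 0.15
    overdispersion_factor: float = 2.0

    def __post_init__(self) -> None:
        unknown = set(self.asfs) - set(ASF_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown ASF categories: {unknown}")
        if self.sd_region < 0 or self.sd_country < 0:
            raise ValueError("random-effect scales must be non-negative")
        if self.overdispersion_factor < 1:
            raise ValueError("overdispersion_factor must be >= 1")
        if self.method_biases.get("24hr_recall", 0.0) != 0.0:
            raise ValueError("reference method bias (24hr_recall) must be 0")


@dataclass
class SurveyDesign:
    """Sampling design of the emulated survey database."""

    n_regions: int = 4
    countries_per_region: int = 5
    surveys_per_country: int = 2
    years: tuple[int, ...] = (1990, 2018)
    p_national: float = 0.88
    p_coarse: float = 0.25
    method_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "24hr_recall": 0.5,
            "ffq": 0.3,
            "short_questionnaire": 0.1,
            "household_budget": 0.1,
        }
    )
    n_log_mean: float = math.log(100.0)  # per-stratum sample-size distribution
    n_log_sd: float = 0.6
    n_min: int = 10
    sigma_within: float = 0.5  # within-survey log-scale SD (individual CV)

    def __post_init__(self) -> None:
        if not (1 <= self.n_regions):
            raise ValueError("need at least one region")
        if self.countries_per_region < 1 or self.surveys_per_country < 1:
            raise ValueError("need at least one country and one survey")
        if len(set(self.years)) < 2:
            raise ValueError("need >=2 distinct years for covariate trends")
        for p in (self.p_national, self.p_coarse):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if set(self.method_mix) - set(METHODS):
            raise ValueError("method_mix contains unknown methods")
        total = sum(self.method_mix.values())
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            raise ValueError("method_mix must sum to 1")
        if self.sigma_within < 0:
            raise ValueError("sigma_within must be non-negative")


@dataclass
class SyntheticTruth:
    """Realized ground-truth parameter set plus its covariate series."""

    asfs: tuple[str, ...]
    intercepts: dict[str, float]
    regions: tuple[str, ...]
    region_effects: dict[str, float]
    countries: tuple[str, ...]
    country_region: dict[str, str]
    country_effects: dict[str, float]
    age_profile: dict[str, float]
    sex_effect: float
    education_effects: dict[str, float]
    urbanicity_effect: float
    method_biases: dict[str, float]
    time_slope: float
    sd_region: float
    sd_country: float
    overdispersion_factor: float
    covariates: pd.DataFrame
    cov_stats: dict[str, tuple[float, float]]
    seed: int

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "asfs", "intercepts", "regions", "region_effects", "countries",
                "country_region", "country_effects", "age_profile", "sex_effect",
                "education_effects", "urbanicity_effect", "method_biases",
                "time_slope", "sd_region", "sd_country",
                "overdispersion_factor", "seed",
            )
        }
        d["asfs"] = list(self.asfs)
        d["regions"] = list(self.regions)
        d["countries"] = list(self.countries)
        return d


@dataclass
class SyntheticWorld:
    """A complete simulated study: truth, surveys, weights, covariates."""

    truth: SyntheticTruth
    surveys: list[SurveyObservation]
    weights: pd.DataFrame
    covariates: pd.DataFrame


def _country_codes(n: int) -> list[str]:
    # "X" prefix: user-assigned ISO3 range, reserved here for synthetic worlds
    return [f"X{chr(65 + i // 26)}{chr(65 + i % 26)}" for i in range(n)]


def build_truth(
    config: TruthConfig, design: SurveyDesign, seed: int
) -> SyntheticTruth:
    """Draw a ground truth: nested effects plus availability covariates."""
    ss = np.random.SeedSequence(seed)
    rng_eff, rng_cov = (np.random.default_rng(s) for s in ss.spawn(2))

    if design.n_regions <= len(SUPERREGIONS):
        regions = tuple(SUPERREGIONS[: design.n_regions])
    else:
        extra = tuple(
            f"synthetic region {i}" for i in range(design.n_regions - len(SUPERREGIONS))
        )
        regions = tuple(SUPERREGIONS) + extra
    countries = _country_codes(design.n_regions * design.countries_per_region)
    country_region = {
        c: regions[i // design.countries_per_region] for i, c in enumerate(countries)
    }
    region_effects = dict(
        zip(regions, config.sd_region * rng_eff.standard_normal(len(regions)))
    )
    country_effects = dict(
        zip(countries, config.sd_country * rng_eff.standard_normal(len(countries)))
    )
    intercepts = dict(config.intercepts or {})
    for asf in config.asfs:
        intercepts.setdefault(asf, DEFAULT_INTERCEPTS[asf])

    years = sorted(set(design.years))
    rows = []
    for country in countries:
        for asf in config.asfs:
            base = math.exp(intercepts[asf]) * rng_cov.uniform(0.8, 2.5)
            trend = rng_cov.normal(0.012, 0.006) * base
            for year in years:
                noise = rng_cov.normal(0.0, 0.03 * base)
                avail = max(base + trend * (year - years[0]) + noise, 0.01 * base)
                rows.append(
                    {"country": country, "asf": asf, "year": year,
                     "availability": avail}
                )
    covariates = pd.DataFrame(rows)
    cov_stats = {}
    for asf in config.asfs:
        vals = covariates.loc[covariates["asf"] == asf, "availability"].to_numpy()
        cov_stats[asf] = (float(vals.mean()), float(max(vals.std(), 1e-12)))

    return SyntheticTruth(
        asfs=tuple(config.asfs),
        intercepts=intercepts,
        regions=regions,
        region_effects=region_effects,
        countries=tuple(countries),
        country_region=country_region,
        country_effects=country_effects,
        age_profile=dict(config.age_profile),
        sex_effect=config.sex_effect,
        education_effects=dict(config.education_effects),
        urbanicity_effect=config.urbanicity_effect,
        method_biases=dict(config.method_biases),
        time_slope=config.time_slope,
        sd_region=config.sd_region,
        sd_country=config.sd_country,
        overdispersion_factor=config.overdispersion_factor,
        covariates=covariates,
        cov_stats=cov_stats,
        seed=seed,
    )


def standardized_availability(
    truth: SyntheticTruth, country: str, asf: str, year: int
) -> float:
    """z-scored (within ASF) availability covariate for a country-year."""
    sel = truth.covariates[
        (truth.covariates["country"] == country)
        & (truth.covariates["asf"] == asf)
        & (truth.covariates["year"] == year)
    ]
    if sel.empty:
        raise KeyError(f"no availability covariate for ({country}, {asf}, {year})")
    mean, sd = truth.cov_stats[asf]
    return (float(sel["availability"].iloc[0]) - mean) / sd


def true_stratum_mean(
    truth: SyntheticTruth, country: str, year: int, asf: str, stratum: StratumKey
) -> float:
    """Noise-free mean intake (g/d) of one fine stratum under the truth."""
    if country not in truth.country_region:
        raise KeyError(f"unknown country {country!r}")
    if not stratum.is_fine:
        raise KeyError(f"stratum {stratum.to_string()!r} is not a fine stratum")
    z = standardized_availability(truth, country, asf, year)
    eta = (
        truth.intercepts[asf]
        + truth.region_effects[truth.country_region[country]]
        + truth.country_effects[country]
        + truth.age_profile[stratum.age_group]
        + (truth.sex_effect if stratum.sex == "male" else 0.0)
        + truth.education_effects[stratum.education]
        + (truth.urbanicity_effect if stratum.urbanicity == "urban" else 0.0)
        + truth.time_slope * z
    )
    return math.exp(eta)


def generate_weights(
    truth: SyntheticTruth, years: Sequence[int], seed: int
) -> pd.DataFrame:
    """Per-country-year person counts for all 72 strata.

    Emulates demographic structure: age shares roughly proportional to band
    widths, near-even sexes, a country-specific education mix and urban
    share, with mild jitter, all reproducible from the seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    base_age = np.array([1.0, 2.0, 2.0, 5.0, 5.0, 5.0])
    rows = []
    for country in truth.countries:
        total = rng.lognormal(math.log(5e6), 0.5)
        age_shares = base_age * rng.lognormal(0.0, 0.1, size=6)
        age_shares /= age_shares.sum()
        male_share = rng.normal(0.512, 0.004)
        edu_shares = rng.dirichlet([3.0, 4.5, 2.5])
        urban0 = rng.beta(5.5, 4.5)
        for year in sorted(set(years)):
            urban = float(np.clip(urban0 + 0.003 * (year - min(years)), 0.05, 0.95))
            for ia, age in enumerate(AGE_GROUPS):
                for sex in SEXES:
                    psex = male_share if sex == "male" else 1.0 - male_share
                    for ie, edu in enumerate(EDUCATION_LEVELS):
                        for urb in URBANICITY_LEVELS:
                            purb = urban if urb == "urban" else 1.0 - urban
                            persons = total * age_shares[ia] * psex * edu_shares[ie] * purb
                            rows.append(
                                {
                                    "country": country,
                                    "year": year,
                                    "age_group": age,
                                    "sex": sex,
                                    "education": edu,
                                    "urbanicity": urb,
                                    "persons": max(int(round(persons)), 1),
                                }
                            )
    return pd.DataFrame(rows)


def _coarse_pattern(rng: np.random.Generator) -> tuple[str, ...]:
    """Factors to collapse for a coarse survey: each w.p. 1/2, at least one."""
    while True:
        mask = rng.random(4) < 0.5
        if mask.any():
            return tuple(f for f, m in zip(STRATUM_FIELDS, mask) if m)


def _stratum_weights(
    weights: pd.DataFrame | None, country: str, year: int
) -> dict[StratumKey, float]:
    if weights is None:
        return {}
    sel = weights[(weights["country"] == country) & (weights["year"] == year)]
    if sel.empty:
        sel = weights[weights["country"] == country]
        if sel.empty:
            return {}
        first_year = sel["year"].min()
        sel = sel[sel["year"] == first_year]
    return {
        StratumKey(r.age_group, r.sex, r.education, r.urbanicity): float(r.persons)
        for r in sel.itertuples()
    }


def simulate_surveys(
    truth: SyntheticTruth,
    design: SurveyDesign,
    weights: pd.DataFrame | None = None,
    seed: int = 0,
) -> list[SurveyObservation]:
    """Sample a survey collection from the truth under the given design.

    Coarse surveys report population-weighted averages of the collapsed
    fine-stratum true means (equal weights when no weight table is given);
    observation noise is multiplicative log-normal with variance
    sigma_within^2/n, inflated by the truth's overdispersion factor for
    non-representative or coarse surveys.  Reported SDs encode the
    within-survey CV so the model's delta-method variance recovers the
    noise scale.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    methods = list(design.method_mix)
    method_p = np.array([design.method_mix[m] for m in methods])
    out: list[SurveyObservation] = []
    for country in truth.countries:
        region = truth.country_region[country]
        for s in range(design.surveys_per_country):
            year = int(rng.choice(list(design.years)))
            method = str(rng.choice(methods, p=method_p))
            national = bool(rng.random() < design.p_national)
            coarse = bool(rng.random() < design.p_coarse)
            collapsed = _coarse_pattern(rng) if coarse else ()
            axes = [
                (ALL,) if f in collapsed else
                {"age_group": AGE_GROUPS, "sex": SEXES,
                 "education": EDUCATION_LEVELS, "urbanicity": URBANICITY_LEVELS}[f]
                for f in STRATUM_FIELDS
            ]
            cells = [
                StratumKey(a, x, e, u)
                for a in axes[0] for x in axes[1] for e in axes[2] for u in axes[3]
            ]
            wlookup = _stratum_weights(weights, country, year)
            flagged = (not national) or coarse
            inflation = truth.overdispersion_factor if flagged else 1.0
            survey_id = f"{country}-{s:02d}"
            for asf in truth.asfs:
                bias = math.exp(truth.method_biases[method])
                for cell in cells:
                    fine = expand_coarse(cell)
                    w = np.array([wlookup.get(f, 1.0) for f in fine])
                    mu = np.array(
                        [true_stratum_mean(truth, country, year, asf, f) for f in fine]
                    )
                    mu_cell = float((w * mu).sum() / w.sum())
                    n = max(
                        design.n_min,
                        int(round(rng.lognormal(design.n_log_mean, design.n_log_sd))),
                    )
                    noise_sd = design.sigma_within * math.sqrt(inflation / n)
                    observed = mu_cell * bias * math.exp(rng.normal(0.0, noise_sd))
                    out.append(
                        SurveyObservation(
                            survey_id=survey_id,
                            country=country,
                            region=region,
                            year=year,
                            asf=asf,
                            stratum=cell,
                            mean_intake=observed,
                            sd_intake=observed * design.sigma_within,
                            n=n,
                            method=method,
                            nationally_representative=national,
                            individual_level=method != "household_budget",
                            mean_energy=None,
                            energy_adjusted=True,
                        )
                    )
    return out


def simulate_world(
    config: TruthConfig, design: SurveyDesign, seed: int
) -> SyntheticWorld:
    """Build truth, weights and surveys from one master seed."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(3)
    truth_seed, weight_seed, survey_seed = (
        int(c.generate_state(1)[0] % (2**31)) for c in children
    )
    truth = build_truth(config, design, truth_seed)
    weights = generate_weights(truth, design.years, weight_seed)
    surveys = simulate_surveys(truth, design, weights=weights, seed=survey_seed)
    return SyntheticWorld(
        truth=truth, surveys=surveys, weights=weights, covariates=truth.covariates
    )
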
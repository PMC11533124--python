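"""Data model and tabular IO for stratified intake surveys.

The atomic estimation unit is the joint demographic stratum: age group x
sex x parental education x urbanicity, giving 6 x 2 x 3 x 2 = 72 cells per
country-year.  Surveys report harmonized per-stratum summaries (mean, SD,
sample size) of animal-source food (ASF) intake in g/d; coarse surveys
collapse one or more stratification factors, marked ``"all"``.

All tables are delimited text (comma or tab, chosen by file extension),
UTF-8, with canonical column names and categorical level spellings fixed
by the shipped ``data/schema.yaml``.  Inputs in other layouts declare a
mapping onto that schema at read time.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AGE_GROUPS",
    "SEXES",
    "EDUCATION_LEVELS",
    "URBANICITY_LEVELS",
    "ALL",
    "ASF_CATEGORIES",
    "METHODS",
    "SUPERREGIONS",
    "StratumKey",
    "SurveyObservation",
    "ValidationReport",
    "SurveyIOError",
    "enumerate_strata",
    "expand_coarse",
    "load_region_lookup",
    "read_surveys",
    "write_surveys",
    "surveys_to_frame",
    "frame_to_surveys",
    "validate_collection",
    "read_weights",
    "write_weights",
    "validate_weights",
    "read_covariates",
    "write_covariates",
    "validate_covariates",
]

AGE_GROUPS = ("<1", "1-2", "3-4", "5-9", "10-14", "15-19")
SEXES = ("female", "male")
EDUCATION_LEVELS = ("low", "medium", "high")
URBANICITY_LEVELS = ("urban", "rural")
ALL = "all"

ASF_CATEGORIES = (
    "milk",
    "cheese",
    "yogurt",
    "eggs",
    "seafood",
    "unprocessed_red_meat",
    "processed_meat",
)

#: Dietary assessment methods; the first entry is the model's reference.
METHODS = ("24hr_recall", "ffq", "short_questionnaire", "household_budget")

SUPERREGIONS = (
    "South Asia",
    "Southeast and East Asia",
    "Central/Eastern Europe and Central Asia",
    "Middle East and Northern Africa",
    "Latin America and the Caribbean",
    "sub-Saharan Africa",
    "High-income countries",
)

STRATUM_FIELDS = ("age_group", "sex", "education", "urbanicity")

_FACTOR_LEVELS = {
    "age_group": AGE_GROUPS,
    "sex": SEXES,
    "education": EDUCATION_LEVELS,
    "urbanicity": URBANICITY_LEVELS,
}


class SurveyIOError(ValueError):
    """Raised on malformed or inconsistent tabular inputs."""


@dataclass(frozen=True, order=True)
class StratumKey:
    """One joint demographic cell, or a coarse cell with factors ``"all"``."""

    age_group: str
    sex: str
    education: str
    urbanicity: str

    def __post_init__(self) -> None:
        for fname in STRATUM_FIELDS:
            value = getattr(self, fname)
            if value != ALL and value not in _FACTOR_LEVELS[fname]:
                raise ValueError(
                    f"invalid {fname} level {value!r}; expected one of "
                    f"{_FACTOR_LEVELS[fname]} or {ALL!r}"
                )

    @property
    def is_fine(self) -> bool:
        return all(getattr(self, f) != ALL for f in STRATUM_FIELDS)

    @property
    def collapsed_factors(self) -> tuple[str, ...]:
        return tuple(f for f in STRATUM_FIELDS if getattr(self, f) == ALL)

    def to_string(self) -> str:
        return "|".join(getattr(self, f) for f in STRATUM_FIELDS)

    @classmethod
    def from_string(cls, text: str) -> "StratumKey":
        parts = text.split("|")
        if len(parts) != 4:
            raise ValueError(f"malformed stratum string {text!r}")
        return cls(*parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


def enumerate_strata() -> tuple[StratumKey, ...]:
    """The canonical ordered enumeration of the 72 fine strata."""
    return tuple(
        StratumKey(a, s, e, u)
        for a, s, e, u in itertools.product(
            AGE_GROUPS, SEXES, EDUCATION_LEVELS, URBANICITY_LEVELS
        )
    )


def expand_coarse(key: StratumKey) -> tuple[StratumKey, ...]:
    """All fine strata covered by ``key`` (itself, if already fine)."""
    axes = [
        _FACTOR_LEVELS[f] if getattr(key, f) == ALL else (getattr(key, f),)
        for f in STRATUM_FIELDS
    ]
    return tuple(StratumKey(*combo) for combo in itertools.product(*axes))


@dataclass
class SurveyObservation:
    """One harmonized survey-by-stratum intake summary for one ASF."""

    survey_id: str
    country: str
    region: str
    year: int
    asf: str
    stratum: StratumKey
    mean_intake: float  # g/d
    sd_intake: float  # g/d
    n: int
    method: str
    nationally_representative: bool
    individual_level: bool = True
    mean_energy: float | None = None  # kcal/d; required for energy adjustment
    energy_adjusted: bool = False

    def __post_init__(self) -> None:
        if self.asf not in ASF_CATEGORIES:
            raise ValueError(f"unknown ASF category {self.asf!r}")
        if self.method not in METHODS:
            raise ValueError(f"unknown assessment method {self.method!r}")
        if not np.isfinite(self.mean_intake) or self.mean_intake < 0:
            raise ValueError("mean_intake must be finite and non-negative")
        if self.sd_intake < 0:
            raise ValueError("sd_intake must be non-negative")
        if self.n < 1:
            raise ValueError("sample size n must be a positive integer")
        if self.mean_energy is not None and not self.mean_energy > 0:
            raise ValueError("mean_energy must be positive when present")


# ---------------------------------------------------------------------------
# shipped configuration assets
# ---------------------------------------------------------------------------


def _load_asset(name: str):
    with resources.files("asfintake.data").joinpath(name).open("r") as fh:
        return yaml.safe_load(fh)


def load_region_lookup(path: str | Path | None = None) -> dict[str, str]:
    """Country (ISO3) -> superregion mapping.

    The shipped lookup is editable configuration; pass ``path`` to use a
    custom YAML file with the same layout.
    """
    data = yaml.safe_load(Path(path).read_text()) if path else _load_asset("regions.yaml")
    lookup = dict(data["countries"])
    bad = {c: r for c, r in lookup.items() if r not in SUPERREGIONS}
    if bad:
        raise SurveyIOError(f"regions not among the 7 superregions: {bad}")
    return lookup


def load_schema() -> dict:
    return _load_asset("schema.yaml")


# ---------------------------------------------------------------------------
# survey tables
# ---------------------------------------------------------------------------

_BOOL_MAP = {
    "true": True, "false": False, "1": True, "0": False,
    "yes": True, "no": False, "t": True, "f": False,
}


def _parse_bool(value, column: str) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    key = str(value).strip().lower()
    if key not in _BOOL_MAP:
        raise SurveyIOError(f"cannot parse boolean {value!r} in column {column!r}")
    return _BOOL_MAP[key]


def _delimiter(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def surveys_to_frame(obs: Iterable[SurveyObservation]) -> pd.DataFrame:
    rows = []
    for o in obs:
        rows.append(
            {
                "survey_id": o.survey_id,
                "country": o.country,
                "region": o.region,
                "year": o.year,
                "asf": o.asf,
                "age_group": o.stratum.age_group,
                "sex": o.stratum.sex,
                "education": o.stratum.education,
                "urbanicity": o.stratum.urbanicity,
                "mean_intake": o.mean_intake,
                "sd_intake": o.sd_intake,
                "n": o.n,
                "method": o.method,
                "nationally_representative": o.nationally_representative,
                "individual_level": o.individual_level,
                "mean_energy": o.mean_energy,
                "energy_adjusted": o.energy_adjusted,
            }
        )
    return pd.DataFrame(rows)


def frame_to_surveys(
    df: pd.DataFrame, region_lookup: Mapping[str, str] | None = None
) -> list[SurveyObservation]:
    """Build observations from a canonical-schema frame, validating levels.

    ``region_lookup`` defaults to the shipped superregion table; a ``region``
    column, when present, must agree with it.
    """
    required = [
        "survey_id", "country", "year", "asf", "age_group", "sex",
        "education", "urbanicity", "mean_intake", "sd_intake", "n",
        "method", "nationally_representative",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SurveyIOError(f"missing required columns: {missing}")

    lookup = dict(region_lookup) if region_lookup is not None else load_region_lookup()
    unknown = sorted(set(df["country"]) - set(lookup))
    if unknown:
        rows = df.index[df["country"].isin(unknown)].tolist()
        raise SurveyIOError(
            f"unknown country codes {unknown} (rows {rows}); extend the "
            "region lookup to ingest them"
        )
    neg = df.index[pd.to_numeric(df["mean_intake"]) < 0].tolist()
    if neg:
        raise SurveyIOError(f"negative mean_intake in rows {neg}")

    out: list[SurveyObservation] = []
    for idx, row in df.iterrows():
        region = lookup[row["country"]]
        if "region" in df.columns and not _is_missing(row.get("region")):
            if row["region"] != region:
                raise SurveyIOError(
                    f"row {idx}: region {row['region']!r} inconsistent with "
                    f"lookup ({region!r}) for {row['country']}"
                )
        energy = row.get("mean_energy")
        energy = None if _is_missing(energy) else float(energy)
        indiv = row.get("individual_level")
        indiv = True if _is_missing(indiv) else _parse_bool(indiv, "individual_level")
        adjusted = row.get("energy_adjusted")
        adjusted = False if _is_missing(adjusted) else _parse_bool(adjusted, "energy_adjusted")
        try:
            out.append(
                SurveyObservation(
                    survey_id=str(row["survey_id"]),
                    country=str(row["country"]),
                    region=region,
                    year=int(row["year"]),
                    asf=str(row["asf"]),
                    stratum=StratumKey(
                        str(row["age_group"]), str(row["sex"]),
                        str(row["education"]), str(row["urbanicity"]),
                    ),
                    mean_intake=float(row["mean_intake"]),
                    sd_intake=float(row["sd_intake"]),
                    n=int(row["n"]),
                    method=str(row["method"]),
                    nationally_representative=_parse_bool(
                        row["nationally_representative"], "nationally_representative"
                    ),
                    individual_level=indiv,
                    mean_energy=energy,
                    energy_adjusted=adjusted,
                )
            )
        except ValueError as err:
            raise SurveyIOError(f"row {idx}: {err}") from err
    return out


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and np.isnan(value):
        return True
    return isinstance(value, str) and value.strip() == ""


def read_surveys(
    path: str | Path,
    schema: Mapping | None = None,
    region_lookup: Mapping[str, str] | None = None,
) -> list[SurveyObservation]:
    """Read a delimited survey table into canonical observations.

    Parameters
    ----------
    path
        CSV (comma) or TSV/TAB/TXT (tab) file with a header row.
    schema
        Optional mapping with keys ``columns`` (raw -> canonical column
        names) and ``levels`` (per-field raw -> canonical level spellings),
        applied before validation.  Coarse strata (``"all"``) are preserved,
        never expanded.
    region_lookup
        Country -> superregion mapping; defaults to the shipped asset.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_delimiter(path))
    if schema:
        if "columns" in schema:
            df = df.rename(columns=dict(schema["columns"]))
        for fname, mapping in (schema.get("levels") or {}).items():
            if fname in df.columns:
                df[fname] = df[fname].map(lambda v: mapping.get(v, v))
    return frame_to_surveys(df, region_lookup=region_lookup)


def write_surveys(obs: Iterable[SurveyObservation], path: str | Path) -> None:
    path = Path(path)
    surveys_to_frame(obs).to_csv(path, sep=_delimiter(path), index=False)


@dataclass
class ValidationReport:
    """Per-rule violation counts over a survey collection (non-mutating)."""

    n_observations: int
    duplicate_rows: list[tuple] = field(default_factory=list)
    dispersion_rows: list[int] = field(default_factory=list)
    year_rows: list[int] = field(default_factory=list)

    @property
    def n_duplicates(self) -> int:
        return len(self.duplicate_rows)

    @property
    def n_dispersion(self) -> int:
        return len(self.dispersion_rows)

    @property
    def n_year(self) -> int:
        return len(self.year_rows)

    @property
    def total_violations(self) -> int:
        return self.n_duplicates + self.n_dispersion + self.n_year

    def to_text(self) -> str:
        return (
            f"{self.n_observations} observations checked\n"
            f"duplicate (survey_id, stratum, asf) rows: {self.n_duplicates}\n"
            f"SD/mean dispersion flags: {self.n_dispersion}\n"
            f"year out of range: {self.n_year}\n"
        )


def validate_collection(
    obs: Sequence[SurveyObservation],
    max_sd_mean_ratio: float = 5.0,
    year_range: tuple[int, int] = (1980, 2030),
) -> ValidationReport:
    """Screen a collection for extraction errors; the collection is unchanged."""
    if len(obs) == 0:
        raise SurveyIOError("empty collection")
    seen: dict[tuple, int] = {}
    report = ValidationReport(n_observations=len(obs))
    for i, o in enumerate(obs):
        key = (o.survey_id, o.stratum.to_string(), o.asf)
        if key in seen:
            report.duplicate_rows.append(key)
        else:
            seen[key] = i
        if o.mean_intake > 0 and o.sd_intake / o.mean_intake > max_sd_mean_ratio:
            report.dispersion_rows.append(i)
        if not (year_range[0] <= o.year <= year_range[1]):
            report.year_rows.append(i)
    return report


# ---------------------------------------------------------------------------
# population weights
# ---------------------------------------------------------------------------

WEIGHT_COLUMNS = ["country", "year"] + list(STRATUM_FIELDS) + ["persons"]


def validate_weights(weights: pd.DataFrame) -> None:
    missing = [c for c in WEIGHT_COLUMNS if c not in weights.columns]
    if missing:
        raise SurveyIOError(f"weights table missing columns: {missing}")
    if (weights["persons"] < 0).any():
        raise SurveyIOError("negative person counts in weights")
    counts = weights.groupby(["country", "year"]).size()
    bad = counts[counts != 72]
    if len(bad):
        raise SurveyIOError(
            f"country-years without all 72 strata: {bad.index.tolist()[:5]}"
        )


def read_weights(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter(path))
    validate_weights(df)
    return df


def write_weights(weights: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    weights.to_csv(path, sep=_delimiter(path), index=False)


# ---------------------------------------------------------------------------
# availability covariates
# ---------------------------------------------------------------------------

COVARIATE_COLUMNS = ["country", "asf", "year", "availability"]


def validate_covariates(cov: pd.DataFrame) -> None:
    missing = [c for c in COVARIATE_COLUMNS if c not in cov.columns]
    if missing:
        raise SurveyIOError(f"covariate table missing columns: {missing}")
    if (cov["availability"] < 0).any():
        raise SurveyIOError("negative availability values")
    nyears = cov.groupby(["country", "asf"])["year"].nunique()
    bad = nyears[nyears < 2]
    if len(bad):
        raise SurveyIOError(
            "covariate series need >=2 distinct years to inform a trend; "
            f"offending country-ASF pairs: {bad.index.tolist()[:5]}"
        )


def read_covariates(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter(path))
    validate_covariates(df)
    return df


def write_covariates(cov: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    cov.to_csv(path, sep=_delimiter(path), index=False)
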
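"""Population-weighted aggregation of posterior draws.

Every reported quantity is a functional of the stratum-level posterior
draws: rollups, subgroup contrasts and period differences are computed
draw-wise (aggregate each posterior draw, then summarize the aggregate's
draw vector), which propagates the full uncertainty and is *not* the same
as aggregating the stratum summaries.  Period differences standardize to
a single year's population weights so demographic change does not
masquerade as intake change.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .harmonize import PORTION_SIZES_G, to_servings
from .model import PosteriorDraws, summarize
from .survey_io import STRATUM_FIELDS

__all__ = [
    "AggregationQuery",
    "AggregateResult",
    "AggregationError",
    "weighted_rollup",
    "subgroup_difference",
    "period_difference",
    "fold_difference",
    "spearman_matrix",
    "SpearmanResult",
]

_FACTOR_LEVELS_DOC = tuple(STRATUM_FIELDS)
UNITS = ("g/d", "servings/day", "servings/week")


class AggregationError(ValueError):
    pass


@dataclass
class AggregationQuery:
    """What to aggregate: level, optional subgroup filter, years, ASFs, unit."""

    level: str = "global"  # {global, region, country}
    subgroup: Mapping[str, str] | None = None  # e.g. {"education": "high"}
    years: Sequence[int] | None = None
    asf: Sequence[str] | str | None = None
    unit: str = "g/d"

    def __post_init__(self) -> None:
        if self.level not in ("global", "region", "country"):
            raise AggregationError(f"unknown level {self.level!r}")
        if self.unit not in UNITS:
            raise AggregationError(f"unknown unit {self.unit!r}")
        if self.subgroup:
            for factor in self.subgroup:
                if factor not in STRATUM_FIELDS:
                    raise AggregationError(f"unknown stratum factor {factor!r}")


@dataclass
class AggregateResult:
    """Group key table plus per-draw aggregate values."""

    keys: pd.DataFrame
    values: np.ndarray  # (n_groups, n_draws)
    unit: str

    def summary(self) -> pd.DataFrame:
        lo, med, hi = np.percentile(self.values, [2.5, 50.0, 97.5], axis=1)
        out = self.keys.copy()
        out["median"] = med
        out["lo95"] = lo
        out["hi95"] = hi
        out["unit"] = self.unit
        return out


def _unit_factor(unit: str, asf: str) -> float:
    if unit == "g/d":
        return 1.0
    per = "day" if unit == "servings/day" else "week"
    return to_servings(1.0, asf, per)


def _group_columns(level: str) -> list[str]:
    if level == "global":
        return ["year", "asf"]
    if level == "region":
        return ["region", "year", "asf"]
    return ["country", "region", "year", "asf"]


def weighted_rollup(
    draws: PosteriorDraws,
    weights: pd.DataFrame,
    query: AggregationQuery,
) -> AggregateResult:
    """Draw-wise population-weighted average of stratum draws.

    For each retained draw d and group g, the aggregate is
    sum_s(w_s * x_sd) / sum_s(w_s) over the in-scope strata s, with w_s
    the person counts from the weight table.  Unit conversion to servings
    happens after aggregation (the conversion is linear, so the order does
    not affect the value; converting once avoids compounding rounding).
    """
    sub = draws.sel(
        year=list(query.years) if query.years is not None else None,
        asf=[query.asf] if isinstance(query.asf, str) else query.asf,
        **(query.subgroup or {}),
    )
    if len(sub) == 0:
        raise AggregationError("query selects no strata")
    merged = sub.keys.merge(
        weights,
        on=["country", "year"] + list(STRATUM_FIELDS),
        how="left",
        validate="many_to_one",
    )
    if merged["persons"].isna().any():
        bad = merged[merged["persons"].isna()].head()
        raise AggregationError(
            f"weights do not cover every stratum in scope, e.g.:\n{bad}"
        )
    w = merged["persons"].to_numpy(dtype=float)

    group_cols = _group_columns(query.level)
    key_rows, value_rows = [], []
    for gkey, gidx in merged.groupby(group_cols, sort=True).groups.items():
        idx = np.asarray(gidx)
        gw = w[idx]
        if gw.sum() <= 0:
            raise AggregationError(f"zero total weight in group {gkey}")
        agg = (gw[:, None] * sub.values[idx]).sum(axis=0) / gw.sum()
        gdict = dict(zip(group_cols, gkey if isinstance(gkey, tuple) else (gkey,)))
        agg = agg * _unit_factor(query.unit, gdict["asf"])
        key_rows.append(gdict)
        value_rows.append(agg)
    return AggregateResult(
        keys=pd.DataFrame(key_rows), values=np.vstack(value_rows), unit=query.unit
    )


def _align(
    a: AggregateResult, b: AggregateResult, drop: Sequence[str] = ()
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    cols = [c for c in a.keys.columns if c not in drop]
    ka = a.keys[cols].reset_index(drop=True)
    kb = b.keys[cols].reset_index(drop=True)
    merged = ka.reset_index().merge(
        kb.reset_index(), on=cols, suffixes=("_a", "_b"), validate="one_to_one"
    )
    if len(merged) != len(ka) or len(merged) != len(kb):
        raise AggregationError("group keys do not align between the two rollups")
    return (
        merged[cols],
        a.values[merged["index_a"].to_numpy()],
        b.values[merged["index_b"].to_numpy()],
    )


def subgroup_difference(
    draws: PosteriorDraws,
    weights: pd.DataFrame,
    factor: str,
    level_hi: str,
    level_lo: str,
    query: AggregationQuery,
) -> AggregateResult:
    """Per-draw difference of two subgroup rollups (level_hi - level_lo).

    Each level is aggregated with its own population weights over the
    remaining factors; a positive value means the high level consumes more.
    """
    if level_hi == level_lo:
        raise AggregationError("subgroup levels must differ")
    if factor not in STRATUM_FIELDS:
        raise AggregationError(f"unknown stratum factor {factor!r}")
    base = dict(query.subgroup or {})
    hi = weighted_rollup(
        draws, weights, replace(query, subgroup={**base, factor: level_hi})
    )
    lo = weighted_rollup(
        draws, weights, replace(query, subgroup={**base, factor: level_lo})
    )
    keys, va, vb = _align(hi, lo)
    keys = keys.copy()
    keys["contrast"] = f"{factor}:{level_hi}-{level_lo}"
    return AggregateResult(keys=keys, values=va - vb, unit=query.unit)


def period_difference(
    draws: PosteriorDraws,
    weights: pd.DataFrame,
    query: AggregationQuery,
    year_ref: int = 1990,
    year_cmp: int = 2018,
    weight_year: int | None = None,
) -> AggregateResult:
    """Draw-wise intake change (year_cmp - year_ref), demographically
    standardized: both years are aggregated with the ``weight_year``
    population weights (default: the comparison year)."""
    weight_year = year_cmp if weight_year is None else weight_year
    wsel = weights[weights["year"] == weight_year]
    if wsel.empty:
        raise AggregationError(
            f"weights table has no rows for standardization year {weight_year}; "
            "pass weight_year explicitly to override"
        )

    def rollup_year(year: int) -> AggregateResult:
        wyear = wsel.copy()
        wyear["year"] = year
        return weighted_rollup(draws, wyear, replace(query, years=[year]))

    ref = rollup_year(year_ref)
    cmp_ = rollup_year(year_cmp)
    keys, vc, vr = _align(cmp_, ref, drop=("year",))
    keys = keys.copy()
    keys["period"] = f"{year_cmp}-{year_ref}"
    return AggregateResult(keys=keys, values=vc - vr, unit=query.unit)


def fold_difference(values: Sequence[float] | Mapping[str, float]) -> float:
    """Exact max/min ratio across group means (e.g. regional extremes)."""
    vals = np.asarray(
        list(values.values()) if isinstance(values, Mapping) else list(values),
        dtype=float,
    )
    if len(vals) == 0:
        raise AggregationError("no values given")
    if (vals <= 0).any():
        raise AggregationError("fold difference requires strictly positive values")
    return float(vals.max() / vals.min())


@dataclass
class SpearmanResult:
    matrix: pd.DataFrame
    undefined: list[tuple[str, str]] = field(default_factory=list)


def spearman_matrix(national_means: pd.DataFrame) -> SpearmanResult:
    """Rank correlations between ASF intakes across countries.

    ``national_means``: countries x ASF table of mean intakes.  Ties get
    average ranks.  Pairs involving a constant column have no defined rank
    correlation; they are listed in ``undefined`` (and set to NaN in the
    matrix) rather than silently propagated.
    """
    if len(national_means) < 3:
        raise AggregationError("need at least 3 countries")
    cols = list(national_means.columns)
    k = len(cols)
    mat = np.eye(k)
    undefined: list[tuple[str, str]] = []
    constant = {
        c for c in cols if national_means[c].nunique(dropna=False) <= 1
    }
    for i in range(k):
        for j in range(i + 1, k):
            if cols[i] in constant or cols[j] in constant:
                mat[i, j] = mat[j, i] = np.nan
                undefined.append((cols[i], cols[j]))
                continue
            rho = spearmanr(national_means[cols[i]], national_means[cols[j]])[0]
            mat[i, j] = mat[j, i] = rho
    return SpearmanResult(
        matrix=pd.DataFrame(mat, index=cols, columns=cols), undefined=undefined
    )
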
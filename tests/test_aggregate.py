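"""Draw-wise population-weighted aggregation and contrasts."""

import numpy as np
import pandas as pd
import pytest

from asfintake.aggregate import (
    AggregationError,
    AggregationQuery,
    fold_difference,
    period_difference,
    spearman_matrix,
    subgroup_difference,
    weighted_rollup,
)
from asfintake.model import PosteriorDraws
from asfintake.survey_io import STRATUM_FIELDS, enumerate_strata


def make_draws(rng=None, countries=("KEN",), years=(2018,), n_draws=50,
               values=None, region="sub-Saharan Africa"):
    strata = enumerate_strata()
    keys = pd.DataFrame(
        [
            {
                "country": c, "region": region, "year": y, "asf": "milk",
                "age_group": s.age_group, "sex": s.sex,
                "education": s.education, "urbanicity": s.urbanicity,
            }
            for c in countries for y in years for s in strata
        ]
    )
    if values is None:
        values = rng.lognormal(4, 0.5, size=(len(keys), n_draws))
    return PosteriorDraws(keys, values)


def make_weights(keys, persons=None, rng=None):
    w = keys[["country", "year"] + list(STRATUM_FIELDS)].drop_duplicates().copy()
    if persons is None:
        persons = rng.integers(100, 10_000, size=len(w))
    w["persons"] = persons
    return w


class TestWeightedRollup:
    def test_equal_weights_average_constant_draws(self, rng):
        draws = make_draws(rng, n_draws=10)
        vals = np.zeros((len(draws), 10))
        vals[0, :] = 1.0
        vals[1, :] = 3.0
        draws = PosteriorDraws(draws.keys, vals)
        w = make_weights(draws.keys, persons=1)
        sub = draws.keys.index[:2]
        two = PosteriorDraws(draws.keys.loc[sub], vals[:2])
        res = weighted_rollup(two, w, AggregationQuery(level="global"))
        assert np.allclose(res.values, 2.0)

    def test_point_mass_weight_selects_one_stratum(self, rng):
        draws = make_draws(rng, n_draws=20)
        persons = np.zeros(len(draws.keys), dtype=int)
        persons[5] = 1000
        w = make_weights(draws.keys, persons=persons)
        res = weighted_rollup(draws, w, AggregationQuery(level="global"))
        assert np.allclose(res.values[0], draws.values[5])

    def test_matches_brute_force_oracle(self, rng):
        draws = make_draws(rng, n_draws=30)
        w = make_weights(draws.keys, rng=rng)
        res = weighted_rollup(draws, w, AggregationQuery(level="global"))
        merged = draws.keys.merge(w, on=["country", "year"] + list(STRATUM_FIELDS))
        ww = merged["persons"].to_numpy(float)
        expected = np.array(
            [
                sum(ww[i] * draws.values[i, d] for i in range(len(ww))) / ww.sum()
                for d in range(30)
            ]
        )
        assert np.allclose(res.values[0], expected, rtol=1e-12, atol=0)

    def test_rollup_of_constant_field_is_constant(self, rng):
        draws = make_draws(n_draws=15, values=np.full((72, 15), 42.0))
        w = make_weights(draws.keys, rng=rng)
        res = weighted_rollup(draws, w, AggregationQuery(level="global"))
        assert np.allclose(res.values, 42.0)

    def test_monotone_in_stratum_draws(self, rng):
        draws = make_draws(rng, n_draws=10)
        w = make_weights(draws.keys, rng=rng)
        base = weighted_rollup(draws, w, AggregationQuery(level="global"))
        bumped_vals = draws.values.copy()
        bumped_vals[7] += 5.0
        bumped = PosteriorDraws(draws.keys, bumped_vals)
        res = weighted_rollup(bumped, w, AggregationQuery(level="global"))
        assert (res.values >= base.values).all()

    def test_aggregate_then_summarize_differs_from_reverse(self, rng):
        # skewed draws: the median of the weighted mean is not the weighted
        # mean of the medians; the implementation must aggregate draw-wise
        vals = rng.lognormal(2, 2, size=(72, 4001))
        draws = make_draws(values=vals)
        w = make_weights(draws.keys, persons=1)
        res = weighted_rollup(draws, w, AggregationQuery(level="global"))
        draw_wise_median = np.median(res.values[0])
        median_then_agg = np.median(vals, axis=1).mean()
        assert draw_wise_median == pytest.approx(np.median(vals.mean(axis=0)))
        assert abs(draw_wise_median - median_then_agg) > 0.05 * draw_wise_median

    def test_region_rollup_equals_reweighted_country_rollups(self, rng):
        draws = make_draws(rng, countries=("KEN", "UGA", "TZA"), n_draws=25)
        w = make_weights(draws.keys, rng=rng)
        regional = weighted_rollup(draws, w, AggregationQuery(level="region"))
        national = weighted_rollup(draws, w, AggregationQuery(level="country"))
        totals = w.groupby("country")["persons"].sum()
        order = national.keys["country"]
        tw = totals.loc[order].to_numpy(float)
        recombined = (tw[:, None] * national.values).sum(axis=0) / tw.sum()
        assert np.allclose(recombined, regional.values[0], rtol=1e-12)

    def test_unit_conversion_after_aggregation(self, rng):
        draws = make_draws(rng, n_draws=12)
        w = make_weights(draws.keys, rng=rng)
        g = weighted_rollup(draws, w, AggregationQuery(unit="g/d"))
        wk = weighted_rollup(draws, w, AggregationQuery(unit="servings/week"))
        assert np.allclose(wk.values, g.values * 7 / 245.0)

    def test_zero_total_weight_errors(self, rng):
        draws = make_draws(rng, n_draws=5)
        w = make_weights(draws.keys, persons=0)
        with pytest.raises(AggregationError, match="zero total weight"):
            weighted_rollup(draws, w, AggregationQuery(level="global"))


class TestSubgroupDifference:
    def test_identical_levels_rejected(self, rng):
        draws = make_draws(rng, n_draws=5)
        w = make_weights(draws.keys, rng=rng)
        with pytest.raises(AggregationError):
            subgroup_difference(
                draws, w, "education", "high", "high", AggregationQuery()
            )

    def test_identical_level_values_give_exact_zero(self, rng):
        vals = np.tile(rng.lognormal(4, 0.3, size=(1, 20)), (72, 1))
        draws = make_draws(values=vals)
        w = make_weights(draws.keys, persons=1)
        res = subgroup_difference(
            draws, w, "urbanicity", "urban", "rural", AggregationQuery()
        )
        assert np.all(res.values == 0.0)

    def test_recovers_constructed_education_gap(self, rng):
        vals = np.full((72, 10), 100.0)
        draws = make_draws(values=vals)
        hi_mask = (draws.keys["education"] == "high").to_numpy()
        vals[hi_mask] = 150.0
        draws = PosteriorDraws(draws.keys, vals)
        w = make_weights(draws.keys, persons=1)
        res = subgroup_difference(
            draws, w, "education", "high", "low", AggregationQuery()
        )
        assert np.allclose(res.values, 50.0)


class TestPeriodDifference:
    def test_identical_years_give_zero(self, rng):
        vals = rng.lognormal(4, 0.4, size=(72, 15))
        draws = make_draws(values=np.vstack([vals, vals]), years=(1990, 2018))
        w = make_weights(draws.keys, rng=rng)
        res = period_difference(draws, w, AggregationQuery())
        assert np.allclose(res.values, 0.0)

    def test_uniform_shift_in_servings_per_week(self, rng):
        vals90 = rng.lognormal(4, 0.4, size=(72, 15))
        draws = make_draws(
            values=np.vstack([vals90, vals90 + 10.0]), years=(1990, 2018)
        )
        w = make_weights(draws.keys, rng=rng)
        res = period_difference(
            draws, w, AggregationQuery(unit="servings/week")
        )
        assert np.allclose(res.values, 10.0 * 7 / 245.0)
        assert res.summary()["median"].iloc[0] == pytest.approx(0.2857, abs=1e-3)

    def test_linearity_with_shared_weights(self, rng):
        v90 = rng.lognormal(4, 0.3, size=(72, 8))
        v18 = rng.lognormal(4, 0.3, size=(72, 8))
        draws = make_draws(values=np.vstack([v90, v18]), years=(1990, 2018))
        w = make_weights(draws.keys, rng=rng)
        diff = period_difference(draws, w, AggregationQuery())
        w18 = w[w["year"] == 2018]
        roll18 = weighted_rollup(
            draws, w, AggregationQuery(years=[2018])
        )
        w90_std = w18.copy()
        w90_std["year"] = 1990
        roll90 = weighted_rollup(draws, w90_std, AggregationQuery(years=[1990]))
        assert np.allclose(diff.values, roll18.values - roll90.values)

    def test_missing_standardization_year_errors(self, rng):
        draws = make_draws(rng, years=(1990, 2018), n_draws=5)
        w = make_weights(draws.keys, rng=rng)
        w = w[w["year"] != 2018]
        with pytest.raises(AggregationError, match="standardization year"):
            period_difference(draws, w, AggregationQuery())


class TestFoldDifference:
    def test_printed_regional_extremes(self):
        from asfintake.harmonize import round_display

        assert round_display(fold_difference([46.0, 252.0]), 1) == 5.5
        assert round_display(fold_difference([3.0, 44.0]), 0) == 15.0

    def test_identical_values_give_one(self):
        assert fold_difference([7.0, 7.0, 7.0]) == 1.0

    def test_nonpositive_rejected(self):
        with pytest.raises(AggregationError):
            fold_difference([0.0, 5.0])


class TestSpearman:
    def test_monotone_relationships(self, rng):
        x = rng.uniform(1, 100, size=10)
        df = pd.DataFrame({"milk": x, "cheese": x**2 + 1, "eggs": -3 * x})
        res = spearman_matrix(df)
        assert res.matrix.loc["milk", "cheese"] == pytest.approx(1.0)
        assert res.matrix.loc["milk", "eggs"] == pytest.approx(-1.0)
        assert np.allclose(np.diag(res.matrix), 1.0)

    def test_ties_match_rank_then_pearson_oracle(self, rng):
        a = rng.integers(0, 4, size=10).astype(float)  # ties guaranteed
        b = rng.integers(0, 4, size=10).astype(float)
        df = pd.DataFrame({"milk": a, "eggs": b})
        res = spearman_matrix(df)
        ra, rb = pd.Series(a).rank(), pd.Series(b).rank()
        oracle = np.corrcoef(ra, rb)[0, 1]
        assert res.matrix.loc["milk", "eggs"] == pytest.approx(oracle)

    def test_constant_column_flagged_not_propagated(self, rng):
        df = pd.DataFrame(
            {"milk": rng.uniform(size=5), "cheese": np.ones(5),
             "eggs": rng.uniform(size=5)}
        )
        res = spearman_matrix(df)
        assert ("milk", "cheese") in res.undefined or ("cheese", "milk") in res.undefined
        assert np.isfinite(res.matrix.loc["milk", "eggs"])

    def test_too_few_countries_rejected(self):
        with pytest.raises(AggregationError):
            spearman_matrix(pd.DataFrame({"milk": [1, 2], "eggs": [2, 1]}))
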
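"""Design assembly, Gibbs sampler correctness, prediction contracts."""

import math

import numpy as np
import pytest

from asfintake.model import (
    ModelError,
    ModelSpec,
    PosteriorDraws,
    build_design,
    fit,
    overdispersion_flag,
    predict_strata,
    summarize,
)
from asfintake.survey_io import ALL, StratumKey, SurveyObservation, enumerate_strata
from asfintake.synthdata import SurveyDesign, TruthConfig, simulate_world

REF_STRATUM = StratumKey("<1", "female", "low", "rural")


def _flat_covariates(countries, years=(1990, 2018), asf="milk"):
    import pandas as pd

    # identical availability in both years -> z-score is exactly 0
    return pd.DataFrame(
        [
            {"country": c, "asf": asf, "year": y, "availability": 10.0}
            for c in countries
            for y in years
        ]
    )


def _obs(country="KEN", region="sub-Saharan Africa", mean=100.0, sd=20.0, n=100,
         stratum=REF_STRATUM, method="24hr_recall", representative=True, **kw):
    base = dict(
        survey_id=kw.pop("survey_id", "S1"),
        country=country,
        region=region,
        year=2018,
        asf="milk",
        stratum=stratum,
        mean_intake=mean,
        sd_intake=sd,
        n=n,
        method=method,
        nationally_representative=representative,
    )
    base.update(kw)
    return SurveyObservation(**base)


class TestBuildDesign:
    def test_delta_method_variance(self):
        obs = [_obs(mean=100.0, sd=20.0, n=100)]
        d = build_design(obs, _flat_covariates(["KEN"]))
        assert d.y[0] == pytest.approx(math.log(100.0), abs=1e-3)
        assert d.v[0] == pytest.approx((20 / 100) ** 2 / 100)

    def test_overdispersion_flags(self):
        fine_rep = _obs()
        not_rep = _obs(representative=False, survey_id="S2")
        coarse = _obs(stratum=StratumKey("5-9", ALL, "low", "rural"), survey_id="S3")
        assert not overdispersion_flag(fine_rep)
        assert overdispersion_flag(not_rep)
        assert overdispersion_flag(coarse)
        d = build_design([fine_rep, not_rep, coarse], _flat_covariates(["KEN"]))
        assert list(d.flagged) == [False, True, True]

    def test_missing_covariate_names_the_gap(self):
        with pytest.raises(ModelError, match="KEN"):
            build_design([_obs()], _flat_covariates(["UGA"]))

    def test_coarse_row_averages_fine_rows(self):
        coarse = _obs(stratum=StratumKey("5-9", ALL, "low", "rural"))
        d = build_design([coarse], _flat_covariates(["KEN"]))
        # equal weights over the two sexes: the male indicator averages to 1/2
        assert d.A[0, d.index["sex[male]"]] == pytest.approx(0.5)


class TestFit:
    def test_degenerate_noiseless_fit_recovers_constant(self):
        obs = [
            _obs(survey_id=f"S{i}", mean=100.0, sd=0.0, n=200) for i in range(50)
        ]
        d = build_design(obs, _flat_covariates(["KEN"]), variance_floor=1e-6)
        f = fit(d, ModelSpec(n_draws=400, chains=1, warmup=200, seed=0))
        row = d.index.fine_stratum_row("sub-Saharan Africa", "KEN", REF_STRATUM, 0.0)
        posterior_mean = np.exp(row @ f.theta.T)
        assert np.median(posterior_mean) == pytest.approx(100.0, rel=0.01)

    def test_conjugate_precision_weighted_oracle(self):
        # one country, one stratum, known variances: the posterior mean of
        # the cell's log intake must match the closed-form precision-weighted
        # combination (the prior contributes negligible precision here)
        rng = np.random.default_rng(42)
        y = rng.normal(math.log(100), 0.1, size=50)
        obs = [
            _obs(survey_id=f"S{i}", mean=float(np.exp(yi)), sd=0.0, n=100)
            for i, yi in enumerate(y)
        ]
        v = 0.01
        d = build_design(obs, _flat_covariates(["KEN"]), variance_floor=v)
        f = fit(d, ModelSpec(n_draws=1000, chains=1, warmup=300, seed=1))
        row = d.index.fine_stratum_row("sub-Saharan Africa", "KEN", REF_STRATUM, 0.0)
        eta = row @ f.theta.T
        closed_form = (y / v).sum() / (len(y) / v)  # equal variances
        assert eta.mean() == pytest.approx(closed_form, abs=0.005)
        assert eta.std() == pytest.approx(math.sqrt(v / len(y)), rel=0.3)

    def test_education_contrast_recovered(self, world, milk_fit):
        truth = world.truth.education_effects["high"]
        draws = milk_fit.contrast("education", "high", "low")
        lo, hi = np.percentile(draws, [2.5, 97.5])
        assert lo <= truth <= hi

    def test_overdispersion_factor_above_one(self, milk_fit):
        assert np.median(milk_fit.phi) > 1.2

    def test_rhat_reported_for_multichain_fit(self, milk_fit):
        assert milk_fit.rhat
        assert milk_fit.max_rhat < 1.1


class TestPredict:
    def test_contract_all_strata_all_finite(self, world, milk_draws):
        n_countries = len(world.truth.countries)
        assert len(milk_draws) == n_countries * 2 * 72
        assert milk_draws.values.shape[1] == 1000
        assert np.isfinite(milk_draws.values).all()
        assert (milk_draws.values >= 0).all()

    def test_rising_covariate_with_positive_slope_raises_medians(
        self, world, milk_draws
    ):
        cov = world.covariates
        med = summarize(milk_draws)
        rising = []
        for c in world.truth.countries:
            sel = cov[(cov.country == c) & (cov.asf == "milk")]
            a90 = sel[sel.year == 1990]["availability"].iloc[0]
            a18 = sel[sel.year == 2018]["availability"].iloc[0]
            if a18 > a90:
                m90 = med[(med.country == c) & (med.year == 1990)]["median"].to_numpy()
                m18 = med[(med.country == c) & (med.year == 2018)]["median"].to_numpy()
                rising.append(m18 >= m90)
        frac = np.concatenate(rising).mean()
        assert frac >= 0.95

    def test_unsurveyed_country_has_wider_intervals(self, world, milk_fit):
        region = world.truth.regions[0]
        surveyed = [
            c for c, r in world.truth.country_region.items() if r == region
        ]
        # the new country needs a covariate row before it can be predicted
        import pandas as pd

        extra = pd.DataFrame(
            [
                {"country": "XZZ", "asf": "milk", "year": y,
                 "availability": world.covariates["availability"].mean()}
                for y in (1990, 2018)
            ]
        )
        milk_fit.design.covariates = pd.concat(
            [world.covariates, extra], ignore_index=True
        )
        new = predict_strata(
            milk_fit, [("XZZ", 2018)], region_lookup={"XZZ": region}, seed=5
        )
        s_new = summarize(new)
        width_new = np.log(s_new["hi95"] / s_new["lo95"]).mean()
        olds = predict_strata(milk_fit, [(c, 2018) for c in surveyed])
        s_old = summarize(olds)
        width_old = np.log(s_old["hi95"] / s_old["lo95"]).mean()
        assert width_new > width_old

    def test_unknown_country_without_region_errors(self, milk_fit):
        with pytest.raises(ModelError, match="unknown country"):
            predict_strata(milk_fit, [("QQQ", 2018)])


class TestSummarize:
    def test_constant_draws_collapse(self):
        keys = summarize_keys(1)
        pd_ = PosteriorDraws(keys, np.full((1, 100), 7.0))
        s = summarize(pd_)
        assert s.loc[0, ["median", "lo95", "hi95"]].tolist() == [7.0, 7.0, 7.0]

    def test_percentile_oracle_1_to_4000(self):
        keys = summarize_keys(1)
        pd_ = PosteriorDraws(keys, np.arange(1.0, 4001.0)[None, :])
        s = summarize(pd_)
        assert s.loc[0, "median"] == pytest.approx(2000.5)
        assert s.loc[0, "lo95"] == pytest.approx(np.percentile(np.arange(1, 4001), 2.5))

    def test_order_property_random_draws(self, rng):
        keys = summarize_keys(5)
        pd_ = PosteriorDraws(keys, rng.lognormal(3, 1, size=(5, 500)))
        s = summarize(pd_)
        assert (s["lo95"] <= s["median"]).all()
        assert (s["median"] <= s["hi95"]).all()

    def test_too_few_draws_rejected(self):
        with pytest.raises(ModelError):
            summarize(PosteriorDraws(summarize_keys(1), np.ones((1, 2))))


def summarize_keys(n):
    import pandas as pd

    strata = enumerate_strata()
    return pd.DataFrame(
        [
            {
                "country": "KEN",
                "region": "sub-Saharan Africa",
                "year": 2018,
                "asf": "milk",
                "age_group": s.age_group,
                "sex": s.sex,
                "education": s.education,
                "urbanicity": s.urbanicity,
            }
            for s in strata[:n]
        ]
    )


class TestDrawsContainer:
    def test_long_frame_round_trip(self, rng):
        keys = summarize_keys(6)
        pd_ = PosteriorDraws(keys, rng.normal(50, 5, size=(6, 40)))
        back = PosteriorDraws.from_frame(pd_.to_frame())
        assert np.allclose(back.values, pd_.values)
        assert back.keys[pd_.KEY_COLUMNS].equals(pd_.keys[pd_.KEY_COLUMNS])

    def test_selection_filters_cells(self, rng):
        keys = summarize_keys(10)
        pd_ = PosteriorDraws(keys, rng.normal(size=(10, 10)))
        subset = pd_.sel(sex="female")
        assert (subset.keys["sex"] == "female").all()
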
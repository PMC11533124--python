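"""Bayesian hierarchical model of stratum-level mean intake.

One model per ASF.  The observed log survey mean of stratum s in country c
(region r) at year t, assessed by method m, is modelled as

    log y ~ Normal(eta, v * phi^flag)
    eta   = beta0 + u_r + u_c + age + sex + education + urbanicity
            + b_m + gamma * z_ct

with nested exchangeable random effects u_r ~ N(0, sigma_R^2) and
u_c ~ N(0, sigma_C^2); global demographic contrasts (reference levels:
age <1, female, low education, rural); fixed-reference method biases
(24-hour recall = 0); and a time component gamma on the z-scored
food-availability covariate z_ct.  v is the delta-method sampling variance
(sd/mean)^2/n of the log mean, and phi >= 1 is a shared multiplicative
overdispersion factor applied to surveys that are not nationally
representative or not fully stratified.  Coarse survey cells enter as
observations of the population-weight-averaged linear predictor over the
collapsed fine strata, keeping the likelihood linear-Gaussian.

Because the model is linear-Gaussian given (sigma_R, sigma_C, phi), the
posterior is explored by a blocked Gibbs sampler: all location parameters
are drawn jointly from their exact multivariate-normal full conditional;
the two SDs and the overdispersion factor are updated by univariate slice
sampling under half-normal priors.  Split-R-hat diagnostics come from
arviz when more than one chain is run.

Posterior draws of stratum mean intake are exp(eta) with the method bias
set to the reference; countries without surveys draw their country effect
from the region-level predictive distribution, which is how missingness
is propagated into wider uncertainty intervals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve, cholesky

from .survey_io import (
    AGE_GROUPS,
    EDUCATION_LEVELS,
    METHODS,
    SEXES,
    STRATUM_FIELDS,
    URBANICITY_LEVELS,
    StratumKey,
    SurveyObservation,
    enumerate_strata,
    expand_coarse,
)

__all__ = [
    "ModelSpec",
    "DesignBundle",
    "ModelFit",
    "PosteriorDraws",
    "ModelError",
    "build_design",
    "fit",
    "predict_strata",
    "summarize",
]

REFERENCE_METHOD = METHODS[0]


class ModelError(ValueError):
    pass


@dataclass
class ModelSpec:
    """Sampler settings and prior scales."""

    n_draws: int = 4000  # retained posterior draws (across chains)
    chains: int = 2
    warmup: int = 500
    prior_intercept_sd: float = 10.0
    prior_effect_sd: float = 1.0  # demographic and method contrasts
    prior_slope_sd: float = 1.0
    prior_region_sd_scale: float = 0.5  # half-normal scale on sigma_R
    prior_country_sd_scale: float = 0.5  # half-normal scale on sigma_C
    prior_overdispersion_scale: float = 1.0  # half-normal on (phi - 1)
    variance_floor: float = 1e-4  # lower bound on observation log-variance
    rhat_threshold: float = 1.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_draws < 100:
            raise ValueError("n_draws must be >= 100")
        if self.chains < 1 or self.warmup < 0:
            raise ValueError("invalid sampler settings")
        for name in (
            "prior_intercept_sd", "prior_effect_sd", "prior_slope_sd",
            "prior_region_sd_scale", "prior_country_sd_scale",
            "prior_overdispersion_scale",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


class ParamIndex:
    """Column layout of the location-parameter vector."""

    def __init__(self, regions: Sequence[str], countries: Sequence[str]):
        self.regions = tuple(regions)
        self.countries = tuple(countries)
        names = ["intercept"]
        names += [f"region[{r}]" for r in self.regions]
        names += [f"country[{c}]" for c in self.countries]
        names += [f"age[{a}]" for a in AGE_GROUPS[1:]]
        names += ["sex[male]"]
        names += [f"education[{e}]" for e in EDUCATION_LEVELS[1:]]
        names += ["urbanicity[urban]"]
        names += [f"method[{m}]" for m in METHODS[1:]]
        names += ["slope"]
        self.names = names
        self.pos = {n: i for i, n in enumerate(names)}
        self.p = len(names)
        self.region_slice = slice(1, 1 + len(self.regions))
        c0 = 1 + len(self.regions)
        self.country_slice = slice(c0, c0 + len(self.countries))

    def __getitem__(self, name: str) -> int:
        return self.pos[name]

    def fine_stratum_row(
        self, region: str, country: str | None, stratum: StratumKey, z: float,
        method: str = REFERENCE_METHOD,
    ) -> np.ndarray:
        row = np.zeros(self.p)
        row[0] = 1.0
        row[self.pos[f"region[{region}]"]] = 1.0
        if country is not None:
            row[self.pos[f"country[{country}]"]] = 1.0
        if stratum.age_group != AGE_GROUPS[0]:
            row[self.pos[f"age[{stratum.age_group}]"]] = 1.0
        if stratum.sex == "male":
            row[self.pos["sex[male]"]] = 1.0
        if stratum.education != EDUCATION_LEVELS[0]:
            row[self.pos[f"education[{stratum.education}]"]] = 1.0
        if stratum.urbanicity == "urban":
            row[self.pos["urbanicity[urban]"]] = 1.0
        if method != REFERENCE_METHOD:
            row[self.pos[f"method[{method}]"]] = 1.0
        row[self.pos["slope"]] = z
        return row


@dataclass
class DesignBundle:
    """Model-ready arrays for one ASF plus the metadata to rebuild rows."""

    asf: str
    y: np.ndarray  # log observed means
    v: np.ndarray  # delta-method sampling variances (log scale)
    flagged: np.ndarray  # overdispersion indicator per observation
    A: np.ndarray  # n x p design matrix
    index: ParamIndex
    country_region: dict[str, str]
    cov_stats: tuple[float, float]  # (mean, sd) used to z-score availability
    covariates: pd.DataFrame
    obs_meta: pd.DataFrame
    weights: pd.DataFrame | None = None
    messages: list[str] = field(default_factory=list)

    @property
    def n_obs(self) -> int:
        return len(self.y)

    def zscore(self, country: str, year: int) -> float:
        sel = self.covariates[
            (self.covariates["country"] == country)
            & (self.covariates["asf"] == self.asf)
            & (self.covariates["year"] == int(year))
        ]
        if sel.empty:
            raise ModelError(
                f"no availability covariate for ({country}, {self.asf}, {year})"
            )
        mean, sd = self.cov_stats
        return (float(sel["availability"].iloc[0]) - mean) / sd

    def design_row(
        self,
        country: str,
        year: int,
        stratum: StratumKey,
        method: str = REFERENCE_METHOD,
    ) -> np.ndarray:
        """Design row for one (possibly coarse) survey cell.

        Coarse cells average the fine-stratum rows with population weights
        (equal weights when no weight table is attached).  A country without
        its own fitted effect (e.g. held out entirely) gets no country
        indicator; callers add a predictive country-effect draw instead.
        """
        region = self.country_region[country]
        z = self.zscore(country, year)
        c = country if f"country[{country}]" in self.index.pos else None
        fine = expand_coarse(stratum)
        if len(fine) == 1:
            return self.index.fine_stratum_row(region, c, stratum, z, method)
        w = _cell_weights(self.weights, country, year, fine)
        rows = np.stack(
            [self.index.fine_stratum_row(region, c, f, z, method) for f in fine]
        )
        return (w[:, None] * rows).sum(axis=0) / w.sum()


def _cell_weights(
    weights: pd.DataFrame | None, country: str, year: int, fine: Sequence[StratumKey]
) -> np.ndarray:
    if weights is None:
        return np.ones(len(fine))
    sel = weights[(weights["country"] == country) & (weights["year"] == int(year))]
    if sel.empty:
        sel = weights[weights["country"] == country]
        if sel.empty:
            return np.ones(len(fine))
        sel = sel[sel["year"] == sel["year"].min()]
    lut = {
        StratumKey(r.age_group, r.sex, r.education, r.urbanicity): float(r.persons)
        for r in sel.itertuples()
    }
    return np.array([lut.get(f, 1.0) for f in fine])


def overdispersion_flag(obs: SurveyObservation) -> bool:
    """True for surveys that are not nationally representative or coarse."""
    return (not obs.nationally_representative) or (not obs.stratum.is_fine)


def build_design(
    obs: Sequence[SurveyObservation],
    covariates: pd.DataFrame,
    weights: pd.DataFrame | None = None,
    asf: str | None = None,
    variance_floor: float = 1e-4,
) -> DesignBundle:
    """Assemble the model-ready design bundle for one ASF.

    Log-transforms observed means, computes delta-method sampling variances
    (sd/mean)^2/n floored at ``variance_floor``, sets overdispersion flags,
    builds indicator structures, and z-scores the availability covariate
    within the ASF over the full covariate table.  Observations with zero
    mean intake cannot enter the log-scale likelihood and are dropped with
    a message.
    """
    asfs = sorted({o.asf for o in obs})
    if asf is None:
        if len(asfs) != 1:
            raise ModelError(
                f"observations span several ASFs {asfs}; pass asf= to select one"
            )
        asf = asfs[0]
    rows = [o for o in obs if o.asf == asf]
    if not rows:
        raise ModelError(f"no observations for ASF {asf!r}")

    cov = covariates[covariates["asf"] == asf]
    missing = sorted(
        {(o.country, o.year) for o in rows}
        - {(r.country, r.year) for r in cov.itertuples()}
    )
    if missing:
        raise ModelError(
            f"covariate series missing for country-years {missing} (asf={asf})"
        )
    vals = cov["availability"].to_numpy(dtype=float)
    cov_stats = (float(vals.mean()), float(max(vals.std(), 1e-12)))

    countries = sorted({o.country for o in rows})
    country_region = {o.country: o.region for o in rows}
    regions = sorted({country_region[c] for c in countries})
    index = ParamIndex(regions, countries)

    bundle = DesignBundle(
        asf=asf,
        y=np.empty(0),
        v=np.empty(0),
        flagged=np.empty(0, dtype=bool),
        A=np.empty((0, index.p)),
        index=index,
        country_region=country_region,
        cov_stats=cov_stats,
        covariates=covariates,
        obs_meta=pd.DataFrame(),
        weights=weights,
    )

    ys, vs, flags, rows_A, meta = [], [], [], [], []
    n_dropped = 0
    for o in rows:
        if o.mean_intake <= 0:
            n_dropped += 1
            continue
        ys.append(math.log(o.mean_intake))
        v = (o.sd_intake / o.mean_intake) ** 2 / o.n
        vs.append(max(v, variance_floor))
        flags.append(overdispersion_flag(o))
        rows_A.append(bundle.design_row(o.country, o.year, o.stratum, o.method))
        meta.append(
            {
                "survey_id": o.survey_id,
                "country": o.country,
                "region": o.region,
                "year": o.year,
                "stratum": o.stratum.to_string(),
                "method": o.method,
                "mean_intake": o.mean_intake,
                "coarse": not o.stratum.is_fine,
            }
        )
    if n_dropped:
        bundle.messages.append(
            f"dropped {n_dropped} zero-mean observation(s): log-scale "
            "likelihood requires positive means"
        )
    if not ys:
        raise ModelError("no usable observations after filtering")
    bundle.y = np.array(ys)
    bundle.v = np.array(vs)
    bundle.flagged = np.array(flags, dtype=bool)
    bundle.A = np.stack(rows_A)
    bundle.obs_meta = pd.DataFrame(meta)
    return bundle


# ---------------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------------


def _slice_sample(
    x0: float, logpost, rng: np.random.Generator, w: float = 0.5, max_steps: int = 50
) -> float:
    """Univariate stepping-out slice sampler (Neal 2003)."""
    lp0 = logpost(x0)
    logu = lp0 + math.log(rng.random() + 1e-300)
    left = x0 - w * rng.random()
    right = left + w
    for _ in range(max_steps):
        if logpost(left) < logu:
            break
        left -= w
    for _ in range(max_steps):
        if logpost(right) < logu:
            break
        right += w
    while True:
        x1 = rng.uniform(left, right)
        if logpost(x1) >= logu:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1


def _sd_logpost(log_sd: float, effects: np.ndarray, scale: float) -> float:
    # half-normal prior on sd; sampled on the log scale (Jacobian +log_sd)
    sd2 = math.exp(2.0 * log_sd)
    k = len(effects)
    return (
        -k * log_sd
        - float(effects @ effects) / (2.0 * sd2)
        - sd2 / (2.0 * scale**2)
        + log_sd
    )


@dataclass
class ModelFit:
    """Posterior draws and diagnostics for one fitted ASF."""

    design: DesignBundle
    spec: ModelSpec
    theta: np.ndarray  # (n_draws, p)
    sigma_region: np.ndarray
    sigma_country: np.ndarray
    phi: np.ndarray
    rhat: dict[str, float] = field(default_factory=dict)
    warnings_: list[str] = field(default_factory=list)

    @property
    def n_draws(self) -> int:
        return self.theta.shape[0]

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values()) if self.rhat else float("nan")

    def param(self, name: str) -> np.ndarray:
        return self.theta[:, self.design.index[name]]

    def contrast(self, factor: str, level_hi: str, level_lo: str) -> np.ndarray:
        """Posterior draws of a log-scale demographic contrast."""
        def col(level: str) -> np.ndarray:
            name = f"{factor}[{level}]"
            if name in self.design.index.pos:
                return self.param(name)
            return np.zeros(self.n_draws)  # reference level

        return col(level_hi) - col(level_lo)

    def method_bias(self, method: str) -> np.ndarray:
        if method == REFERENCE_METHOD:
            return np.zeros(self.n_draws)
        return self.param(f"method[{method}]")

    def diagnostics_text(self) -> str:
        lines = [
            f"asf: {self.design.asf}",
            f"observations: {self.design.n_obs}",
            f"retained draws: {self.n_draws} over {self.spec.chains} chain(s)",
        ]
        if self.rhat:
            lines.append(f"max split-R-hat: {self.max_rhat:.4f}")
        lines += [f"WARNING: {w}" for w in self.warnings_]
        lines += [f"NOTE: {m}" for m in self.design.messages]
        return "\n".join(lines) + "\n"


def fit(design: DesignBundle, spec: ModelSpec) -> ModelFit:
    """Run the blocked Gibbs sampler on a design bundle."""
    A, y, v, flagged = design.A, design.y, design.v, design.flagged
    index = design.index
    p = index.p

    w_all = 1.0 / v
    A_u, y_u, w_u = A[~flagged], y[~flagged], w_all[~flagged]
    A_f, y_f, w_f = A[flagged], y[flagged], w_all[flagged]
    G0 = (A_u * w_u[:, None]).T @ A_u
    g0 = (A_u * w_u[:, None]).T @ y_u
    G1 = (A_f * w_f[:, None]).T @ A_f
    g1 = (A_f * w_f[:, None]).T @ y_f
    any_flagged = bool(flagged.any())

    prior_prec = np.full(p, 1.0 / spec.prior_effect_sd**2)
    prior_prec[0] = 1.0 / spec.prior_intercept_sd**2
    prior_prec[index.pos["slope"]] = 1.0 / spec.prior_slope_sd**2

    n_chains = spec.chains
    keep_per_chain = -(-spec.n_draws // n_chains)  # ceil
    chain_theta = np.empty((n_chains, keep_per_chain, p))
    chain_sr = np.empty((n_chains, keep_per_chain))
    chain_sc = np.empty((n_chains, keep_per_chain))
    chain_phi = np.empty((n_chains, keep_per_chain))

    seeds = np.random.SeedSequence(spec.seed).spawn(n_chains)
    for ci, child in enumerate(seeds):
        rng = np.random.default_rng(child)
        sigma_r = spec.prior_region_sd_scale
        sigma_c = spec.prior_country_sd_scale
        phi = 1.5 if any_flagged else 1.0
        theta = np.zeros(p)
        for it in range(spec.warmup + keep_per_chain):
            # --- location block: exact MVN conditional
            dinv = prior_prec.copy()
            dinv[index.region_slice] = 1.0 / max(sigma_r, 1e-6) ** 2
            dinv[index.country_slice] = 1.0 / max(sigma_c, 1e-6) ** 2
            P = G0 + (G1 / phi if any_flagged else 0.0) + np.diag(dinv)
            b = g0 + (g1 / phi if any_flagged else 0.0)
            L = cholesky(P, lower=True)
            mean = cho_solve((L, True), b)
            zdraw = rng.standard_normal(p)
            theta = mean + np.linalg.solve(L.T, zdraw)

            # --- variance components: slice updates on log sd
            r_eff = theta[index.region_slice]
            c_eff = theta[index.country_slice]
            sigma_r = math.exp(
                _slice_sample(
                    math.log(max(sigma_r, 1e-4)),
                    lambda t: _sd_logpost(t, r_eff, spec.prior_region_sd_scale),
                    rng,
                )
            )
            sigma_c = math.exp(
                _slice_sample(
                    math.log(max(sigma_c, 1e-4)),
                    lambda t: _sd_logpost(t, c_eff, spec.prior_country_sd_scale),
                    rng,
                )
            )

            # --- overdispersion factor phi = 1 + exp(u)
            if any_flagged:
                e_f = y_f - A_f @ theta
                sse = float((e_f * e_f * w_f).sum())
                n_f = len(y_f)
                s2 = spec.prior_overdispersion_scale**2

                def phi_logpost(u: float) -> float:
                    ph = 1.0 + math.exp(u)
                    return (
                        -0.5 * n_f * math.log(ph)
                        - sse / (2.0 * ph)
                        - (ph - 1.0) ** 2 / (2.0 * s2)
                        + u
                    )

                u0 = math.log(max(phi - 1.0, 1e-6))
                phi = 1.0 + math.exp(_slice_sample(u0, phi_logpost, rng))
            else:
                phi = 1.0 + abs(rng.normal(0.0, spec.prior_overdispersion_scale))

            if it >= spec.warmup:
                k = it - spec.warmup
                chain_theta[ci, k] = theta
                chain_sr[ci, k] = sigma_r
                chain_sc[ci, k] = sigma_c
                chain_phi[ci, k] = phi

    fit_ = ModelFit(
        design=design,
        spec=spec,
        theta=chain_theta.reshape(-1, p)[: spec.n_draws],
        sigma_region=chain_sr.reshape(-1)[: spec.n_draws],
        sigma_country=chain_sc.reshape(-1)[: spec.n_draws],
        phi=chain_phi.reshape(-1)[: spec.n_draws],
    )
    if n_chains >= 2:
        fit_.rhat = _compute_rhat(index, chain_theta, chain_sr, chain_sc, chain_phi)
        if fit_.max_rhat > spec.rhat_threshold:
            worst = max(fit_.rhat, key=fit_.rhat.get)
            fit_.warnings_.append(
                f"possible non-convergence: split-R-hat {fit_.max_rhat:.3f} "
                f"for {worst} exceeds {spec.rhat_threshold}"
            )
    return fit_


def _compute_rhat(index, chain_theta, chain_sr, chain_sc, chain_phi) -> dict:
    import arviz as az

    data = {
        "theta": chain_theta,
        "sigma_region": chain_sr,
        "sigma_country": chain_sc,
        "phi": chain_phi,
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rh = az.rhat(az.convert_to_dataset(data))
    out: dict[str, float] = {}
    theta_rhat = np.asarray(rh["theta"])
    for i, name in enumerate(index.names):
        out[name] = float(theta_rhat[i])
    for name in ("sigma_region", "sigma_country", "phi"):
        out[name] = float(np.asarray(rh[name]))
    return {k: v for k, v in out.items() if np.isfinite(v)}


# ---------------------------------------------------------------------------
# prediction and summaries
# ---------------------------------------------------------------------------


class PosteriorDraws:
    """Draw-indexed stratum mean intakes: a key table plus a value matrix.

    ``keys`` has one row per (country, region, year, asf, stratum) cell;
    ``values[i]`` holds that cell's n_draws intake values in g/d.
    """

    KEY_COLUMNS = ["country", "region", "year", "asf"] + list(STRATUM_FIELDS)

    def __init__(self, keys: pd.DataFrame, values: np.ndarray):
        if len(keys) != values.shape[0]:
            raise ValueError("keys and values are misaligned")
        self.keys = keys.reset_index(drop=True)
        self.values = np.asarray(values, dtype=float)

    @property
    def n_draws(self) -> int:
        return self.values.shape[1]

    def __len__(self) -> int:
        return len(self.keys)

    def sel(self, **filters) -> "PosteriorDraws":
        mask = np.ones(len(self.keys), dtype=bool)
        for col, val in filters.items():
            if val is None:
                continue
            if isinstance(val, (list, tuple, set, frozenset)):
                mask &= self.keys[col].isin(list(val)).to_numpy()
            else:
                mask &= (self.keys[col] == val).to_numpy()
        return PosteriorDraws(self.keys[mask], self.values[mask])

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per cell-draw, column ``value`` in g/d."""
        n = self.n_draws
        rep = self.keys.loc[self.keys.index.repeat(n)].reset_index(drop=True)
        rep["draw"] = np.tile(np.arange(n), len(self.keys))
        rep["value"] = self.values.reshape(-1)
        return rep

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PosteriorDraws":
        key_cols = cls.KEY_COLUMNS
        wide = df.pivot_table(
            index=key_cols, columns="draw", values="value", sort=False
        )
        keys = wide.index.to_frame(index=False)
        return cls(keys, wide.to_numpy())

    @classmethod
    def concat(cls, parts: Iterable["PosteriorDraws"]) -> "PosteriorDraws":
        parts = list(parts)
        keys = pd.concat([p.keys for p in parts], ignore_index=True)
        values = np.vstack([p.values for p in parts])
        return cls(keys, values)

    def summarize(self) -> pd.DataFrame:
        return summarize(self)


def predict_strata(
    fit_: ModelFit,
    targets: Sequence[tuple[str, int]],
    region_lookup: Mapping[str, str] | None = None,
    seed: int | None = None,
) -> PosteriorDraws:
    """Posterior draws of mean intake for all 72 strata of each target.

    Method bias is set to the reference (24-hour recall).  Countries absent
    from the fitted surveys draw a country effect from N(0, sigma_C) per
    posterior draw, using the fitted region effect of the region given by
    ``region_lookup`` (defaulting to the design's country-region map).
    """
    design = fit_.design
    index = design.index
    lookup = dict(design.country_region)
    if region_lookup:
        lookup.update(region_lookup)
    rng = np.random.default_rng(
        fit_.spec.seed + 1_000_003 if seed is None else seed
    )
    strata = enumerate_strata()
    n_draws = fit_.n_draws
    new_country_effects: dict[str, np.ndarray] = {}

    key_rows = []
    blocks = []
    for country, year in targets:
        if country not in lookup:
            raise ModelError(
                f"unknown country {country!r}: not fitted and no region given"
            )
        region = lookup[country]
        if f"region[{region}]" not in index.pos:
            raise ModelError(
                f"region {region!r} absent from the fitted hierarchy"
            )
        z = design.zscore(country, year)
        fitted = f"country[{country}]" in index.pos
        X = np.stack(
            [
                index.fine_stratum_row(
                    region, country if fitted else None, s, z
                )
                for s in strata
            ]
        )
        eta = X @ fit_.theta.T  # (72, n_draws)
        if not fitted:
            if country not in new_country_effects:
                new_country_effects[country] = (
                    rng.standard_normal(n_draws) * fit_.sigma_country
                )
            eta = eta + new_country_effects[country][None, :]
        blocks.append(np.exp(eta))
        for s in strata:
            key_rows.append(
                {
                    "country": country,
                    "region": region,
                    "year": int(year),
                    "asf": design.asf,
                    "age_group": s.age_group,
                    "sex": s.sex,
                    "education": s.education,
                    "urbanicity": s.urbanicity,
                }
            )
    return PosteriorDraws(pd.DataFrame(key_rows), np.vstack(blocks))


def summarize(draws: PosteriorDraws) -> pd.DataFrame:
    """Median and 95% uncertainty interval (2.5/50/97.5 percentiles).

    Percentiles use linear interpolation between order statistics.
    """
    if draws.n_draws < 3:
        raise ModelError("need at least 3 draws to summarize")
    lo, med, hi = np.percentile(draws.values, [2.5, 50.0, 97.5], axis=1)
    out = draws.keys.copy()
    out["median"] = med
    out["lo95"] = lo
    out["hi95"] = hi
    out["unit"] = "g/d"
    return out
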
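"""Model validation: fivefold cross-validation and plausibility screens.

Folds are drawn at the survey level (all strata of a survey move together)
so correlated within-survey errors cannot leak between train and test.
Held-out observations are predicted at their own country-year-stratum with
the held-out survey's method bias applied, and compared with the observed
means; metrics are computed on the log scale, matching the likelihood, and
reported on both scales.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

from .model import (
    DesignBundle,
    ModelFit,
    ModelSpec,
    build_design,
    fit,
    overdispersion_flag,
)
from .survey_io import SurveyObservation

__all__ = [
    "CrossvalError",
    "kfold_plan",
    "run_cv",
    "CVReport",
    "plausibility_screen",
    "DEFAULT_PLAUSIBILITY_BOUNDS",
]


class CrossvalError(ValueError):
    pass


def kfold_plan(
    obs: Sequence[SurveyObservation], k: int = 5, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Random k-fold partition of observation indices at survey granularity.

    Surveys are shuffled and split into k groups whose sizes differ by at
    most one, so each test fold holds as close to 1/k of the surveys as
    integer division allows.
    """
    if len(obs) < k:
        raise CrossvalError("fewer observations than folds")
    survey_ids = sorted({o.survey_id for o in obs})
    if k > len(survey_ids):
        raise CrossvalError(
            f"k={k} exceeds the number of distinct surveys ({len(survey_ids)})"
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    order = rng.permutation(len(survey_ids))
    groups = np.array_split(np.array(survey_ids, dtype=object)[order], k)
    by_survey: dict[str, list[int]] = {s: [] for s in survey_ids}
    for i, o in enumerate(obs):
        by_survey[o.survey_id].append(i)
    plan = []
    for g in groups:
        test = np.array(sorted(i for s in g for i in by_survey[s]), dtype=int)
        mask = np.ones(len(obs), dtype=bool)
        mask[test] = False
        plan.append((np.flatnonzero(mask), test))
    return plan


@dataclass
class CVReport:
    """Predicted-versus-observed pairs and pooled accuracy metrics."""

    pairs: pd.DataFrame  # one row per held-out observation
    metrics: pd.DataFrame  # per-ASF and pooled rows
    flagged_folds: list[int] = field(default_factory=list)

    def to_text(self) -> str:
        lines = ["cross-validation report"]
        if self.flagged_folds:
            lines.append(
                f"folds excluded for non-convergence: {self.flagged_folds}"
            )
        lines.append(self.metrics.to_string(index=False))
        return "\n".join(lines) + "\n"


def _metrics_row(scope: str, df: pd.DataFrame) -> dict:
    obs_nat = df["observed"].to_numpy()
    pred_nat = df["predicted"].to_numpy()
    obs_log = np.log(obs_nat)
    pred_log = np.log(pred_nat)
    cover = float(
        ((df["pi_lo"] <= df["observed"]) & (df["observed"] <= df["pi_hi"])).mean()
    )
    row = {
        "scope": scope,
        "n": len(df),
        "pearson_log": float(pearsonr(obs_log, pred_log)[0]) if len(df) > 2 else np.nan,
        "spearman": float(spearmanr(obs_nat, pred_nat)[0]) if len(df) > 2 else np.nan,
        "bias_log": float((pred_log - obs_log).mean()),
        "rmse_log": float(np.sqrt(((pred_log - obs_log) ** 2).mean())),
        "pearson": float(pearsonr(obs_nat, pred_nat)[0]) if len(df) > 2 else np.nan,
        "bias": float((pred_nat - obs_nat).mean()),
        "rmse": float(np.sqrt(((pred_nat - obs_nat) ** 2).mean())),
        "pi95_coverage": cover,
    }
    return row


def run_cv(
    obs: Sequence[SurveyObservation],
    covariates: pd.DataFrame,
    weights: pd.DataFrame | None,
    spec: ModelSpec,
    plan: Sequence[tuple[np.ndarray, np.ndarray]],
) -> CVReport:
    """Fit on each training fold, predict its held-out observations.

    A held-out cell's prediction applies the posterior method-bias draw for
    the survey's own method, so observed and predicted are on the same
    footing.  The 95% prediction interval adds the observation-level noise
    (delta-method variance, inflated by the posterior overdispersion factor
    when the observation is flagged).  Folds whose sampler diagnostics
    indicate non-convergence are excluded from pooled metrics with notice.
    """
    obs = list(obs)
    asfs = sorted({o.asf for o in obs})
    rows = []
    flagged_folds: list[int] = []
    for fold_id, (train_idx, test_idx) in enumerate(plan):
        train = [obs[i] for i in train_idx]
        test = [obs[i] for i in test_idx]
        fold_ok = True
        fold_rows = []
        for asf in asfs:
            train_asf = [o for o in train if o.asf == asf]
            test_asf = [o for o in test if o.asf == asf and o.mean_intake > 0]
            if not train_asf or not test_asf:
                continue
            design = build_design(
                train_asf, covariates, weights=weights, asf=asf,
                variance_floor=spec.variance_floor,
            )
            fold_fit = fit(design, spec)
            if any("non-convergence" in w for w in fold_fit.warnings_):
                fold_ok = False
            rng = np.random.default_rng(
                np.random.SeedSequence([spec.seed, fold_id, asfs.index(asf)])
            )
            new_effects: dict[str, np.ndarray] = {}
            for o in test_asf:
                eta = _held_out_eta(fold_fit, design, o, rng, new_effects)
                vdm = max(
                    (o.sd_intake / o.mean_intake) ** 2 / o.n, spec.variance_floor
                )
                noise_sd = np.sqrt(
                    vdm * np.where(overdispersion_flag(o), fold_fit.phi, 1.0)
                )
                predictive = np.exp(eta + rng.standard_normal(len(eta)) * noise_sd)
                lo, hi = np.percentile(predictive, [2.5, 97.5])
                fold_rows.append(
                    {
                        "fold": fold_id,
                        "asf": asf,
                        "survey_id": o.survey_id,
                        "country": o.country,
                        "year": o.year,
                        "stratum": o.stratum.to_string(),
                        "method": o.method,
                        "observed": o.mean_intake,
                        "predicted": float(np.median(np.exp(eta))),
                        "pi_lo": float(lo),
                        "pi_hi": float(hi),
                    }
                )
        if not fold_ok:
            flagged_folds.append(fold_id)
        else:
            rows.extend(fold_rows)
    if not rows:
        raise CrossvalError("no usable fold produced predictions")
    pairs = pd.DataFrame(rows)
    if len(pairs) != sum(
        1
        for fold_id, (_, test_idx) in enumerate(plan)
        if fold_id not in flagged_folds
        for i in test_idx
        if obs[i].mean_intake > 0
    ):
        # bookkeeping guard: every held-out observation of a converged fold
        # must be paired exactly once
        raise CrossvalError("predicted/observed pairing lost observations")
    metric_rows = [_metrics_row("pooled", pairs)]
    for asf in asfs:
        sub = pairs[pairs["asf"] == asf]
        if len(sub):
            metric_rows.append(_metrics_row(asf, sub))
    return CVReport(
        pairs=pairs, metrics=pd.DataFrame(metric_rows), flagged_folds=flagged_folds
    )


def _held_out_eta(
    fold_fit: ModelFit,
    design: DesignBundle,
    o: SurveyObservation,
    rng: np.random.Generator,
    new_effects: dict[str, np.ndarray],
) -> np.ndarray:
    """Linear-predictor draws at a held-out observation's cell and method."""
    index = design.index
    if f"country[{o.country}]" in index.pos:
        row = design.design_row(o.country, o.year, o.stratum, o.method)
        return row @ fold_fit.theta.T
    # country entirely held out: predictive country effect within its region
    design.country_region.setdefault(o.country, o.region)
    row = design.design_row(o.country, o.year, o.stratum, o.method)
    eta = row @ fold_fit.theta.T
    if o.country not in new_effects:
        new_effects[o.country] = (
            rng.standard_normal(fold_fit.n_draws) * fold_fit.sigma_country
        )
    return eta + new_effects[o.country]


# Broad per-ASF plausibility bounds (g/d) for screening model output; any
# stratum summary outside its band is listed for review.
DEFAULT_PLAUSIBILITY_BOUNDS: dict[str, tuple[float, float]] = {
    "milk": (0.1, 2000.0),
    "cheese": (0.01, 300.0),
    "yogurt": (0.01, 1000.0),
    "eggs": (0.01, 300.0),
    "seafood": (0.01, 500.0),
    "unprocessed_red_meat": (0.01, 500.0),
    "processed_meat": (0.01, 400.0),
}


def plausibility_screen(
    summaries: pd.DataFrame,
    bounds: Mapping[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """List every stratum summary whose median falls outside its ASF bounds."""
    bounds = dict(bounds or DEFAULT_PLAUSIBILITY_BOUNDS)
    for asf, (lo, hi) in bounds.items():
        if lo <= 0 or hi <= 0 or hi <= lo:
            raise CrossvalError(f"invalid bounds for {asf}: ({lo}, {hi})")
    rows = []
    for _, r in summaries.iterrows():
        lo, hi = bounds.get(r["asf"], (-np.inf, np.inf))
        if not (lo <= r["median"] <= hi):
            rec = r.to_dict()
            rec["bound_lo"], rec["bound_hi"] = lo, hi
            rows.append(rec)
    return pd.DataFrame(rows)
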
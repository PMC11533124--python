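"""Energy adjustment and gram/serving conversion.

Reported mean intakes from heterogeneous surveys are rescaled to a common
age-specific standard energy level (700-2,000 kcal/d) so that differences
in total energy reporting do not masquerade as intake differences, and
converted between g/d and servings per day or week using fixed portion
sizes (e.g. 245 g milk, 50 g processed meat).
"""

from __future__ import annotations

import math
from dataclasses import replace
from pathlib import Path
from typing import Mapping

import yaml

from .survey_io import AGE_GROUPS, ALL, ASF_CATEGORIES, SurveyObservation, _load_asset

__all__ = [
    "PORTION_SIZES_G",
    "ENERGY_STANDARDS",
    "AGE_GROUP_TO_BAND",
    "load_portions",
    "load_energy_standards",
    "energy_adjust",
    "to_servings",
    "round_display",
    "HarmonizeError",
]


class HarmonizeError(ValueError):
    pass


def load_portions(path: str | Path | None = None) -> dict[str, float]:
    """ASF -> serving size in grams; shipped values are overridable by file."""
    data = yaml.safe_load(Path(path).read_text()) if path else _load_asset("portions.yaml")
    table = {k: float(v) for k, v in data.items()}
    unknown = set(table) - set(ASF_CATEGORIES)
    if unknown:
        raise HarmonizeError(f"portion table has unknown ASF categories: {unknown}")
    if any(v <= 0 for v in table.values()):
        raise HarmonizeError("portion sizes must be positive")
    return table


def load_energy_standards(path: str | Path | None = None) -> list[dict]:
    """Energy bands partitioning ages 0-19, each with its standard kcal/d."""
    data = (
        yaml.safe_load(Path(path).read_text())
        if path
        else _load_asset("energy_standards.yaml")
    )
    bands = sorted(data, key=lambda b: b["age_lo"])
    ages = [a for b in bands for a in range(int(b["age_lo"]), int(b["age_hi"]) + 1)]
    if ages != list(range(0, 20)):
        raise HarmonizeError("energy bands must partition completed ages 0-19")
    return bands


PORTION_SIZES_G: dict[str, float] = load_portions()
ENERGY_STANDARDS: list[dict] = load_energy_standards()

# Model age groups do not nest exactly in the energy bands (the group 5-9
# straddles the 2-5/6-10 boundary at age 5, and 10-14 straddles 6-10/11-19
# at age 10).  Each group is assigned the band covering the majority of its
# completed-year span; the two-year group 1-2 ties between the 1-<2 and
# 2-5 bands and is assigned the lower band containing its label anchor.
AGE_GROUP_TO_BAND: dict[str, str] = {
    "<1": "<1",
    "1-2": "1-<2",
    "3-4": "2-5",
    "5-9": "6-10",
    "10-14": "11-19",
    "15-19": "11-19",
}


def _band_kcal(age_group: str, standards: list[dict]) -> float:
    if age_group == ALL:
        raise HarmonizeError(
            "cannot energy-adjust a record whose age group spans multiple "
            "energy bands (age_group='all'); adjust before collapsing"
        )
    if age_group not in AGE_GROUPS:
        raise HarmonizeError(f"unknown age group {age_group!r}")
    band = AGE_GROUP_TO_BAND[age_group]
    for b in standards:
        if b["band"] == band:
            return float(b["kcal"])
    raise HarmonizeError(f"energy standards missing band {band!r}")


def energy_adjust(
    obs: SurveyObservation, standards: list[dict] | None = None
) -> SurveyObservation:
    """Rescale a record's mean and SD to its age band's standard energy.

    The adjustment is multiplicative density scaling: intake is multiplied
    by (standard kcal / observed mean energy), preserving zeros.  A record
    already flagged ``energy_adjusted`` is returned unchanged, making the
    operation idempotent.
    """
    if obs.energy_adjusted:
        return obs
    if obs.mean_energy is None:
        raise HarmonizeError(
            f"survey {obs.survey_id}: mean_energy missing; skip adjustment "
            "explicitly if the survey is already energy-standardized"
        )
    kcal = _band_kcal(obs.stratum.age_group, standards or ENERGY_STANDARDS)
    factor = kcal / obs.mean_energy
    return replace(
        obs,
        mean_intake=obs.mean_intake * factor,
        sd_intake=obs.sd_intake * factor,
        mean_energy=kcal,
        energy_adjusted=True,
    )


def to_servings(
    amount: float,
    asf: str,
    per: str = "day",
    portions: Mapping[str, float] | None = None,
) -> float:
    """Convert g/d to servings per day or per week (exact, no rounding)."""
    table = portions if portions is not None else PORTION_SIZES_G
    if asf not in table:
        raise HarmonizeError(f"unknown ASF category {asf!r}")
    if amount < 0:
        raise HarmonizeError("amount must be non-negative")
    servings = amount / table[asf]
    if per == "day":
        return servings
    if per == "week":
        return 7.0 * servings
    raise HarmonizeError(f"per must be 'day' or 'week', got {per!r}")


def round_display(x: float, decimals: int = 0) -> float:
    """Round half away from zero at the given precision (display convention)."""
    if decimals < 0:
        raise HarmonizeError("decimals must be >= 0")
    scale = 10.0 ** decimals
    return math.copysign(math.floor(abs(x) * scale + 0.5), x) / scale
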
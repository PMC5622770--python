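"""Person-day outcome totals: nutrients, food-pattern groups, empty
calories and diet cost.

Empty calories (SoFAAS: solid fats, alcohol beyond an allowance, and added
sugars) are computed from the food-pattern constituents with configurable
energy conversion factors: 9 kcal per g solid fat, 16.8 kcal per teaspoon
equivalent of added sugar (4.2 g/tsp at 4 kcal/g) and 6.93 kcal per g of
alcohol counted only above an allowance of 13 g per 1000 kcal.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd

from .schema import DENSITY_FIELDS, FPED_FIELDS, NUTRIENT_FIELDS


@dataclasses.dataclass(frozen=True)
class EmptyCalorieConstants:
    """Energy conversion factors for the empty-calorie (SoFAAS) total."""

    kcal_per_g_solid_fat: float = 9.0
    kcal_per_tsp_added_sugar: float = 16.8
    kcal_per_g_alcohol: float = 6.93
    alcohol_allowance_g_per_1000kcal: float = 13.0


DEFAULT_CONSTANTS = EmptyCalorieConstants()

#: columns of the person-day totals table beyond the two key columns
TOTAL_FIELDS: tuple[str, ...] = (
    "energy_kcal", *DENSITY_FIELDS, "sofaas_kcal", "diet_cost_usd",
)


def sofaas_kcal(
    solid_fat_g: float | np.ndarray,
    added_sugar_tspeq: float | np.ndarray,
    alcohol_g: float | np.ndarray = 0.0,
    energy_kcal: float | np.ndarray = 0.0,
    constants: EmptyCalorieConstants = DEFAULT_CONSTANTS,
):
    """Empty-calorie energy from solid fat, added sugar and excess alcohol."""
    allowance = constants.alcohol_allowance_g_per_1000kcal * np.asarray(energy_kcal) / 1000.0
    excess = np.maximum(0.0, np.asarray(alcohol_g) - allowance)
    return (
        constants.kcal_per_g_solid_fat * np.asarray(solid_fat_g)
        + constants.kcal_per_tsp_added_sugar * np.asarray(added_sugar_tspeq)
        + constants.kcal_per_g_alcohol * excess
    )


def record_costs(
    records: pd.DataFrame,
    inflation_factors: Mapping[str, float] | None = None,
) -> pd.Series:
    """Per-record cost in USD: grams/100 x price per 100 g x inflation factor.

    ``inflation_factors`` maps a food-group key — the leading 3 digits of the
    food code — to a multiplicative price adjustment; groups absent from the
    mapping get factor 1.0 (identity when prices are pre-adjusted).
    """
    cost = records["grams"] / 100.0 * records["price_per_100g"]
    if inflation_factors:
        factors = records["food_code"].astype(str).str[:3].map(
            lambda g: inflation_factors.get(g, 1.0)
        )
        cost = cost * factors
    return cost


def diet_cost(
    records: pd.DataFrame,
    inflation_factors: Mapping[str, float] | None = None,
) -> float:
    """Total daily diet cost (USD) of one person-day of records."""
    return float(record_costs(records, inflation_factors).sum())


def person_day_totals(
    records: pd.DataFrame,
    inflation_factors: Mapping[str, float] | None = None,
    constants: EmptyCalorieConstants = DEFAULT_CONSTANTS,
) -> pd.DataFrame:
    """Sum records into per person-day totals.

    Works on any number of person-days at once; returns one row per
    (participant_id, recall_day) with energy, every nutrient and
    food-pattern total, empty-calorie energy and diet cost.  Totals are
    straight sums, so substitution and totalling commute.
    """
    keys = ["participant_id", "recall_day"]
    df = records.copy()
    df["_cost"] = record_costs(df, inflation_factors)
    agg = {c: "sum" for c in ("energy_kcal", *DENSITY_FIELDS, "_cost")}
    totals = df.groupby(keys, as_index=False).agg(agg)
    totals = totals.rename(columns={"_cost": "diet_cost_usd"})
    totals["sofaas_kcal"] = sofaas_kcal(
        totals["solid_fat_g"], totals["added_sugar_tspeq"],
        totals["alcohol_g"], totals["energy_kcal"], constants,
    )
    return totals[keys + list(TOTAL_FIELDS)]


def whole_grain_share(totals: pd.DataFrame | Mapping[str, float]) -> float | pd.Series:
    """Whole grains as a fraction of total grains; 0 when no grains at all."""
    whole = totals["whole_grain_ozeq"]
    refined = totals["refined_grain_ozeq"]
    denom = whole + refined
    if np.isscalar(whole) or isinstance(totals, Mapping):
        return float(whole / denom) if denom > 0 else 0.0
    out = (whole / denom).where(denom > 0, 0.0)
    return out
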
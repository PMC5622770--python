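"""Canonical column sets shared across the package.

The tables exchanged between modules are plain pandas DataFrames with the
column contracts defined here (see also ``data/schema_reference.md``).
"""

from __future__ import annotations

AGE_GROUPS: tuple[str, ...] = (
    "1-3", "4-8", "9-13", "14-19", "20-30", "31-50", "51-70", "71+",
)

#: upper age (inclusive) of each finite age bin, aligned with AGE_GROUPS[:-1]
AGE_BIN_UPPER: tuple[int, ...] = (3, 8, 13, 19, 30, 50, 70)

RACE_GROUPS: tuple[str, ...] = (
    "NHWhite", "NHBlack", "MexAmerican", "OtherHispanic", "OtherMixed",
)

SEXES: tuple[str, ...] = ("male", "female")

OCCASIONS: tuple[str, ...] = (
    "breakfast", "desayuno", "brunch", "lunch", "dinner", "snack",
    "beverage_occasion", "other",
)

#: occasions whose solid foods are candidates for replacement
BREAKFAST_CLASS: frozenset[str] = frozenset({"breakfast", "desayuno", "brunch"})

#: free-text labels normalized onto the canonical occasion set
OCCASION_ALIASES: dict[str, str] = {
    "breakfast": "breakfast",
    "desayuno": "desayuno",
    "almuerzo": "brunch",
    "brunch": "brunch",
    "lunch": "lunch",
    "comida": "lunch",
    "dinner": "dinner",
    "supper": "dinner",
    "cena": "dinner",
    "snack": "snack",
    "merienda": "snack",
    "drink": "beverage_occasion",
    "beverage": "beverage_occasion",
    "beverage_occasion": "beverage_occasion",
    "bebida": "beverage_occasion",
    "other": "other",
    "extended consumption": "other",
}

#: ready-to-eat cereal food-code prefixes (FNDDS convention)
RTEC_PREFIXES: tuple[str, ...] = ("571", "572", "573", "574")

NUTRIENT_FIELDS: tuple[str, ...] = (
    "fiber_g",
    "vitaminD_ug",
    "calcium_mg",
    "potassium_mg",
    "magnesium_mg",
    "iron_mg",
    "folic_acid_ug",
    "vitaminB12_ug",
    "sodium_mg",
    "sfa_g",
    "mufa_g",
    "pufa_g",
    "alcohol_g",
)

FPED_FIELDS: tuple[str, ...] = (
    "whole_grain_ozeq",
    "refined_grain_ozeq",
    "dairy_cupeq",
    "total_fruit_cupeq",
    "whole_fruit_cupeq",
    "total_veg_cupeq",
    "greens_beans_cupeq",
    "protein_ozeq",
    "seafood_plant_ozeq",
    "solid_fat_g",
    "added_sugar_tspeq",
)

#: every per-food quantity that scales linearly with energy in a composite
DENSITY_FIELDS: tuple[str, ...] = NUTRIENT_FIELDS + FPED_FIELDS

PARTICIPANT_COLUMNS: tuple[str, ...] = (
    "participant_id",
    "age_years",
    "sex",
    "race_eth",
    "wic_flag",
    "stratum_id",
    "psu_id",
    "weight_day1",
    "weight_2day",
    "n_recalls",
)

FOOD_RECORD_COLUMNS: tuple[str, ...] = (
    "participant_id",
    "recall_day",
    "line_id",
    "food_code",
    "occasion",
    "grams",
    "energy_kcal",
    *NUTRIENT_FIELDS,
    *FPED_FIELDS,
    "price_per_100g",
    "is_beverage",
    "is_beverage_addition",
    "is_rtec",
    "is_milk",
)

FLAG_COLUMNS: tuple[str, ...] = (
    "is_beverage", "is_beverage_addition", "is_rtec", "is_milk",
)


def age_to_group(age_years: int) -> str:
    """Map integer age (years, >= 1) to its age-group label.

    The binning is total and disjoint over integers >= 1; ages above the
    last finite bin fall in the open-ended ``71+`` group.
    """
    if age_years < 1:
        raise ValueError(f"age_years must be >= 1, got {age_years}")
    for upper, label in zip(AGE_BIN_UPPER, AGE_GROUPS):
        if age_years <= upper:
            return label
    return AGE_GROUPS[-1]


def is_rtec_code(food_code: str) -> bool:
    """True iff the food code carries a ready-to-eat-cereal prefix."""
    return str(food_code).startswith(RTEC_PREFIXES)


def normalize_occasion(label: str) -> str:
    """Normalize a reported eating-occasion label onto the canonical set.

    Unrecognized labels map to ``other``.
    """
    key = str(label).strip().lower()
    return OCCASION_ALIASES.get(key, "other")
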
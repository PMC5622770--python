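"""Synthetic two-day recall cohorts with known ground truth.

The generator emulates the statistical structure the substitution analysis
assumes: a stratified two-PSU survey design with dietary weights; two
non-consecutive recalls per person with 15% single-recall participants;
named eating occasions including breakfast, "desayuno" and brunch; per
person-day breakfast behavior drawn from {skip, beverage only, cereal
consumer, solid food}; cereal choice from per-stratum popularity vectors;
milk co-consumed with cereal at a configured energy share, with milk-type
mix shifting from whole milk in young children toward skim in older
adults; and lognormal within-/between-person variation in intake amounts.

Default behavior rates mirror national 24-h-recall surveys: 83% of
person-days include breakfast and about 42% carry solid non-cereal
breakfast food eligible for replacement.

Because every portion is drawn from known class-level distributions, the
expected effect of the substitution models on every outcome has a closed
form (:func:`analytic_expected_deltas`), which downstream estimates can be
tested against.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd

from .schema import AGE_GROUPS, DENSITY_FIELDS, RACE_GROUPS

SUGAR_ADDITION_CODE = "91100000"


@dataclasses.dataclass(frozen=True)
class FoodClassSpec:
    """Count and sampling ranges for one class of library foods.

    Density ranges are per 1000 kcal; fields not listed default to zero.
    ``portion_kcal`` is the range of the base (pre-variation) portion
    energy drawn each time a food of this class is eaten.
    """

    count: int
    energy_density: tuple[float, float]          # kcal per g
    portion_kcal: tuple[float, float]
    price_per_100g: tuple[float, float]          # USD
    densities: Mapping[str, tuple[float, float]] = dataclasses.field(
        default_factory=dict
    )


#: fixed milk types (per-1000-kcal densities); the stratum mix over these
#: shifts with age (younger -> more whole milk)
MILK_TYPES: tuple[dict, ...] = (
    {
        "name": "whole", "energy_density": 0.61, "price_per_100g": 0.10,
        "dairy_cupeq": 6.7, "sfa_g": 30.0, "solid_fat_g": 53.0, "mufa_g": 13.0, "pufa_g": 2.0,
        "calcium_mg": 1850.0, "potassium_mg": 2160.0, "magnesium_mg": 160.0,
        "vitaminD_ug": 19.0, "vitaminB12_ug": 7.4, "sodium_mg": 700.0,
        "protein_ozeq": 0.0, "fiber_g": 0.0,
    },
    {
        "name": "reduced_fat", "energy_density": 0.50, "price_per_100g": 0.10,
        "dairy_cupeq": 8.2, "sfa_g": 24.0, "solid_fat_g": 39.0, "mufa_g": 11.0, "pufa_g": 1.5,
        "calcium_mg": 2260.0, "potassium_mg": 2640.0, "magnesium_mg": 200.0,
        "vitaminD_ug": 24.0, "vitaminB12_ug": 9.0, "sodium_mg": 860.0,
        "protein_ozeq": 0.0, "fiber_g": 0.0,
    },
    {
        "name": "skim", "energy_density": 0.35, "price_per_100g": 0.09,
        "dairy_cupeq": 11.7, "sfa_g": 3.6, "solid_fat_g": 2.4, "mufa_g": 1.5, "pufa_g": 0.4,
        "calcium_mg": 3320.0, "potassium_mg": 3880.0, "magnesium_mg": 290.0,
        "vitaminD_ug": 35.0, "vitaminB12_ug": 13.0, "sodium_mg": 1230.0,
        "protein_ozeq": 0.0, "fiber_g": 0.0,
    },
)


def _default_library_spec() -> dict[str, FoodClassSpec]:
    return {
        "rtec": FoodClassSpec(
            count=8, energy_density=(3.5, 4.0), portion_kcal=(100.0, 220.0),
            price_per_100g=(0.35, 0.65),
            densities={
                "whole_grain_ozeq": (0.5, 6.0), "refined_grain_ozeq": (1.0, 3.0),
                "fiber_g": (3.0, 15.0), "folic_acid_ug": (300.0, 900.0),
                "iron_mg": (8.0, 20.0), "vitaminD_ug": (5.0, 15.0),
                "added_sugar_tspeq": (0.0, 10.0), "solid_fat_g": (0.0, 2.0),
                "sodium_mg": (300.0, 800.0), "calcium_mg": (100.0, 1300.0),
                "potassium_mg": (150.0, 600.0), "magnesium_mg": (40.0, 150.0),
                "vitaminB12_ug": (2.0, 8.0), "sfa_g": (0.5, 2.0),
                "mufa_g": (0.5, 3.0), "pufa_g": (0.5, 3.0),
                "protein_ozeq": (0.2, 0.8),
            },
        ),
        "milk": FoodClassSpec(
            count=3, energy_density=(0.35, 0.61), portion_kcal=(60.0, 140.0),
            price_per_100g=(0.09, 0.10),
        ),
        "breakfast_solid": FoodClassSpec(
            count=12, energy_density=(2.0, 4.5), portion_kcal=(120.0, 260.0),
            price_per_100g=(0.50, 1.10),
            densities={
                "refined_grain_ozeq": (1.0, 3.0), "whole_grain_ozeq": (0.0, 0.4),
                "solid_fat_g": (8.0, 25.0), "added_sugar_tspeq": (1.0, 8.0),
                "fiber_g": (1.0, 4.0), "sodium_mg": (500.0, 1500.0),
                "protein_ozeq": (1.0, 4.0), "sfa_g": (5.0, 15.0),
                "mufa_g": (5.0, 15.0), "pufa_g": (2.0, 8.0),
                "calcium_mg": (100.0, 400.0), "potassium_mg": (300.0, 900.0),
                "magnesium_mg": (20.0, 60.0), "iron_mg": (1.0, 5.0),
                "folic_acid_ug": (40.0, 200.0), "vitaminB12_ug": (0.5, 3.0),
                "vitaminD_ug": (0.2, 1.5), "dairy_cupeq": (0.0, 0.5),
            },
        ),
        "beverage": FoodClassSpec(
            count=6, energy_density=(0.2, 0.8), portion_kcal=(40.0, 160.0),
            price_per_100g=(0.03, 0.15),
            densities={
                "added_sugar_tspeq": (0.0, 15.0), "potassium_mg": (200.0, 1500.0),
                "total_fruit_cupeq": (0.0, 3.0), "calcium_mg": (0.0, 300.0),
                "vitaminD_ug": (0.0, 2.0), "magnesium_mg": (10.0, 120.0),
            },
        ),
        "other_food": FoodClassSpec(
            count=16, energy_density=(0.8, 3.5), portion_kcal=(150.0, 400.0),
            price_per_100g=(0.20, 0.90),
            densities={
                "total_veg_cupeq": (0.0, 1.5), "greens_beans_cupeq": (0.0, 0.5),
                "total_fruit_cupeq": (0.0, 1.0), "whole_fruit_cupeq": (0.0, 0.8),
                "protein_ozeq": (0.5, 3.0), "seafood_plant_ozeq": (0.0, 1.0),
                "dairy_cupeq": (0.0, 1.0), "refined_grain_ozeq": (0.0, 2.5),
                "whole_grain_ozeq": (0.0, 0.8), "fiber_g": (2.0, 10.0),
                "solid_fat_g": (3.0, 15.0), "added_sugar_tspeq": (0.0, 6.0),
                "sodium_mg": (400.0, 1600.0), "sfa_g": (2.0, 10.0),
                "mufa_g": (3.0, 12.0), "pufa_g": (2.0, 8.0),
                "calcium_mg": (100.0, 500.0), "potassium_mg": (400.0, 1500.0),
                "magnesium_mg": (30.0, 150.0), "iron_mg": (1.0, 6.0),
                "folic_acid_ug": (30.0, 150.0), "vitaminB12_ug": (0.5, 4.0),
                "vitaminD_ug": (0.0, 1.5),
            },
        ),
    }


def _default_age_dist() -> dict[str, float]:
    return {
        "1-3": 0.04, "4-8": 0.07, "9-13": 0.07, "14-19": 0.09,
        "20-30": 0.15, "31-50": 0.27, "51-70": 0.22, "71+": 0.09,
    }


def _default_race_dist() -> dict[str, float]:
    return {
        "NHWhite": 0.65, "NHBlack": 0.12, "MexAmerican": 0.09,
        "OtherHispanic": 0.06, "OtherMixed": 0.08,
    }


@dataclasses.dataclass
class GeneratorConfig:
    seed: int = 0
    n_strata: int = 8
    n_participants: int = 2000
    age_dist: dict[str, float] = dataclasses.field(default_factory=_default_age_dist)
    race_dist: dict[str, float] = dataclasses.field(default_factory=_default_race_dist)
    #: per-person-day breakfast behavior; remainder is the eligible
    #: solid-food class (defaults: 17% skip -> 83% consume breakfast,
    #: ~42% eligible, matching national recall-survey rates)
    p_skip_breakfast: float = 0.17
    p_beverage_only: float = 0.25
    p_rtec_breakfast: float = 0.16
    p_second_recall: float = 0.85
    #: Dirichlet concentration for per-stratum cereal popularity vectors
    rtec_popularity_alpha: float = 1.0
    p_milk_with_cereal: float = 0.6
    milk_energy_share: float = 0.28
    within_person_cv: float = 0.35
    between_person_cv: float = 0.30
    weekend_effect: float = 1.05      # multiplicative, on portion amounts
    recall2_effect: float = 0.97      # telephone-mode effect on amounts
    p_breakfast_beverage: float = 0.5
    p_beverage_addition: float = 0.2
    food_library_spec: dict[str, FoodClassSpec] = dataclasses.field(
        default_factory=_default_library_spec
    )

    def __post_init__(self) -> None:
        for name, dist in (("age_dist", self.age_dist), ("race_dist", self.race_dist)):
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        probs = (
            self.p_skip_breakfast, self.p_beverage_only, self.p_rtec_breakfast,
            self.p_second_recall, self.p_milk_with_cereal,
            self.p_breakfast_beverage, self.p_beverage_addition,
        )
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.p_skip_breakfast + self.p_beverage_only + self.p_rtec_breakfast > 1.0:
            raise ValueError("breakfast behavior probabilities exceed 1")
        if not 0.0 <= self.milk_energy_share < 1.0:
            raise ValueError("milk_energy_share must be in [0, 1)")
        if self.n_strata < 2:
            raise ValueError("need at least 2 strata")

    @property
    def p_eligible(self) -> float:
        return 1.0 - self.p_skip_breakfast - self.p_beverage_only - self.p_rtec_breakfast


@dataclasses.dataclass
class GroundTruth:
    """Closed-form expectations implied by a generator configuration."""

    composite_densities: dict[tuple[str, str], dict[str, float]]
    milk_densities: dict[tuple[str, str], dict[str, float]]
    rtec_popularity: dict[tuple[str, str], dict[str, float]]
    p_eligible: float
    expected_replaced_kcal: float            # per eligible person-day
    expected_delta_model1: dict[str, float]  # per capita per person-day
    expected_delta_model2: dict[str, float]


def _rng(config: GeneratorConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2**31), stream])


def _strata(config: GeneratorConfig) -> list[tuple[str, str]]:
    return [(a, r) for a in AGE_GROUPS for r in RACE_GROUPS]


def generate_food_library(config: GeneratorConfig) -> pd.DataFrame:
    """Draw the food library: one row per food with densities and price.

    Cereals get codes with ready-to-eat prefixes (571xx...); milk rows come
    from the fixed type table; everything else is drawn uniformly from the
    class ranges.  Deterministic given ``config.seed``.
    """
    rng = _rng(config, 1)
    rows: list[dict] = []
    code_counters = {"rtec": 0, "breakfast_solid": 0, "beverage": 0,
                     "other_food": 0}
    for cls, spec in config.food_library_spec.items():
        if spec.count <= 0:
            raise ValueError(f"food class {cls!r} must have a positive count")
        if cls == "milk":
            for j, mt in enumerate(MILK_TYPES[: spec.count]):
                row = {f: 0.0 for f in DENSITY_FIELDS}
                row.update({k: v for k, v in mt.items()
                            if k in DENSITY_FIELDS})
                row.update({
                    "food_code": f"111{j:05d}",
                    "food_class": "milk",
                    "name": f"milk_{mt['name']}",
                    "energy_density": mt["energy_density"],
                    "price_per_100g": mt["price_per_100g"],
                    "is_beverage": True,
                    "is_milk": True,
                })
                rows.append(row)
            continue
        for j in range(spec.count):
            row = {f: 0.0 for f in DENSITY_FIELDS}
            for f, (lo, hi) in spec.densities.items():
                row[f] = float(rng.uniform(lo, hi))
            if cls == "rtec":
                prefix = ("571", "572", "573", "574")[j % 4]
                code = f"{prefix}{j:05d}"
            else:
                base = {"breakfast_solid": "531", "beverage": "921",
                        "other_food": "271"}[cls]
                code = f"{base}{j:05d}"
            code_counters[cls] = j
            row.update({
                "food_code": code,
                "food_class": cls,
                "name": f"{cls}_{j}",
                "energy_density": float(rng.uniform(*spec.energy_density)),
                "price_per_100g": float(rng.uniform(*spec.price_per_100g)),
                "is_beverage": cls == "beverage",
                "is_milk": False,
            })
            rows.append(row)
    # sugar added to coffee/tea: the canonical beverage addition
    sugar = {f: 0.0 for f in DENSITY_FIELDS}
    sugar.update({
        "food_code": SUGAR_ADDITION_CODE, "food_class": "addition",
        "name": "sugar", "energy_density": 3.87, "price_per_100g": 0.03,
        "is_beverage": False, "is_milk": False,
        "added_sugar_tspeq": 59.5,
    })
    rows.append(sugar)
    return pd.DataFrame(rows)


def stratum_popularity(config: GeneratorConfig,
                       rtec_codes: list[str]) -> dict[tuple[str, str], np.ndarray]:
    """Per-stratum cereal popularity vectors (Dirichlet, seed-determined)."""
    rng = _rng(config, 2)
    alpha = np.full(len(rtec_codes), config.rtec_popularity_alpha)
    return {s: rng.dirichlet(alpha) for s in _strata(config)}


def milk_type_weights(age_group: str, n_types: int = 3) -> np.ndarray:
    """Milk-type mix per age group: whole milk fades with age, skim grows."""
    idx = AGE_GROUPS.index(age_group)
    whole = max(0.05, 0.60 - 0.08 * idx)
    skim = min(0.80, 0.05 + 0.08 * idx)
    reduced = max(0.0, 1.0 - whole - skim)
    w = np.array([whole, reduced, skim][:n_types])
    return w / w.sum()


def _cv_to_sigma(cv: float) -> float:
    return float(np.sqrt(np.log(1.0 + cv * cv)))


def generate_cohort(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (participants, food_records, ground_truth).

    Participants are spread over ``n_strata`` design strata with two PSUs
    each and positive lognormal dietary weights.  Each person contributes
    one or two recall days; each person-day draws a breakfast behavior and
    full non-breakfast meals (lunch, dinner, possibly a snack).  All
    portion energies carry a shared lognormal person effect (between-person
    variation), a lognormal day effect (within-person variation), a weekend
    multiplier (weekend drawn Bernoulli(2/7)) and a second-recall mode
    multiplier.
    """
    library = generate_food_library(config)
    rtec_lib = library[library["food_class"] == "rtec"].reset_index(drop=True)
    milk_lib = library[library["food_class"] == "milk"].reset_index(drop=True)
    solid_lib = library[library["food_class"] == "breakfast_solid"].reset_index(drop=True)
    bev_lib = library[library["food_class"] == "beverage"].reset_index(drop=True)
    other_lib = library[library["food_class"] == "other_food"].reset_index(drop=True)
    sugar = library[library["food_class"] == "addition"].iloc[0]
    popularity = stratum_popularity(config, list(rtec_lib["food_code"]))

    rng = _rng(config, 3)
    n = config.n_participants
    ages = list(config.age_dist)
    races = list(config.race_dist)
    age_group = rng.choice(ages, size=n, p=list(config.age_dist.values()))
    race = rng.choice(races, size=n, p=list(config.race_dist.values()))

    age_years = np.empty(n, dtype=int)
    bounds = {"1-3": (1, 3), "4-8": (4, 8), "9-13": (9, 13), "14-19": (14, 19),
              "20-30": (20, 30), "31-50": (31, 50), "51-70": (51, 70),
              "71+": (71, 90)}
    for i, g in enumerate(age_group):
        lo, hi = bounds[g]
        age_years[i] = rng.integers(lo, hi + 1)

    stratum = rng.integers(0, config.n_strata, size=n)
    # alternate PSU assignment within each stratum so the two-PSU BRR
    # precondition holds even for small cohorts
    psu = np.empty(n, dtype=int)
    counters: dict[int, int] = {}
    for i, s in enumerate(stratum):
        c = counters.get(int(s), 0)
        psu[i] = 1 + (c % 2)
        counters[int(s)] = c + 1
    w1 = rng.lognormal(mean=0.0, sigma=0.3, size=n)
    n_recalls = 1 + (rng.random(n) < config.p_second_recall).astype(int)
    w2 = np.where(n_recalls == 2, w1 * rng.lognormal(0.0, 0.05, size=n), 0.0)
    wic = (age_years <= 4) & (rng.random(n) < 0.45)

    participants = pd.DataFrame({
        "participant_id": [f"P{i:06d}" for i in range(n)],
        "age_years": age_years,
        "sex": rng.choice(["male", "female"], size=n),
        "race_eth": race,
        "age_group": age_group,
        "wic_flag": wic,
        "stratum_id": [f"S{s:03d}" for s in stratum],
        "psu_id": psu,
        "weight_day1": w1,
        "weight_2day": w2,
        "n_recalls": n_recalls,
    })

    sigma_b = _cv_to_sigma(config.between_person_cv)
    sigma_w = _cv_to_sigma(config.within_person_cv)
    person_effect = rng.lognormal(-sigma_b ** 2 / 2.0, sigma_b, size=n)

    breakfast_occasions = np.array(["breakfast", "desayuno", "brunch"])
    breakfast_occ_p = np.array([0.85, 0.10, 0.05])

    cols: dict[str, list] = {c: [] for c in (
        "participant_id", "recall_day", "line_id", "food_code", "occasion",
        "grams", "energy_kcal", *DENSITY_FIELDS, "price_per_100g",
        "is_beverage", "is_beverage_addition", "is_rtec", "is_milk",
        "weekend",
    )}

    def emit(pid: str, day: int, line: int, food: pd.Series, kcal: float,
             occasion: str, weekend: int,
             is_bev_add: bool = False) -> None:
        cols["participant_id"].append(pid)
        cols["recall_day"].append(day)
        cols["line_id"].append(f"{pid}-d{day}-l{line}")
        cols["food_code"].append(food["food_code"])
        cols["occasion"].append(occasion)
        cols["grams"].append(kcal / food["energy_density"])
        cols["energy_kcal"].append(kcal)
        for f in DENSITY_FIELDS:
            cols[f].append(food[f] * kcal / 1000.0)
        cols["price_per_100g"].append(food["price_per_100g"])
        cols["is_beverage"].append(bool(food["is_beverage"]))
        cols["is_beverage_addition"].append(is_bev_add)
        cols["is_rtec"].append(str(food["food_code"]).startswith(
            ("571", "572", "573", "574")))
        cols["is_milk"].append(bool(food["is_milk"]))
        cols["weekend"].append(weekend)

    spec = config.food_library_spec
    behavior_p = np.array([
        config.p_skip_breakfast, config.p_beverage_only,
        config.p_rtec_breakfast, config.p_eligible,
    ])
    behavior_p = np.clip(behavior_p, 0.0, None)
    behavior_p /= behavior_p.sum()

    for i in range(n):
        pid = participants.at[i, "participant_id"]
        strat = (age_group[i], race[i])
        pop = popularity[strat]
        mtw = milk_type_weights(age_group[i], len(milk_lib))
        for day in range(1, int(n_recalls[i]) + 1):
            weekend = int(rng.random() < 2.0 / 7.0)
            mult = (
                person_effect[i]
                * rng.lognormal(-sigma_w ** 2 / 2.0, sigma_w)
                * (config.weekend_effect if weekend else 1.0)
                * (config.recall2_effect if day == 2 else 1.0)
            )
            line = 0

            def portion(cls: str) -> float:
                lo, hi = spec[cls].portion_kcal
                return float(rng.uniform(lo, hi)) * mult

            behavior = rng.choice(4, p=behavior_p)
            b_occ = str(rng.choice(breakfast_occasions, p=breakfast_occ_p))
            if behavior == 1:  # beverage only
                bev = bev_lib.iloc[int(rng.integers(len(bev_lib)))]
                emit(pid, day, (line := line + 1), bev, portion("beverage"),
                     b_occ, weekend)
                if rng.random() < config.p_beverage_addition:
                    emit(pid, day, (line := line + 1), sugar,
                         float(rng.uniform(15, 35)) * mult, b_occ, weekend,
                         is_bev_add=True)
            elif behavior == 2:  # cereal consumer
                cereal = rtec_lib.iloc[int(rng.choice(len(rtec_lib), p=pop))]
                ck = portion("rtec")
                emit(pid, day, (line := line + 1), cereal, ck, b_occ, weekend)
                if rng.random() < config.p_milk_with_cereal:
                    milk = milk_lib.iloc[int(rng.choice(len(milk_lib), p=mtw))]
                    s = config.milk_energy_share
                    emit(pid, day, (line := line + 1), milk,
                         ck * s / (1.0 - s), b_occ, weekend)
            elif behavior == 3:  # eligible solid-food breakfast
                n_items = 1 + int(rng.binomial(2, 0.5))
                for _ in range(n_items):
                    food = solid_lib.iloc[int(rng.integers(len(solid_lib)))]
                    emit(pid, day, (line := line + 1), food,
                         portion("breakfast_solid"), b_occ, weekend)
                if rng.random() < config.p_breakfast_beverage:
                    bev = bev_lib.iloc[int(rng.integers(len(bev_lib)))]
                    emit(pid, day, (line := line + 1), bev,
                         portion("beverage"), b_occ, weekend)
                    if rng.random() < config.p_beverage_addition:
                        emit(pid, day, (line := line + 1), sugar,
                             float(rng.uniform(15, 35)) * mult, b_occ,
                             weekend, is_bev_add=True)
            # non-breakfast meals
            for occasion, lo_n, hi_n in (("lunch", 2, 4), ("dinner", 2, 4)):
                for _ in range(int(rng.integers(lo_n, hi_n + 1))):
                    food = other_lib.iloc[int(rng.integers(len(other_lib)))]
                    emit(pid, day, (line := line + 1), food,
                         portion("other_food"), occasion, weekend)
            if rng.random() < 0.5:
                food = other_lib.iloc[int(rng.integers(len(other_lib)))]
                emit(pid, day, (line := line + 1), food,
                     portion("other_food"), "snack", weekend)

    records = pd.DataFrame(cols)
    truth = analytic_expected_deltas(config, library)
    return participants, records, truth


def analytic_expected_deltas(
    config: GeneratorConfig, library: pd.DataFrame | None = None
) -> GroundTruth:
    """Closed-form expected per-capita outcome changes under both models.

    For any density field, the expected per-person-day change is::

        E[delta] = p_eligible * E[replaced kcal] * (composite - replaced) / 1000

    where ``composite`` is the population-averaged composite density
    (stratum popularity vectors mixed by the age/race distribution; for
    Model 2 a cereal+milk blend at the deterministic milk fraction
    ``p_milk * milk_energy_share``) and ``replaced`` is the mean density of
    the breakfast-solid class.  ``E[replaced kcal]`` averages the portion
    draw, item count, weekend multiplier and recall-mode multiplier.
    """
    if library is None:
        library = generate_food_library(config)
    rtec_lib = library[library["food_class"] == "rtec"].reset_index(drop=True)
    milk_lib = library[library["food_class"] == "milk"].reset_index(drop=True)
    solid_lib = library[library["food_class"] == "breakfast_solid"]
    popularity = stratum_popularity(config, list(rtec_lib["food_code"]))

    comp_dens: dict[tuple[str, str], dict[str, float]] = {}
    milk_dens: dict[tuple[str, str], dict[str, float]] = {}
    for strat, pop in popularity.items():
        comp_dens[strat] = {
            f: float(pop @ rtec_lib[f].to_numpy()) for f in DENSITY_FIELDS
        }
        mtw = milk_type_weights(strat[0], len(milk_lib))
        milk_dens[strat] = {
            f: float(mtw @ milk_lib[f].to_numpy()) for f in DENSITY_FIELDS
        }

    # population mixture over strata (age and race independent)
    p_strat = {
        (a, r): config.age_dist[a] * config.race_dist[r]
        for a in config.age_dist for r in config.race_dist
    }
    pop_comp = {
        f: sum(p_strat[s] * comp_dens[s][f] for s in p_strat)
        for f in DENSITY_FIELDS
    }
    pop_milk = {
        f: sum(p_strat[s] * milk_dens[s][f] for s in p_strat)
        for f in DENSITY_FIELDS
    }
    repl_mean = {f: float(solid_lib[f].mean()) for f in DENSITY_FIELDS}

    lo, hi = config.food_library_spec["breakfast_solid"].portion_kcal
    f_weekend = 5.0 / 7.0 + 2.0 / 7.0 * config.weekend_effect
    p2 = config.p_second_recall
    f_recall = p2 * (1.0 + config.recall2_effect) / 2.0 + (1.0 - p2)
    expected_kcal = 2.0 * (lo + hi) / 2.0 * f_weekend * f_recall

    m = config.p_milk_with_cereal * config.milk_energy_share
    blend = {
        f: (1.0 - m) * pop_comp[f] + m * pop_milk[f] for f in DENSITY_FIELDS
    }
    scale = config.p_eligible * expected_kcal / 1000.0
    delta1 = {f: scale * (pop_comp[f] - repl_mean[f]) for f in DENSITY_FIELDS}
    delta2 = {f: scale * (blend[f] - repl_mean[f]) for f in DENSITY_FIELDS}

    return GroundTruth(
        composite_densities=comp_dens,
        milk_densities=milk_dens,
        rtec_popularity={
            s: dict(zip(rtec_lib["food_code"], map(float, pop)))
            for s, pop in popularity.items()
        },
        p_eligible=config.p_eligible,
        expected_replaced_kcal=2.0 * (lo + hi) / 2.0,
        expected_delta_model1=delta1,
        expected_delta_model2=delta2,
    )


def simulate_intake_days(
    n_persons: int,
    sigma_between: float,
    sigma_within: float,
    mu: float = 2.5,
    beta_weekend: float = 0.0,
    beta_recall2: float = 0.0,
    p_second_recall: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Direct lognormal day-intake simulator for measurement-error checks.

    Day value = exp(mu + b_weekend*weekend + b_recall2*recall2 + u_i + e_id)
    with u ~ N(0, sigma_between^2) and e ~ N(0, sigma_within^2).  Returns a
    tidy frame with columns participant_id, value, weekend, recall2.
    """
    rng = np.random.default_rng(seed)
    u = rng.normal(0.0, sigma_between, size=n_persons)
    rows = []
    for i in range(n_persons):
        n_days = 2 if rng.random() < p_second_recall else 1
        for day in range(1, n_days + 1):
            weekend = int(rng.random() < 2.0 / 7.0)
            recall2 = int(day == 2)
            y = (mu + beta_weekend * weekend + beta_recall2 * recall2
                 + u[i] + rng.normal(0.0, sigma_within))
            rows.append((f"P{i:06d}", float(np.exp(y)), weekend, recall2))
    return pd.DataFrame(rows, columns=["participant_id", "value", "weekend", "recall2"])
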
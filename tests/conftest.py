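import numpy as np
import pandas as pd
import pytest

from dietswap.schema import DENSITY_FIELDS


def make_participant(pid="P1", age=30, race="NHWhite", stratum="S0", psu=1,
                     w1=1.0, w2=1.0, n_recalls=2, sex="male", wic=False):
    from dietswap.schema import age_to_group
    return {
        "participant_id": pid, "age_years": age, "sex": sex, "race_eth": race,
        "age_group": age_to_group(age), "wic_flag": wic, "stratum_id": stratum,
        "psu_id": psu, "weight_day1": w1, "weight_2day": w2,
        "n_recalls": n_recalls,
    }


def make_record(pid="P1", day=1, line="l1", code="53100000", occasion="breakfast",
                kcal=200.0, grams=None, energy_density=2.0, price=0.5,
                beverage=False, addition=False, milk=False, **densities):
    """One food record; keyword densities are per-1000-kcal and scaled."""
    kcal = float(kcal)
    rec = {f: densities.get(f, 0.0) * kcal / 1000.0 for f in DENSITY_FIELDS}
    rec.update({
        "participant_id": pid, "recall_day": day, "line_id": line,
        "food_code": code, "occasion": occasion,
        "grams": grams if grams is not None else max(kcal, 1.0) / energy_density,
        "energy_kcal": kcal, "price_per_100g": price,
        "is_beverage": beverage, "is_beverage_addition": addition,
        "is_rtec": str(code).startswith(("571", "572", "573", "574")),
        "is_milk": milk,
    })
    return rec


@pytest.fixture
def toy_participants():
    return pd.DataFrame([
        make_participant("P1", age=30, stratum="S0", psu=1),
        make_participant("P2", age=35, stratum="S0", psu=2),
        make_participant("P3", age=10, race="NHBlack", stratum="S1", psu=1),
        make_participant("P4", age=12, race="NHBlack", stratum="S1", psu=2,
                         n_recalls=1, w2=0.0),
    ])


@pytest.fixture
def toy_records():
    return pd.DataFrame([
        make_record("P1", 1, "l1", "57100001", kcal=150, energy_density=3.75,
                    whole_grain_ozeq=4.0, fiber_g=10.0),
        make_record("P1", 1, "l2", "11100000", kcal=60, energy_density=0.5,
                    occasion="breakfast", beverage=True, milk=True,
                    dairy_cupeq=8.0),
        make_record("P1", 2, "l1", "53100000", kcal=300, solid_fat_g=15.0),
        make_record("P2", 1, "l1", "53100001", kcal=250, solid_fat_g=20.0),
        make_record("P2", 1, "l2", "92100000", kcal=100, occasion="breakfast",
                    beverage=True, added_sugar_tspeq=12.0),
        make_record("P3", 1, "l1", "57200002", kcal=180, energy_density=3.6,
                    whole_grain_ozeq=1.0, added_sugar_tspeq=9.0),
        make_record("P3", 1, "l2", "27100000", kcal=500, occasion="dinner"),
        make_record("P4", 1, "l1", "92100000", kcal=120, occasion="breakfast",
                    beverage=True),
    ])


@pytest.fixture(scope="session")
def small_cohort():
    """Seed-fixed synthetic cohort shared by the slower integration tests."""
    from dietswap.synthetic_cohort import GeneratorConfig, generate_cohort
    cfg = GeneratorConfig(seed=7, n_participants=1200)
    participants, records, truth = generate_cohort(cfg)
    return cfg, participants, records, truth
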
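"""Isocaloric breakfast substitution: Model 1 (cereal) and Model 2 (+ milk).

A person-day is eligible when it has at least one breakfast-class record
(breakfast, desayuno or brunch) that is a solid food — not a beverage, not
a beverage addition — and no ready-to-eat cereal at a breakfast-class
occasion (diets of existing cereal consumers are left untouched).  The
eligible solid breakfast energy is removed and replaced, calorie for
calorie, by the stratum's composite cereal (Model 1) or by a deterministic
cereal+milk mix (Model 2).

Model 2 allocates ``replaced_kcal * p_milk * milk_energy_share`` kcal to
milk — the expected value of the stratum's milk-with-cereal behavior —
rather than a stochastic per-day assignment; population means coincide and
results need no seed.  Eligibility is assessed independently per recall
day: the same person can be eligible on one day and not the other.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd

from .composite_profiles import CompositeProfile, MilkProfile, Stratum
from .schema import BREAKFAST_CLASS, DENSITY_FIELDS

#: synthetic record food codes (cereal keeps an RTEC-class prefix)
COMPOSITE_RTEC_CODE = "57199999"
COMPOSITE_MILK_CODE = "11199999"


@dataclasses.dataclass
class EligibilityStatus:
    person_day: tuple[str, int]
    status: str  # skipped_breakfast | beverage_only | rtec_at_breakfast | eligible
    replaced_kcal: float
    replaced_record_ids: frozenset

    def __post_init__(self) -> None:
        if (self.status == "eligible") != (self.replaced_kcal > 0):
            raise ValueError("replaced_kcal > 0 iff status is eligible")


@dataclasses.dataclass
class SubstitutedDay:
    person_day: tuple[str, int]
    records: pd.DataFrame
    model_id: str  # observed | model1 | model2


def assess_eligibility(day_records: pd.DataFrame) -> EligibilityStatus:
    """Classify one person-day and measure its replaceable breakfast energy.

    Precedence: no breakfast-class record -> ``skipped_breakfast``; any
    cereal at a breakfast-class occasion -> ``rtec_at_breakfast``; only
    beverages/beverage additions at breakfast -> ``beverage_only``; else
    ``eligible`` with ``replaced_kcal`` the summed energy of the solid
    breakfast-class records.  A breakfast of a cappuccino plus a doughnut is
    eligible for the doughnut's calories only.
    """
    key = _person_day_key(day_records)
    bc = day_records["occasion"].isin(BREAKFAST_CLASS)
    if not bc.any():
        return EligibilityStatus(key, "skipped_breakfast", 0.0, frozenset())
    if (bc & day_records["is_rtec"]).any():
        return EligibilityStatus(key, "rtec_at_breakfast", 0.0, frozenset())
    solid = bc & ~day_records["is_beverage"] & ~day_records["is_beverage_addition"]
    if not solid.any():
        return EligibilityStatus(key, "beverage_only", 0.0, frozenset())
    kcal = float(day_records.loc[solid, "energy_kcal"].sum())
    ids = frozenset(day_records.loc[solid, "line_id"])
    if kcal <= 0:
        # zero-calorie solids (e.g. water-packed items) leave nothing to swap
        return EligibilityStatus(key, "beverage_only", 0.0, frozenset())
    return EligibilityStatus(key, "eligible", kcal, ids)


def _person_day_key(day_records: pd.DataFrame) -> tuple[str, int]:
    keys = day_records[["participant_id", "recall_day"]].drop_duplicates()
    if len(keys) != 1:
        raise ValueError("records span more than one person-day")
    return (str(keys.iloc[0, 0]), int(keys.iloc[0, 1]))


def _synthetic_record(template: pd.DataFrame, key: tuple[str, int], kcal: float,
                      code: str, dens: dict[str, float], energy_density: float,
                      price_per_1000kcal: float, is_milk: bool) -> dict:
    grams = kcal / energy_density
    rec = {c: 0.0 for c in template.columns}
    rec.update({
        "participant_id": key[0],
        "recall_day": key[1],
        "line_id": f"syn-{code}-{key[0]}-{key[1]}",
        "food_code": code,
        "occasion": "breakfast",
        "grams": grams,
        "energy_kcal": kcal,
        "price_per_100g": price_per_1000kcal * energy_density / 10.0,
        "is_beverage": False,
        "is_beverage_addition": False,
        "is_rtec": not is_milk,
        "is_milk": is_milk,
        "synthetic": True,
    })
    for f in DENSITY_FIELDS:
        rec[f] = dens[f] * kcal / 1000.0
    return rec


def _apply(day_records: pd.DataFrame, composite: CompositeProfile,
           milk: MilkProfile | None, model_id: str) -> SubstitutedDay:
    key = _person_day_key(day_records)
    elig = assess_eligibility(day_records)
    out = day_records.copy()
    if "synthetic" not in out.columns:
        out["synthetic"] = False
    if elig.status != "eligible":
        return SubstitutedDay(key, out, model_id)

    kept = out[~out["line_id"].isin(elig.replaced_record_ids)]
    milk_kcal = 0.0
    if milk is not None:
        milk_kcal = elig.replaced_kcal * milk.p_milk * milk.milk_energy_share
    cereal_kcal = elig.replaced_kcal - milk_kcal

    new_rows = [
        _synthetic_record(
            out, key, cereal_kcal, COMPOSITE_RTEC_CODE,
            composite.density_per_1000kcal, composite.energy_density_kcal_per_g,
            composite.price_per_1000kcal, is_milk=False,
        )
    ]
    if milk is not None and milk_kcal > 0:
        new_rows.append(
            _synthetic_record(
                out, key, milk_kcal, COMPOSITE_MILK_CODE,
                milk.density_per_1000kcal, milk.energy_density_kcal_per_g,
                milk.price_per_1000kcal, is_milk=True,
            )
        )
    records = pd.concat([kept, pd.DataFrame(new_rows)], ignore_index=True)
    return SubstitutedDay(key, records, model_id)


def apply_model1(day_records: pd.DataFrame,
                 composite: CompositeProfile) -> SubstitutedDay:
    """Replace the day's solid breakfast energy with composite cereal."""
    return _apply(day_records, composite, None, "model1")


def apply_model2(day_records: pd.DataFrame, composite: CompositeProfile,
                 milk: MilkProfile) -> SubstitutedDay:
    """Replace solid breakfast energy with the cereal + milk expected mix."""
    return _apply(day_records, composite, milk, "model2")


# ---------------------------------------------------------------------------
# cohort-scale vectorized application


def assess_eligibility_all(records: pd.DataFrame) -> pd.DataFrame:
    """Eligibility status and replaced kcal for every person-day at once.

    Returns one row per (participant_id, recall_day) with columns
    ``status`` and ``replaced_kcal``; semantics identical to
    :func:`assess_eligibility`.
    """
    keys = ["participant_id", "recall_day"]
    bc = records["occasion"].isin(BREAKFAST_CLASS)
    solid = bc & ~records["is_beverage"] & ~records["is_beverage_addition"]
    g = records.assign(
        _bc=bc,
        _rtec_bc=bc & records["is_rtec"],
        _solid_kcal=records["energy_kcal"].where(solid, 0.0),
    ).groupby(keys, as_index=False).agg(
        has_bc=("_bc", "any"),
        has_rtec_bc=("_rtec_bc", "any"),
        replaced_kcal=("_solid_kcal", "sum"),
    )
    status = np.select(
        [~g["has_bc"], g["has_rtec_bc"], g["replaced_kcal"] <= 0],
        ["skipped_breakfast", "rtec_at_breakfast", "beverage_only"],
        default="eligible",
    )
    g["status"] = status
    g.loc[g["status"] != "eligible", "replaced_kcal"] = 0.0
    return g[keys + ["status", "replaced_kcal"]]


def apply_model_all(
    records: pd.DataFrame,
    participants: pd.DataFrame,
    composites: Mapping[Stratum, CompositeProfile],
    milks: Mapping[Stratum, MilkProfile] | None = None,
) -> pd.DataFrame:
    """Apply Model 1 (``milks`` is None) or Model 2 to a whole cohort.

    Equivalent to calling the per-day operations for every person-day, but
    built with bulk column operations.  Missing composite for a person's
    stratum is fatal; fallback profiles are resolved upstream.
    """
    keys = ["participant_id", "recall_day"]
    elig = assess_eligibility_all(records)
    eligible = elig[elig["status"] == "eligible"]

    part = participants.set_index("participant_id")
    strata = {
        pid: (part.at[pid, "age_group"], part.at[pid, "race_eth"])
        for pid in eligible["participant_id"].unique()
    }
    missing = {s for s in strata.values() if s not in composites}
    if missing:
        raise KeyError(f"no composite profile for strata: {sorted(missing)}")
    if milks is not None:
        missing = {s for s in strata.values() if s not in milks}
        if missing:
            raise KeyError(f"no milk profile for strata: {sorted(missing)}")

    out = records.copy()
    if "synthetic" not in out.columns:
        out["synthetic"] = False

    bc = out["occasion"].isin(BREAKFAST_CLASS)
    solid = bc & ~out["is_beverage"] & ~out["is_beverage_addition"]
    elig_keys = set(map(tuple, eligible[keys].itertuples(index=False)))
    day_key = list(map(tuple, out[keys].itertuples(index=False)))
    replace_mask = solid & pd.Series(
        [k in elig_keys for k in day_key], index=out.index
    )
    kept = out[~replace_mask]

    new_rows: list[dict] = []
    for _, row in eligible.iterrows():
        pid, day = row["participant_id"], int(row["recall_day"])
        stratum = strata[pid]
        comp = composites[stratum]
        kcal = float(row["replaced_kcal"])
        milk_kcal = 0.0
        if milks is not None:
            m = milks[stratum]
            milk_kcal = kcal * m.p_milk * m.milk_energy_share
        new_rows.append(
            _synthetic_record(
                out, (pid, day), kcal - milk_kcal, COMPOSITE_RTEC_CODE,
                comp.density_per_1000kcal, comp.energy_density_kcal_per_g,
                comp.price_per_1000kcal, is_milk=False,
            )
        )
        if milks is not None and milk_kcal > 0:
            m = milks[stratum]
            new_rows.append(
                _synthetic_record(
                    out, (pid, day), milk_kcal, COMPOSITE_MILK_CODE,
                    m.density_per_1000kcal, m.energy_density_kcal_per_g,
                    m.price_per_1000kcal, is_milk=True,
                )
            )
    if not new_rows:
        return kept.reset_index(drop=True)
    return pd.concat([kept, pd.DataFrame(new_rows)], ignore_index=True)
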
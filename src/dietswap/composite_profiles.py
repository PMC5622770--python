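"""Frequency-weighted composite cereal and milk profiles per stratum.

A stratum is an (age group, race/ethnicity) cell.  The composite
ready-to-eat cereal (RTEC) for a stratum is the convex combination of the
cereals its members actually ate, with component weights given by each
cereal's survey-weighted share of the stratum's total RTEC energy.  Because
the substitution is energy-based, energy-share weighting makes the
composite's per-1000-kcal densities equal the stratum's realized mean RTEC
density; an occasion-count weighting mode is retained for sensitivity
analyses.

The milk profile captures how the stratum consumes milk with cereal: the
probability that a cereal occasion includes milk, the conditional energy
share milk contributes to the cereal+milk combination, and the density
profile of the milk types used.  A milk record counts as co-consumed iff it
shares the person, recall day and eating occasion with an RTEC record —
a documented approximation to combination-code linkage, which the reduced
schema does not carry.

Empty strata are filled by a deterministic fallback chain:
stratum -> same age group pooled across races -> national pool.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .schema import AGE_GROUPS, DENSITY_FIELDS, RACE_GROUPS

logger = logging.getLogger(__name__)

Stratum = tuple[str, str]  # (age_group, race_eth)


@dataclasses.dataclass
class CompositeProfile:
    """Per-stratum composite cereal: component mix and per-energy densities."""

    stratum: Stratum
    component_weights: dict[str, float]
    density_per_1000kcal: dict[str, float]
    energy_density_kcal_per_g: float
    price_per_1000kcal: float
    fallback_level: str = "stratum"  # stratum | age_group | national

    def __post_init__(self) -> None:
        total = sum(self.component_weights.values())
        if self.component_weights and abs(total - 1.0) > 1e-9:
            raise ValueError(f"component weights sum to {total}, expected 1")


@dataclasses.dataclass
class MilkProfile:
    """Per-stratum milk-with-cereal usage and milk-composite densities."""

    stratum: Stratum
    p_milk: float
    milk_energy_share: float
    density_per_1000kcal: dict[str, float]
    energy_density_kcal_per_g: float
    price_per_1000kcal: float
    fallback_level: str = "stratum"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_milk <= 1.0:
            raise ValueError(f"p_milk out of [0, 1]: {self.p_milk}")
        if not 0.0 <= self.milk_energy_share < 1.0:
            raise ValueError(f"milk_energy_share out of [0, 1): {self.milk_energy_share}")


def grams_for_energy(kcal: float, energy_density: float) -> float:
    """Portion mass (g) delivering ``kcal`` at ``energy_density`` kcal/g."""
    if energy_density <= 0:
        raise ValueError(f"energy_density must be positive, got {energy_density}")
    if kcal == 0:
        return 0.0
    return kcal / energy_density


def _base_weight(participants: pd.DataFrame) -> pd.Series:
    """Survey weight used for profile construction (two-day when present)."""
    w = participants["weight_2day"].where(
        participants["weight_2day"] > 0, participants["weight_day1"]
    )
    return pd.Series(w.values, index=participants["participant_id"].values)


def _attach_weights(records: pd.DataFrame, participants: pd.DataFrame,
                    survey_weighted: bool) -> pd.DataFrame:
    out = records.copy()
    if survey_weighted:
        out["_w"] = out["participant_id"].map(_base_weight(participants)).astype(float)
    else:
        out["_w"] = 1.0
    out["_age_group"] = out["participant_id"].map(
        pd.Series(participants["age_group"].values,
                  index=participants["participant_id"].values)
    )
    out["_race"] = out["participant_id"].map(
        pd.Series(participants["race_eth"].values,
                  index=participants["participant_id"].values)
    )
    return out


def _pool_composite(pool: pd.DataFrame, stratum: Stratum,
                    fallback_level: str) -> CompositeProfile:
    """Energy-share-weighted composite of the RTEC records in ``pool``."""
    we = pool["_w"] * pool["energy_kcal"]
    total_e = we.sum()
    by_code = we.groupby(pool["food_code"]).sum()
    weights = (by_code / total_e).to_dict()
    dens = {
        f: float((pool[f] * pool["_w"]).sum() / total_e * 1000.0)
        for f in DENSITY_FIELDS
    }
    total_g = (pool["_w"] * pool["grams"]).sum()
    price = (pool["_w"] * pool["grams"] / 100.0 * pool["price_per_100g"]).sum()
    return CompositeProfile(
        stratum=stratum,
        component_weights={k: float(v) for k, v in weights.items()},
        density_per_1000kcal=dens,
        energy_density_kcal_per_g=float(total_e / total_g),
        price_per_1000kcal=float(price / total_e * 1000.0),
        fallback_level=fallback_level,
    )


def build_rtec_composite(
    records: pd.DataFrame,
    participants: pd.DataFrame,
    fallback_policy: str = "chain",
    survey_weighted: bool = True,
) -> dict[Stratum, CompositeProfile]:
    """Build the composite cereal profile for every stratum.

    Component weight of cereal *c* in a stratum is the survey-weighted energy
    from *c* divided by survey-weighted energy from all cereals eaten by that
    stratum, over all eating occasions of both recall days (the composite
    reflects total cereal consumption, not just breakfast).  Densities are
    the matching energy-share-weighted means, i.e. pooled weighted ratios.

    ``fallback_policy='chain'`` fills strata without any cereal records from
    the same age group pooled across races, then from the national pool;
    ``'none'`` leaves such strata out of the result.
    """
    rtec = records[records["is_rtec"]]
    if rtec.empty:
        raise ValueError("no RTEC records in dataset; composite undefined")
    rtec = _attach_weights(rtec, participants, survey_weighted)

    national = _pool_composite(rtec, ("national", "national"), "national")
    by_age: dict[str, pd.DataFrame] = {
        str(a): g for a, g in rtec.groupby("_age_group")
    }
    by_stratum: dict[Stratum, pd.DataFrame] = {
        (str(a), str(r)): g for (a, r), g in rtec.groupby(["_age_group", "_race"])
    }

    out: dict[Stratum, CompositeProfile] = {}
    for age in AGE_GROUPS:
        for race in RACE_GROUPS:
            stratum = (age, race)
            if stratum in by_stratum:
                out[stratum] = _pool_composite(by_stratum[stratum], stratum, "stratum")
            elif fallback_policy == "chain":
                if age in by_age:
                    prof = _pool_composite(by_age[age], stratum, "age_group")
                else:
                    prof = dataclasses.replace(national, stratum=stratum)
                logger.info(
                    "stratum %s has no RTEC records; using %s pool",
                    stratum, prof.fallback_level,
                )
                out[stratum] = prof
    return out


def _co_consumed_milk(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split occasion-level RTEC/milk energy and identify co-consumed milk rows.

    Returns (occasion table with rtec_kcal/milk_kcal per RTEC-containing
    person-day-occasion, milk records co-consumed with cereal).
    """
    keys = ["participant_id", "recall_day", "occasion"]
    rtec_occ = (
        records[records["is_rtec"]]
        .groupby(keys, as_index=False)["energy_kcal"].sum()
        .rename(columns={"energy_kcal": "rtec_kcal"})
    )
    milk = records[records["is_milk"] & ~records["is_rtec"]]
    milk_occ = (
        milk.groupby(keys, as_index=False)["energy_kcal"].sum()
        .rename(columns={"energy_kcal": "milk_kcal"})
    )
    occ = rtec_occ.merge(milk_occ, on=keys, how="left")
    occ["milk_kcal"] = occ["milk_kcal"].fillna(0.0)
    co_milk = milk.merge(rtec_occ[keys], on=keys, how="inner")
    return occ, co_milk


def _pool_milk(occ: pd.DataFrame, co_milk: pd.DataFrame, stratum: Stratum,
               fallback_level: str) -> MilkProfile | None:
    if occ.empty:
        return None
    w = occ["_w"]
    p_milk = float((w * (occ["milk_kcal"] > 0)).sum() / w.sum())
    with_milk = occ[occ["milk_kcal"] > 0]
    if with_milk.empty:
        share = 0.0
    else:
        frac = with_milk["milk_kcal"] / (with_milk["milk_kcal"] + with_milk["rtec_kcal"])
        share = float((with_milk["_w"] * frac).sum() / with_milk["_w"].sum())
    if co_milk.empty:
        dens = {f: 0.0 for f in DENSITY_FIELDS}
        ed, price = 1.0, 0.0
    else:
        we = co_milk["_w"] * co_milk["energy_kcal"]
        total_e = we.sum()
        dens = {
            f: float((co_milk[f] * co_milk["_w"]).sum() / total_e * 1000.0)
            for f in DENSITY_FIELDS
        }
        ed = float(total_e / (co_milk["_w"] * co_milk["grams"]).sum())
        price = float(
            (co_milk["_w"] * co_milk["grams"] / 100.0 * co_milk["price_per_100g"]).sum()
            / total_e * 1000.0
        )
    return MilkProfile(
        stratum=stratum,
        p_milk=p_milk,
        milk_energy_share=min(share, 1.0 - 1e-12),
        density_per_1000kcal=dens,
        energy_density_kcal_per_g=ed,
        price_per_1000kcal=price,
        fallback_level=fallback_level,
    )


def build_milk_profile(
    records: pd.DataFrame,
    participants: pd.DataFrame,
    co_consumption_rule: str = "same_occasion",
    fallback_policy: str = "chain",
    survey_weighted: bool = True,
) -> dict[Stratum, MilkProfile]:
    """Build the milk-with-cereal profile for every stratum.

    Only milk consumed with cereal enters the profile: under the default
    rule a milk record counts iff it shares person, recall day and occasion
    with an RTEC record.  ``p_milk`` is the survey-weighted share of
    RTEC-containing person-day-occasions that include milk;
    ``milk_energy_share`` is the survey-weighted mean of milk kcal over
    combined milk+cereal kcal among occasions with milk (conditional on
    use).
    """
    if co_consumption_rule != "same_occasion":
        raise ValueError(f"unknown co_consumption_rule: {co_consumption_rule}")
    recs = _attach_weights(records, participants, survey_weighted)
    occ, co_milk = _co_consumed_milk(recs)
    # occasion table loses the per-record metadata; re-attach stratum/weight
    pid_map = recs.drop_duplicates("participant_id").set_index("participant_id")
    for col in ("_w", "_age_group", "_race"):
        occ[col] = occ["participant_id"].map(pid_map[col])

    national = _pool_milk(occ, co_milk, ("national", "national"), "national")
    if national is None:
        raise ValueError("no RTEC occasions in dataset; milk profile undefined")

    out: dict[Stratum, MilkProfile] = {}
    for age in AGE_GROUPS:
        for race in RACE_GROUPS:
            stratum = (age, race)
            occ_s = occ[(occ["_age_group"] == age) & (occ["_race"] == race)]
            co_s = co_milk[
                (co_milk["_age_group"] == age) & (co_milk["_race"] == race)
            ]
            prof = _pool_milk(occ_s, co_s, stratum, "stratum")
            if prof is None and fallback_policy == "chain":
                occ_a = occ[occ["_age_group"] == age]
                co_a = co_milk[co_milk["_age_group"] == age]
                prof = _pool_milk(occ_a, co_a, stratum, "age_group")
                if prof is None:
                    prof = dataclasses.replace(national, stratum=stratum)
                logger.info(
                    "stratum %s has no RTEC occasions; milk profile from %s pool",
                    stratum, prof.fallback_level,
                )
            if prof is not None:
                out[stratum] = prof
    return out


def profiles_to_dict(
    composites: Mapping[Stratum, CompositeProfile],
    milks: Mapping[Stratum, MilkProfile] | None = None,
) -> dict:
    """JSON-serializable form of the profile tables (the module contract)."""
    out: dict = {"rtec": {}, "milk": {}}
    for (age, race), p in composites.items():
        out["rtec"][f"{age}|{race}"] = {
            "component_weights": p.component_weights,
            "density_per_1000kcal": p.density_per_1000kcal,
            "energy_density_kcal_per_g": p.energy_density_kcal_per_g,
            "price_per_1000kcal": p.price_per_1000kcal,
            "fallback_level": p.fallback_level,
        }
    for (age, race), m in (milks or {}).items():
        out["milk"][f"{age}|{race}"] = {
            "p_milk": m.p_milk,
            "milk_energy_share": m.milk_energy_share,
            "density_per_1000kcal": m.density_per_1000kcal,
            "energy_density_kcal_per_g": m.energy_density_kcal_per_g,
            "price_per_1000kcal": m.price_per_1000kcal,
            "fallback_level": m.fallback_level,
        }
    return out


def profiles_from_dict(d: dict) -> tuple[
    dict[Stratum, CompositeProfile], dict[Stratum, MilkProfile]
]:
    composites: dict[Stratum, CompositeProfile] = {}
    milks: dict[Stratum, MilkProfile] = {}
    for key, p in d.get("rtec", {}).items():
        age, race = key.split("|")
        composites[(age, race)] = CompositeProfile(
            stratum=(age, race),
            component_weights=p["component_weights"],
            density_per_1000kcal=p["density_per_1000kcal"],
            energy_density_kcal_per_g=p["energy_density_kcal_per_g"],
            price_per_1000kcal=p["price_per_1000kcal"],
            fallback_level=p.get("fallback_level", "stratum"),
        )
    for key, m in d.get("milk", {}).items():
        age, race = key.split("|")
        milks[(age, race)] = MilkProfile(
            stratum=(age, race),
            p_milk=m["p_milk"],
            milk_energy_share=m["milk_energy_share"],
            density_per_1000kcal=m["density_per_1000kcal"],
            energy_density_kcal_per_g=m["energy_density_kcal_per_g"],
            price_per_1000kcal=m["price_per_1000kcal"],
            fallback_level=m.get("fallback_level", "stratum"),
        )
    return composites, milks
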
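"""End-to-end scenario runs: observed vs. Model 1 vs. Model 2.

``run_all`` executes profile construction, substitution, person-day
aggregation, survey-weighted estimation with Fay-BRR standard errors,
difference tests and effect classification, the population-ratio HEI-2010
on day-1 recalls, and (optionally) usual-intake distributions for selected
outcomes.  Everything is a pure function of the input tables and the run
configuration.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd

from . import composite_profiles, day_metrics, hei2010, recall_io, substitution
from . import survey_stats, usual_intake
from .day_metrics import TOTAL_FIELDS
from .schema import AGE_GROUPS

logger = logging.getLogger(__name__)

DEFAULT_OUTCOMES: tuple[str, ...] = (
    "energy_kcal", "whole_grain_ozeq", "refined_grain_ozeq", "dairy_cupeq",
    "fiber_g", "vitaminD_ug", "calcium_mg", "potassium_mg", "magnesium_mg",
    "iron_mg", "folic_acid_ug", "vitaminB12_ug", "solid_fat_g",
    "added_sugar_tspeq", "sofaas_kcal", "diet_cost_usd",
)


@dataclasses.dataclass
class UsualOutcomeSpec:
    outcome: str
    episodic: str = "auto"          # "auto" | "yes" | "no"
    thresholds: tuple[float, ...] = ()


@dataclasses.dataclass
class RunConfig:
    outcomes: tuple[str, ...] = DEFAULT_OUTCOMES
    fay: float = 0.7
    n_replicates: int = 32
    seed: int = 0
    hei_standards_path: str | None = None
    usual_outcomes: tuple[UsualOutcomeSpec, ...] = (
        UsualOutcomeSpec("fiber_g", "no", (25.0,)),
        UsualOutcomeSpec("whole_grain_ozeq", "auto", (3.0,)),
    )
    usual_n_mc: int = 20000
    inflation_factors: dict[str, float] = dataclasses.field(default_factory=dict)
    subgroups: str = "full"          # "full" | "total_only"


@dataclasses.dataclass
class RunResult:
    results: pd.DataFrame            # tidy long table of estimates/tests
    hei: pd.DataFrame                # population-ratio HEI per subgroup/scenario
    usual: dict                      # usual-intake summaries per outcome/scenario
    eligibility: dict                # filter-stage accounting
    profiles: dict                   # composite + milk profiles (serializable)


def _person_weight(participants: pd.DataFrame) -> pd.Series:
    w = participants["weight_2day"].where(
        participants["weight_2day"] > 0, participants["weight_day1"]
    )
    return pd.Series(w.to_numpy(float), index=participants["participant_id"])


def _person_means(totals: pd.DataFrame, outcomes: Sequence[str]) -> pd.DataFrame:
    """Per-person mean daily value of each outcome across recall days."""
    return totals.groupby("participant_id")[list(outcomes)].mean()


def _replicate_factors(participants: pd.DataFrame, fay: float,
                       n_replicates: int) -> np.ndarray:
    """Per-participant BRR weight factors, shape (n, R)."""
    rw = survey_stats.make_brr_weights(
        participants, fay=fay, n_replicates=n_replicates, weight_col="weight_day1"
    )
    return rw.replicates / rw.base[:, None]


def _brr_means(values: np.ndarray, base_w: np.ndarray,
               factors: np.ndarray, fay: float) -> tuple[np.ndarray, np.ndarray]:
    """Weighted means and Fay-BRR SEs for a value matrix (n, k)."""
    def wmean(w: np.ndarray) -> np.ndarray:
        return (values * w[:, None]).sum(axis=0) / w.sum()

    theta0 = wmean(base_w)
    R = factors.shape[1]
    devs = np.stack([wmean(base_w * factors[:, r]) - theta0 for r in range(R)])
    var = (devs ** 2).sum(axis=0) / (R * (1.0 - fay) ** 2)
    return theta0, np.sqrt(var)


def eligibility_summary(
    participants: pd.DataFrame, records: pd.DataFrame
) -> dict:
    """Filter-stage accounting: status counts, weighted shares, replaced kcal.

    Statuses are mutually exclusive and exhaustive over person-days.
    Person-days are weighted by the participant's survey weight (two-day
    weight when two recalls were completed).
    """
    elig = substitution.assess_eligibility_all(records)
    wmap = _person_weight(participants)
    elig = elig.assign(_w=elig["participant_id"].map(wmap))
    counts = elig["status"].value_counts().to_dict()
    wtot = elig["_w"].sum()
    shares = {
        s: float(elig.loc[elig["status"] == s, "_w"].sum() / wtot)
        for s in elig["status"].unique()
    }
    consumed = 1.0 - shares.get("skipped_breakfast", 0.0)
    eligible = elig[elig["status"] == "eligible"]
    age_map = participants.set_index("participant_id")["age_group"]
    per_age = (
        eligible.assign(_age=eligible["participant_id"].map(age_map))
        .groupby("_age")["replaced_kcal"].mean().to_dict()
    )
    return {
        "n_person_days": int(len(elig)),
        "counts": {k: int(v) for k, v in counts.items()},
        "weighted_shares": shares,
        "breakfast_consumer_share": float(consumed),
        "eligible_share": shares.get("eligible", 0.0),
        "mean_replaced_kcal": float(eligible["replaced_kcal"].mean())
        if len(eligible) else 0.0,
        "median_replaced_kcal": float(eligible["replaced_kcal"].median())
        if len(eligible) else 0.0,
        "mean_replaced_kcal_by_age": {k: float(v) for k, v in per_age.items()},
    }


def _subgroup_masks(participants: pd.DataFrame, mode: str) -> dict[str, np.ndarray]:
    masks = {"total": np.ones(len(participants), dtype=bool)}
    if mode == "total_only":
        return masks
    for age in AGE_GROUPS:
        masks[f"age_{age}"] = (participants["age_group"] == age).to_numpy()
    masks["wic_children"] = (
        participants["wic_flag"] & (participants["age_years"] <= 19)
    ).to_numpy()
    return masks


def run_all(
    participants: pd.DataFrame,
    records: pd.DataFrame,
    config: RunConfig | None = None,
) -> RunResult:
    """Run the full observed / Model 1 / Model 2 comparison.

    Raises on validation errors; otherwise returns a :class:`RunResult`
    whose ``results`` table has one row per (subgroup, outcome, scenario)
    with estimate and SE, plus difference, percent change, p-value and
    effect label for model scenarios.
    """
    config = config or RunConfig()
    report = recall_io.validate_dataset(participants, records)
    if report.error_count:
        raise ValueError(f"dataset failed validation:\n{report}")

    logger.info("building composite profiles")
    comps = composite_profiles.build_rtec_composite(records, participants)
    milks = composite_profiles.build_milk_profile(records, participants)

    logger.info("applying substitution models")
    scenarios = {
        "observed": records,
        "model1": substitution.apply_model_all(records, participants, comps),
        "model2": substitution.apply_model_all(records, participants, comps, milks),
    }
    totals = {
        name: day_metrics.person_day_totals(recs, config.inflation_factors)
        for name, recs in scenarios.items()
    }

    elig = eligibility_summary(participants, records)
    logger.info(
        "person-days: %s; eligible share %.1f%%",
        elig["n_person_days"], 100 * elig["eligible_share"],
    )

    pid_order = participants["participant_id"].to_numpy()
    means = {
        name: _person_means(t, config.outcomes).reindex(pid_order)
        for name, t in totals.items()
    }
    base_w = _person_weight(participants).to_numpy()
    factors = _replicate_factors(participants, config.fay, config.n_replicates)
    n_strata = participants["stratum_id"].nunique()

    rows: list[dict] = []
    for sub, mask in _subgroup_masks(participants, config.subgroups).items():
        if mask.sum() == 0:
            continue
        w = base_w[mask]
        fac = factors[mask]
        est: dict[str, np.ndarray] = {}
        se: dict[str, np.ndarray] = {}
        for name in scenarios:
            v = means[name].to_numpy(float)[mask]
            est[name], se[name] = _brr_means(v, w, fac, config.fay)
        for j, outcome in enumerate(config.outcomes):
            rows.append({
                "subgroup": sub, "outcome": outcome, "scenario": "observed",
                "estimate": est["observed"][j], "se": se["observed"][j],
            })
            for model in ("model1", "model2"):
                diff_vals = (
                    means[model].to_numpy(float)[mask][:, j]
                    - means["observed"].to_numpy(float)[mask][:, j]
                )
                d_est, d_se = _brr_means(diff_vals[:, None], w, fac, config.fay)
                delta, delta_se = float(d_est[0]), float(d_se[0])
                obs = float(est["observed"][j])
                pct = 100.0 * delta / obs if obs != 0 else np.nan
                if delta_se > 0:
                    _, p = survey_stats.ttest_unequal(
                        delta, delta_se, 0.0, 0.0,
                        df_policy="strata", n_strata=n_strata,
                    )
                else:
                    p = 1.0 if delta == 0 else 0.0
                label = (
                    survey_stats.classify_effect(pct, p).label
                    if np.isfinite(pct) else "no_change"
                )
                rows.append({
                    "subgroup": sub, "outcome": outcome, "scenario": model,
                    "estimate": est[model][j], "se": se[model][j],
                    "delta": delta, "delta_se": delta_se,
                    "pct_change": pct, "p_value": p, "effect": label,
                })
    results = pd.DataFrame(rows)

    hei_rows = _hei_table(participants, totals, config, n_strata)
    usual = _usual_tables(participants, totals, records, config)

    return RunResult(
        results=results,
        hei=hei_rows,
        usual=usual,
        eligibility=elig,
        profiles=composite_profiles.profiles_to_dict(comps, milks),
    )


def _hei_table(participants: pd.DataFrame, totals: dict[str, pd.DataFrame],
               config: RunConfig, n_strata: int) -> pd.DataFrame:
    """Population-ratio HEI-2010 per subgroup and scenario, day-1 recalls."""
    standards = hei2010.load_standards(config.hei_standards_path)
    needed = sorted({"energy_kcal", "mufa_g", "pufa_g", "sfa_g"} | {
        c.constituent for c in standards.components
        if c.density_basis != "fatty_acid_ratio"
    })
    day1 = {
        name: t[t["recall_day"] == 1]
        .set_index("participant_id")[needed]
        .reindex(participants["participant_id"].to_numpy())
        .fillna(0.0)
        for name, t in totals.items()
    }
    w1 = participants["weight_day1"].to_numpy(float)
    factors = _replicate_factors(participants, config.fay, config.n_replicates)

    def score(df: pd.DataFrame, w: np.ndarray) -> float:
        return hei2010.population_ratio_hei(df, w, standards).total_points

    rows = []
    for sub, mask in _subgroup_masks(participants, config.subgroups).items():
        if mask.sum() == 0:
            continue
        w = w1[mask]
        fac = factors[mask]
        R = fac.shape[1]
        idx = np.flatnonzero(mask)
        base_scores = {name: score(df.iloc[idx], w) for name, df in day1.items()}
        devs = {name: np.empty(R) for name in day1}
        for r in range(R):
            wr = w * fac[:, r]
            for name, df in day1.items():
                devs[name][r] = score(df.iloc[idx], wr) - base_scores[name]
        scale = 1.0 / (R * (1.0 - config.fay) ** 2)
        ses = {n: float(np.sqrt((d ** 2).sum() * scale)) for n, d in devs.items()}
        for name in day1:
            row = {
                "subgroup": sub, "scenario": name,
                "hei_total": base_scores[name], "se": ses[name],
            }
            if name != "observed":
                d = devs[name] - devs["observed"]
                d_se = float(np.sqrt((d ** 2).sum() * scale))
                delta = base_scores[name] - base_scores["observed"]
                if d_se > 0:
                    _, p = survey_stats.ttest_unequal(
                        delta, d_se, 0.0, 0.0,
                        df_policy="strata", n_strata=n_strata,
                    )
                else:
                    p = 1.0 if delta == 0 else 0.0
                row.update({"delta": delta, "p_value": p})
            rows.append(row)
    return pd.DataFrame(rows)


def _usual_tables(participants: pd.DataFrame, totals: dict[str, pd.DataFrame],
                  records: pd.DataFrame, config: RunConfig) -> dict:
    """Usual-intake distributions for the configured outcomes (total pop)."""
    if not config.usual_outcomes:
        return {}
    wmap = _person_weight(participants)
    covars = _day_covariates(records)
    out: dict = {}
    for spec in config.usual_outcomes:
        per_outcome: dict = {}
        for name, t in totals.items():
            dv = t[["participant_id", "recall_day", spec.outcome]].rename(
                columns={spec.outcome: "value"}
            )
            dv = dv.merge(covars, on=["participant_id", "recall_day"], how="left")
            dv["weekend"] = dv["weekend"].fillna(0).astype(int)
            dv["recall2"] = (dv["recall_day"] == 2).astype(int)
            w = dv["participant_id"].map(wmap)
            zero_share = float((dv["value"] <= 0).mean())
            episodic = (
                spec.episodic == "yes"
                or (spec.episodic == "auto" and zero_share > 0.1)
            )
            try:
                if episodic:
                    model = usual_intake.fit_episodic(dv, w)
                else:
                    model = usual_intake.fit_ubiquitous(dv, w)
                dist = usual_intake.usual_distribution(
                    model, n_mc=config.usual_n_mc, seed=config.seed,
                    thresholds=spec.thresholds,
                )
            except ValueError as exc:
                logger.warning("usual intake for %s/%s skipped: %s",
                               spec.outcome, name, exc)
                continue
            per_outcome[name] = {
                "episodic": episodic,
                "mean": dist.mean,
                "p10": float(dist.percentiles.loc[10]),
                "p50": float(dist.percentiles.loc[50]),
                "p90": float(dist.percentiles.loc[90]),
                "proportion_above": dist.proportion_above,
            }
        out[spec.outcome] = per_outcome
    return out


def _day_covariates(records: pd.DataFrame) -> pd.DataFrame:
    keys = ["participant_id", "recall_day"]
    if "weekend" in records.columns:
        return records.groupby(keys, as_index=False)["weekend"].max()
    base = records[keys].drop_duplicates().reset_index(drop=True)
    base["weekend"] = 0
    return base
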
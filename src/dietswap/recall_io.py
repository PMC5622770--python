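"""Readers, writers and validation for recall-survey tables.

The interchange format is delimited text (CSV) with the header contract in
``data/schema_reference.md``: one participant table, one food-record table
and an optional price table keyed by food code.  The reader derives all
derivable columns (age group from age, the RTEC flag from the food-code
prefix, normalized occasion labels) instead of trusting them from the file.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from . import schema
from .schema import (
    FLAG_COLUMNS,
    FOOD_RECORD_COLUMNS,
    PARTICIPANT_COLUMNS,
    RACE_GROUPS,
    SEXES,
)


class SchemaError(ValueError):
    """Fatal structural problem in an input table."""


@dataclasses.dataclass
class ValidationMessage:
    severity: str  # "error" | "warning"
    locator: str   # table/row identifier
    message: str


@dataclasses.dataclass
class ValidationReport:
    """Itemized content-level findings for a loaded dataset."""

    messages: list[ValidationMessage] = dataclasses.field(default_factory=list)

    @property
    def error_count(self) -> int:
        return sum(m.severity == "error" for m in self.messages)

    @property
    def warning_count(self) -> int:
        return sum(m.severity == "warning" for m in self.messages)

    def add_error(self, locator: str, message: str) -> None:
        self.messages.append(ValidationMessage("error", locator, message))

    def add_warning(self, locator: str, message: str) -> None:
        self.messages.append(ValidationMessage("warning", locator, message))

    def __str__(self) -> str:  # pragma: no cover - debugging aid
        lines = [f"{self.error_count} error(s), {self.warning_count} warning(s)"]
        lines += [f"  [{m.severity}] {m.locator}: {m.message}" for m in self.messages]
        return "\n".join(lines)


def _require_columns(df: pd.DataFrame, required: Iterable[str], table: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}: missing required column(s): {', '.join(missing)}")


def read_participants(path: str | Path) -> pd.DataFrame:
    """Read the participant table from delimited text.

    ``age_group`` is always derived from ``age_years``; a value present in
    the file is ignored.  Rows with ``age_years`` below 1 (the cohort floor)
    are rejected.
    """
    df = pd.read_csv(path)
    required = [c for c in PARTICIPANT_COLUMNS]
    _require_columns(df, required, "participants")

    df = df.copy()
    df["participant_id"] = df["participant_id"].astype(str)
    df["stratum_id"] = df["stratum_id"].astype(str)
    df["age_years"] = df["age_years"].astype(int)
    bad_age = df["age_years"] < 1
    if bad_age.any():
        df = df.loc[~bad_age]
    bad_race = ~df["race_eth"].isin(RACE_GROUPS)
    if bad_race.any():
        row = df.index[bad_race][0]
        raise SchemaError(
            f"participants row {row}: unknown race_eth "
            f"{df.loc[row, 'race_eth']!r} (expected one of {RACE_GROUPS})"
        )
    bad_sex = ~df["sex"].isin(SEXES)
    if bad_sex.any():
        row = df.index[bad_sex][0]
        raise SchemaError(f"participants row {row}: unknown sex {df.loc[row, 'sex']!r}")
    df["age_group"] = df["age_years"].map(schema.age_to_group)
    df["wic_flag"] = df["wic_flag"].astype(bool)
    df["psu_id"] = df["psu_id"].astype(int)
    df["n_recalls"] = df["n_recalls"].astype(int)
    for col in ("weight_day1", "weight_2day"):
        df[col] = df[col].astype(float)
        if (df[col] < 0).any():
            row = df.index[df[col] < 0][0]
            raise SchemaError(f"participants row {row}: negative {col}")
    return df.reset_index(drop=True)


def read_food_records(path: str | Path) -> pd.DataFrame:
    """Read the food-record table from delimited text.

    Occasion labels are normalized onto the canonical 8-value set and the
    RTEC flag is recomputed from the food-code prefix, overriding any flag
    present in the file.
    """
    df = pd.read_csv(path, dtype={"food_code": str})
    _require_columns(df, FOOD_RECORD_COLUMNS, "food_records")
    df = df.copy()
    df["participant_id"] = df["participant_id"].astype(str)
    df["recall_day"] = df["recall_day"].astype(int)
    df["occasion"] = df["occasion"].map(schema.normalize_occasion)
    for col in ("grams", "energy_kcal", *schema.DENSITY_FIELDS, "price_per_100g"):
        df[col] = df[col].astype(float)
    if (df["grams"] <= 0).any():
        row = df.index[df["grams"] <= 0][0]
        raise SchemaError(f"food_records row {row}: nonpositive grams")
    if (df["energy_kcal"] < 0).any():
        row = df.index[df["energy_kcal"] < 0][0]
        raise SchemaError(f"food_records row {row}: negative energy_kcal")
    for col in FLAG_COLUMNS:
        df[col] = df[col].astype(bool)
    df["is_rtec"] = df["food_code"].map(schema.is_rtec_code)
    return df.reset_index(drop=True)


def read_prices(path: str | Path) -> pd.DataFrame:
    """Read the price table (``food_code``, ``price_per_100g``)."""
    df = pd.read_csv(path, dtype={"food_code": str})
    _require_columns(df, ["food_code", "price_per_100g"], "prices")
    df["price_per_100g"] = df["price_per_100g"].astype(float)
    return df


def write_participants(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in PARTICIPANT_COLUMNS if c in df.columns]
    df[cols].to_csv(path, index=False)


def write_food_records(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in FOOD_RECORD_COLUMNS if c in df.columns]
    extra = [c for c in ("model_id", "synthetic") if c in df.columns]
    df[cols + extra].to_csv(path, index=False)


def validate_dataset(participants: pd.DataFrame, records: pd.DataFrame) -> ValidationReport:
    """Check cross-table invariants; report findings, never raise on content.

    Checked: participant referential integrity, recall-day consistency with
    ``n_recalls``, the two-PSU-per-stratum precondition for balanced repeated
    replication, weight/recall consistency, RTEC-flag consistency with the
    food-code prefix, and beverage-addition linkage (an addition must share
    an occasion with some beverage record on the same person-day).
    """
    report = ValidationReport()

    known = set(participants["participant_id"])
    orphan = ~records["participant_id"].isin(known)
    for row in records.index[orphan]:
        report.add_error(
            f"food_records row {row}",
            f"unknown participant_id {records.loc[row, 'participant_id']!r}",
        )

    n_recalls = participants.set_index("participant_id")["n_recalls"]
    merged_days = records.loc[~orphan, ["participant_id", "recall_day"]].copy()
    merged_days["max_day"] = merged_days["participant_id"].map(n_recalls)
    too_late = merged_days["recall_day"] > merged_days["max_day"]
    for row in merged_days.index[too_late]:
        report.add_error(
            f"food_records row {row}",
            "recall_day exceeds participant n_recalls",
        )

    psu_counts = participants.groupby("stratum_id")["psu_id"].nunique()
    for stratum, n_psu in psu_counts.items():
        if n_psu != 2:
            report.add_error(
                f"stratum {stratum}",
                f"{n_psu} distinct PSU(s); balanced repeated replication "
                "requires exactly 2 per stratum",
            )

    bad_w2 = (participants["n_recalls"] == 2) != (participants["weight_2day"] > 0)
    for row in participants.index[bad_w2]:
        report.add_error(
            f"participants row {row}",
            "weight_2day must be positive iff n_recalls = 2",
        )

    flag_mismatch = records["is_rtec"] != records["food_code"].map(schema.is_rtec_code)
    for row in records.index[flag_mismatch]:
        report.add_error(
            f"food_records row {row}",
            "is_rtec inconsistent with food-code prefix",
        )

    additions = records[records["is_beverage_addition"]]
    if len(additions):
        bev_occ = records[records["is_beverage"]].groupby(
            ["participant_id", "recall_day"]
        )["occasion"].agg(set)
        for row, rec in additions.iterrows():
            occ = bev_occ.get((rec["participant_id"], rec["recall_day"]), set())
            if rec["occasion"] not in occ:
                report.add_error(
                    f"food_records row {row}",
                    "beverage addition without a beverage at the same "
                    "person-day occasion",
                )

    zero_price = records["price_per_100g"] == 0
    n_zero = int(zero_price.sum())
    if n_zero:
        report.add_warning(
            "food_records", f"{n_zero} record(s) carry zero price_per_100g"
        )
    return report


def person_day_keys(records: pd.DataFrame) -> pd.DataFrame:
    """Distinct (participant_id, recall_day) pairs present in ``records``."""
    return records[["participant_id", "recall_day"]].drop_duplicates().reset_index(drop=True)
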
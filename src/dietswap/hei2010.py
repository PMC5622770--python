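"""Healthy Eating Index 2010 scoring via the population ratio method.

The HEI-2010 is a 12-component, 100-point energy-adjusted diet quality
score: nine adequacy components (fruit, whole fruit, vegetables, greens and
beans, whole grains, dairy, protein foods, seafood/plant proteins, and the
unsaturated-to-saturated fatty-acid ratio) and three moderation components
(refined grains, sodium, and empty calories from solid fats, alcohol and
added sugars).  Component scores interpolate linearly between a zero- and a
max-score density threshold and are clamped to [0, max points].

Population scoring uses the population ratio method: survey-weighted sums
of every constituent (including energy) are pooled across persons FIRST,
densities are formed from the pooled ratios, and the pooled densities are
scored.  This is not the mean of per-person scores.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import logging
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class ComponentStandard:
    name: str
    constituent: str
    density_basis: str  # per_1000kcal | fatty_acid_ratio | pct_energy
    direction: str      # adequacy | moderation
    zero_threshold: float
    max_threshold: float
    max_points: float


@dataclasses.dataclass(frozen=True)
class HEIStandards:
    components: tuple[ComponentStandard, ...]

    def __post_init__(self) -> None:
        if len(self.components) != 12:
            raise ValueError(f"expected 12 components, got {len(self.components)}")
        total = sum(c.max_points for c in self.components)
        if abs(total - 100.0) > 1e-9:
            raise ValueError(f"max points sum to {total}, expected 100")
        for c in self.components:
            lo, hi = sorted((c.zero_threshold, c.max_threshold))
            ordered = (
                c.zero_threshold < c.max_threshold
                if c.direction == "adequacy"
                else c.zero_threshold > c.max_threshold
            )
            if not ordered:
                raise ValueError(f"{c.name}: thresholds inconsistent with direction")


@dataclasses.dataclass
class HEIScore:
    component_points: dict[str, float]
    total_points: float

    def __post_init__(self) -> None:
        if abs(self.total_points - sum(self.component_points.values())) > 1e-9:
            raise ValueError("total is not the sum of component points")


def load_standards(path: str | None = None) -> HEIStandards:
    """Load component standards from YAML (package default when no path)."""
    if path is None:
        text = (
            importlib.resources.files("dietswap").joinpath("data/hei2010.yaml")
        ).read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    comps = tuple(
        ComponentStandard(name=name, **fields)
        for name, fields in raw["components"].items()
    )
    return HEIStandards(components=comps)


def hei_densities(
    totals: Mapping[str, float], standards: HEIStandards
) -> dict[str, float]:
    """Energy-adjusted density for every component from constituent totals.

    ``totals`` must carry energy plus every constituent the standards name.
    Zero-energy input yields zero densities except the fatty-acid ratio,
    which maps a zero-SFA diet with unsaturated fat to the max-score
    threshold (ratio treated as +infinity).
    """
    energy = float(totals["energy_kcal"])
    out: dict[str, float] = {}
    for c in standards.components:
        if c.density_basis == "fatty_acid_ratio":
            unsat = float(totals["mufa_g"]) + float(totals["pufa_g"])
            sfa = float(totals["sfa_g"])
            if sfa > 0:
                out[c.name] = unsat / sfa
            else:
                out[c.name] = c.max_threshold if unsat > 0 else 0.0
        elif energy <= 0:
            out[c.name] = 0.0
        elif c.density_basis == "per_1000kcal":
            out[c.name] = float(totals[c.constituent]) / energy * 1000.0
        elif c.density_basis == "pct_energy":
            out[c.name] = float(totals[c.constituent]) / energy * 100.0
        else:  # pragma: no cover - guarded by standards validation
            raise ValueError(f"unknown density basis {c.density_basis}")
    return out


def score_component(density: float, standard: ComponentStandard) -> float:
    """Linear interpolation between the thresholds, clamped to [0, max]."""
    z, m = standard.zero_threshold, standard.max_threshold
    frac = (density - z) / (m - z)  # works for both directions
    return standard.max_points * float(np.clip(frac, 0.0, 1.0))


def score_totals(totals: Mapping[str, float], standards: HEIStandards) -> HEIScore:
    """Score a single set of constituent totals (one person or a pool).

    Zero-energy input scores 0 on adequacy components and full points on
    moderation components (nothing discouraged was consumed); a warning is
    logged since such days carry no dietary information.
    """
    energy = float(totals["energy_kcal"])
    if energy <= 0:
        logger.warning("scoring a zero-energy total; moderation components max out")
        points = {
            c.name: (0.0 if c.direction == "adequacy" else float(c.max_points))
            for c in standards.components
        }
        return HEIScore(points, sum(points.values()))
    dens = hei_densities(totals, standards)
    points = {c.name: score_component(dens[c.name], c) for c in standards.components}
    return HEIScore(points, sum(points.values()))


def population_ratio_hei(
    day1_totals: pd.DataFrame,
    weights: pd.Series | np.ndarray,
    standards: HEIStandards,
) -> HEIScore:
    """Population HEI-2010 from day-1 totals by the population ratio method.

    Weighted constituent sums are pooled across persons first; densities and
    component scores come from the pooled ratios.  For a single person (or
    when all weight is on one person) this degenerates to that person's
    score.
    """
    w = np.asarray(weights, dtype=float)
    if len(w) != len(day1_totals):
        raise ValueError("weights length does not match totals")
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("weights must be nonnegative and not all zero")
    needed = {"energy_kcal", "mufa_g", "pufa_g", "sfa_g"} | {
        c.constituent for c in standards.components
        if c.density_basis != "fatty_acid_ratio"
    }
    pooled = {col: float((day1_totals[col].to_numpy() * w).sum()) for col in needed}
    if pooled["energy_kcal"] <= 0:
        raise ValueError("pooled energy is zero; population score undefined")
    return score_totals(pooled, standards)
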
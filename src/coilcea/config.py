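"""Run configuration: horizon, discounting, strategies, population scaling."""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError, ValidationError
from .parameters import HtiEfficacySpec

STRATEGY_STANDARD = "standard"
STRATEGY_HTI = "standard_plus_hti"
STRATEGIES = (STRATEGY_STANDARD, STRATEGY_HTI)

DEFAULT_THRESHOLDS = (50_000.0, 100_000.0, 150_000.0)


def load_life_table(path=None) -> pd.DataFrame:
    """Load an abridged life table (age_low, age_high, annual probability)."""
    if path is None:
        with resources.files("coilcea.data").joinpath("life_table.csv").open("rb") as fh:
            df = pd.read_csv(fh, comment="#")
    else:
        df = pd.read_csv(path, comment="#")
    needed = {"age_low", "age_high", "annual_mortality_probability"}
    if not needed.issubset(df.columns):
        raise SchemaError(f"life table must have columns {sorted(needed)}")
    return df.sort_values("age_low").reset_index(drop=True)


@dataclass(frozen=True)
class ModelConfig:
    """Model settings; the defaults are the published base case."""

    cycle_years: float = 0.5
    n_cycles: int = 60
    start_age: float = 45.0
    discount_rate: float = 0.015  # annual, applied to costs and QALYs alike
    max_procedures: int = 4
    hti_price: float = 10_000.0
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    background_mortality: bool = True
    life_table: Optional[pd.DataFrame] = None
    half_cycle_correction: bool = False  # accrual at cycle start
    #: how period-quoted probabilities are rescaled to one cycle:
    #: "linear" (p * cycle/period) or "hazard" (1 - (1-p)**(cycle/period))
    prob_conversion: str = "linear"
    #: recanalization risk is active while model time < this many years
    #: (None = the whole horizon); reflects the surveillance window over
    #: which the published cumulative recanalization probability was counted
    recan_window_years: Optional[float] = 5.5
    #: treat the published 6-year retreatment probability as conditional on
    #: recanalization (applied to unsecured occupants as v5/v4) rather than
    #: as a marginal hazard
    retreat_conditional: bool = True

    def __post_init__(self):
        if self.cycle_years <= 0 or self.n_cycles <= 0:
            raise ValidationError("cycle_years and n_cycles must be positive")
        if self.discount_rate < 0:
            raise ValidationError("discount_rate must be non-negative")
        if any(t <= 0 for t in self.thresholds):
            raise ValidationError("thresholds must be positive")
        if self.hti_price < 0:
            raise ValidationError("hti_price must be non-negative")
        if self.prob_conversion not in ("linear", "hazard"):
            raise ValidationError("prob_conversion must be 'linear' or 'hazard'")
        if self.background_mortality and self.life_table is None:
            object.__setattr__(self, "life_table", load_life_table())

    @property
    def horizon_years(self) -> float:
        return self.cycle_years * self.n_cycles

    def age_at_cycle(self, cycle: int) -> float:
        return self.start_age + cycle * self.cycle_years

    def annual_background_mortality(self, age: float) -> float:
        if not self.background_mortality:
            return 0.0
        t = self.life_table
        row = t[(t["age_low"] <= age) & (age < t["age_high"])]
        if row.empty:
            return float(t["annual_mortality_probability"].iloc[-1])
        return float(row["annual_mortality_probability"].iloc[0])


@dataclass(frozen=True)
class PopulationSpec:
    """US population scale for value-of-information results."""

    procedures_per_year: float = 15_925.0
    horizon_years: float = 10.0
    # population totals are plain multiplication, not discounted

    def __post_init__(self):
        if self.procedures_per_year <= 0 or self.horizon_years <= 0:
            raise ValidationError("population spec values must be positive")

    @property
    def size(self) -> float:
        return self.procedures_per_year * self.horizon_years


_CONFIG_KEYS = {
    "cycle_years", "n_cycles", "start_age", "discount_rate", "thresholds",
    "hti_price", "hti_efficacy", "background_mortality", "seed",
    "n_iterations", "n_replicates", "population", "prob_conversion",
    "recan_window_years", "retreat_conditional",
}


@dataclass(frozen=True)
class RunSettings:
    """Full run settings parsed from a YAML config file."""

    model: ModelConfig
    hti: HtiEfficacySpec
    population: PopulationSpec
    seed: int = 0
    n_iterations: int = 7_000
    n_replicates: int = 100


def load_config(path=None) -> RunSettings:
    """Parse a YAML config; an empty or missing mapping yields the base case.

    Unknown keys and out-of-range values raise :class:`ValidationError`
    naming the offending key.
    """
    raw = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh)
        raw = loaded or {}
    if not isinstance(raw, dict):
        raise ValidationError("config root must be a mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValidationError(f"unknown config key(s): {sorted(unknown)}")

    model_kwargs = {}
    for key in ("cycle_years", "n_cycles", "start_age", "discount_rate",
                "hti_price", "prob_conversion", "recan_window_years",
                "retreat_conditional"):
        if key in raw:
            model_kwargs[key] = raw[key]
    if "thresholds" in raw:
        model_kwargs["thresholds"] = tuple(float(t) for t in raw["thresholds"])
    bm = raw.get("background_mortality", {})
    if isinstance(bm, dict):
        model_kwargs["background_mortality"] = bool(bm.get("enabled", True))
        if bm.get("table_path"):
            model_kwargs["life_table"] = load_life_table(bm["table_path"])
    else:
        model_kwargs["background_mortality"] = bool(bm)
    try:
        model = ModelConfig(**model_kwargs)
    except TypeError as exc:
        raise ValidationError(str(exc)) from exc

    eff = raw.get("hti_efficacy", {}) or {}
    hti = HtiEfficacySpec(
        family=eff.get("family", "uniform01"),
        mu=float(eff.get("mu", 0.5)),
        sigma=float(eff.get("sigma", 0.15)),
        fixed_value=float(eff.get("fixed_value", 0.0)),
    )

    popraw = raw.get("population", {}) or {}
    population = PopulationSpec(
        procedures_per_year=float(popraw.get("procedures_per_year", 15_925)),
        horizon_years=float(popraw.get("horizon_years", 10)),
    )

    return RunSettings(
        model=model,
        hti=hti,
        population=population,
        seed=int(raw.get("seed", 0)),
        n_iterations=int(raw.get("n_iterations", 7_000)),
        n_replicates=int(raw.get("n_replicates", 100)),
    )
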
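"""Scenario studies on the stem-cell model: sweeps, composites, overlap.

Turnover estimates from the hierarchical (stem-cell) model are famously
sensitive to indirectly measured inputs -- most of all the expansion
exponent E (turnover scales like 2**E, so a 20 % error in E moves turnover
roughly two-fold) and the apoptotic fraction, whose influence grows with
subject age as the adjusting denominator equilibrates.  This module turns
those sensitivities into explicit objects: multiplier sweeps around a
baseline parameterization, envelope bands, gender-weighted composite
trajectories, and the per-age intersection of two uncertainty bands (the
region of turnover levels simultaneously compatible with two datasets).

Bands here are scenario envelopes, not confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd

from .population import (
    HierarchicalParams,
    SubjectProfile,
    simulate_hierarchical,
    turnover_series,
)

__all__ = [
    "SWEEPABLE_PARAMETERS",
    "SweepSpec",
    "TurnoverBand",
    "sensitivity_sweep",
    "substitute_apoptosis",
    "gender_composite",
    "band_from_sweep",
    "corner_band",
    "overlap_region",
]

SWEEPABLE_PARAMETERS = (
    "expansion_exponent",
    "apoptotic_frac",
    "halflife_years",
    "mitosis_hours",
    "apoptosis_hours",
)

Denominator = float | Literal["adjusting"]


@dataclass(frozen=True)
class SweepSpec:
    """One-parameter multiplier sweep around a baseline parameterization."""

    parameter: str
    multipliers: Sequence[float] = (0.8, 1.0, 1.2)
    sex: Literal["male", "female"] = "male"
    denominator: Denominator = "adjusting"

    def __post_init__(self) -> None:
        if self.parameter not in SWEEPABLE_PARAMETERS:
            raise ValueError(
                f"unknown sweep parameter {self.parameter!r}; choose from {SWEEPABLE_PARAMETERS}"
            )
        if any(m < 0 for m in self.multipliers):
            raise ValueError("multipliers must be >= 0")


def _turnover_for(params: HierarchicalParams, subject: SubjectProfile, denominator: Denominator) -> pd.Series:
    ledger = simulate_hierarchical(params, subject)
    return turnover_series(ledger, denominator)


def sensitivity_sweep(
    params: HierarchicalParams,
    spec: SweepSpec,
    lifespan: int = 80,
    birth_year: int = 1920,
) -> pd.DataFrame:
    """Turnover trajectory per multiplier (columns), indexed by subject age.

    The multiplier scales the swept parameter uniformly across all ages;
    the central trajectory is multiplier 1.0.
    """
    subject = SubjectProfile("sweep", spec.sex, birth_year, lifespan)
    columns = {}
    for mult in spec.multipliers:
        swept = params.with_multipliers(**{spec.parameter: float(mult)})
        columns[float(mult)] = _turnover_for(swept, subject, spec.denominator)
    return pd.DataFrame(columns)


def substitute_apoptosis(
    params: HierarchicalParams,
    alternative: Callable[[float], float],
    lifespan: int = 80,
    sex: Literal["male", "female"] = "male",
    birth_year: int = 1920,
    denominator: Denominator = "adjusting",
) -> pd.Series:
    """Turnover trajectory with the apoptotic fraction replaced by
    ``alternative(age)`` (e.g. an age-constant literature estimate)."""
    return _turnover_for(params.with_apoptotic_frac(alternative), SubjectProfile("subst", sex, birth_year, lifespan), denominator)


def gender_composite(
    male: pd.Series, female: pd.Series, weights: tuple[float, float] = (0.75, 0.25)
) -> pd.Series:
    """Pointwise weighted mean of male and female turnover trajectories.

    The default weights mirror a 9:3 male:female demographic mix.
    """
    if abs(sum(weights) - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    if not male.index.equals(female.index):
        raise ValueError("male and female trajectories must share the same age support")
    return weights[0] * male + weights[1] * female


@dataclass
class TurnoverBand:
    """Per-age (lower, central, upper) turnover band (%/year)."""

    ages: np.ndarray
    lower: np.ndarray
    central: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages)
        for name in ("lower", "central", "upper"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != self.ages.shape:
                raise ValueError("band arrays must share the age support")
        if np.any(self.lower > self.central + 1e-9) or np.any(self.central > self.upper + 1e-9):
            raise ValueError("band must satisfy lower <= central <= upper at every age")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"age": self.ages, "lower": self.lower, "central": self.central, "upper": self.upper}
        )


def band_from_sweep(sweep: pd.DataFrame, central: float = 1.0) -> TurnoverBand:
    """Envelope band of a multiplier sweep (central = the 1.0 column)."""
    if central not in sweep.columns:
        raise ValueError("sweep does not contain the central multiplier column")
    values = sweep.to_numpy()
    return TurnoverBand(
        ages=sweep.index.to_numpy(),
        lower=values.min(axis=1),
        central=sweep[central].to_numpy(),
        upper=values.max(axis=1),
    )


def corner_band(
    params: HierarchicalParams,
    parameters: Sequence[str] = ("apoptotic_frac", "expansion_exponent"),
    spread: float = 0.2,
    sex: Literal["male", "female"] = "male",
    lifespan: int = 80,
    birth_year: int = 1920,
    denominator: Denominator = "adjusting",
) -> TurnoverBand:
    """Envelope over all +-spread corner combinations of several parameters.

    Varies the listed parameters simultaneously through every corner of the
    multiplier hypercube {1-spread, 1+spread}^p and takes the pointwise
    envelope; the central trajectory uses all multipliers at 1.0.
    """
    subject = SubjectProfile("band", sex, birth_year, lifespan)
    central = _turnover_for(params, subject, denominator)
    trajectories = [central.to_numpy()]
    n = len(parameters)
    for corner in range(2**n):
        mults = {
            p: (1.0 - spread if corner & (1 << i) else 1.0 + spread)
            for i, p in enumerate(parameters)
        }
        trajectories.append(_turnover_for(params.with_multipliers(**mults), subject, denominator).to_numpy())
    stack = np.vstack(trajectories)
    return TurnoverBand(
        ages=central.index.to_numpy(),
        lower=stack.min(axis=0),
        central=central.to_numpy(),
        upper=stack.max(axis=0),
    )


@dataclass
class OverlapRegion:
    """Per-age interval where two bands intersect (NaN where empty)."""

    ages: np.ndarray
    lower: np.ndarray
    upper: np.ndarray

    @property
    def nonempty(self) -> np.ndarray:
        return ~np.isnan(self.lower)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "lower": self.lower, "upper": self.upper})


def overlap_region(band_a: TurnoverBand, band_b: TurnoverBand) -> OverlapRegion:
    """Per-age intersection [max(lowers), min(uppers)] of two bands."""
    if not np.array_equal(band_a.ages, band_b.ages):
        raise ValueError("bands must share the same age support")
    lower = np.maximum(band_a.lower, band_b.lower)
    upper = np.minimum(band_a.upper, band_b.upper)
    empty = lower > upper
    lower = lower.astype(float).copy()
    upper = upper.astype(float).copy()
    lower[empty] = np.nan
    upper[empty] = np.nan
    return OverlapRegion(band_a.ages, lower, upper)
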
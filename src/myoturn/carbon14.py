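"""Bomb-pulse atmospheric radiocarbon and the DNA C14 forward model.

Atmospheric Δ14C is handled as a *differential* series, per mil relative to
the 1955 baseline: values for years before 1955 are exactly 0 (no nuclear
weapons testing signal).  A CM cohort incorporates the atmospheric value at
its formation time (optionally delayed, since dietary carbon reaches solid
tissue with a lag), then drifts toward later atmospheric values through
polyploidization: every year a fraction of CM nuclei replicates DNA without
dividing, mixing in contemporary C14 and mimicking cardiomyogenesis.

The subject-level observables are the count-weighted end-of-life average
DNA C14 (``end_c14``) and ΛC14 = end C14 minus the atmospheric value at
birth -- the pulse-chase quantity inverted by :mod:`myoturn.solvers`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np

from .population import CohortLedger, SubjectProfile

__all__ = [
    "BombCurve",
    "PloidyModel",
    "IncorporationPolicy",
    "C14Assignment",
    "smooth_curve",
    "synthetic_bomb_curve",
    "initial_c14",
    "cohort_c14_at_death",
    "cohort_c14_values",
    "assign_c14",
    "end_c14",
    "lambda_c14",
]

PRE_BOMB_YEAR = 1955

Resolution = Literal["monthly", "yearly"]
InitialMode = Literal["smoothed", "min_within_12mo", "max_within_12mo"]
PloidyUpdate = Literal["as_described", "normalized"]


# ---------------------------------------------------------------------------
# Bomb curve
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BombCurve:
    """Calendar-indexed atmospheric Δ14C series (per mil, rel. 1955).

    ``times`` are decimal years -- integers for yearly resolution, month
    midpoints (``year + (month - 0.5)/12``) for monthly resolution.  Any
    query before 1955 returns 0 even outside the tabulated range; queries
    after the tabulated range raise.
    """

    times: np.ndarray
    values: np.ndarray
    resolution: Resolution = "yearly"
    smoothed: bool = False

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.size == 0:
            raise ValueError("empty bomb curve")
        if times.size != values.size:
            raise ValueError("times and values must have equal length")
        if np.any(np.diff(times) <= 0):
            raise ValueError("bomb curve timestamps must be strictly increasing")
        if not np.all(np.isfinite(values)):
            raise ValueError("bomb curve values must be finite")
        pre = times < PRE_BOMB_YEAR
        if np.any(values[pre] != 0.0):
            raise ValueError(f"bomb curve values before {PRE_BOMB_YEAR} must be 0")

    @property
    def start_year(self) -> int:
        return int(math.floor(self.times[0]))

    @property
    def end_year(self) -> int:
        return int(math.floor(self.times[-1]))

    def at(self, year: float) -> float:
        """Value at a calendar time (pre-1955 is identically 0)."""
        if year < PRE_BOMB_YEAR:
            return 0.0
        if year > self.times[-1] + (1.0 if self.resolution == "yearly" else 1.0 / 12.0):
            raise ValueError(
                f"bomb curve ends at {self.times[-1]:.2f}; no value for {year:.2f}"
            )
        return float(np.interp(year, self.times, self.values))

    def window(self, start: float, end: float) -> np.ndarray:
        """Raw tabulated values with timestamps in [start, end]."""
        mask = (self.times >= start) & (self.times <= end)
        vals = self.values[mask]
        out = []
        if start < PRE_BOMB_YEAR:
            out.append(0.0)  # the pre-bomb baseline is part of any early window
        out.extend(vals.tolist())
        if not out:
            raise ValueError(f"bomb curve has no samples in [{start:.2f}, {end:.2f}]")
        return np.asarray(out)


def smooth_curve(raw: BombCurve, mode: Literal["centered", "trailing"] = "centered") -> BombCurve:
    """One-year smoothing, resampled to yearly resolution.

    For a monthly series the yearly value is the 12-month moving average
    (centered on mid-year by default, or the trailing window ending at the
    year's close); a yearly series passes through unchanged.  Pre-1955
    values remain exactly 0.
    """
    if raw.resolution == "yearly":
        years = raw.times.astype(int)
        vals = raw.values.copy()
    else:
        # centered: window centred on mid-year (the calendar year's months);
        # trailing: 12-month window ending at mid-year Y (Jul Y-1 .. Jun Y)
        years_all = (
            np.floor(raw.times).astype(int) if mode == "centered" else np.round(raw.times).astype(int)
        )
        years = np.unique(years_all)
        vals = np.array([raw.values[years_all == y].mean() for y in years])
    vals[years < PRE_BOMB_YEAR] = 0.0
    return BombCurve(years.astype(float), vals, resolution="yearly", smoothed=True)


def synthetic_bomb_curve(
    peak_year: int = 1963,
    peak_value: float = 800.0,
    rise_years: int = 8,
    decay_constant: float = 0.04,
    baseline: float = 0.0,
    start_year: int = 1930,
    end_year: int = 2010,
    resolution: Resolution = "monthly",
) -> BombCurve:
    """Deterministic bomb-pulse-shaped fixture curve.

    Flat at 0 before 1955, monotone (smoothstep) rise from 1955 to the peak,
    then exponential relaxation toward ``baseline``:
    ``baseline + (peak - baseline) * exp(-decay_constant * (t - peak_year))``.
    """
    if peak_year < PRE_BOMB_YEAR:
        raise ValueError("peak_year must be >= 1955")
    if peak_value < 0 or decay_constant < 0 or rise_years <= 0:
        raise ValueError("peak_value and decay_constant must be >= 0, rise_years > 0")
    if baseline < 0 or baseline > peak_value:
        raise ValueError("baseline must lie in [0, peak_value]")
    if start_year >= end_year:
        raise ValueError("start_year must precede end_year")
    rise_start = max(PRE_BOMB_YEAR, peak_year - rise_years)
    if resolution == "monthly":
        times = np.arange(start_year, end_year + 1, 1 / 12.0) + 0.5 / 12.0
        times = times[times < end_year + 1]
    else:
        times = np.arange(start_year, end_year + 1, dtype=float)
    vals = np.zeros_like(times)
    rising = (times >= rise_start) & (times <= peak_year)
    x = (times[rising] - rise_start) / max(peak_year - rise_start, 1e-9)
    vals[rising] = peak_value * (3 * x**2 - 2 * x**3)  # smoothstep: monotone rise
    after = times > peak_year
    vals[after] = baseline + (peak_value - baseline) * np.exp(
        -decay_constant * (times[after] - peak_year)
    )
    vals[times < PRE_BOMB_YEAR] = 0.0
    return BombCurve(times, vals, resolution=resolution, smoothed=False)


# ---------------------------------------------------------------------------
# Polyploidization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PloidyModel:
    """Age-dependent cumulative polyploidization of CM nuclei.

    ``cumulative(age)`` is the fraction of nuclei that have undergone a
    polyploidization event by the given subject age (sigmoidal; essentially
    complete during childhood/adolescence), multiplied by ``scale``
    (1.0 = the Bergmann/Adler magnitude, ~0.78 = the Takamatsu magnitude,
    0.0 disables the correction).  ``incremental(age)`` is the fraction
    undergoing the event during the year ending at ``age``.
    """

    cumulative_fn: Callable[[float], float]
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.scale < 0:
            raise ValueError("ploidy scale must be >= 0")

    @classmethod
    def sigmoid(
        cls,
        midpoint: float = 8.0,
        steepness: float = 2.0,
        plateau: float = 0.6,
        scale: float = 1.0,
    ) -> "PloidyModel":
        """Parametric logistic curve anchored so ``cumulative(0) = 0``."""
        if steepness <= 0 or not 0 <= plateau <= 1:
            raise ValueError("steepness must be > 0 and plateau in [0, 1]")
        s0 = 1.0 / (1.0 + math.exp(midpoint / steepness))

        def cum(age: float) -> float:
            if age <= 0:
                return 0.0
            s = 1.0 / (1.0 + math.exp(-(age - midpoint) / steepness))
            return plateau * (s - s0) / (1.0 - s0)

        return cls(cum, scale=scale)

    @classmethod
    def from_table(cls, ages: Sequence[float], fractions: Sequence[float], scale: float = 1.0) -> "PloidyModel":
        ages_a = np.asarray(ages, dtype=float)
        frac_a = np.asarray(fractions, dtype=float)
        if np.any(np.diff(frac_a) < 0) or np.any((frac_a < 0) | (frac_a > 1)):
            raise ValueError("tabulated cumulative fractions must be non-decreasing in [0, 1]")
        return cls(lambda age: float(np.interp(age, ages_a, frac_a)), scale=scale)

    @classmethod
    def none(cls) -> "PloidyModel":
        return cls(lambda age: 0.0, scale=0.0)

    def cumulative(self, age: float) -> float:
        value = self.scale * float(self.cumulative_fn(age))
        return min(max(value, 0.0), 1.0)

    def incremental(self, age: float) -> float:
        return max(self.cumulative(age) - self.cumulative(age - 1), 0.0)


@dataclass(frozen=True)
class IncorporationPolicy:
    """How atmospheric C14 enters newly made DNA.

    ``delay_years`` shifts every atmospheric lookup back in time (dietary
    carbon reaches solid tissue with a lag of up to 2 years); the default is
    instantaneous incorporation.  ``initial_mode`` selects the value given
    to the initial (perinatal) cohort and to the subject's initial C14:
    the smoothed yearly value at birth, or the lowest/highest raw reading
    within 12 months of birth.
    """

    delay_years: int = 0
    initial_mode: InitialMode = "smoothed"

    def __post_init__(self) -> None:
        if self.delay_years < 0:
            raise ValueError("delay_years must be >= 0")


# ---------------------------------------------------------------------------
# C14 assignment
# ---------------------------------------------------------------------------


def initial_c14(
    curve: BombCurve,
    birth_year: int,
    mode: InitialMode = "smoothed",
    raw_curve: BombCurve | None = None,
) -> float:
    """Subject initial C14: atmospheric level at birth (per mil).

    ``"smoothed"`` reads the 1-year-smoothed curve at the birth year; the
    min/max modes take the extreme raw reading within 12 months of birth
    (``raw_curve`` may supply the unsmoothed monthly series; defaults to
    ``curve`` itself).
    """
    if mode == "smoothed":
        smoothed = curve if curve.smoothed else smooth_curve(curve)
        return smoothed.at(birth_year)
    raw = raw_curve if raw_curve is not None else curve
    window = raw.window(birth_year - 1, birth_year + 1)
    return float(window.min() if mode == "min_within_12mo" else window.max())


def _ploidy_step(value: float, atmospheric: float, p: float, update: PloidyUpdate) -> float:
    if p <= 0:
        return value
    if update == "as_described":
        # weighted average: existing value at weight 1, contemporary
        # atmospheric at the incremental polyploidization fraction p
        return (value + atmospheric * p) / (1.0 + p)
    if update == "normalized":
        return (1.0 - p) * value + p * atmospheric
    raise ValueError(f"unknown ploidy update {update!r}")


def cohort_c14_at_death(
    formation_year: int,
    subject: SubjectProfile,
    curve: BombCurve,
    ploidy: PloidyModel,
    policy: IncorporationPolicy = IncorporationPolicy(),
    raw_curve: BombCurve | None = None,
    update: PloidyUpdate = "as_described",
) -> float:
    """DNA C14 at subject death for the cohort formed in ``formation_year``.

    Starts from the (delay-shifted) atmospheric value at formation -- the
    initial cohort honours ``policy.initial_mode`` -- then applies the
    iterative polyploidization update for every subsequent year of subject
    life: ``value <- (value + atm * p) / (1 + p)`` with ``p`` the incremental
    polyploidization fraction at that subject age.
    """
    if not subject.birth_year <= formation_year <= subject.death_year:
        raise ValueError(
            f"formation year {formation_year} outside subject lifespan "
            f"[{subject.birth_year}, {subject.death_year}]"
        )
    d = policy.delay_years
    if formation_year == subject.birth_year:
        value = initial_c14(curve, subject.birth_year - d, policy.initial_mode, raw_curve)
    else:
        smoothed = curve if curve.smoothed else smooth_curve(curve)
        value = smoothed.at(formation_year - d)
    smoothed = curve if curve.smoothed else smooth_curve(curve)
    for year in range(formation_year + 1, subject.death_year + 1):
        age = year - subject.birth_year
        p = ploidy.incremental(age)
        value = _ploidy_step(value, smoothed.at(year - d), p, update)
    return value


def cohort_c14_values(
    subject: SubjectProfile,
    curve: BombCurve,
    ploidy: PloidyModel,
    policy: IncorporationPolicy = IncorporationPolicy(),
    raw_curve: BombCurve | None = None,
    update: PloidyUpdate = "as_described",
) -> np.ndarray:
    """Per-cohort C14 at death for every formation offset 0..lifespan.

    These values depend only on the subject, curve, ploidy model and policy
    -- not on the turnover dynamics -- so solvers compute them once and
    reuse them across candidate scenarios.
    """
    return np.array(
        [
            cohort_c14_at_death(
                subject.birth_year + k, subject, curve, ploidy, policy, raw_curve, update
            )
            for k in range(subject.lifespan + 1)
        ]
    )


@dataclass(frozen=True)
class C14Assignment:
    """Per-cohort C14 at death plus the subject-level summary values."""

    per_cohort: np.ndarray
    end_c14: float
    initial_c14: float

    @property
    def lambda_c14(self) -> float:
        return self.end_c14 - self.initial_c14


def end_c14(ledger: CohortLedger, assignments: np.ndarray) -> float:
    """Count-weighted mean DNA C14 over all surviving cohorts (per mil)."""
    assignments = np.asarray(assignments, dtype=float)
    if assignments.shape != ledger.counts.shape:
        raise ValueError("assignments must cover every cohort in the ledger")
    total = ledger.counts.sum()
    if total <= 0:
        raise ValueError("empty ledger: no surviving CMs to average")
    if np.any(~np.isfinite(assignments[ledger.counts > 0])):
        raise ValueError("non-finite assignment for a surviving cohort")
    return float(np.average(assignments, weights=ledger.counts))


def lambda_c14(end: float, initial: float) -> float:
    """ΛC14 = end-of-life average DNA C14 minus initial (birth) C14."""
    return end - initial


def assign_c14(
    ledger: CohortLedger,
    curve: BombCurve,
    ploidy: PloidyModel,
    policy: IncorporationPolicy = IncorporationPolicy(),
    raw_curve: BombCurve | None = None,
    update: PloidyUpdate = "as_described",
) -> C14Assignment:
    """Full forward model: cohort values, end C14 and initial C14."""
    subject = ledger.subject
    values = cohort_c14_values(subject, curve, ploidy, policy, raw_curve, update)
    init = initial_c14(
        curve, subject.birth_year - policy.delay_years, policy.initial_mode, raw_curve
    )
    return C14Assignment(values, end_c14(ledger, values), init)
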
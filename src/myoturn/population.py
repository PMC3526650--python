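"""Year-stepped cohort models of cardiomyocyte (CM) birth and death.

A simulated heart starts with an initial pool of CMs (the perinatal cohort)
and is advanced one year at a time over a subject's lifespan.  Each event
year may form a new cohort of CMs and deplete existing cohorts; at the end
of the run the surviving count of every formation-year cohort is recorded
in a :class:`CohortLedger`, together with the per-year total-count
trajectory and formation/destruction tallies.

Four scenario families are provided:

* :func:`simulate_hierarchical` -- a stem-cell driven model in which annual
  CM formation is computed from cardiac stem cell (CSC) counts, cycling
  fractions, mitosis kinetics, and an expansion exponent, while destruction
  follows measured apoptotic fractions and apoptosis kinetics.
* :func:`simulate_rates` -- direct annual formation/destruction schedules,
  with destruction targeting the whole pool uniformly, cohorts by the
  subject age at their formation, or cohorts by current CM age.
* :func:`simulate_tvb_tvdr` -- the four-parameter time-varying birth rate /
  time-varying death rate model: formation rate linear in subject age,
  and each cohort carrying a permanent annual death rate fixed by the
  subject age at which it was formed.
* :func:`simulate_age_structured` -- a half-life driven age-distribution
  generator with an iteratively applied mortality deduction.

Conventions (see docs/methods.md for rationale): event years are indexed by
the subject age attained at the end of the year, t = 1..lifespan; formation
and destruction for a year are both computed from the start-of-year state
and applied simultaneously, and a cohort is never depleted during its own
formation year.  Per-year cohort survival under a death rate ``d`` uses
either the ``"annual"`` kernel (multiply by ``1 - d``) or the
``"continuous"`` kernel (multiply by ``exp(-d)``, i.e. ``d`` acts as a
constant hazard spread over the year).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "HOURS_PER_YEAR",
    "DEFAULT_N0",
    "Sex",
    "SubjectProfile",
    "CohortLedger",
    "HierarchicalParams",
    "RateSchedule",
    "TVBTVDRParams",
    "simulate_hierarchical",
    "simulate_rates",
    "simulate_tvb_tvdr",
    "simulate_age_structured",
    "turnover_series",
    "surviving_original_fraction",
]

#: Mean hours in a calendar year, used to convert sub-year event kinetics
#: (mitosis/apoptosis durations) into annual event counts.
HOURS_PER_YEAR = 8766.0

#: Default bookkeeping mass: CM count per 10 g of tissue.  Turnover is
#: scale-invariant so this only matters for absolute-count outputs.
DEFAULT_N0 = 5e8

Sex = Literal["male", "female"]
Kernel = Literal["annual", "continuous"]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubjectProfile:
    """A modeled subject: identity, sex, birth year and lifespan.

    ``death_year`` is derived as ``birth_year + lifespan``.  ``end_c14`` and
    ``lambda_c14`` (per mil) are optional measured values carried along for
    fitting.
    """

    id: str
    sex: Sex
    birth_year: int
    lifespan: int
    end_c14: float | None = None
    lambda_c14: float | None = None

    def __post_init__(self) -> None:
        if self.lifespan < 0:
            raise ValueError(f"subject {self.id!r}: lifespan must be >= 0, got {self.lifespan}")
        if self.sex not in ("male", "female"):
            raise ValueError(f"subject {self.id!r}: sex must be 'male' or 'female', got {self.sex!r}")

    @property
    def death_year(self) -> int:
        return self.birth_year + self.lifespan


@dataclass
class CohortLedger:
    """Surviving CM count per formation-year cohort at subject death.

    ``counts[k]`` is the surviving count of the cohort formed at
    formation-year offset ``k`` (0 = the initial, perinatal pool; k = the
    end-of-year subject age of the formation year).  ``trajectory[t]`` is
    the total CM count at subject age ``t`` (``trajectory[0]`` is the
    starting count).  ``formed_per_year[t]`` / ``destroyed_per_year[t]``
    tally the events of event year ``t`` (index 0 unused, kept for
    alignment).
    """

    subject: SubjectProfile
    counts: np.ndarray
    trajectory: np.ndarray
    formed_per_year: np.ndarray
    destroyed_per_year: np.ndarray

    def __post_init__(self) -> None:
        L = self.subject.lifespan
        for name in ("counts", "trajectory", "formed_per_year", "destroyed_per_year"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != (L + 1,):
                raise ValueError(f"{name} must have length lifespan+1 = {L + 1}, got {arr.shape}")
        if np.any(self.counts < -1e-12):
            raise ValueError("negative cohort count in ledger")

    @property
    def total(self) -> float:
        """Total CM count at subject death."""
        return float(self.counts.sum())

    @property
    def formation_years(self) -> np.ndarray:
        """Calendar year in which each cohort was formed (offset 0 = birth)."""
        return self.subject.birth_year + np.arange(self.subject.lifespan + 1)

    def cm_ages_at_death(self) -> np.ndarray:
        """CM age at subject death for each formation offset."""
        return self.subject.lifespan - np.arange(self.subject.lifespan + 1)

    def mean_cm_age_at_death(self) -> float:
        """Count-weighted mean CM age at autopsy."""
        if self.total <= 0:
            raise ValueError("empty ledger has no mean CM age")
        return float(np.average(self.cm_ages_at_death(), weights=self.counts))

    def conservation_error(self) -> float:
        """Relative error of trajectory[end] vs trajectory[0] + formed - destroyed."""
        expected = self.trajectory[0] + self.formed_per_year.sum() - self.destroyed_per_year.sum()
        scale = max(abs(expected), abs(self.trajectory[-1]), 1.0)
        return abs(self.trajectory[-1] - expected) / scale


@dataclass(frozen=True)
class TVBTVDRParams:
    """Time-varying birth rate / time-varying death rate parameters.

    All rates are annual fractions (0.01 = 1 %/year); slopes are per year of
    subject age (fraction/year^2).  ``b_i`` is the formation rate at birth and
    ``b_s`` its slope with subject age; a cohort formed at subject age t is
    assigned the permanent annual death rate ``d_i + d_s * t``.  Negative
    slopes are permitted.
    """

    b_s: float
    b_i: float
    d_s: float
    d_i: float

    def formation_rate(self, t: int) -> float:
        return self.b_i + self.b_s * t

    def death_rate(self, t_formed: int) -> float:
        return self.d_i + self.d_s * t_formed


DestructionMode = Literal["uniform", "by_formation_age", "by_cm_age"]


@dataclass(frozen=True)
class RateSchedule:
    """Direct annual formation/destruction schedules (Mode B).

    ``formation(t)`` gives the annual formation rate (fraction of the
    start-of-year total) at end-of-year subject age ``t``.  Destruction is
    targeted according to ``destruction_mode``:

    * ``"uniform"`` -- ``destruction(t)`` is the fraction destroyed across
      all cohorts during event year ``t``;
    * ``"by_formation_age"`` -- ``destruction(t_formed)`` is the permanent
      annual death rate assigned to a cohort when it is formed at subject
      age ``t_formed`` (the initial pool uses ``t_formed = 0``);
    * ``"by_cm_age"`` -- ``destruction(a)`` is the hazard experienced by a
      CM of age ``a`` (a >= 1) in any year.
    """

    formation: Callable[[int], float]
    destruction: Callable[[int], float]
    destruction_mode: DestructionMode = "uniform"

    @classmethod
    def constant(cls, formation: float, destruction: float) -> "RateSchedule":
        return cls(lambda t: formation, lambda t: destruction, "uniform")

    @classmethod
    def uniform(cls, formation: Callable[[int], float], destruction: Callable[[int], float]) -> "RateSchedule":
        return cls(formation, destruction, "uniform")

    @classmethod
    def by_formation_age(
        cls, formation: Callable[[int], float], death_rate: Callable[[int], float]
    ) -> "RateSchedule":
        return cls(formation, death_rate, "by_formation_age")

    @classmethod
    def by_cm_age(cls, formation: Callable[[int], float], hazard: Callable[[int], float]) -> "RateSchedule":
        return cls(formation, hazard, "by_cm_age")


# ---------------------------------------------------------------------------
# Hierarchical (stem-cell) parameterization
# ---------------------------------------------------------------------------

_PARAM_COLUMNS = (
    "n_csc",
    "cyc_frac",
    "mitosis_hours",
    "expansion_exponent",
    "apoptotic_frac",
    "apoptosis_hours",
    "halflife_years",
)


@dataclass
class HierarchicalParams:
    """Age/sex-resolved stem-cell kinetics parameters.

    Wraps a table with columns ``age, sex, n_csc, cyc_frac, mitosis_hours,
    expansion_exponent, apoptotic_frac, apoptosis_hours, halflife_years``;
    values are linearly interpolated between listed ages.  ``multipliers``
    scale a parameter uniformly across all ages (used by sensitivity
    sweeps), ``n0`` is the starting CM count per 10 g.
    """

    table: pd.DataFrame
    n0: float = DEFAULT_N0
    multipliers: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = {"age", "sex", *_PARAM_COLUMNS} - set(self.table.columns)
        if missing:
            raise ValueError(f"parameter table missing columns: {sorted(missing)}")
        bad = set(self.multipliers) - set(_PARAM_COLUMNS)
        if bad:
            raise ValueError(f"unknown multiplier parameters: {sorted(bad)}")
        for mult in self.multipliers.values():
            if mult < 0:
                raise ValueError("multipliers must be >= 0")

    def with_multipliers(self, **multipliers: float) -> "HierarchicalParams":
        merged = {**self.multipliers, **multipliers}
        return HierarchicalParams(self.table, n0=self.n0, multipliers=merged)

    def with_apoptotic_frac(self, alternative: Callable[[float], float]) -> "HierarchicalParams":
        """Return a copy whose apoptotic fraction column is replaced by
        ``alternative(age)`` (evaluated at the table's listed ages)."""
        table = self.table.copy()
        table["apoptotic_frac"] = [alternative(a) for a in table["age"]]
        return HierarchicalParams(table, n0=self.n0, multipliers=dict(self.multipliers))

    def row(self, sex: Sex, age: float) -> dict[str, float]:
        """Interpolated parameter values (multipliers applied) for one age."""
        sub = self.table[self.table["sex"] == sex].sort_values("age")
        if sub.empty:
            raise KeyError(f"parameter table has no rows for sex={sex!r}")
        ages = sub["age"].to_numpy(dtype=float)
        if age < ages[0] or age > ages[-1]:
            raise KeyError(
                f"parameter table for sex={sex!r} covers ages {ages[0]}..{ages[-1]}; "
                f"age {age} requested"
            )
        out: dict[str, float] = {}
        for col in _PARAM_COLUMNS:
            value = float(np.interp(age, ages, sub[col].to_numpy(dtype=float)))
            out[col] = value * float(self.multipliers.get(col, 1.0))
        if not 0.0 <= out["apoptotic_frac"]:
            raise ValueError(f"apoptotic_frac must be >= 0 at age {age}")
        if out["mitosis_hours"] <= 0 or out["apoptosis_hours"] <= 0:
            raise ValueError(f"durations must be > 0 at age {age}")
        return out


def default_formation_formula(row: Mapping[str, float]) -> float:
    """Annual CM formation from stem-cell kinetics.

    Each cycling CSC completes one mitosis per ``mitosis_hours``; the
    expansion exponent E amplifies each activation into ``2**E`` progeny::

        formed/year = n_csc * cyc_frac * (8766 / mitosis_hours) * 2**E
    """
    return (
        row["n_csc"]
        * row["cyc_frac"]
        * (HOURS_PER_YEAR / row["mitosis_hours"])
        * 2.0 ** row["expansion_exponent"]
    )


# ---------------------------------------------------------------------------
# Internal year-stepping engine
# ---------------------------------------------------------------------------


def _clip_rate(rate: float, what: str, t: int) -> float:
    if not np.isfinite(rate):
        raise ValueError(f"{what} evaluated to a non-finite value at year {t}")
    if rate < 0.0 or rate > 1.0:
        warnings.warn(
            f"{what} = {rate:.6g} at year {t} outside [0, 1]; clipped", stacklevel=3
        )
        rate = min(max(rate, 0.0), 1.0)
    return rate


def _survival_factor(rate: float, kernel: Kernel) -> float:
    if kernel == "annual":
        return 1.0 - rate
    if kernel == "continuous":
        return math.exp(-rate)
    raise ValueError(f"unknown survival kernel {kernel!r}")


def _run_cohorts(
    subject: SubjectProfile,
    n0: float,
    formed_fn: Callable[[int, np.ndarray], float],
    death_rate_fn: Callable[[int, int], float],
    new_cohort_death_rate_fn: Callable[[int], float] | None,
    kernel: Kernel,
) -> CohortLedger:
    """Shared year-stepping loop.

    ``formed_fn(t, counts)`` returns the absolute count formed during event
    year ``t`` from the start-of-year cohort counts.  ``death_rate_fn(k, t)``
    returns the annual death rate applied during year ``t`` to the cohort at
    formation offset ``k`` (k < t).  When ``new_cohort_death_rate_fn`` is
    given the per-cohort rate is fixed at formation time instead (the rate
    of the cohort formed at offset ``t``; offset 0 = initial pool).
    """
    L = subject.lifespan
    counts = np.zeros(L + 1)
    counts[0] = n0
    trajectory = np.zeros(L + 1)
    trajectory[0] = n0
    formed_per_year = np.zeros(L + 1)
    destroyed_per_year = np.zeros(L + 1)

    fixed_rates: np.ndarray | None = None
    if new_cohort_death_rate_fn is not None:
        fixed_rates = np.zeros(L + 1)
        fixed_rates[0] = _clip_rate(new_cohort_death_rate_fn(0), "death rate", 0)

    for t in range(1, L + 1):
        start = counts.copy()
        formed = formed_fn(t, start)
        if formed < 0:
            raise ValueError(f"negative formation count computed at year {t}")
        if fixed_rates is not None:
            rates = fixed_rates[:t]
        else:
            rates = np.array([_clip_rate(death_rate_fn(k, t), "death rate", t) for k in range(t)])
        factors = (
            (1.0 - rates) if kernel == "annual" else np.exp(-np.minimum(rates, np.inf))
        )
        survivors = start[:t] * factors
        destroyed = float((start[:t] - survivors).sum())
        counts[:t] = survivors
        counts[t] = formed
        if fixed_rates is not None:
            fixed_rates[t] = _clip_rate(new_cohort_death_rate_fn(t), "death rate", t)
        formed_per_year[t] = formed
        destroyed_per_year[t] = destroyed
        trajectory[t] = counts.sum()
        if np.any(counts < -1e-9 * max(n0, 1.0)):
            raise ValueError(f"negative cohort count at year {t}")
    counts[counts < 0] = 0.0

    return CohortLedger(subject, counts, trajectory, formed_per_year, destroyed_per_year)


# ---------------------------------------------------------------------------
# Scenario simulators
# ---------------------------------------------------------------------------


def simulate_rates(
    schedule: RateSchedule,
    subject: SubjectProfile,
    n0: float = DEFAULT_N0,
    kernel: Kernel = "annual",
) -> CohortLedger:
    """Simulate a direct-rate (Mode B) scenario.

    During event year t, ``formed = formation(t) * start-of-year total`` and
    destruction is applied per the schedule's targeting mode; both act on the
    start-of-year state simultaneously.  The default ``"annual"`` kernel makes
    constant full replacement exactly count-preserving, with the surviving
    initial-pool fraction ``(1 - r)**lifespan``.
    """

    def formed_fn(t: int, counts: np.ndarray) -> float:
        rate = _clip_rate(schedule.formation(t), "formation rate", t)
        return rate * float(counts.sum())

    mode = schedule.destruction_mode
    if mode == "uniform":
        return _run_cohorts(
            subject, n0, formed_fn, lambda k, t: schedule.destruction(t), None, kernel
        )
    if mode == "by_formation_age":
        return _run_cohorts(
            subject, n0, formed_fn, lambda k, t: 0.0, schedule.destruction, kernel
        )
    if mode == "by_cm_age":
        return _run_cohorts(
            subject, n0, formed_fn, lambda k, t: schedule.destruction(t - k), None, kernel
        )
    raise ValueError(f"unknown destruction mode {mode!r}")


FormationBasis = Literal["initial", "current"]


def simulate_tvb_tvdr(
    theta: TVBTVDRParams,
    subject: SubjectProfile,
    n0: float = DEFAULT_N0,
    formation_basis: FormationBasis = "initial",
    kernel: Kernel = "continuous",
) -> CohortLedger:
    """Simulate the time-varying birth rate / time-varying death rate model.

    The cohort formed at subject age t receives the permanent annual death
    rate ``d_i + d_s*t`` (the initial pool uses t = 0), applied in every
    subsequent year.  Annual formation at age t is ``(b_i + b_s*t)`` times
    the count at birth (default) or the start-of-year total when
    ``formation_basis="current"``.  The default continuous survival kernel
    treats each cohort's death rate as a constant yearly hazard.
    """

    def formed_fn(t: int, counts: np.ndarray) -> float:
        base = n0 if formation_basis == "initial" else float(counts.sum())
        rate = _clip_rate(theta.formation_rate(t), "formation rate", t)
        return rate * base

    return _run_cohorts(subject, n0, formed_fn, lambda k, t: 0.0, theta.death_rate, kernel)


def simulate_hierarchical(
    params: HierarchicalParams,
    subject: SubjectProfile,
    formation_formula: Callable[[Mapping[str, float]], float] | None = None,
    kernel: Kernel = "annual",
) -> CohortLedger:
    """Simulate the stem-cell (hierarchical, Mode A) scenario.

    Annual formation is computed from the interpolated parameter row via the
    pluggable ``formation_formula`` (default :func:`default_formation_formula`);
    annual destruction is the start-of-year total times the apoptotic fraction
    times apoptosis events per year (``8766 / apoptosis_hours``), applied
    uniformly across cohorts (random elimination).
    """
    formula = formation_formula or default_formation_formula
    rows = {t: params.row(subject.sex, t) for t in range(subject.lifespan + 1)}

    def formed_fn(t: int, counts: np.ndarray) -> float:
        return formula(rows[t])

    def death_rate_fn(k: int, t: int) -> float:
        row = rows[t]
        return row["apoptotic_frac"] * (HOURS_PER_YEAR / row["apoptosis_hours"])

    return _run_cohorts(subject, params.n0, formed_fn, death_rate_fn, None, kernel)


def simulate_age_structured(
    halflife: Callable[[float], float],
    mortality: Callable[[int, int], float],
    subject: SubjectProfile,
    n0: float = DEFAULT_N0,
    halflife_at: Literal["formation", "current"] = "formation",
) -> CohortLedger:
    """Generate an end-of-life CM age distribution from half-life decay.

    One reference cohort of size ``n0`` is seeded at birth and at every
    subsequent year; each cohort decays by ``2**(-1/h)`` per year (``h``
    evaluated at the subject age of cohort formation by default, or at the
    current age) with the extra mortality fraction ``mortality(a, t)``
    (CM age ``a``, subject age ``t``) deducted iteratively.  The resulting
    ledger's ``counts`` are the age distribution ``n(a)`` at autopsy (read
    through :meth:`CohortLedger.cm_ages_at_death`): with zero mortality a
    cohort of age ``a`` holds ``n0 * 2**(-a/h)``.
    """
    L = subject.lifespan
    counts = np.zeros(L + 1)
    counts[0] = n0
    h0 = float(halflife(0))
    if h0 <= 0:
        raise ValueError("half-life must be positive")
    h_fixed = np.zeros(L + 1)
    h_fixed[0] = h0
    trajectory = np.zeros(L + 1)
    trajectory[0] = n0
    formed = np.zeros(L + 1)
    destroyed = np.zeros(L + 1)
    for t in range(1, L + 1):
        start = counts.copy()
        removed = 0.0
        for k in range(t):
            h = h_fixed[k] if halflife_at == "formation" else float(halflife(t))
            if h <= 0:
                raise ValueError(f"half-life must be positive (age {t})")
            a = t - k
            mu = _clip_rate(float(mortality(a, t)), "mortality", t)
            factor = 2.0 ** (-1.0 / h) * (1.0 - mu)
            removed += start[k] * (1.0 - factor)
            counts[k] = start[k] * factor
        counts[t] = n0
        h_t = float(halflife(t))
        if h_t <= 0:
            raise ValueError(f"half-life must be positive (age {t})")
        h_fixed[t] = h_t
        formed[t] = n0
        destroyed[t] = removed
        trajectory[t] = counts.sum()
    return CohortLedger(subject, counts, trajectory, formed, destroyed)


# ---------------------------------------------------------------------------
# Derived quantities
# ---------------------------------------------------------------------------


def turnover_series(
    ledger: CohortLedger,
    denominator: float | Literal["adjusting"] = "adjusting",
) -> pd.Series:
    """Annual turnover (%/year): CMs formed in a year over CMs present.

    ``denominator`` is either a fixed CM count (the constant-density
    convention) or ``"adjusting"`` to divide by the start-of-year total of
    the simulated trajectory.  Indexed by end-of-year subject age 1..L.
    """
    L = ledger.subject.lifespan
    formed = ledger.formed_per_year[1:]
    if denominator == "adjusting":
        denom = ledger.trajectory[:-1]
    else:
        denom = np.full(L, float(denominator))
    if np.any(denom == 0):
        raise ZeroDivisionError("turnover denominator is zero")
    return pd.Series(100.0 * formed / denom, index=pd.RangeIndex(1, L + 1, name="age"))


def surviving_original_fraction(rate: float, years: int) -> float:
    """Fraction of the initial pool surviving constant annual replacement.

    Closed form ``(1 - rate)**years``; serves as the oracle for
    constant-replacement simulations under the annual kernel.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    if years < 0:
        raise ValueError("years must be >= 0")
    return (1.0 - rate) ** years
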
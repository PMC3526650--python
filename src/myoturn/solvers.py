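"""Inverse problems: turnover rates and scenario parameters from ΛC14.

The forward map composes a cohort simulation (:mod:`myoturn.population`)
with the radiocarbon assignment (:mod:`myoturn.carbon14`) to predict a
subject's ΛC14 under a turnover scenario.  Because a subject's per-cohort
C14-at-death values are independent of the turnover dynamics, they are
computed once and candidate scenarios only re-weight them -- which makes
dense rate scans and exhaustive grid searches cheap.

For subjects born before the bomb pulse the forward map rate -> ΛC14 is not
monotone: moderate turnover accumulates pulse-era C14, while high turnover
flushes those cohorts again and lowers ΛC14.  A single measured ΛC14 can
therefore have two preimages (a low and a high solution);
:func:`solve_constant` reports both branches and
:func:`bifurcation_scan` exposes the low branch's saturation.

Model selection follows the source methodology exactly: exhaustive grid
evaluation of the sum of squared errors over subjects, compared across
scenario families with an AIC penalty on parameter count (the AIC formula
is pluggable; see :func:`aic`).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from . import population as pop
from .carbon14 import (
    BombCurve,
    IncorporationPolicy,
    PloidyModel,
    assign_c14,
    cohort_c14_values,
    initial_c14,
)
from .population import (
    DEFAULT_N0,
    CohortLedger,
    HierarchicalParams,
    RateSchedule,
    SubjectProfile,
    TVBTVDRParams,
)

__all__ = [
    "ConstantTurnover",
    "TimeDependentTurnover",
    "ScenarioE2Params",
    "TurnoverScenario",
    "GridSpec",
    "BranchPoint",
    "BranchedSolution",
    "FitResult",
    "simulate_scenario",
    "predict_lambda",
    "solve_constant",
    "bifurcation_scan",
    "fit_global",
    "aic",
    "AIC_FORMULAS",
]


# ---------------------------------------------------------------------------
# Scenario families
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConstantTurnover:
    """Constant annual turnover with full random replacement (Scenario A)."""

    rate: float


@dataclass(frozen=True)
class TimeDependentTurnover:
    """Full random replacement with turnover linear in subject age.

    ``rate(t) = intercept + slope * t`` (fractions/year), total count held
    constant by balancing formation and destruction.
    """

    intercept: float
    slope: float


@dataclass(frozen=True)
class ScenarioE2Params:
    """CM-age-dependent destruction balanced by time-varying formation (E2).

    The hazard for a CM of age ``a`` is ``gamma0 * a**(-gamma1)`` (capped at
    1): destruction is inversely related to CM age, so young CMs die more
    often.  Formation each year equals total deaths, keeping the CM count
    constant.
    """

    gamma0: float
    gamma1: float

    def hazard(self, a: int) -> float:
        if a < 1:
            raise ValueError("CM-age hazard defined for a >= 1")
        return min(1.0, self.gamma0 * float(a) ** (-self.gamma1))


TurnoverScenario = (
    ConstantTurnover
    | TimeDependentTurnover
    | ScenarioE2Params
    | TVBTVDRParams
    | RateSchedule
    | HierarchicalParams
)


def _simulate_e2(theta: ScenarioE2Params, subject: SubjectProfile, n0: float) -> CohortLedger:
    def formed_fn(t: int, counts: np.ndarray) -> float:
        ages = t - np.arange(t)
        hz = np.array([theta.hazard(int(a)) for a in ages])
        return float((counts[:t] * hz).sum())

    return pop._run_cohorts(
        subject, n0, formed_fn, lambda k, t: theta.hazard(t - k), None, "annual"
    )


def simulate_scenario(
    scenario: TurnoverScenario,
    subject: SubjectProfile,
    n0: float = DEFAULT_N0,
) -> CohortLedger:
    """Dispatch a scenario object to the matching cohort simulator."""
    if isinstance(scenario, ConstantTurnover):
        r = scenario.rate
        return pop.simulate_rates(RateSchedule.constant(r, r), subject, n0=n0)
    if isinstance(scenario, TimeDependentTurnover):
        rate = lambda t: scenario.intercept + scenario.slope * t
        return pop.simulate_rates(RateSchedule.uniform(rate, rate), subject, n0=n0)
    if isinstance(scenario, TVBTVDRParams):
        return pop.simulate_tvb_tvdr(scenario, subject, n0=n0)
    if isinstance(scenario, ScenarioE2Params):
        return _simulate_e2(scenario, subject, n0)
    if isinstance(scenario, RateSchedule):
        return pop.simulate_rates(scenario, subject, n0=n0)
    if isinstance(scenario, HierarchicalParams):
        return pop.simulate_hierarchical(scenario, subject)
    raise TypeError(f"unknown scenario type {type(scenario).__name__}")


def predict_lambda(
    subject: SubjectProfile,
    scenario: TurnoverScenario,
    curve: BombCurve,
    ploidy: PloidyModel,
    policy: IncorporationPolicy = IncorporationPolicy(),
    n0: float = DEFAULT_N0,
    raw_curve: BombCurve | None = None,
) -> float:
    """Predicted ΛC14 (per mil) for a subject under a turnover scenario."""
    ledger = simulate_scenario(scenario, subject, n0=n0)
    assignment = assign_c14(ledger, curve, ploidy, policy, raw_curve)
    return assignment.lambda_c14


# ---------------------------------------------------------------------------
# Precomputed per-subject data and closed-form cohort weights
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _SubjectData:
    subject: SubjectProfile
    cohort_c14: np.ndarray  # per formation offset 0..L
    initial: float

    @property
    def lifespan(self) -> int:
        return self.subject.lifespan


def _subject_data(
    subject: SubjectProfile,
    curve: BombCurve,
    ploidy: PloidyModel,
    policy: IncorporationPolicy,
    raw_curve: BombCurve | None,
) -> _SubjectData:
    values = cohort_c14_values(subject, curve, ploidy, policy, raw_curve)
    init = initial_c14(
        curve, subject.birth_year - policy.delay_years, policy.initial_mode, raw_curve
    )
    return _SubjectData(subject, values, init)


def _constant_weights(rates: np.ndarray, L: int) -> np.ndarray:
    """Cohort weights under constant full replacement, per rate (rows)."""
    rates = np.atleast_1d(np.asarray(rates, dtype=float))
    t = np.arange(1, L + 1)
    w = np.empty((rates.size, L + 1))
    w[:, 0] = (1.0 - rates) ** L
    w[:, 1:] = rates[:, None] * (1.0 - rates[:, None]) ** (L - t)[None, :]
    return w


def _lambda_for_weights(w: np.ndarray, data: _SubjectData) -> np.ndarray:
    num = w @ data.cohort_c14
    den = w.sum(axis=1)
    return num / den - data.initial


def _predict_lambda_family(family: str, params: Mapping[str, float], data: _SubjectData) -> float:
    """Closed-form/fast ΛC14 for the grid-searchable families."""
    L = data.lifespan
    if family == "scenario_a":
        w = _constant_weights(np.array([params["rate"]]), L)
        return float(_lambda_for_weights(w, data)[0])
    if family == "time_dependent":
        t = np.arange(1, L + 1)
        r = np.clip(params["intercept"] + params["slope"] * t, 0.0, 1.0)
        # survival of the cohort formed at t through years t+1..L
        suffix = np.concatenate([np.cumprod((1.0 - r)[::-1])[::-1], [1.0]])
        w = np.empty(L + 1)
        w[0] = suffix[0]
        w[1:] = r * suffix[1:]
        return float(_lambda_for_weights(w[None, :], data)[0])
    if family == "tvb_tvdr":
        t = np.arange(1, L + 1)
        b = np.clip(params["b_i"] + params["b_s"] * t, 0.0, 1.0)
        d = np.clip(params["d_i"] + params["d_s"] * t, 0.0, 1.0)
        w = np.empty(L + 1)
        w[0] = math.exp(-min(max(params["d_i"], 0.0), 1.0) * L)
        w[1:] = b * np.exp(-d * (L - t))
        return float(_lambda_for_weights(w[None, :], data)[0])
    if family == "e2":
        theta = ScenarioE2Params(params["gamma0"], params["gamma1"])
        ledger = _simulate_e2(theta, data.subject, 1.0)
        w = ledger.counts
        return float(_lambda_for_weights(w[None, :], data)[0])
    raise ValueError(f"unknown scenario family {family!r}")


_FAMILY_PARAMS: dict[str, tuple[str, ...]] = {
    "scenario_a": ("rate",),
    "time_dependent": ("intercept", "slope"),
    "e2": ("gamma0", "gamma1"),
    "tvb_tvdr": ("b_s", "b_i", "d_s", "d_i"),
}


def scenario_from_params(family: str, params: Mapping[str, float]) -> TurnoverScenario:
    """Build the scenario object for a family/parameter combination."""
    if family == "scenario_a":
        return ConstantTurnover(params["rate"])
    if family == "time_dependent":
        return TimeDependentTurnover(params["intercept"], params["slope"])
    if family == "e2":
        return ScenarioE2Params(params["gamma0"], params["gamma1"])
    if family == "tvb_tvdr":
        return TVBTVDRParams(params["b_s"], params["b_i"], params["d_s"], params["d_i"])
    raise ValueError(f"unknown scenario family {family!r}")


# ---------------------------------------------------------------------------
# Grid specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridSpec:
    """Per-parameter (min, max, step) axes of an exhaustive search grid."""

    axes: Mapping[str, tuple[float, float, float]]

    def __post_init__(self) -> None:
        for name, (lo, hi, step) in self.axes.items():
            if step <= 0:
                raise ValueError(f"grid axis {name!r}: step must be > 0")
            if lo > hi:
                raise ValueError(f"grid axis {name!r}: min must be <= max")

    def axis(self, name: str) -> np.ndarray:
        lo, hi, step = self.axes[name]
        n = int(round((hi - lo) / step)) + 1
        points = lo + step * np.arange(n)
        return points[points <= hi + 1e-12 * max(abs(hi), 1.0)]

    def coarsened(self, factor: int) -> "GridSpec":
        return GridSpec({k: (lo, hi, step * factor) for k, (lo, hi, step) in self.axes.items()})

    @property
    def n_combinations(self) -> int:
        n = 1
        for name in self.axes:
            n *= self.axis(name).size
        return n


# ---------------------------------------------------------------------------
# Constant-turnover branch solver
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BranchPoint:
    """One branch of a constant-turnover inversion."""

    rate: float  # fraction/year
    predicted_lambda: float  # per mil
    residual: float  # per mil, |predicted - target|


@dataclass(frozen=True)
class BranchedSolution:
    low: BranchPoint
    high: BranchPoint | None
    bifurcation_exists: bool
    threshold_lambda: float | None
    converged: bool
    degenerate: bool = False


DEFAULT_RATE_GRID = GridSpec({"rate": (0.0, 0.50, 0.0001)})


def _local_minima(resid: np.ndarray) -> list[int]:
    """Indices of local minima of a residual scan (plateau-collapsed)."""
    n = resid.size
    minima: list[int] = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and resid[j + 1] == resid[i]:
            j += 1
        left_ok = i == 0 or resid[i - 1] > resid[i]
        right_ok = j == n - 1 or resid[j + 1] > resid[j]
        if left_ok and right_ok:
            minima.append(i)
        i = j + 1
    return minima


def solve_constant(
    subject: SubjectProfile,
    curve: BombCurve,
    ploidy: PloidyModel,
    policy: IncorporationPolicy,
    target_lambda: float,
    grid: GridSpec = DEFAULT_RATE_GRID,
    tol: float = 1.0,
    raw_curve: BombCurve | None = None,
) -> BranchedSolution:
    """Invert a measured ΛC14 into constant annual turnover rate(s).

    Scans predicted ΛC14 over a dense rate grid; local minima of
    ``|predicted - target|`` within ``tol`` (per mil) define the branches --
    the smallest-rate minimum is the low branch, the largest-rate one the
    high branch.  On a flat forward map (e.g. a constant curve) the result
    is flagged ``degenerate`` with the tie broken to the smallest rate; if
    no grid point fits within ``tol`` the best-effort global minimum is
    returned with ``converged=False``.
    """
    data = _subject_data(subject, curve, ploidy, policy, raw_curve)
    rates = grid.axis("rate")
    pred = _lambda_for_weights(_constant_weights(rates, data.lifespan), data)
    resid = np.abs(pred - target_lambda)

    def point(i: int) -> BranchPoint:
        return BranchPoint(float(rates[i]), float(pred[i]), float(resid[i]))

    if np.ptp(pred) < 1e-9:
        i = 0
        return BranchedSolution(
            low=point(i),
            high=None,
            bifurcation_exists=False,
            threshold_lambda=None,
            converged=bool(resid[i] <= tol),
            degenerate=True,
        )

    i_peak = int(np.argmax(pred))
    threshold = float(pred[i_peak:].min()) if 0 < i_peak < pred.size - 1 else None

    minima = _local_minima(resid)
    fitting = [i for i in minima if resid[i] <= tol]
    if not fitting:
        best = int(np.argmin(resid))
        return BranchedSolution(
            low=point(best),
            high=None,
            bifurcation_exists=False,
            threshold_lambda=threshold,
            converged=False,
        )
    lo_i, hi_i = fitting[0], fitting[-1]
    step = grid.axes["rate"][2]
    high = point(hi_i) if rates[hi_i] - rates[lo_i] > 1.5 * step else None
    return BranchedSolution(
        low=point(lo_i),
        high=high,
        bifurcation_exists=high is not None,
        threshold_lambda=threshold,
        converged=True,
    )


def bifurcation_scan(
    subject: SubjectProfile,
    curve: BombCurve,
    ploidy: PloidyModel,
    policy: IncorporationPolicy,
    true_rates: Sequence[float],
    grid: GridSpec = DEFAULT_RATE_GRID,
    tol: float = 1.0,
    raw_curve: BombCurve | None = None,
) -> dict[float, BranchedSolution]:
    """Forward-simulate ΛC14 at each true rate, then invert it.

    Exposes the low branch's saturation (the low solution stops tracking the
    input once the bifurcation opens) and the high branch's fidelity to the
    identity line.
    """
    data = _subject_data(subject, curve, ploidy, policy, raw_curve)
    out: dict[float, BranchedSolution] = {}
    for r in true_rates:
        lam = float(_lambda_for_weights(_constant_weights(np.array([r]), data.lifespan), data)[0])
        out[float(r)] = solve_constant(
            subject, curve, ploidy, policy, lam, grid=grid, tol=tol, raw_curve=raw_curve
        )
    return out


# ---------------------------------------------------------------------------
# AIC
# ---------------------------------------------------------------------------


def _aic_default(sse: float, n: int, k: int) -> float:
    return n * math.log(sse / n) + 2 * k


def _aic_corrected(sse: float, n: int, k: int) -> float:
    if n - k - 1 <= 0:
        raise ValueError("AICc requires n > k + 1")
    return _aic_default(sse, n, k) + 2 * k * (k + 1) / (n - k - 1)


def _aic_per_observation(sse: float, n: int, k: int) -> float:
    return math.log(sse / n) + 2 * k / n


AIC_FORMULAS = {
    "default": _aic_default,
    "aicc": _aic_corrected,
    "per_observation": _aic_per_observation,
}


def aic(sse: float, n_subjects: int, k_params: int, formula_id: str = "default") -> float:
    """Akaike information criterion for an SSE-based fit.

    The default is ``n*ln(SSE/n) + 2k``.  The formula is pluggable because
    published AIC magnitudes for these datasets do not pin down a unique
    form; comparisons should rely on AIC *ranking* between families rather
    than absolute values.
    """
    if sse <= 0:
        raise ValueError("sse must be > 0")
    if n_subjects <= 0:
        raise ValueError("n_subjects must be > 0")
    if k_params < 0:
        raise ValueError("k_params must be >= 0")
    try:
        fn = AIC_FORMULAS[formula_id]
    except KeyError:
        raise ValueError(f"unknown AIC formula {formula_id!r}") from None
    return float(fn(float(sse), int(n_subjects), int(k_params)))


# ---------------------------------------------------------------------------
# Global grid fit
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Outcome of an exhaustive grid fit of one scenario family."""

    family: str
    best_params: dict[str, float]
    sse: float
    aic: float
    k_params: int
    predictions: pd.DataFrame  # columns: subject, observed, predicted, residual
    grid: GridSpec
    ties: list[dict[str, float]] = field(default_factory=list)
    strategy: str = "exhaustive"

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "best_params": self.best_params,
            "sse": self.sse,
            "aic": self.aic,
            "k_params": self.k_params,
            "strategy": self.strategy,
            "grid": {k: list(v) for k, v in self.grid.axes.items()},
            "ties": self.ties,
            "predictions": self.predictions.to_dict(orient="records"),
        }


def _sse_for_params(
    family: str, params: Mapping[str, float], data: Sequence[_SubjectData], observed: np.ndarray
) -> float:
    pred = np.array([_predict_lambda_family(family, params, d) for d in data])
    return float(((pred - observed) ** 2).sum())


def _enumerate_grid(
    family: str,
    axes: Mapping[str, np.ndarray],
    data: Sequence[_SubjectData],
    observed: np.ndarray,
    tie_tol: float = 1e-9,
) -> tuple[dict[str, float], float, list[dict[str, float]]]:
    names = list(axes)
    best_sse = math.inf
    ties: list[tuple[tuple[float, ...], float]] = []
    for combo in itertools.product(*(axes[n] for n in names)):
        params = dict(zip(names, (float(v) for v in combo)))
        sse = _sse_for_params(family, params, data, observed)
        if sse < best_sse - tie_tol:
            best_sse = sse
            ties = [(tuple(params[n] for n in names), sse)]
        elif sse <= best_sse + tie_tol:
            ties.append((tuple(params[n] for n in names), sse))
    ties_sorted = sorted(ties)
    best_combo = ties_sorted[0][0]
    best = dict(zip(names, best_combo))
    tie_dicts = [dict(zip(names, c)) for c, _ in ties_sorted]
    return best, best_sse, tie_dicts


def fit_global(
    subjects: Sequence[SubjectProfile],
    family: str,
    grid: GridSpec,
    curve: BombCurve,
    ploidy: PloidyModel,
    policy: IncorporationPolicy = IncorporationPolicy(),
    observations: Mapping[str, float] | None = None,
    strategy: Literal["exhaustive", "coarse_to_fine"] = "coarse_to_fine",
    coarse_factor: int = 4,
    aic_formula: str = "default",
    raw_curve: BombCurve | None = None,
) -> FitResult:
    """Exhaustive (or coarse-to-fine) grid fit of a scenario family.

    Observed ΛC14 values come from ``observations[subject.id]`` or, failing
    that, ``subject.lambda_c14``; subjects without an observation are
    skipped.  SSE = sum over subjects of (predicted - observed)^2 on ΛC14.
    All grid points tied with the minimum within 1e-9 are reported; the
    canonical best is the lexicographically smallest parameter vector.
    ``coarse_to_fine`` evaluates a ``coarse_factor``-times coarser grid
    first, then refines around its optimum at the full resolution; both
    stages only visit points of the requested grid.
    """
    expected = _FAMILY_PARAMS.get(family)
    if expected is None:
        raise ValueError(f"unknown scenario family {family!r}; choose from {sorted(_FAMILY_PARAMS)}")
    if set(grid.axes) != set(expected):
        raise ValueError(f"grid axes {sorted(grid.axes)} do not match family parameters {sorted(expected)}")
    if grid.n_combinations == 0:
        raise ValueError("empty grid")

    usable: list[SubjectProfile] = []
    obs_list: list[float] = []
    for s in subjects:
        value = (observations or {}).get(s.id, s.lambda_c14)
        if value is not None:
            usable.append(s)
            obs_list.append(float(value))
    if not usable:
        raise ValueError("no subject has an observed ΛC14 value")
    observed = np.array(obs_list)
    data = [_subject_data(s, curve, ploidy, policy, raw_curve) for s in usable]

    names = list(expected)
    fine_axes = {n: grid.axis(n) for n in names}

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # grid corners may clip rates; not informative here
        if strategy == "exhaustive":
            best, best_sse, ties = _enumerate_grid(family, fine_axes, data, observed)
        elif strategy == "coarse_to_fine":
            coarse_axes = {
                n: fine_axes[n][:: max(1, int(coarse_factor))] for n in names
            }
            coarse_best, _, _ = _enumerate_grid(family, coarse_axes, data, observed)
            refined_axes = {}
            for n in names:
                axis = fine_axes[n]
                step = grid.axes[n][2]
                half = coarse_factor * step
                mask = (axis >= coarse_best[n] - half - 1e-12) & (axis <= coarse_best[n] + half + 1e-12)
                refined_axes[n] = axis[mask]
            best, best_sse, ties = _enumerate_grid(family, refined_axes, data, observed)
        else:
            raise ValueError(f"unknown strategy {strategy!r}")

        pred = np.array([_predict_lambda_family(family, best, d) for d in data])

    predictions = pd.DataFrame(
        {
            "subject": [s.id for s in usable],
            "observed": observed,
            "predicted": pred,
            "residual": pred - observed,
        }
    )
    k = len(names)
    return FitResult(
        family=family,
        best_params=best,
        sse=best_sse,
        aic=aic(best_sse, len(usable), k, aic_formula),
        k_params=k,
        predictions=predictions,
        grid=grid,
        ties=ties,
        strategy=strategy,
    )
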
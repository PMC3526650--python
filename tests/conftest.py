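"""Shared fixtures: synthetic curves, ploidy models, and a discrete-agent
oracle for the continuous cohort bookkeeping."""

from __future__ import annotations

import numpy as np
import pytest

from myoturn import (
    IncorporationPolicy,
    PloidyModel,
    smooth_curve,
    synthetic_bomb_curve,
    synthetic_params,
)


@pytest.fixture(scope="session")
def raw_curve():
    """Monthly synthetic bomb-pulse curve (flat 0 pre-1955, 1963 peak)."""
    return synthetic_bomb_curve()


@pytest.fixture(scope="session")
def curve(raw_curve):
    """Yearly 1-year-smoothed version of the synthetic pulse curve."""
    return smooth_curve(raw_curve)


@pytest.fixture(scope="session")
def no_ploidy():
    return PloidyModel.none()


@pytest.fixture(scope="session")
def ploidy():
    return PloidyModel.sigmoid()


@pytest.fixture(scope="session")
def policy():
    return IncorporationPolicy()


@pytest.fixture(scope="session")
def stem_params():
    return synthetic_params()


def agent_constant_replacement(
    rate: float, lifespan: int, n0: int, reps: int, seed: int
) -> np.ndarray:
    """Discrete-agent constant-replacement simulation.

    Bernoulli per-agent deaths (binomial per cohort) and Poisson-rounded
    births from the start-of-year total, per replicate.  Returns the
    (reps, lifespan+1) array of per-cohort survivor counts at death; its
    column means estimate the continuous ledger's cohort counts.
    """
    rng = np.random.default_rng(seed)
    counts = np.zeros((reps, lifespan + 1), dtype=np.int64)
    counts[:, 0] = n0
    for t in range(1, lifespan + 1):
        total = counts.sum(axis=1)
        births = rng.poisson(rate * total)
        counts = rng.binomial(counts, 1.0 - rate)
        counts[:, t] = births
    return counts
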
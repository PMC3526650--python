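"""Inversion machinery: branch solving, bifurcation, grid fits, AIC."""

import itertools
import math

import numpy as np
import pytest

from myoturn import (
    ConstantTurnover,
    GridSpec,
    IncorporationPolicy,
    ScenarioE2Params,
    SubjectProfile,
    SyntheticCohortSpec,
    TimeDependentTurnover,
    TVBTVDRParams,
    aic,
    bifurcation_scan,
    fit_global,
    generate_subjects,
    predict_lambda,
    solve_constant,
    subjects_from_frame,
)
from myoturn.solvers import _predict_lambda_family, _subject_data, scenario_from_params

PRE_PULSE = SubjectProfile("old", "male", 1936, 70)  # born before the pulse
POST_PEAK = SubjectProfile("young", "male", 1970, 35)  # born on the decaying flank


class TestForwardMap:
    def test_zero_turnover_zero_ploidy_lambda_zero(self, curve, no_ploidy, policy):
        lam = predict_lambda(POST_PEAK, ConstantTurnover(0.0), curve, no_ploidy, policy)
        assert lam == pytest.approx(0.0, abs=1e-12)

    def test_monotone_decreasing_for_post_peak_subject(self, curve, no_ploidy, policy):
        """On the decaying flank of the pulse, more turnover can only pull
        the end average down: the forward map has a unique preimage."""
        lams = [
            predict_lambda(POST_PEAK, ConstantTurnover(r), curve, no_ploidy, policy)
            for r in np.linspace(0.005, 0.4, 25)
        ]
        assert np.all(np.diff(lams) < 0)

    def test_interior_extremum_for_pre_pulse_subject(self, curve, no_ploidy, policy):
        rates = np.linspace(0.0, 0.4, 81)
        lams = np.array(
            [predict_lambda(PRE_PULSE, ConstantTurnover(r), curve, no_ploidy, policy) for r in rates]
        )
        peak = int(np.argmax(lams))
        assert 0 < peak < rates.size - 1
        assert np.all(np.diff(lams[: peak + 1]) > 0)
        assert np.all(np.diff(lams[peak:]) < 0)

    @pytest.mark.parametrize(
        "family,params",
        [
            ("scenario_a", {"rate": 0.02}),
            ("time_dependent", {"intercept": 0.01, "slope": 0.0005}),
            ("e2", {"gamma0": 0.123, "gamma1": 1.42}),
            ("tvb_tvdr", {"b_s": 0.001, "b_i": 0.025, "d_s": 0.005, "d_i": 0.01}),
        ],
    )
    def test_fast_family_predictor_matches_simulation_route(
        self, curve, ploidy, policy, family, params
    ):
        """The solver's closed-form cohort weights agree with the generic
        simulate-then-assign forward route for every fittable family."""
        data = _subject_data(PRE_PULSE, curve, ploidy, policy, None)
        fast = _predict_lambda_family(family, params, data)
        slow = predict_lambda(PRE_PULSE, scenario_from_params(family, params), curve, ploidy, policy)
        assert fast == pytest.approx(slow, rel=1e-9, abs=1e-9)


class TestSolveConstant:
    def test_degenerate_on_constant_curve(self, no_ploidy, policy):
        from myoturn import BombCurve

        years = np.arange(1955, 2011, dtype=float)
        c = BombCurve(years, np.full(years.size, 50.0), resolution="yearly", smoothed=True)
        sol = solve_constant(POST_PEAK, c, no_ploidy, policy, target_lambda=0.0)
        assert sol.degenerate
        assert sol.low.rate == 0.0
        assert sol.converged

    @pytest.mark.parametrize("true_rate", [0.005, 0.02, 0.10])
    def test_round_trip_recovery_within_one_grid_step(
        self, curve, no_ploidy, policy, true_rate
    ):
        """Simulated ΛC14 at a known constant rate is inverted back to that
        rate (on whichever branch contains it) within one grid step."""
        lam = predict_lambda(PRE_PULSE, ConstantTurnover(true_rate), curve, no_ploidy, policy)
        sol = solve_constant(PRE_PULSE, curve, no_ploidy, policy, lam)
        step = 0.0001
        candidates = [sol.low.rate] + ([sol.high.rate] if sol.high else [])
        assert min(abs(c - true_rate) for c in candidates) <= step + 1e-12
        assert sol.converged

    def test_nonconverged_flag_for_unreachable_target(self, curve, no_ploidy, policy):
        sol = solve_constant(PRE_PULSE, curve, no_ploidy, policy, target_lambda=1e5)
        assert not sol.converged
        assert sol.low.residual > 1.0


class TestBifurcation:
    def test_pre_pulse_subject_bifurcates_at_high_rates(self, curve, no_ploidy, policy):
        scan = bifurcation_scan(PRE_PULSE, curve, no_ploidy, policy, [0.06, 0.10, 0.15, 0.20])
        assert all(sol.bifurcation_exists for sol in scan.values())

    def test_high_branch_tracks_identity(self, curve, no_ploidy, policy):
        scan = bifurcation_scan(PRE_PULSE, curve, no_ploidy, policy, [0.06, 0.10, 0.15, 0.20])
        for true, sol in scan.items():
            assert sol.high is not None
            assert sol.high.rate == pytest.approx(true, abs=0.0001 + 1e-12)

    def test_low_branch_saturates_below_true_input(self, curve, no_ploidy, policy):
        """Once the bifurcation opens, the low branch stops tracking the
        input and saturates at a small, slowly drifting rate."""
        true_rates = [0.10, 0.15, 0.20]
        scan = bifurcation_scan(PRE_PULSE, curve, no_ploidy, policy, true_rates)
        lows = [scan[r].low.rate for r in true_rates]
        assert all(low < 0.05 for low in lows)
        assert max(lows) - min(lows) < 0.01

    def test_post_peak_subject_has_single_branch(self, curve, no_ploidy, policy):
        scan = bifurcation_scan(POST_PEAK, curve, no_ploidy, policy, [0.02, 0.10, 0.20])
        for true, sol in scan.items():
            assert not sol.bifurcation_exists
            assert sol.high is None
            assert sol.low.rate == pytest.approx(true, abs=0.0001 + 1e-12)


class TestAIC:
    def test_penalty_monotone_in_k(self):
        for formula in ("default", "per_observation"):
            values = [aic(100.0, 12, k, formula) for k in range(5)]
            assert np.all(np.diff(values) > 0)

    def test_default_formula_zero_point(self):
        assert aic(12.0, 12, 0) == pytest.approx(0.0)

    def test_default_formula_value(self):
        assert aic(5589.0, 12, 4) == pytest.approx(12 * math.log(5589 / 12) + 8)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            aic(0.0, 12, 1)
        with pytest.raises(ValueError):
            aic(10.0, 0, 1)
        with pytest.raises(ValueError):
            aic(10.0, 12, -1)
        with pytest.raises(ValueError):
            aic(10.0, 12, 1, "no_such_formula")


class TestGridSpec:
    def test_axis_inclusive_of_endpoints(self):
        g = GridSpec({"x": (0.0, 1.0, 0.25)})
        np.testing.assert_allclose(g.axis("x"), [0, 0.25, 0.5, 0.75, 1.0])

    def test_invalid_axis_rejected(self):
        with pytest.raises(ValueError):
            GridSpec({"x": (0.0, 1.0, 0.0)})
        with pytest.raises(ValueError):
            GridSpec({"x": (2.0, 1.0, 0.1)})

    def test_combination_count(self):
        g = GridSpec({"a": (0, 1, 0.5), "b": (0, 1, 0.25)})
        assert g.n_combinations == 3 * 5


TVB_GRID = GridSpec(
    {
        "b_s": (0.0005, 0.0025, 0.0005),
        "b_i": (0.07, 0.11, 0.01),
        "d_s": (0.001, 0.003, 0.0005),
        "d_i": (0.05, 0.09, 0.01),
    }
)
THETA_TRUE = TVBTVDRParams(b_s=0.0015, b_i=0.09, d_s=0.002, d_i=0.07)


@pytest.fixture(scope="module")
def cohort(curve, ploidy, policy):
    spec = SyntheticCohortSpec(n_subjects=12, seed=7, scenario=THETA_TRUE)
    frame = generate_subjects(spec, curve, ploidy, policy)
    return subjects_from_frame(frame)


class TestFitGlobal:
    def test_exhaustive_matches_brute_force_oracle(self, curve, ploidy, policy, cohort):
        """The fitter's grid argmin equals an independent re-enumeration of
        the same 5^4 grid via the generic simulation route."""
        result = fit_global(cohort, "tvb_tvdr", TVB_GRID, curve, ploidy, policy, strategy="exhaustive")

        names = ["b_s", "b_i", "d_s", "d_i"]
        best_sse, best_combo = math.inf, None
        for combo in itertools.product(*(TVB_GRID.axis(n) for n in names)):
            params = dict(zip(names, combo))
            theta = TVBTVDRParams(**params)
            sse = 0.0
            for s in cohort:
                pred = predict_lambda(s, theta, curve, ploidy, policy)
                sse += (pred - s.lambda_c14) ** 2
            if sse < best_sse:
                best_sse, best_combo = sse, params
        assert result.best_params == pytest.approx(best_combo)
        assert result.sse == pytest.approx(best_sse, rel=1e-6, abs=1e-9)

    def test_recovers_generating_parameters_exactly(self, curve, ploidy, policy, cohort):
        """End-to-end: a cohort generated from an on-grid parameter vector is
        fitted back to exactly that vector (SSE ~ 0)."""
        result = fit_global(cohort, "tvb_tvdr", TVB_GRID, curve, ploidy, policy, strategy="exhaustive")
        assert result.best_params["b_s"] == pytest.approx(THETA_TRUE.b_s)
        assert result.best_params["b_i"] == pytest.approx(THETA_TRUE.b_i)
        assert result.best_params["d_s"] == pytest.approx(THETA_TRUE.d_s)
        assert result.best_params["d_i"] == pytest.approx(THETA_TRUE.d_i)
        assert result.sse < 1e-12

    def test_coarse_to_fine_matches_exhaustive(self, curve, ploidy, policy, cohort):
        exhaustive = fit_global(cohort, "tvb_tvdr", TVB_GRID, curve, ploidy, policy, strategy="exhaustive")
        ctf = fit_global(
            cohort, "tvb_tvdr", TVB_GRID, curve, ploidy, policy, strategy="coarse_to_fine", coarse_factor=2
        )
        assert ctf.best_params == pytest.approx(exhaustive.best_params)

    def test_sse_self_consistency(self, curve, ploidy, policy, cohort):
        result = fit_global(cohort, "tvb_tvdr", TVB_GRID, curve, ploidy, policy, strategy="exhaustive")
        recomputed = float((result.predictions["residual"] ** 2).sum())
        assert result.sse == pytest.approx(recomputed, rel=1e-9, abs=1e-12)
        # best parameters lie on the requested grid
        for name in result.best_params:
            axis = TVB_GRID.axis(name)
            assert np.min(np.abs(axis - result.best_params[name])) < 1e-12

    def test_single_subject_scenario_a_recovery(self, curve, no_ploidy, policy):
        true_rate = 0.02
        lam = predict_lambda(POST_PEAK, ConstantTurnover(true_rate), curve, no_ploidy, policy)
        s = SubjectProfile("y", "male", 1970, 35, lambda_c14=lam)
        grid = GridSpec({"rate": (0.0, 0.05, 0.005)})
        result = fit_global([s], "scenario_a", grid, curve, no_ploidy, policy, strategy="exhaustive")
        assert result.best_params["rate"] == pytest.approx(true_rate)
        assert result.sse < 1e-15

    def test_aic_ranking_prefers_generating_family(self, curve, ploidy, policy, cohort):
        """On data generated by the four-parameter model, the richer family
        achieves a lower AIC than a constant-turnover fit despite its
        parameter-count penalty."""
        tvb = fit_global(cohort, "tvb_tvdr", TVB_GRID, curve, ploidy, policy, strategy="exhaustive")
        const = fit_global(
            cohort, "scenario_a", GridSpec({"rate": (0.0, 0.2, 0.002)}), curve, ploidy, policy,
            strategy="exhaustive",
        )
        assert tvb.aic < const.aic

    def test_empty_grid_or_missing_observations_rejected(self, curve, ploidy, policy):
        s = SubjectProfile("n", "male", 1970, 30)  # no observed ΛC14
        with pytest.raises(ValueError, match="observed"):
            fit_global([s], "scenario_a", GridSpec({"rate": (0.0, 0.1, 0.01)}), curve, ploidy, policy)
        with pytest.raises(ValueError, match="family"):
            fit_global([PRE_PULSE], "no_such_family", GridSpec({"rate": (0, 1, 1)}), curve, ploidy, policy)

    def test_e2_fit_recovers_generating_parameters(self, curve, ploidy, policy):
        theta = ScenarioE2Params(0.12, 1.4)
        subjects = []
        for i, (birth, L) in enumerate([(1936, 70), (1950, 55), (1970, 35)]):
            s = SubjectProfile(f"e{i}", "male", birth, L)
            lam = predict_lambda(s, theta, curve, ploidy, policy)
            subjects.append(SubjectProfile(f"e{i}", "male", birth, L, lambda_c14=lam))
        grid = GridSpec({"gamma0": (0.04, 0.2, 0.04), "gamma1": (0.6, 1.8, 0.2)})
        result = fit_global(subjects, "e2", grid, curve, ploidy, policy, strategy="exhaustive")
        assert result.best_params["gamma0"] == pytest.approx(0.12)
        assert result.best_params["gamma1"] == pytest.approx(1.4)
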
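"""Bomb-curve handling, polyploidization correction, and ΛC14 identities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from myoturn import (
    BombCurve,
    IncorporationPolicy,
    PloidyModel,
    RateSchedule,
    SubjectProfile,
    assign_c14,
    cohort_c14_at_death,
    end_c14,
    initial_c14,
    lambda_c14,
    smooth_curve,
    synthetic_bomb_curve,
)
from myoturn.carbon14 import _ploidy_step
from myoturn.population import simulate_rates


def constant_curve(value=120.0, start=1955, end=2010):
    years = np.arange(start, end + 1, dtype=float)
    return BombCurve(years, np.full(years.size, value), resolution="yearly", smoothed=True)


class TestBombCurve:
    def test_pre_1955_values_must_be_zero(self):
        with pytest.raises(ValueError, match="1955"):
            BombCurve(np.array([1950.0, 1960.0]), np.array([5.0, 10.0]))

    def test_pre_1955_query_is_zero_even_outside_coverage(self, curve):
        assert curve.at(1940) == 0.0
        assert curve.at(1800) == 0.0

    def test_query_beyond_coverage_raises(self, curve):
        with pytest.raises(ValueError, match="ends at"):
            curve.at(2050)

    def test_empty_curve_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            BombCurve(np.array([]), np.array([]))


class TestSmoothing:
    def test_constant_series_unchanged(self):
        months = np.arange(1960, 1965, 1 / 12.0) + 0.5 / 12.0
        raw = BombCurve(months, np.full(months.size, 42.0), resolution="monthly")
        sm = smooth_curve(raw)
        assert np.all(sm.values == pytest.approx(42.0))
        assert sm.resolution == "yearly" and sm.smoothed

    def test_single_month_spike_averages_down(self):
        months = np.arange(1960, 1961, 1 / 12.0) + 0.5 / 12.0
        values = np.zeros(12)
        values[4] = 12 * 7.0
        raw = BombCurve(months, values, resolution="monthly")
        assert smooth_curve(raw).at(1960) == pytest.approx(7.0)

    def test_smoothed_peak_not_above_raw_peak(self, raw_curve, curve):
        assert curve.values.max() <= raw_curve.values.max() + 1e-12

    def test_pre_1955_stays_zero(self, curve):
        assert np.all(curve.values[curve.times < 1955] == 0.0)


class TestSyntheticCurve:
    def test_peak_value_exact(self, raw_curve):
        yearly = synthetic_bomb_curve(resolution="yearly")
        assert yearly.at(1963) == 800.0
        # monthly samples sit at month midpoints, so the sampled maximum
        # only approximates the analytic peak
        assert raw_curve.values.max() == pytest.approx(800.0, rel=1e-3)
        assert abs(raw_curve.times[np.argmax(raw_curve.values)] - 1963) < 1.0
        assert smooth_curve(raw_curve).at(1963) <= 800.0

    def test_zero_peak_gives_null_curve(self):
        c = synthetic_bomb_curve(peak_value=0.0)
        assert np.all(c.values == 0.0)

    def test_zero_decay_plateaus(self):
        c = synthetic_bomb_curve(decay_constant=0.0, resolution="yearly")
        after = c.values[c.times >= 1963]
        assert np.all(after == pytest.approx(800.0))

    def test_monotone_rise(self, raw_curve):
        rise = raw_curve.values[(raw_curve.times >= 1955) & (raw_curve.times <= 1963)]
        assert np.all(np.diff(rise) >= 0)

    def test_nonphysical_parameters_rejected(self):
        with pytest.raises(ValueError):
            synthetic_bomb_curve(peak_year=1940)
        with pytest.raises(ValueError):
            synthetic_bomb_curve(peak_value=-5)


class TestInitialC14:
    def test_pre_bomb_birth_is_zero_for_all_modes(self, raw_curve, curve):
        for mode in ("smoothed", "min_within_12mo", "max_within_12mo"):
            assert initial_c14(curve, 1940, mode, raw_curve) == 0.0

    def test_constant_curve_all_modes_agree(self):
        c = constant_curve(88.0)
        for mode in ("smoothed", "min_within_12mo", "max_within_12mo"):
            assert initial_c14(c, 1980, mode) == pytest.approx(88.0)

    def test_mode_ordering_at_peak(self, raw_curve, curve):
        lo = initial_c14(curve, 1963, "min_within_12mo", raw_curve)
        mid = initial_c14(curve, 1963, "smoothed", raw_curve)
        hi = initial_c14(curve, 1963, "max_within_12mo", raw_curve)
        assert lo <= mid <= hi
        assert lo < hi


class TestPloidyModel:
    def test_cumulative_monotone_in_unit_interval(self, ploidy):
        cum = [ploidy.cumulative(a) for a in range(0, 100)]
        assert cum[0] == 0.0
        assert np.all(np.diff(cum) >= 0)
        assert all(0 <= c <= 1 for c in cum)

    def test_incremental_nonnegative(self, ploidy):
        assert all(ploidy.incremental(a) >= 0 for a in range(0, 100))

    def test_scale_zero_disables_correction(self, curve):
        s = SubjectProfile("p", "male", 1960, 40)
        off = PloidyModel.sigmoid(scale=0.0)
        v0 = cohort_c14_at_death(1960, s, curve, PloidyModel.none())
        v1 = cohort_c14_at_death(1960, s, curve, off)
        assert v0 == v1

    def test_takamatsu_scaling_reduces_cumulative(self):
        full = PloidyModel.sigmoid(scale=1.0)
        tak = PloidyModel.sigmoid(scale=0.78)
        assert tak.cumulative(30) == pytest.approx(0.78 * full.cumulative(30))


class TestCohortC14:
    def test_zero_ploidy_zero_delay_reads_curve(self, curve, no_ploidy):
        s = SubjectProfile("c", "male", 1950, 50)
        for offset in (0, 10, 25):
            v = cohort_c14_at_death(1950 + offset, s, curve, no_ploidy)
            assert v == pytest.approx(curve.at(1950 + offset))

    def test_equal_weight_update(self):
        assert _ploidy_step(0.0, 100.0, 1.0, "as_described") == pytest.approx(50.0)

    def test_update_stays_between_old_value_and_atmosphere(self):
        v = 10.0
        for atm, p in [(100.0, 0.2), (0.0, 0.5), (50.0, 0.05)]:
            new = _ploidy_step(v, atm, p, "as_described")
            assert min(v, atm) <= new <= max(v, atm)
            v = new

    @given(
        offset=st.integers(0, 50),
        scale=st.floats(0.0, 1.0),
        delay=st.integers(0, 2),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_cohort_value_is_convex_combination_of_curve(self, curve, offset, scale, delay):
        """Every cohort value lies within the atmospheric range spanned
        during the subject's life (the update is a running convex mix)."""
        s = SubjectProfile("c", "male", 1950, 50)
        pol = IncorporationPolicy(delay_years=delay)
        pl = PloidyModel.sigmoid(scale=scale)
        v = cohort_c14_at_death(1950 + offset, s, curve, pl, pol)
        window = [curve.at(y - delay) for y in range(1950 + offset, 2001)]
        assert min(window) - 1e-9 <= v <= max(window) + 1e-9

    def test_delay_equals_time_shifted_curve(self, curve, ploidy):
        """Reading the curve with a 2-year incorporation delay is identical
        to reading a curve shifted 2 years forward in time."""
        d = 2
        shifted = BombCurve(curve.times + d, curve.values, resolution="yearly", smoothed=True)
        s = SubjectProfile("c", "male", 1958, 45)
        led = simulate_rates(RateSchedule.constant(0.02, 0.02), s, n0=1.0)
        a_delay = assign_c14(led, curve, ploidy, IncorporationPolicy(delay_years=d))
        a_shift = assign_c14(led, shifted, ploidy, IncorporationPolicy(delay_years=0))
        np.testing.assert_allclose(a_delay.per_cohort, a_shift.per_cohort, rtol=1e-12)
        assert a_delay.lambda_c14 == pytest.approx(a_shift.lambda_c14, rel=1e-12)

    def test_formation_outside_lifespan_rejected(self, curve, no_ploidy):
        s = SubjectProfile("c", "male", 1950, 30)
        with pytest.raises(ValueError, match="outside"):
            cohort_c14_at_death(1990, s, curve, no_ploidy)


class TestSubjectLevel:
    def test_single_cohort_end_is_its_assignment(self, curve, no_ploidy):
        s = SubjectProfile("e", "male", 1950, 10)
        led = simulate_rates(RateSchedule.constant(0.0, 0.0), s, n0=5.0)
        a = assign_c14(led, curve, no_ploidy)
        assert a.end_c14 == pytest.approx(a.per_cohort[0])

    def test_lambda_zero_on_constant_curve_any_dynamics(self, no_ploidy):
        """ΛC14 vanishes on a constant atmosphere with zero ploidy,
        whatever the turnover dynamics."""
        c = constant_curve(77.0)
        s = SubjectProfile("e", "male", 1970, 35)
        for rates in [(0.0, 0.0), (0.05, 0.05), (0.3, 0.1)]:
            led = simulate_rates(RateSchedule.constant(*rates), s, n0=1.0)
            a = assign_c14(led, c, no_ploidy)
            assert a.end_c14 == pytest.approx(77.0)
            assert a.lambda_c14 == pytest.approx(0.0, abs=1e-12)

    def test_zero_turnover_zero_ploidy_lambda_zero(self, curve, no_ploidy):
        s = SubjectProfile("e", "female", 1962, 40)
        led = simulate_rates(RateSchedule.constant(0.0, 0.0), s, n0=1.0)
        a = assign_c14(led, curve, no_ploidy)
        assert a.end_c14 == pytest.approx(a.initial_c14)
        assert a.lambda_c14 == pytest.approx(0.0, abs=1e-12)

    def test_full_replacement_reads_death_year(self, curve, no_ploidy):
        s = SubjectProfile("e", "male", 1950, 40)
        led = simulate_rates(RateSchedule.constant(1.0, 1.0), s, n0=1.0)
        a = assign_c14(led, curve, no_ploidy)
        assert a.end_c14 == pytest.approx(curve.at(1990))

    def test_pre_bomb_birth_lambda_equals_end(self, curve, no_ploidy):
        s = SubjectProfile("e", "male", 1933, 73)
        led = simulate_rates(RateSchedule.constant(0.01, 0.01), s, n0=1.0)
        a = assign_c14(led, curve, no_ploidy)
        assert a.initial_c14 == 0.0
        assert a.lambda_c14 == pytest.approx(a.end_c14)

    def test_lambda_identity(self):
        assert lambda_c14(58.0, 21.0) == pytest.approx(37.0)
        assert lambda_c14(5.0, 5.0) == 0.0

    def test_empty_ledger_rejected(self, curve, no_ploidy):
        s = SubjectProfile("e", "male", 1960, 5)
        led = simulate_rates(RateSchedule.constant(0.0, 1.0), s, n0=1.0)
        led.counts[:] = 0.0
        with pytest.raises(ValueError, match="empty"):
            end_c14(led, np.zeros(6))
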
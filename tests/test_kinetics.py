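"""First-order decay fitting, half-life arithmetic and initial rates."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from descreen.kinetics import (
    DecayTimeSeries,
    FitError,
    MINUTES_PER_DAY,
    fit_first_order_decay,
    half_life_from_rate,
    initial_rate,
    rate_from_half_life,
    read_time_series,
    relative_activity,
    single_point_rate,
    write_time_series,
)
from descreen.synthetic_data import gen_decay


def make_series(k, a0=100.0, t=None, unit="day"):
    t = np.arange(0.0, 15.0) if t is None else np.asarray(t, float)
    return DecayTimeSeries(times=t, values=a0 * np.exp(-k * t), time_unit=unit)


class TestHalfLifeArithmetic:
    def test_ln2_rate_gives_unit_half_life(self):
        assert half_life_from_rate(math.log(2)) == pytest.approx(1.0)

    def test_direct_evaluation(self):
        # ln2 / 0.0232 and the buffer enzyme's 2.1-day half-life inverse
        assert half_life_from_rate(0.0232) == pytest.approx(29.879, abs=5e-3)
        assert rate_from_half_life(2.1) == pytest.approx(0.3301, abs=5e-5)

    def test_zero_rate_yields_infinity_sentinel(self):
        assert half_life_from_rate(0.0) == math.inf

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            half_life_from_rate(-0.1)
        with pytest.raises(ValueError):
            rate_from_half_life(0.0)

    def test_round_trip_inverse_identity(self):
        assert half_life_from_rate(rate_from_half_life(65.6)) == pytest.approx(
            65.6, abs=1e-12
        )

    @given(st.floats(min_value=1e-6, max_value=1e6))
    @settings(deadline=None, max_examples=50)
    def test_rate_times_half_life_is_ln2(self, k):
        assert k * half_life_from_rate(k) == pytest.approx(math.log(2), abs=1e-12)


class TestFirstOrderFit:
    @pytest.mark.parametrize("k", [0.33, 0.0232, rate_from_half_life(29.9)])
    def test_noiseless_generative_identity(self, k):
        fit = fit_first_order_decay(make_series(k))
        assert fit.rate_constant == pytest.approx(k, abs=1e-9)
        assert fit.rate_constant * fit.half_life == pytest.approx(math.log(2), abs=1e-12)

    def test_constant_series_fits_zero_rate_with_infinite_half_life(self):
        fit = fit_first_order_decay(make_series(0.0))
        assert fit.rate_constant == pytest.approx(0.0, abs=1e-12)
        assert fit.half_life == math.inf

    def test_short_term_absorbance_series_in_minutes(self):
        # 0.009 min^-1 is the largest short-term degradation class observed
        t = np.arange(0.0, 91.0, 5.0)
        series = DecayTimeSeries(times=t, values=0.8 * np.exp(-0.009 * t),
                                 time_unit="minute", signal_kind="absorbance")
        fit = fit_first_order_decay(series)
        assert fit.rate_constant == pytest.approx(0.009, rel=1e-9)

    def test_all_zero_signal_raises_fit_error(self):
        s = DecayTimeSeries(times=np.arange(3.0), values=np.zeros(3))
        with pytest.raises(FitError, match="identically zero"):
            fit_first_order_decay(s)

    def test_unit_coherence_days_vs_minutes(self):
        k_day = 0.25
        t_days = np.arange(0.0, 15.0)
        fit_day = fit_first_order_decay(make_series(k_day, t=t_days, unit="day"))
        fit_min = fit_first_order_decay(
            DecayTimeSeries(times=t_days * MINUTES_PER_DAY,
                            values=100 * np.exp(-k_day * t_days), time_unit="minute")
        )
        assert fit_day.rate_constant == pytest.approx(
            fit_min.rate_constant * MINUTES_PER_DAY, rel=1e-9
        )

    def test_matches_log_linear_slope_oracle_on_noiseless_data(self):
        s = make_series(0.11)
        slope = -np.polyfit(s.times, np.log(s.values), 1)[0]
        fit = fit_first_order_decay(s)
        assert fit.rate_constant == pytest.approx(slope, abs=1e-9)

    def test_matches_single_point_diagnostic_on_noiseless_data(self):
        s = make_series(0.2)
        k1 = single_point_rate(s.values[0], s.values[10], s.times[10])
        assert fit_first_order_decay(s).rate_constant == pytest.approx(k1, abs=1e-9)

    def test_parameter_recovery_under_multiplicative_noise(self):
        # 5% CV, 15 points, 200 replicates: median relative bias < 2%,
        # recovery within +/-10% in >= 90% of replicates
        k_true = rate_from_half_life(10.0)
        t = np.arange(0.0, 15.0)
        rels = []
        for rep in range(200):
            s = gen_decay(k_true, 100.0, t, noise_sd=0.05, seed=1000 + rep)
            rels.append(fit_first_order_decay(s).rate_constant / k_true - 1.0)
        rels = np.array(rels)
        assert abs(np.median(rels)) < 0.02
        assert np.mean(np.abs(rels) <= 0.10) >= 0.90


class TestInitialRateAndRelativeActivity:
    def test_exact_line_slope(self):
        t = np.arange(0.0, 5.1, 0.5)
        s = DecayTimeSeries(times=t, values=0.1 + 0.02 * t, time_unit="minute",
                            signal_kind="absorbance")
        assert initial_rate(s) == pytest.approx(0.02, abs=1e-12)

    def test_noisy_line_slope_within_three_standard_errors(self, rng):
        t = np.arange(0.0, 5.25, 0.25)
        noise = 0.002 * rng.standard_normal(t.shape)
        s = DecayTimeSeries(times=t, values=np.clip(0.1 + 0.02 * t + noise, 0, None),
                            time_unit="minute", signal_kind="absorbance")
        # closed-form OLS slope SE: sigma / sqrt(sum (t - tbar)^2)
        se = 0.002 / math.sqrt(np.sum((t - t.mean()) ** 2))
        assert initial_rate(s) == pytest.approx(0.02, abs=3 * se)

    def test_flat_series_has_zero_slope(self):
        t = np.arange(0.0, 6.0)
        s = DecayTimeSeries(times=t, values=np.full_like(t, 0.5), time_unit="minute")
        assert initial_rate(s) == pytest.approx(0.0, abs=1e-15)

    def test_window_must_hold_three_points(self):
        t = np.array([0.0, 10.0, 20.0])
        s = DecayTimeSeries(times=t, values=np.array([1.0, 2.0, 3.0]), time_unit="minute")
        with pytest.raises(ValueError, match="window"):
            initial_rate(s, window=5.0)

    @pytest.mark.parametrize(
        "rate,ref,expected", [(0.5, 0.5, 100.0), (0.0, 0.5, 0.0), (0.46, 0.5, 92.0)]
    )
    def test_relative_activity_percentages(self, rate, ref, expected):
        assert relative_activity(rate, ref) == pytest.approx(expected)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            relative_activity(1.0, 0.0)


class TestSeriesValidationAndIO:
    def test_times_must_strictly_increase(self):
        with pytest.raises(ValueError):
            DecayTimeSeries(times=np.array([0.0, 1.0, 1.0]), values=np.ones(3))

    def test_minimum_three_points(self):
        with pytest.raises(ValueError):
            DecayTimeSeries(times=np.array([0.0, 1.0]), values=np.ones(2))

    def test_csv_round_trip_preserves_series_and_metadata(self, tmp_path):
        s = make_series(0.1, unit="day")
        path = tmp_path / "ts.csv"
        write_time_series(s, path)
        back = read_time_series(path)
        assert back.time_unit == "day" and back.signal_kind == "activity"
        np.testing.assert_allclose(back.values, s.values, rtol=0, atol=0)
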
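"""IS, IV, M5/L10 and relative amplitude against closed-form oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import temprhythm as tr
from temprhythm import DailyProfile, EpochSeries, InsufficientDataError


def _cosine_profile(M=30.0, A=2.0, bin_minutes=15):
    grid = np.arange(0, 1440, bin_minutes)
    tc = (grid + bin_minutes / 2) / 60.0
    vals = M + A * np.cos(2 * np.pi * tc / 24)
    return DailyProfile(grid, vals, np.ones(len(grid), int), bin_minutes)


class TestInterdailyStability:
    def test_identical_days_give_one(self, make_series, rng):
        day = rng.normal(30, 1, 24)
        s = make_series(np.tile(day, 5))
        assert tr.interdaily_stability(s) == pytest.approx(1.0)

    def test_constant_series_undefined(self, make_series):
        s = make_series(np.full(48, 30.0))
        assert np.isnan(tr.interdaily_stability(s))

    def test_single_day_raises(self, make_series):
        with pytest.raises(InsufficientDataError):
            tr.interdaily_stability(make_series(np.arange(24.0)))

    def test_cosine_plus_noise_matches_variance_ratio(self, rng):
        """Signal variance 2, hourly noise variance 2: the finite-day
        expectation is (S + sigma^2/n)/(S + sigma^2)."""
        n_days = 14
        t = np.arange(n_days * 24)
        signal = 2 * np.cos(2 * np.pi * t / 24)
        vals = []
        for _ in range(200):
            y = signal + rng.normal(0, np.sqrt(2.0), len(t))
            ts = pd.date_range("2024-01-01", periods=len(t), freq="1h")
            vals.append(tr.interdaily_stability(EpochSeries(ts, 30 + y)))
        expected = (2.0 + 2.0 / n_days) / 4.0
        assert np.mean(vals) == pytest.approx(expected, abs=0.02)
        assert abs(np.mean(vals) - 0.5) < 0.06

    def test_invariant_to_affine_value_transform(self, make_series, rng):
        y = rng.normal(30, 1, 72)
        a = tr.interdaily_stability(make_series(y))
        b = tr.interdaily_stability(make_series(3.0 * y + 7.0))
        assert b == pytest.approx(a)

    def test_invariant_to_day_permutation(self, make_series, rng):
        days = [rng.normal(30, 1, 24) for _ in range(4)]
        a = tr.interdaily_stability(make_series(np.concatenate(days)))
        b = tr.interdaily_stability(
            make_series(np.concatenate([days[2], days[3], days[0], days[1]]))
        )
        assert b == pytest.approx(a)


class TestIntradailyVariability:
    def test_alternating_series_is_four(self, make_series):
        s = make_series(30 + np.tile([1.0, -1.0], 24))
        assert tr.intradaily_variability(s) == pytest.approx(4.0)

    def test_noiseless_hourly_cosine_closed_form(self, hourly_cosine):
        expected = 4 * np.sin(np.pi / 24) ** 2
        assert tr.intradaily_variability(hourly_cosine) == pytest.approx(
            expected, abs=1e-9
        )

    def test_white_noise_tends_to_two(self, make_series, rng):
        vals = [
            tr.intradaily_variability(make_series(rng.normal(30, 1, 14 * 24)))
            for _ in range(100)
        ]
        assert np.mean(vals) == pytest.approx(2.0, abs=0.05)

    def test_constant_series_undefined(self, make_series):
        assert np.isnan(tr.intradaily_variability(make_series(np.full(48, 30.0))))

    def test_invariant_to_affine_value_transform(self, make_series, rng):
        y = rng.normal(30, 1, 72)
        a = tr.intradaily_variability(make_series(y))
        b = tr.intradaily_variability(make_series(2.0 * y - 4.0))
        assert b == pytest.approx(a)

    def test_gap_transitions_excluded(self, make_series):
        """Two contiguous blocks at different constant levels: no valid
        successive difference crosses the gap, so IV is exactly 0."""
        ts = pd.DatetimeIndex(
            list(pd.date_range("2024-01-01", periods=24, freq="1h"))
            + list(pd.date_range("2024-01-03", periods=24, freq="1h"))
        )
        vals = np.concatenate([np.full(24, 30.0), np.full(24, 32.0)])
        assert tr.intradaily_variability(EpochSeries(ts, vals)) == pytest.approx(0.0)


class TestM5L10:
    def test_constant_profile(self):
        prof = DailyProfile(np.arange(0, 1440, 15), np.full(96, 30.0),
                            np.ones(96, int), 15)
        m5, l10, m5_mid, l10_mid = tr.m5_l10(prof)
        assert m5 == l10 == 30.0
        assert m5_mid == pytest.approx(2.5)   # earliest window by tie-break
        assert l10_mid == pytest.approx(5.0)

    def test_rectangular_plateaus(self):
        grid = np.arange(0, 1440, 15)
        vals = np.where(grid < 14 * 60, 31.0, 28.0)  # 14 h high, 10 h low
        prof = DailyProfile(grid, vals, np.ones(96, int), 15)
        m5, l10, m5_mid, l10_mid = tr.m5_l10(prof)
        assert m5 == 31.0 and l10 == 28.0
        assert l10_mid == pytest.approx(19.0)  # low window is exactly 14:00-24:00

    def test_pure_cosine_window_integrals(self):
        m5, l10, m5_mid, l10_mid = tr.m5_l10(_cosine_profile())
        m5_oracle = 30 + 2 * (24 / (5 * np.pi)) * np.sin(5 * np.pi / 24)
        l10_oracle = 30 - 2 * (24 / (10 * np.pi)) * np.sin(10 * np.pi / 24)
        assert m5 == pytest.approx(m5_oracle, abs=1e-3)
        assert l10 == pytest.approx(l10_oracle, abs=1e-3)
        assert m5_mid == pytest.approx(0.0, abs=0.25) or m5_mid == pytest.approx(
            24.0, abs=0.25
        )
        assert l10_mid == pytest.approx(12.0, abs=0.25)

    def test_rotation_invariance(self, rng):
        grid = np.arange(0, 1440, 15)
        vals = 30 + rng.normal(0, 1, 96)
        a = tr.m5_l10(DailyProfile(grid, vals, np.ones(96, int), 15))
        k = 17
        b = tr.m5_l10(DailyProfile(grid, np.roll(vals, k), np.ones(96, int), 15))
        assert b[0] == pytest.approx(a[0])
        assert b[1] == pytest.approx(a[1])
        assert b[2] == pytest.approx((a[2] + k * 0.25) % 24)


class TestRelativeAmplitude:
    def test_flat_rhythm(self):
        assert tr.relative_amplitude(30.0, 30.0) == 0.0

    def test_maximal(self):
        assert tr.relative_amplitude(5.0, 0.0) == 1.0

    def test_pure_cosine_value(self):
        m5, l10, *_ = tr.m5_l10(_cosine_profile())
        assert tr.relative_amplitude(m5, l10) == pytest.approx(0.0553, abs=0.001)

    def test_rejects_inverted_inputs(self):
        with pytest.raises(ValueError):
            tr.relative_amplitude(28.0, 31.0)

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(0.1, 100), st.floats(0.0, 100), st.floats(0.0, 100))
    def test_scale_invariant(self, scale, lo, span):
        m5, l10 = lo + span, lo
        if m5 + l10 <= 0:
            return
        assert tr.relative_amplitude(scale * m5, scale * l10) == pytest.approx(
            tr.relative_amplitude(m5, l10)
        )
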
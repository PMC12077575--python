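import logging

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from nirsfeed.errors import InsufficientDataError
from nirsfeed.feedback_engine import (
    AMPLITUDE_EPS,
    FeedbackSettings,
    bars_filled,
    compute_feedback,
    compute_rest_profile,
    midline,
    thermometer_value,
    trailing_rest_baseline,
)


def rest_series_with_spread(spread: float, n: int = 150) -> np.ndarray:
    """150 samples whose trimmed top-25/bottom-25 means differ by `spread`:
    10 outliers per tail (dropped), 25 at ±spread/2 (averaged), 80 middle."""
    return np.concatenate([
        np.full(10, -100.0),
        np.full(25, -spread / 2),
        np.zeros(80),
        np.full(25, spread / 2),
        np.full(10, 100.0),
    ])


class TestRestProfile:
    def test_trimmed_spread_of_0p2_gives_correction_factor_0p5(self):
        profile = compute_rest_profile(rest_series_with_spread(0.2))
        assert profile.amplitude_rest == pytest.approx(0.2)
        assert profile.correction_factor == pytest.approx(0.5)  # 0.1 / 0.2

    def test_spread_equal_to_expected_amplitude_gives_unit_factor(self):
        profile = compute_rest_profile(rest_series_with_spread(0.1))
        assert profile.correction_factor == pytest.approx(1.0)

    def test_outliers_beyond_the_drop_count_do_shift_the_estimate(self):
        base = rest_series_with_spread(0.2)
        spiked = base.copy()
        spiked[:11] = -1000.0  # 11 low outliers, only 10 dropped
        assert (
            compute_rest_profile(spiked).amplitude_rest
            > compute_rest_profile(base).amplitude_rest
        )

    def test_constant_series_caps_the_factor_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING):
            profile = compute_rest_profile(np.zeros(150))
        assert profile.correction_factor == pytest.approx(0.1 / AMPLITUDE_EPS)
        assert any("capping" in r.message for r in caplog.records)

    def test_trim_counts_scale_with_sample_count(self):
        # 90 samples (60% of the nominal 150) → drop 6, average 15 per tail
        series = np.linspace(-1, 1, 90)
        profile = compute_rest_profile(series)
        trimmed = np.sort(series)[6:-6]
        expected = np.mean(trimmed[-15:]) - np.mean(trimmed[:15])
        assert profile.amplitude_rest == pytest.approx(expected)

    def test_far_too_few_samples_rejected(self):
        with pytest.raises(InsufficientDataError):
            compute_rest_profile(np.zeros(3))


class TestRestBaseline:
    def test_constant_series(self):
        assert trailing_rest_baseline(np.full(300, 0.7), fs=10.0) == pytest.approx(0.7)

    def test_trailing_window_ignores_earlier_variation(self):
        fs = 10.0
        series = np.concatenate([np.sin(np.arange(250)), np.full(50, 0.2)])
        assert trailing_rest_baseline(series, fs=fs) == pytest.approx(0.2)

    def test_short_rest_falls_back_to_full_mean_with_warning(self):
        series = np.array([1.0, 2.0, 3.0] * 10)  # 3 s at 10 Hz
        with pytest.warns(UserWarning, match="shorter"):
            value = trailing_rest_baseline(series, fs=10.0)
        assert value == pytest.approx(2.0)


class TestFeedback:
    def test_zero_deviation_is_zero_feedback(self):
        assert compute_feedback(0.3, 0.3, 0.8) == 0.0

    def test_worked_product(self):
        assert compute_feedback(0.5, 0.2, 0.8) == pytest.approx(0.24)

    @pytest.mark.parametrize("c", [0.1, 0.5, 2.0, 37.0])
    def test_scale_invariance_under_global_hbo_rescaling(self, c):
        rest = rest_series_with_spread(0.25) + 0.05
        prev_rest = np.sin(np.arange(300) / 7) * 0.1 + 0.02
        reg_mean = 0.31

        def feedback(scale):
            profile = compute_rest_profile(scale * rest)
            baseline = trailing_rest_baseline(scale * prev_rest, fs=10.0)
            return compute_feedback(
                scale * reg_mean, baseline, profile.correction_factor
            )

        assert feedback(c) == pytest.approx(feedback(1.0), rel=1e-9)


class TestThermometer:
    @pytest.mark.parametrize(
        "feedback,expected",
        [(0.24, 0.8), (0.0, 0.5), (-0.4, 0.0), (0.4, 1.0), (0.6, 1.0), (-0.9, 0.0)],
    )
    def test_affine_map_with_default_ranges(self, feedback, expected):
        assert thermometer_value(feedback) == pytest.approx(expected)

    @given(
        hbo_min=st.floats(-5, -0.01),
        hbo_max=st.floats(0.01, 5),
        thermo_max=st.floats(0.5, 10),
    )
    @hyp_settings(derandomize=True, max_examples=50)
    def test_midpoint_of_symmetric_range_is_midline(self, hbo_min, hbo_max, thermo_max):
        s = FeedbackSettings(hbo_min=hbo_min, hbo_max=-hbo_min,
                             thermo_min=0.0, thermo_max=thermo_max)
        assert midline(s) == pytest.approx(thermo_max / 2)
        assert hbo_max > 0  # strategy sanity

    @given(a=st.floats(-0.4, 0.4), b=st.floats(-0.4, 0.4))
    @hyp_settings(derandomize=True, max_examples=100)
    def test_strictly_increasing_on_the_expected_range(self, a, b):
        if a + 1e-9 < b:  # separated enough to survive float rounding
            assert thermometer_value(a) < thermometer_value(b)


class TestBars:
    @pytest.mark.parametrize("r,expected", [(0.8, 9), (1.0, 10), (0.0, 1), (0.5, 6)])
    def test_lower_edge_convention(self, r, expected):
        assert bars_filled(r) == expected

    def test_agrees_with_brute_force_enumeration_on_a_fine_grid(self):
        settings = FeedbackSettings()
        levels = [settings.thermo_min + k * 0.1 for k in range(10)]
        for r in np.linspace(0.0, 1.0, 1001):
            expected = min(
                10, sum(1 for lv in levels if lv <= r + 1e-9)
            )
            assert bars_filled(float(r), settings) == expected

    def test_non_decreasing_in_r(self):
        values = [bars_filled(float(r)) for r in np.linspace(0, 1, 101)]
        assert values == sorted(values)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bars_filled(1.5)
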
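import numpy as np
import pytest
from scipy.signal import periodogram

from nirsfeed.errors import LayoutMismatchError, SignalDomainError
from nirsfeed.protocol_session import MARKER_REGULATION, MARKER_REST
from nirsfeed.simulator import (
    DEFAULT_COEFFICIENTS,
    OpticalCoefficients,
    SimulationConfig,
    WavelengthCoefficients,
    canonical_hrf,
    iter_frames,
    mbll_forward,
    mbll_inverse,
    regulation_boxcar,
    simulate_concentrations,
)

from conftest import make_descriptor


class TestCanonicalHrf:
    def test_peaks_at_requested_time_within_one_sample(self):
        fs = 10.0
        t = np.arange(0, 30, 1 / fs)
        h = canonical_hrf(t, peak_s=5.0)
        assert abs(t[np.argmax(h)] - 5.0) <= 1 / fs
        assert h.max() == pytest.approx(1.0)

    def test_starts_at_baseline_and_bounded_undershoot(self):
        t = np.arange(0, 30, 0.1)
        h = canonical_hrf(t, peak_s=5.0)
        assert h[0] == 0.0
        assert h.min() >= -0.2

    def test_grid_density_does_not_move_the_peak(self):
        t1 = np.arange(0, 30, 0.1)
        t2 = np.arange(0, 30, 0.05)
        p1 = t1[np.argmax(canonical_hrf(t1, 4.5))]
        p2 = t2[np.argmax(canonical_hrf(t2, 4.5))]
        assert abs(p1 - p2) <= 0.1

    def test_peak_outside_physiological_range_warns(self):
        t = np.arange(0, 30, 0.1)
        with pytest.warns(UserWarning):
            canonical_hrf(t, peak_s=8.0)


class TestSimulateConcentrations:
    def test_same_seed_is_bit_identical(self, short_sim_config):
        a = simulate_concentrations(short_sim_config)
        b = simulate_concentrations(short_sim_config)
        np.testing.assert_array_equal(a.hbo, b.hbo)
        np.testing.assert_array_equal(a.hbr, b.hbr)

    def test_zero_activation_equalizes_long_and_short_power(
        self, short_schedule
    ):
        config = SimulationConfig(
            schedule=short_schedule, activation_amp=0.0, seed=3,
            n_long=4, n_short=4,
        )
        r = simulate_concentrations(config)
        p_long = np.var(r.hbo[:, : config.n_long], axis=0).mean()
        p_short = np.var(r.hbo[:, config.n_long :], axis=0).mean()
        # same systemic + white construction; gains differ per channel
        assert p_long == pytest.approx(p_short, rel=0.35)
        assert np.all(r.truth_activation == 0)

    def test_regulation_blocks_raise_long_channel_hbo(self, short_sim_config):
        r = simulate_concentrations(short_sim_config)
        box = regulation_boxcar(short_sim_config.schedule, r.t)
        rest = np.zeros_like(box)
        for e in short_sim_config.schedule.epochs:
            if e.marker_id == MARKER_REST:
                rest[(r.t >= e.start_s) & (r.t < e.end_s)] = 1.0
        long_mean = r.hbo[:, : short_sim_config.n_long].mean(axis=1)
        assert long_mean[box == 1].mean() > long_mean[rest == 1].mean()

    def test_systemic_spectrum_peaks_at_configured_frequencies(
        self, short_schedule
    ):
        config = SimulationConfig(schedule=short_schedule, seed=5,
                                  activation_amp=0.0, n_long=1, n_short=1)
        r = simulate_concentrations(config)
        f, p = periodogram(r.hbo[:, 0], fs=config.fs)
        df = f[1] - f[0]
        for target in (config.noise.cardiac_hz, config.noise.resp_hz,
                       config.noise.mayer_hz):
            band = (f > target - 5 * df) & (f < target + 5 * df)
            local = (f > target - 0.06) & (f < target + 0.06)
            assert f[local][np.argmax(p[local])] == pytest.approx(
                target, abs=df
            ), f"no spectral peak at {target} Hz"
            assert p[band].max() > 10 * np.median(p[f > 0.05])


class TestMbll:
    def test_unchanged_intensity_means_zero_concentration_change(self):
        hbo, hbr = mbll_forward(np.array([1.0, 1.0]))
        assert hbo == pytest.approx(0.0) and hbr == pytest.approx(0.0)

    def test_zero_concentration_means_unit_ratio(self):
        np.testing.assert_allclose(mbll_inverse(0.0, 0.0), [1.0, 1.0])

    def test_forward_inverse_identity_on_random_grid(self):
        rng = np.random.default_rng(0)
        hbo = rng.uniform(-1, 1, 100)
        hbr = rng.uniform(-1, 1, 100)
        ratios = mbll_inverse(hbo, hbr)
        hbo2, hbr2 = mbll_forward(ratios)
        np.testing.assert_allclose(hbo2, hbo, atol=1e-9)
        np.testing.assert_allclose(hbr2, hbr, atol=1e-9)

    def test_inverse_forward_identity(self):
        hbo, hbr = mbll_forward(mbll_inverse(0.1, -0.03))
        assert hbo == pytest.approx(0.1, abs=1e-9)
        assert hbr == pytest.approx(-0.03, abs=1e-9)

    def test_hbo_rise_absorbs_more_850nm_light(self):
        ratios = mbll_inverse(5.0, 0.0)  # large ΔHbO, μmol/L
        assert ratios[1] < 1.0

    def test_singular_extinction_matrix_rejected(self):
        coeffs = OpticalCoefficients(
            per_wavelength=(
                WavelengthCoefficients(760, 1.0, 2.0, 6.0),
                WavelengthCoefficients(850, 1.0, 2.0, 6.0),
            )
        )
        with pytest.raises(SignalDomainError):
            mbll_forward(np.array([0.9, 0.9]), coeffs)

    def test_non_positive_intensity_rejected(self):
        with pytest.raises(SignalDomainError):
            mbll_forward(np.array([1.0, 0.0]))


class TestFrameStream:
    def test_frames_match_descriptor_layout(self, short_sim_config):
        desc = make_descriptor(short_sim_config.n_channels)
        frames = list(iter_frames(simulate_concentrations(short_sim_config), desc))
        assert all(f.values.shape == (105,) for f in frames)
        counters = np.array([f.values[0] for f in frames])
        np.testing.assert_array_equal(np.diff(counters), 1)

    def test_raw_columns_encode_concentrations_via_mbll(self, short_sim_config):
        desc = make_descriptor(short_sim_config.n_channels)
        result = simulate_concentrations(short_sim_config)
        f0 = next(iter(iter_frames(result, desc)))
        raw = np.array([f0.values[1], f0.values[1 + 26]])  # channel 1, both λ
        hbo, hbr = mbll_forward(raw / short_sim_config.i0,
                                short_sim_config.coefficients)
        assert hbo == pytest.approx(result.hbo[0, 0], abs=1e-9)
        assert hbr == pytest.approx(result.hbr[0, 0], abs=1e-9)

    def test_channel_count_mismatch_rejected(self, short_sim_config):
        desc = make_descriptor(short_sim_config.n_channels + 1)
        with pytest.raises(LayoutMismatchError):
            next(iter_frames(simulate_concentrations(short_sim_config), desc))

    def test_quiet_lead_in_delays_the_schedule(self, short_schedule):
        config = SimulationConfig(
            schedule=short_schedule, seed=2, n_long=2, n_short=1,
            baseline_lead_in_s=120.0,
        )
        r = simulate_concentrations(config)
        lead = r.t < 120.0
        assert np.all(r.truth_activation[lead] == 0)
        # first regulation epoch starts 35 s into the schedule
        first_reg = next(e for e in short_schedule.epochs
                         if e.marker_id == MARKER_REGULATION)
        onset = 120.0 + first_reg.start_s
        assert np.all(r.truth_activation[r.t < onset + 1e-9] <= 1e-12)
        assert r.truth_activation[r.t > onset + 10].max() > 0
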
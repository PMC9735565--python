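"""STFT, ACF, ICA+BPF and peak-count baseline estimators."""

import numpy as np
import pytest

from facepulse import (
    AcfConfig,
    ChromaSeries,
    ConfigurationError,
    NoPulseDetectedError,
    PulseWave,
    StftConfig,
    acf_rate,
    band_isolate,
    generate_cg_fixture,
    ica_bpf_rate,
    peak_count_rate,
    stft_rate,
)
from facepulse.baselines import autocorrelation


def series_from_channels(r, g, b, fs=30.0, roi_id="ROI1"):
    n = len(r)
    return ChromaSeries.from_rgb(roi_id, fs, np.arange(n), r, g, b)


class TestStftRate:
    def test_pure_tone_fixture_exact(self, clean_fixture_72):
        est = stft_rate(clean_fixture_72)
        assert est.bpm == pytest.approx(72.0, abs=0.1)  # 1.2 Hz on an exact bin
        assert est.method == "stft"

    def test_two_window_argmax_mean(self):
        # 1.0 Hz for 10 s then 1.4 Hz for 10 s; mean argmax 1.2 Hz -> 72 bpm
        fs = 30.0
        t1 = np.arange(300) / fs
        x = np.concatenate([np.sin(2 * np.pi * 1.0 * t1), np.sin(2 * np.pi * 1.4 * t1)])
        s = series_from_channels(np.full(600, 100.0), 100.0 + 2 * x, np.full(600, 100.0))
        est = stft_rate(s, cfg=StftConfig(window_s=10.0, hop_s=10.0))
        assert est.bpm == pytest.approx(72.0, abs=1e-9)

    def test_amplitude_invariance(self, clean_fixture_72):
        s = clean_fixture_72
        scaled = series_from_channels(s.mean_r, 100.0 + 50 * (s.mean_g - 100.0), s.mean_b)
        assert stft_rate(scaled).bpm == pytest.approx(stft_rate(s).bpm, abs=1e-9)

    def test_window_too_short_rejected(self):
        s = generate_cg_fixture(72.0, duration_s=20.0)
        with pytest.raises(ConfigurationError):
            stft_rate(s, cfg=StftConfig(window_s=1.0, hop_s=1.0))


class TestAcfRate:
    def test_exact_period_25_samples(self):
        fs = 30.0
        t = np.arange(1800) / fs
        wave = PulseWave(fs, np.sin(2 * np.pi * t * fs / 25.0 / 1.0))  # period 25 samples
        est = acf_rate(wave)
        assert est.bpm == pytest.approx(60.0 * fs / 25.0, abs=1e-9)  # 72 bpm

    def test_autocorrelation_matches_direct_summation_oracle(self, rng):
        x = rng.normal(size=200)
        max_lag = 50
        got = autocorrelation(x, max_lag)
        xc = x - x.mean()
        expected = np.array(
            [np.sum(xc[: len(x) - lag] * xc[lag:]) for lag in range(max_lag + 1)]
        )
        expected /= expected[0]
        np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_white_noise_rejected_or_flagged(self, rng):
        wave = PulseWave(30.0, rng.normal(size=1800))
        try:
            with pytest.warns(UserWarning, match="weak periodicity"):
                acf_rate(wave)
        except NoPulseDetectedError:
            pass  # equally acceptable: no stable periodicity

    def test_noiseless_fixture_through_band_isolation(self, clean_fixture_72):
        wave = band_isolate(clean_fixture_72)
        assert acf_rate(wave).bpm == pytest.approx(72.0, abs=2.0)

    def test_short_wave_rejected(self):
        with pytest.raises(ConfigurationError):
            acf_rate(PulseWave(30.0, np.zeros(100)), cfg=AcfConfig(max_lag_s=10.0))


class TestIcaBpfRate:
    def test_single_source_recovered_up_to_sign_scale(self, rng):
        fs = 30.0
        t = np.arange(1800) / fs
        s = np.sin(2 * np.pi * 1.2 * t)
        noise = 0.01 * rng.normal(size=(3, 1800))
        series = series_from_channels(
            100 + s + noise[0], 100 + 2 * s + noise[1], 100 - s + noise[2]
        )
        est = ica_bpf_rate(series, seed=0)
        assert est.bpm == pytest.approx(72.0, abs=2.0)

    def test_channel_sign_flip_leaves_rate_unchanged(self, rng):
        fs = 30.0
        t = np.arange(1800) / fs
        s = np.sin(2 * np.pi * 1.2 * t)
        noise = 0.01 * rng.normal(size=1800)
        a = series_from_channels(100 + s + noise, 100 + 2 * s, 100 - s)
        b = series_from_channels(100 - s - noise, 100 - 2 * s, 100 + s)
        assert ica_bpf_rate(a).bpm == pytest.approx(ica_bpf_rate(b).bpm, abs=1.0)

    def test_noiseless_three_channel_fixture(self, clean_fixture_72):
        assert ica_bpf_rate(clean_fixture_72).bpm == pytest.approx(72.0, abs=2.0)

    def test_forced_component_index_out_of_range(self, clean_fixture_72):
        with pytest.raises(ConfigurationError):
            ica_bpf_rate(clean_fixture_72, component=5)

    def test_constant_channels_fail(self):
        series = series_from_channels(
            np.full(900, 100.0), np.full(900, 100.0), np.full(900, 100.0)
        )
        from facepulse import EstimatorFailureError

        with pytest.raises(EstimatorFailureError):
            ica_bpf_rate(series)


class TestPeakCountRate:
    def test_twelve_peaks_in_ten_seconds(self):
        fs = 30.0
        t = np.arange(600) / fs
        wave = PulseWave(fs, np.sin(2 * np.pi * 1.2 * t))  # 12 cycles in 10 s
        est = peak_count_rate(wave, 10.0)
        assert est.bpm == pytest.approx(72.0)

    def test_zero_peaks_warns_and_reports_zero(self):
        wave = PulseWave(30.0, np.zeros(600))
        with pytest.warns(UserWarning, match="no peaks"):
            est = peak_count_rate(wave, 10.0)
        assert est.bpm == 0.0

    def test_sixty_peaks_in_sixty_seconds(self):
        fs = 30.0
        t = np.arange(1800) / fs
        wave = PulseWave(fs, np.sin(2 * np.pi * 1.0 * t))
        assert peak_count_rate(wave, 60.0).bpm == pytest.approx(60.0)

    def test_window_longer_than_wave_rejected(self):
        with pytest.raises(ConfigurationError):
            peak_count_rate(PulseWave(30.0, np.zeros(300)), 20.0)


def test_all_estimators_agree_on_clean_tone(clean_fixture_72):
    """On a single-tone fixture all four estimators land within one STFT
    bin width (0.1 Hz -> 6 bpm) of each other."""
    wave = band_isolate(clean_fixture_72)
    from facepulse import detect_peaks, rfpr

    rates = [
        rfpr(detect_peaks(wave)).bpm,
        stft_rate(clean_fixture_72).bpm,
        acf_rate(wave).bpm,
        ica_bpf_rate(clean_fixture_72).bpm,
    ]
    assert max(rates) - min(rates) <= 6.0
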
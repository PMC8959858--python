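"""Spike detection and pattern statistics: hand-computed oracles,
generator round trips, and invariance properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import clampkit as ck
from clampkit import GeneratorConfig, SpikeShape, Trace


def _hand_built_trace(peak_times_s, fs=10_000.0, baseline=-60.0,
                      duration=1.0, peak_v=0.0):
    """Triangular spikes (0.5 ms up, 0.5 ms down) at given times."""
    n = int(duration * fs)
    v = np.full(n, baseline)
    half = int(0.5e-3 * fs)
    rise = np.linspace(baseline, peak_v, half + 1)
    fall = np.linspace(peak_v, baseline, half + 1)[1:]
    spike = np.concatenate([rise, fall]) - baseline
    for t in peak_times_s:
        p = int(round(t * fs))
        v[p - half:p - half + spike.size] += spike
    return Trace(v, fs)


class TestDetectSpikes:
    def test_round_trip_against_generator_truth(self):
        cfg = GeneratorConfig(duration=5.0, noise_sd=0.3, seed=1)
        trace, truth = ck.gen_spontaneous_trace(10, 0.5, SpikeShape(), -55, cfg)
        train = ck.detect_spikes(trace)
        assert train.n == truth.spike_times.size
        assert np.max(np.abs(train.spike_times - truth.spike_times)) <= 0.5e-3

    def test_flat_trace_has_no_events(self):
        trace = Trace(np.full(5000, -55.0), 10_000.0)
        assert ck.detect_spikes(trace).n == 0

    def test_close_pair_not_merged(self):
        # two spikes 5 ms apart must both survive the 1-ms refractory guard
        trace = _hand_built_trace([0.100, 0.105])
        train = ck.detect_spikes(trace)
        assert train.n == 2
        assert np.allclose(train.spike_times, [0.100, 0.105], atol=1e-4)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="100 ms"):
            ck.detect_spikes(Trace(np.zeros(100), 10_000.0))


class TestISIStatistics:
    def test_perfectly_regular_train(self):
        stats = ck.isi_statistics(np.arange(0, 2, 0.1))
        assert stats.cv == pytest.approx(0.0, abs=1e-12)
        assert stats.lv == pytest.approx(0.0, abs=1e-12)

    def test_hand_evaluated_lv_and_cv(self):
        # ISIs 10, 20, 10 ms: LV = (1/2)(3*100/900 + 3*100/900) = 1/3
        spikes = np.array([0.0, 0.010, 0.030, 0.040])
        stats = ck.isi_statistics(spikes)
        assert stats.lv == pytest.approx(1 / 3, abs=1e-12)
        assert stats.cv == pytest.approx(np.sqrt(100 / 3) / (40 / 3), abs=1e-9)

    def test_moment_skewness_and_kurtosis(self):
        # symmetric ISIs 10, 15, 20 ms: m3 = 0; m4/m2^2 = 416.67/277.78 = 1.5
        spikes = np.cumsum([0, 0.010, 0.015, 0.020])
        stats = ck.isi_statistics(spikes)
        assert stats.skewness == pytest.approx(0.0, abs=1e-12)
        assert stats.kurtosis == pytest.approx(1.5, abs=1e-9)

    def test_too_few_spikes_reported_missing_not_zero(self):
        stats = ck.isi_statistics(np.array([0.0, 0.1]))
        assert np.isnan(stats.cv) and np.isnan(stats.lv)
        assert "cv" in stats.missing

    def test_mean_rate_consistent_with_mean_isi(self):
        spikes = np.cumsum([0, 0.08, 0.12, 0.1, 0.09])
        stats = ck.isi_statistics(spikes)
        assert stats.mean_rate == pytest.approx(1000.0 / stats.mean_isi_ms, rel=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(1.0, 500.0), min_size=3, max_size=50),
           st.floats(0.1, 10.0))
    def test_cv_lv_invariant_to_time_rescaling(self, isis_ms, scale):
        spikes = np.cumsum([0.0] + isis_ms) / 1000.0
        a = ck.isi_statistics(spikes)
        b = ck.isi_statistics(spikes * scale)
        assert a.cv == pytest.approx(b.cv, rel=1e-9)
        assert a.lv == pytest.approx(b.lv, rel=1e-9)
        assert 0.0 <= a.lv < 3.0

    def test_matches_gamma_cv_at_large_n(self, rng):
        isis = ck.gamma_isis(10.0, 0.5, 5000, rng)
        stats = ck.isi_statistics(np.concatenate([[0], np.cumsum(isis)]))
        assert abs(stats.cv - 0.5) < 0.03

    def test_detection_plus_stats_recovers_cv_target(self):
        cfg = GeneratorConfig(duration=120.0, noise_sd=0.5, seed=42)
        trace, _ = ck.gen_spontaneous_trace(10, 0.5, SpikeShape(), -55, cfg)
        train = ck.detect_spikes(trace)
        stats = ck.isi_statistics(train.spike_times)
        assert abs(stats.cv - 0.5) < 0.05


class TestAutocorrelation:
    def test_regular_train_peaks_at_period_multiples(self):
        lags, acf = ck.spike_autocorrelation(np.arange(0, 50, 0.1))
        top = set(np.abs(lags[np.argsort(acf)[-6:]]))
        assert top == {100.0, 200.0, 300.0}

    def test_poisson_train_is_flat_at_the_rate(self, rng):
        spikes = np.cumsum(rng.exponential(0.1, size=20_000))
        lags, acf = ck.spike_autocorrelation(spikes, bin_ms=20, max_lag_ms=500)
        off_zero = np.abs(lags) > 25
        assert np.allclose(acf[off_zero], 10.0, atol=1.0)

    def test_symmetric_in_lag(self, rng):
        spikes = np.sort(rng.uniform(0, 30, size=300))
        lags, acf = ck.spike_autocorrelation(spikes)
        assert np.allclose(acf, acf[::-1])

    def test_bin_wider_than_max_lag_rejected(self):
        with pytest.raises(ValueError, match="bin"):
            ck.spike_autocorrelation(np.arange(0, 5, 0.1), bin_ms=200, max_lag_ms=100)


class TestWaveformStatistics:
    @pytest.fixture
    def clean_recording(self):
        cfg = GeneratorConfig(duration=5.0, noise_sd=0.0, lowpass_cutoff=None, seed=1)
        shape = SpikeShape(threshold_v=-45, peak_v=-10, ahp_depth=12,
                          onset_ms=1.5, ahp_recovery_ms=15)
        trace, truth = ck.gen_spontaneous_trace(10, 0.5, shape, -55, cfg)
        return trace, ck.detect_spikes(trace)

    def test_ahp_amplitude_round_trip(self, clean_recording):
        trace, train = clean_recording
        wf = ck.waveform_statistics(trace, train)
        assert wf.ahp_amplitude == pytest.approx(12.0, abs=0.1)

    def test_onset_duration_round_trip(self, clean_recording):
        trace, train = clean_recording
        wf = ck.waveform_statistics(trace, train)
        assert wf.onset_duration_ms == pytest.approx(1.5, abs=0.1)

    def test_spike_free_trace_reports_rmp_only(self):
        trace = Trace(np.full(10_000, -60.0), 10_000.0)
        wf = ck.waveform_statistics(trace, ck.detect_spikes(trace))
        assert wf.rmp == -60.0
        assert np.isnan(wf.ahp_amplitude) and "ahp_amplitude" in wf.missing


class TestWaveletPower:
    def test_pure_sinusoid_peaks_at_its_frequency(self):
        t = np.arange(0, 6, 1e-4)
        trace = Trace(np.sin(2 * np.pi * 5 * t) - 60, 10_000.0)
        grid = np.geomspace(0.5, 100, 40)
        res = ck.wavelet_power(trace, grid)
        assert res.frequencies[res.power.argmax()] == \
            grid[np.abs(grid - 5).argmin()]

    def test_deterministic_on_identical_input(self, rng):
        x = rng.normal(-60, 1, 60_000)
        res1 = ck.wavelet_power(Trace(x, 10_000.0))
        res2 = ck.wavelet_power(Trace(x.copy(), 10_000.0))
        assert np.array_equal(res1.power, res2.power)

    def test_two_tones_give_two_local_maxima(self):
        t = np.arange(0, 6, 1e-4)
        x = np.sin(2 * np.pi * 2 * t) + np.sin(2 * np.pi * 20 * t)
        grid = np.geomspace(1, 50, 30)
        res = ck.wavelet_power(Trace(x - 60, 10_000.0), grid)
        p = res.power
        local_max = [i for i in range(1, p.size - 1)
                     if p[i] > p[i - 1] and p[i] > p[i + 1]]
        expected = {np.abs(grid - 2).argmin(), np.abs(grid - 20).argmin()}
        assert expected <= set(local_max)

    def test_super_nyquist_frequency_rejected(self):
        trace = Trace(np.zeros(60_000) - 60, 10_000.0)
        with pytest.raises(ValueError, match="Nyquist"):
            ck.wavelet_power(trace, np.array([6000.0]))
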
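"""PSP pipeline: median-filter preprocessing, noise-thresholded event
detection, exact two-means classification, Markov transition estimates."""

import numpy as np
import pytest

import clampkit as ck
from clampkit import GeneratorConfig, Trace
from clampkit.psp import two_means_1d

FS = 10_000.0


class TestPreprocess:
    def test_constant_trace_unchanged_with_zero_noise(self):
        trace = Trace(np.full(20_000, -107.0), FS)
        filtered, rms = ck.preprocess(trace)
        assert np.array_equal(filtered.samples, trace.samples)
        assert rms == 0.0

    def test_single_sample_outlier_removed_by_median(self):
        v = np.full(20_000, -107.0)
        v[10_000] = -90.0
        filtered, _ = ck.preprocess(Trace(v, FS), median_ms=3.0)
        assert filtered.samples[10_000] == -107.0

    def test_noise_rms_matches_gaussian_sd(self, rng):
        v = -107.0 + rng.normal(0, 0.5, 100_000)
        _, rms = ck.preprocess(Trace(v, FS))
        assert rms == pytest.approx(0.5, abs=0.05)

    def test_window_longer_than_trace_rejected(self):
        with pytest.raises(ValueError, match="window"):
            ck.preprocess(Trace(np.full(12_000, -107.0), FS), median_ms=2000.0)


class TestDetectEvents:
    def test_high_snr_events_all_found_no_false_positives(self):
        cfg = GeneratorConfig(duration=20.0, noise_sd=0.3, seed=11)
        trace, truth = ck.gen_psp_trace(-107, 5.0, 8.0, 0.0, 2, 20, 1.0,
                                        [[0.5, 0.5], [0.5, 0.5]], cfg)
        filtered, rms = ck.preprocess(trace)
        events = ck.detect_events(filtered, rms)
        matched = [np.min(np.abs(events.peak_times - t)) < 3e-3
                   for t in truth.event_times]
        assert all(matched)
        assert events.n == truth.event_times.size

    def test_event_free_noise_yields_few_then_no_events(self, rng):
        v = -107.0 + rng.normal(0, 0.5, 100_000)
        filtered, rms = ck.preprocess(Trace(v, FS))
        assert ck.detect_events(filtered, rms, k_threshold=3).n <= 10
        assert ck.detect_events(filtered, rms, k_threshold=5).n <= 2

    def test_amplitude_and_rising_slope_of_clean_event(self):
        # direct construction: −105 mV baseline, linear 2-ms rise to
        # −100 mV, exponential decay → amplitude 5 mV, slope 2.5 mV/ms
        n = int(10 * FS)
        v = np.full(n, -105.0)
        p = n // 2
        rise = int(2e-3 * FS)
        v[p - rise:p + 1] += np.linspace(0, 5.0, rise + 1)
        decay = np.arange(1, int(0.2 * FS)) / FS
        v[p + 1:p + decay.size + 1] += 5.0 * np.exp(-decay / 0.02)
        events = ck.detect_events(Trace(v, FS), noise_rms=0.1)
        assert events.n == 1
        assert events.amplitudes[0] == pytest.approx(5.0, rel=0.05)
        assert events.rising_slopes[0] == pytest.approx(2.5, rel=0.1)

    def test_amplitude_invariant_to_constant_offset(self):
        cfg = GeneratorConfig(duration=20.0, noise_sd=0.3, seed=12)
        trace, _ = ck.gen_psp_trace(-107, 5.0, 8.0, 0.0, 2, 20, 1.0,
                                    [[0.5, 0.5], [0.5, 0.5]], cfg)
        filtered, rms = ck.preprocess(trace)
        ev1 = ck.detect_events(filtered, rms)
        shifted = Trace(filtered.samples + 3.0, FS)
        ev2 = ck.detect_events(shifted, rms)
        assert np.allclose(ev1.amplitudes, ev2.amplitudes)

    def test_zero_noise_rms_applies_amplitude_floor(self):
        trace = Trace(np.full(20_000, -107.0), FS)
        events = ck.detect_events(trace, noise_rms=0.0)
        assert events.n == 0  # floor applied, nothing crosses it


class TestClassifyEvents:
    def test_matches_exhaustive_split_oracle(self):
        amps = np.array([0.5, 0.6, 0.7, 2.0, 2.1])
        cls = ck.classify_events(amps)
        assert cls.labels == [ck.MPSP] * 3 + [ck.PSP] * 2
        assert cls.centers[ck.MPSP] == pytest.approx(0.6)
        assert cls.centers[ck.PSP] == pytest.approx(2.05)
        assert cls.separation_ok

    def test_agrees_with_kmeans_cross_check(self, rng):
        sklearn = pytest.importorskip("sklearn.cluster")
        amps = np.concatenate([rng.lognormal(0.3, 0.2, 200),
                               rng.lognormal(1.7, 0.2, 150)])
        rng.shuffle(amps)
        ours = ck.classify_events(amps)
        km = sklearn.KMeans(n_clusters=2, n_init=10, random_state=0).fit(
            amps.reshape(-1, 1))
        hi = np.argmax(km.cluster_centers_.ravel())
        ref = [ck.PSP if l == hi else ck.MPSP for l in km.labels_]
        assert ours.labels == ref

    def test_well_separated_classes_recover_truth_labels(self):
        cfg = GeneratorConfig(duration=120.0, noise_sd=0.3, seed=13)
        _, truth = ck.gen_psp_trace(-107, 1.5, 6.0, 0.25, 2, 20, 2.0,
                                    [[0.7, 0.3], [0.3, 0.7]], cfg)
        amps = truth.generative_params["amplitudes"]
        cls = ck.classify_events(amps)
        agree = np.mean([a == b for a, b in zip(cls.labels, truth.event_labels)])
        assert agree >= 0.95

    def test_identical_amplitudes_degenerate(self):
        cls = ck.classify_events([1.0, 1.0, 1.0, 1.0])
        assert not cls.separation_ok
        assert cls.labels == [ck.MPSP] * 4

    def test_two_means_is_globally_optimal(self, rng):
        vals = rng.uniform(0, 10, 40)
        upper, lo_c, hi_c, _ = two_means_1d(vals)
        sse = np.sum((vals[~upper] - vals[~upper].mean()) ** 2) + \
            np.sum((vals[upper] - vals[upper].mean()) ** 2)
        s = np.sort(vals)
        brute = min(
            np.sum((s[:k] - s[:k].mean()) ** 2) + np.sum((s[k:] - s[k:].mean()) ** 2)
            for k in range(1, vals.size))
        assert sse == pytest.approx(brute, rel=1e-12)


class TestTransitionProbabilities:
    def test_hand_counted_sequence(self):
        m, P = ck.MPSP, ck.PSP
        tm = ck.transition_probabilities([m, m, P, m, P, P])
        assert tm.probs[0, 0] == pytest.approx(1 / 3)
        assert tm.probs[0, 1] == pytest.approx(2 / 3)
        assert tm.probs[1, 0] == pytest.approx(1 / 2)
        assert tm.probs[1, 1] == pytest.approx(1 / 2)
        assert tm.counts.sum() == 5

    def test_single_state_row_missing_not_zero(self):
        m = ck.MPSP
        tm = ck.transition_probabilities([m, m, m])
        assert tm.probs[0, 0] == 1.0
        assert np.isnan(tm.probs[1]).all()

    def test_observed_rows_sum_to_one(self, rng):
        labels = [ck.MPSP if rng.random() < 0.6 else ck.PSP for _ in range(500)]
        tm = ck.transition_probabilities(labels)
        assert np.allclose(tm.probs.sum(axis=1), 1.0, atol=1e-12)

    def test_mle_consistency_on_known_chain(self, rng):
        T = np.array([[0.8, 0.2], [0.3, 0.7]])
        states = [ck.MPSP, ck.PSP]
        labels, cur = [], 0
        for _ in range(5000):
            cur = rng.choice(2, p=T[cur])
            labels.append(states[cur])
        tm = ck.transition_probabilities(labels)
        assert np.abs(tm.probs - T).max() < 0.03
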
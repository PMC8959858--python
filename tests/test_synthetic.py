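"""Generator-level checks: the synthetic data must carry the statistical
structure the downstream analysis assumes, with faithful ground truth."""

import numpy as np
import pytest

import clampkit as ck
from clampkit import GeneratorConfig, SpikeShape


class TestSpontaneousGenerator:
    def test_regular_limit_gives_constant_isis(self):
        cfg = GeneratorConfig(duration=5.0, noise_sd=0.0, lowpass_cutoff=None, seed=0)
        _, truth = ck.gen_spontaneous_trace(10.0, 0.01, SpikeShape(), -55.0, cfg)
        isis = np.diff(truth.spike_times)
        assert np.allclose(isis, 0.1, atol=0.005)

    def test_gamma_cv_recovered_from_truth_isis(self, rng):
        # moments of a gamma with shape 4 give CV = 0.5
        isis = ck.gamma_isis(10.0, 0.5, 5000, rng)
        cv = isis.std(ddof=1) / isis.mean()
        assert abs(cv - 0.5) < 0.05
        assert abs(isis.mean() - 0.1) < 0.005

    def test_quiet_trace_is_constant_at_rmp(self):
        cfg = GeneratorConfig(duration=2.0, noise_sd=0.0, lowpass_cutoff=None, seed=0)
        trace, truth = ck.gen_quiet_trace(-60.0, cfg)
        assert np.all(trace.samples == -60.0)
        assert truth.spike_times.size == 0

    def test_too_short_duration_names_minimum(self):
        cfg = GeneratorConfig(duration=0.1, noise_sd=0.0, seed=0)
        with pytest.raises(ValueError, match="0.2 s"):
            ck.gen_spontaneous_trace(10.0, 0.5, SpikeShape(), -55.0, cfg)

    def test_gamma_renewal_lv_cv_consistency(self, rng):
        # analytic gamma-renewal relation LV = 3 cv^2 / (2 + cv^2)
        for cv in (0.3, 0.7, 1.0):
            isis = ck.gamma_isis(10.0, cv, 6000, rng)
            lv = ck.local_variation(isis)
            assert abs(lv - 3 * cv**2 / (2 + cv**2)) < 0.05


class TestEvokedGenerator:
    @pytest.fixture
    def sweepset(self):
        cfg = GeneratorConfig(duration=0.6, noise_sd=0.0, lowpass_cutoff=None, seed=2)
        return ck.gen_evoked_sweepset(20.0, 2.0, 5.0, 39.0624, cfg)

    def test_no_truth_spikes_below_rheobase(self, sweepset):
        _, truth = sweepset
        per_sweep = truth.generative_params["spike_times_per_sweep"]
        currents = truth.generative_params["currents"]
        for amp, times in zip(currents, per_sweep):
            if amp < 20.0:
                assert times.size == 0
            else:
                assert times.size >= 1

    def test_truth_mean_rates_exactly_collinear(self, sweepset):
        _, truth = sweepset
        rates = truth.generative_params["mean_rates"]
        currents = truth.generative_params["currents"]
        sel = currents >= 20.0
        slope = np.polyfit(currents[sel], rates[sel], 1)[0]
        assert slope == pytest.approx(2.0, abs=1e-9)

    def test_isis_non_decreasing_under_adaptation(self, sweepset):
        # monotone up to the one-sample grid snap of truth spike times
        _, truth = sweepset
        for times in truth.generative_params["spike_times_per_sweep"]:
            if times.size >= 3:
                isis = np.diff(times)
                assert np.all(np.diff(isis) >= -1.01e-4)

    def test_nonpositive_plateau_rejected(self):
        cfg = GeneratorConfig(duration=0.6, seed=0)
        with pytest.raises(ValueError, match="plateau"):
            ck.gen_evoked_sweepset(20.0, 10.0, 5.0, 5.0, cfg)


class TestPSPGenerator:
    def test_poisson_event_count_within_sampling_bounds(self):
        cfg = GeneratorConfig(duration=100.0, noise_sd=0.0, lowpass_cutoff=None, seed=3)
        _, truth = ck.gen_psp_trace(-107, 1.5, 5.0, 0.25, 2, 20, 2.0,
                                    [[0.7, 0.3], [0.3, 0.7]], cfg)
        n = truth.event_times.size
        assert abs(n - 200) <= 3 * np.sqrt(200)

    def test_absorbing_chain_keeps_initial_label(self):
        cfg = GeneratorConfig(duration=30.0, noise_sd=0.0, lowpass_cutoff=None, seed=4)
        _, truth = ck.gen_psp_trace(-107, 1.5, 5.0, 0.25, 2, 20, 2.0,
                                    [[1, 0], [0, 1]], cfg, initial_state=ck.MPSP)
        assert truth.event_times.size > 10
        assert all(lab == ck.MPSP for lab in truth.event_labels)

    def test_single_event_peak_equals_drawn_amplitude(self):
        # difference-of-exponentials kernel is normalized to unit peak
        cfg = GeneratorConfig(duration=5.0, noise_sd=0.0, lowpass_cutoff=None, seed=5)
        trace, truth = ck.gen_psp_trace(-107, 1.0, 4.0, 0.0, 2, 20, 0.5,
                                        [[0, 1], [0, 1]], cfg)
        assert truth.event_times.size >= 1
        assert trace.samples.max() - (-107.0) == pytest.approx(4.0, abs=1e-3)

    def test_nonphysical_kinetics_rejected(self):
        cfg = GeneratorConfig(duration=5.0, seed=0)
        with pytest.raises(ValueError, match="rise"):
            ck.gen_psp_trace(-107, 1.5, 5.0, 0.25, 20, 2, 2.0,
                             [[0.7, 0.3], [0.3, 0.7]], cfg)


class TestCompartmentImageGenerator:
    def test_zero_cv_gives_exact_compartment_means(self):
        cfg = GeneratorConfig(seed=6)
        img, _ = ck.gen_compartment_image(80, 100, 60, 0.0, 0.0, 128, cfg)
        membrane = img.compartment_mask("membrane")
        assert np.all(img.pixels[membrane] == 100.0)

    def test_background_region_mean(self):
        cfg = GeneratorConfig(seed=6)
        img, _ = ck.gen_compartment_image(80, 100, 60, 0.05, 10.0, 256, cfg)
        bg = img.compartment_mask("background")
        assert img.pixels[bg].mean() == pytest.approx(10.0, abs=0.3)

    def test_pixel_cv_matches_heterogeneity(self):
        cfg = GeneratorConfig(seed=7)
        img, _ = ck.gen_compartment_image(80, 100, 60, 0.2, 10.0, 512, cfg)
        px = img.pixels[img.masks == 1]  # cytoplasm bulk
        assert abs(px.std() / px.mean() - 0.2) < 0.02

    def test_compartment_masks_are_disjoint(self):
        cfg = GeneratorConfig(seed=8)
        img, _ = ck.gen_compartment_image(80, 100, 60, 0.1, 10.0, 128, cfg)
        m = img.compartment_mask("membrane")
        p = img.compartment_mask("perinuclear")
        c = img.compartment_mask("cytoplasm")
        assert not (m & p).any() and not (m & c).any() and not (p & c).any()


class TestDeterminism:
    def test_same_seed_bit_identical_different_seed_differs(self):
        mk = lambda seed: GeneratorConfig(duration=2.0, noise_sd=0.3, seed=seed)
        t1, _ = ck.gen_spontaneous_trace(10, 0.5, SpikeShape(), -55, mk(9))
        t2, _ = ck.gen_spontaneous_trace(10, 0.5, SpikeShape(), -55, mk(9))
        t3, _ = ck.gen_spontaneous_trace(10, 0.5, SpikeShape(), -55, mk(10))
        assert np.array_equal(t1.samples, t2.samples)
        assert not np.array_equal(t1.samples, t3.samples)
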
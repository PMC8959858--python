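"""Ground-truth-labelled synthetic data generators.

Every generator emulates one acquisition protocol of a current-clamp /
imaging study of *Drosophila* DN1p clock neurons and returns both the
synthetic record and a :class:`~clampkit.core.GroundTruth` carrying the
generative labels, so downstream analysis stages can be validated by
round trip.

Models
------
* Spontaneous firing: gamma-renewal interspike intervals with shape
  ``1/cv**2`` (one knob controls irregularity; cv→0 is the regular
  limit, cv=1 is Poisson-like), stereotyped spike waveforms with
  afterhyperpolarization inserted at the renewal times.
* Evoked firing: 300-ms current steps on a 5–35 pA grid; at and above
  rheobase the instantaneous rate follows a monoexponential
  spike-frequency-adaptation law ``f(t) = plateau + (f0 − plateau) ·
  2**(−t/half_life)`` and spike times are placed by inverting its
  cumulative intensity, so truth interspike intervals are deterministic
  and non-decreasing.
* Synaptic input: hyperpolarized baseline (−105 to −110 mV) carrying
  shot-noise postsynaptic potentials; event times Poisson, two amplitude
  classes (mPSP/PSP) whose sequence follows a two-state discrete-time
  Markov chain, lognormal amplitudes, difference-of-exponentials
  kinetics.
* Immunofluorescence: disk-shaped cell with membrane and perinuclear
  annuli, Gaussian per-pixel intensity heterogeneity on a 16-bit scale.

The acquisition chain adds Gaussian recording noise and then a
zero-phase 4-pole Butterworth low-pass (default 1 kHz at 10 kHz
sampling), in that order, matching a rig whose anti-alias filter sees
the noisy signal.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, signal

from .core import (
    BACKGROUND,
    CYTOPLASM,
    MEMBRANE,
    PERINUCLEAR,
    CompartmentImage,
    GeneratorConfig,
    GroundTruth,
    SpikeShape,
    SweepSet,
    Trace,
)

__all__ = [
    "gamma_isis",
    "gen_spontaneous_trace",
    "gen_quiet_trace",
    "gen_evoked_sweepset",
    "gen_rc_sweep",
    "gen_psp_trace",
    "gen_compartment_image",
    "adaptation_frequency",
    "MPSP",
    "PSP",
]

MPSP, PSP = "mPSP", "PSP"

# Duration (ms) of the slow sub-threshold depolarization preceding spike
# threshold; its maximum slope must stay below typical dV/dt detection
# thresholds so detected threshold crossings land on the fast onset ramp.
_PRE_DEPOL_MS = 2.5
_FALL_MS = 1.0


def _apply_acquisition(samples: np.ndarray, cfg: GeneratorConfig,
                       rng: np.random.Generator) -> np.ndarray:
    """Add recording noise, then the anti-alias low-pass (zero phase)."""
    out = samples.copy()
    if cfg.noise_sd > 0:
        out += rng.normal(0.0, cfg.noise_sd, size=out.size)
    if cfg.lowpass_cutoff is not None:
        sos = signal.butter(4, cfg.lowpass_cutoff, btype="low",
                            fs=cfg.sampling_rate, output="sos")
        out = signal.sosfiltfilt(sos, out)
    return out


# ---------------------------------------------------------------------------
# Spontaneous firing
# ---------------------------------------------------------------------------

def gamma_isis(rate: float, cv: float, n: int,
               rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` interspike intervals (s) from a gamma renewal process.

    Shape ``k = 1/cv**2`` and scale ``1/(rate*k)`` give mean ISI
    ``1/rate`` and coefficient of variation ``cv`` exactly in
    expectation. For a gamma renewal process the local variation
    statistic satisfies ``LV = 3*cv**2 / (2 + cv**2)`` analytically,
    which downstream tests exploit as an oracle.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    if not 0 < cv <= 2:
        raise ValueError("cv must lie in (0, 2]")
    shape = 1.0 / cv**2
    scale = 1.0 / (rate * shape)
    return rng.gamma(shape, scale, size=n)


def _spike_kernel(shape: SpikeShape, rmp: float, fs: float):
    """Additive spike waveform sampled at ``fs``; returns (kernel, peak_idx).

    Piecewise: half-cosine sub-threshold depolarization (rmp→threshold,
    slope → 0 at both ends), linear fast onset ramp (threshold→peak over
    ``onset_ms`` so dV/dt is constant from the first suprathreshold
    sample), linear repolarization to the AHP trough
    (threshold − ahp_depth), exponential AHP recovery back to rmp.
    """
    dt_ms = 1000.0 / fs

    def seg(n):  # at least one sample per segment
        return max(int(round(n / dt_ms)), 1)

    n_pre = seg(_PRE_DEPOL_MS)
    n_on = seg(shape.onset_ms)
    n_fall = seg(_FALL_MS)
    n_rec = seg(2.0 * shape.ahp_recovery_ms)

    thr, peak = shape.threshold_v, shape.peak_v
    ahp_v = thr - shape.ahp_depth

    pre = rmp + (thr - rmp) * 0.5 * (1 - np.cos(np.pi * np.arange(n_pre) / n_pre))
    onset = thr + (peak - thr) * np.arange(n_on + 1) / n_on  # ends at peak
    fall = peak + (ahp_v - peak) * np.arange(1, n_fall + 1) / n_fall
    tau = shape.ahp_recovery_ms / 3.0
    t_rec = np.arange(1, n_rec + 1) * dt_ms
    rec = rmp + (ahp_v - rmp) * np.exp(-t_rec / tau)
    # remove the residual so the kernel lands exactly back on rmp
    rec -= (rec[-1] - rmp) * t_rec / t_rec[-1]

    wave = np.concatenate([pre, onset, fall, rec])
    peak_idx = n_pre + n_on
    return wave - rmp, peak_idx


def gen_spontaneous_trace(rate: float, cv_target: float, shape: SpikeShape,
                          rmp: float, cfg: GeneratorConfig):
    """Synthesize a spontaneously firing membrane-potential trace.

    Spike times follow a gamma renewal process with mean rate ``rate``
    (Hz) and ISI coefficient of variation ``cv_target``; each spike
    inserts the stereotyped waveform of ``shape`` on a baseline at
    ``rmp`` (mV). Returns ``(Trace, GroundTruth)`` with truth spike
    times at waveform peaks, snapped to the sample grid.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    expected = rate * cfg.duration
    if expected < 2:
        raise ValueError(
            f"duration {cfg.duration} s too short for rate {rate} Hz: "
            f"need at least {2.0 / rate:.3g} s for 2 expected spikes"
        )
    rng = cfg.rng()
    fs = cfg.sampling_rate
    n = cfg.n_samples

    # draw a comfortable surplus of ISIs, then trim to the trace window
    n_draw = int(expected + 6 * math.sqrt(expected) + 10)
    isis = gamma_isis(rate, cv_target, n_draw, rng)
    while isis.sum() < cfg.duration:
        isis = np.concatenate([isis, gamma_isis(rate, cv_target, n_draw, rng)])
    times = np.cumsum(isis)

    kernel, peak_idx = _spike_kernel(shape, rmp, fs)
    lead = peak_idx / fs
    tail = (kernel.size - peak_idx) / fs
    times = times[(times > lead) & (times < cfg.duration - tail)]

    # snap to the sample grid; drop grid collisions (sub-sample ISIs)
    snapped = np.round(times * fs).astype(int)
    snapped = snapped[np.concatenate([[True], np.diff(snapped) > 0])]

    samples = np.full(n, float(rmp))
    truth_times = snapped / fs
    for i_peak in snapped:
        start = max(i_peak - peak_idx, 0)
        stop = min(start + kernel.size, n)
        samples[start:stop] += kernel[:stop - start]

    samples = _apply_acquisition(samples, cfg, rng)
    trace = Trace(samples, fs, meta={"protocol": "spontaneous"})
    truth = GroundTruth(
        spike_times=truth_times,
        generative_params={"rate": rate, "cv_target": cv_target, "rmp": rmp,
                           "shape": shape, "seed": cfg.seed},
    )
    return trace, truth


def gen_quiet_trace(rmp: float, cfg: GeneratorConfig):
    """Event-free trace: constant baseline plus the acquisition chain."""
    rng = cfg.rng()
    samples = _apply_acquisition(np.full(cfg.n_samples, float(rmp)), cfg, rng)
    trace = Trace(samples, cfg.sampling_rate, meta={"protocol": "spontaneous"})
    return trace, GroundTruth(generative_params={"rmp": rmp, "seed": cfg.seed})


# ---------------------------------------------------------------------------
# Evoked firing (current steps)
# ---------------------------------------------------------------------------

def adaptation_frequency(t_ms, half_life_ms: float, plateau: float,
                         f0: float) -> np.ndarray:
    """Monoexponential spike-frequency-adaptation law.

    ``f(t) = plateau + (f0 − plateau) · 2**(−t/half_life)`` with ``t``
    and ``half_life`` in ms, frequencies in Hz. The half-life
    parameterization makes the fitted parameter directly the reported
    quantity (equivalent to ``exp(−t·ln2/half_life)``).
    """
    t_ms = np.asarray(t_ms, dtype=float)
    return plateau + (f0 - plateau) * np.exp2(-t_ms / half_life_ms)


def _cumulative_intensity(t_s, half_life_ms, plateau, f0):
    """Integral of the adaptation law from 0 to t (t in seconds) = expected spikes."""
    hl_s = half_life_ms / 1000.0
    t_s = np.asarray(t_s, dtype=float)
    return plateau * t_s + (f0 - plateau) * hl_s / math.log(2) * (1 - np.exp2(-t_s / hl_s))


def adaptation_spike_times(half_life_ms: float, plateau: float, f0: float,
                           step_duration: float, first_spike_mass: float = 0.5
                           ) -> np.ndarray:
    """Deterministic spike times (s from step onset) under the adaptation law.

    The k-th spike is placed where the cumulative intensity reaches
    ``k − 1 + first_spike_mass``, i.e. spikes are laid out at unit
    increments of expected count; ISIs are non-decreasing because the
    rate law is non-increasing.
    """
    total = float(_cumulative_intensity(step_duration, half_life_ms, plateau, f0))
    count = int(math.floor(total + 1 - first_spike_mass - 1e-9))
    times = np.empty(count)
    for k in range(count):
        level = k + first_spike_mass
        times[k] = optimize.brentq(
            lambda t: _cumulative_intensity(t, half_life_ms, plateau, f0) - level,
            0.0, step_duration)
    return times


def _mean_rate_gain(half_life_ms: float, step_duration: float,
                    f0_scale: float) -> float:
    """Ratio of step-mean rate to plateau when f0 = f0_scale × plateau."""
    hl_s = half_life_ms / 1000.0
    return 1.0 + (f0_scale - 1.0) * hl_s / (step_duration * math.log(2)) * (
        1 - math.exp2(-step_duration / hl_s))


def gen_evoked_sweepset(rheobase: float, fi_slope: float,
                        adapt_half_life: float, adapt_plateau: float,
                        cfg: GeneratorConfig, *,
                        shape: Optional[SpikeShape] = None,
                        rmp: float = -55.0, step_on: float = 0.1,
                        step_duration: float = 0.3, f0_scale: float = 2.0,
                        passive_r: float = 150.0, passive_tau_ms: float = 20.0,
                        currents: Optional[Sequence[float]] = None):
    """Synthesize a family of 300-ms current-step sweeps (5–35 pA, 5-pA grid).

    Sweeps below ``rheobase`` (pA) show only the passive RC response; at
    and above it, spikes follow the monoexponential adaptation law with
    half-life ``adapt_half_life`` (ms). ``adapt_plateau`` (Hz) is the
    plateau of the highest-current sweep; plateaus of lower sweeps scale
    linearly in ``(I − rheobase)`` such that the truth mean-rate-vs-
    current relation has slope ``fi_slope`` (Hz/pA). ``f0 = f0_scale ×
    plateau`` per sweep.

    Returns ``(SweepSet, GroundTruth)``; truth spike times (per sweep,
    absolute seconds) and mean rates live in ``generative_params``.
    """
    if currents is None:
        currents = np.arange(5.0, 36.0, 5.0)
    currents = np.asarray(currents, dtype=float)
    if rheobase not in currents:
        raise ValueError(f"rheobase {rheobase} pA must lie on the current grid {currents}")
    if adapt_half_life <= 0:
        raise ValueError("adapt_half_life must be positive")
    if adapt_plateau <= 0:
        raise ValueError("plateau must be positive")
    gain = _mean_rate_gain(adapt_half_life, step_duration, f0_scale)
    i_max = currents.max()

    fs = cfg.sampling_rate
    n = cfg.n_samples
    step_off = step_on + step_duration
    if step_off >= cfg.duration:
        raise ValueError("cfg.duration must cover step_on + step_duration")
    t = np.arange(n) / fs
    shape = shape or SpikeShape()
    kernel, peak_idx = _spike_kernel(shape, rmp, fs)

    sweeps, spike_times_per_sweep, mean_rates = [], [], []
    for si, amp in enumerate(currents):
        # passive RC response to the step (mV = pA × MΩ / 1000)
        v_inf = amp * passive_r / 1000.0
        tau_s = passive_tau_ms / 1000.0
        samples = np.full(n, float(rmp))
        on = (t >= step_on) & (t < step_off)
        samples[on] += v_inf * (1 - np.exp(-(t[on] - step_on) / tau_s))
        after = t >= step_off
        v_end = v_inf * (1 - math.exp(-step_duration / tau_s))
        samples[after] += v_end * np.exp(-(t[after] - step_off) / tau_s)

        truth_t = np.empty(0)
        if amp >= rheobase:
            plateau_i = adapt_plateau - fi_slope / gain * (i_max - amp)
            if plateau_i <= 0:
                raise ValueError(
                    f"plateau at {amp} pA is non-positive ({plateau_i:.3g} Hz); "
                    "raise adapt_plateau or lower fi_slope")
            f0_i = f0_scale * plateau_i
            rel = adaptation_spike_times(adapt_half_life, plateau_i, f0_i,
                                         step_duration)
            truth_t = np.empty(rel.size)
            for j, tr in enumerate(rel):
                i_peak = int(round((step_on + tr) * fs))
                start = i_peak - peak_idx
                stop = min(start + kernel.size, n)
                samples[start:stop] += kernel[:stop - start]
                truth_t[j] = i_peak / fs

        rng = np.random.default_rng([cfg.seed, si])
        samples = _apply_acquisition(samples, cfg, rng)
        sweeps.append(Trace(samples, fs, meta={"protocol": "evoked",
                                               "current_pA": float(amp)}))
        spike_times_per_sweep.append(truth_t)
        mean_rates.append(truth_t.size / step_duration)

    sweepset = SweepSet(sweeps, currents, step_on, step_off)
    truth = GroundTruth(generative_params={
        "rheobase": rheobase, "fi_slope": fi_slope,
        "adapt_half_life": adapt_half_life, "adapt_plateau": adapt_plateau,
        "f0_scale": f0_scale, "currents": currents,
        "spike_times_per_sweep": spike_times_per_sweep,
        "mean_rates": np.asarray(mean_rates), "seed": cfg.seed,
    })
    return sweepset, truth


def gen_rc_sweep(r_in: float, tau_ms: float, delta_i: float, cfg: GeneratorConfig,
                 *, baseline: float = -60.0, step_on: float = 0.1,
                 step_duration: float = 0.3):
    """Passive RC response to a (typically −10 pA hyperpolarizing) step.

    ``r_in`` in MΩ, ``delta_i`` in pA; steady-state deflection is
    ``delta_i × r_in / 1000`` mV. Used to exercise the input-resistance
    estimator.
    """
    fs = cfg.sampling_rate
    n = cfg.n_samples
    t = np.arange(n) / fs
    step_off = step_on + step_duration
    tau_s = tau_ms / 1000.0
    v_inf = delta_i * r_in / 1000.0
    samples = np.full(n, float(baseline))
    on = (t >= step_on) & (t < step_off)
    samples[on] += v_inf * (1 - np.exp(-(t[on] - step_on) / tau_s))
    after = t >= step_off
    v_end = v_inf * (1 - math.exp(-step_duration / tau_s))
    samples[after] += v_end * np.exp(-(t[after] - step_off) / tau_s)
    samples = _apply_acquisition(samples, cfg, cfg.rng())
    trace = Trace(samples, fs, meta={"protocol": "evoked",
                                     "current_pA": float(delta_i)})
    truth = GroundTruth(generative_params={
        "r_in": r_in, "tau_ms": tau_ms, "delta_i": delta_i,
        "baseline": baseline, "step_on": step_on, "step_off": step_off,
        "seed": cfg.seed})
    return trace, truth


# ---------------------------------------------------------------------------
# Synaptic input (PSP shot noise)
# ---------------------------------------------------------------------------

def _psp_kernel(rise_ms: float, decay_ms: float, fs: float):
    """Unit-peak difference-of-exponentials kernel; returns (kernel, peak_idx)."""
    tau_r, tau_d = rise_ms / 1000.0, decay_ms / 1000.0
    t_peak = tau_r * tau_d / (tau_d - tau_r) * math.log(tau_d / tau_r)
    t = np.arange(int(round(8 * tau_d * fs)) + 1) / fs
    k = np.exp(-t / tau_d) - np.exp(-t / tau_r)
    k /= math.exp(-t_peak / tau_d) - math.exp(-t_peak / tau_r)
    return k, int(round(t_peak * fs))


def gen_psp_trace(baseline: float, mpsp_amp_mean: float, psp_amp_mean: float,
                  amp_cv: float, rise_ms: float, decay_ms: float,
                  event_rate: float, transition, cfg: GeneratorConfig,
                  *, initial_state: str = MPSP):
    """Synthesize a hyperpolarized trace carrying two classes of PSP events.

    Event times are Poisson at ``event_rate`` (Hz); each event's class
    (mPSP or PSP) is drawn by iterating the two-state Markov chain
    ``transition`` (rows = from-state in order (mPSP, PSP)) from the
    previous label; amplitudes are lognormal with class mean and
    coefficient of variation ``amp_cv``; kinetics are a
    difference-of-exponentials with the given rise/decay constants.

    Returns ``(Trace, GroundTruth)``; truth event times are waveform
    peak times snapped to the sample grid, with per-event labels and
    drawn amplitudes in ``generative_params``.
    """
    if not (psp_amp_mean > mpsp_amp_mean > 0):
        raise ValueError("require psp_amp_mean > mpsp_amp_mean > 0")
    if rise_ms >= decay_ms:
        raise ValueError("rise_ms must be shorter than decay_ms (non-physical kinetics)")
    if not -120.0 <= baseline <= -40.0:
        raise ValueError("baseline outside physiologic hyperpolarized range (−120..−40 mV)")
    transition = np.asarray(transition, dtype=float)
    if transition.shape != (2, 2) or not np.allclose(transition.sum(axis=1), 1.0):
        raise ValueError("transition must be 2×2 with rows summing to 1")
    if initial_state not in (MPSP, PSP):
        raise ValueError(f"initial_state must be {MPSP!r} or {PSP!r}")

    rng = cfg.rng()
    fs = cfg.sampling_rate
    n = cfg.n_samples
    kernel, peak_idx = _psp_kernel(rise_ms, decay_ms, fs)
    lead, tail = peak_idx / fs, (kernel.size - peak_idx) / fs

    # Poisson process: exponential gaps
    gaps = rng.exponential(1.0 / event_rate,
                           size=int(event_rate * cfg.duration * 1.5) + 20)
    while gaps.sum() < cfg.duration:
        gaps = np.concatenate([gaps, rng.exponential(1.0 / event_rate, size=20)])
    times = np.cumsum(gaps)
    times = times[(times > lead) & (times < cfg.duration - tail)]

    states = (MPSP, PSP)
    labels = []
    cur = initial_state
    for _ in range(times.size):
        cur = states[rng.choice(2, p=transition[states.index(cur)])]
        labels.append(cur)

    sigma = math.sqrt(math.log(1 + amp_cv**2)) if amp_cv > 0 else 0.0
    amps = np.empty(times.size)
    for j, lab in enumerate(labels):
        mean = mpsp_amp_mean if lab == MPSP else psp_amp_mean
        mu = math.log(mean) - sigma**2 / 2
        amps[j] = rng.lognormal(mu, sigma) if sigma > 0 else mean

    # snap peaks to the sample grid; drop the rare event that collides
    # with its predecessor's sample so truth times stay strictly increasing
    snapped = np.round(times * fs).astype(int)
    keep = np.concatenate([[True], np.diff(snapped) > 0])
    snapped = snapped[keep]
    labels = [lab for lab, k in zip(labels, keep) if k]
    amps = amps[keep]

    samples = np.full(n, float(baseline))
    truth_times = snapped / fs
    for j, i_peak in enumerate(snapped):
        start = max(i_peak - peak_idx, 0)
        stop = min(start + kernel.size, n)
        samples[start:stop] += amps[j] * kernel[:stop - start]

    samples = _apply_acquisition(samples, cfg, rng)
    trace = Trace(samples, fs, meta={"protocol": "psp"})
    truth = GroundTruth(
        event_times=truth_times, event_labels=labels,
        generative_params={"baseline": baseline, "amplitudes": amps,
                           "transition": transition, "event_rate": event_rate,
                           "rise_ms": rise_ms, "decay_ms": decay_ms,
                           "seed": cfg.seed})
    return trace, truth


# ---------------------------------------------------------------------------
# Immunofluorescence images
# ---------------------------------------------------------------------------

def gen_compartment_image(mean_total: float, mean_membrane: float,
                          mean_perinuclear: float, heterogeneity_cv: float,
                          background: float, size_px: int,
                          cfg: GeneratorConfig):
    """Synthesize a two-compartment cell image with a label mask.

    Disk-shaped cell of diameter ``0.8 × size_px`` with a 3-px plasma-
    membrane annulus at the rim and a 3-px perinuclear annulus at
    0.35 × radius; the remaining disk interior (labelled cytoplasm)
    carries ``mean_total``. Per-pixel intensities are Gaussian with the
    compartment mean and sd ``mean × heterogeneity_cv``, clipped at
    zero; everything outside the disk is background. Intensities are on
    a 16-bit scale (arbitrary units).
    """
    if not (min(mean_total, mean_membrane, mean_perinuclear) >= background >= 0):
        raise ValueError("compartment means must be ≥ background ≥ 0")
    if heterogeneity_cv < 0:
        raise ValueError("heterogeneity_cv must be non-negative")
    rng = cfg.rng()
    yy, xx = np.mgrid[0:size_px, 0:size_px]
    c = (size_px - 1) / 2.0
    r = np.hypot(yy - c, xx - c)
    radius = 0.4 * size_px

    masks = np.full((size_px, size_px), BACKGROUND, dtype=np.uint8)
    disk = r <= radius
    masks[disk] = CYTOPLASM
    masks[disk & (r > radius - 3)] = MEMBRANE
    peri_r = 0.35 * radius
    masks[disk & (np.abs(r - peri_r) <= 1.5)] = PERINUCLEAR

    means = {BACKGROUND: background, CYTOPLASM: mean_total,
             MEMBRANE: mean_membrane, PERINUCLEAR: mean_perinuclear}
    pixels = np.zeros((size_px, size_px))
    for label, mean in means.items():
        sel = masks == label
        if heterogeneity_cv > 0 and mean > 0:
            pixels[sel] = rng.normal(mean, mean * heterogeneity_cv, sel.sum())
        else:
            pixels[sel] = mean
    np.clip(pixels, 0.0, 65535.0, out=pixels)

    image = CompartmentImage(pixels, masks)
    truth = GroundTruth(generative_params={
        "mean_total": mean_total, "mean_membrane": mean_membrane,
        "mean_perinuclear": mean_perinuclear,
        "heterogeneity_cv": heterogeneity_cv, "background": background,
        "size_px": size_px, "seed": cfg.seed})
    return image, truth
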
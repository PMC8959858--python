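# Methods

This note documents the models, estimators and numerical choices behind
`clampkit`, the assumptions they encode, and what validation against
the built-in synthetic generators does and does not establish.

## Signal model and acquisition chain

All voltage traces are uniformly sampled membrane potentials in mV. The
synthetic acquisition chain mirrors a patch-clamp rig: the ideal signal
is built first, Gaussian recording noise (`noise_sd`, default 0.3 mV)
is added, and a zero-phase 4-pole Butterworth low-pass at
`lowpass_cutoff` (default 1 kHz at 10 kHz sampling) is applied last, as
an anti-alias filter sees the noisy signal. No noise magnitude is
standard for these recordings; 0.3 mV makes typical miniature synaptic
events (~1.5 mV) clearly suprathreshold while keeping detection
non-trivial. Note that the 1 kHz low-pass shrinks broadband noise: the
in-band RMS of 0.3 mV white noise at 10 kHz is ≈0.14 mV, and all
noise-referenced thresholds operate on that recorded, not injected,
magnitude.

## Spontaneous firing

**Generative model.** Interspike intervals are drawn from a gamma
renewal process with shape k = 1/CV² and scale 1/(rate·k), giving an
exact one-knob mapping from the target CV to the ISI distribution
(CV→0 is the regular limit; CV=1 is Poisson). The gamma family also
provides an analytic oracle for the local-variation statistic,
LV = 3·CV²/(2+CV²), used to cross-check the LV implementation. A
stereotyped spike waveform is inserted additively at each renewal time:
a 2.5-ms half-cosine subthreshold depolarization to threshold (its
maximum slope stays below the detector's dV/dt criterion), a linear
onset ramp from threshold to peak over `onset_ms` (constant dV/dt from
the first suprathreshold sample, so the detected threshold voltage is
exact in the noise-free limit), a 1-ms repolarization to the
afterhyperpolarization trough at threshold − `ahp_depth`, and an
exponential recovery to rest (τ = `ahp_recovery_ms`/3, linearly
corrected to land exactly on the resting potential). Truth spike times
are waveform peaks snapped to the sample grid; sub-sample collisions
are dropped.

**Detection.** Spikes are local maxima with prominence ≥ 10 mV
preceded by a contiguous run of forward-difference slope ≥ 10 mV/ms
(both configurable); the spike time is the peak, the threshold is the
first sample of the suprathreshold-slope run, and the AHP minimum is
taken up to the next threshold crossing, capped at 50 ms. A 1-ms
refractory guard prevents double counting without merging genuinely
close spikes.

**ISI statistics.** CV uses the n−1 sample standard deviation. LV
follows the adjacent-pair dispersion formula and needs ≥ 2 ISIs.
Skewness (m₃/m₂^1.5) and kurtosis (m₄/m₂², non-excess, Gaussian = 3)
are biased moment estimators computed on the raw ISIs, not on binned
histograms — binning loses information and adds a bandwidth parameter.
They require ≥ 3 ISIs, the minimum at which both are defined; metrics
below their minimum, or on zero-variance trains, are reported missing
with a reason, never as zero. The mean rate is (count−1)/span.

**Autocorrelation.** Ordered spike pairs are histogrammed by signed
lag into bins centered on 0, ±bin, ±2·bin … (defaults 10 ms, ±1 s),
excluding zero-lag self pairs, and normalized by (spike count × bin
width) so a Poisson train reads out its mean rate at every lag.
Center-aligned bins make periodic trains peak exactly on multiples of
their period.

**Wavelet power.** The complex Morlet wavelet with bandwidth 1.5 and
center frequency 6/2π (the classic ω₀ = 6 Morlet) is applied via
FFT-based CWT on the mean-subtracted trace; power is the time-averaged
squared magnitude over a log-spaced 0.5–100 Hz grid (30 points by
default). The trace must span ≥ 3 cycles of the lowest frequency.

## Evoked excitability

**Step protocol.** Sweeps use 300-ms steps on the 5–35 pA grid.
Sub-rheobase sweeps show the passive RC response (default 150 MΩ,
τ = 20 ms). At and above rheobase, spike times are placed
deterministically by inverting the cumulative intensity of the
adaptation law f(t) = plateau + (f0 − plateau)·2^(−t/t½) at unit
increments of expected count (first spike at mass 0.5, i.e. counts
round the expected number). `adapt_plateau` parameterizes the
highest-current sweep; lower sweeps scale linearly in (I − rheobase)
so the truth mean-rate-vs-current relation has exactly the requested
f-I slope. f0 defaults to 2×plateau (configurable): the initial rate
of an adapting neuron is not separately reported, and a factor of two
gives a visible but not extreme transient.

**Estimators.** Rates are spike counts in the step window over 0.3 s;
rheobase is the smallest spiking current; slope and intercept are OLS
over sweeps from the point of initial spiking, which makes the slope
invariant to prepending silent sweeps. Input resistance is the mean
voltage over the last 50 ms of the step minus the 50-ms pre-step
baseline, divided by the injected current (1 mV/1 pA = 1000 MΩ);
spikes during the step abort the estimate rather than contaminate it.

**Adaptation fit.** The monoexponential is parameterized directly in
half-life (2^(−t/t½) ≡ exp(−t·ln2/t½)) so the fitted parameter equals
the reported quantity. Instantaneous frequency is 1/ISI timestamped at
the ISI midpoint from step onset ("occurrence time" has no standard
definition; the midpoint is unbiased for slowly varying rates). Bounds:
t½ ∈ (0.1, 300] ms, plateau ∈ [0, 500] Hz, f0 ∈ [0, 2000] Hz;
initialization from the first/last frequency points; trust-region least
squares. A flat series reports the plateau and flags the half-life as
unidentifiable; bound-hitting parameters are flagged.

A structural caveat: at plateau rates near 20–27 Hz with half-lives of
a few ms, the adaptation transient carries well under one expected
spike, so the half-life is not identifiable from single-sweep spike
times in that regime — only from a frequency series (as in the
round-trip validations) or from pooling. The spike-time route is
validated at a parameter point with ≥ 7 transient spikes (f0 = 300 Hz,
plateau = 50 Hz, t½ = 20 ms), where time-rescaling inversion recovers
both parameters within 10%.

## Synaptic events

**Generative model.** Event times are Poisson (default 2 Hz); each
event's class is drawn by iterating a two-state (mPSP, PSP) Markov
chain from the previous label; amplitudes are lognormal around the
class mean (defaults 1.5 and 5–6 mV, CV 0.25), matching the skewed
cumulative amplitude distributions characteristic of these events;
kinetics are a unit-peak difference of exponentials (rise 2 ms, decay
20 ms). Note the kernel peaks ≈ 5 ms after onset for these constants —
the rise time constant is not the onset-to-peak time.

**Preprocessing.** The trace is smoothed with a median filter whose
window is the nearest odd sample count to 3 ms. Background noise RMS
is computed from the all-points amplitude of the raw trace about a
slow baseline, iteratively re-estimated over samples within 3×RMS so
event excursions are excluded (for pure Gaussian input the 3σ clip
biases the estimate down by only ≈1.3%). The slow baseline is a
~100-ms median computed on a 50× decimated copy and re-interpolated —
equally robust to events as a full-rate long median at a fraction of
the cost. Traces rising above −40 mV trigger a warning (possible
spikes in a nominally hyperpolarized recording).

**Detection.** Events are local maxima exceeding the slow baseline by
k×RMS (k = 3 by default; the criterion exists in the field but k is a
free choice, so it is exposed on the CLI), separated by a 10-ms
refractory/merge window, with a matching prominence requirement as the
noise-rejection criterion — without it, noise ripples riding on the
decay tail of large events satisfy the absolute threshold and double
the event count. When the noise estimate is zero a 0.1 mV floor is
applied and logged. Amplitude is peak voltage minus the mean of the
entire filtered trace (computed after filtering), making it invariant
to constant offsets; onset is the last crossing of baseline + 0.5×RMS
before the peak; rising slope is the onset-to-peak voltage change per
ms.

**Classification and transitions.** The mPSP/PSP split is the exact
global optimum of 1-D 2-means, found by contiguous-split search on the
sorted amplitudes — deterministic, no random initialization. The
smaller-center cluster is mPSP; `separation_ok` requires the centers to
differ by ≥ 2× the pooled within-cluster sd, operationalizing the
requirement that the separation look binary. Transition probabilities
are maximum-likelihood counts P(a→b) = n(a→b)/n(a→·); a state never
observed in the from-position yields a missing (NaN) row, not zeros.

## Imaging

The generator builds a disk-shaped cell of diameter 0.8× the image
size with a 3-px plasma-membrane annulus at the rim and a 3-px
perinuclear annulus at 0.35× radius, emulating single-plane
quantification at the slice of maximum nuclear diameter; per-pixel
intensities are Gaussian with sd = mean × `heterogeneity_cv`, clipped
at zero, on a 16-bit scale. All pixels outside the disk form the
background region (label 0) — a single label image cannot distinguish
designated corner patches from other extracellular pixels, and the
background is statistically uniform, so the whole exterior serves as
the adjacent-background measurement.

Quantification subtracts the background-mask mean from each
compartment mean (total = union of all cell labels), flooring negative
corrected means at zero with a flag. "Signal variability" is
operationalized as the coefficient of variation (population sd/mean) of
background-subtracted pixel intensities within the compartment — the
metric itself has no standard definition, so sd and IQR/median are
exposed as alternatives. The CV is computed per cell across pixels;
group-level CV across cell means can be formed from the summary table.
Because subtraction shifts the mean but not the sd, the measured CV of
a compartment with generative heterogeneity h is h·m/(m−b) for mean m
and background b (e.g. 0.25 → 0.273 at m = 120, b = 10); validation
tolerances account for this.

## Reporting and determinism

Per-cell metrics accumulate in a long-format table (cell × metric ×
value × units, with age-group and circadian-window annotations); the
report stage aggregates to condition-level n, mean and SEM (sample
sd/√n, missing values excluded and counted). All file writes are
atomic (temp file + rename) and all randomness flows from a single
seed through `numpy.random.default_rng`, so identical configs and
seeds reproduce byte-identical tables.

## Validation scale

The test suite validates each stage by round trip against the
generators at sizes chosen to keep statistical tolerances meaningful:
5000-ISI gamma trains for CV/LV recovery (±0.05), a ~520-s synthetic
recording with ≥1000 PSP events for detection recall, classification
accuracy and transition-probability recovery (≥0.95, ≥0.95, ±0.05), a
3×3 grid of adaptation parameters spanning half-lives ≈3–13 ms and
plateaus ≈20–27 Hz for noise-free refits, and 512–1024-px images for
compartment means (±3%) and heterogeneity (±0.03).

## Limitations

- The spike generator is phenomenological (inserted waveforms on a
  renewal process), not conductance-based; it does not produce
  rate–waveform covariation, bursting, or subthreshold oscillations,
  so passing round trips demonstrate estimator correctness under the
  assumed statistical structure, not robustness to every biological
  waveform.
- PSP events are a linear superposition; dendritic filtering,
  amplitude–kinetics correlations and excitatory/inhibitory mixtures
  are not modeled, and classification uses amplitude only (no kinetic
  criterion).
- Vendor acquisition formats (ABF) are out of scope; traces are
  exchanged as delimited text with JSON sidecars.
- Hypothesis testing between conditions is deliberately excluded; the
  condition-level summary table is the hand-off to standard statistics
  tools.
- Images are single-plane with externally supplied masks; no
  segmentation, deconvolution or 3-D quantification.
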
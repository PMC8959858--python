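"""Spike detection and spontaneous-firing pattern statistics.

Quantifies the temporal structure of spontaneous spike trains: global
irregularity (coefficient of variation of interspike intervals), local
irregularity (local variation over adjacent ISI pairs), ISI-distribution
shape (skewness, non-excess kurtosis), spike-timing autocorrelation,
time-averaged continuous-wavelet power, and per-spike waveform metrics
(resting membrane potential, afterhyperpolarization amplitude,
threshold-to-peak onset duration).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pywt
from scipy import signal, stats

from .core import Trace

__all__ = [
    "SpikeTrain",
    "ISIStats",
    "WaveformStats",
    "SpectralResult",
    "detect_spikes",
    "isi_statistics",
    "local_variation",
    "spike_autocorrelation",
    "waveform_statistics",
    "wavelet_power",
]


@dataclass
class SpikeTrain:
    """Detected spikes: peak times (s) plus per-spike waveform features."""

    spike_times: np.ndarray          # peak times, s
    threshold_times: np.ndarray      # dV/dt threshold-crossing times, s
    threshold_v: np.ndarray          # mV at threshold crossing
    peak_v: np.ndarray               # mV at peak
    ahp_min_v: np.ndarray            # post-spike minimum, mV (NaN if truncated)

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.size > 1:
            isis = np.diff(self.spike_times)
            if not np.all(isis > 0):
                raise ValueError("spike times must be strictly increasing")
            if np.any(isis < 1e-3):
                raise ValueError("refractory violation: ISI below 1 ms")

    @property
    def n(self) -> int:
        return self.spike_times.size


@dataclass
class ISIStats:
    """Interspike-interval pattern statistics.

    ``cv`` uses the n−1 sample standard deviation over the mean; ``lv``
    is the local variation over adjacent ISI pairs, bounded [0, 3);
    ``skewness``/``kurtosis`` are biased moment estimators on the raw
    ISIs with kurtosis non-excess (Gaussian → 3). Metrics that cannot
    be computed are NaN with the reason in ``missing``.
    """

    n: int
    mean_isi_ms: float = float("nan")
    cv: float = float("nan")
    lv: float = float("nan")
    skewness: float = float("nan")
    kurtosis: float = float("nan")
    mean_rate: float = float("nan")
    missing: dict = field(default_factory=dict)


@dataclass
class WaveformStats:
    rmp: float
    mean_rate: float = float("nan")
    ahp_amplitude: float = float("nan")
    onset_duration_ms: float = float("nan")
    missing: dict = field(default_factory=dict)


@dataclass
class SpectralResult:
    frequencies: np.ndarray   # Hz
    power: np.ndarray         # time-averaged |CWT|^2, arbitrary units


def detect_spikes(trace: Trace, dvdt_threshold: float = 10.0,
                  min_peak_prominence: float = 10.0,
                  ahp_window_ms: float = 50.0) -> SpikeTrain:
    """Detect action potentials by dV/dt-threshold onset with a prominence guard.

    A spike is a local maximum with prominence ≥ ``min_peak_prominence``
    (mV) preceded by a contiguous run of samples whose forward slope
    reaches ``dvdt_threshold`` (mV/ms). The spike time is the peak time;
    ``threshold_v`` is the voltage at the first sample of that
    suprathreshold-slope run; ``ahp_min_v`` is the post-peak minimum up
    to the next spike's threshold crossing, capped at ``ahp_window_ms``.
    Zero detected spikes is a valid result.
    """
    if trace.duration < 0.1:
        raise ValueError("trace must be at least 100 ms long")
    v = trace.samples
    fs = trace.sampling_rate
    dt_ms = 1000.0 / fs
    dvdt = np.diff(v) / dt_ms  # forward slope, mV/ms; length n-1

    min_dist = max(int(round(1e-3 * fs)), 1)  # 1-ms refractory guard
    peaks, _ = signal.find_peaks(v, prominence=min_peak_prominence,
                                 distance=min_dist)

    peak_idx, thr_idx = [], []
    for p in peaks:
        # walk back through the contiguous fast-depolarization run
        i = p - 1
        if i < 0 or dvdt[i] < dvdt_threshold:
            # peak without a fast upstroke immediately before it: scan a
            # short window back for the run (the sample before the peak
            # can dip below threshold as the waveform rounds off)
            lo = max(p - int(round(5e-3 * fs)), 0)
            run = np.nonzero(dvdt[lo:p] >= dvdt_threshold)[0]
            if run.size == 0:
                continue  # no suprathreshold upstroke: reject
            i = lo + run[-1]
        while i - 1 >= 0 and dvdt[i - 1] >= dvdt_threshold:
            i -= 1
        peak_idx.append(p)
        thr_idx.append(i)

    peak_idx = np.asarray(peak_idx, dtype=int)
    thr_idx = np.asarray(thr_idx, dtype=int)

    cap = int(round(ahp_window_ms * 1e-3 * fs))
    ahp = np.full(peak_idx.size, np.nan)
    for j, p in enumerate(peak_idx):
        end = thr_idx[j + 1] if j + 1 < peak_idx.size else v.size
        end = min(end, p + 1 + cap)
        if end > p + 1:
            ahp[j] = v[p + 1:end].min()

    return SpikeTrain(
        spike_times=trace.t0 + peak_idx / fs,
        threshold_times=trace.t0 + thr_idx / fs,
        threshold_v=v[thr_idx] if thr_idx.size else np.empty(0),
        peak_v=v[peak_idx] if peak_idx.size else np.empty(0),
        ahp_min_v=ahp,
    )


def local_variation(isis: np.ndarray) -> float:
    """Local variation of a spike train.

    ``LV = 1/(n−1) Σ_{i=1}^{n−1} 3 (ISI_i − ISI_{i+1})² / (ISI_i + ISI_{i+1})²``
    where n is the number of ISIs. Zero for a perfectly regular train,
    bounded below 3; invariant to uniform time rescaling.
    """
    isis = np.asarray(isis, dtype=float)
    if isis.size < 2:
        raise ValueError("local variation needs at least 2 ISIs")
    a, b = isis[:-1], isis[1:]
    return float(np.mean(3.0 * (a - b) ** 2 / (a + b) ** 2))


def isi_statistics(spike_times: np.ndarray) -> ISIStats:
    """Pattern statistics of the interspike intervals of a spike train.

    Needs ≥ 3 spikes (2 ISIs) for CV and LV and ≥ 4 spikes (3 ISIs) for
    skewness/kurtosis; metrics below their minimum are NaN with the
    reason recorded, never silently zero. ``mean_rate`` is
    (spike count − 1) / span of the train.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    isis = np.diff(spike_times) * 1000.0  # ms
    out = ISIStats(n=isis.size)
    if isis.size < 2:
        out.missing["cv"] = out.missing["lv"] = (
            f"need at least 2 ISIs for CV/LV, got {isis.size}")
        out.missing["skewness"] = out.missing["kurtosis"] = (
            f"need at least 3 ISIs, got {isis.size}")
        if isis.size == 1:
            out.mean_isi_ms = float(isis[0])
            out.mean_rate = 1000.0 / out.mean_isi_ms
        return out

    out.mean_isi_ms = float(np.mean(isis))
    out.cv = float(np.std(isis, ddof=1) / np.mean(isis))
    out.lv = local_variation(isis)
    span = spike_times[-1] - spike_times[0]
    out.mean_rate = (spike_times.size - 1) / span

    if isis.size < 3:
        out.missing["skewness"] = out.missing["kurtosis"] = (
            f"need at least 3 ISIs for distribution shape, got {isis.size}")
    elif np.std(isis) <= 1e-9 * np.mean(isis):
        out.missing["skewness"] = out.missing["kurtosis"] = (
            "zero ISI variance: distribution shape undefined")
    else:
        out.skewness = float(stats.skew(isis, bias=True))
        out.kurtosis = float(stats.kurtosis(isis, fisher=False, bias=True))
    return out


def spike_autocorrelation(spike_times: np.ndarray, bin_ms: float = 10.0,
                          max_lag_ms: float = 1000.0):
    """Spike-timing autocorrelation histogram, normalized to conditional rate.

    Counts ordered spike pairs per signed lag bin over ±``max_lag_ms``,
    excluding zero-lag self pairs, divided by (spike count × bin width)
    so a Poisson train reads out its mean rate (Hz) at every lag.
    Returns ``(lag centers in ms, rate in Hz)``; symmetric in lag.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    if spike_times.size < 10:
        raise ValueError("autocorrelation needs at least 10 spikes")
    if bin_ms > max_lag_ms:
        raise ValueError("bin_ms must not exceed max_lag_ms")
    max_lag = max_lag_ms / 1000.0
    n_half = int(round(max_lag_ms / bin_ms))
    # bins centered on 0, ±bin, ±2·bin … so periodic trains peak on-center
    edges = (np.arange(-n_half, n_half + 2) - 0.5) * bin_ms / 1000.0

    reach = max_lag + bin_ms / 2000.0  # cover the outermost bins fully
    counts = np.zeros(edges.size - 1)
    for i, t in enumerate(spike_times):
        lo = np.searchsorted(spike_times, t - reach, side="left")
        hi = np.searchsorted(spike_times, t + reach, side="right")
        lags = spike_times[lo:hi] - t
        lags = lags[np.arange(lo, hi) != i]  # drop the self pair
        counts += np.histogram(lags, bins=edges)[0]

    centers = (edges[:-1] + edges[1:]) / 2 * 1000.0  # ms
    rate = counts / (spike_times.size * (bin_ms / 1000.0))
    return centers, rate


def waveform_statistics(trace: Trace, train: SpikeTrain,
                        exclude_ms: float = 5.0) -> WaveformStats:
    """Resting potential and per-spike waveform metrics.

    RMP is the median voltage excluding ±``exclude_ms`` around each
    spike peak (median, not mean, to resist residual AHP tails);
    ``ahp_amplitude`` averages (threshold_v − ahp_min_v) over spikes;
    ``onset_duration_ms`` averages the threshold-to-peak time.
    """
    v = trace.samples
    fs = trace.sampling_rate
    keep = np.ones(v.size, dtype=bool)
    half = int(round(exclude_ms * 1e-3 * fs))
    for t in train.spike_times:
        p = trace.index_at(t)
        keep[max(p - half, 0):p + half + 1] = False
    rmp = float(np.median(v[keep])) if keep.any() else float(np.median(v))

    out = WaveformStats(rmp=rmp)
    if train.n == 0:
        out.missing["mean_rate"] = out.missing["ahp_amplitude"] = \
            out.missing["onset_duration_ms"] = "no spikes detected"
        return out
    if train.n > 1:
        out.mean_rate = (train.n - 1) / (train.spike_times[-1] - train.spike_times[0])
    else:
        out.missing["mean_rate"] = "need at least 2 spikes for a rate"
    ok = np.isfinite(train.ahp_min_v)
    if ok.any():
        out.ahp_amplitude = float(np.mean(train.threshold_v[ok] - train.ahp_min_v[ok]))
    else:
        out.missing["ahp_amplitude"] = "no post-spike window available"
    out.onset_duration_ms = float(
        np.mean((train.spike_times - train.threshold_times) * 1000.0))
    return out


def wavelet_power(trace: Trace, freq_grid: Optional[np.ndarray] = None,
                  wavelet: str = "cmor1.5-0.9549") -> SpectralResult:
    """Time-averaged continuous-wavelet power of the mean-subtracted trace.

    Uses an analytic complex Morlet wavelet (bandwidth 1.5, center
    frequency 0.9549 ≈ 6/2π, i.e. the classic ω₀ = 6 Morlet). The
    default grid is 30 log-spaced frequencies over 0.5–100 Hz. Requires
    the trace to span ≥ 3 cycles of the lowest requested frequency and
    every frequency to lie below Nyquist.
    """
    fs = trace.sampling_rate
    if freq_grid is None:
        freq_grid = np.geomspace(0.5, 100.0, 30)
    freq_grid = np.asarray(freq_grid, dtype=float)
    if np.any(freq_grid <= 0) or np.any(freq_grid >= fs / 2):
        raise ValueError("frequencies must lie in (0, Nyquist)")
    if trace.duration < 3.0 / freq_grid.min():
        raise ValueError(
            f"trace of {trace.duration:.3g} s spans fewer than 3 cycles of "
            f"{freq_grid.min():.3g} Hz")

    x = trace.samples - trace.samples.mean()
    scales = pywt.frequency2scale(wavelet, freq_grid / fs)
    coef, _ = pywt.cwt(x, scales, wavelet, sampling_period=1.0 / fs,
                       method="fft")
    power = np.mean(np.abs(coef) ** 2, axis=1)
    return SpectralResult(frequencies=freq_grid, power=power)
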
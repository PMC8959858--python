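"""Postsynaptic-potential event detection, classification and state transitions.

Pipeline for hyperpolarized sharp-electrode traces (soma held near −105
to −110 mV so spikes are absent and PSPs stand alone): a 3-ms median
filter smooths the raw potential; background noise is measured as the
RMS of the all-points amplitude about a slow baseline with iterative
3×RMS clipping to exclude event-driven excursions; events are local
maxima exceeding the baseline by a noise-scaled threshold; amplitudes
are referenced to the mean of the entire trace and rising slopes to the
onset-to-peak voltage change per millisecond. Detected amplitudes are
split into miniature (mPSP) and spike-induced (PSP) classes by an exact
1-D two-means clustering, and the label sequence is summarized as a
discrete-time Markov transition matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence, Tuple

import numpy as np
from scipy import ndimage, signal

from .core import Trace
from .synthetic import MPSP, PSP

__all__ = [
    "PSPEventSet",
    "EventClassification",
    "TransitionMatrix",
    "preprocess",
    "detect_events",
    "classify_events",
    "two_means_1d",
    "transition_probabilities",
    "ecdf",
]

logger = logging.getLogger(__name__)

_STATES = (MPSP, PSP)


@dataclass
class PSPEventSet:
    """Detected synaptic events and their biophysical parameters.

    Amplitudes are peak voltage minus the mean of the entire (filtered)
    trace, making them invariant to constant offsets; rising slopes are
    mV/ms from the onset crossing to the peak. ``frequency`` is event
    count over trace duration.
    """

    peak_times: np.ndarray      # s
    amplitudes: np.ndarray      # mV
    rising_slopes: np.ndarray   # mV/ms
    inter_event_intervals: np.ndarray  # s
    trace_mean: float           # mV
    noise_rms: float            # mV
    frequency: float            # Hz

    @property
    def n(self) -> int:
        return self.peak_times.size


@dataclass
class EventClassification:
    """mPSP/PSP labels from amplitude clustering.

    ``separation_ok`` is False when the class centers are closer than
    twice the pooled within-cluster standard deviation, i.e. when the
    amplitude distribution does not support a binary split.
    """

    labels: list
    centers: dict
    separation_ok: bool


@dataclass
class TransitionMatrix:
    """Discrete-time Markov chain estimate over the (mPSP, PSP) state order.

    ``probs[a, b] = count(a→b) / count(a→·)``; a state never observed in
    the from-position has a NaN row (missing, not zero).
    """

    counts: np.ndarray
    probs: np.ndarray
    states: tuple = _STATES


def _slow_baseline(v: np.ndarray, fs: float, window_ms: float = 100.0,
                   decimate: int = 50) -> np.ndarray:
    """Slow median baseline: median-filter a decimated copy, re-interpolate."""
    sub = v[::decimate]
    w = int(round(window_ms / 1000.0 * fs / decimate))
    w += 1 - w % 2  # odd
    if w >= 3 and sub.size > w:
        sub = ndimage.median_filter(sub, size=w, mode="nearest")
    idx = np.arange(0, v.size, decimate)
    return np.interp(np.arange(v.size), idx, sub)


def preprocess(trace: Trace, median_ms: float = 3.0
               ) -> Tuple[Trace, float]:
    """Median-filter the raw potential and measure the background noise RMS.

    The filter window is the nearest odd sample count to ``median_ms``
    (edges reflected). Noise RMS is computed from the all-points
    amplitude of the raw trace about a slow baseline, iteratively
    re-estimated over samples within 3×RMS so PSP excursions do not
    inflate it. Traces containing samples above −40 mV (possible
    spikes) trigger a warning.
    """
    if trace.duration < 1.0:
        raise ValueError("PSP analysis needs at least 1 s of trace")
    v = trace.samples
    fs = trace.sampling_rate
    if np.any(v > -40.0):
        warnings.warn("trace rises above −40 mV: possible action potentials "
                      "in a nominally hyperpolarized recording")
    w = int(round(median_ms / 1000.0 * fs))
    w += 1 - w % 2
    if w > v.size:
        raise ValueError(f"median window of {w} samples exceeds trace length {v.size}")
    filtered = ndimage.median_filter(v, size=w, mode="reflect") if w >= 3 else v.copy()

    resid = v - _slow_baseline(v, fs)
    rms = float(np.sqrt(np.mean(resid ** 2)))
    for _ in range(10):
        if rms == 0:
            break
        clipped = resid[np.abs(resid) <= 3 * rms]
        new = float(np.sqrt(np.mean(clipped ** 2))) if clipped.size else 0.0
        if abs(new - rms) <= 1e-6 * max(rms, 1e-12):
            rms = new
            break
        rms = new

    out = Trace(filtered, fs, t0=trace.t0, meta=dict(trace.meta))
    return out, rms


def detect_events(filtered: Trace, noise_rms: float, k_threshold: float = 3.0,
                  refractory_ms: float = 10.0) -> PSPEventSet:
    """Detect PSP events as noise-thresholded local maxima above baseline.

    Candidates must exceed the slow baseline by ``k_threshold ×
    noise_rms`` (floored at 0.1 mV when the noise estimate is zero) and
    be separated by ``refractory_ms``. Event amplitude is peak voltage
    minus the mean of the entire trace; onset is the last crossing of
    baseline + 0.5×noise_rms before the peak, and the rising slope is
    the onset-to-peak voltage change per ms.
    """
    v = filtered.samples
    fs = filtered.sampling_rate
    threshold = k_threshold * noise_rms
    if threshold <= 0:
        threshold = 0.1
        logger.info("noise_rms is zero: applying 0.1 mV amplitude floor")

    baseline = _slow_baseline(v, fs)
    above = v - baseline
    dist = max(int(round(refractory_ms / 1000.0 * fs)), 1)
    # height is the event-finding criterion; prominence is the noise
    # rejection — it discards ripples riding on the decay tail of a
    # larger event, which clear the baseline threshold but rise only by
    # noise above their local surroundings
    peaks, _ = signal.find_peaks(above, height=threshold, distance=dist,
                                 prominence=threshold)

    trace_mean = float(np.mean(v))
    onset_level = 0.5 * noise_rms
    amps = v[peaks] - trace_mean
    slopes = np.full(peaks.size, np.nan)
    below_idx = np.nonzero(above <= onset_level)[0]
    for j, p in enumerate(peaks):
        k = np.searchsorted(below_idx, p)  # crossings strictly before the peak
        if k == 0:
            continue
        o = below_idx[k - 1]
        slopes[j] = (v[p] - v[o]) / ((p - o) * 1000.0 / fs)

    peak_times = filtered.t0 + peaks / fs
    return PSPEventSet(
        peak_times=peak_times,
        amplitudes=amps,
        rising_slopes=slopes,
        inter_event_intervals=np.diff(peak_times),
        trace_mean=trace_mean,
        noise_rms=noise_rms,
        frequency=peaks.size / filtered.duration,
    )


def two_means_1d(values: np.ndarray) -> Tuple[np.ndarray, float, float, float]:
    """Exact 1-D 2-means by contiguous-split search on sorted values.

    The optimal 2-means partition of scalars is a contiguous split of
    the sorted sequence, so scanning all n−1 splits finds the global
    optimum deterministically (no random initialization). Returns
    ``(boolean upper-cluster membership, lower center, upper center,
    pooled within-cluster sd)``.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    order = np.argsort(values, kind="stable")
    s = values[order]
    csum = np.cumsum(s)
    csq = np.cumsum(s ** 2)
    best_sse, best_k = np.inf, None
    for k in range(1, n):  # lower cluster = s[:k]
        m1 = csum[k - 1] / k
        m2 = (csum[-1] - csum[k - 1]) / (n - k)
        sse = (csq[k - 1] - k * m1 ** 2) + (csq[-1] - csq[k - 1] - (n - k) * m2 ** 2)
        if sse < best_sse - 1e-15:
            best_sse, best_k = sse, k
    k = best_k
    lower_c = float(csum[k - 1] / k)
    upper_c = float((csum[-1] - csum[k - 1]) / (n - k))
    upper = np.zeros(n, dtype=bool)
    upper[order[k:]] = True
    pooled_sd = float(np.sqrt(max(best_sse, 0.0) / max(n - 2, 1)))
    return upper, lower_c, upper_c, pooled_sd


def classify_events(amplitudes: Sequence[float]) -> EventClassification:
    """Split event amplitudes into mPSP (smaller) and PSP (larger) classes.

    Exact two-means on the amplitudes; the cluster with the smaller
    center is labelled mPSP. ``separation_ok`` requires the centers to
    differ by at least twice the pooled within-cluster sd (the split
    must look binary). All-identical amplitudes yield a degenerate
    single cluster.
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    if amplitudes.size < 4:
        raise ValueError("classification needs at least 4 events")
    if np.ptp(amplitudes) == 0:
        return EventClassification(labels=[MPSP] * amplitudes.size,
                                   centers={MPSP: float(amplitudes[0])},
                                   separation_ok=False)
    upper, lo_c, hi_c, pooled_sd = two_means_1d(amplitudes)
    labels = [PSP if u else MPSP for u in upper]
    sep_ok = bool(hi_c - lo_c >= 2.0 * pooled_sd) if pooled_sd > 0 else True
    return EventClassification(labels=labels,
                               centers={MPSP: lo_c, PSP: hi_c},
                               separation_ok=sep_ok)


def transition_probabilities(labels: Sequence[str]) -> TransitionMatrix:
    """Maximum-likelihood transition matrix of the mPSP/PSP label sequence.

    ``P(a→b)`` = count of a immediately followed by b, over all
    transitions out of a. Rows for states never observed in the
    from-position are NaN (missing), preserving the distinction from a
    measured zero.
    """
    labels = list(labels)
    if len(labels) < 2:
        raise ValueError("need at least 2 labelled events for transitions")
    bad = set(labels) - set(_STATES)
    if bad:
        raise ValueError(f"unknown state labels: {sorted(bad)}")
    idx = {s: i for i, s in enumerate(_STATES)}
    counts = np.zeros((2, 2), dtype=int)
    for a, b in zip(labels[:-1], labels[1:]):
        counts[idx[a], idx[b]] += 1
    probs = np.full((2, 2), np.nan)
    for i in range(2):
        total = counts[i].sum()
        if total > 0:
            probs[i] = counts[i] / total
    return TransitionMatrix(counts=counts, probs=probs)


def ecdf(values: Sequence[float]) -> Tuple[np.ndarray, np.ndarray]:
    """Empirical CDF of raw event values: (sorted values, cumulative probability)."""
    values = np.sort(np.asarray(values, dtype=float))
    if values.size == 0:
        return values, values
    return values, np.arange(1, values.size + 1) / values.size
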
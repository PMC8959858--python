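"""Evoked-excitability metrics from current-step sweep families.

Covers the standard 300-ms step protocol (5-pA increments up to 35 pA):
the f-I curve with rheobase (minimal current evoking a spike) and its
linear-regression slope from the point of initial spiking, input
resistance from a small hyperpolarizing step, and monoexponential
spike-frequency-adaptation fits parameterized directly in half-life so
the fitted parameter is the reported quantity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import optimize, stats

from .core import SweepSet, Trace
from .spikes import detect_spikes
from .synthetic import adaptation_frequency

__all__ = [
    "FICurve",
    "InputResistance",
    "AdaptationFit",
    "fi_curve",
    "input_resistance",
    "fit_adaptation",
    "HALF_LIFE_BOUNDS_MS",
    "PLATEAU_BOUNDS_HZ",
]

# fit bounds: half-life in (0.1, 300] ms, plateau in [0, 500] Hz
HALF_LIFE_BOUNDS_MS = (0.1, 300.0)
PLATEAU_BOUNDS_HZ = (0.0, 500.0)
_F0_BOUNDS_HZ = (0.0, 2000.0)


@dataclass
class FICurve:
    """Firing rate vs injected current with threshold and regression slope.

    ``rates`` are spike counts during the step divided by the step
    duration (Hz). ``rheobase`` is the smallest current with ≥ 1 spike;
    slope/intercept come from ordinary least squares over sweeps at and
    above rheobase. Underdetermined quantities are NaN with reasons in
    ``missing``.
    """

    currents: np.ndarray
    rates: np.ndarray
    rheobase: float = float("nan")
    slope: float = float("nan")
    intercept: float = float("nan")
    missing: dict = field(default_factory=dict)


@dataclass
class InputResistance:
    """Steady-state voltage deflection per unit injected current.

    ``r_in`` (MΩ) = 1000 × |delta_v| / |delta_i| with delta_v in mV and
    delta_i in pA.
    """

    r_in: float
    delta_v: float
    delta_i: float


@dataclass
class AdaptationFit:
    """Monoexponential spike-frequency-adaptation fit.

    Model: ``f(t) = plateau + (f0 − plateau) · 2**(−t/half_life)`` with
    t and half_life in ms, frequencies in Hz. ``flags`` records
    degeneracies (unidentifiable half-life on a flat series, parameters
    at bounds, non-convergence).
    """

    half_life: float = float("nan")
    plateau: float = float("nan")
    f0: float = float("nan")
    rss: float = float("nan")
    n_points: int = 0
    flags: dict = field(default_factory=dict)


def fi_curve(sweeps: SweepSet, dvdt_threshold: float = 10.0,
             min_peak_prominence: float = 10.0) -> FICurve:
    """f-I curve from a sweep family: per-sweep step rate, rheobase, OLS slope.

    Spikes are counted within [step_on, step_off); the regression runs
    from the point of initial spiking (current ≥ rheobase), so adding
    silent sub-rheobase sweeps cannot change the slope.
    """
    rates = np.empty(len(sweeps.sweeps))
    for i, sw in enumerate(sweeps.sweeps):
        train = detect_spikes(sw, dvdt_threshold, min_peak_prominence)
        in_step = (train.spike_times >= sweeps.step_on) & \
                  (train.spike_times < sweeps.step_off)
        rates[i] = in_step.sum() / sweeps.step_duration

    out = FICurve(currents=sweeps.currents.copy(), rates=rates)
    spiking = np.nonzero(rates > 0)[0]
    if spiking.size == 0:
        out.missing["rheobase"] = "no sweep evoked spikes"
        out.missing["slope"] = "no spiking sweeps to regress"
        return out
    out.rheobase = float(sweeps.currents[spiking[0]])

    sel = sweeps.currents >= out.rheobase
    if sel.sum() < 2:
        out.missing["slope"] = "need at least 2 sweeps at or above rheobase"
        return out
    res = stats.linregress(sweeps.currents[sel], rates[sel])
    out.slope = float(res.slope)
    out.intercept = float(res.intercept)
    return out


def input_resistance(sweep: Trace, step_on: float, step_off: float,
                     delta_i: float, window_s: float = 0.05) -> InputResistance:
    """Input resistance from a hyperpolarizing current step.

    ``delta_v`` is the mean voltage over the last ``window_s`` of the
    step minus the mean over the ``window_s`` immediately before the
    step. Spikes during the step contaminate the steady state and raise
    an error.
    """
    if delta_i == 0:
        raise ValueError("delta_i must be non-zero")
    train = detect_spikes(sweep)
    if np.any((train.spike_times >= step_on) & (train.spike_times < step_off)):
        raise ValueError("spikes during the step contaminate the input-resistance estimate")
    v = sweep.samples
    i_on, i_off = sweep.index_at(step_on), sweep.index_at(step_off)
    w = int(round(window_s * sweep.sampling_rate))
    baseline = float(np.mean(v[max(i_on - w, 0):i_on]))
    steady = float(np.mean(v[i_off - w:i_off]))
    delta_v = steady - baseline
    return InputResistance(r_in=1000.0 * abs(delta_v) / abs(delta_i),
                           delta_v=delta_v, delta_i=delta_i)


def _freq_series_from_spikes(spike_times: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Instantaneous frequency 1/ISI (Hz) at the ISI midpoint (ms from onset)."""
    spike_times = np.asarray(spike_times, dtype=float)
    isis = np.diff(spike_times)
    t_ms = (spike_times[:-1] + spike_times[1:]) / 2 * 1000.0
    return t_ms, 1.0 / isis


def fit_adaptation(spike_times: Optional[np.ndarray] = None,
                   freq_series: Optional[Tuple[np.ndarray, np.ndarray]] = None
                   ) -> AdaptationFit:
    """Fit the monoexponential adaptation law to a spike train or frequency series.

    Provide either ``spike_times`` (s, measured from step onset; ≥ 4
    spikes) — converted to instantaneous frequencies 1/ISI timestamped
    at the ISI midpoint — or an explicit ``freq_series`` of (time in
    ms, frequency in Hz) pairs with ≥ 3 points. Least squares with
    half-life ∈ (0.1, 300] ms and plateau ∈ [0, 500] Hz, initialized
    from the first/last frequency points.
    """
    if (spike_times is None) == (freq_series is None):
        raise ValueError("provide exactly one of spike_times or freq_series")
    if spike_times is not None:
        spike_times = np.asarray(spike_times, dtype=float)
        if spike_times.size < 4:
            raise ValueError("need at least 4 spikes (3 instantaneous-frequency points)")
        t_ms, f_hz = _freq_series_from_spikes(spike_times)
    else:
        t_ms = np.asarray(freq_series[0], dtype=float)
        f_hz = np.asarray(freq_series[1], dtype=float)
    out = AdaptationFit(n_points=t_ms.size)
    if t_ms.size < 3:
        out.flags["missing"] = "need at least 3 frequency points"
        return out

    if np.ptp(f_hz) < 1e-9 * max(abs(f_hz).max(), 1.0):
        # flat series: plateau identified, half-life is not
        out.plateau = out.f0 = float(np.mean(f_hz))
        out.rss = float(np.sum((f_hz - out.plateau) ** 2))
        out.flags["half_life"] = "unidentifiable: constant frequency series"
        return out

    f_first, f_last = float(f_hz[0]), float(f_hz[-1])
    hl0 = float(np.clip(np.median(t_ms) / 2, *HALF_LIFE_BOUNDS_MS))
    p0 = [hl0,
          float(np.clip(f_last, *PLATEAU_BOUNDS_HZ)),
          float(np.clip(f_first, *_F0_BOUNDS_HZ))]
    lower = [HALF_LIFE_BOUNDS_MS[0], PLATEAU_BOUNDS_HZ[0], _F0_BOUNDS_HZ[0]]
    upper = [HALF_LIFE_BOUNDS_MS[1], PLATEAU_BOUNDS_HZ[1], _F0_BOUNDS_HZ[1]]
    try:
        popt, _ = optimize.curve_fit(
            adaptation_frequency, t_ms, f_hz, p0=p0,
            bounds=(lower, upper), maxfev=20000)
    except RuntimeError as exc:
        out.flags["missing"] = f"fit did not converge: {exc}"
        return out

    out.half_life, out.plateau, out.f0 = map(float, popt)
    resid = f_hz - adaptation_frequency(t_ms, *popt)
    out.rss = float(np.sum(resid ** 2))
    for name, val, (lo, hi) in (
            ("half_life", out.half_life, HALF_LIFE_BOUNDS_MS),
            ("plateau", out.plateau, PLATEAU_BOUNDS_HZ),
            ("f0", out.f0, _F0_BOUNDS_HZ)):
        if np.isclose(val, lo, rtol=1e-6, atol=1e-9) or np.isclose(val, hi, rtol=1e-6):
            out.flags[name] = f"parameter at fit bound ({val:.4g})"
    return out
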
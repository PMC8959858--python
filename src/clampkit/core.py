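"""Core data containers shared across the analysis stages.

All voltages are millivolts, currents picoamperes, resistances megaohms.
Time is seconds inside containers and files; millisecond quantities are
explicit in field names (e.g. ``mean_isi_ms``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "GeneratorConfig",
    "SpikeShape",
    "GroundTruth",
    "Trace",
    "SweepSet",
    "CompartmentImage",
]


@dataclass
class GeneratorConfig:
    """Acquisition-chain parameters for the synthetic generators.

    Defaults mirror a typical perforated-patch rig: 10 kHz sampling with a
    1 kHz low-pass anti-alias filter.

    Parameters
    ----------
    sampling_rate : float
        Samples per second (Hz). Must exceed twice the low-pass cutoff.
    lowpass_cutoff : float or None
        Cutoff (Hz) of the zero-phase 4-pole Butterworth applied after
        noise injection; ``None`` disables filtering.
    duration : float
        Trace length in seconds.
    noise_sd : float
        Standard deviation (mV) of additive Gaussian recording noise.
    seed : int
        Seed for the generator's private RNG stream.
    """

    sampling_rate: float = 10_000.0
    lowpass_cutoff: Optional[float] = 1_000.0
    duration: float = 10.0
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.lowpass_cutoff is not None and self.sampling_rate <= 2 * self.lowpass_cutoff:
            raise ValueError(
                "sampling_rate must exceed twice the lowpass_cutoff "
                f"(got {self.sampling_rate} Hz vs cutoff {self.lowpass_cutoff} Hz)"
            )
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class SpikeShape:
    """Stereotyped action-potential waveform parameters.

    ``ahp_depth`` is the afterhyperpolarization measured downward from
    spike threshold (positive values hyperpolarize); ``onset_ms`` is the
    threshold-to-peak depolarization time.
    """

    threshold_v: float = -45.0
    peak_v: float = -10.0
    ahp_depth: float = 12.0
    onset_ms: float = 1.5
    ahp_recovery_ms: float = 15.0

    def __post_init__(self) -> None:
        if self.peak_v <= self.threshold_v:
            raise ValueError("peak_v must exceed threshold_v")
        if self.onset_ms <= 0:
            raise ValueError("onset_ms must be positive")
        if self.ahp_depth < 0:
            raise ValueError("ahp_depth must be non-negative")
        if self.ahp_recovery_ms <= 0:
            raise ValueError("ahp_recovery_ms must be positive")


@dataclass
class GroundTruth:
    """Generative labels recorded alongside every synthetic output."""

    spike_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    event_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    event_labels: list = field(default_factory=list)
    generative_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        self.event_times = np.asarray(self.event_times, dtype=float)
        for name, t in (("spike_times", self.spike_times), ("event_times", self.event_times)):
            if t.size > 1 and not np.all(np.diff(t) > 0):
                raise ValueError(f"{name} must be strictly increasing")
        if len(self.event_labels) != self.event_times.size:
            raise ValueError("event_labels must match event_times in length")


@dataclass
class Trace:
    """Uniformly sampled membrane-potential time series.

    ``samples`` are voltages in mV at ``sampling_rate`` Hz starting at
    ``t0`` seconds. ``meta`` carries experiment annotations such as
    ``age_group`` (young/aged), ``zt_window`` (ZT6-8/ZT18-20), ``cell_id``
    and ``protocol``.
    """

    samples: np.ndarray
    sampling_rate: float
    t0: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.samples.size == 0:
            raise ValueError("samples must be non-empty")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain missing or non-finite values")

    @property
    def duration(self) -> float:
        """Trace length in seconds (n samples / rate)."""
        return self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.sampling_rate

    def index_at(self, t: float) -> int:
        """Sample index nearest to time ``t`` (seconds)."""
        return int(round((t - self.t0) * self.sampling_rate))


@dataclass
class SweepSet:
    """Family of current-step sweeps sharing step timing.

    One injected-current level (pA) per sweep; the step is on during
    ``[step_on, step_off)`` seconds (300 ms by default protocol).
    """

    sweeps: list
    currents: np.ndarray
    step_on: float
    step_off: float

    def __post_init__(self) -> None:
        self.currents = np.asarray(self.currents, dtype=float)
        if len(self.sweeps) != self.currents.size:
            raise ValueError("one current level per sweep required")
        if self.currents.size > 1 and not np.all(np.diff(self.currents) > 0):
            raise ValueError("currents must be strictly increasing")
        if self.step_off <= self.step_on:
            raise ValueError("step_off must follow step_on")

    @property
    def step_duration(self) -> float:
        return self.step_off - self.step_on


# Label codes of the compartment mask image.
BACKGROUND, CYTOPLASM, MEMBRANE, PERINUCLEAR = 0, 1, 2, 3

COMPARTMENT_LABELS = {
    "background": BACKGROUND,
    "cytoplasm": CYTOPLASM,
    "membrane": MEMBRANE,
    "perinuclear": PERINUCLEAR,
}


@dataclass
class CompartmentImage:
    """Single-plane fluorescence image with a compartment label mask.

    ``pixels`` holds intensities on a 16-bit scale (arbitrary units);
    ``masks`` is a same-shape label image using the codes in
    :data:`COMPARTMENT_LABELS`. The "total" compartment used in
    quantification is the union of cytoplasm, membrane and perinuclear
    labels.
    """

    pixels: np.ndarray
    masks: np.ndarray
    pixel_size: Optional[float] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.masks = np.asarray(self.masks)
        if self.pixels.shape != self.masks.shape:
            raise ValueError("masks must match pixels in shape")

    def compartment_mask(self, name: str) -> np.ndarray:
        if name == "total":
            return self.masks > BACKGROUND
        if name not in COMPARTMENT_LABELS:
            raise KeyError(
                f"unknown compartment {name!r}; valid: total, "
                + ", ".join(COMPARTMENT_LABELS)
            )
        return self.masks == COMPARTMENT_LABELS[name]
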
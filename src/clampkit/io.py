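"""Trace/sweep file IO, results tables and the pipeline driver.

File conventions
----------------
* Trace: two-column delimited text (``time_s``, ``voltage_mV``) with a
  JSON metadata sidecar at ``<file>.json`` carrying ``sampling_rate``,
  ``t0`` and free-form ``meta``. The sampling rate is never guessed
  from the time column; a missing sidecar or missing rate is a hard
  error. Voltages are serialized with full float precision so a
  write→read round trip is exact.
* SweepSet: a directory of numbered trace files plus a
  ``sweepset.json`` manifest (currents, step timing).
* Results: long-format CSV, one row per cell × metric with value and
  units; every emitted metric carries a units entry.

All writes are atomic (temp file in the destination directory, then
rename), so re-running with the same config and seed reproduces
byte-identical outputs and a crash never leaves a partial file.
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import evoked as _evoked
from . import imaging as _imaging
from . import psp as _psp
from . import spikes as _spikes
from . import synthetic as _synth
from .core import GeneratorConfig, SpikeShape, SweepSet, Trace

__all__ = [
    "read_trace",
    "write_trace",
    "read_sweepset",
    "write_sweepset",
    "ResultsTable",
    "atomic_write_text",
    "write_csv",
    "run_pipeline",
    "PROTOCOLS",
]

logger = logging.getLogger(__name__)

PROTOCOLS = ("spontaneous", "evoked", "psp", "imaging")

# canonical units of every metric the pipeline emits
METRIC_UNITS = {
    "rmp": "mV", "mean_rate": "Hz", "ahp_amplitude": "mV",
    "onset_duration": "ms", "mean_isi": "ms", "cv": "1", "lv": "1",
    "skewness": "1", "kurtosis": "1", "n_isis": "count",
    "rheobase": "pA", "fi_slope": "Hz/pA", "fi_intercept": "Hz",
    "input_resistance": "MOhm", "adapt_half_life": "ms",
    "adapt_plateau": "Hz", "adapt_f0": "Hz",
    "psp_frequency": "Hz", "psp_amplitude_mean": "mV",
    "psp_rising_slope_mean": "mV/ms", "noise_rms": "mV",
    "p_mpsp_to_mpsp": "1", "p_mpsp_to_psp": "1",
    "p_psp_to_mpsp": "1", "p_psp_to_psp": "1",
    "total_mean_corrected": "au", "membrane_mean_corrected": "au",
    "perinuclear_mean_corrected": "au",
    "total_variability": "1", "membrane_variability": "1",
    "perinuclear_variability": "1",
}


def atomic_write_text(text: str, path) -> None:
    """Write text via a temp file + rename in the destination directory."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_csv(df: pd.DataFrame, path) -> None:
    """Atomic CSV write with deterministic float formatting."""
    atomic_write_text(df.to_csv(index=False), path)


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def write_trace(trace: Trace, path) -> None:
    """Write a trace as two-column text plus its JSON metadata sidecar."""
    path = Path(path)
    times = trace.times
    lines = ["time_s\tvoltage_mV"]
    lines += [f"{t:.17g}\t{v:.17g}" for t, v in zip(times, trace.samples)]
    atomic_write_text("\n".join(lines) + "\n", path)
    sidecar = {"sampling_rate": trace.sampling_rate, "t0": trace.t0,
               "meta": trace.meta}
    atomic_write_text(json.dumps(sidecar, indent=1, sort_keys=True) + "\n",
                      _sidecar_path(path))


def read_trace(path) -> Trace:
    """Read a two-column trace file and its metadata sidecar.

    Errors if the sidecar is absent or lacks ``sampling_rate`` (a rate
    is never inferred), or if the time column is non-uniform relative
    to the declared rate.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trace file not found: {path}")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"metadata sidecar not found: {sidecar}")
    meta = json.loads(sidecar.read_text())
    if "sampling_rate" not in meta:
        raise ValueError(f"sidecar {sidecar} lacks required sampling_rate")
    rate = float(meta["sampling_rate"])

    data = np.loadtxt(path, delimiter="\t", skiprows=1)
    data = np.atleast_2d(data)
    times, volts = data[:, 0], data[:, 1]
    if times.size > 1:
        dt = np.diff(times)
        if not np.allclose(dt, 1.0 / rate, rtol=1e-6, atol=1e-9):
            raise ValueError(f"non-uniform time column in {path} "
                             f"(expected 1/{rate} s steps)")
    return Trace(samples=volts, sampling_rate=rate,
                 t0=float(meta.get("t0", times[0] if times.size else 0.0)),
                 meta=meta.get("meta", {}))


def write_sweepset(sweeps: SweepSet, directory) -> None:
    """Write each sweep as a trace file plus a sweepset.json manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = []
    for i, sw in enumerate(sweeps.sweeps):
        name = f"sweep_{i:03d}.tsv"
        write_trace(sw, directory / name)
        names.append(name)
    manifest = {"sweeps": names, "currents_pA": list(map(float, sweeps.currents)),
                "step_on_s": sweeps.step_on, "step_off_s": sweeps.step_off}
    atomic_write_text(json.dumps(manifest, indent=1) + "\n",
                      directory / "sweepset.json")


def read_sweepset(directory) -> SweepSet:
    directory = Path(directory)
    manifest_path = directory / "sweepset.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"sweepset manifest not found: {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    sweeps = [read_trace(directory / name) for name in manifest["sweeps"]]
    return SweepSet(sweeps, np.asarray(manifest["currents_pA"], dtype=float),
                    manifest["step_on_s"], manifest["step_off_s"])


class ResultsTable:
    """Long-format per-cell metrics: cell_id × metric → value with units.

    Group metadata (age_group, zt_window) travels with each row so the
    report stage can aggregate by condition.
    """

    COLUMNS = ["cell_id", "age_group", "zt_window", "metric", "value", "units"]

    def __init__(self) -> None:
        self._rows: list = []

    def add(self, cell_id: str, metric: str, value, units: Optional[str] = None,
            age_group: str = "", zt_window: str = "") -> None:
        if units is None:
            if metric not in METRIC_UNITS:
                raise KeyError(f"no units registered for metric {metric!r}; "
                               "pass units explicitly")
            units = METRIC_UNITS[metric]
        self._rows.append({"cell_id": cell_id, "age_group": age_group,
                           "zt_window": zt_window, "metric": metric,
                           "value": value, "units": units})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self._rows, columns=self.COLUMNS)

    def metrics(self) -> set:
        return {r["metric"] for r in self._rows}


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------

def _derive_cfg(config: dict, seed: int, cell_index: int) -> GeneratorConfig:
    gen = dict(config.get("generator", {}))
    gen.setdefault("duration", config.get("duration", 10.0))
    gen.setdefault("noise_sd", config.get("noise_sd", 0.3))
    gen["seed"] = int(np.random.default_rng([seed, cell_index]).integers(2**31))
    return GeneratorConfig(**gen)


def _spontaneous_cell(cfg: GeneratorConfig, params: dict, table: ResultsTable,
                      cell_id: str, meta: dict) -> None:
    shape = SpikeShape(**params.get("shape", {}))
    trace, _ = _synth.gen_spontaneous_trace(
        params.get("rate", 10.0), params.get("cv_target", 0.5), shape,
        params.get("rmp", -55.0), cfg)
    train = _spikes.detect_spikes(trace)
    stats = _spikes.isi_statistics(train.spike_times)
    wf = _spikes.waveform_statistics(trace, train)
    for metric, value in [
            ("cv", stats.cv), ("lv", stats.lv), ("skewness", stats.skewness),
            ("kurtosis", stats.kurtosis), ("mean_isi", stats.mean_isi_ms),
            ("mean_rate", stats.mean_rate), ("rmp", wf.rmp),
            ("ahp_amplitude", wf.ahp_amplitude),
            ("onset_duration", wf.onset_duration_ms)]:
        table.add(cell_id, metric, value, **meta)


def _evoked_cell(cfg: GeneratorConfig, params: dict, table: ResultsTable,
                 cell_id: str, meta: dict) -> None:
    sweeps, _ = _synth.gen_evoked_sweepset(
        params.get("rheobase", 20.0), params.get("fi_slope", 2.0),
        params.get("adapt_half_life", 5.0), params.get("adapt_plateau", 39.0),
        cfg)
    fi = _evoked.fi_curve(sweeps)
    table.add(cell_id, "rheobase", fi.rheobase, **meta)
    table.add(cell_id, "fi_slope", fi.slope, **meta)
    table.add(cell_id, "fi_intercept", fi.intercept, **meta)

    top = sweeps.sweeps[-1]
    train = _spikes.detect_spikes(top)
    in_step = train.spike_times[(train.spike_times >= sweeps.step_on)
                                & (train.spike_times < sweeps.step_off)]
    if in_step.size >= 4:
        fit = _evoked.fit_adaptation(spike_times=in_step - sweeps.step_on)
        table.add(cell_id, "adapt_half_life", fit.half_life, **meta)
        table.add(cell_id, "adapt_plateau", fit.plateau, **meta)
        table.add(cell_id, "adapt_f0", fit.f0, **meta)
    else:
        for m in ("adapt_half_life", "adapt_plateau", "adapt_f0"):
            table.add(cell_id, m, float("nan"), **meta)

    rc_cfg = GeneratorConfig(sampling_rate=cfg.sampling_rate,
                             lowpass_cutoff=cfg.lowpass_cutoff,
                             duration=cfg.duration, noise_sd=cfg.noise_sd,
                             seed=cfg.seed + 1)
    rc, rc_truth = _synth.gen_rc_sweep(params.get("r_in", 150.0),
                                       params.get("tau_ms", 20.0), -10.0, rc_cfg)
    gp = rc_truth.generative_params
    rin = _evoked.input_resistance(rc, gp["step_on"], gp["step_off"],
                                   gp["delta_i"])
    table.add(cell_id, "input_resistance", rin.r_in, **meta)


def _psp_cell(cfg: GeneratorConfig, params: dict, table: ResultsTable,
              cell_id: str, meta: dict) -> None:
    trace, _ = _synth.gen_psp_trace(
        params.get("baseline", -107.0), params.get("mpsp_amp_mean", 1.5),
        params.get("psp_amp_mean", 5.0), params.get("amp_cv", 0.25),
        params.get("rise_ms", 2.0), params.get("decay_ms", 20.0),
        params.get("event_rate", 2.0),
        params.get("transition", [[0.7, 0.3], [0.3, 0.7]]), cfg)
    filtered, rms = _psp.preprocess(trace)
    events = _psp.detect_events(filtered, rms,
                                k_threshold=params.get("k_threshold", 3.0))
    table.add(cell_id, "noise_rms", rms, **meta)
    table.add(cell_id, "psp_frequency", events.frequency, **meta)
    table.add(cell_id, "psp_amplitude_mean",
              float(np.mean(events.amplitudes)) if events.n else float("nan"),
              **meta)
    table.add(cell_id, "psp_rising_slope_mean",
              float(np.nanmean(events.rising_slopes)) if events.n else float("nan"),
              **meta)
    if events.n >= 4:
        cls = _psp.classify_events(events.amplitudes)
        tm = _psp.transition_probabilities(cls.labels)
        table.add(cell_id, "p_mpsp_to_mpsp", tm.probs[0, 0], **meta)
        table.add(cell_id, "p_mpsp_to_psp", tm.probs[0, 1], **meta)
        table.add(cell_id, "p_psp_to_mpsp", tm.probs[1, 0], **meta)
        table.add(cell_id, "p_psp_to_psp", tm.probs[1, 1], **meta)


def _imaging_cell(cfg: GeneratorConfig, params: dict, table: ResultsTable,
                  cell_id: str, meta: dict) -> None:
    image, _ = _synth.gen_compartment_image(
        params.get("mean_total", 80.0), params.get("mean_membrane", 120.0),
        params.get("mean_perinuclear", 60.0),
        params.get("heterogeneity_cv", 0.2), params.get("background", 10.0),
        params.get("size_px", 256), cfg)
    for sig in _imaging.measure_compartments(image):
        table.add(cell_id, f"{sig.compartment}_mean_corrected",
                  sig.mean_corrected, **meta)
        table.add(cell_id, f"{sig.compartment}_variability", sig.variability,
                  **meta)


_CELL_RUNNERS = {"spontaneous": _spontaneous_cell, "evoked": _evoked_cell,
                 "psp": _psp_cell, "imaging": _imaging_cell}


def run_pipeline(config: dict) -> pd.DataFrame:
    """Run one protocol over synthetic cells or input trace files.

    ``config`` names a ``protocol`` (spontaneous | evoked | psp |
    imaging) plus either generator parameters with ``n_cells`` or an
    ``input_dir`` of trace files; ``seed`` drives all randomness and
    ``out_dir`` (optional) receives the metrics CSV and a JSON run log.
    Returns the long-format metrics table.
    """
    protocol = config.get("protocol")
    if protocol not in PROTOCOLS:
        raise ValueError(f"unknown protocol {protocol!r}; valid protocols: "
                         + ", ".join(PROTOCOLS))
    seed = int(config.get("seed", 0))
    meta = {"age_group": config.get("age_group", ""),
            "zt_window": config.get("zt_window", "")}
    params = dict(config.get("params", {}))
    table = ResultsTable()

    input_dir = config.get("input_dir")
    if input_dir is not None:
        input_dir = Path(input_dir)
        files = sorted(input_dir.glob("*.tsv")) + sorted(input_dir.glob("*.csv"))
        if not files:
            raise ValueError(f"no trace files found in {input_dir}")
        if protocol == "spontaneous":
            for f in files:
                trace = read_trace(f)
                cell_id = trace.meta.get("cell_id", f.stem)
                train = _spikes.detect_spikes(trace)
                stats = _spikes.isi_statistics(train.spike_times)
                wf = _spikes.waveform_statistics(trace, train)
                for metric, value in [
                        ("cv", stats.cv), ("lv", stats.lv),
                        ("skewness", stats.skewness), ("kurtosis", stats.kurtosis),
                        ("mean_isi", stats.mean_isi_ms), ("mean_rate", stats.mean_rate),
                        ("rmp", wf.rmp), ("ahp_amplitude", wf.ahp_amplitude),
                        ("onset_duration", wf.onset_duration_ms)]:
                    table.add(cell_id, metric, value,
                              age_group=trace.meta.get("age_group", ""),
                              zt_window=trace.meta.get("zt_window", ""))
        elif protocol == "psp":
            for f in files:
                trace = read_trace(f)
                cell_id = trace.meta.get("cell_id", f.stem)
                filtered, rms = _psp.preprocess(trace)
                events = _psp.detect_events(filtered, rms)
                table.add(cell_id, "noise_rms", rms,
                          age_group=trace.meta.get("age_group", ""),
                          zt_window=trace.meta.get("zt_window", ""))
                table.add(cell_id, "psp_frequency", events.frequency,
                          age_group=trace.meta.get("age_group", ""),
                          zt_window=trace.meta.get("zt_window", ""))
        else:
            raise ValueError(
                f"file input for protocol {protocol!r} is not supported; "
                "provide generator params instead")
    else:
        n_cells = int(config.get("n_cells", 3))
        runner = _CELL_RUNNERS[protocol]
        for i in range(n_cells):
            cfg = _derive_cfg(config, seed, i)
            runner(cfg, params, table, f"cell{i:03d}", meta)

    df = table.to_frame()
    out_dir = config.get("out_dir")
    if out_dir is not None:
        out_dir = Path(out_dir)
        write_csv(df, out_dir / f"{protocol}_metrics.csv")
        log = {"protocol": protocol, "seed": seed, "params": params,
               "n_rows": int(len(df))}
        atomic_write_text(json.dumps(log, indent=1, sort_keys=True,
                                     default=str) + "\n",
                          out_dir / "run_log.json")
        logger.info("wrote %d metric rows to %s", len(df), out_dir)
    return df
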
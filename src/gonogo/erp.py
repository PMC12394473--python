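"""Condition ERPs, NoGo-Go difference waves, and component measurement.

The difference wave (NOGO minus GO) indexes reactive cognitive
control; its P3d peak (default window [300, 500) ms) and SPWd window
mean (default [500, 800) ms) at the midline electrodes are the
component measures carried into the clinical and correlational
analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import EpochSet

#: Default component measurement windows (ms), config-exposed.
DEFAULT_WINDOWS = {"P3d": (300.0, 500.0), "SPWd": (500.0, 800.0)}


@dataclass
class ERPWaveform:
    data: np.ndarray          # channels x time, uV
    time_ms: np.ndarray
    channel_names: list[str]
    condition: str            # GO, NOGO or DIFF
    n_trials: dict            # per parent condition
    label: str = ""           # subject id or group label

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.data[self.channel_names.index(name)]
        except ValueError:
            raise KeyError(f"channel {name!r} not in {self.channel_names}") from None


@dataclass
class ComponentMeasure:
    name: str
    channel: str
    window_ms: tuple[float, float]
    amplitude_uv: float       # peak amplitude in window
    latency_ms: float         # peak latency (earliest on ties)
    mean_amplitude_uv: float  # window mean


def average_condition(epochs: EpochSet, condition: str, label: str = "") -> ERPWaveform:
    """Pointwise mean over the *valid* epochs of one condition."""
    mask = epochs.valid & (epochs.condition == condition)
    n = int(mask.sum())
    if n == 0:
        raise ValueError(
            f"no valid {condition} epochs{f' for {label}' if label else ''}")
    return ERPWaveform(data=epochs.data[mask].mean(axis=0),
                       time_ms=epochs.time_ms,
                       channel_names=list(epochs.channel_names),
                       condition=condition, n_trials={condition: n}, label=label)


def difference_wave(nogo: ERPWaveform, go: ERPWaveform) -> ERPWaveform:
    """NOGO minus GO, pointwise, on identical channel/time axes."""
    if nogo.channel_names != go.channel_names:
        raise ValueError("channel axes differ between NOGO and GO waveforms")
    if nogo.time_ms.shape != go.time_ms.shape or not np.allclose(nogo.time_ms, go.time_ms):
        raise ValueError("time axes differ between NOGO and GO waveforms")
    return ERPWaveform(data=nogo.data - go.data, time_ms=nogo.time_ms,
                       channel_names=list(nogo.channel_names), condition="DIFF",
                       n_trials={**go.n_trials, **nogo.n_trials},
                       label=nogo.label or go.label)


def grand_average(waves: list[ERPWaveform], label: str = "",
                  weight_by_trials: bool = False) -> ERPWaveform:
    """Average over subjects (equal weights by default)."""
    if not waves:
        raise ValueError("no waveforms to average")
    ref = waves[0]
    stack = np.stack([w.data for w in waves])
    if weight_by_trials:
        weights = np.array([sum(w.n_trials.values()) for w in waves], dtype=float)
        data = np.tensordot(weights / weights.sum(), stack, axes=1)
    else:
        data = stack.mean(axis=0)
    return ERPWaveform(data=data, time_ms=ref.time_ms,
                       channel_names=list(ref.channel_names),
                       condition=ref.condition,
                       n_trials={"subjects": len(waves)}, label=label)


def measure_component(wave: ERPWaveform, name: str, channel: str,
                      window_ms: tuple[float, float] | None = None) -> ComponentMeasure:
    """Peak (max, earliest tie) and window-mean amplitude at one channel.

    Components here are positive-going, so the peak is the in-window
    maximum.  The window is half-open [start, end).
    """
    if window_ms is None:
        window_ms = DEFAULT_WINDOWS[name]
    start, end = window_ms
    x = wave.channel(channel)
    mask = (wave.time_ms >= start) & (wave.time_ms < end)
    if not mask.any():
        raise ValueError(f"window {window_ms} falls outside the epoch "
                         f"({wave.time_ms[0]}..{wave.time_ms[-1]} ms)")
    xw = x[mask]
    tw = wave.time_ms[mask]
    i = int(np.argmax(xw))  # argmax returns the earliest index on ties
    return ComponentMeasure(name=name, channel=channel, window_ms=(start, end),
                            amplitude_uv=float(xw[i]), latency_ms=float(tw[i]),
                            mean_amplitude_uv=float(xw.mean()))


def erp_long_table(waves: list[ERPWaveform]) -> pd.DataFrame:
    """Long-format export (subject/label, condition, channel, time, amplitude)."""
    rows = []
    for w in waves:
        for ci, ch in enumerate(w.channel_names):
            rows.append(pd.DataFrame({
                "label": w.label, "condition": w.condition, "channel": ch,
                "time_ms": w.time_ms, "amplitude_uv": w.data[ci]}))
    return pd.concat(rows, ignore_index=True)


def component_table(measures: list[ComponentMeasure], labels: list[str]) -> pd.DataFrame:
    return pd.DataFrame([{
        "label": lab, "component": m.name, "channel": m.channel,
        "window_start_ms": m.window_ms[0], "window_end_ms": m.window_ms[1],
        "amplitude_uv": m.amplitude_uv, "latency_ms": m.latency_ms,
        "mean_amplitude_uv": m.mean_amplitude_uv,
    } for m, lab in zip(measures, labels)])
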
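"""Spike detection and electrophysiological feature extraction.

A spike is a strict upward crossing of the detection threshold (default
-20 mV): ``v[i] < thr <= v[i+1]``, with the onset time linearly
interpolated and the peak taken as the maximum voltage before the next
downward crossing.

The catalogue holds 20 features spanning firing rate, spike shape,
inter-spike-interval statistics and subthreshold voltage summaries.  Unless
noted otherwise a feature is computed from the spikes and samples inside
the stimulus window [delay, delay + duration); ``voltage_base`` (mean
pre-stimulus voltage) and ``max_voltage`` use the whole trace.  A feature
whose prerequisites are unmet (e.g. after-hyperpolarisation depth with
fewer than two spikes) evaluates to the distinguished ``undefined`` value,
represented as ``None``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .model import Trace
from .stimuli import Stimulus

__all__ = [
    "FeatureSet",
    "FeatureValue",
    "SpikeEvent",
    "DEFAULT_THRESHOLD_MV",
    "FEATURE_NAMES",
    "FEATURE_UNITS",
    "default_feature_set",
    "detect_spikes",
    "compute_feature",
    "feature_vector",
]

DEFAULT_THRESHOLD_MV = -20.0

#: catalogue feature -> unit (drives the std floors of the scoring policy)
FEATURE_UNITS = {
    "spike_count": "count",
    "time_to_first_spike": "ms",
    "time_to_last_spike": "ms",
    "mean_frequency": "Hz",
    "inv_first_ISI": "Hz",
    "ISI_mean": "ms",
    "ISI_CV": "dimensionless",
    "adaptation_index": "dimensionless",
    "AP_amplitude_mean": "mV",
    "AP_peak_mean": "mV",
    "AP_halfwidth_mean": "ms",
    "AP_max_rise_rate_mean": "mV/ms",
    "AHP_depth_mean": "mV",
    "AHP_time_from_peak_mean": "ms",
    "voltage_base": "mV",
    "steady_state_voltage_stimend": "mV",
    "mean_voltage_during_stim": "mV",
    "min_voltage_during_stim": "mV",
    "max_voltage": "mV",
    "voltage_deflection": "mV",
}
FEATURE_NAMES = tuple(FEATURE_UNITS)


@dataclass(frozen=True)
class FeatureSet:
    """Ordered list of catalogue feature names (repeats allowed)."""

    names: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "names", tuple(self.names))
        unknown = set(self.names) - set(FEATURE_NAMES)
        if unknown:
            raise ConfigurationError(
                f"unknown features {sorted(unknown)}; "
                f"valid: {list(FEATURE_NAMES)}"
            )

    @property
    def size(self) -> int:
        return len(self.names)

    def __len__(self):
        return len(self.names)

    def __iter__(self):
        return iter(self.names)


def default_feature_set() -> FeatureSet:
    return FeatureSet(FEATURE_NAMES)


@dataclass(frozen=True)
class FeatureValue:
    name: str
    value: float | None     # None marks `undefined`

    @property
    def is_defined(self) -> bool:
        return self.value is not None


@dataclass(frozen=True)
class SpikeEvent:
    onset_ms: float
    peak_ms: float
    peak_mv: float


def detect_spikes(trace: Trace,
                  threshold: float = DEFAULT_THRESHOLD_MV) -> list[SpikeEvent]:
    """Strict upward threshold crossings with interpolated onsets.

    One event per crossing ``v[i] < threshold <= v[i+1]``; the peak is the
    maximum sample up to (and including) the next downward crossing.  A
    trace that touches the threshold from below without ever exceeding it
    yields no event (an action potential must rise above the threshold).
    """
    v = trace.v
    t = trace.t
    above = v >= threshold
    up = np.flatnonzero(~above[:-1] & above[1:])
    down = np.flatnonzero(above[:-1] & ~above[1:])
    events = []
    for i in up:
        onset = t[i] + (threshold - v[i]) / (v[i + 1] - v[i]) * (t[i + 1] - t[i])
        pos = int(np.searchsorted(down, i))
        j = int(down[pos]) if pos < len(down) else len(v) - 1
        k = i + 1 + int(np.argmax(v[i + 1:j + 1]))
        if v[k] <= threshold:
            continue
        events.append(SpikeEvent(float(onset), float(t[k]), float(v[k])))
    return events


def _window(trace: Trace, stimulus: Stimulus) -> slice:
    i0 = int(np.searchsorted(trace.t, stimulus.delay - 1e-9))
    i1 = int(np.searchsorted(trace.t, stimulus.delay + stimulus.duration - 1e-9))
    return slice(i0, i1)


def _spikes_in_window(spikes, stimulus):
    lo = stimulus.delay
    hi = stimulus.delay + stimulus.duration
    return [s for s in spikes if lo <= s.onset_ms < hi]


def _halfwidth(trace, spike, threshold):
    """Width (ms) at half height between onset threshold and peak."""
    half = 0.5 * (threshold + spike.peak_mv)
    t, v = trace.t, trace.v
    ip = int(np.searchsorted(t, spike.peak_ms))
    # rising crossing of the half level before the peak
    i = ip
    while i > 0 and v[i - 1] >= half:
        i -= 1
    if i == 0:
        return None
    t_rise = t[i - 1] + (half - v[i - 1]) / (v[i] - v[i - 1]) * (t[i] - t[i - 1])
    # falling crossing after the peak
    j = ip
    while j + 1 < len(v) and v[j + 1] >= half:
        j += 1
    if j + 1 >= len(v):
        return None
    t_fall = t[j] + (half - v[j]) / (v[j + 1] - v[j]) * (t[j + 1] - t[j])
    return t_fall - t_rise


class _FeatureContext:
    """Shared per-trace state (spike events, window, baseline) so a whole
    feature vector costs one spike detection."""

    def __init__(self, trace, stimulus, threshold):
        self.trace = trace
        self.stimulus = stimulus
        self.threshold = threshold
        self.spikes = _spikes_in_window(detect_spikes(trace, threshold),
                                        stimulus)
        self.win = _window(trace, stimulus)
        self.isis = (np.diff([s.onset_ms for s in self.spikes])
                     if len(self.spikes) >= 2 else None)

    def base(self):
        i = int(np.searchsorted(self.trace.t, self.stimulus.delay - 1e-9))
        if i == 0:
            return None
        return float(np.mean(self.trace.v[:i]))

    def stimend(self):
        lo = self.stimulus.delay + self.stimulus.duration - 100.0
        i0 = int(np.searchsorted(self.trace.t, max(lo, 0.0) - 1e-9))
        i1 = self.win.stop
        if i1 <= i0:
            return None
        return float(np.mean(self.trace.v[i0:i1]))


def compute_feature(trace: Trace, stimulus: Stimulus, name: str,
                    threshold: float = DEFAULT_THRESHOLD_MV) -> FeatureValue:
    """One catalogue feature on one trace; ``undefined`` when prerequisites
    (usually a minimum spike count) are unmet."""
    return _compute(_FeatureContext(trace, stimulus, threshold), name)


def _compute(ctx: _FeatureContext, name: str) -> FeatureValue:
    if name not in FEATURE_UNITS:
        raise ConfigurationError(
            f"unknown feature {name!r}; valid: {list(FEATURE_NAMES)}"
        )
    trace, stimulus, threshold = ctx.trace, ctx.stimulus, ctx.threshold
    spikes, win, isis = ctx.spikes, ctx.win, ctx.isis
    base, stimend = ctx.base, ctx.stimend
    t, v = trace.t, trace.v

    val: float | None
    if name == "spike_count":
        val = float(len(spikes))
    elif name == "time_to_first_spike":
        val = spikes[0].onset_ms - stimulus.delay if spikes else None
    elif name == "time_to_last_spike":
        val = spikes[-1].onset_ms - stimulus.delay if spikes else None
    elif name == "mean_frequency":
        val = 1e3 * len(spikes) / stimulus.duration
    elif name == "inv_first_ISI":
        val = 1e3 / isis[0] if isis is not None else None
    elif name == "ISI_mean":
        val = float(np.mean(isis)) if isis is not None else None
    elif name == "ISI_CV":
        if isis is None or len(isis) < 2:
            val = None
        else:
            val = float(np.std(isis, ddof=1) / np.mean(isis))
    elif name == "adaptation_index":
        if isis is None or len(isis) < 2:
            val = None
        else:
            val = float(np.mean(np.diff(isis) / (isis[1:] + isis[:-1])))
    elif name == "AP_amplitude_mean":
        val = (float(np.mean([s.peak_mv - threshold for s in spikes]))
               if spikes else None)
    elif name == "AP_peak_mean":
        val = float(np.mean([s.peak_mv for s in spikes])) if spikes else None
    elif name == "AP_halfwidth_mean":
        if spikes:
            widths = [_halfwidth(trace, s, threshold) for s in spikes]
            widths = [w for w in widths if w is not None]
            val = float(np.mean(widths)) if widths else None
        else:
            val = None
    elif name == "AP_max_rise_rate_mean":
        if spikes:
            rates = []
            dv = np.diff(v) / np.diff(t)
            for s in spikes:
                i0 = int(np.searchsorted(t, s.onset_ms)) - 1
                i1 = int(np.searchsorted(t, s.peak_ms))
                i0 = max(i0, 0)
                if i1 > i0:
                    rates.append(np.max(dv[i0:i1]))
            val = float(np.mean(rates)) if rates else None
        else:
            val = None
    elif name in ("AHP_depth_mean", "AHP_time_from_peak_mean"):
        if len(spikes) < 2:
            val = None
        else:
            depths, delays = [], []
            for a, b in zip(spikes[:-1], spikes[1:]):
                i0 = int(np.searchsorted(t, a.peak_ms))
                i1 = int(np.searchsorted(t, b.peak_ms))
                seg = v[i0:i1]
                k = int(np.argmin(seg))
                depths.append(seg[k])
                delays.append(t[i0 + k] - a.peak_ms)
            if name == "AHP_depth_mean":
                vb = base()
                val = (float(np.mean(depths)) - vb
                       if vb is not None else None)
            else:
                val = float(np.mean(delays))
    elif name == "voltage_base":
        val = base()
    elif name == "steady_state_voltage_stimend":
        val = stimend()
    elif name == "mean_voltage_during_stim":
        val = float(np.mean(v[win])) if win.stop > win.start else None
    elif name == "min_voltage_during_stim":
        val = float(np.min(v[win])) if win.stop > win.start else None
    elif name == "max_voltage":
        val = float(np.max(v))
    else:  # voltage_deflection
        vb, ss = base(), stimend()
        val = ss - vb if (vb is not None and ss is not None) else None

    if val is not None:
        val = float(val)
        if not np.isfinite(val):
            val = None
    return FeatureValue(name, val)


def feature_vector(trace: Trace, stimulus: Stimulus, feature_set: FeatureSet,
                   threshold: float = DEFAULT_THRESHOLD_MV,
                   ) -> list[FeatureValue]:
    """All features of ``feature_set`` on one trace, order preserving."""
    ctx = _FeatureContext(trace, stimulus, threshold)
    return [_compute(ctx, name) for name in feature_set]
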
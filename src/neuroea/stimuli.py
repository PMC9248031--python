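"""Current-clamp stimulus generators.

Four stimulus classes drive the fitting procedure: long square steps, brief
(3 ms) square pulses, linear ramps, and noisy steps (a pedestal plus seeded,
low-pass-filtered Gaussian noise).  The default suite holds 18 stimuli —
8 long squares on a linear amplitude grid, 6 noisy steps (3 pedestals x 2
noise seeds), 2 short squares and 2 ramps.

Waveforms are realised on the simulation grid on demand via
:meth:`Stimulus.samples`; sample k covers t = k*dt.  The support convention
is onset-inclusive and offset-exclusive: samples are nonzero exactly on
[delay, delay + duration).  A ramp rises from 0 at onset to its final
amplitude on the last sample inside the window, which makes its trapezoidal
charge exactly half that of a square of equal peak and duration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "Stimulus",
    "StimulusSuite",
    "make_long_square",
    "make_short_square",
    "make_ramp",
    "make_noisy",
    "default_suite",
    "SHORT_SQUARE_MS",
    "NOISE_FILTER_TAU_MS",
]

SHORT_SQUARE_MS = 3.0
NOISE_FILTER_TAU_MS = 1.0
NOISE_MASTER_DT_MS = 0.05   # master grid on which noise is realised

KINDS = ("long_square", "short_square", "ramp", "noisy")


def _grid_index(t: float, dt: float) -> int:
    """First grid index at or after time t (tolerant of float division)."""
    return int(math.ceil(t / dt - 1e-9))


@dataclass(frozen=True)
class Stimulus:
    id: str
    kind: str
    amplitude: float          # nA; pedestal for noisy, final value for ramp
    delay: float              # ms
    duration: float           # ms
    t_stop: float             # ms
    seed: int | None = None   # noisy only
    noise_cv: float = 0.0     # noisy only; std = noise_cv * |pedestal|

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ConfigurationError(f"unknown stimulus kind {self.kind!r}")
        if self.delay < 0:
            raise ConfigurationError("delay must be >= 0")
        if self.duration <= 0:
            raise ConfigurationError("duration must be positive")
        if self.delay + self.duration > self.t_stop + 1e-9:
            raise ConfigurationError(
                f"stimulus {self.id!r}: delay + duration "
                f"({self.delay + self.duration} ms) exceeds t_stop "
                f"({self.t_stop} ms)"
            )
        if self.noise_cv < 0:
            raise ConfigurationError("noise_cv must be >= 0")
        if self.kind == "noisy" and self.seed is None:
            raise ConfigurationError("noisy stimulus requires a seed")

    def samples(self, dt: float) -> np.ndarray:
        """Injected current (nA) on the grid t = 0, dt, ..., ~t_stop."""
        if dt <= 0:
            raise ConfigurationError("dt must be positive")
        n = int(round(self.t_stop / dt)) + 1
        out = np.zeros(n)
        k_on = _grid_index(self.delay, dt)
        k_off = min(_grid_index(self.delay + self.duration, dt), n)
        if k_off <= k_on:
            return out
        width = k_off - k_on
        if self.kind in ("long_square", "short_square"):
            out[k_on:k_off] = self.amplitude
        elif self.kind == "ramp":
            if width == 1:
                out[k_on] = self.amplitude
            else:
                out[k_on:k_off] = self.amplitude * (
                    np.arange(width) / (width - 1)
                )
        else:  # noisy
            # noise is realised on a fixed master grid and interpolated to
            # the simulation grid, so the waveform is independent of dt
            master_dt = NOISE_MASTER_DT_MS
            n_master = int(round(self.duration / master_dt)) + 1
            rng = np.random.default_rng(self.seed)
            noise = rng.normal(
                0.0, self.noise_cv * abs(self.amplitude), size=n_master
            )
            a = math.exp(-master_dt / NOISE_FILTER_TAU_MS)
            filt = np.empty(n_master)
            y = 0.0
            for i in range(n_master):
                y = a * y + (1.0 - a) * noise[i]
                filt[i] = y
            t_rel = np.arange(k_on, k_off) * dt - self.delay
            t_master = np.arange(n_master) * master_dt
            out[k_on:k_off] = self.amplitude + np.interp(t_rel, t_master,
                                                         filt)
        return out

    def shifted(self, delta: float, new_id: str | None = None) -> "Stimulus":
        """Same waveform with the onset delayed by ``delta`` ms."""
        return Stimulus(
            new_id or self.id, self.kind, self.amplitude,
            self.delay + delta, self.duration, self.t_stop + delta,
            self.seed, self.noise_cv,
        )


def make_long_square(amplitude: float, delay: float = 200.0,
                     duration: float = 1000.0, t_stop: float = 1400.0,
                     stimulus_id: str = "long_square") -> Stimulus:
    return Stimulus(stimulus_id, "long_square", amplitude, delay, duration,
                    t_stop)


def make_short_square(amplitude: float, delay: float = 200.0,
                      t_stop: float = 1400.0,
                      stimulus_id: str = "short_square") -> Stimulus:
    """A brief 3 ms pulse."""
    return Stimulus(stimulus_id, "short_square", amplitude, delay,
                    SHORT_SQUARE_MS, t_stop)


def make_ramp(amplitude_final: float, delay: float = 200.0,
              duration: float = 1000.0, t_stop: float = 1400.0,
              stimulus_id: str = "ramp") -> Stimulus:
    return Stimulus(stimulus_id, "ramp", amplitude_final, delay, duration,
                    t_stop)


def make_noisy(pedestal: float, noise_cv: float = 0.2, delay: float = 200.0,
               duration: float = 1000.0, t_stop: float = 1400.0,
               seed: int = 0, stimulus_id: str = "noisy") -> Stimulus:
    """A step of ``pedestal`` nA plus seeded filtered Gaussian noise.

    The noise has per-sample std ``noise_cv * |pedestal|`` before a
    single-pole low-pass filter with a 1 ms time constant; the waveform is
    deterministic given (seed, dt).
    """
    return Stimulus(stimulus_id, "noisy", pedestal, delay, duration, t_stop,
                    seed=seed, noise_cv=noise_cv)


@dataclass(frozen=True)
class StimulusSuite:
    stimuli: tuple[Stimulus, ...]

    def __post_init__(self):
        object.__setattr__(self, "stimuli", tuple(self.stimuli))
        ids = [s.id for s in self.stimuli]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("stimulus ids must be unique")

    @property
    def size(self) -> int:
        return len(self.stimuli)

    def __len__(self):
        return len(self.stimuli)

    def __iter__(self):
        return iter(self.stimuli)

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.stimuli]

    def select(self, kind: str) -> "StimulusSuite":
        """Sub-suite of one stimulus kind, order preserved."""
        if kind not in KINDS:
            raise ConfigurationError(f"unknown stimulus kind {kind!r}")
        return StimulusSuite(tuple(s for s in self.stimuli if s.kind == kind))

    def take(self, n: int) -> "StimulusSuite":
        return StimulusSuite(self.stimuli[:n])

    def counts_by_kind(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for s in self.stimuli:
            out[s.kind] = out.get(s.kind, 0) + 1
        return out


# default amplitude design: the long-square grid spans sub- to
# supra-threshold responses of the shipped model; short squares probe single
# spikes at 2x / 3x the top step amplitude
LONG_SQUARE_AMPLITUDES = tuple(np.linspace(0.05, 0.4, 8))
NOISY_PEDESTALS = (0.1, 0.2, 0.3)
NOISY_SEEDS = (41, 42)
NOISY_CV = 0.2
RAMP_FINALS = (0.3, 0.45)


def default_suite() -> StimulusSuite:
    """The 18-stimulus default suite: 8 long square, 6 noisy, 2 short
    square, 2 ramp."""
    stims: list[Stimulus] = []
    for i, amp in enumerate(LONG_SQUARE_AMPLITUDES, start=1):
        stims.append(make_long_square(amp, stimulus_id=f"long_square_{i:02d}"))
    k = 1
    for ped in NOISY_PEDESTALS:
        for seed in NOISY_SEEDS:
            stims.append(make_noisy(ped, NOISY_CV, seed=seed,
                                    stimulus_id=f"noisy_{k:02d}"))
            k += 1
    top = LONG_SQUARE_AMPLITUDES[-1]
    for i, mult in enumerate((2.0, 3.0), start=1):
        stims.append(make_short_square(mult * top,
                                       stimulus_id=f"short_square_{i:02d}"))
    for i, final in enumerate(RAMP_FINALS, start=1):
        stims.append(make_ramp(final, stimulus_id=f"ramp_{i:02d}"))
    return StimulusSuite(tuple(stims))
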
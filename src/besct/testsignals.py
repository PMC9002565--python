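"""Analytic nonstationary test signals with known instantaneous frequency.

Two standard benchmark signals sampled at 100 Hz over 10 s:

* ``example1`` — a sinusoidal-FM tone, ``sin(2*pi*(25 t + 10 sin t))`` on
  [0, 6) s, switching abruptly to a pure 34.2 Hz tone on [6, 10] s. Its
  instantaneous frequency is ``25 + 10 cos t`` Hz before the switch.
* ``example2`` — ``sin(30 + 50 t + 60 t^2 + 40 sin t)``, a quadratic-phase
  chirp with sinusoidal modulation. The phase carries no 2*pi factor, so the
  IF is ``(50 + 120 t + 40 cos t) / (2*pi)`` Hz, which crosses the 50 Hz
  Nyquist limit of the default sampling rate near t = 1.9 s; the generator
  evaluates the formula literally and the sampled signal aliases beyond that
  point.

Additive white Gaussian noise is parameterized by its *variance* (default
0.1), which puts the noisy records near 10*log10(0.5/0.1) = 6.99 dB SNR for
these unit-amplitude tones.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .timeseries import TimeSeries

#: boundary between the two segments of example1, in seconds
EXAMPLE1_SWITCH_T = 6.0
#: tone frequency of example1's second segment, Hz
EXAMPLE1_TONE_HZ = 34.2


@dataclass
class SignalSpec:
    which: str = "example1"
    fs: float = 100.0
    duration: float = 10.0

    def __post_init__(self) -> None:
        if self.which not in ("example1", "example2"):
            raise ValueError(f"unknown test signal {self.which!r}")
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be positive")


@dataclass
class NoiseSpec:
    variance: float = 0.1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError("noise variance must be >= 0")


def _phase(which: str, t: np.ndarray) -> np.ndarray:
    """Signal phase in radians (the argument of sin)."""
    t = np.asarray(t, float)
    if which == "example1":
        # t = 6 s belongs to the tone segment (half-open convention)
        return np.where(
            t < EXAMPLE1_SWITCH_T,
            2 * np.pi * (25.0 * t + 10.0 * np.sin(t)),
            2 * np.pi * EXAMPLE1_TONE_HZ * t,
        )
    return 30.0 + 50.0 * t + 60.0 * t**2 + 40.0 * np.sin(t)


def gen_example(spec: SignalSpec | str = "example1", fs: float | None = None,
                duration: float | None = None) -> TimeSeries:
    """Generate one of the two analytic test signals.

    Accepts either a :class:`SignalSpec` or the signal name plus keyword
    overrides. The record includes both endpoints: ``round(duration*fs)+1``
    samples.
    """
    if isinstance(spec, str):
        spec = SignalSpec(which=spec, fs=fs or 100.0, duration=duration or 10.0)
    n = int(round(spec.duration * spec.fs)) + 1
    t = np.arange(n) / spec.fs
    return TimeSeries(values=np.sin(_phase(spec.which, t)), fs=spec.fs)


def add_noise(ts: TimeSeries, noise: NoiseSpec | float = 0.1,
              seed: int | None = None) -> TimeSeries:
    """Add i.i.d. zero-mean Gaussian noise of the given variance."""
    if not isinstance(noise, NoiseSpec):
        noise = NoiseSpec(variance=float(noise), seed=seed)
    if noise.variance == 0:
        return TimeSeries(ts.values.copy(), ts.fs, ts.start_time)
    rng = np.random.default_rng(noise.seed)
    eps = rng.normal(0.0, np.sqrt(noise.variance), ts.values.size)
    return TimeSeries(ts.values + eps, ts.fs, ts.start_time)


def snr_db(clean: TimeSeries, noisy: TimeSeries) -> float:
    """Signal-to-noise ratio 10*log10(sum(clean^2) / sum((noisy-clean)^2))."""
    c = np.asarray(clean.values, float)
    y = np.asarray(noisy.values, float)
    if c.size != y.size:
        raise ValueError("records must have equal length")
    noise_power = float(np.sum((y - c) ** 2))
    if noise_power == 0:
        raise ValueError("zero noise power: SNR is infinite")
    return float(10.0 * np.log10(np.sum(c**2) / noise_power))


def true_if(which: str, t) -> np.ndarray | float:
    """Analytic instantaneous frequency in Hz (phase derivative / 2*pi)."""
    scalar = np.isscalar(t)
    t = np.atleast_1d(np.asarray(t, float))
    if np.any(t < 0) or np.any(t > 10.0 + 1e-12):
        raise ValueError("t outside the [0, 10] s record")
    if which == "example1":
        out = np.where(t < EXAMPLE1_SWITCH_T, 25.0 + 10.0 * np.cos(t),
                       EXAMPLE1_TONE_HZ)
    elif which == "example2":
        out = (50.0 + 120.0 * t + 40.0 * np.cos(t)) / (2 * np.pi)
    else:
        raise ValueError(f"unknown test signal {which!r}")
    return float(out[0]) if scalar else out
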
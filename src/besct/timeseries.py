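"""Uniformly sampled time-series container and CSV/WAV I/O."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.io import wavfile


@dataclass
class TimeSeries:
    """A uniformly sampled real- or complex-valued signal.

    Parameters
    ----------
    values : ndarray
        Sample amplitudes, length >= 2, all finite.
    fs : float
        Sampling rate in Hz, > 0.
    start_time : float
        Time of the first sample in seconds.
    """

    values: np.ndarray
    fs: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("signal must be 1-D with at least 2 samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("signal contains non-finite values")

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.start_time + np.arange(self.values.size) / self.fs

    @property
    def duration(self) -> float:
        return (self.values.size - 1) / self.fs

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration

    # ------------------------------------------------------------------ I/O
    def to_csv(self, path) -> None:
        """Write a two-column CSV (time_s, value) with header."""
        if np.iscomplexobj(self.values):
            raise ValueError("CSV export supports real signals only")
        pd.DataFrame({"time_s": self.times, "value": self.values}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "TimeSeries":
        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise ValueError(f"{path}: expected two columns (time_s, value)")
        t = df.iloc[:, 0].to_numpy(float)
        v = df.iloc[:, 1].to_numpy(float)
        if t.size < 2:
            raise ValueError(f"{path}: need at least 2 samples")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise ValueError(f"{path}: samples are not uniformly spaced")
        return cls(values=v, fs=1.0 / dt[0], start_time=float(t[0]))

    def to_wav(self, path) -> None:
        wavfile.write(path, int(round(self.fs)), self.values.astype(np.float32))

    @classmethod
    def from_wav(cls, path) -> "TimeSeries":
        fs, data = wavfile.read(path)
        if data.ndim > 1:
            raise ValueError(f"{path}: expected a single-channel WAV")
        if np.issubdtype(data.dtype, np.integer):
            data = data / float(np.iinfo(data.dtype).max)
        return cls(values=np.asarray(data, float), fs=float(fs))
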
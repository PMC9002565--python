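"""Time-frequency representation container and its CSV convention."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class TFR:
    """Complex coefficients on a frequency-line x time-center grid.

    ``coeffs[s, i]`` is the coefficient of frequency line ``freqs[s]`` (Hz,
    strictly increasing, within [0, fs/2]) at column center ``times[i]`` (s).
    """

    times: np.ndarray
    freqs: np.ndarray
    coeffs: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.freqs = np.asarray(self.freqs, float)
        self.coeffs = np.asarray(self.coeffs)
        if self.coeffs.shape != (self.freqs.size, self.times.size):
            raise ValueError(
                f"coeffs shape {self.coeffs.shape} != "
                f"(n_freqs={self.freqs.size}, n_times={self.times.size})"
            )
        if self.freqs.size > 1 and np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency lines must be strictly increasing")
        if not np.all(np.isfinite(self.coeffs)):
            raise ValueError("TFR contains non-finite coefficients")

    @property
    def shape(self) -> tuple[int, int]:
        return self.coeffs.shape

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.coeffs)

    def ridge_argmax(self) -> np.ndarray:
        """Per-column frequency (Hz) of maximal magnitude."""
        return self.freqs[np.argmax(np.abs(self.coeffs), axis=0)]

    # ------------------------------------------------------------------ I/O
    def to_csv(self, magnitude_path, phase_path=None) -> None:
        """Write magnitude (and optionally phase) matrices as CSV.

        First row holds the column times, first column the frequency lines.
        """
        for path, mat in ((magnitude_path, np.abs(self.coeffs)),
                          (phase_path, np.angle(self.coeffs))):
            if path is None:
                continue
            df = pd.DataFrame(mat, index=self.freqs, columns=self.times)
            df.index.name = "freq_hz"
            df.to_csv(path, float_format="%.10g")

    @classmethod
    def from_csv(cls, magnitude_path, phase_path=None) -> "TFR":
        mdf = pd.read_csv(magnitude_path, index_col=0)
        freqs = mdf.index.to_numpy(float)
        times = mdf.columns.to_numpy(float)
        mag = mdf.to_numpy(float)
        if phase_path is not None:
            ph = pd.read_csv(phase_path, index_col=0).to_numpy(float)
            coeffs = mag * np.exp(1j * ph)
        else:
            coeffs = mag.astype(complex)
        return cls(times=times, freqs=freqs, coeffs=coeffs)
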
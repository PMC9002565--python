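"""Dynamic spectrum-aware filtering: amplitude-gated passband schedules.

The denoised motion spectrogram separates large motions (high-amplitude
cells, typically at low frequency) from subtle ones.  An amplitude window
[rho_l, rho_h] selects the subtle-motion cells (Eq.-style 0/1 weighting);
contiguous selected frequency bins within each time interval become the
passbands handed to the temporal filter of the magnification stage.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tfr import TFR

__all__ = ["Thresholds", "WeightMask", "PassbandSchedule", "build_weight",
           "split_components", "passbands_from_mask", "auto_rho_h"]


@dataclass
class Thresholds:
    """Amplitude bounds: rho_l <= |coeff| <= rho_h marks subtle motion."""

    rho_l: float = 0.0
    rho_h: float = np.inf

    def __post_init__(self) -> None:
        if not 0 <= self.rho_l < self.rho_h:
            raise ValueError("need 0 <= rho_l < rho_h")


@dataclass
class WeightMask:
    """Binary weighting W(s, i) on the TFR grid."""

    W: np.ndarray
    freqs: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W)
        if self.W.shape != (len(self.freqs), len(self.times)):
            raise ValueError("mask shape must match (freqs, times)")
        if not np.isin(self.W, (0, 1)).all():
            raise ValueError("mask entries must be 0 or 1")


@dataclass
class PassbandSchedule:
    """Per-interval frequency ranges (Hz) selected for amplification."""

    times: np.ndarray
    bands: list = field(default_factory=list)  # per interval: list of (lo, hi)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        if len(self.bands) != self.times.size:
            raise ValueError("one band list per interval required")

    @property
    def is_uniform(self) -> bool:
        return all(b == self.bands[0] for b in self.bands)

    def union_bands(self) -> list:
        """Merged union of all intervals' bands (the global-band fallback)."""
        edges = sorted(b for bl in self.bands for b in bl)
        merged: list = []
        for lo, hi in edges:
            if merged and lo <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
            else:
                merged.append((lo, hi))
        return merged

    def covers(self, freq_hz: float) -> bool:
        return any(lo <= freq_hz <= hi for lo, hi in self.union_bands())

    def to_csv(self, path) -> None:
        rows = [(i, lo, hi) for i, bl in enumerate(self.bands) for lo, hi in bl]
        pd.DataFrame(rows, columns=["interval_index", "f_low_hz", "f_high_hz"]
                     ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, times) -> "PassbandSchedule":
        df = pd.read_csv(path)
        times = np.asarray(times, float)
        bands: list = [[] for _ in times]
        for _, r in df.iterrows():
            bands[int(r.interval_index)].append((r.f_low_hz, r.f_high_hz))
        return cls(times=times, bands=bands)


def build_weight(tfr: TFR, th: Thresholds) -> WeightMask:
    """W(s, i) = 1 iff |coeff(s, i)| lies in [rho_l, rho_h]."""
    mag = np.abs(tfr.coeffs)
    W = ((mag >= th.rho_l) & (mag <= th.rho_h)).astype(np.uint8)
    return WeightMask(W=W, freqs=tfr.freqs, times=tfr.times)


def split_components(tfr: TFR, th: Thresholds) -> tuple[TFR, TFR]:
    """Partition into (above rho_h, the rest); the two sum back cellwise."""
    mag = np.abs(tfr.coeffs)
    above = np.where(mag > th.rho_h, tfr.coeffs, 0.0)
    below = tfr.coeffs - above
    return (TFR(tfr.times, tfr.freqs, above), TFR(tfr.times, tfr.freqs, below))


def passbands_from_mask(mask: WeightMask, freqs: np.ndarray | None = None,
                        min_band_bins: int = 1) -> PassbandSchedule:
    """Maximal runs of selected bins per interval become passbands.

    Runs shorter than ``min_band_bins`` are dropped.  Band edges are widened
    half a bin beyond the outermost selected bin centers (clipped at 0).
    """
    freqs = mask.freqs if freqs is None else np.asarray(freqs, float)
    half_bin = 0.5 * (freqs[1] - freqs[0]) if freqs.size > 1 else 0.0
    bands: list = []
    for i in range(mask.W.shape[1]):
        col = mask.W[:, i].astype(bool)
        runs = []
        s = 0
        while s < col.size:
            if col[s]:
                e = s
                while e + 1 < col.size and col[e + 1]:
                    e += 1
                if e - s + 1 >= min_band_bins:
                    runs.append((max(freqs[s] - half_bin, 0.0),
                                 min(freqs[e] + half_bin, freqs[-1])))
                s = e + 1
            else:
                s += 1
        bands.append(runs)
    return PassbandSchedule(times=mask.times, bands=bands)


def auto_rho_h(tfr: TFR, fraction: float = 0.5) -> float:
    """Default large-motion threshold: ``fraction`` of the peak magnitude."""
    return float(fraction * np.abs(tfr.coeffs).max())
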
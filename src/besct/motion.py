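"""Global-motion metric: per-frame spatial signatures and earth mover's distance.

Each frame is summarized by a pair of intensity-weighted spatial marginals
(column and row mass distributions, each normalized to unit mass).  The
motion metric of frame t is the 1-D earth mover's (Wasserstein-1) distance
of its column marginal to frame 0's, plus the same for the row marginals —
translation of the scene by d pixels along an axis moves that axis's
marginal by d and costs exactly d.  The series of distances against the
first frame is the global-motion signal fed to the spectrogram model.

A plain intensity histogram would be translation-invariant and blind to
pure motion; a full 2-D transport problem costs O(N^2).  The marginal pair
is translation-sensitive and costs O(width + height).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .timeseries import TimeSeries
from .video import VideoSequence, luminance

__all__ = ["FrameSignature", "MotionSeries", "frame_signature", "emd_1d",
           "emod_series"]


@dataclass
class FrameSignature:
    """Unit-mass column and row marginals of one frame."""

    col_positions: np.ndarray
    col_masses: np.ndarray
    row_positions: np.ndarray
    row_masses: np.ndarray


@dataclass
class MotionSeries:
    """EMD of each frame to the first frame, in pixels, at the frame rate."""

    values: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values[0] != 0.0 or np.any(self.values < 0):
            raise ValueError("motion series must start at 0 and be >= 0")

    def to_timeseries(self) -> TimeSeries:
        return TimeSeries(self.values, self.fs)


def frame_signature(frame: np.ndarray) -> FrameSignature:
    """Intensity-weighted column/row marginals, each normalized to 1."""
    frame = np.asarray(frame, float)
    if frame.ndim != 2:
        raise ValueError("frame_signature expects a 2-D grayscale frame")
    if np.any(frame < 0):
        raise ValueError("frame intensities must be nonnegative")
    total = frame.sum()
    if total == 0:
        raise ValueError("cannot build a signature for an all-zero frame")
    return FrameSignature(
        col_positions=np.arange(frame.shape[1], dtype=float),
        col_masses=frame.sum(axis=0) / total,
        row_positions=np.arange(frame.shape[0], dtype=float),
        row_masses=frame.sum(axis=1) / total,
    )


def emd_1d(p: np.ndarray, q: np.ndarray,
           positions: np.ndarray | None = None) -> float:
    """Exact 1-D earth mover's distance between equal-mass distributions.

    ``sum_k |CDF_p(k) - CDF_q(k)| * binwidth`` on a common (default
    unit-spaced) grid — the closed form of the transportation optimum on
    the line.
    """
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    if p.shape != q.shape:
        raise ValueError("distributions must share one support grid")
    if abs(p.sum() - q.sum()) > 1e-6:
        raise ValueError(
            f"total masses differ by {abs(p.sum() - q.sum()):.3g} > 1e-6")
    cdf_diff = np.abs(np.cumsum(p - q))[:-1]
    if positions is None:
        return float(cdf_diff.sum())
    widths = np.diff(np.asarray(positions, float))
    if np.any(widths <= 0):
        raise ValueError("positions must be strictly increasing")
    return float(np.sum(cdf_diff * widths))


def emod_series(video: VideoSequence) -> MotionSeries:
    """Per-frame EMD (column + row marginals) to the first frame.

    The luminance channel carries the intensity weights.
    """
    if video.n_frames < 2:
        raise ValueError("need at least 2 frames")
    sigs = [frame_signature(luminance(f)) for f in video.frames]
    ref = sigs[0]
    vals = np.empty(video.n_frames)
    vals[0] = 0.0
    for t in range(1, video.n_frames):
        vals[t] = (emd_1d(sigs[t].col_masses, ref.col_masses)
                   + emd_1d(sigs[t].row_masses, ref.row_masses))
    return MotionSeries(values=vals, fs=video.fps)
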
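"""Spline-kerneled chirplet transform (SCT).

The SCT is a demodulated short-time transform: an instantaneous-frequency
(IF) model ``kappa(t)`` — here a cubic spline — drives a frequency-rotate
operator ``exp(-j 2*pi * int_0^t kappa(u) du)`` that flattens the modeled
modulation, and a frequency-shift operator ``exp(+j 2*pi kappa(t0) t)`` that
moves the flattened component back to its instantaneous frequency at each
window center ``t0``:

    SCT(t0, f) = sum_t z(t) w(t - t0)
                 exp(-j 2*pi Phi(t)) exp(+j 2*pi kappa(t0) t) exp(-j 2*pi f t)

with ``z`` the analytic signal, ``w`` a Gaussian window and ``Phi`` the
antiderivative of ``kappa``.  A component whose true IF equals ``kappa``
appears as a sharply concentrated ridge along ``kappa(t0)``; with
``kappa == 0`` both operators vanish and the transform reduces exactly to a
Gaussian-windowed STFT.

The kernel itself is estimated from the data by alternating ridge extraction
(dynamic programming) and least-squares spline fitting (:func:`iterate_sct`).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline
from scipy.signal import hilbert

from .tfr import TFR
from .timeseries import TimeSeries

__all__ = [
    "SplineIFKernel",
    "SCTConfig",
    "SCTRefinement",
    "stft",
    "sct",
    "extract_ridge",
    "fit_spline_kernel",
    "iterate_sct",
    "renyi_entropy",
]


# --------------------------------------------------------------------------
# IF kernel
# --------------------------------------------------------------------------
@dataclass
class SplineIFKernel:
    """Cubic-spline model of instantaneous frequency kappa(t) in Hz."""

    spline: BSpline
    residual: float = 0.0  # RMS of the fit that produced this kernel

    def __call__(self, t):
        return np.asarray(self.spline(np.asarray(t, float)), float)

    def phase(self, t):
        """Antiderivative int_0^t kappa(u) du, in cycles."""
        anti = self.spline.antiderivative()
        return np.asarray(anti(np.asarray(t, float)) - anti(0.0), float)

    @property
    def knots(self) -> np.ndarray:
        return np.asarray(self.spline.t)

    @property
    def is_zero(self) -> bool:
        return bool(np.all(self.spline.c == 0.0))

    @classmethod
    def zero(cls, t_start: float = 0.0, t_end: float = 1.0) -> "SplineIFKernel":
        return cls.constant(0.0, t_start, t_end)

    @classmethod
    def constant(cls, freq_hz: float, t_start: float = 0.0,
                 t_end: float = 1.0) -> "SplineIFKernel":
        k = 3
        t = np.r_[[t_start] * (k + 1), [t_end] * (k + 1)]
        c = np.full(k + 1, float(freq_hz))
        return cls(BSpline(t, c, k))

    @classmethod
    def from_function(cls, fn, t_start: float, t_end: float,
                      n_knots: int = 16, n_samples: int = 512) -> "SplineIFKernel":
        """Least-squares spline approximation of an arbitrary IF law."""
        t = np.linspace(t_start, t_end, n_samples)
        return fit_spline_kernel(np.c_[t, np.asarray(fn(t), float)], n_knots)


# --------------------------------------------------------------------------
# Transforms
# --------------------------------------------------------------------------
@dataclass
class SCTConfig:
    """Tunables of the transform and its kernel-refinement loop."""

    window_sd: float = 0.5      # Gaussian window std dev, seconds
    hop: int = 10               # samples between columns
    n_lines: int = 256          # frequency lines on [0, fs/2]
    n_knots: int = 8            # spline knots (incl. endpoints), equispaced
    jump_penalty: float | None = None  # ridge DP cost per bin step; None -> 2*df
    n_iter: int = 2             # kernel refinement iterations


def _window(window_sd: float, fs: float) -> tuple[np.ndarray, int]:
    """Gaussian window truncated at +-4 sd; returns (window, half-width)."""
    half = int(round(4.0 * window_sd * fs))
    k = np.arange(-half, half + 1)
    return np.exp(-0.5 * (k / (window_sd * fs)) ** 2), half


def _transform(ts: TimeSeries, kernel: SplineIFKernel | None,
               window_sd: float, hop: int, n_lines: int,
               centers: np.ndarray | None = None) -> TFR:
    if window_sd <= 0:
        raise ValueError("window_sd must be positive")
    if hop < 1:
        raise ValueError("hop must be >= 1")
    if n_lines < 2:
        raise ValueError("n_lines must be >= 2")
    n = len(ts)
    w, half = _window(window_sd, ts.fs)
    if n < 2 * half + 1:
        raise ValueError(
            f"signal of {n} samples is shorter than one window: at least "
            f"{2 * half + 1} samples required (window_sd={window_sd} s at "
            f"fs={ts.fs} Hz, truncated at +-4 sd)"
        )
    z = hilbert(ts.values.real) if not np.iscomplexobj(ts.values) else ts.values
    t = ts.times
    if centers is None:
        centers = np.arange(0, n, hop)
    centers = np.asarray(centers, int)

    freqs = np.linspace(0.0, ts.fs / 2.0, n_lines)
    # complex exponential bank over absolute sample times
    bank = np.exp(-2j * np.pi * freqs[:, None] * t[None, :])

    if kernel is not None and not kernel.is_zero:
        kap_c = kernel(t[centers])
        if np.any(np.abs(kernel(t)) > ts.fs / 2):
            warnings.warn(
                "IF kernel exceeds the Nyquist frequency fs/2 somewhere in "
                "the record; the transform will alias", stacklevel=3)
        demod = z * np.exp(-2j * np.pi * kernel.phase(t))
    else:
        kap_c = np.zeros(centers.size)
        demod = z

    coeffs = np.empty((n_lines, centers.size), complex)
    for j, c in enumerate(centers):
        lo, hi = max(0, c - half), min(n, c + half + 1)
        seg = demod[lo:hi] * w[lo - (c - half): hi - (c - half)]
        if kap_c[j] != 0.0:
            seg = seg * np.exp(2j * np.pi * kap_c[j] * t[lo:hi])
        coeffs[:, j] = bank[:, lo:hi] @ seg
    return TFR(times=t[centers], freqs=freqs, coeffs=coeffs)


def stft(ts: TimeSeries, window_sd: float = 0.5, hop: int = 10,
         n_lines: int = 256, centers: np.ndarray | None = None) -> TFR:
    """Gaussian-windowed short-time Fourier transform of the analytic signal."""
    return _transform(ts, None, window_sd, hop, n_lines, centers)


def sct(ts: TimeSeries, kernel: SplineIFKernel, window_sd: float = 0.5,
        hop: int = 10, n_lines: int = 256,
        centers: np.ndarray | None = None) -> TFR:
    """Spline-kerneled chirplet transform; kappa == 0 reduces to :func:`stft`."""
    return _transform(ts, kernel, window_sd, hop, n_lines, centers)


# --------------------------------------------------------------------------
# Ridge extraction and kernel fitting
# --------------------------------------------------------------------------
def extract_ridge(tfr: TFR, jump_penalty: float | None = None) -> np.ndarray:
    """Maximum-magnitude time-frequency path by dynamic programming.

    Maximizes ``sum |coeff| - penalty * sum |delta bin|`` over all
    one-frequency-per-column paths.  Returns an array of (time_s, freq_hz)
    rows, one per column.
    """
    mag = np.abs(tfr.coeffs)
    if mag.size == 0 or not np.any(mag > 0):
        raise ValueError("cannot extract a ridge from an all-zero TFR")
    S, C = mag.shape
    df = tfr.freqs[1] - tfr.freqs[0] if S > 1 else 1.0
    pen = 2.0 * df if jump_penalty is None else float(jump_penalty)

    score = mag[:, 0].copy()
    back = np.zeros((S, C), int)
    idx = np.arange(S)
    for i in range(1, C):
        # best[s] = max_u score[u] - pen*|s-u|, argmax tracked in two sweeps
        best = score.copy()
        arg = idx.copy()
        for s in range(1, S):
            if best[s - 1] - pen > best[s]:
                best[s] = best[s - 1] - pen
                arg[s] = arg[s - 1]
        for s in range(S - 2, -1, -1):
            if best[s + 1] - pen > best[s]:
                best[s] = best[s + 1] - pen
                arg[s] = arg[s + 1]
        back[:, i] = arg
        score = best + mag[:, i]
    path = np.empty(C, int)
    path[-1] = int(np.argmax(score))
    for i in range(C - 1, 0, -1):
        path[i - 1] = back[path[i], i]
    return np.c_[tfr.times, tfr.freqs[path]]


def fit_spline_kernel(track: np.ndarray, n_knots: int = 8) -> SplineIFKernel:
    """Least-squares cubic spline through a (time, Hz) ridge track.

    ``n_knots`` counts equispaced knots including both endpoints. The RMS
    residual of the fit is stored on the returned kernel.
    """
    track = np.asarray(track, float)
    if n_knots < 2:
        raise ValueError("n_knots must be >= 2")
    t, f = track[:, 0], track[:, 1]
    order = np.argsort(t, kind="stable")
    t, f = t[order], f[order]
    if t[-1] <= t[0]:
        raise ValueError("degenerate track: all points share one time")
    if np.unique(t).size < n_knots:
        raise ValueError(
            f"track has {np.unique(t).size} distinct times, fewer than "
            f"n_knots={n_knots}")
    k = 3
    knots = np.linspace(t[0], t[-1], n_knots)
    full = np.r_[[t[0]] * (k + 1), knots[1:-1], [t[-1]] * (k + 1)]
    # least squares on the B-spline design matrix (minimum-norm solution
    # when the track has fewer points than basis functions)
    X = BSpline.design_matrix(t, full, k).toarray()
    c, *_ = np.linalg.lstsq(X, f, rcond=None)
    spl = BSpline(full, c, k)
    resid = float(np.sqrt(np.mean((spl(t) - f) ** 2)))
    return SplineIFKernel(spline=spl, residual=resid)


@dataclass
class SCTRefinement:
    """Result of the iterative kernel-refinement loop."""

    kernel: SplineIFKernel
    tfr: TFR
    rms_history: list[float] = field(default_factory=list)
    ridge: np.ndarray | None = None


def iterate_sct(ts: TimeSeries, n_iter: int = 2,
                config: SCTConfig | None = None) -> SCTRefinement:
    """STFT -> ridge -> spline fit -> SCT -> ridge -> refit, ``n_iter`` times.

    Each iteration extracts the magnitude ridge of the current transform,
    fits the spline IF kernel to it and recomputes the SCT under that
    kernel.  ``rms_history`` records the ridge-vs-kernel RMS (Hz) of each
    fit, a convergence diagnostic.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    cfg = config or SCTConfig()
    tfr = stft(ts, cfg.window_sd, cfg.hop, cfg.n_lines)
    kernel: SplineIFKernel | None = None
    rms: list[float] = []
    ridge = None
    for _ in range(n_iter):
        ridge = extract_ridge(tfr, cfg.jump_penalty)
        kernel = fit_spline_kernel(ridge, cfg.n_knots)
        rms.append(kernel.residual)
        tfr = sct(ts, kernel, cfg.window_sd, cfg.hop, cfg.n_lines)
    return SCTRefinement(kernel=kernel, tfr=tfr, rms_history=rms, ridge=ridge)


# --------------------------------------------------------------------------
# Concentration metric
# --------------------------------------------------------------------------
def renyi_entropy(tfr: TFR, order: float = 3.0) -> float:
    """Renyi entropy (bits) of the normalized TFR energy distribution.

    ``(1/(1-order)) * log2 sum p^order`` with ``p = |c|^2 / sum |c|^2``.
    Lower values mean sharper time-frequency concentration; a single
    occupied cell gives 0, a uniform surface over N cells gives log2 N.
    """
    e = np.abs(tfr.coeffs) ** 2
    total = e.sum()
    if total <= 0:
        raise ValueError("TFR has zero total energy")
    p = e / total
    p = p[p > 0]
    return float(np.log2(np.sum(p**order)) / (1.0 - order))
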
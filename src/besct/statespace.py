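"""Per-frequency-line complex linear-Gaussian state-space inference.

The record is segmented into I contiguous, nonoverlapping stationary
intervals of J samples.  On each interval the chirplet coefficient at line s
is modeled as a noisy observation of a latent complex spectral increment
that evolves as a random walk across intervals:

    Y_{i,s}  = dZ_{i,s} + eps_{i,s},      eps ~ CN(0, sigma_eps^2)
    dZ_{i,s} = dZ_{i-1,s} + v_{i,s},      v   ~ CN(0, sigma_v,s^2)

All complex Gaussians are circularly symmetric with scalar variances, so
each line decouples into an independent 1-D complex Kalman filtering /
fixed-interval smoothing problem.  The smoothed means over the full grid
form the denoised (empirical-Bayes) spectrogram.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sct import SCTConfig, SplineIFKernel, _transform
from .tfr import TFR
from .timeseries import TimeSeries

__all__ = [
    "IntervalGrid",
    "SpectralObs",
    "ModelParams",
    "FilterStats",
    "IncrementPosterior",
    "VARIANCE_FLOOR",
    "build_observations",
    "kalman_filter_line",
    "smooth_line",
    "lag_covariances",
    "lag_covariance",
    "sample_posterior",
    "denoised_spectrogram",
]

#: floor applied to all estimated variances so Kalman gains stay defined
VARIANCE_FLOOR = 1e-12


# --------------------------------------------------------------------------
# Containers
# --------------------------------------------------------------------------
@dataclass
class IntervalGrid:
    """I contiguous stationary intervals of J samples each."""

    J: int
    I: int
    start_sample: int = 0

    def __post_init__(self) -> None:
        if self.J < 1:
            raise ValueError("J must be >= 1")
        if self.I < 2:
            raise ValueError("need at least I = 2 stationary intervals")

    @classmethod
    def for_record(cls, n_samples: int, J: int) -> "IntervalGrid":
        I = n_samples // J
        if I < 2:
            raise ValueError(
                f"record of {n_samples} samples holds fewer than 2 intervals "
                f"of J={J} samples")
        return cls(J=J, I=I)

    @property
    def n_samples(self) -> int:
        return self.I * self.J

    def center_samples(self) -> np.ndarray:
        """Center sample index of each interval."""
        return self.start_sample + np.arange(self.I) * self.J + self.J // 2

    def center_times(self, fs: float, start_time: float = 0.0) -> np.ndarray:
        return start_time + self.center_samples() / fs


@dataclass
class SpectralObs:
    """Chirplet coefficients Y[s, i] on the line x interval grid."""

    Y: np.ndarray
    freqs: np.ndarray
    grid: IntervalGrid
    times: np.ndarray

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, complex)
        if self.Y.shape != (len(self.freqs), self.grid.I):
            raise ValueError(
                f"Y shape {self.Y.shape} != (S={len(self.freqs)}, "
                f"I={self.grid.I})")
        if not np.all(np.isfinite(self.Y)):
            raise ValueError("observations contain non-finite values")

    @property
    def S(self) -> int:
        return self.Y.shape[0]

    @property
    def I(self) -> int:
        return self.Y.shape[1]


@dataclass
class ModelParams:
    """Hyperparameters Theta of the per-line state-space model."""

    sigma_eps2: float           # shared observation-noise variance
    sigma_v2: np.ndarray        # (S,) state-noise variances
    z0: np.ndarray              # (S,) initial states dZ_{0,s}
    sigma02: np.ndarray         # (S,) initial-state variances

    def __post_init__(self) -> None:
        self.sigma_v2 = np.atleast_1d(np.asarray(self.sigma_v2, float))
        self.z0 = np.atleast_1d(np.asarray(self.z0, complex))
        self.sigma02 = np.atleast_1d(np.asarray(self.sigma02, float))
        if self.sigma_eps2 <= 0:
            raise ValueError("sigma_eps2 must be positive")
        if np.any(self.sigma_v2 <= 0):
            raise ValueError("sigma_v2 must be positive (after flooring)")
        if np.any(self.sigma02 < 0):
            raise ValueError("sigma02 must be >= 0")

    def line(self, s: int) -> "ModelParams":
        return ModelParams(self.sigma_eps2, self.sigma_v2[s:s + 1],
                           self.z0[s:s + 1], self.sigma02[s:s + 1])


@dataclass
class FilterStats:
    """Forward (predicted/filtered) moments per line; arrays are (S, I)."""

    pred_mean: np.ndarray
    pred_var: np.ndarray
    filt_mean: np.ndarray
    filt_var: np.ndarray
    gain: np.ndarray


@dataclass
class IncrementPosterior:
    """Filtered, predicted and smoothed moments of the spectral increments.

    All arrays are (S, I).  ``smooth_mean0``/``smooth_var0`` hold the
    smoothed moments of the initial state (the extra i = 0 smoothing step),
    and ``lag1`` the smoothed lag-one covariances sigma_{i,i+1|I,s} with
    ``lag1[:, 0]`` = cov(dZ_0, dZ_1 | Y).
    """

    pred_mean: np.ndarray
    pred_var: np.ndarray
    filt_mean: np.ndarray
    filt_var: np.ndarray
    gain: np.ndarray
    smooth_mean: np.ndarray
    smooth_var: np.ndarray
    smooth_gain: np.ndarray      # A_{i,s}, (S, I-1): A_i for i=1..I-1
    smooth_mean0: np.ndarray
    smooth_var0: np.ndarray
    smooth_gain0: np.ndarray     # A_{0,s}
    lag1: np.ndarray             # (S, I): [cov(0,1), cov(1,2), ..., cov(I-1,I)]


# --------------------------------------------------------------------------
# Observation construction
# --------------------------------------------------------------------------
def build_observations(ts: TimeSeries, grid: IntervalGrid,
                       config: SCTConfig | None = None,
                       kernel: SplineIFKernel | None = None) -> SpectralObs:
    """One chirplet coefficient per interval, taken at its center sample."""
    cfg = config or SCTConfig()
    if grid.start_sample + grid.n_samples > len(ts):
        raise ValueError(
            f"grid of {grid.I} x {grid.J} samples does not fit the record "
            f"of {len(ts)} samples")
    centers = grid.center_samples()
    tfr = _transform(ts, kernel, cfg.window_sd, cfg.hop, cfg.n_lines,
                     centers=centers)
    return SpectralObs(Y=tfr.coeffs, freqs=tfr.freqs, grid=grid,
                       times=tfr.times)


# --------------------------------------------------------------------------
# Kalman filter / smoother (vectorized across lines)
# --------------------------------------------------------------------------
def _filter(Y: np.ndarray, params: ModelParams) -> FilterStats:
    Y = np.atleast_2d(Y)
    S, I = Y.shape
    se2 = float(params.sigma_eps2)
    sv2 = params.sigma_v2
    pm = np.empty((S, I), complex)
    pv = np.empty((S, I))
    fm = np.empty((S, I), complex)
    fv = np.empty((S, I))
    C = np.empty((S, I))
    m, v = params.z0.copy(), params.sigma02.copy()
    for i in range(I):
        pm[:, i] = m
        pv[:, i] = v + sv2
        C[:, i] = pv[:, i] / (se2 + pv[:, i])
        fm[:, i] = pm[:, i] + C[:, i] * (Y[:, i] - pm[:, i])
        fv[:, i] = (1.0 - C[:, i]) * pv[:, i]
        m, v = fm[:, i], fv[:, i]
    return FilterStats(pm, pv, fm, fv, C)


def kalman_filter_line(y_line: np.ndarray, params: ModelParams,
                       s: int = 0) -> FilterStats:
    """1-D complex Kalman filter for a single frequency line.

    Predict ``dZ_{i|i-1} = dZ_{i-1|i-1}``, ``var_{i|i-1} = var_{i-1|i-1} +
    sigma_v^2``; gain ``C_i = var_{i|i-1} / (sigma_eps^2 + var_{i|i-1})``;
    update per the standard linear-Gaussian recursions.
    """
    y_line = np.asarray(y_line, complex).ravel()
    return _filter(y_line[None, :], params.line(s))


def _smooth(filt: FilterStats, params: ModelParams) -> IncrementPosterior:
    pm, pv, fm, fv = filt.pred_mean, filt.pred_var, filt.filt_mean, filt.filt_var
    S, I = fm.shape
    sm = np.empty((S, I), complex)
    sv = np.empty((S, I))
    A = np.empty((S, I - 1)) if I > 1 else np.empty((S, 0))
    sm[:, -1], sv[:, -1] = fm[:, -1], fv[:, -1]
    for i in range(I - 2, -1, -1):
        Ai = np.where(pv[:, i + 1] > 0, fv[:, i] / np.maximum(pv[:, i + 1],
                                                              VARIANCE_FLOOR), 0.0)
        Ai = np.where(pv[:, i + 1] <= 0, 0.0, Ai)
        A[:, i] = Ai
        sm[:, i] = fm[:, i] + Ai * (sm[:, i + 1] - pm[:, i + 1])
        sv[:, i] = fv[:, i] + Ai**2 * (sv[:, i + 1] - pv[:, i + 1])
    # extra step to the initial state (prior CN(z0, sigma0^2))
    A0 = np.where(pv[:, 0] > 0,
                  params.sigma02 / np.maximum(pv[:, 0], VARIANCE_FLOOR), 0.0)
    sm0 = params.z0 + A0 * (sm[:, 0] - pm[:, 0])
    sv0 = params.sigma02 + A0**2 * (sv[:, 0] - pv[:, 0])
    # lag-one smoothed covariances: sigma_{i,i+1|I} = A_i * sigma^2_{i+1|I}
    lag1 = np.empty((S, I))
    lag1[:, 0] = A0 * sv[:, 0]
    if I > 1:
        lag1[:, 1:] = A * sv[:, 1:]
    return IncrementPosterior(
        pred_mean=pm, pred_var=pv, filt_mean=fm, filt_var=fv, gain=filt.gain,
        smooth_mean=sm, smooth_var=np.maximum(sv, 0.0), smooth_gain=A,
        smooth_mean0=sm0, smooth_var0=np.maximum(sv0, 0.0), smooth_gain0=A0,
        lag1=lag1)


def smooth_line(filtered: FilterStats, params: ModelParams,
                s: int = 0) -> IncrementPosterior:
    """Fixed-interval (RTS) smoother for one line of filtered stats.

    ``A_i = var_{i|i} / var_{i+1|i}`` (defined as 0 when the predicted
    variance vanishes), initialized at i = I with the filtered values.
    """
    if filtered.filt_mean.shape[0] == 1:
        return _smooth(filtered, params.line(s) if params.z0.size > 1 else params)
    return _smooth(filtered, params)


def posterior_moments(Y: np.ndarray, params: ModelParams) -> IncrementPosterior:
    """Filter + smooth + lag covariances for a full (S, I) observation matrix."""
    return _smooth(_filter(Y, params), params)


def lag_covariances(posterior: IncrementPosterior) -> np.ndarray:
    """Smoothed lag-one covariances sigma_{i,i+1|I,s}, shape (S, I)."""
    return posterior.lag1


def lag_covariance(posterior: IncrementPosterior, i: int, u: int) -> np.ndarray:
    """General smoothed covariance sigma_{i,u|I,s} for 0 <= i <= u <= I.

    Indices follow the interval numbering with 0 the initial state and
    1..I the stationary intervals.  Computed by the backward recursion
    sigma_{i,u|I} = A_i sigma_{i+1,u|I} with sigma_{u,u|I} the smoothed
    variance.
    """
    if not 0 <= i <= u:
        raise ValueError("need 0 <= i <= u")
    S, I = posterior.smooth_mean.shape
    if u > I:
        raise ValueError(f"u={u} exceeds I={I}")
    cov = (posterior.smooth_var0 if u == 0
           else posterior.smooth_var[:, u - 1]).copy()
    for k in range(u - 1, i - 1, -1):
        Ak = posterior.smooth_gain0 if k == 0 else posterior.smooth_gain[:, k - 1]
        cov = Ak * cov
    return cov


# --------------------------------------------------------------------------
# Posterior sampling and the denoised surface
# --------------------------------------------------------------------------
def sample_posterior(posterior: IncrementPosterior, params: ModelParams,
                     n_draws: int, seed: int | None = None) -> np.ndarray:
    """Joint posterior draws of dZ_{1..I,s} by forward-filter backward-sampling.

    Returns an array of shape (n_draws, S, I) with circularly-symmetric
    complex noise; zero posterior variances reproduce the smoothed means
    exactly.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    fm, fv = posterior.filt_mean, posterior.filt_var
    pm, pv = posterior.pred_mean, posterior.pred_var
    S, I = fm.shape

    def crandn(size):
        return (rng.standard_normal(size) + 1j * rng.standard_normal(size)) / np.sqrt(2)

    draws = np.empty((n_draws, S, I), complex)
    draws[:, :, -1] = fm[:, -1] + crandn((n_draws, S)) * np.sqrt(fv[:, -1])
    for i in range(I - 2, -1, -1):
        Ai = np.where(pv[:, i + 1] > 0, fv[:, i] / np.maximum(pv[:, i + 1],
                                                              VARIANCE_FLOOR), 0.0)
        cmean = fm[:, i] + Ai * (draws[:, :, i + 1] - pm[:, i + 1])
        cvar = np.maximum(fv[:, i] - Ai**2 * pv[:, i + 1], 0.0)
        draws[:, :, i] = cmean + crandn((n_draws, S)) * np.sqrt(cvar)
    return draws


def denoised_spectrogram(posterior: IncrementPosterior, freqs: np.ndarray,
                         times: np.ndarray) -> TFR:
    """TFR whose coefficients are the smoothed increment means dZ_{i|I,s}."""
    return TFR(times=times, freqs=freqs, coeffs=posterior.smooth_mean.copy())
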
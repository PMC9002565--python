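"""Model/Results interface to the Bayesian-embedded chirplet transform.

:class:`BESCT` bundles the three stages of the signal-analysis workflow —
iterative spline-kernel refinement of the chirplet transform, interval
segmentation into spectral observations, and MAP-EM estimation of the
state-space variances — behind a statsmodels-style ``Model.fit() ->
Results`` surface.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .em import EMConfig, EMTrace, run_em
from .sct import SCTConfig, SCTRefinement, SplineIFKernel, iterate_sct, renyi_entropy
from .statespace import (IncrementPosterior, IntervalGrid, ModelParams,
                         SpectralObs, build_observations, denoised_spectrogram,
                         sample_posterior)
from .tfr import TFR
from .timeseries import TimeSeries

__all__ = ["BESCT", "BESCTResults"]


class BESCT:
    """Empirical-Bayes spline-chirplet spectrogram model of one signal.

    Parameters
    ----------
    endog : array-like or TimeSeries
        The observed record. If an array, ``fs`` must be given.
    fs : float
        Sampling rate in Hz.
    window_sd : float
        Gaussian analysis-window standard deviation in seconds.
    n_lines : int
        Frequency lines on [0, fs/2].
    interval_len : int
        Samples per stationary interval J (also the transform hop), so each
        interval contributes exactly one chirplet column.
    kernel : SplineIFKernel, "auto" or None
        IF kernel for the transform. ``"auto"`` (default) estimates it by
        ``sct_iter`` rounds of ridge extraction and spline refitting; None
        uses the plain STFT.
    n_knots, jump_penalty, sct_iter
        Kernel-refinement tunables (see :mod:`besct.sct`).
    alpha, beta, em_eps, em_max
        Gamma-prior and stopping tunables of the EM (see :mod:`besct.em`).
    """

    def __init__(self, endog, fs: float | None = None, *, start_time: float = 0.0,
                 window_sd: float = 0.5, n_lines: int = 256,
                 interval_len: int = 10, kernel="auto", n_knots: int = 8,
                 jump_penalty: float | None = None, sct_iter: int = 2,
                 alpha: float = 3.0, beta: float = 1e-3,
                 em_eps: float = 1e-4, em_max: int = 50):
        if isinstance(endog, TimeSeries):
            self.ts = endog
        else:
            if fs is None:
                raise ValueError("fs is required when endog is a plain array")
            self.ts = TimeSeries(np.asarray(endog, float), fs, start_time)
        self.sct_config = SCTConfig(window_sd=window_sd, hop=interval_len,
                                    n_lines=n_lines, n_knots=n_knots,
                                    jump_penalty=jump_penalty, n_iter=sct_iter)
        self.em_config = EMConfig(alpha=alpha, beta=beta, eps=em_eps,
                                  em_max=em_max)
        self.kernel = kernel
        self.grid = IntervalGrid.for_record(len(self.ts), interval_len)

    @classmethod
    def from_timeseries(cls, ts: TimeSeries, **kwargs) -> "BESCT":
        return cls(ts, **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "BESCT":
        return cls(TimeSeries.from_csv(path), **kwargs)

    def fit(self) -> "BESCTResults":
        """Estimate the kernel (if requested) and run the EM smoother."""
        refinement: SCTRefinement | None = None
        if isinstance(self.kernel, SplineIFKernel):
            kernel = self.kernel
        elif self.kernel == "auto":
            refinement = iterate_sct(self.ts, self.sct_config.n_iter,
                                     self.sct_config)
            kernel = refinement.kernel
        elif self.kernel is None:
            kernel = None
        else:
            raise ValueError("kernel must be a SplineIFKernel, 'auto' or None")
        obs = build_observations(self.ts, self.grid, self.sct_config, kernel)
        params, posterior, trace = run_em(obs, self.em_config)
        return BESCTResults(model=self, kernel=kernel, obs=obs, params=params,
                            posterior=posterior, em_trace=trace,
                            refinement=refinement)


@dataclass
class BESCTResults:
    """Fitted spectrogram model: parameter estimates and the posterior."""

    model: BESCT
    kernel: SplineIFKernel | None
    obs: SpectralObs
    params: ModelParams
    posterior: IncrementPosterior
    em_trace: EMTrace
    refinement: SCTRefinement | None = None
    _cache: dict = field(default_factory=dict, repr=False)

    # ------------------------------------------------------------ surfaces
    @property
    def sct_tfr(self) -> TFR:
        """The raw chirplet coefficients on the interval grid."""
        if "sct" not in self._cache:
            self._cache["sct"] = TFR(times=self.obs.times, freqs=self.obs.freqs,
                                     coeffs=self.obs.Y.copy())
        return self._cache["sct"]

    @property
    def denoised_tfr(self) -> TFR:
        """The empirical-Bayes surface: smoothed increment means."""
        if "den" not in self._cache:
            self._cache["den"] = denoised_spectrogram(
                self.posterior, self.obs.freqs, self.obs.times)
        return self._cache["den"]

    # ---------------------------------------------------------- inference
    def sample_posterior(self, n_draws: int, seed: int | None = None) -> np.ndarray:
        """Monte Carlo draws of the spectral increments, (n_draws, S, I)."""
        return sample_posterior(self.posterior, self.params, n_draws, seed)

    def ridge(self) -> np.ndarray:
        """Columnwise magnitude-argmax track of the denoised surface (Hz)."""
        return self.denoised_tfr.ridge_argmax()

    def entropies(self) -> dict:
        """Renyi (order 3) concentration of raw vs denoised surfaces."""
        return {"sct": renyi_entropy(self.sct_tfr),
                "denoised": renyi_entropy(self.denoised_tfr)}

    # ------------------------------------------------------------ reports
    def summary(self) -> str:
        ts, grid = self.model.ts, self.model.grid
        sv = self.params.sigma_v2
        lines = [
            "Empirical-Bayes spline-chirplet spectrogram (BE-SCT)",
            "=" * 56,
            f"samples: {len(ts)}   fs: {ts.fs:g} Hz   duration: {ts.duration:g} s",
            f"intervals: I = {grid.I}  x  J = {grid.J} samples",
            f"frequency lines: S = {self.obs.S} on [0, {ts.fs / 2:g}] Hz",
            f"kernel: {'none (STFT)' if self.kernel is None else 'cubic spline IF'}",
            f"EM iterations: {self.em_trace.n_iter}"
            f"   final convergence stat: {self.em_trace.conv[-1]:.3g}",
            "-" * 56,
            f"sigma_eps^2 (observation noise): {self.params.sigma_eps2:.6g}",
            f"sigma_v^2 (state noise) min/median/max: "
            f"{sv.min():.4g} / {np.median(sv):.4g} / {sv.max():.4g}",
            f"penalized log-likelihood: {self.em_trace.loglik[-1]:.6g}",
            "-" * 56,
        ]
        ent = self.entropies()
        lines.append(f"Renyi entropy (order 3): raw {ent['sct']:.3f} bits, "
                     f"denoised {ent['denoised']:.3f} bits")
        return "\n".join(lines)

    def plot_spectrogram(self, which: str = "denoised", ax=None, db_floor=-60):
        """Render the raw or denoised surface (dB magnitude) with matplotlib."""
        import matplotlib.pyplot as plt

        tfr = self.denoised_tfr if which == "denoised" else self.sct_tfr
        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        mag = tfr.magnitude
        ref = mag.max() if mag.max() > 0 else 1.0
        db = 20 * np.log10(np.maximum(mag / ref, 10 ** (db_floor / 20)))
        im = ax.pcolormesh(tfr.times, tfr.freqs, db, shading="nearest",
                           cmap="magma", vmin=db_floor, vmax=0)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("frequency (Hz)")
        ax.figure.colorbar(im, ax=ax, label="magnitude (dB)")
        return ax
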
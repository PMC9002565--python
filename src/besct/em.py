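"""MAP-EM estimation of the state-space variances with gamma priors.

The observation-noise variance ``sigma_eps^2`` (shared across lines) and the
per-line state-noise variances ``sigma_v,s^2`` are estimated by
expectation-maximization on their precisions ``tau = 1/sigma^2``, each with
a gamma(alpha, beta) prior.  The E-step runs the complex Kalman filter,
fixed-interval smoother and lag-one covariance smoother per line; the M-step
has closed-form precision updates

    tau_v,s = (I + alpha) / (SS_v,s + |dZ0_s|^2 + beta)
    tau_eps = (S*I + alpha - 1) / (D + beta)

where ``SS_v,s = sum_i E[|dZ_i - dZ_{i-1}|^2 | Y]`` is the expected sum of
squared increments (i = 1..I, with the i = 0 moments from the extended
smoother) and ``D = sum_{i,s} |Y_is|^2 + W_is - 2 Re(conj(Y_is) dZ_{i|I,s})``
the expected squared observation residual.  The ``|dZ0|^2`` term in the
state update comes from the initial-state density of the complete-data
likelihood, which depends on sigma_v^2; it is equivalent to tightening the
gamma prior on tau_v to gamma(alpha + 1, beta + |dZ0|^2), so the penalized
observed-data log-likelihood is non-decreasing across iterations.

Initial states are the first-interval coefficients and initial variances
their squared magnitudes (elementwise); both are held fixed across EM
iterations.  Convergence is declared when the summed relative change of the
smoothed increments drops below ``eps``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .statespace import (VARIANCE_FLOOR, IncrementPosterior, ModelParams,
                         SpectralObs, _filter, posterior_moments)

__all__ = [
    "EMConfig",
    "SufficientStats",
    "EMTrace",
    "init_params",
    "e_step",
    "m_step",
    "run_em",
    "penalized_loglik",
]


@dataclass
class EMConfig:
    alpha: float = 3.0       # gamma prior shape, > 1
    beta: float = 1e-3       # gamma prior rate, > 0
    em_max: int = 50         # maximum EM iterations
    eps: float = 1e-4        # convergence threshold, in (0, 0.001]

    def __post_init__(self) -> None:
        if not self.alpha > 1:
            raise ValueError("alpha must be > 1")
        if not self.beta > 0:
            raise ValueError("beta must be > 0")
        if not 0 < self.eps <= 1e-3:
            raise ValueError("eps must lie in (0, 0.001]")


@dataclass
class SufficientStats:
    """Posterior moments needed by the M-step.

    ``W1[s, i] = E[|dZ_{i,s}|^2 | Y]`` and ``Wx[s, i] = E[dZ_{i+1,s}
    conj(dZ_{i,s}) | Y]`` for i = 0..I-1 (so ``Wx[:, 0]`` couples the
    initial state to the first interval); ``W0`` is the initial-state
    second moment.
    """

    W1: np.ndarray
    Wx: np.ndarray
    W0: np.ndarray
    smooth_mean: np.ndarray
    posterior: IncrementPosterior
    loglik: float = np.nan   # penalized observed-data log-lik at the params used


@dataclass
class EMTrace:
    """Per-iteration record of the EM run."""

    params: list = field(default_factory=list)
    loglik: list = field(default_factory=list)
    conv: list = field(default_factory=list)
    n_iter: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "iteration": np.arange(1, self.n_iter + 1),
            "sigma_eps2": [p.sigma_eps2 for p in self.params],
            "mean_sigma_v2": [float(np.mean(p.sigma_v2)) for p in self.params],
            "convergence": self.conv,
            "penalized_loglik": self.loglik,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# --------------------------------------------------------------------------
def init_params(obs: SpectralObs, config: EMConfig | None = None) -> ModelParams:
    """Seed parameters from the data (Hadamard-square initial variances).

    ``dZ_{0,s}`` is the first-interval coefficient, ``sigma_{0,s}^2 =
    |dZ_{0,s}|^2``; the noise variances are seeded from halves of the mean
    squared first differences / magnitudes, floored.
    """
    z0 = obs.Y[:, 0].copy()
    sigma02 = np.maximum(np.abs(z0) ** 2, VARIANCE_FLOOR)
    d = np.diff(obs.Y, axis=1) if obs.I > 1 else obs.Y
    sigma_v2 = np.maximum(0.5 * np.mean(np.abs(d) ** 2, axis=1), VARIANCE_FLOOR)
    sigma_eps2 = max(0.5 * float(np.mean(np.abs(d) ** 2)), VARIANCE_FLOOR)
    return ModelParams(sigma_eps2=sigma_eps2, sigma_v2=sigma_v2, z0=z0,
                       sigma02=sigma02)


def penalized_loglik(obs: SpectralObs, params: ModelParams,
                     config: EMConfig) -> float:
    """Observed-data log-likelihood plus the log gamma priors (per line the
    innovation form of the Kalman filter), up to Theta-independent constants."""
    filt = _filter(obs.Y, params)
    F = params.sigma_eps2 + filt.pred_var
    innov = obs.Y - filt.pred_mean
    ll = float(np.sum(-np.log(np.pi * F) - np.abs(innov) ** 2 / F))
    tau_v = 1.0 / params.sigma_v2
    tau_e = 1.0 / params.sigma_eps2
    a, b = config.alpha, config.beta
    # effective gamma(alpha+1, beta+|z0|^2) prior on tau_v (see module doc)
    ll += float(np.sum(a * np.log(tau_v) - (b + np.abs(params.z0) ** 2) * tau_v))
    ll += (a - 1) * np.log(tau_e) - b * tau_e
    return ll


def e_step(obs: SpectralObs, params: ModelParams,
           config: EMConfig | None = None) -> SufficientStats:
    """Run filter/smoother/covariance smoother and assemble the moments."""
    post = posterior_moments(obs.Y, params)
    W1 = np.abs(post.smooth_mean) ** 2 + post.smooth_var
    W0 = np.abs(post.smooth_mean0) ** 2 + post.smooth_var0
    prev_mean = np.concatenate([post.smooth_mean0[:, None],
                                post.smooth_mean[:, :-1]], axis=1)
    Wx = post.smooth_mean * np.conj(prev_mean) + post.lag1
    ll = (penalized_loglik(obs, params, config) if config is not None
          else np.nan)
    return SufficientStats(W1=W1, Wx=Wx, W0=W0,
                           smooth_mean=post.smooth_mean, posterior=post,
                           loglik=ll)


def m_step(stats: SufficientStats, obs: SpectralObs, config: EMConfig,
           params: ModelParams) -> ModelParams:
    """Closed-form MAP precision updates (initial state held fixed)."""
    S, I = obs.Y.shape
    a, b = config.alpha, config.beta
    Wprev = np.concatenate([stats.W0[:, None], stats.W1[:, :-1]], axis=1)
    SS_v = np.sum(stats.W1 + Wprev - 2.0 * np.real(stats.Wx), axis=1)
    SS_v = np.maximum(SS_v, 0.0)
    tau_v = (I + a) / (SS_v + np.abs(params.z0) ** 2 + b)
    D = np.sum(np.abs(obs.Y) ** 2 + stats.W1
               - 2.0 * np.real(np.conj(obs.Y) * stats.smooth_mean))
    D = max(float(D), 0.0)
    tau_e = (S * I + a - 1) / (D + b)
    return ModelParams(
        sigma_eps2=max(1.0 / tau_e, VARIANCE_FLOOR),
        sigma_v2=np.maximum(1.0 / tau_v, VARIANCE_FLOOR),
        z0=params.z0, sigma02=params.sigma02)


def run_em(obs: SpectralObs, config: EMConfig | None = None,
           init: ModelParams | None = None
           ) -> tuple[ModelParams, IncrementPosterior, EMTrace]:
    """Alternate E/M steps until the smoothed increments stabilize.

    Stops when ``sum |dZ^it - dZ^{it-1}|^2 / sum |dZ^{it-1}|^2 < eps`` or at
    ``em_max`` iterations; the returned posterior is recomputed under the
    final parameters.
    """
    cfg = config or EMConfig()
    if cfg.em_max < 1:
        raise ValueError("em_max must be >= 1")
    params = init if init is not None else init_params(obs, cfg)
    trace = EMTrace()
    prev_mean = None
    for it in range(cfg.em_max):
        stats = e_step(obs, params, cfg)
        new_params = m_step(stats, obs, cfg, params)
        if prev_mean is None:
            conv = np.inf
        else:
            denom = float(np.sum(np.abs(prev_mean) ** 2))
            conv = (float(np.sum(np.abs(stats.smooth_mean - prev_mean) ** 2))
                    / max(denom, VARIANCE_FLOOR))
        trace.params.append(params)
        trace.loglik.append(stats.loglik)
        trace.conv.append(conv)
        trace.n_iter = it + 1
        prev_mean = stats.smooth_mean
        params = new_params
        if conv < cfg.eps:
            break
    posterior = posterior_moments(obs.Y, params)
    return params, posterior, trace
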
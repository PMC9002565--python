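import numpy as np
import pytest

import besct as B
from besct.statespace import (IntervalGrid, SpectralObs, posterior_moments,
                              _filter)
from conftest import batch_posterior_oracle


def random_line_problem(rng, I=None):
    I = I if I is not None else int(rng.integers(2, 9))
    params = B.ModelParams(
        sigma_eps2=float(rng.uniform(0.1, 2.0)),
        sigma_v2=np.array([rng.uniform(0.1, 2.0)]),
        z0=np.array([rng.normal() + 1j * rng.normal()]),
        sigma02=np.array([rng.uniform(0.0, 2.0)]),
    )
    y = rng.normal(size=I) + 1j * rng.normal(size=I)
    return y, params


# ------------------------------------------------------------------ filter
def test_filter_degenerate_prior_keeps_initial_state():
    params = B.ModelParams(1.0, np.array([1e-12]), np.array([2 + 1j]),
                           np.array([0.0]))
    stats = B.kalman_filter_line(np.ones(5, complex), params)
    assert np.all(stats.gain < 1e-10)
    assert np.allclose(stats.filt_mean, 2 + 1j, atol=1e-9)


def test_filter_noiseless_limit_tracks_observations():
    rng = np.random.default_rng(0)
    y = rng.normal(size=6) + 1j * rng.normal(size=6)
    params = B.ModelParams(1e-14, np.array([1.0]), np.array([0j]),
                           np.array([1.0]))
    stats = B.kalman_filter_line(y, params)
    assert np.allclose(stats.gain, 1.0, atol=1e-10)
    assert np.allclose(stats.filt_mean[0], y, atol=1e-6)


def test_filter_rejects_nonpositive_observation_noise():
    with pytest.raises(ValueError):
        B.ModelParams(0.0, np.array([1.0]), np.array([0j]), np.array([1.0]))


@pytest.mark.parametrize("seed", range(10))
def test_smoother_matches_batch_gaussian_oracle(seed):
    """Filter/smoother/lag-covariances equal the joint posterior solve."""
    rng = np.random.default_rng(seed)
    y, p = random_line_problem(rng)
    post = posterior_moments(y[None, :], p)
    mean, cov = batch_posterior_oracle(y, p.sigma_eps2, p.sigma_v2[0],
                                       p.z0[0], p.sigma02[0])
    assert np.allclose(post.smooth_mean[0], mean, atol=1e-10)
    assert np.allclose(post.smooth_var[0], np.diag(cov).real, atol=1e-10)
    if y.size > 1:
        assert np.allclose(post.lag1[0, 1:], np.diag(cov, 1).real, atol=1e-10)


def test_smoother_initializes_at_filtered_endpoint():
    rng = np.random.default_rng(3)
    y, p = random_line_problem(rng, I=5)
    filt = B.kalman_filter_line(y, p)
    post = B.smooth_line(filt, p)
    assert post.smooth_mean[0, -1] == filt.filt_mean[0, -1]
    assert post.smooth_var[0, -1] == filt.filt_var[0, -1]


def test_smoother_zero_state_noise_shrinks_to_single_state():
    """sigma_v^2 -> 0: all smoothed means coincide (complex LS oracle)."""
    rng = np.random.default_rng(4)
    I = 6
    y = rng.normal(size=I) + 1j * rng.normal(size=I)
    se2, s02 = 0.5, 2.0
    p = B.ModelParams(se2, np.array([1e-12]), np.array([0.3 + 0.1j]),
                      np.array([s02]))
    post = posterior_moments(y[None, :], p)
    assert np.allclose(post.smooth_mean[0], post.smooth_mean[0, 0], atol=1e-4)
    # oracle: posterior of one shared state given I obs and CN(z0, s02) prior
    expected = (np.sum(y) / se2 + p.z0[0] / s02) / (I / se2 + 1 / s02)
    assert np.allclose(post.smooth_mean[0], expected, atol=1e-4)


def test_variance_orderings_hold_on_random_instances():
    rng = np.random.default_rng(5)
    for _ in range(20):
        y, p = random_line_problem(rng)
        post = posterior_moments(y[None, :], p)
        assert np.all(post.gain >= 0) and np.all(post.gain < 1)
        assert np.all(post.smooth_var <= post.filt_var + 1e-12)
        assert np.all(post.filt_var <= post.pred_var + 1e-12)
        assert np.all(post.smooth_var >= 0)


# ----------------------------------------------------------- covariances
def test_lag_covariance_cauchy_schwarz_and_zero_gain():
    rng = np.random.default_rng(6)
    y, p = random_line_problem(rng, I=7)
    post = posterior_moments(y[None, :], p)
    lag = B.lag_covariances(post)
    bound = np.sqrt(post.smooth_var[0, :-1] * post.smooth_var[0, 1:])
    assert np.all(np.abs(lag[0, 1:]) <= bound + 1e-12)
    # degenerate prior: A_0 = 0 so cov(dZ_0, dZ_1) = 0
    p0 = B.ModelParams(1.0, np.array([1.0]), np.array([0j]), np.array([0.0]))
    post0 = posterior_moments(y[None, :], p0)
    assert post0.lag1[0, 0] == pytest.approx(0.0, abs=1e-12)


def test_general_lag_covariance_consistent_with_lag_one():
    rng = np.random.default_rng(7)
    y, p = random_line_problem(rng, I=6)
    post = posterior_moments(y[None, :], p)
    for i in range(1, 6):
        assert B.lag_covariance(post, i, i + 1)[0] == pytest.approx(
            post.lag1[0, i], abs=1e-12)
    mean, cov = batch_posterior_oracle(y, p.sigma_eps2, p.sigma_v2[0],
                                       p.z0[0], p.sigma02[0])
    assert B.lag_covariance(post, 2, 5)[0] == pytest.approx(
        cov[1, 4].real, abs=1e-9)


# -------------------------------------------------------------- sampling
def test_sampling_degenerate_posterior_returns_smoothed_mean():
    p = B.ModelParams(1e-12, np.array([1e-12]), np.array([1 + 1j]),
                      np.array([1e-12]))
    y = np.full(4, 1 + 1j)
    post = posterior_moments(y[None, :], p)
    draws = B.sample_posterior(post, p, 8, seed=0)
    assert np.allclose(draws, post.smooth_mean[None], atol=1e-5)


def test_sampling_moments_match_smoother():
    rng = np.random.default_rng(8)
    y, p = random_line_problem(rng, I=5)
    post = posterior_moments(y[None, :], p)
    draws = B.sample_posterior(post, p, 10_000, seed=1)
    se = np.sqrt(post.smooth_var[0] / 10_000)
    assert np.all(np.abs(draws.mean(0)[0] - post.smooth_mean[0]) < 3.5 * se)
    centered = draws[:, 0, :] - post.smooth_mean[0]
    lag_mc = np.mean(centered[:, 1:] * np.conj(centered[:, :-1]), axis=0)
    scale = np.sqrt(post.smooth_var[0, 1:] * post.smooth_var[0, :-1])
    assert np.all(np.abs(lag_mc - post.lag1[0, 1:]) < 4.5 * scale / 100)


# ------------------------------------------------- observations / surface
def test_build_observations_shapes_and_zero_signal():
    z = B.TimeSeries(np.zeros(500), 100.0)
    grid = IntervalGrid.for_record(500, 25)
    obs = B.build_observations(z, grid, B.SCTConfig(n_lines=64))
    assert obs.Y.shape == (64, 20)
    assert not np.any(obs.Y)


def test_build_observations_tone_is_stationary():
    t = np.arange(1001) / 100.0
    ts = B.TimeSeries(np.sin(2 * np.pi * 10 * t), 100.0)
    grid = IntervalGrid.for_record(1001, 50)
    obs = B.build_observations(ts, grid, B.SCTConfig(n_lines=128))
    line = np.argmin(np.abs(obs.freqs - 10.0))
    mags = np.abs(obs.Y[line, 2:-2])  # boundary windows are truncated
    assert mags.std() / mags.mean() < 0.05


def test_build_observations_grid_mismatch_rejected():
    z = B.TimeSeries(np.zeros(100), 100.0)
    with pytest.raises(ValueError):
        B.build_observations(z, IntervalGrid(J=40, I=3), B.SCTConfig())


def test_interval_grid_validation():
    with pytest.raises(ValueError):
        IntervalGrid(J=10, I=1)
    with pytest.raises(ValueError):
        IntervalGrid.for_record(15, 10)


def test_denoised_spectrogram_is_smoothed_means():
    rng = np.random.default_rng(9)
    Y = rng.normal(size=(3, 6)) + 1j * rng.normal(size=(3, 6))
    p = B.ModelParams(1.0, np.ones(3), Y[:, 0].copy(), np.ones(3))
    post = posterior_moments(Y, p)
    tfr = B.denoised_spectrogram(post, np.arange(3.0), np.arange(6.0))
    assert tfr.shape == (3, 6)
    assert np.array_equal(tfr.coeffs, post.smooth_mean)
    zero = posterior_moments(np.zeros((2, 5), complex),
                             B.ModelParams(1.0, np.ones(2),
                                           np.zeros(2, complex), np.ones(2)))
    assert not np.any(B.denoised_spectrogram(zero, np.arange(2.0),
                                             np.arange(5.0)).coeffs)
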
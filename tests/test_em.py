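import numpy as np
import pytest
from scipy.optimize import minimize_scalar

import besct as B
from besct.em import EMConfig, e_step, init_params, m_step, run_em
from besct.statespace import IntervalGrid, SpectralObs, posterior_moments


def make_obs(Y):
    S, I = Y.shape
    return SpectralObs(Y=Y, freqs=np.arange(S, dtype=float),
                       grid=IntervalGrid(J=1, I=I),
                       times=np.arange(I, dtype=float))


def random_obs(rng, S=4, I=6, scale=1.0):
    Y = scale * (rng.normal(size=(S, I)) + 1j * rng.normal(size=(S, I)))
    return make_obs(Y)


def simulate_random_walk(rng, S, I, sigma_v2, sigma_eps2):
    def crandn(*sh):
        return (rng.standard_normal(sh) + 1j * rng.standard_normal(sh)) \
            / np.sqrt(2)

    z0 = crandn(S)
    dz = z0[:, None] + np.cumsum(crandn(S, I) * np.sqrt(sigma_v2), axis=1)
    return make_obs(dz + crandn(S, I) * np.sqrt(sigma_eps2))


# -------------------------------------------------------------- init/e-step
def test_init_params_zero_observations_floored():
    obs = make_obs(np.zeros((3, 4), complex))
    p = init_params(obs)
    assert np.all(p.z0 == 0)
    assert np.all(p.sigma02 == 1e-12)
    assert p.sigma_eps2 > 0 and np.all(p.sigma_v2 > 0)


def test_init_params_dominant_line_gets_largest_initial_variance():
    rng = np.random.default_rng(0)
    Y = 0.01 * (rng.normal(size=(5, 6)) + 1j * rng.normal(size=(5, 6)))
    Y[2] += 10.0
    p = init_params(make_obs(Y))
    assert np.argmax(p.sigma02) == 2
    assert np.allclose(p.sigma02, np.abs(p.z0) ** 2, atol=1e-15)


def test_e_step_degenerate_model_moments_are_products_of_means():
    """Zero posterior variance: W1 = |mean|^2, Wx = mean products."""
    Y = np.full((2, 4), 1.0 + 1.0j)
    p = B.ModelParams(1e-12, np.full(2, 1e-12), Y[:, 0].copy(),
                      np.full(2, 1e-12))
    stats = e_step(make_obs(Y), p)
    assert np.allclose(stats.W1, np.abs(stats.smooth_mean) ** 2, atol=1e-6)
    prev = np.c_[stats.posterior.smooth_mean0, stats.smooth_mean[:, :-1]]
    assert np.allclose(stats.Wx, stats.smooth_mean * np.conj(prev), atol=1e-6)


def test_e_step_invariants_on_random_instances():
    rng = np.random.default_rng(1)
    for _ in range(10):
        obs = random_obs(rng)
        p = init_params(obs)
        stats = e_step(obs, p)
        assert np.all(stats.W1 >= np.abs(stats.smooth_mean) ** 2 - 1e-12)
        Wprev = np.c_[stats.W0, stats.W1[:, :-1]]
        assert np.all(np.abs(stats.Wx) <= np.sqrt(stats.W1 * Wprev) + 1e-9)


def test_e_step_second_moment_matches_monte_carlo():
    rng = np.random.default_rng(2)
    obs = random_obs(rng, S=2, I=5)
    p = init_params(obs)
    stats = e_step(obs, p)
    draws = B.sample_posterior(stats.posterior, p, 20_000, seed=3)
    W_mc = np.mean(np.abs(draws) ** 2, axis=0)
    assert np.allclose(W_mc, stats.W1, rtol=0.05, atol=0.02)


# ------------------------------------------------------------------ m-step
def test_m_step_matches_numeric_maximization_oracle():
    """Closed-form precision updates maximize the penalized Q function."""
    rng = np.random.default_rng(4)
    obs = random_obs(rng, S=3, I=4)
    cfg = EMConfig(alpha=3.0, beta=1e-3)
    p = init_params(obs, cfg)
    stats = e_step(obs, p)
    new = m_step(stats, obs, cfg, p)
    S, I = obs.Y.shape

    Wprev = np.c_[stats.W0, stats.W1[:, :-1]]
    SS_v = np.sum(stats.W1 + Wprev - 2 * np.real(stats.Wx), axis=1)
    for s in range(S):
        def neg_q_v(tau, s=s):
            return -((I + cfg.alpha) * np.log(tau)
                     - tau * (SS_v[s] + np.abs(p.z0[s]) ** 2 + cfg.beta))
        res = minimize_scalar(neg_q_v, bounds=(1e-8, 1e8), method="bounded",
                              options={"xatol": 1e-12})
        assert 1.0 / new.sigma_v2[s] == pytest.approx(res.x, rel=1e-6)

    D = float(np.sum(np.abs(obs.Y) ** 2 + stats.W1
                     - 2 * np.real(np.conj(obs.Y) * stats.smooth_mean)))

    def neg_q_eps(tau):
        return -((S * I + cfg.alpha - 1) * np.log(tau)
                 - tau * (D + cfg.beta))
    res = minimize_scalar(neg_q_eps, bounds=(1e-8, 1e8), method="bounded",
                          options={"xatol": 1e-12})
    assert 1.0 / new.sigma_eps2 == pytest.approx(res.x, rel=1e-6)


def test_m_step_vanishing_prior_reduces_to_maximum_likelihood():
    """alpha -> 1+, beta -> 0+: updates become mean residual moments."""
    rng = np.random.default_rng(5)
    obs = random_obs(rng, S=3, I=8)
    cfg = EMConfig(alpha=1.0 + 1e-9, beta=1e-12)
    p = init_params(obs, cfg)
    stats = e_step(obs, p)
    new = m_step(stats, obs, cfg, p)
    S, I = obs.Y.shape
    Wprev = np.c_[stats.W0, stats.W1[:, :-1]]
    SS_v = np.sum(stats.W1 + Wprev - 2 * np.real(stats.Wx), axis=1)
    # ML for the state precision counts the I transitions plus the
    # initial-state factor of the complete-data likelihood
    assert np.allclose(new.sigma_v2,
                       (SS_v + np.abs(p.z0) ** 2) / (I + 1), rtol=1e-6)
    D = float(np.sum(np.abs(obs.Y) ** 2 + stats.W1
                     - 2 * np.real(np.conj(obs.Y) * stats.smooth_mean)))
    assert new.sigma_eps2 == pytest.approx(D / (S * I), rel=1e-6)


def test_em_recovers_simulation_variances():
    """sigma_v^2 = 0.5, sigma_eps^2 = 0.1, I = 200, S = 8, 20 seeds:
    median relative error of both variances below 25%."""
    errs_v, errs_e = [], []
    cfg = EMConfig(eps=1e-9, em_max=200)
    for seed in range(20):
        rng = np.random.default_rng(100 + seed)
        obs = simulate_random_walk(rng, S=8, I=200, sigma_v2=0.5,
                                   sigma_eps2=0.1)
        params, _, _ = run_em(obs, cfg)
        errs_v.append(abs(float(np.median(params.sigma_v2)) - 0.5) / 0.5)
        errs_e.append(abs(params.sigma_eps2 - 0.1) / 0.1)
    assert np.median(errs_v) < 0.25
    assert np.median(errs_e) < 0.25


# ------------------------------------------------------------------ run_em
def test_run_em_single_iteration_budget():
    rng = np.random.default_rng(6)
    obs = random_obs(rng)
    _, _, trace = run_em(obs, EMConfig(em_max=1))
    assert trace.n_iter == 1
    with pytest.raises(ValueError):
        run_em(obs, EMConfig(em_max=0))


@pytest.mark.parametrize("seed", range(5))
def test_em_objective_monotone(seed):
    """The penalized observed-data log-likelihood never decreases."""
    rng = np.random.default_rng(10 + seed)
    obs = random_obs(rng, S=5, I=12, scale=rng.uniform(0.3, 3.0))
    _, _, trace = run_em(obs, EMConfig(eps=1e-9, em_max=40))
    ll = np.asarray(trace.loglik)
    assert np.all(np.diff(ll) >= -1e-8)


def test_em_converges_on_noisy_benchmark_signal(ex1_noisy):
    grid = IntervalGrid.for_record(len(ex1_noisy), 10)
    obs = B.build_observations(ex1_noisy, grid, B.SCTConfig(n_lines=64))
    _, _, trace = run_em(obs, EMConfig(em_max=50))
    assert trace.n_iter < 50
    assert trace.conv[-1] < 1e-4


def test_em_fixed_point_near_truth():
    """Starting EM at the generating parameters moves them by < 10%."""
    rng = np.random.default_rng(42)
    obs = simulate_random_walk(rng, S=8, I=400, sigma_v2=0.5, sigma_eps2=0.1)
    cfg = EMConfig()
    truth = B.ModelParams(0.1, np.full(8, 0.5), obs.Y[:, 0].copy(),
                          np.abs(obs.Y[:, 0]) ** 2)
    stats = e_step(obs, truth, cfg)
    new = m_step(stats, obs, cfg, truth)
    assert abs(new.sigma_eps2 - 0.1) / 0.1 < 0.10
    assert abs(float(np.median(new.sigma_v2)) - 0.5) / 0.5 < 0.10


def test_em_trace_export(tmp_path):
    rng = np.random.default_rng(7)
    _, _, trace = run_em(random_obs(rng), EMConfig(em_max=5, eps=1e-9))
    path = tmp_path / "trace.csv"
    trace.to_csv(path)
    import pandas as pd
    df = pd.read_csv(path)
    assert list(df.columns) == ["iteration", "sigma_eps2", "mean_sigma_v2",
                                "convergence", "penalized_loglik"]
    assert len(df) == trace.n_iter
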
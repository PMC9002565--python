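import itertools

import numpy as np
import pytest

import besct as B
from besct.sct import SCTConfig


def tone(freq=10.0, fs=100.0, n=1001):
    return B.TimeSeries(np.sin(2 * np.pi * freq * np.arange(n) / fs), fs)


# ----------------------------------------------------------------- stft/sct
def test_stft_zero_signal_and_linearity():
    z = B.TimeSeries(np.zeros(500) + 0.0, 100.0)
    assert not np.any(B.stft(z).coeffs)
    a, b = tone(10), tone(17)
    s = B.TimeSeries(a.values + b.values, 100.0)
    assert np.allclose(B.stft(s).coeffs,
                       B.stft(a).coeffs + B.stft(b).coeffs, atol=1e-9)


def test_stft_tone_peaks_at_tone_frequency():
    T = B.stft(tone(10.0))
    df = T.freqs[1] - T.freqs[0]
    assert np.all(np.abs(T.ridge_argmax() - 10.0) <= df + 1e-12)


def test_stft_too_short_signal_names_minimum():
    with pytest.raises(ValueError, match="401"):
        B.stft(B.TimeSeries(np.ones(100), 100.0), window_sd=0.5)


def test_sct_zero_kernel_equals_stft_exactly(ex1_noisy):
    k0 = B.SplineIFKernel.zero(0.0, 10.0)
    assert np.array_equal(B.sct(ex1_noisy, k0).coeffs,
                          B.stft(ex1_noisy).coeffs)


def test_sct_matched_linear_chirp_ridge():
    """10->30 Hz chirp with matched linear kernel: ridge within one bin."""
    fs, n = 100.0, 1001
    t = np.arange(n) / fs
    chirp = B.TimeSeries(np.sin(2 * np.pi * (10 * t + 1.0 * t**2)), fs)
    kernel = B.SplineIFKernel.from_function(lambda u: 10 + 2 * u, 0, 10, 8)
    T = B.sct(chirp, kernel)
    df = T.freqs[1] - T.freqs[0]
    assert np.all(np.abs(T.ridge_argmax() - (10 + 2 * T.times)) <= df + 1e-9)


def test_sct_aliasing_kernel_warns(ex2_clean):
    kernel = B.SplineIFKernel.from_function(
        lambda t: B.true_if("example2", t), 0, 10, 16)
    with pytest.warns(UserWarning, match="Nyquist"):
        B.sct(ex2_clean, kernel)


# -------------------------------------------------------------------- ridge
def brute_force_ridge(mag, penalty):
    best, best_score = None, -np.inf
    S, C = mag.shape
    for path in itertools.product(range(S), repeat=C):
        score = sum(mag[s, i] for i, s in enumerate(path))
        score -= penalty * sum(abs(path[i + 1] - path[i])
                               for i in range(C - 1))
        if score > best_score:
            best, best_score = path, score
    return np.array(best)


@pytest.mark.parametrize("seed", range(6))
def test_ridge_matches_exhaustive_enumeration(seed):
    rng = np.random.default_rng(seed)
    S, C = rng.integers(2, 7), rng.integers(2, 7)
    mag = rng.random((S, C))
    tfr = B.TFR(times=np.arange(C) * 0.1, freqs=np.arange(S) * 1.0,
                coeffs=mag.astype(complex))
    penalty = rng.uniform(0.0, 0.5)
    track = B.extract_ridge(tfr, penalty)
    expected = brute_force_ridge(mag, penalty)
    assert np.array_equal(track[:, 1], tfr.freqs[expected])


def test_ridge_follows_stronger_tone():
    s = B.TimeSeries(10 * tone(10).values + tone(30).values, 100.0)
    track = B.extract_ridge(B.stft(s))
    assert np.all(np.abs(track[:, 1] - 10.0) < 1.0)


def test_ridge_zero_penalty_is_columnwise_argmax():
    rng = np.random.default_rng(1)
    mag = rng.random((12, 9))
    tfr = B.TFR(np.arange(9.0), np.arange(12.0), mag.astype(complex))
    track = B.extract_ridge(tfr, jump_penalty=0.0)
    assert np.array_equal(track[:, 1], tfr.freqs[np.argmax(mag, axis=0)])


def test_ridge_all_zero_tfr_rejected():
    tfr = B.TFR(np.arange(3.0), np.arange(4.0), np.zeros((4, 3), complex))
    with pytest.raises(ValueError):
        B.extract_ridge(tfr)


# -------------------------------------------------------------- spline fit
def test_spline_fit_constant_track():
    track = np.c_[np.linspace(0, 10, 40), np.full(40, 34.2)]
    kernel = B.fit_spline_kernel(track, 8)
    assert kernel.residual == pytest.approx(0.0, abs=1e-9)
    assert np.allclose(kernel(np.linspace(0, 10, 100)), 34.2, atol=1e-8)


def test_spline_fit_reproduces_cubic():
    t = np.linspace(0, 10, 60)
    track = np.c_[t, 1 + 0.5 * t - 0.2 * t**2 + 0.03 * t**3]
    assert B.fit_spline_kernel(track, 4).residual < 1e-8


def test_spline_residual_nonincreasing_on_nested_knots():
    """Dyadic knot refinements nest, so the residual cannot grow."""
    rng = np.random.default_rng(2)
    t = np.linspace(0, 10, 120)
    track = np.c_[t, np.sin(t) + 0.1 * rng.standard_normal(t.size)]
    resids = [B.fit_spline_kernel(track, n).residual for n in (3, 5, 9, 17)]
    assert all(b <= a + 1e-10 for a, b in zip(resids, resids[1:]))


def test_spline_fit_degenerate_track_rejected():
    with pytest.raises(ValueError):
        B.fit_spline_kernel(np.c_[np.full(10, 2.0), np.arange(10.0)], 4)


# -------------------------------------------------------------- refinement
def test_iterate_sct_pure_tone_converges_immediately():
    ref = B.iterate_sct(tone(12.0), n_iter=1)
    kappa = ref.kernel(np.linspace(0.2, 9.8, 50))
    assert np.all(np.abs(kappa - 12.0) < 0.3)


def test_iterate_sct_tone_segment_recovers_34p2(ex1_clean):
    seg = B.TimeSeries(ex1_clean.values[600:], 100.0, start_time=6.0)
    ref = B.iterate_sct(seg, n_iter=2)
    kappa = ref.kernel(seg.times)
    assert np.all(np.abs(kappa - 34.2) < 0.5)


def test_iterate_sct_rms_diagnostic_nonincreasing(ex1_clean):
    ref = B.iterate_sct(ex1_clean, n_iter=3)
    assert len(ref.rms_history) == 3
    assert all(b <= a + 1e-9 for a, b in
               zip(ref.rms_history, ref.rms_history[1:]))


def test_iterated_ridge_recovers_analytic_if(ex1_clean):
    """>=95% of columns within 0.5 Hz of the true IF, switch excluded."""
    ref = B.iterate_sct(ex1_clean, n_iter=3)
    ridge = ref.tfr.ridge_argmax()
    truth = B.true_if("example1", np.clip(ref.tfr.times, 0, 10))
    keep = np.abs(ref.tfr.times - 6.0) > 0.5
    frac = np.mean(np.abs(ridge - truth)[keep] < 0.5)
    assert frac >= 0.95


# ----------------------------------------------------------------- entropy
def test_renyi_entropy_closed_forms():
    one = np.zeros((4, 4), complex)
    one[2, 1] = 3.0
    assert B.renyi_entropy(B.TFR(np.arange(4.0), np.arange(4.0), one)) == \
        pytest.approx(0.0, abs=1e-12)
    uniform = np.full((8, 4), 0.7, complex)
    assert B.renyi_entropy(B.TFR(np.arange(4.0), np.arange(8.0), uniform)) == \
        pytest.approx(np.log2(32), abs=1e-10)
    with pytest.raises(ValueError):
        B.renyi_entropy(B.TFR(np.arange(2.0), np.arange(2.0),
                              np.zeros((2, 2), complex)))


def test_matched_kernel_concentrates_chirp_energy():
    fs, n = 100.0, 1001
    t = np.arange(n) / fs
    chirp = B.TimeSeries(np.sin(2 * np.pi * (10 * t + 1.5 * t**2)), fs)
    kernel = B.SplineIFKernel.from_function(lambda u: 10 + 3 * u, 0, 10, 8)
    assert (B.renyi_entropy(B.sct(chirp, kernel))
            < B.renyi_entropy(B.stft(chirp)))
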
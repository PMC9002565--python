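# besct

Empirical-Bayes spline-chirplet spectrograms and spectrum-aware video
motion magnification.

`besct` is for researchers who need to (a) track sharply time-varying
frequency content in noisy nonstationary 1-D signals — physiological
rhythms, structural vibrations, bio-acoustic recordings — and (b) amplify
subtle periodic motions in video (micro-vibrations, pulsation) without the
large motions in the scene destroying the result.

## The model

A record `y_t = x_t + eps_t` is split into `I` stationary intervals.  On
interval `i`, the complex amplitude of `x_t` at frequency line `omega_s`
(the spectral increment `dZ_{i,s}`) is observed through a spline-kerneled
chirplet coefficient and evolves as a random walk:

    Y_{i,s}  = dZ_{i,s}  + eps_{i,s},   eps ~ CN(0, sigma_eps^2)
    dZ_{i,s} = dZ_{i-1,s} + v_{i,s},    v   ~ CN(0, sigma_{v,s}^2)

Each line is solved exactly by a 1-D complex Kalman filter and
fixed-interval smoother; the variances are estimated from the data by EM
with gamma priors on the precisions, making the smoothed surface an
empirical-Bayes estimate.  The chirplet kernel — a cubic-spline model of
instantaneous frequency fitted by iterated ridge extraction — concentrates
components with nonlinearly varying frequency into sharp ridges before the
statistical machinery ever sees them.

The video pipeline builds a global-motion signal (per-frame 1-D earth
mover's distance of intensity marginals against the first frame), fits the
same spectrogram model to it, thresholds the denoised surface into
per-interval frequency passbands, and amplifies only those bands with a
phase-based complex-steerable-pyramid magnifier (in-band motion of
amplitude `a` comes out at `(1 + alpha) a`).

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```python
import besct as B

# a noisy benchmark signal: sinusoidal FM switching to a 34.2 Hz tone
clean = B.gen_example("example1")           # 1001 samples at 100 Hz
noisy = B.add_noise(clean, 0.1, seed=7)
print(f"SNR: {B.snr_db(clean, noisy):.2f} dB")

res = B.BESCT(noisy).fit()
print(res.summary())
```

prints (exact EM figures vary with the noise seed):

```
SNR: 7.10 dB
Empirical-Bayes spline-chirplet spectrogram (BE-SCT)
========================================================
samples: 1001   fs: 100 Hz   duration: 10 s
intervals: I = 100  x  J = 10 samples
frequency lines: S = 256 on [0, 50] Hz
kernel: cubic spline IF
EM iterations: 13   final convergence stat: 8.14e-05
--------------------------------------------------------
sigma_eps^2 (observation noise): 30.354
sigma_v^2 (state noise) min/median/max: 1.971 / 5.96 / 1.168e+04
penalized log-likelihood: -178898
--------------------------------------------------------
Renyi entropy (order 3): raw 9.042 bits, denoised 8.794 bits
```

The SNR sits at the ~7 dB level expected for variance-0.1 noise on a unit
sine; the denoised surface is more concentrated than the raw transform
(lower entropy), and its columnwise ridge

```python
import numpy as np
ridge = res.ridge()                          # Hz, one value per interval
truth = B.true_if("example1", np.clip(res.denoised_tfr.times, 0, 10))
keep = np.abs(res.denoised_tfr.times - 6.0) > 0.5   # skip the jump
print(f"within 1 Hz of truth: {np.mean(np.abs(ridge-truth)[keep] < 1):.0%}")
```

```
within 1 Hz of truth: 99%
```

tracks the analytic instantaneous frequency (25 + 10 cos t Hz, then
34.2 Hz) at 99% of columns away from the t = 6 s switch.

For video, the same flow from the shell:

```sh
besct simulate-ball --out ball/            # drifting + vibrating disc
besct magnify --in ball/input --out mag --fps 30 --alpha 1
besct evaluate --ref ball/ground_truth --test mag/frames --out metrics.csv
```

The magnify step writes the motion series, its denoised spectrum, the
passband schedule (which covers the 3 Hz vibration and excludes the drift
band) and the amplified frames; `evaluate` reports mean PSNR/MAE against
the ground-truth clip.

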
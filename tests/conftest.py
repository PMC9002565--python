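import numpy as np
import pytest

import besct as B
from besct.evaluation import BallConfig, gen_ball_video
from besct.magnify import MagConfig, magnify
from besct.specfilter import PassbandSchedule


@pytest.fixture(scope="session")
def ex1_clean():
    return B.gen_example("example1")


@pytest.fixture(scope="session")
def ex1_noisy():
    return B.add_noise(B.gen_example("example1"), 0.1, seed=7)


@pytest.fixture(scope="session")
def ex2_clean():
    return B.gen_example("example2")


@pytest.fixture(scope="session")
def ball_pair():
    """Default drifting/vibrating ball clip and its ground truth."""
    return gen_ball_video(BallConfig())


@pytest.fixture(scope="session")
def small_ball():
    """A shorter, smaller ball clip for per-module magnification tests."""
    cfg = BallConfig(height=96, width=192, n_frames=90)
    return gen_ball_video(cfg)


@pytest.fixture(scope="session")
def vibration_band_schedule():
    return PassbandSchedule(times=np.array([0.0]), bands=[[(2.5, 3.5)]])


@pytest.fixture(scope="session")
def magnified_alpha5(ball_pair, vibration_band_schedule):
    video, _ = ball_pair
    return magnify(video, vibration_band_schedule, MagConfig(alpha=5.0))


@pytest.fixture(scope="session")
def magnified_alpha0(ball_pair, vibration_band_schedule):
    video, _ = ball_pair
    return magnify(video, vibration_band_schedule, MagConfig(alpha=0.0))


def batch_posterior_oracle(y, sigma_eps2, sigma_v2, z0, sigma02):
    """Exact joint complex-Gaussian posterior of the random-walk model.

    Prior over the I latent increments: mean z0, covariance
    sigma02 + sigma_v2 * min(i, j) (1-based).  Returns (mean, covariance).
    """
    y = np.asarray(y, complex).ravel()
    I = y.size
    ii = np.arange(1, I + 1)
    P = sigma02 + sigma_v2 * np.minimum.outer(ii, ii)
    Pinv = np.linalg.inv(P)
    cov = np.linalg.inv(Pinv + np.eye(I) / sigma_eps2)
    mean = cov @ (Pinv @ np.full(I, z0, complex) + y / sigma_eps2)
    return mean, cov
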
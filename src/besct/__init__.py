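"""Spline-kerneled chirplet analysis with empirical-Bayes denoising and
spectrum-aware video motion magnification."""

from .timeseries import TimeSeries
from .tfr import TFR
from .sct import (SCTConfig, SplineIFKernel, extract_ridge, fit_spline_kernel,
                  iterate_sct, renyi_entropy, sct, stft)
from .statespace import (IncrementPosterior, IntervalGrid, ModelParams,
                         SpectralObs, build_observations, denoised_spectrogram,
                         kalman_filter_line, lag_covariance, lag_covariances,
                         sample_posterior, smooth_line)
from .em import EMConfig, EMTrace, SufficientStats, e_step, init_params, m_step, run_em
from .testsignals import (NoiseSpec, SignalSpec, add_noise, gen_example,
                          snr_db, true_if)
from .video import VideoSequence, color_convert, luminance
from .motion import FrameSignature, MotionSeries, emd_1d, emod_series, frame_signature
from .specfilter import (PassbandSchedule, Thresholds, WeightMask, auto_rho_h,
                         build_weight, passbands_from_mask, split_components)
from .pyramid import PyramidCoeffs, SteerablePyramid
from .magnify import MagConfig, magnify, temporal_bandpass
from .evaluation import (BallConfig, MetricReport, centroid_trace,
                         fit_sine_amplitude, gen_ball_video, mae,
                         metric_report, psnr)

__all__ = [
    "TimeSeries", "TFR",
    "SCTConfig", "SplineIFKernel", "stft", "sct", "extract_ridge",
    "fit_spline_kernel", "iterate_sct", "renyi_entropy",
    "IntervalGrid", "SpectralObs", "ModelParams", "IncrementPosterior",
    "build_observations", "kalman_filter_line", "smooth_line",
    "lag_covariances", "lag_covariance", "sample_posterior",
    "denoised_spectrogram",
    "EMConfig", "EMTrace", "SufficientStats", "init_params", "e_step",
    "m_step", "run_em",
    "SignalSpec", "NoiseSpec", "gen_example", "add_noise", "snr_db", "true_if",
    "VideoSequence", "color_convert", "luminance",
    "FrameSignature", "MotionSeries", "frame_signature", "emd_1d", "emod_series",
    "Thresholds", "WeightMask", "PassbandSchedule", "build_weight",
    "split_components", "passbands_from_mask", "auto_rho_h",
    "SteerablePyramid", "PyramidCoeffs",
    "MagConfig", "magnify", "temporal_bandpass",
    "BallConfig", "MetricReport", "gen_ball_video", "centroid_trace",
    "fit_sine_amplitude", "psnr", "mae", "metric_report",
    "BESCT", "BESCTResults",
]

__version__ = "0.1.0"


def __getattr__(name):
    # deferred to avoid importing matplotlib-dependent modules eagerly
    if name in ("BESCT", "BESCTResults"):
        from . import model
        return getattr(model, name)
    raise AttributeError(name)
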
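"""Top-level workflows: signal analysis and video magnification.

Both workflows consume a :class:`RunConfig`, validate it, write their
artifacts next to the requested output prefix and serialize the resolved
configuration alongside so a run can be reproduced bit-for-bit.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .magnify import MagConfig, magnify
from .model import BESCT
from .motion import emod_series
from .specfilter import (Thresholds, auto_rho_h, build_weight,
                         passbands_from_mask)
from .timeseries import TimeSeries
from .video import VideoSequence

__all__ = ["RunConfig", "analyze_signal", "magnify_video"]

log = logging.getLogger("besct")


@dataclass
class RunConfig:
    """All tunables of a pipeline run, serializable to JSON."""

    # I/O
    input_path: str = ""
    output_dir: str = "."
    fps: float = 30.0
    # transform / state space
    window_sd: float = 0.5
    n_lines: int = 256
    interval_len: int = 10
    n_knots: int = 8
    sct_iter: int = 2
    use_kernel: bool = True
    # EM
    alpha_prior: float = 3.0
    beta_prior: float = 1e-3
    em_eps: float = 1e-4
    em_max: int = 50
    # spectrum-aware filter
    rho_l: float = 0.0
    rho_h: float | None = None     # None -> 0.5 * peak denoised magnitude
    min_band_bins: int = 2
    # magnification
    alpha: float = 8.0
    levels: int | None = None
    # misc
    seed: int = 0

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


def _fit_model(ts: TimeSeries, cfg: RunConfig) -> "BESCT":
    window_sd = cfg.window_sd
    max_sd = (len(ts) - 1) / (8.0 * ts.fs)  # window truncated at +-4 sd
    if window_sd > max_sd:
        log.warning("window_sd=%g s does not fit a %d-sample record; "
                    "reduced to %.3g s", window_sd, len(ts), 0.95 * max_sd)
        window_sd = 0.95 * max_sd
    n_cols = int(np.ceil(len(ts) / cfg.interval_len))
    n_knots = max(2, min(cfg.n_knots, n_cols))
    if n_knots != cfg.n_knots:
        log.warning("n_knots reduced to %d for a %d-column record", n_knots,
                    n_cols)
    return BESCT(ts, window_sd=window_sd, n_lines=cfg.n_lines,
                 interval_len=cfg.interval_len, n_knots=n_knots,
                 sct_iter=cfg.sct_iter,
                 kernel="auto" if cfg.use_kernel else None,
                 alpha=cfg.alpha_prior, beta=cfg.beta_prior,
                 em_eps=cfg.em_eps, em_max=cfg.em_max)


def analyze_signal(cfg: RunConfig) -> dict:
    """Fit the spectrogram model to a signal file and write its artifacts.

    Writes the raw chirplet TFR (magnitude + phase CSV), the denoised TFR,
    the EM trace CSV, a rendered spectrogram PNG and the resolved config.
    Returns the artifact paths.
    """
    src = Path(cfg.input_path)
    if not src.exists():
        raise FileNotFoundError(f"input signal not found: {src}")
    ts = (TimeSeries.from_wav(src) if src.suffix.lower() == ".wav"
          else TimeSeries.from_csv(src))
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("analyzing %s: %d samples at %g Hz", src, len(ts), ts.fs)

    res = _fit_model(ts, cfg).fit()
    paths = {
        "sct_magnitude": out / "sct_magnitude.csv",
        "sct_phase": out / "sct_phase.csv",
        "besct_magnitude": out / "besct_magnitude.csv",
        "besct_phase": out / "besct_phase.csv",
        "em_trace": out / "em_trace.csv",
        "spectrogram": out / "spectrogram.png",
        "config": out / "run_config.json",
    }
    res.sct_tfr.to_csv(paths["sct_magnitude"], paths["sct_phase"])
    res.denoised_tfr.to_csv(paths["besct_magnitude"], paths["besct_phase"])
    res.em_trace.to_csv(paths["em_trace"])

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, axes = plt.subplots(1, 2, figsize=(12, 4))
    res.plot_spectrogram("sct", ax=axes[0])
    axes[0].set_title("chirplet transform")
    res.plot_spectrogram("denoised", ax=axes[1])
    axes[1].set_title("empirical-Bayes denoised")
    fig.tight_layout()
    fig.savefig(paths["spectrogram"], dpi=110)
    plt.close(fig)

    cfg.to_json(paths["config"])
    return {k: str(v) for k, v in paths.items()}


def magnify_video(cfg: RunConfig) -> dict:
    """Spectrum-aware magnification of a PNG frame directory.

    Extracts the global-motion series, fits the spectrogram model,
    thresholds the denoised surface into a passband schedule, magnifies,
    and writes: motion series CSV, motion-spectrum TFR CSV, schedule CSV,
    magnified frames and a run log.  Returns the artifact paths.
    """
    src = Path(cfg.input_path)
    if not src.is_dir():
        raise FileNotFoundError(f"frame directory not found: {src}")
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        video = VideoSequence.from_dir(src, fps=cfg.fps)
        log.info("loaded %d frames %sx%s at %g fps", video.n_frames,
                 *video.shape, video.fps)
        motion = emod_series(video)
        res = _fit_model(motion.to_timeseries(), cfg).fit()
        den = res.denoised_tfr
        rho_h = cfg.rho_h if cfg.rho_h is not None else auto_rho_h(den)
        log.info("rho_h = %g (peak magnitude %g)", rho_h,
                 float(np.abs(den.coeffs).max()))
        mask = build_weight(den, Thresholds(cfg.rho_l, rho_h))
        schedule = passbands_from_mask(mask, min_band_bins=cfg.min_band_bins)
        log.info("schedule union bands: %s", schedule.union_bands())
        result = magnify(video, schedule,
                         MagConfig(alpha=cfg.alpha, levels=cfg.levels))
        paths = {
            "emod_series": out / "emod_series.csv",
            "motion_magnitude": out / "motion_spectrum_magnitude.csv",
            "motion_phase": out / "motion_spectrum_phase.csv",
            "schedule": out / "schedule.csv",
            "frames": out / "frames",
            "config": out / "run_config.json",
            "log": out / "run.log",
        }
        motion.to_timeseries().to_csv(paths["emod_series"])
        den.to_csv(paths["motion_magnitude"], paths["motion_phase"])
        schedule.to_csv(paths["schedule"])
        result.to_dir(paths["frames"])
        cfg.to_json(paths["config"])
        log.info("wrote %d magnified frames to %s", result.n_frames,
                 paths["frames"])
        return {k: str(v) for k, v in paths.items()}
    finally:
        log.removeHandler(handler)
        handler.close()
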
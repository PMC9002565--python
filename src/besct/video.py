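"""Video container, lossless PNG frame-directory I/O, YIQ color conversion."""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.color import rgb2yiq, yiq2rgb

__all__ = ["VideoSequence", "color_convert", "luminance"]


@dataclass
class VideoSequence:
    """Frame stack (T, H, W, 3), intensities in [0, 1], with a frame rate."""

    frames: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, float)
        if self.frames.ndim == 3:  # grayscale -> replicate to RGB
            self.frames = np.repeat(self.frames[..., None], 3, axis=-1)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise ValueError("frames must have shape (T, H, W, 3)")
        if self.frames.shape[0] < 2:
            raise ValueError("need at least 2 frames")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames contain non-finite intensities")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:3]

    # ------------------------------------------------------------------ I/O
    def to_dir(self, path) -> None:
        """Write numbered 8-bit PNG frames (frame_000000.png, ...)."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        data = np.clip(np.round(self.frames * 255.0), 0, 255).astype(np.uint8)
        for t in range(self.n_frames):
            iio.imwrite(path / f"frame_{t:06d}.png", data[t])

    @classmethod
    def from_dir(cls, path, fps: float) -> "VideoSequence":
        path = Path(path)
        files = sorted(path.glob("*.png"))
        if not files:
            raise ValueError(f"no PNG frames found in {path}")
        frames = np.stack([iio.imread(f) for f in files]).astype(float) / 255.0
        if frames.ndim == 4 and frames.shape[-1] == 4:
            frames = frames[..., :3]
        return cls(frames=frames, fps=fps)

    @classmethod
    def from_file(cls, path, fps: float | None = None) -> "VideoSequence":
        """Read a common video container (lossy codecs accepted with a warning)."""
        path = Path(path)
        warnings.warn(f"{path.suffix} input may be lossy; PNG frame "
                      "directories are the lossless interchange format")
        frames = iio.imread(path)
        meta = iio.immeta(path)
        fps = fps or float(meta.get("fps", 0)) or None
        if fps is None:
            raise ValueError("frame rate not found in metadata; pass fps")
        return cls(frames=np.asarray(frames, float) / 255.0, fps=fps)


def color_convert(frames: np.ndarray, direction: str = "rgb2yiq") -> np.ndarray:
    """Standard YIQ transform of a (..., 3) stack and its inverse."""
    frames = np.asarray(frames, float)
    if direction == "rgb2yiq":
        return rgb2yiq(frames)
    if direction == "yiq2rgb":
        return yiq2rgb(frames)
    raise ValueError("direction must be 'rgb2yiq' or 'yiq2rgb'")


def luminance(frame: np.ndarray) -> np.ndarray:
    """Y (luminance) channel of an RGB frame; grayscale passes through."""
    frame = np.asarray(frame, float)
    if frame.ndim == 2:
        return frame
    return color_convert(frame, "rgb2yiq")[..., 0]
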
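"""Complex steerable pyramid (frequency-domain, octave bandwidth).

A self-inverting (tight-frame) multiscale, multi-orientation decomposition
built from raised-cosine radial masks and cos^(K-1) angular masks on the 2-D
DFT grid.  Orientation masks are single-sided (supported on one frequency
half-plane), so band coefficients are complex-valued analytic signals whose
phase encodes local translation — the representation used for phase-based
motion processing.

Bands are kept at full resolution (no downsampling), which makes the
round trip ``reconstruct(decompose(x)) == x`` exact to machine precision:
the squared masks, together with their mirrored copies and the high/low
residuals, sum to one everywhere on the frequency plane.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SteerablePyramid", "PyramidCoeffs"]


def _raised_cos_low(log_rad: np.ndarray) -> np.ndarray:
    """1 below a half-octave transition ending at log_rad = 0."""
    lr = np.clip(log_rad, -1.0, 0.0)
    return np.cos(np.pi / 2.0 * (lr + 1.0))


@dataclass
class PyramidCoeffs:
    """One frame's decomposition: residuals plus per-level/orientation bands."""

    highpass: np.ndarray       # real residual, r > pi/2 region
    lowpass: np.ndarray        # real residual below the last octave
    bands: list                # bands[level][orientation] -> complex array

    @property
    def n_levels(self) -> int:
        return len(self.bands)

    @property
    def n_orientations(self) -> int:
        return len(self.bands[0]) if self.bands else 0


class SteerablePyramid:
    """Reusable decompose/reconstruct operator for one frame shape.

    Parameters
    ----------
    shape : (H, W)
        Frame shape. Masks are precomputed for it.
    n_levels : int or None
        Octave bands; None picks ``floor(log2(min(H, W))) - 3`` (at least 3
        if the frame allows), keeping the coarsest band well resolved.
    n_orientations : int
        Angular bands covering pi (default 4).
    """

    def __init__(self, shape: tuple[int, int], n_levels: int | None = None,
                 n_orientations: int = 4):
        H, W = shape
        max_levels = int(np.floor(np.log2(min(H, W)))) - 2
        if max_levels < 1:
            raise ValueError(
                f"frame {H}x{W} too small for a pyramid: need min side >= 8")
        if n_levels is None:
            n_levels = min(max(max_levels - 1, 3), max_levels)
        if n_levels > max_levels:
            raise ValueError(
                f"{n_levels} levels need min side >= {2 ** (n_levels + 2)}, "
                f"got {min(H, W)}")
        self.shape = (H, W)
        self.n_levels = n_levels
        self.n_orientations = n_orientations
        self._build_masks()

    # ---------------------------------------------------------------- masks
    def _build_masks(self) -> None:
        H, W = self.shape
        K = self.n_orientations
        fy = np.fft.fftfreq(H)[:, None] * 2 * np.pi
        fx = np.fft.fftfreq(W)[None, :] * 2 * np.pi
        rad = np.hypot(fy, fx)
        rad[0, 0] = rad.flat[np.abs(rad).argmin() + 1]  # avoid log(0) at DC
        log_rad = np.log2(rad / np.pi)
        theta = np.arctan2(fy, fx)

        lo = _raised_cos_low(log_rad)
        self._hi0 = np.sqrt(np.clip(1.0 - lo**2, 0.0, 1.0))
        self._hi0[0, 0] = 0.0

        # single-sided angular masks, normalized so own + mirrored squares sum to 1
        ang = []
        norm = np.zeros_like(theta)
        for k in range(K):
            th_k = np.mod(theta - np.pi * k / K + np.pi, 2 * np.pi) - np.pi
            a = np.where(np.abs(th_k) < np.pi / 2,
                         np.cos(th_k) ** (K - 1), 0.0)
            ang.append(a)
            norm += a**2 + a[self._mirror_index]**2
        norm = np.sqrt(np.maximum(norm, 1e-30))
        ang = [a / norm for a in ang]

        self._bands = []
        for lev in range(self.n_levels):
            lo_out = _raised_cos_low(log_rad + lev)
            lo_in = _raised_cos_low(log_rad + lev + 1)
            radial = np.sqrt(np.clip(1.0 - lo_in**2, 0.0, 1.0)) * lo_out
            self._bands.append([radial * a for a in ang])
        self._lo = _raised_cos_low(log_rad + self.n_levels)
        self._lo[0, 0] = 1.0

    @property
    def _mirror_index(self):
        H, W = self.shape
        iy = (-np.arange(H)) % H
        ix = (-np.arange(W)) % W
        return np.ix_(iy, ix)

    def _conj_mirror(self, G: np.ndarray) -> np.ndarray:
        """conj(G(-u)): the negative-frequency copy of a half-plane band.

        Mirrors the trailing two (frequency) axes; leading axes (e.g. time)
        pass through.
        """
        iy, ix = self._mirror_index
        return np.conj(G[..., iy, ix])

    # ----------------------------------------------------------- transforms
    def decompose(self, frame: np.ndarray) -> PyramidCoeffs:
        if frame.shape != self.shape:
            raise ValueError(f"frame shape {frame.shape} != {self.shape}")
        F = np.fft.fft2(frame)
        bands = [[np.fft.ifft2(F * m) for m in level] for level in self._bands]
        high = np.fft.ifft2(F * self._hi0).real
        low = np.fft.ifft2(F * self._lo).real
        return PyramidCoeffs(highpass=high, lowpass=low, bands=bands)

    def reconstruct(self, coeffs: PyramidCoeffs) -> np.ndarray:
        F = (np.fft.fft2(coeffs.highpass) * self._hi0
             + np.fft.fft2(coeffs.lowpass) * self._lo)
        for level, masks in zip(coeffs.bands, self._bands):
            for band, m in zip(level, masks):
                G = np.fft.fft2(band) * m
                F += G + self._conj_mirror(G)
        return np.fft.ifft2(F).real
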
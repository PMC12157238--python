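"""Pixel-level fusion of the two feature channels by wavelet transform.

Both feature planes are decomposed with a 3-level 2-D discrete wavelet
transform.  Detail (high-frequency) coefficients are fused by keeping the
one of larger absolute value at each position, which preserves the sharper
edge response of either channel; the coarsest approximation (low-frequency)
planes are blended by a weighted average, C_f = alpha * C_a + beta * C_i
with alpha = beta = 0.5 by default.  The fused pyramid is inverted to give a
single feature image that combines the contrast of both channels.

An orthogonal Daubechies wavelet (db2) with symmetric boundary extension is
used, which gives perfect reconstruction on the round trip.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

from .color_spaces import FeatureChannel

__all__ = [
    "DEFAULT_WAVELET",
    "DEFAULT_LEVELS",
    "FusionWeights",
    "WaveletPyramid",
    "PyramidMismatchError",
    "decompose",
    "fuse",
    "reconstruct",
    "fuse_feature_images",
]

DEFAULT_WAVELET = "db2"
DEFAULT_LEVELS = 3


class PyramidMismatchError(ValueError):
    """Two pyramids cannot be fused (shape, level, or wavelet mismatch)."""


@dataclass(frozen=True)
class FusionWeights:
    """Convex weights for the approximation-plane average."""

    alpha: float = 0.5
    beta: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0 and 0.0 <= self.beta <= 1.0):
            raise ValueError("fusion weights must lie in [0, 1]")
        if abs(self.alpha + self.beta - 1.0) > 1e-9:
            raise ValueError("fusion weights must sum to 1")


@dataclass
class WaveletPyramid:
    """Coefficients of a multi-level 2-D wavelet decomposition.

    ``details`` is ordered coarsest-to-finest; each entry holds the
    (horizontal, vertical, diagonal) orientation planes of one level.
    """

    approximation: np.ndarray
    details: list[tuple[np.ndarray, np.ndarray, np.ndarray]]
    wavelet_name: str
    original_shape: tuple[int, int]

    @property
    def levels(self) -> int:
        return len(self.details)

    def compatible_with(self, other: "WaveletPyramid") -> bool:
        if self.wavelet_name != other.wavelet_name or self.levels != other.levels:
            return False
        if self.original_shape != other.original_shape:
            return False
        if self.approximation.shape != other.approximation.shape:
            return False
        return all(
            a.shape == b.shape
            for lev_a, lev_b in zip(self.details, other.details)
            for a, b in zip(lev_a, lev_b)
        )


def _as_plane(channel: FeatureChannel | np.ndarray) -> np.ndarray:
    if isinstance(channel, FeatureChannel):
        return channel.values
    plane = np.asarray(channel, dtype=float)
    if plane.ndim != 2:
        raise ValueError("expected a 2-D plane")
    return plane


def decompose(channel: FeatureChannel | np.ndarray, levels: int = DEFAULT_LEVELS,
              wavelet: str = DEFAULT_WAVELET) -> WaveletPyramid:
    """Multi-level 2-D wavelet decomposition of a feature plane.

    Raises
    ------
    ValueError
        If the image is too small for the requested number of levels (each
        side must be at least ``2**levels`` pixels).
    """
    plane = np.asarray(_as_plane(channel), dtype=float)
    if levels < 1:
        raise ValueError("levels must be >= 1")
    min_side = 2 ** levels
    if plane.shape[0] < min_side or plane.shape[1] < min_side:
        raise ValueError(
            f"image of shape {plane.shape} too small for {levels} decomposition "
            f"levels; each side must be at least {min_side} pixels"
        )
    coeffs = pywt.wavedec2(plane, wavelet=wavelet, level=levels, mode="symmetric")
    approximation = coeffs[0]
    details = [tuple(np.asarray(d) for d in level) for level in coeffs[1:]]
    return WaveletPyramid(
        approximation=np.asarray(approximation),
        details=details,  # type: ignore[arg-type]
        wavelet_name=wavelet,
        original_shape=plane.shape,
    )


def fuse(pyr_a: WaveletPyramid, pyr_i: WaveletPyramid,
         weights: FusionWeights = FusionWeights()) -> WaveletPyramid:
    """Fuse two pyramids coefficient-wise.

    Detail coefficients: take the input of larger absolute value, keeping its
    sign; ties go to the first (a-channel) pyramid.  Approximation plane:
    ``alpha * A_a + beta * A_i``.
    """
    if not pyr_a.compatible_with(pyr_i):
        raise PyramidMismatchError(
            "pyramids differ in wavelet, level count, or coefficient shapes"
        )
    fused_approx = weights.alpha * pyr_a.approximation + weights.beta * pyr_i.approximation
    fused_details = []
    for level_a, level_i in zip(pyr_a.details, pyr_i.details):
        fused_level = tuple(
            np.where(np.abs(ca) >= np.abs(ci), ca, ci) for ca, ci in zip(level_a, level_i)
        )
        fused_details.append(fused_level)
    return WaveletPyramid(
        approximation=fused_approx,
        details=fused_details,
        wavelet_name=pyr_a.wavelet_name,
        original_shape=pyr_a.original_shape,
    )


def reconstruct(pyr: WaveletPyramid) -> FeatureChannel:
    """Invert a pyramid back to a feature plane of the original shape."""
    if not isinstance(pyr.approximation, np.ndarray) or not pyr.details:
        raise ValueError("malformed pyramid: missing approximation or detail levels")
    for level in pyr.details:
        if len(level) != 3:
            raise ValueError("malformed pyramid: each level needs 3 orientation planes")
    coeffs = [pyr.approximation] + [tuple(level) for level in pyr.details]
    plane = pywt.waverec2(coeffs, wavelet=pyr.wavelet_name, mode="symmetric")
    # waverec2 can overshoot odd dimensions by one pixel; crop back.
    h, w = pyr.original_shape
    plane = plane[:h, :w]
    return FeatureChannel(values=plane, source="reconstructed")


def _minmax_scale(plane: np.ndarray) -> np.ndarray:
    """Continuous min–max rescale to [0, 255]; constant planes map to zeros."""
    lo, hi = float(plane.min()), float(plane.max())
    if hi <= lo:
        return np.zeros_like(plane, dtype=float)
    return (plane - lo) * (255.0 / (hi - lo))


def fuse_feature_images(chan_a: FeatureChannel | np.ndarray,
                        chan_i: FeatureChannel | np.ndarray,
                        weights: FusionWeights = FusionWeights(),
                        levels: int = DEFAULT_LEVELS,
                        wavelet: str = DEFAULT_WAVELET) -> FeatureChannel:
    """Full fusion pipeline: rescale, decompose, fuse, reconstruct.

    The a* and I planes live on different native scales, so both are min–max
    rescaled to a common [0, 255] range before decomposition; the weighted
    average then mixes commensurate magnitudes.
    """
    plane_a = _as_plane(chan_a)
    plane_i = _as_plane(chan_i)
    if plane_a.shape != plane_i.shape:
        raise PyramidMismatchError(
            f"feature channels have different shapes: {plane_a.shape} vs {plane_i.shape}"
        )
    scaled_a = _minmax_scale(plane_a)
    scaled_i = _minmax_scale(plane_i)
    pyr_a = decompose(scaled_a, levels=levels, wavelet=wavelet)
    pyr_i = decompose(scaled_i, levels=levels, wavelet=wavelet)
    fused = reconstruct(fuse(pyr_a, pyr_i, weights))
    return FeatureChannel(values=fused.values, source="fused")
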
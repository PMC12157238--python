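"""Color-space conversions and feature-channel extraction.

Red, ripe wolfberry fruit separates from green foliage most cleanly on two
chroma axes: the a* axis of an Lab-style representation (green <-> red) and
the I axis of the NTSC YIQ representation (cyan <-> orange).  This module
converts 8-bit RGB rasters into those representations and extracts the two
feature planes that the downstream fusion and segmentation stages consume.

The Lab conversion used here is deliberately non-standard: RGB is first
chromaticity-normalized (each channel divided by the channel sum), mapped to
XYZ by a fixed 3x3 matrix, and the cube-root compression f(t) is applied to
X, Y, Z directly with no reference-white division.  Because the intensity is
divided out up front, the resulting planes depend on hue alone, which is the
property that makes the a* channel robust to illumination gradients.  The
textbook CIE Lab (D65) conversion is available separately as
:func:`rgb_to_lab_d65` for comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "RGB_TO_XYZ_MATRIX",
    "RGB_TO_YIQ_MATRIX",
    "FeatureChannel",
    "normalize_rgb",
    "rgb_to_xyz",
    "xyz_to_lab",
    "rgb_to_lab",
    "rgb_to_yiq",
    "rgb_to_lab_d65",
    "extract_feature_channel",
    "rescale_to_8bit",
]

#: Matrix mapping chromaticity-normalized (r, g, b) to (X, Y, Z).
RGB_TO_XYZ_MATRIX = np.array(
    [
        [0.433953, 0.376219, 0.289828],
        [0.212671, 0.715160, 0.072169],
        [0.017758, 0.109477, 0.872765],
    ]
)

#: Matrix mapping raw 8-bit (R, G, B) to (Y, I, Q).
RGB_TO_YIQ_MATRIX = np.array(
    [
        [0.2990, 0.5870, 0.1140],
        [0.5957, -0.2745, -0.3213],
        [0.2115, -0.5226, 0.3111],
    ]
)

#: Threshold of the piecewise cube-root compression.
_LAB_T0 = 0.008856
_LAB_SLOPE = 7.787
_LAB_OFFSET = 16.0 / 116.0


def _validate_rgb(rgb: np.ndarray) -> np.ndarray:
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 RGB raster, got shape {rgb.shape}")
    if rgb.shape[0] < 1 or rgb.shape[1] < 1:
        raise ValueError("image must have at least one pixel")
    if np.issubdtype(rgb.dtype, np.floating):
        if rgb.min() < 0 or rgb.max() > 255:
            raise ValueError("RGB values must lie in [0, 255]")
    return rgb


@dataclass
class FeatureChannel:
    """A single-channel real-valued feature image.

    ``display_range`` records the (min, max) used when the plane is rescaled
    to an 8-bit view for histogramming and PNG export, so the mapping is
    reproducible.
    """

    values: np.ndarray
    source: str
    display_range: tuple[float, float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature channel must be a 2-D plane")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature channel contains non-finite values")
        if self.display_range is None:
            self.display_range = (float(self.values.min()), float(self.values.max()))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    def as_8bit(self) -> np.ndarray:
        """8-bit view of the plane using the recorded display range."""
        return rescale_to_8bit(self.values, self.display_range)


def rescale_to_8bit(values: np.ndarray, display_range: tuple[float, float] | None = None) -> np.ndarray:
    """Linearly rescale a real-valued plane to uint8 [0, 255].

    A constant plane maps to zeros (the range is degenerate, so any affine
    choice is arbitrary; zero keeps the histogram well defined).
    """
    values = np.asarray(values, dtype=float)
    lo, hi = display_range if display_range is not None else (values.min(), values.max())
    if hi <= lo:
        return np.zeros(values.shape, dtype=np.uint8)
    scaled = (values - lo) * (255.0 / (hi - lo))
    return np.clip(np.rint(scaled), 0, 255).astype(np.uint8)


def normalize_rgb(rgb: np.ndarray) -> np.ndarray:
    """Per-pixel chromaticity normalization r = R/(R+G+B), etc.

    Black pixels (R+G+B == 0) map to (0, 0, 0) by convention, so the map is
    total and never produces NaN.
    """
    rgb = _validate_rgb(rgb).astype(float)
    total = rgb.sum(axis=2, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        chroma = np.where(total > 0, rgb / np.where(total > 0, total, 1.0), 0.0)
    return chroma


def rgb_to_xyz(rgb: np.ndarray) -> np.ndarray:
    """Map an RGB raster to the XYZ planes via the fixed linear transform.

    The matrix is applied to the chromaticity triple, not to raw 8-bit
    values, so the result is intensity-free and bounded by the matrix row
    sums (all <= 1.1).
    """
    chroma = normalize_rgb(rgb)
    return chroma @ RGB_TO_XYZ_MATRIX.T


def _lab_f(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    out = np.where(t > _LAB_T0, np.cbrt(np.maximum(t, 0.0)), _LAB_SLOPE * t + _LAB_OFFSET)
    return out


def xyz_to_lab(xyz: np.ndarray) -> np.ndarray:
    """Compute (L*, a*, b*) planes from XYZ.

    L* = 116 f(Y) - 16, a* = 500 (f(X) - f(Y)), b* = 200 (f(Y) - f(Z)) with
    the piecewise f(t) = t^(1/3) above 0.008856 and 7.787 t + 16/116 below.
    f is applied to X, Y, Z directly — there is no reference-white division
    in this variant (see module docstring).
    """
    xyz = np.asarray(xyz, dtype=float)
    if xyz.ndim != 3 or xyz.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 XYZ raster, got shape {xyz.shape}")
    fx = _lab_f(xyz[..., 0])
    fy = _lab_f(xyz[..., 1])
    fz = _lab_f(xyz[..., 2])
    lab = np.empty_like(xyz)
    lab[..., 0] = 116.0 * fy - 16.0
    lab[..., 1] = 500.0 * (fx - fy)
    lab[..., 2] = 200.0 * (fy - fz)
    return lab


def rgb_to_lab(rgb: np.ndarray) -> np.ndarray:
    """Convenience composition ``xyz_to_lab(rgb_to_xyz(rgb))``."""
    return xyz_to_lab(rgb_to_xyz(rgb))


def rgb_to_lab_d65(rgb: np.ndarray) -> np.ndarray:
    """Standard CIE Lab (sRGB, D65 white point), for comparison only.

    This is *not* the conversion the segmentation pipelines use; it exists so
    the intensity-free variant above can be contrasted against the textbook
    one in experiments and tests.
    """
    from skimage.color import rgb2lab

    rgb = _validate_rgb(rgb)
    return rgb2lab(np.asarray(rgb, dtype=np.uint8))


def rgb_to_yiq(rgb: np.ndarray) -> np.ndarray:
    """Map raw 8-bit (R, G, B) to (Y, I, Q) planes.

    The NTSC coefficients are applied to the unnormalized 0–255 values, so Y
    lands in [0, 255] and I/Q on commensurate signed scales.
    """
    rgb = _validate_rgb(rgb).astype(float)
    return rgb @ RGB_TO_YIQ_MATRIX.T


def extract_feature_channel(rgb: np.ndarray, which: str) -> FeatureChannel:
    """Extract the a* or I feature plane from an RGB raster.

    Parameters
    ----------
    rgb:
        HxWx3 8-bit raster.
    which:
        ``"a_channel"`` for the Lab-variant a* plane, ``"i_channel"`` for
        the YIQ I plane.
    """
    if which == "a_channel":
        plane = rgb_to_lab(rgb)[..., 1]
    elif which == "i_channel":
        plane = rgb_to_yiq(rgb)[..., 1]
    else:
        raise ValueError(f"unknown feature channel {which!r}; expected 'a_channel' or 'i_channel'")
    return FeatureChannel(values=plane, source=which)
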